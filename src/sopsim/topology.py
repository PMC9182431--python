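"""SOP Go-topology construction: FENE bonds and classified native contacts.

The SOP model partitions every bead pair of the native structure into three
disjoint groups: consecutive intra-chain pairs become FENE backbone bonds;
pairs within the native-contact cutoff (with intra-chain sequence separation
|i−j| ≥ 3) become attractive native contacts with an interface-class-specific
well depth ϵh; everything else is subject to generic repulsion. The
interface classes and their default contact strengths (kcal/mol) for
lattice–machine assemblies are:

=================  =====
intra_monomer       1.9
intra_dimer         1.9
longitudinal        1.0
lateral             0.9
seam                0.9
intra_protomer      1.3
inter_protomer      1.3
mt_protomer         1.0
mit_mt              1.0 (the machine-anchoring sweep variable)
protomer_e15        1.0 (pore-loop grip on the pulled tail)
substrate           1.3 (internal contacts of a globular substrate)
=================  =====
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .structures import BeadModel, MAX_BOND_LENGTH

__all__ = [
    "InteractionTable",
    "SOPTopology",
    "classify_interface",
    "build_native_contacts",
    "set_mit_interaction",
    "repulsive_pairs",
]

DEFAULT_EPS_H = {
    "intra_monomer": 1.9,
    "intra_dimer": 1.9,
    "longitudinal": 1.0,
    "lateral": 0.9,
    "seam": 0.9,
    "intra_protomer": 1.3,
    "inter_protomer": 1.3,
    "mt_protomer": 1.0,
    "mit_mt": 1.0,
    "protomer_e15": 1.0,
    "substrate": 1.3,
}


@dataclass
class InteractionTable:
    """Per-interface contact strengths and non-bonded parameters.

    ``eps_mit_mt`` is the machine–lattice anchoring strength swept over
    1.0–4.0 kcal/mol in the free-MIT experiments; it overrides the
    ``mit_mt`` entry of ``eps_h_by_class``. ``contact_cutoff`` is the
    native-contact distance cutoff (13 Å for Cα lattice systems; globular
    substrates use a 6 Å Cα surrogate, see the experiment presets).
    """

    eps_h_by_class: dict = field(default_factory=lambda: dict(DEFAULT_EPS_H))
    eps_mit_mt: float = 1.0
    eps_l: float = 1.0
    sigma: float = 3.8
    contact_cutoff: float = 13.0

    def __post_init__(self) -> None:
        merged = dict(DEFAULT_EPS_H)
        merged.update(self.eps_h_by_class)
        merged["mit_mt"] = self.eps_mit_mt
        self.eps_h_by_class = merged
        if any(v <= 0 for v in self.eps_h_by_class.values()):
            raise ValueError("all contact strengths must be positive")
        if self.eps_l <= 0 or self.sigma <= 0:
            raise ValueError("eps_l and sigma must be positive")
        if self.contact_cutoff <= self.sigma:
            raise ValueError("contact_cutoff must exceed sigma")

    def eps_for(self, interface_class: str) -> float:
        return self.eps_h_by_class[interface_class]


@dataclass
class SOPTopology:
    """FENE bond list plus classified native-contact list.

    ``chain_index`` maps each bead to an integer chain label; it determines
    the |i−j| ≥ 3 intra-chain exclusion and the repulsive complement.
    Cross-links (e.g. the covalent tail fusion between the pulled handle and
    a substrate peptide) are FENE bonds between non-consecutive beads and
    are included in ``bond_i``/``bond_j``.
    """

    n_beads: int
    bond_i: np.ndarray
    bond_j: np.ndarray
    bond_r0: np.ndarray
    contact_i: np.ndarray
    contact_j: np.ndarray
    contact_r0: np.ndarray
    contact_eps: np.ndarray
    contact_class: np.ndarray
    chain_index: np.ndarray
    fene_k: float = 20.0
    fene_R0: float = 2.0

    def __post_init__(self) -> None:
        for name in ("bond_i", "bond_j", "contact_i", "contact_j", "chain_index"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=np.intp))
        for name in ("bond_r0", "contact_r0", "contact_eps"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        self.contact_class = np.asarray(self.contact_class, dtype=object)
        if np.any(self.bond_i >= self.bond_j) or np.any(self.contact_i >= self.contact_j):
            raise ValueError("pairs must be stored with i < j")

    @property
    def n_contacts(self) -> int:
        return len(self.contact_i)

    def contact_pair_set(self) -> set[tuple[int, int]]:
        return set(zip(self.contact_i.tolist(), self.contact_j.tolist()))

    def bond_pair_set(self) -> set[tuple[int, int]]:
        return set(zip(self.bond_i.tolist(), self.bond_j.tolist()))

    def contact_mask(self, classes: str | list[str]) -> np.ndarray:
        wanted = [classes] if isinstance(classes, str) else list(classes)
        return np.isin(self.contact_class.astype(str), wanted)

    def save(self, prefix: str | Path) -> None:
        """Serialize as ``<prefix>.contacts.tsv``, ``.bonds.tsv``, ``.meta.json``."""
        prefix = Path(prefix)
        pd.DataFrame(
            {
                "i": self.contact_i,
                "j": self.contact_j,
                "r0": self.contact_r0,
                "eps_h": self.contact_eps,
                "class": self.contact_class.astype(str),
            }
        ).to_csv(prefix.with_suffix(".contacts.tsv"), sep="\t", index=False)
        pd.DataFrame(
            {"i": self.bond_i, "j": self.bond_j, "r0": self.bond_r0}
        ).to_csv(prefix.with_suffix(".bonds.tsv"), sep="\t", index=False)
        meta = {
            "n_beads": int(self.n_beads),
            "fene_k": self.fene_k,
            "fene_R0": self.fene_R0,
            "chain_index": self.chain_index.tolist(),
        }
        prefix.with_suffix(".meta.json").write_text(json.dumps(meta))

    @classmethod
    def load(cls, prefix: str | Path) -> "SOPTopology":
        prefix = Path(prefix)
        contacts = pd.read_csv(prefix.with_suffix(".contacts.tsv"), sep="\t")
        bonds = pd.read_csv(prefix.with_suffix(".bonds.tsv"), sep="\t")
        meta = json.loads(prefix.with_suffix(".meta.json").read_text())
        return cls(
            n_beads=meta["n_beads"],
            bond_i=bonds["i"].to_numpy(),
            bond_j=bonds["j"].to_numpy(),
            bond_r0=bonds["r0"].to_numpy(),
            contact_i=contacts["i"].to_numpy(),
            contact_j=contacts["j"].to_numpy(),
            contact_r0=contacts["r0"].to_numpy(),
            contact_eps=contacts["eps_h"].to_numpy(),
            contact_class=contacts["class"].to_numpy(dtype=object),
            chain_index=np.array(meta["chain_index"]),
            fene_k=meta["fene_k"],
            fene_R0=meta["fene_R0"],
        )


# ---------------------------------------------------------------------------
# Interface classification
# ---------------------------------------------------------------------------

_LATTICE_RE = re.compile(r"pf(\d+)\.d(\d+)\.([ab])")
_MACHINE_TAGS = {"NBD", "pore_loop", "linker", "MIT"}
_SUBSTRATE_TAGS = {"substrate_core", "substrate_tail"}


def _bead_kind(subunit: str, tag: str) -> str:
    if tag in _MACHINE_TAGS:
        return "machine"
    if tag in _SUBSTRATE_TAGS:
        return "substrate"
    if subunit.startswith("pf") or tag == "HBD_tail":
        return "lattice"
    if subunit.startswith("prot") or (len(subunit) == 1 and subunit in "ABCDEF"):
        return "machine"
    return "lattice"


def classify_interface(i: int, j: int, model: BeadModel) -> str:
    """Deterministic interface class of a bead pair, from annotations alone.

    Symmetric in (i, j). Lattice subunit labels must follow the
    ``pf{p}.d{d}.{a|b}`` convention (as produced by the lattice generator or
    supplied through a ``chain_map``) for the lattice interface split.
    """
    si, sj = str(model.subunit_id[i]), str(model.subunit_id[j])
    ti, tj = str(model.domain_tag[i]), str(model.domain_tag[j])
    if si == "none" or sj == "none":
        raise ValueError(f"bead {i if si == 'none' else j} has no subunit annotation")
    ki, kj = _bead_kind(si, ti), _bead_kind(sj, tj)

    if ki == kj == "lattice":
        if si == sj:
            return "intra_monomer"
        mi, mj = _LATTICE_RE.fullmatch(si), _LATTICE_RE.fullmatch(sj)
        if mi is None or mj is None:
            raise ValueError(
                f"cannot classify lattice pair {si!r}-{sj!r}: labels must follow "
                "'pf{p}.d{d}.{a|b}'"
            )
        pi, di, moni = int(mi[1]), int(mi[2]), mi[3]
        pj, dj, monj = int(mj[1]), int(mj[2]), mj[3]
        if pi == pj:
            if di == dj:
                return "intra_dimer"  # α-β within one dimer
            return "longitudinal"
        seam = model.meta.get("seam_pair")
        if seam is not None and {pi, pj} == set(seam):
            return "seam"
        return "lateral"

    if ki == kj == "machine":
        return "intra_protomer" if si == sj else "inter_protomer"

    if ki == kj == "substrate":
        return "substrate"

    # mixed kinds
    kinds = {ki, kj}
    tags = {ti, tj}
    if "machine" in kinds:
        if "MIT" in tags:
            return "mit_mt"
        if "pore_loop" in tags and ({"HBD_tail", "substrate_tail"} & tags):
            return "protomer_e15"
        return "mt_protomer"
    return "mt_protomer"


# ---------------------------------------------------------------------------
# Topology construction
# ---------------------------------------------------------------------------


def _chain_index(model: BeadModel) -> np.ndarray:
    idx = np.empty(model.n_beads, dtype=np.intp)
    for c, (start, stop) in enumerate(model.chain_slices()):
        idx[start:stop] = c
    return idx


def build_native_contacts(
    model: BeadModel,
    table: InteractionTable,
    cross_links: list[tuple[int, int]] | None = None,
) -> SOPTopology:
    """Build the SOP topology from a model in its native configuration.

    Native contacts are all pairs within ``table.contact_cutoff`` that are
    either inter-chain or intra-chain with |i−j| ≥ 3; each stores its native
    distance and the ϵh of its interface class. Bonds are all consecutive
    intra-chain pairs plus declared ``cross_links`` (e.g. the covalent
    fusion of a pulled-handle peptide to a tail bead), at their native
    lengths.
    """
    coords = model.coords
    chain_idx = _chain_index(model)

    bi, bj, br0 = [], [], []
    for start, stop in model.chain_slices():
        for k in range(start, stop - 1):
            bi.append(k)
            bj.append(k + 1)
            br0.append(float(np.linalg.norm(coords[k + 1] - coords[k])))
    for a, b in cross_links or []:
        a, b = (a, b) if a < b else (b, a)
        bi.append(a)
        bj.append(b)
        br0.append(float(np.linalg.norm(coords[b] - coords[a])))
    for a, b, r0 in zip(bi, bj, br0):
        if r0 >= MAX_BOND_LENGTH:
            raise ValueError(
                f"bond {a}-{b} has native length {r0:.2f} Å >= {MAX_BOND_LENGTH} Å; "
                "FENE is undefined at this extension"
            )
    bond_set = set(zip(bi, bj))

    tree = cKDTree(coords)
    pairs = tree.query_pairs(table.contact_cutoff, output_type="ndarray")
    ci, cj, cr0, ceps, ccls = [], [], [], [], []
    for a, b in pairs:
        a, b = int(min(a, b)), int(max(a, b))
        if (a, b) in bond_set:
            continue
        if chain_idx[a] == chain_idx[b] and b - a < 3:
            continue
        cls = classify_interface(a, b, model)
        ci.append(a)
        cj.append(b)
        cr0.append(float(np.linalg.norm(coords[b] - coords[a])))
        ceps.append(table.eps_for(cls))
        ccls.append(cls)

    order = np.lexsort((cj, ci)) if ci else np.array([], dtype=np.intp)
    return SOPTopology(
        n_beads=model.n_beads,
        bond_i=np.array(bi, dtype=np.intp),
        bond_j=np.array(bj, dtype=np.intp),
        bond_r0=np.array(br0),
        contact_i=np.array(ci, dtype=np.intp)[order],
        contact_j=np.array(cj, dtype=np.intp)[order],
        contact_r0=np.array(cr0)[order],
        contact_eps=np.array(ceps)[order],
        contact_class=np.array(ccls, dtype=object)[order] if ci else np.array([], dtype=object),
        chain_index=chain_idx,
    )


def set_mit_interaction(topology: SOPTopology, eps: float) -> SOPTopology:
    """Return a topology with every MIT–lattice contact set to strength ``eps``."""
    if eps <= 0:
        raise ValueError("eps must be positive")
    new_eps = topology.contact_eps.copy()
    new_eps[topology.contact_mask("mit_mt")] = eps
    return replace(topology, contact_eps=new_eps)


def repulsive_pairs(topology: SOPTopology) -> tuple[np.ndarray, np.ndarray]:
    """Enumerate the repulsive complement: (i,i+2) pairs, and all other pairs.

    Returns ``(pairs_i2, pairs_far)`` where ``pairs_i2`` are the intra-chain
    (i, i+2) pairs (always repulsive) and ``pairs_far`` are every pair that
    is neither a bond, nor a native contact, nor intra-chain with |i−j| < 3.
    Quadratic in bead count; intended for small systems and oracle tests —
    the energy module uses it below its exact-evaluation size threshold.
    """
    n = topology.n_beads
    chain = topology.chain_index
    if len(chain) != n:
        raise ValueError("topology lacks a chain_index of length n_beads")
    exclude = topology.bond_pair_set() | topology.contact_pair_set()

    i2 = [
        (i, i + 2)
        for i in range(n - 2)
        if chain[i] == chain[i + 2] and (i, i + 2) not in exclude
    ]
    far = []
    for i in range(n):
        for j in range(i + 1, n):
            if chain[i] == chain[j] and j - i < 3:
                continue
            if (i, j) in exclude:
                continue
            far.append((i, j))
    # (i,i+2) intra-chain pairs are handled by the dedicated term
    i2_set = set(i2)
    far = [p for p in far if p not in i2_set]
    to_arr = lambda lst: (
        np.array(lst, dtype=np.intp).reshape(-1, 2) if lst else np.empty((0, 2), dtype=np.intp)
    )
    return to_arr(i2), to_arr(far)
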