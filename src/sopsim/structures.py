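"""Cα bead structures: PDB input and synthetic desk-scale assemblies.

The package works at one-bead-per-residue (Cα) resolution. A
:class:`BeadModel` carries, for each bead, its coordinates plus the
annotations that drive topology construction and analysis: the chain it
belongs to, a *subunit* label (protofilament/dimer/monomer for lattices,
protomer letter for the hexameric machine), a coarse *domain tag*, and a
fixed flag used by the integrator.

Besides reading real Cα structures from PDB files, this module generates
three synthetic systems that emulate the assemblies studied with the model
at desk scale:

* a multi-protofilament lattice of two-monomer (α/β) subunits with
  intra-dimer, longitudinal, lateral and (optionally) seam interfaces, where
  each β monomer carries a C-terminal tail bead (the pulled handle);
* a hexameric ring machine with pore-loop beads facing the central channel
  and, optionally, six flexible-linker arms ending in three-bead MIT-like
  anchor clusters;
* a small β-sheet-like globule with a terminal pulling tail whose anchor
  strand can sit at the sheet edge (soft, unzipping-like interface) or in
  the core (strong, shearing-like interface).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

__all__ = [
    "DOMAIN_TAGS",
    "BeadModel",
    "read_calpha_pdb",
    "write_model",
    "read_model",
    "make_toy_lattice",
    "make_toy_hexamer",
    "make_toy_globule",
]

DOMAIN_TAGS = frozenset(
    {
        "NBD",
        "HBD_tail",
        "pore_loop",
        "linker",
        "MIT",
        "substrate_core",
        "substrate_tail",
        "none",
    }
)

#: Cα–Cα virtual bond length, Å.
CA_SPACING = 3.8
#: Minimum allowed inter-bead distance in generated systems, Å.
MIN_SEPARATION = 1.0
#: Upper bound on a bonded (consecutive intra-chain) distance: r0 + R0.
MAX_BOND_LENGTH = CA_SPACING + 2.0


@dataclass
class BeadModel:
    """Annotated Cα bead structure.

    Beads are ordered by chain and, within a chain, by residue number.
    ``meta`` holds assembly-level annotations that individual beads cannot
    carry (e.g. the declared seam protofilament pair of a lattice).
    """

    coords: np.ndarray
    chain_id: np.ndarray
    resid: np.ndarray
    subunit_id: np.ndarray
    domain_tag: np.ndarray
    fixed: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        n = self.coords.shape[0]
        self.chain_id = np.asarray(self.chain_id, dtype=object)
        self.resid = np.asarray(self.resid, dtype=int)
        self.subunit_id = np.asarray(self.subunit_id, dtype=object)
        self.domain_tag = np.asarray(self.domain_tag, dtype=object)
        self.fixed = np.asarray(self.fixed, dtype=bool)
        for name in ("chain_id", "resid", "subunit_id", "domain_tag", "fixed"):
            arr = getattr(self, name)
            if arr.shape != (n,):
                raise ValueError(f"{name} has shape {arr.shape}, expected ({n},)")
        self.validate()

    @property
    def n_beads(self) -> int:
        return self.coords.shape[0]

    def validate(self) -> None:
        if self.n_beads == 0:
            raise ValueError("BeadModel must contain at least one bead")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates in BeadModel")
        bad = set(self.domain_tag) - DOMAIN_TAGS
        if bad:
            raise ValueError(f"unknown domain tags: {sorted(bad)}")
        for start, stop in self.chain_slices():
            seg = self.coords[start:stop]
            if len(seg) > 1:
                d = np.linalg.norm(np.diff(seg, axis=0), axis=1)
                if np.any(d >= MAX_BOND_LENGTH):
                    k = int(np.argmax(d >= MAX_BOND_LENGTH))
                    raise ValueError(
                        f"consecutive beads {start + k}-{start + k + 1} of chain "
                        f"{self.chain_id[start]} are {d[k]:.2f} Å apart "
                        f"(>= {MAX_BOND_LENGTH} Å)"
                    )

    def chain_slices(self) -> list[tuple[int, int]]:
        """Contiguous (start, stop) index runs, one per chain, in bead order."""
        out = []
        start = 0
        for i in range(1, self.n_beads):
            if self.chain_id[i] != self.chain_id[i - 1]:
                out.append((start, i))
                start = i
        out.append((start, self.n_beads))
        return out

    def select(
        self,
        domain_tag: str | None = None,
        chain: str | list[str] | None = None,
        subunit: str | None = None,
    ) -> np.ndarray:
        """Indices of beads matching all given criteria."""
        mask = np.ones(self.n_beads, dtype=bool)
        if domain_tag is not None:
            mask &= self.domain_tag == domain_tag
        if chain is not None:
            chains = [chain] if isinstance(chain, str) else list(chain)
            mask &= np.isin(self.chain_id.astype(str), chains)
        if subunit is not None:
            mask &= self.subunit_id == subunit
        return np.flatnonzero(mask)

    def with_fixed(self, indices: np.ndarray) -> "BeadModel":
        """Copy of the model with exactly ``indices`` flagged fixed."""
        fixed = np.zeros(self.n_beads, dtype=bool)
        fixed[np.asarray(indices, dtype=int)] = True
        return BeadModel(
            self.coords.copy(),
            self.chain_id.copy(),
            self.resid.copy(),
            self.subunit_id.copy(),
            self.domain_tag.copy(),
            fixed,
            dict(self.meta),
        )


def _check_overlap(coords: np.ndarray) -> None:
    tree = cKDTree(coords)
    pairs = tree.query_pairs(MIN_SEPARATION)
    if pairs:
        i, j = sorted(pairs)[0]
        d = float(np.linalg.norm(coords[i] - coords[j]))
        raise ValueError(f"geometric overlap: beads {i} and {j} are {d:.2f} Å apart")


# ---------------------------------------------------------------------------
# PDB input/output
# ---------------------------------------------------------------------------


def read_calpha_pdb(path: str | Path, chain_map: dict[str, str] | None = None) -> BeadModel:
    """Extract one bead per residue (the Cα atom) from a PDB file.

    Altloc records are resolved to the highest-occupancy alternative.
    ``chain_map`` maps PDB chain IDs to subunit labels; unmapped chains get
    subunit ``"none"``. A residue that has atoms but no Cα is an error.
    """
    import biotite.structure as struc
    import biotite.structure.io.pdb as pdb

    pdb_file = pdb.PDBFile.read(str(path))
    atoms = pdb_file.get_structure(model=1, altloc="occupancy")
    amino = atoms[struc.filter_amino_acids(atoms)]
    if len(amino) == 0:
        amino = atoms  # synthetic CG files may use non-standard residue names
    ca = amino[amino.atom_name == "CA"]
    if len(ca) == 0:
        raise ValueError(f"no CA atoms found in {path}")

    # every residue that has atoms must have a CA
    res_keys = {(c, int(r)) for c, r in zip(amino.chain_id, amino.res_id)}
    ca_keys = {(c, int(r)) for c, r in zip(ca.chain_id, ca.res_id)}
    missing = res_keys - ca_keys
    if missing:
        c, r = sorted(missing)[0]
        raise ValueError(f"residue {r} of chain {c} has no CA atom")

    if chain_map is not None:
        present = set(np.unique(ca.chain_id).astype(str))
        unknown = set(chain_map) - present
        if unknown:
            raise ValueError(f"chain_map references unknown chains: {sorted(unknown)}")

    order = np.lexsort((ca.res_id, ca.chain_id))
    ca = ca[order]
    chains = ca.chain_id.astype(str)
    subunits = np.array(
        [chain_map.get(c, "none") if chain_map else "none" for c in chains], dtype=object
    )
    return BeadModel(
        coords=ca.coord.astype(float),
        chain_id=chains.astype(object),
        resid=ca.res_id.astype(int),
        subunit_id=subunits,
        domain_tag=np.full(len(ca), "none", dtype=object),
        fixed=np.zeros(len(ca), dtype=bool),
    )


def write_model(model: BeadModel, path: str | Path) -> None:
    """Write a model as PDB plus a ``<path>.beads.tsv`` annotation sidecar.

    Standard PDB columns cannot carry subunit/domain/fixed annotations (and
    hold only one chain character), so the PDB stores coordinates with
    surrogate one-character chain IDs while the sidecar keeps the full
    per-bead annotation table; :func:`read_model` restores both.
    """
    import biotite.structure as struc
    import biotite.structure.io.pdb as pdb

    path = Path(path)
    n = model.n_beads
    arr = struc.AtomArray(n)
    arr.coord = model.coords
    # surrogate single-character chain IDs, one per distinct chain
    alphabet = "ABCDEFGHIJKLMNOPQRSTUVWXYZabcdefghijklmnopqrstuvwxyz0123456789"
    uniq = list(dict.fromkeys(model.chain_id))
    surrogate = {c: alphabet[i % len(alphabet)] for i, c in enumerate(uniq)}
    arr.chain_id = np.array([surrogate[c] for c in model.chain_id])
    arr.res_id = model.resid
    arr.res_name = np.full(n, "GLY")
    arr.atom_name = np.full(n, "CA")
    arr.element = np.full(n, "C")
    f = pdb.PDBFile()
    f.set_structure(arr)
    f.write(str(path))

    side = pd.DataFrame(
        {
            "bead_index": np.arange(n),
            "chain": model.chain_id.astype(str),
            "resid": model.resid,
            "subunit_id": model.subunit_id.astype(str),
            "domain_tag": model.domain_tag.astype(str),
            "fixed": model.fixed.astype(int),
        }
    )
    side.to_csv(path.with_suffix(path.suffix + ".beads.tsv"), sep="\t", index=False)


def read_model(path: str | Path, meta: dict | None = None) -> BeadModel:
    """Read a model written by :func:`write_model` (PDB + sidecar)."""
    import biotite.structure.io.pdb as pdb

    path = Path(path)
    atoms = pdb.PDBFile.read(str(path)).get_structure(model=1)
    side = pd.read_csv(path.with_suffix(path.suffix + ".beads.tsv"), sep="\t")
    if len(side) != atoms.array_length():
        raise ValueError("sidecar row count does not match PDB atom count")
    return BeadModel(
        coords=atoms.coord.astype(float),
        chain_id=side["chain"].astype(str).to_numpy(dtype=object),
        resid=side["resid"].to_numpy(dtype=int),
        subunit_id=side["subunit_id"].astype(str).to_numpy(dtype=object),
        domain_tag=side["domain_tag"].astype(str).to_numpy(dtype=object),
        fixed=side["fixed"].to_numpy(dtype=bool),
        meta=dict(meta or {}),
    )


# ---------------------------------------------------------------------------
# Synthetic generators
# ---------------------------------------------------------------------------

#: Gap between facing beads of longitudinally adjacent monomers, Å.
LONG_GAP = 4.5
#: Spacing between adjacent protofilament rows, Å.
LAT_SPACING = 9.0
#: Coordinate jitter amplitude applied to lattice core beads, Å.
JITTER = 0.1


def make_toy_lattice(
    n_pf: int,
    n_dimers: int,
    beads_per_monomer: int,
    radius: float | None = None,
    seam: bool = False,
    seed: int = 0,
) -> BeadModel:
    """Generate a protofilament lattice of α/β dimers.

    Each monomer is a straight run of ``beads_per_monomer`` beads (its own
    chain) along the filament axis; dimers stack longitudinally, rows of
    dimers pack laterally — on a cylinder of the given radius when
    ``n_pf >= 5``, in a plane otherwise. Every β monomer carries one extra
    outward-facing tail bead tagged ``HBD_tail`` (the pulled handle).
    Monomer subunit labels encode ``pf{p}.d{d}.{a|b}``. Lateral spacing is
    comparable to the longitudinal gap so interface strength is dominated by
    the per-class contact energies rather than by geometry. Deterministic
    for a fixed seed.
    """
    if n_pf < 1 or n_dimers < 1 or beads_per_monomer < 2:
        raise ValueError("need n_pf >= 1, n_dimers >= 1, beads_per_monomer >= 2")
    rng = np.random.default_rng(seed)
    planar = n_pf < 5
    if radius is None:
        radius = n_pf * LAT_SPACING / (2.0 * np.pi)

    pitch = (beads_per_monomer - 1) * CA_SPACING + LONG_GAP
    coords, chains, resids, subunits, tags = [], [], [], [], []

    for p in range(n_pf):
        if planar:
            lat_pos = np.array([0.0, p * LAT_SPACING, 0.0])
            outward = np.array([0.0, 0.0, 1.0])
        else:
            ang = 2.0 * np.pi * p / n_pf
            lat_pos = np.array([0.0, radius * np.cos(ang), radius * np.sin(ang)])
            outward = np.array([0.0, np.cos(ang), np.sin(ang)])
        for d in range(n_dimers):
            for m, mono in enumerate("ab"):
                sub = f"pf{p}.d{d}.{mono}"
                x0 = (2 * d + m) * pitch
                for b in range(beads_per_monomer):
                    pos = lat_pos + np.array([x0 + b * CA_SPACING, 0.0, 0.0])
                    pos = pos + rng.uniform(-JITTER, JITTER, size=3)
                    coords.append(pos)
                    chains.append(sub)
                    resids.append(b + 1)
                    subunits.append(sub)
                    tags.append("none")
                if mono == "b":
                    # C-terminal tail bead pointing away from the lattice body
                    tip = coords[-1] + outward * CA_SPACING
                    coords.append(tip)
                    chains.append(sub)
                    resids.append(beads_per_monomer + 1)
                    subunits.append(sub)
                    tags.append("HBD_tail")

    coords = np.asarray(coords)
    _check_overlap(coords)
    meta: dict = {"system": "lattice", "n_pf": n_pf, "n_dimers": n_dimers, "planar": planar}
    if seam:
        meta["seam_pair"] = (n_pf - 1, 0) if not planar else (0, 1)
    return BeadModel(
        coords,
        np.array(chains, dtype=object),
        np.array(resids),
        np.array(subunits, dtype=object),
        np.array(tags, dtype=object),
        np.zeros(len(coords), dtype=bool),
        meta,
    )


PROTOMERS = "ABCDEF"
#: Beads in a protomer core cluster (1 pore loop + NBD beads).
HEX_CORE_BEADS = 6


def make_toy_hexamer(
    with_arms: bool = False,
    pore_radius: float = 8.0,
    linker_beads: int = 10,
    arm_drop: float = 8.0,
    seed: int = 0,
) -> BeadModel:
    """Generate a hexameric ring machine around a central pore on the z axis.

    Six protomers (chains A–F, in clockwise ring order as viewed from the
    cis side, z<0) are radial bead runs in the z=0 plane. The innermost bead
    of each protomer is tagged ``pore_loop`` and sits exactly ``pore_radius``
    from the symmetry axis, so the pore admits a single substrate chain.
    With ``with_arms`` each chain continues outward-and-downward (a total
    vertical droop of ``arm_drop`` Å spread along the arm, emulating
    flexible linkers draping toward a surface the ring sits above) with
    ``linker_beads`` linker beads and a three-bead MIT-like anchor cluster.
    """
    if pore_radius <= 0:
        raise ValueError("pore_radius must be positive")
    if pore_radius < 2.0:
        raise ValueError(
            f"pore_radius {pore_radius} Å is smaller than the bead excluded volume (~2 Å)"
        )
    if linker_beads < 0:
        raise ValueError("linker_beads must be >= 0")

    coords, chains, resids, subunits, tags = [], [], [], [], []
    for k, name in enumerate(PROTOMERS):
        ang = -2.0 * np.pi * k / 6.0  # clockwise viewed from +z (trans side)
        u = np.array([np.cos(ang), np.sin(ang), 0.0])
        r = 1
        for b in range(HEX_CORE_BEADS):
            coords.append(u * (pore_radius + b * CA_SPACING))
            chains.append(name)
            resids.append(r)
            subunits.append(name)
            tags.append("pore_loop" if b == 0 else "NBD")
            r += 1
        if with_arms:
            n_arm = linker_beads + 3
            dz = min(arm_drop / n_arm, CA_SPACING * 0.9)
            dr = np.sqrt(CA_SPACING**2 - dz**2)
            base = pore_radius + (HEX_CORE_BEADS - 1) * CA_SPACING
            for b in range(n_arm):
                radial = base + (b + 1) * dr
                coords.append(u * radial + np.array([0.0, 0.0, -(b + 1) * dz]))
                chains.append(name)
                resids.append(r)
                subunits.append(name)
                tags.append("linker" if b < linker_beads else "MIT")
                r += 1

    coords = np.asarray(coords)
    _check_overlap(coords)
    return BeadModel(
        coords,
        np.array(chains, dtype=object),
        np.array(resids),
        np.array(subunits, dtype=object),
        np.array(tags, dtype=object),
        np.zeros(len(coords), dtype=bool),
        {"system": "hexamer", "pore_radius": pore_radius, "with_arms": with_arms},
    )


#: Inter-strand spacing of the toy sheet, Å (typical β-sheet rise).
STRAND_SPACING = 4.8


def make_toy_globule(
    n_strands: int,
    strand_len: int,
    tail_len: int,
    topology: str = "sheet_antiparallel",
    terminal_strand: int = 0,
    seed: int = 0,
) -> BeadModel:
    """Generate a planar β-sheet-like globule with a pulling tail.

    Strands are parallel rows (one chain each, ``S0``…); the tail
    (``substrate_tail``) continues the chain of ``terminal_strand`` beyond
    the sheet. ``terminal_strand=0`` (or ``n_strands-1``) puts the pulled
    anchor strand at the sheet edge, where it shares native contacts with a
    single neighbouring strand (soft, unzipping-like); an interior index
    puts it in the core with contacts to two neighbours (strong,
    shearing-like) — the wild-type vs circular-permutant terminal analogy.
    """
    if n_strands < 2:
        raise ValueError("need n_strands >= 2")
    if topology not in ("sheet_parallel", "sheet_antiparallel"):
        raise ValueError(f"unknown topology {topology!r}")
    if not 0 <= terminal_strand < n_strands:
        raise ValueError("terminal_strand out of range")

    coords, chains, resids, subunits, tags = [], [], [], [], []
    for s in range(n_strands):
        reverse = topology == "sheet_antiparallel" and s % 2 == 1
        xs = np.arange(strand_len) * CA_SPACING
        if reverse:
            xs = xs[::-1]
        for b, x in enumerate(xs):
            coords.append(np.array([x, s * STRAND_SPACING, 0.0]))
            chains.append(f"S{s}")
            resids.append(b + 1)
            subunits.append("sub")
            tags.append("substrate_core")
    # tail leaves the sheet plane perpendicularly from the terminal strand's
    # end bead: pulling along the tail then unzips the anchor strand bead by
    # bead instead of shearing all its inter-strand contacts at once
    model_coords = np.asarray(coords)
    term_idx = [i for i, c in enumerate(chains) if c == f"S{terminal_strand}"]
    last = model_coords[term_idx[-1]]
    direction = np.array([0.0, 0.0, 1.0])
    tail = [last + direction * CA_SPACING * (b + 1) for b in range(tail_len)]
    insert_at = term_idx[-1] + 1
    coords = coords[:insert_at] + tail + coords[insert_at:]
    chains = chains[:insert_at] + [f"S{terminal_strand}"] * tail_len + chains[insert_at:]
    resids = resids[:insert_at] + list(range(strand_len + 1, strand_len + 1 + tail_len)) + resids[insert_at:]
    subunits = subunits[:insert_at] + ["sub"] * tail_len + subunits[insert_at:]
    tags = tags[:insert_at] + ["substrate_tail"] * tail_len + tags[insert_at:]

    coords = np.asarray(coords)
    _check_overlap(coords)
    return BeadModel(
        coords,
        np.array(chains, dtype=object),
        np.array(resids),
        np.array(subunits, dtype=object),
        np.array(tags, dtype=object),
        np.zeros(len(coords), dtype=bool),
        {"system": "globule", "terminal_strand": terminal_strand, "topology": topology},
    )
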