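"""Config-driven experiment presets: lattice severing and pore translocation.

A declarative :class:`ExperimentConfig` describes a full setup — the system
(synthetic generator parameters or PDB paths), the interaction table, the
pulling or cycle protocol, fixed-bead selectors, and trajectory counts —
and :func:`run_experiment` executes it, producing per-trajectory force
traces and event reports plus an aggregate table (mean critical breaking
force, machine-oligomer decomposition and lattice fragments lost per
interaction strength, mirroring the free-anchor sweep bookkeeping).

Desk-scale defaults: a 3×3-dimer lattice with 4 beads per monomer pulled by
the tail of its central β monomer, and a 4×5-strand sheet substrate
threaded through the toy hexamer pore.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .brownian import CantileverProtocol, run_pulling
from .energy import SOPParameters
from .observables import EventReport, detect_breaking_forces, fragment_census
from .pore_cycle import (
    CycleProtocol,
    build_pore_topology,
    run_translocation,
    thread_substrate,
)
from .structures import (
    BeadModel,
    make_toy_globule,
    make_toy_hexamer,
    make_toy_lattice,
    read_model,
)
from .topology import InteractionTable, build_native_contacts, set_mit_interaction

__all__ = [
    "ExperimentConfig",
    "resolve_selector",
    "mount_machine_on_lattice",
    "build_system",
    "run_experiment",
    "pathway_census",
]


@dataclass
class ExperimentConfig:
    """Declarative experiment description (YAML-serialisable).

    ``kind`` is ``"cantilever"`` (constant-loading-rate severing pull) or
    ``"pore"`` (repetitive-force translocation). ``eps_sweep`` optionally
    lists MIT–lattice interaction strengths; each value is run with
    ``n_trajectories`` independent seeds.
    """

    kind: str = "cantilever"
    lattice: dict | None = field(
        default_factory=lambda: {"n_pf": 3, "n_dimers": 3, "beads_per_monomer": 4}
    )
    machine: dict | None = None
    globule: dict | None = None
    pdb: dict | None = None  # {"path": ..., "chain_map": {...}} alternative input
    table: dict = field(default_factory=dict)
    protocol: dict = field(default_factory=dict)
    fixed: list = field(default_factory=list)
    pulled: dict | None = None
    eps_sweep: list | None = None
    n_trajectories: int = 3
    n_steps: int = 20_000
    n_cycles: int = 200
    seed: int = 0
    output_every: int = 50
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in ("cantilever", "pore"):
            raise ValueError(f"unknown experiment kind {self.kind!r}")
        if self.n_trajectories < 1:
            raise ValueError("n_trajectories must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        import yaml

        return cls(**yaml.safe_load(Path(path).read_text()))

    def to_yaml(self, path: str | Path) -> None:
        import yaml

        Path(path).write_text(yaml.safe_dump(asdict(self)))


def resolve_selector(model: BeadModel, selector: dict) -> np.ndarray:
    """Resolve a fixed-bead selector to bead indices.

    Keys: ``domain_tag``, ``chain`` (one label or a list), ``subunit``,
    ``resid`` (exact residue number), ``which`` (``"all"`` default,
    ``"first"``/``"last"`` take one bead per matching chain).
    """
    idx = model.select(
        domain_tag=selector.get("domain_tag"),
        chain=selector.get("chain"),
        subunit=selector.get("subunit"),
    )
    if "resid" in selector:
        idx = idx[model.resid[idx] == selector["resid"]]
    which = selector.get("which", "all")
    if which in ("first", "last") and len(idx):
        out = []
        for c in dict.fromkeys(model.chain_id[idx]):
            sub = idx[model.chain_id[idx] == c]
            out.append(sub[0] if which == "first" else sub[-1])
        idx = np.array(out, dtype=int)
    if len(idx) == 0:
        raise ValueError(f"selector {selector!r} matches no beads")
    return idx


#: Ring height above a planar lattice surface, Å — close enough that
#: pore-loop/tail and MIT/lattice pairs fall inside the 13 Å contact cutoff.
MOUNT_HEIGHT = 12.0


def mount_machine_on_lattice(
    lattice: BeadModel, machine: BeadModel, over_subunit: str
) -> BeadModel:
    """Mount a hexamer ring above a planar lattice, pore over a β-monomer tail.

    The ring (built in the z = 0 plane with its pore axis on z) is
    translated so its pore sits ``MOUNT_HEIGHT`` above the lattice surface,
    centred over the tail bead of ``over_subunit``; the tail threads toward
    the pore. Machine beads stay mobile; anchoring is configured through
    fixed-bead selectors or the MIT interaction strength.
    """
    tail = lattice.select(subunit=over_subunit, domain_tag="HBD_tail")
    if len(tail) != 1:
        raise ValueError(f"subunit {over_subunit!r} has no single HBD tail bead")
    target = lattice.coords[tail[0]].copy()
    body = lattice.domain_tag != "HBD_tail"
    surface_z = lattice.coords[body, 2].max()
    shift = np.array([target[0], target[1], surface_z + MOUNT_HEIGHT])
    coords = machine.coords + shift
    return BeadModel(
        coords=np.vstack([lattice.coords, coords]),
        chain_id=np.concatenate([lattice.chain_id, machine.chain_id]),
        resid=np.concatenate([lattice.resid, machine.resid]),
        subunit_id=np.concatenate([lattice.subunit_id, machine.subunit_id]),
        domain_tag=np.concatenate([lattice.domain_tag, machine.domain_tag]),
        fixed=np.concatenate([lattice.fixed, machine.fixed]),
        meta={**lattice.meta, "mounted_over": over_subunit},
    )


def _central_beta(cfg_lattice: dict) -> str:
    p = cfg_lattice.get("n_pf", 3) // 2
    d = cfg_lattice.get("n_dimers", 3) // 2
    return f"pf{p}.d{d}.b"


def build_system(config: ExperimentConfig, seed: int):
    """Build (model, topology, pulled_bead_or_None) for one trajectory."""
    table = InteractionTable(**config.table)
    if config.kind == "cantilever":
        if config.pdb is not None:
            model = read_model(config.pdb["path"])
        else:
            model = make_toy_lattice(seed=seed, **(config.lattice or {}))
        if config.machine is not None:
            ring = make_toy_hexamer(seed=seed, **config.machine)
            model = mount_machine_on_lattice(model, ring, _central_beta(config.lattice or {}))
        fixed_idx = [resolve_selector(model, s) for s in config.fixed] or [
            _default_lattice_anchors(model)
        ]
        model = model.with_fixed(np.concatenate(fixed_idx))
        topo = build_native_contacts(model, table)
        if config.pulled is not None:
            pulled = int(resolve_selector(model, config.pulled)[0])
        else:
            pulled = int(
                model.select(subunit=_central_beta(config.lattice or {}), domain_tag="HBD_tail")[0]
            )
        return model, topo, pulled

    # pore translocation
    glob_cfg = dict(config.globule or {"n_strands": 4, "strand_len": 5, "tail_len": 3})
    substrate = make_toy_globule(seed=seed, **glob_cfg)
    ring = make_toy_hexamer(seed=seed, **(config.machine or {}))
    combined = thread_substrate(ring, substrate)
    gtable = InteractionTable(**{"contact_cutoff": 6.0, **config.table})
    topo = build_pore_topology(combined, gtable, grip=config.protocol.get("grip", False))
    return combined, topo, None


def _default_lattice_anchors(model: BeadModel) -> np.ndarray:
    """First bead of every monomer in the first and last dimer of each PF."""
    subs = model.subunit_id.astype(str)
    dimer_ids = sorted(
        {s.split(".")[1] for s in subs if s.startswith("pf")}, key=lambda s: int(s[1:])
    )
    if not dimer_ids:
        raise ValueError("no lattice subunits to anchor")
    ends = {dimer_ids[0], dimer_ids[-1]}
    idx = [
        i
        for i in range(model.n_beads)
        if subs[i].startswith("pf") and subs[i].split(".")[1] in ends and model.resid[i] == 1
    ]
    return np.array(idx, dtype=int)


def run_experiment(config: ExperimentConfig):
    """Run all trajectories of a config; returns (results, aggregate).

    ``results`` is a list of per-trajectory dicts (eps, seed, trace, report,
    frames); ``aggregate`` a DataFrame with one row per trajectory and the
    per-ϵh mean CBF, oligomer and pathway columns recomputable from the
    saved event reports.
    """
    eps_values = config.eps_sweep or [None]
    params = SOPParameters(**config.params)
    results, rows = [], []
    for e_idx, eps in enumerate(eps_values):
        for t in range(config.n_trajectories):
            seed = config.seed + 1000 * e_idx + t
            model, topo, pulled = build_system(config, seed=config.seed)
            if eps is not None:
                topo = set_mit_interaction(topo, eps)
            if config.kind == "cantilever":
                proto = CantileverProtocol(
                    pulled_bead=pulled, **{"direction": (0, 0, 1.0), **config.protocol}
                )
                times, frames, trace = run_pulling(
                    model,
                    topo,
                    params,
                    proto,
                    n_steps=config.n_steps,
                    seed=seed,
                    output_every=config.output_every,
                )
                fbf, cbf, _ = detect_breaking_forces(trace)
                report = fragment_census(frames[-1], topo, model, fbf=fbf, cbf=cbf)
            else:
                cycle_cfg = {k: v for k, v in config.protocol.items() if k != "grip"}
                proto = CycleProtocol(**cycle_cfg)
                times, frames, log = run_translocation(
                    model, topo, params, proto, n_cycles=config.n_cycles, seed=seed
                )
                trace = log
                report = EventReport(fbf=None, cbf=float(log["total_force_pN"].max()))
                report.pathway_label = f"x={log['x'].iloc[-1]:.2f}"
            results.append(
                {"eps": eps, "seed": seed, "trace": trace, "report": report, "frames": frames}
            )
            rows.append(
                {
                    "eps_h": eps,
                    "trajectory": t,
                    "seed": seed,
                    "fbf_pN": report.fbf,
                    "cbf_pN": report.cbf,
                    "oligomers": report.oligomers,
                    "pathway": report.pathway_label,
                }
            )
    return results, pd.DataFrame(rows)


def pathway_census(reports: list[EventReport]) -> pd.DataFrame:
    """Frequency table of (fragments-lost label, oligomer decomposition).

    Percentages are reported alongside raw counts, since trajectory counts
    are small.
    """
    if not reports:
        raise ValueError("need at least one event report")
    rows = [(r.pathway_label, r.oligomers) for r in reports]
    df = pd.DataFrame(rows, columns=["pathway", "oligomers"])
    out = (
        df.value_counts(["pathway", "oligomers"])
        .rename("count")
        .reset_index()
        .sort_values("count", ascending=False, ignore_index=True)
    )
    out["percent"] = 100.0 * out["count"] / len(reports)
    return out
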