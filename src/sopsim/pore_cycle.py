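"""Repetitive pore-force translocation protocol at Cα resolution.

The allosteric cycle of a Clp-family ATPase is reduced to its force
bookkeeping: each cycle of duration τ consists of two hemicycles of six
sequential protomer transitions each (open→close then close→open, twelve
transitions per cycle). During the open→close hemicycle an axial force —
magnitude drawn from a Gaussian truncated at zero — is distributed
uniformly over the substrate beads transiently inside the pore window
(|z − ⟨z_loop⟩| < half-width, evaluated at cycle start). The ring itself is
static: the machine's conformational loop motions are not propagated, only
the cycle timing, the pore-window selection, and the stochastic force they
generate. The first protomer of a hemicycle is chosen uniformly at random,
and subsequent transitions follow the clockwise ring order.

Conventions: the pore axis is +z with the machine centre of mass at the
origin; cis (entry) side is z < 0, trans (exit) side z > 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .energy import EnergyModel, SOPParameters
from .brownian import _advance
from .structures import BeadModel, PROTOMERS
from .topology import InteractionTable, SOPTopology, build_native_contacts
from .units import force_from_pn

__all__ = [
    "CycleProtocol",
    "schedule_transitions",
    "select_pore_atoms",
    "sample_and_distribute_force",
    "effective_loop_speed",
    "thread_substrate",
    "build_pore_topology",
    "run_translocation",
]


@dataclass
class CycleProtocol:
    """Timing and force parameters of the repetitive-force cycle.

    Defaults follow the wild-type C→N threading setup (mean 400 pN,
    s.d. 20 pN); N→C threading of the wild type uses 700 ± 50 pN, and the
    circular-permutant variants 400 (P25) and 600 (K38) ± 20 pN.
    """

    tau: float = 120.0
    n_transitions_per_cycle: int = 12
    loop_excursion: float = 10.0
    mean_force: float = 400.0
    sd_force: float = 20.0
    window_half_width: float = 5.0
    z_trans: float = 12.0
    z_lumen: float = -8.0
    force_axis: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))

    def __post_init__(self) -> None:
        self.force_axis = np.asarray(self.force_axis, dtype=float)
        self.force_axis = self.force_axis / np.linalg.norm(self.force_axis)
        if self.tau <= 0 or self.window_half_width <= 0:
            raise ValueError("tau and window_half_width must be positive")
        if self.sd_force < 0 or self.mean_force < 0:
            raise ValueError("force parameters must be non-negative")
        if self.n_transitions_per_cycle < 2 or self.n_transitions_per_cycle % 2:
            raise ValueError("n_transitions_per_cycle must be an even count >= 2")


def schedule_transitions(
    protomers: int | list[str] = 6,
    seed: int | np.random.Generator = 0,
    start: int | None = None,
) -> list[str]:
    """Protomer firing order for one hemicycle.

    A cyclic permutation of the ring order starting at a uniformly random
    protomer (or at ``start`` when forced), proceeding clockwise as viewed
    from the cis side.
    """
    labels = list(PROTOMERS[:protomers]) if isinstance(protomers, int) else list(protomers)
    n = len(labels)
    if start is None:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        start = int(rng.integers(n))
    return [labels[(start + k) % n] for k in range(n)]


def select_pore_atoms(
    coords: np.ndarray,
    loop_beads: np.ndarray,
    substrate_beads: np.ndarray,
    protocol: CycleProtocol,
) -> np.ndarray:
    """Substrate beads inside the pore window |z − ⟨z_loop⟩| < half-width."""
    loop_beads = np.asarray(loop_beads, dtype=int)
    substrate_beads = np.asarray(substrate_beads, dtype=int)
    if len(loop_beads) == 0:
        raise ValueError("no pore-loop beads given")
    z0 = float(np.mean(coords[loop_beads, 2]))
    z = coords[substrate_beads, 2]
    sel = substrate_beads[np.abs(z - z0) < protocol.window_half_width]
    if len(sel) == 0:
        warnings.warn("empty pore-window selection; no force applied this hemicycle")
    return sel


def sample_and_distribute_force(
    selected: np.ndarray,
    protocol: CycleProtocol,
    seed: int | np.random.Generator = 0,
) -> tuple[float, np.ndarray]:
    """Draw one total force magnitude and split it evenly over the selection.

    Returns ``(total_pN, per_bead_vectors_pN)`` with one row per selected
    bead, each ``total/len(selected)`` along the pore axis. The Gaussian
    draw is truncated at zero (negative magnitudes are unphysical).
    """
    selected = np.asarray(selected, dtype=int)
    if len(selected) == 0:
        raise ValueError("selection is empty")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    total = max(0.0, float(rng.normal(protocol.mean_force, protocol.sd_force)))
    per_bead = (total / len(selected)) * protocol.force_axis
    return total, np.tile(per_bead, (len(selected), 1))


def effective_loop_speed(protocol: CycleProtocol) -> float:
    """Effective pulling speed of the pore loops, Å/ps.

    One transition lasts τ/n_transitions; the loop excursion divided by
    that interval gives the speed (1 Å/ps at the default 10 Å excursion,
    τ = 120 ps, 12 transitions per cycle).
    """
    return protocol.loop_excursion / (protocol.tau / protocol.n_transitions_per_cycle)


# ---------------------------------------------------------------------------
# System composition and the translocation run
# ---------------------------------------------------------------------------


def _rotation_to_z(v: np.ndarray) -> np.ndarray:
    """Rotation matrix taking unit vector v onto +z."""
    v = v / np.linalg.norm(v)
    z = np.array([0.0, 0.0, 1.0])
    c = float(np.dot(v, z))
    if c > 1.0 - 1e-12:
        return np.eye(3)
    if c < -1.0 + 1e-12:
        return np.diag([1.0, -1.0, -1.0])
    axis = np.cross(v, z)
    s = np.linalg.norm(axis)
    axis = axis / s
    K = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]])
    return np.eye(3) + s * K + (1 - c) * (K @ K)


def thread_substrate(
    machine: BeadModel,
    substrate: BeadModel,
    insertion: float = 2.0,
) -> BeadModel:
    """Mount a substrate below a pore ring, tail pre-threaded through it.

    The machine (assumed to lie around the origin with its pore axis on z)
    is frozen in place; the substrate is rigidly rotated so its tail points
    along +z and translated so the tail tip sits at z = ``insertion`` on
    the trans side, with the folded body on the cis side (z < 0).
    """
    tail = substrate.select(domain_tag="substrate_tail")
    if len(tail) < 1:
        raise ValueError("substrate has no substrate_tail beads")
    coords = substrate.coords.copy()
    if len(tail) >= 2:
        direction = coords[tail[-1]] - coords[tail[-2]]
    else:
        direction = coords[tail[-1]] - coords.mean(axis=0)
    R = _rotation_to_z(direction)
    coords = coords @ R.T
    coords += np.array([0.0, 0.0, insertion]) - coords[tail[-1]]

    mach = machine.with_fixed(np.arange(machine.n_beads))
    return BeadModel(
        coords=np.vstack([mach.coords, coords]),
        chain_id=np.concatenate([mach.chain_id, substrate.chain_id]),
        resid=np.concatenate([mach.resid, substrate.resid]),
        subunit_id=np.concatenate([mach.subunit_id, substrate.subunit_id]),
        domain_tag=np.concatenate([mach.domain_tag, substrate.domain_tag]),
        fixed=np.concatenate([mach.fixed, substrate.fixed]),
        meta={**machine.meta, "n_machine_beads": machine.n_beads},
    )


def build_pore_topology(
    combined: BeadModel,
    table: InteractionTable,
    grip: bool = False,
) -> SOPTopology:
    """Topology for a static ring plus substrate.

    Substrate-internal and machine-internal native contacts are kept; all
    machine–substrate pairs are purely repulsive unless ``grip`` enables
    the pore-loop grip contacts (class ``protomer_e15``).
    """
    from dataclasses import replace

    topo = build_native_contacts(combined, table)
    cls = topo.contact_class.astype(str)
    keep = {"substrate", "intra_protomer", "inter_protomer"}
    if grip:
        keep.add("protomer_e15")
    mask = np.isin(cls, sorted(keep))
    return replace(
        topo,
        contact_i=topo.contact_i[mask],
        contact_j=topo.contact_j[mask],
        contact_r0=topo.contact_r0[mask],
        contact_eps=topo.contact_eps[mask],
        contact_class=topo.contact_class[mask],
    )


def run_translocation(
    combined: BeadModel,
    topology: SOPTopology,
    params: SOPParameters,
    protocol: CycleProtocol,
    n_cycles: int = 200,
    seed: int = 0,
    output_every_cycles: int = 1,
) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Run the repetitive-force protocol on a pre-threaded system.

    Returns ``(frame_times, frames, log)``: one frame and one log row per
    ``output_every_cycles`` cycles. Log columns: cycle, start_protomer,
    n_selected, total_force_pN, x (translocated fraction) and I
    (translocation line, pulled-chain position numbered from the tip).
    """
    loop_beads = combined.select(domain_tag="pore_loop")
    sub_core = combined.select(domain_tag="substrate_core")
    sub_tail = combined.select(domain_tag="substrate_tail")
    substrate_beads = np.sort(np.concatenate([sub_core, sub_tail]))
    if len(substrate_beads) == 0:
        raise ValueError("combined model contains no substrate beads")

    # pulled-chain order, tip first, for the translocation line
    tip_chain = combined.chain_id[sub_tail[-1]]
    pulled = combined.select(chain=str(tip_chain))
    pulled_order = pulled[np.argsort(-combined.resid[pulled])]

    rng = np.random.default_rng(seed)
    energy = EnergyModel(topology, params, fixed=combined.fixed, skip_fixed=True)
    coords = combined.coords.copy()
    fixed = combined.fixed.copy()
    steps_per_hemi = max(1, int(round(protocol.tau / 2.0 / params.dt)))
    protomer_labels = sorted(set(combined.chain_id[loop_beads].astype(str)))

    times, frames, rows = [], [], []
    max_translocated = 0

    for cycle in range(n_cycles):
        order = schedule_transitions(protomer_labels or 6, rng)
        selected = select_pore_atoms(coords, loop_beads, substrate_beads, protocol)
        ext = np.zeros_like(coords)
        total_pn = 0.0
        if len(selected):
            total_pn, per_bead_pn = sample_and_distribute_force(selected, protocol, rng)
            ext[selected] = force_from_pn(1.0) * per_bead_pn
        # open -> close hemicycle: force on
        for _ in range(steps_per_hemi):
            _, forces = energy.energy_forces(coords)
            coords = _advance(coords, forces + ext, params, rng, fixed)
        # close -> open hemicycle: force off
        for _ in range(steps_per_hemi):
            _, forces = energy.energy_forces(coords)
            coords = _advance(coords, forces, params, rng, fixed)

        z = coords[:, 2]
        x = float(np.mean(z[substrate_beads] > protocol.z_trans))
        over = np.flatnonzero(z[pulled_order] > protocol.z_trans)
        if len(over):
            max_translocated = max(max_translocated, int(over[-1]) + 1)
        if (cycle + 1) % output_every_cycles == 0:
            times.append((cycle + 1) * 2 * steps_per_hemi * params.dt)
            frames.append(coords.copy())
            rows.append(
                {
                    "cycle": cycle,
                    "start_protomer": order[0],
                    "n_selected": int(len(selected)),
                    "total_force_pN": total_pn,
                    "x": x,
                    "I": max_translocated,
                }
            )

    return np.array(times), np.array(frames), pd.DataFrame(rows)
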