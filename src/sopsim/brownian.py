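"""Overdamped Brownian dynamics with a constant-loading-rate cantilever.

The position update for every mobile bead is the Ermak–McCammon step

    Δr = μ·F_total + ξ,   ⟨ξ⟩ = 0,  ⟨ξ_α²⟩ = 2·kBT·μ   per component,

where μ is the per-step mobility·time product ``SOPParameters.mobility_step``
(0.16·a²/ζ in the standard SOP convention) and the physical time advanced
per step is ``dt``. Fixed beads never move. Noise is drawn for all beads in
index order every step, so trajectories are bitwise reproducible for a
given seed regardless of which beads are fixed.

The cantilever is a harmonic spring of stiffness ``k_trans`` acting along a
constant unit direction; its anchor advances by ``dx`` every ``n_av`` steps,
giving a pulling speed v_f = dx/(n_av·dt).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .energy import EnergyModel, SOPParameters
from .structures import BeadModel
from .topology import SOPTopology
from .units import force_to_pn

__all__ = [
    "CantileverProtocol",
    "SimState",
    "ForceTrace",
    "brownian_step",
    "cantilever_force",
    "run_pulling",
]

#: Per-step displacement cap, Å — a numerical guard that prevents a rare
#: large noise kick from overshooting the FENE extensibility limit.
MAX_STEP_DISPLACEMENT = 1.0


@dataclass
class CantileverProtocol:
    """Constant-direction, constant-loading-rate pulling parameters."""

    pulled_bead: int
    direction: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))
    k_trans: float = 0.025
    dx: float = 0.0008
    n_av: int = 1000

    def __post_init__(self) -> None:
        self.direction = np.asarray(self.direction, dtype=float)
        nrm = np.linalg.norm(self.direction)
        if nrm == 0:
            raise ValueError("direction must be a non-zero vector")
        self.direction = self.direction / nrm
        if self.k_trans <= 0 or self.dx <= 0 or self.n_av < 1:
            raise ValueError("k_trans, dx must be positive and n_av >= 1")

    def speed(self, dt: float) -> float:
        """Pulling speed v_f = dx/(n_av·dt), Å/ps."""
        return self.dx / (self.n_av * dt)


@dataclass
class SimState:
    """Time-stamped simulation state with its own random generator."""

    coords: np.ndarray
    time: float = 0.0
    step_index: int = 0
    cantilever_anchor: np.ndarray | None = None
    rng: np.random.Generator = field(default_factory=lambda: np.random.default_rng(0))

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)


@dataclass
class ForceTrace:
    """Uniformly sampled cantilever force-extension record."""

    time: np.ndarray
    extension: np.ndarray
    force: np.ndarray

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.extension = np.asarray(self.extension, dtype=float)
        self.force = np.asarray(self.force, dtype=float)
        if len(self.time) > 1 and np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"time_ps": self.time, "extension_A": self.extension, "force_pN": self.force}
        )


def _advance(
    coords: np.ndarray,
    forces: np.ndarray,
    params: SOPParameters,
    rng: np.random.Generator,
    fixed: np.ndarray,
) -> np.ndarray:
    """One in-place position update; returns the new coordinate array."""
    if not np.all(np.isfinite(forces)):
        bad = int(np.flatnonzero(~np.isfinite(forces).all(axis=1))[0])
        raise FloatingPointError(f"non-finite force on bead {bad}")
    mu = params.mobility_step
    noise = rng.standard_normal(coords.shape) * np.sqrt(2.0 * params.kBT * mu)
    step = mu * forces + noise
    norms = np.linalg.norm(step, axis=1)
    over = norms > MAX_STEP_DISPLACEMENT
    if np.any(over):
        step[over] *= (MAX_STEP_DISPLACEMENT / norms[over])[:, None]
    step[fixed] = 0.0
    return coords + step


def brownian_step(
    state: SimState,
    topology_or_model: SOPTopology | EnergyModel,
    params: SOPParameters,
    external_forces: np.ndarray | None = None,
    fixed: np.ndarray | None = None,
) -> SimState:
    """Advance the state by one Brownian step (functional: returns new state)."""
    model = (
        topology_or_model
        if isinstance(topology_or_model, EnergyModel)
        else EnergyModel(topology_or_model, params)
    )
    _, forces = model.energy_forces(state.coords)
    if external_forces is not None:
        forces = forces + external_forces
    if fixed is None:
        fixed = np.zeros(len(state.coords), dtype=bool)
    new_coords = _advance(state.coords.copy(), forces, params, state.rng, fixed)
    return SimState(
        coords=new_coords,
        time=state.time + params.dt,
        step_index=state.step_index + 1,
        cantilever_anchor=state.cantilever_anchor,
        rng=state.rng,
    )


def cantilever_force(
    state: SimState, protocol: CantileverProtocol
) -> tuple[float, np.ndarray, np.ndarray]:
    """Current cantilever restoring force and per-bead force vector.

    The anchor is advanced by the caller (see :func:`run_pulling`); here the
    1-D spring force along the pulling direction is evaluated as
    k_trans·(anchor − bead)·d̂. Returns ``(force_pN, force_vector,
    anchor)`` where the vector (kcal/(mol·Å)) acts on the pulled bead.
    """
    d = protocol.direction
    anchor = state.cantilever_anchor
    if anchor is None:
        anchor = state.coords[protocol.pulled_bead].copy()
    gap = float(np.dot(anchor - state.coords[protocol.pulled_bead], d))
    f = protocol.k_trans * gap
    return force_to_pn(f), f * d, anchor


def run_pulling(
    model: BeadModel,
    topology: SOPTopology,
    params: SOPParameters,
    protocol: CantileverProtocol,
    fixed_beads: np.ndarray | None = None,
    n_steps: int = 10_000,
    seed: int = 0,
    output_every: int = 100,
    stop_at_rupture: bool = False,
) -> tuple[np.ndarray, np.ndarray, ForceTrace]:
    """Run a constant-loading-rate pulling trajectory.

    Returns ``(frame_times, frames, trace)`` where frames (T, N, 3) and the
    force trace are sampled every ``output_every`` steps. ``fixed_beads``
    supplements the model's own fixed flags. With ``stop_at_rupture`` the
    run ends early once the cantilever force has dropped to below 10% of
    its running maximum after loading past it (the pulled handle came
    free); otherwise the full ``n_steps`` are integrated.
    """
    if params.dt > 100.0:
        warnings.warn(f"dt = {params.dt} ps is large; integration may be unstable")
    fixed = model.fixed.copy()
    if fixed_beads is not None:
        fixed[np.asarray(fixed_beads, dtype=int)] = True
    if fixed[protocol.pulled_bead]:
        raise ValueError("pulled bead cannot be fixed")

    energy = EnergyModel(topology, params, fixed=fixed, skip_fixed=True)
    rng = np.random.default_rng(seed)
    coords = model.coords.copy()
    anchor = coords[protocol.pulled_bead].copy()
    start = coords[protocol.pulled_bead].copy()
    d = protocol.direction

    times, frames, t_rec, x_rec, f_rec = [], [], [], [], []
    peak = 0.0

    for step in range(n_steps):
        if step > 0 and step % protocol.n_av == 0:
            anchor = anchor + protocol.dx * d
        _, forces = energy.energy_forces(coords)
        gap = float(np.dot(anchor - coords[protocol.pulled_bead], d))
        f_cant = protocol.k_trans * gap
        forces[protocol.pulled_bead] += f_cant * d
        coords = _advance(coords, forces, params, rng, fixed)
        if step % output_every == 0:
            t = (step + 1) * params.dt
            times.append(t)
            frames.append(coords.copy())
            t_rec.append(t)
            x_rec.append(float(np.dot(coords[protocol.pulled_bead] - start, d)))
            f_rec.append(force_to_pn(f_cant))
            peak = max(peak, f_rec[-1])
            if stop_at_rupture and peak > 0 and f_rec[-1] < 0.1 * peak and len(f_rec) > 10:
                break

    trace = ForceTrace(np.array(t_rec), np.array(x_rec), np.array(f_rec))
    return np.array(times), np.array(frames), trace
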