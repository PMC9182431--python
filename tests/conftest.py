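"""Shared fixtures. Expensive simulation batches are session-scoped so the
statistical-mechanics and mechanical-anisotropy checks run once and are
shared between the unit suites and the acceptance suite."""

from __future__ import annotations

import warnings

import numpy as np
import pytest

import sopsim as s
from sopsim.brownian import CantileverProtocol, SimState, brownian_step, run_pulling
from sopsim.energy import EnergyModel
from sopsim.pore_cycle import (
    CycleProtocol,
    build_pore_topology,
    run_translocation,
    thread_substrate,
)
from sopsim.structures import BeadModel


def two_bead_contact(eps: float = 1.0, r0: float = 5.0):
    """Two beads on separate chains joined by a single native contact."""
    model = BeadModel(
        np.array([[0.0, 0.0, 0.0], [r0, 0.0, 0.0]]),
        ["x", "y"],
        [1, 1],
        ["pf0.d0.a", "pf0.d0.b"],
        ["none", "none"],
        [True, False],
    )
    topo = s.build_native_contacts(model, s.InteractionTable(eps_h_by_class={"intra_dimer": eps}))
    return model, topo


def rupture_force(eps: float, seed: int, dx: float = 0.005, kbt: float = 0.1) -> float:
    """Peak cantilever force while pulling a single native contact apart.

    Run at reduced temperature so rupture is force-driven rather than by
    thermal escape over the shallow single-contact barrier.
    """
    model, topo = two_bead_contact(eps)
    proto = CantileverProtocol(pulled_bead=1, direction=(1, 0, 0), dx=dx, n_av=1)
    _, _, trace = run_pulling(
        model,
        topo,
        s.SOPParameters(kBT=kbt),
        proto,
        n_steps=8000,
        seed=seed,
        output_every=20,
        stop_at_rupture=True,
    )
    return float(trace.force.max())


@pytest.fixture(scope="session")
def rupture_vs_eps():
    """Median rupture force over 8 seeds for contact strengths 0.5/1/2."""
    return {
        eps: float(np.median([rupture_force(eps, sd) for sd in range(8)]))
        for eps in (0.5, 1.0, 2.0)
    }


@pytest.fixture(scope="session")
def rupture_vs_rate():
    """Median rupture force over 8 seeds across two decades of loading rate."""
    return {
        dx: float(np.median([rupture_force(1.0, sd, dx=dx) for sd in range(8)]))
        for dx in (0.001, 0.01, 0.1)
    }


@pytest.fixture(scope="session")
def trap_variance():
    """Positional variance of one bead in a harmonic trap over 10^6 steps."""
    model = BeadModel(np.zeros((1, 3)), ["a"], [1], ["pf0.d0.a"], ["none"], [False])
    topo = s.build_native_contacts(model, s.InteractionTable())
    params = s.SOPParameters()
    em = EnergyModel(topo, params)
    k_trap = 0.2
    state = SimState(coords=np.zeros((1, 3)), rng=np.random.default_rng(11))
    n = 10**6
    xs = np.empty((n, 3))
    for i in range(n):
        ext = -k_trap * state.coords
        state = brownian_step(state, em, params, external_forces=ext)
        xs[i] = state.coords[0]
    return xs[n // 10 :].var(axis=0), k_trap, params.kBT


@pytest.fixture(scope="session")
def severing_runs():
    """Three toy-lattice severing pulls on the central β-monomer tail."""
    from sopsim.experiments import ExperimentConfig, build_system

    cfg = ExperimentConfig()
    model, topo, pulled = build_system(cfg, seed=0)
    params = s.SOPParameters()
    proto = CantileverProtocol(pulled_bead=pulled, direction=(0, 0, 1), dx=0.02, n_av=1)
    out = []
    for seed in range(3):
        times, frames, trace = run_pulling(
            model, topo, params, proto, n_steps=20_000, seed=seed, output_every=50
        )
        out.append({"frames": frames, "trace": trace})
    return model, topo, out


def translocation_final_x(terminal: int, seed: int, mean_force: float = 190.0) -> float:
    """Final translocated fraction of the toy sheet substrate.

    Desk-scale conditions: substrate contact strength 3.0 kcal/mol and a
    total pore force whose per-contact tension sits between the one- and
    two-contact peel forces of the sheet, the regime where terminal
    anisotropy governs extraction.
    """
    glob = s.make_toy_globule(4, 5, 3, terminal_strand=terminal, seed=seed)
    ring = s.make_toy_hexamer(pore_radius=5.0, seed=seed)  # single-chain aperture
    comb = thread_substrate(ring, glob)
    topo = build_pore_topology(
        comb, s.InteractionTable(contact_cutoff=6.0, eps_h_by_class={"substrate": 3.0})
    )
    params = s.SOPParameters(dt=20.0)
    proto = CycleProtocol(mean_force=mean_force, sd_force=20.0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        _, _, log = run_translocation(
            comb, topo, params, proto, n_cycles=2000, seed=seed, output_every_cycles=2000
        )
    return float(log["x"].iloc[-1])


@pytest.fixture(scope="session")
def translocation_medians():
    """Median final x over 8 seeds: edge vs core terminal, and half force."""
    edge = [translocation_final_x(0, sd) for sd in range(8)]
    core = [translocation_final_x(1, sd) for sd in range(8)]
    half = [translocation_final_x(0, sd, mean_force=95.0) for sd in range(8)]
    return {
        "edge": float(np.median(edge)),
        "core": float(np.median(core)),
        "edge_half_force": float(np.median(half)),
    }
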