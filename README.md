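# sopsim

Coarse-grained simulations of how AAA+ ring machines mechanically unfold
their substrates. The package is aimed at molecular-biophysics researchers
studying microtubule-severing enzymes (spastin, katanin) and protein
translocases of the Clp family (ClpY/HslU): it builds one-bead-per-residue
Go-like models of large assemblies — a microtubule lattice with a severing
hexamer mounted on it, or a globular substrate threaded through an ATPase
pore — runs overdamped Brownian-dynamics pulling experiments on them, and
computes the rupture, census, orientation and translocation observables by
which unfoldase action is characterised.

## The model

Structures are reduced to their Cα beads and governed by the
self-organized-polymer (SOP) potential

```
V_T = V_FENE + V_NB^ATT + V_NB^REP

V_FENE   = Σ_bonds  −(k/2) R0² ln[1 − (r_{i,i+1} − r⁰_{i,i+1})²/R0²]
V_NB^ATT = Σ_native ϵ_h [(r⁰_ij/r_ij)¹² − 2 (r⁰_ij/r_ij)⁶] Δ_ij
V_NB^REP = Σ_{i,i+2} ϵ_l (σ/r_{i,i+2})⁶ + Σ_non-native ϵ_l (σ/r_ij)⁶ (1 − Δ_ij)
```

with k = 20 kcal/(mol·Å²), R0 = 2.0 Å, ϵ_l = 1.0 kcal/mol, σ = 3.8 Å.
Native contacts (Δ_ij = 1) are pairs within 13 Å in the native structure
(|i−j| ≥ 3 within a chain; all pairs between chains), and each carries the
contact strength ϵ_h of its interface class — e.g. 1.9 kcal/mol inside a
tubulin dimer but only 0.9 kcal/mol across the lateral interface between
protofilaments, the asymmetry that shapes how a lattice breaks. Dynamics
are overdamped Brownian steps at ζ = 50 with a 40 ps time label per step;
pulling is applied either by a stiff-loading cantilever
(k_trans = 0.025 kcal/(mol·Å²), speed Δx/(n_av·Δt)) or by a repetitive
pore force — a per-cycle Gaussian force magnitude distributed uniformly
over the substrate beads inside the pore window and applied axially during
the open→close hemicycle of the ring's 120 ps cycle.

Synthetic desk-scale systems (a protofilament lattice, a hexameric ring
with pore loops and MIT-like anchor arms, and a β-sheet-like globule with
an edge- or core-anchored pulling tail) are first-class generators, so
every analysis can be exercised end-to-end without external structure
files; real Cα structures are read from PDB.

## Worked example: severing a toy lattice

```python
import sopsim as s
from sopsim.brownian import CantileverProtocol, run_pulling
from sopsim.observables import detect_breaking_forces, fragment_census
from sopsim.experiments import ExperimentConfig, build_system

model, topology, pulled = build_system(ExperimentConfig(), seed=0)
print(f"{model.n_beads} beads, {topology.n_contacts} native contacts")

proto = CantileverProtocol(pulled_bead=pulled, direction=(0, 0, 1), dx=0.02, n_av=1)
times, frames, trace = run_pulling(model, topology, s.SOPParameters(), proto,
                                   n_steps=40_000, seed=1, output_every=50)
fbf, cbf, events = detect_breaking_forces(trace)
report = fragment_census(frames[-1], topology, model, fbf=fbf, cbf=cbf)
print(f"FBF = {fbf:.0f} pN, CBF = {cbf:.0f} pN")
print(f"dimers lost: {report.pathway_label}; fragments: {[n for n, _ in report.fragments]}")
```

prints

```
81 beads, 430 native contacts
FBF = 1173 pN, CBF = 1173 pN
dimers lost: 1; fragments: [17, 1]
```

The default setup is a 3×3-dimer lattice anchored at both ends, pulled by
the C-terminal tail bead of its central β monomer. The trace shows a single
rupture event (first breaking force FBF coincides with the critical
breaking force CBF); the census of the final frame shows the lattice split
into an anchored 17-monomer body plus the one extracted monomer — one
lattice dimer disturbed, the severing outcome at this pulling speed.

A `sopsim` command-line tool wraps the same pipeline
(`sopsim build|simulate|analyze|census --config experiment.yaml`).

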