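# Methods

## Model

Proteins and assemblies are represented at one bead per residue (Cα). The
potential is the self-organized-polymer (SOP) form: FENE bonds between
consecutive beads of a chain (and across declared covalent fusions, such as
a pulled-handle peptide bonded to a tail bead), attractive 12–6
Lennard-Jones wells on the fixed native-contact list, and a purely
repulsive (σ/r)⁶ term on everything else, including the dedicated
(i, i+2) pairs. Energies are kcal/mol, lengths Å, times ps; forces are
converted with 1 kcal/(mol·Å) = 69.479 pN wherever pN is reported.

Native contacts are built from the native configuration with a cKDTree
search: any inter-chain pair, or intra-chain pair with |i−j| ≥ 3, whose
native distance is within the contact cutoff. The cutoff is 13 Å for
lattice/machine systems. For globular substrates, whose contact maps are
conventionally defined on heavy atoms at 6 Å — information a Cα model does
not carry — we use a 6 Å Cα-distance surrogate; with the sheet geometry
used here it retains exactly the nearest-register inter-strand pairs.

Each contact carries the strength ϵ_h of its interface class, resolved
from bead annotations (protofilament/dimer/monomer labels on lattices,
protomer chains on the machine, domain tags for pore loops, MIT anchors and
tails). Defaults (kcal/mol): intra-monomer and intra-dimer 1.9,
longitudinal 1.0, lateral and seam 0.9, intra- and inter-protomer 1.3,
machine–lattice 1.0, pore-loop–tail grip 1.0, MIT–lattice 1.0 (the
anchoring-strength sweep variable, 1.0–4.0), substrate-internal 1.3
(raised to 3.0 in the translocation preset, see below). ϵ_l = 1.0 kcal/mol
and σ = 3.8 Å; these are the conventional SOP values, exposed in
`InteractionTable`.

## Brownian dynamics and the friction convention

Positions evolve by the overdamped Euler step Δr = μF + ξ with
⟨ξ_α²⟩ = 2 k_BT μ per component (fluctuation–dissipation) and fixed beads
pinned exactly. The friction setting ζ = 50 is the dimensionless multiple
of the standard CG reference friction; in that convention the per-step
mobility·time product is μ = 0.16·a²/ζ ≈ 0.046 Å²·mol/kcal (a = 3.8 Å),
and each step advances the physical clock by Δt = 40 ps. We use this
mapping rather than reading ζ directly in kcal·mol⁻¹·ps·Å⁻², because the
naive unit closure (μ = Δt/ζ = 0.8 Å²·mol/kcal) violates the Euler
stability bound k·μ < 2 for the FENE backbone stiffness k = 20 and is
unusable in practice. Absolute time scales in this class of models are in
any case nominal: implicit-solvent CG dynamics map to longer effective
biological times.

Numerical guards: a per-step displacement cap of 1 Å (≥4 standard
deviations of the thermal kick at default temperature; it prevents a rare
noise spike from overshooting the FENE extensibility limit), and an
explicit overstretch error naming the bond if a FENE separation still
reaches R0. k_BT defaults to 0.6 kcal/mol (≈300 K). Repulsive pairs are
enumerated exactly (full complement) for systems up to 1500 beads; above
that a KD-tree neighbour list truncated at 3.25σ is used, where the
neglected per-pair energy ϵ_l/3.25⁶ ≈ 9×10⁻⁴ kcal/mol. Pairs in which
both beads are fixed can be skipped (used for the static-ring protocol);
they contribute no force on mobile beads.

The cantilever is a 1-D harmonic spring (k_trans = 0.025 kcal/(mol·Å²))
along a constant unit direction whose anchor advances by Δx every n_av
steps — pulling speed v_f = Δx/(n_av·Δt); the literature protocol
(Δx = 0.0008 Å, n_av = 1000) gives 2 μm/s. Desk-scale experiments
accelerate loading (Δx = 0.02 Å, n_av = 1) so rupture happens within 10⁴–10⁵
steps; breaking forces then carry the usual loading-rate dependence and are
comparable only within a protocol.

## Pore-cycle protocol

The ATPase ring is held static; what is retained from its allosteric cycle
is the force bookkeeping. Each 120 ps cycle comprises two hemicycles of six
sequential protomer transitions (twelve per cycle); the first protomer is
drawn uniformly and the rest follow clockwise ring order as seen from the
cis side. With the 10 Å pore-loop excursion this yields the effective
pulling speed of 1 Å/ps. At each cycle start, substrate beads with
|z − ⟨z_loop⟩| < 5 Å form the pore window; during the open→close hemicycle
a total force drawn from a Gaussian (truncated at zero) is split equally
among them and applied along +z. Per-variant settings: 700 ± 50 pN
(wild-type N→C), 400 ± 20 pN (wild-type C→N and the P25 circular
permutant), 600 ± 20 pN (the K38 permutant); over the ~20 atoms typically
in the window these give ≈35, 20, 20 and 30 pN per atom. The machine
centre sits at the origin with the pore axis on +z; cis is z < 0.
Translocation thresholds are z_trans = 12 Å and z_lumen = −8 Å. Whether
120 ps spans a half or a full cycle is ambiguous in the source protocol; we
adopt the full-cycle (twelve-transition) reading because it reproduces the
stated 1 Å/ps, and expose the count in `CycleProtocol`.

The translocation preset integrates at Δt = 20 ps so one cycle is exactly
six steps (three forced, three free).

## Synthetic systems

The generators produce annotated `BeadModel`s deterministically per seed.

* **Lattice** — monomers are 4-bead runs (own chain) along the filament
  axis; α/β monomers alternate within protofilaments; rows pack planar
  below five protofilaments, else on a cylinder. Longitudinal gap 4.5 Å and
  lateral row spacing 9.0 Å are comparable, so interface strength is set by
  the ϵ_h table, not geometry; 0.1 Å seeded jitter breaks exact degeneracy.
  Each β monomer carries one outward tail bead (the pulled handle). A
  declared seam labels one adjacent protofilament pair. The default
  experiment lattice is 3×3 dimers (81 beads), anchored by the first bead
  of every monomer in the first and last dimer ring.
* **Hexamer** — six radial 6-bead protomers (chains A–F) in a plane, the
  innermost bead of each being a pore-loop bead exactly `pore_radius` from
  the axis. Optional arms (linker beads + 3-bead MIT cluster) leave the
  ring outward and downward with a total droop of 8 Å, emulating linkers
  draping toward the surface the ring is mounted over. Mounted on a
  lattice, the ring sits 12 Å above the surface over a chosen β-monomer
  tail: pore loops then grip the tail (contact class of the pulled-handle
  grip) and, with arms, MIT clusters of the protomers pointing along the
  filament axis reach the lattice (MIT–lattice contacts for the
  anchoring-strength sweep). A 3×3 lattice is narrower than the armspan, so
  only those protomers anchor — the partial-anchoring regime.
* **Globule** — an n×m planar sheet (strand per chain, rows 4.8 Å apart,
  register-matched contacts only under the 6 Å cutoff) with a tail leaving
  the plane perpendicularly from the end of a designated anchor strand.
  Pulling the tail through a pore therefore unzips the anchor strand bead
  by bead: an edge strand costs one contact per bead, a core strand two —
  the minimal embodiment of terminal-dependent mechanical anisotropy
  (wild-type vs circular-permutant terminals).

## Desk-scale study conditions

The translocation comparison uses a 4×5-strand sheet with a 3-bead tail,
pore radius 5 Å (admits a single chain; the folded sheet cannot pass),
substrate contacts at 3.0 kcal/mol, and a 190 ± 20 pN total force over
2000 cycles. The force level is chosen on mechanism grounds: the maximum
restoring force of one contact is 2.69·ϵ_h/r0 ≈ 117 pN, so 190 pN exceeds
the single-contact peel force but not the two-contact one (~233 pN) —
the regime in which the edge- and core-anchored variants must diverge if
anisotropy, rather than brute force or free diffusion, controls
extraction. Single-contact rupture tests run at k_BT = 0.1 so rupture is
force-driven rather than thermal escape over the shallow (≲3 k_BT)
single-contact barrier. Severing runs use three trajectories per setup,
mirroring the small-n convention of such studies; statistics are reported
with counts.

## Observables

* **Q_N** — fraction of (optionally class-filtered) native contacts with
  |r_ij − r⁰_ij| < η, η = 2 Å. The same criterion defines "contact formed"
  package-wide, including the census graph.
* **f_NN** — currently-formed non-native pairs within 6 Å divided by the
  native-contact count (may exceed 1).
* **FBF/CBF** — rupture events are local maxima of the moving-average
  (50-frame) force trace followed by a ≥50 pN drop; FBF is the first event,
  CBF the global maximum. Both smoothing and drop threshold are exposed —
  they are detection conventions, not physics.
* **Census** — connected components of the graph whose nodes are subunits
  and whose edges are surviving inter-subunit contacts (networkx). Lattice
  pathway labels count dimers in components detached from the anchored
  component; machine oligomer strings list protomer counts ("0" = intact,
  "3;3" = two trimers).
* **Angles** — θ/ϕ/ψ between a protofilament axis (plus-end dimer COM to
  pulled dimer COM) and, respectively, the major principal axis of the full
  machine, of the motor ring only, and the designated pore-loop pair
  vector. Principal axes are gyration-tensor eigenvectors; near-degenerate
  spectra are tie-broken by largest eigenvalue with a deterministic sign
  (first non-zero component positive). Axis semantics fold angles to
  [0°, 90°]; a flag selects vector semantics for regimes where orientations
  beyond 90° are meaningful. Substrate orientation near the pore uses the
  polar angle of the first principal axis against the pore axis and the
  azimuth between in-plane projections, in [0°, 180°].
* **Translocation** — x(t) is the fraction of substrate beads past
  z_trans; I(t) the highest threading-order position translocated
  (non-decreasing ratchet by default, raw per-frame variant available);
  w(I) the pre-translocation residence time of residue I at z ≥ z_lumen.
* **Free-energy landscapes** — 2-D histogram Boltzmann inversion
  −k_BT ln P with the minimum shifted to zero; empty bins are NaN, never an
  infinite sentinel.

## What the toys show — and what they do not

The synthetic systems preserve the contact-strength hierarchy between
interfaces, chain connectivity, excluded volume, and protocol bookkeeping;
they do not reproduce tubulin or hexamer internal geometry, contact counts
per interface, or absolute energy scales. Tests passing on them establish
that the machinery is correct (potentials, integrator statistics, event
detection, census bookkeeping) and that the qualitative mechanics follow
the right asymmetries (weak interfaces fail before strong ones, rupture
force grows with contact strength and loading rate, soft terminals
translocate more readily). They do not validate absolute breaking forces of
real lattices: those depend on PDB-derived structures and sampling budgets
far beyond the desk-scale suite, and the experiment configs for such runs
are provided for long-horizon use with user-supplied coordinates.

## Known limitations

* Absolute time scales are nominal (friction convention above); only
  comparisons within a protocol are meaningful.
* The FENE divergence is logarithmic, so extreme bond tensions are
  represented by the overstretch guard rather than by unbounded forces.
* The static-ring pore protocol omits allosteric grip/release kinematics;
  translocation rates reflect the external-force bookkeeping only.
* Multi-chain toy substrates stop feeding the pore once the pulled chain
  clears the window, bounding the achievable translocated fraction;
  single-chain substrates at paper scale do not share this ceiling.
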