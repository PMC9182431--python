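"""Analysis observables: contact fractions, rupture forces, fragment and
oligomer census, orientation angles, free-energy landscapes, and
translocation metrics.

All angle outputs are degrees; forces pN; energies kcal/mol. The single
package-wide "contact formed" criterion is |r_ij − r⁰_ij| < η with
η = 2 Å; it defines both the native-contact fraction Q_N and the edge
criterion of the fragment census graph.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .structures import BeadModel
from .topology import SOPTopology

__all__ = [
    "EventReport",
    "fraction_native_contacts",
    "fraction_nonnative",
    "detect_breaking_forces",
    "fragment_census",
    "orientation_angles",
    "sp_orientation",
    "translocation_metrics",
    "free_energy_landscape",
]

#: Contact-formation tolerance η, Å.
DEFAULT_ETA = 2.0


@dataclass
class EventReport:
    """Summary of one pulling trajectory.

    ``fragments`` lists (subunit count, sorted subunit labels) per connected
    component of the inter-subunit contact graph; ``pathway_label`` is the
    multiset of dimer counts in lattice fragments detached from the anchored
    component (e.g. ``"6"`` or ``"6 + 2"``, ``"0"`` for an intact lattice);
    ``oligomers`` is the machine-ring decomposition as a protomer-count
    string (``"0"`` = intact hexamer, ``"3;3"`` = two trimers, ...).
    """

    fbf: float | None
    cbf: float
    fragments: list = field(default_factory=list)
    oligomers: str = "0"
    pathway_label: str = "0"

    def __post_init__(self) -> None:
        if self.fbf is not None and self.cbf < self.fbf - 1e-9:
            raise ValueError("CBF cannot be below FBF")

    def to_dict(self) -> dict:
        return {
            "fbf_pN": self.fbf,
            "cbf_pN": self.cbf,
            "fragments": [[n, list(subs)] for n, subs in self.fragments],
            "oligomers": self.oligomers,
            "pathway_label": self.pathway_label,
        }


# ---------------------------------------------------------------------------
# Contact fractions
# ---------------------------------------------------------------------------


def _contact_distances(coords: np.ndarray, topology: SOPTopology, mask=None):
    i, j, r0 = topology.contact_i, topology.contact_j, topology.contact_r0
    if mask is not None:
        i, j, r0 = i[mask], j[mask], r0[mask]
    r = np.linalg.norm(coords[j] - coords[i], axis=1)
    return r, r0


def fraction_native_contacts(
    coords: np.ndarray,
    topology: SOPTopology,
    eta: float = DEFAULT_ETA,
    subset: str | list[str] | None = None,
) -> float:
    """Fraction Q_N of native contacts still formed, |r − r0| < η.

    ``subset`` restricts to one or more interface classes — e.g.
    ``"longitudinal"`` or ``["lateral", "seam"]`` for the along-filament vs
    side-interface split of a pulled protofilament.
    """
    mask = None if subset is None else topology.contact_mask(subset)
    if mask is not None and not mask.any():
        raise ValueError(f"no contacts of class {subset!r} in topology")
    if topology.n_contacts == 0:
        raise ValueError("topology has no native contacts")
    r, r0 = _contact_distances(np.asarray(coords, dtype=float), topology, mask)
    return float(np.mean(np.abs(r - r0) < eta))


def fraction_nonnative(
    coords: np.ndarray,
    topology: SOPTopology,
    cutoff: float = 6.0,
) -> float:
    """Ratio f_NN = N_NC / N_C of currently formed non-native pairs.

    N_NC counts pairs within ``cutoff`` that are neither native contacts
    nor bonds nor intra-chain pairs with |i−j| < 3; the normalisation N_C
    is the native-contact count, so f_NN may exceed 1.
    """
    from scipy.spatial import cKDTree

    if topology.n_contacts == 0:
        raise ValueError("topology has no native contacts")
    coords = np.asarray(coords, dtype=float)
    chain = topology.chain_index
    exclude = topology.contact_pair_set() | topology.bond_pair_set()
    pairs = cKDTree(coords).query_pairs(cutoff, output_type="ndarray")
    n_nc = 0
    for a, b in pairs:
        a, b = int(min(a, b)), int(max(a, b))
        if chain[a] == chain[b] and b - a < 3:
            continue
        if (a, b) in exclude:
            continue
        n_nc += 1
    return n_nc / topology.n_contacts


# ---------------------------------------------------------------------------
# Rupture events
# ---------------------------------------------------------------------------


def detect_breaking_forces(
    trace,
    smooth_window: int = 50,
    min_drop: float = 50.0,
) -> tuple[float | None, float, np.ndarray]:
    """First (FBF) and critical (CBF) breaking force of a force trace.

    The force series is smoothed with a centred moving average; rupture
    events are local maxima followed by a drop of at least ``min_drop`` pN
    before the force recovers past the peak. FBF is the force at the first
    event (None if there are no events), CBF the global maximum of the
    smoothed trace. Returns ``(fbf, cbf, event_times)``.
    """
    force = np.asarray(trace.force, dtype=float)
    time = np.asarray(trace.time, dtype=float)
    if len(force) <= smooth_window:
        smooth_window = max(1, len(force) // 2)
    if smooth_window > 1:
        kernel = np.ones(smooth_window) / smooth_window
        sm = np.convolve(force, kernel, mode="same")
    else:
        sm = force.copy()

    events = []
    peak_idx = 0
    armed = False
    for k in range(1, len(sm)):
        if sm[k] >= sm[peak_idx]:
            peak_idx = k
            armed = True
        elif armed and sm[peak_idx] - sm[k] >= min_drop:
            events.append(peak_idx)
            peak_idx = k
            armed = False
    cbf = float(sm.max()) if len(sm) else 0.0
    fbf = float(sm[events[0]]) if events else None
    return fbf, cbf, time[events] if events else np.array([])


# ---------------------------------------------------------------------------
# Fragment and oligomer census
# ---------------------------------------------------------------------------


def _subunit_graph(
    coords: np.ndarray,
    topology: SOPTopology,
    model: BeadModel,
    break_tolerance: float,
    subunits: np.ndarray,
) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(np.unique(subunits.astype(str)))
    r, r0 = _contact_distances(coords, topology)
    formed = np.abs(r - r0) < break_tolerance
    si = subunits[topology.contact_i].astype(str)
    sj = subunits[topology.contact_j].astype(str)
    for a, b, ok in zip(si, sj, formed):
        if ok and a != b:
            g.add_edge(a, b)
    return g


def fragment_census(
    coords: np.ndarray,
    topology: SOPTopology,
    model: BeadModel,
    break_tolerance: float = DEFAULT_ETA,
    fbf: float | None = None,
    cbf: float = 0.0,
) -> EventReport:
    """Connected-component census of the inter-subunit contact graph.

    Subunits are nodes; an edge exists where at least one inter-subunit
    native contact is still formed. The lattice pathway label is the
    multiset of dimer counts of lattice components detached from the
    anchored component (the one holding fixed lattice beads, or the largest
    one); the machine oligomer string lists protomer counts of ring
    components when the hexamer has broken up.
    """
    coords = np.asarray(coords, dtype=float)
    g = _subunit_graph(coords, topology, model, break_tolerance, model.subunit_id)
    components = [sorted(c) for c in nx.connected_components(g)]
    components.sort(key=len, reverse=True)
    fragments = [(len(c), c) for c in components]

    sub_str = model.subunit_id.astype(str)
    lattice_subs = {s for s, t in zip(sub_str, model.domain_tag) if s.startswith("pf")}
    machine_subs = {
        s
        for s, t in zip(sub_str, model.domain_tag)
        if t in ("NBD", "pore_loop", "linker", "MIT")
    }

    pathway_label = "0"
    if lattice_subs:
        anchored_subs = set(sub_str[model.fixed]) & lattice_subs
        lattice_comps = [set(c) & lattice_subs for c in components if set(c) & lattice_subs]
        if anchored_subs:
            anchored = [c for c in lattice_comps if c & anchored_subs]
            anchored_comp = max(anchored, key=len) if anchored else max(lattice_comps, key=len)
        else:
            anchored_comp = max(lattice_comps, key=len)
        lost = []
        for c in lattice_comps:
            if c is anchored_comp or c == anchored_comp:
                continue
            dimers = {s.rsplit(".", 1)[0] for s in c}
            lost.append(len(dimers))
        pathway_label = " + ".join(str(n) for n in sorted(lost, reverse=True)) if lost else "0"

    oligomers = "0"
    if machine_subs:
        ring_comps = sorted(
            (len(set(c) & machine_subs) for c in components if set(c) & machine_subs),
            reverse=True,
        )
        if len(ring_comps) > 1:
            oligomers = ";".join(str(n) for n in ring_comps)

    return EventReport(
        fbf=fbf, cbf=cbf, fragments=fragments, oligomers=oligomers, pathway_label=pathway_label
    )


# ---------------------------------------------------------------------------
# Orientation angles
# ---------------------------------------------------------------------------


def _principal_axis(coords: np.ndarray) -> np.ndarray:
    """Major principal axis (largest-eigenvalue eigenvector of the gyration
    tensor); deterministic sign (first non-zero component positive)."""
    c = coords - coords.mean(axis=0)
    if len(c) < 3:
        raise ValueError("need >= 3 beads for a principal axis")
    gyr = c.T @ c
    w, v = np.linalg.eigh(gyr)
    if w[-1] < 1e-12:
        raise ValueError("degenerate (zero-extent) bead selection")
    axis = v[:, -1]
    nz = np.flatnonzero(np.abs(axis) > 1e-12)
    if len(nz) and axis[nz[0]] < 0:
        axis = -axis
    return axis


def _angle_deg(u: np.ndarray, v: np.ndarray, fold: bool = True) -> float:
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu < 1e-12 or nv < 1e-12:
        raise ValueError("degenerate (zero-length) axis")
    cosang = float(np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0))
    ang = float(np.degrees(np.arccos(cosang)))
    if fold and ang > 90.0:
        ang = 180.0 - ang
    return ang


def orientation_angles(
    coords: np.ndarray,
    model: BeadModel,
    pf_axis: np.ndarray,
    loop_pair: tuple[int, int],
    machine_selection: np.ndarray | None = None,
    motor_selection: np.ndarray | None = None,
    fold: bool = True,
) -> tuple[float, float, float]:
    """Machine-orientation angles (θ, ϕ, ψ) versus a protofilament axis.

    θ uses the major principal axis of the full machine (ring + arms),
    ϕ that of the motor ring only, and ψ the unit vector between the two
    designated pore-loop beads. ``pf_axis`` is the long axis of the pulled
    protofilament, conventionally the vector between the plus-end dimer
    centre of mass and that of the pulled dimer. With ``fold`` angles use
    axis semantics (folded to [0°, 90°]); disable it for the signed-vector
    reading when orientations beyond 90° are meaningful.
    """
    coords = np.asarray(coords, dtype=float)
    if machine_selection is None:
        machine_selection = np.sort(
            np.concatenate(
                [model.select(domain_tag=t) for t in ("NBD", "pore_loop", "linker", "MIT")]
            )
        )
    if motor_selection is None:
        motor_selection = np.sort(
            np.concatenate([model.select(domain_tag=t) for t in ("NBD", "pore_loop")])
        )
    theta = _angle_deg(pf_axis, _principal_axis(coords[machine_selection]), fold)
    phi = _angle_deg(pf_axis, _principal_axis(coords[motor_selection]), fold)
    a, b = loop_pair
    psi = _angle_deg(pf_axis, coords[b] - coords[a], fold)
    return theta, phi, psi


def pf_axis_from_dimers(
    coords: np.ndarray, model: BeadModel, plus_end_dimer: str, pulled_dimer: str
) -> np.ndarray:
    """Protofilament long axis: vector between two dimer centres of mass.

    Dimer labels are ``pf{p}.d{d}`` prefixes of the subunit labels.
    """
    subs = model.subunit_id.astype(str)
    sel_plus = np.flatnonzero(np.char.startswith(subs.astype(str), plus_end_dimer))
    sel_pull = np.flatnonzero(np.char.startswith(subs.astype(str), pulled_dimer))
    if len(sel_plus) == 0 or len(sel_pull) == 0:
        raise ValueError("dimer label matches no beads")
    axis = coords[sel_plus].mean(axis=0) - coords[sel_pull].mean(axis=0)
    if np.linalg.norm(axis) < 1e-9:
        raise ValueError("degenerate protofilament axis")
    return axis


def sp_orientation(
    coords: np.ndarray,
    substrate_beads: np.ndarray,
    ring_subunit_com: np.ndarray,
    pore_axis: np.ndarray = (0.0, 0.0, 1.0),
) -> tuple[float, float]:
    """Polar and azimuthal orientation of an untranslocated substrate body.

    θ ∈ [0°, 90°] is the angle between the substrate's first principal axis
    and the pore axis; ϕ ∈ [0°, 180°] the angle between the projections,
    onto the plane perpendicular to the pore axis, of that principal axis
    and of the designated ring subunit's centre-of-mass position vector.
    """
    coords = np.asarray(coords, dtype=float)
    pore_axis = np.asarray(pore_axis, dtype=float)
    pore_axis = pore_axis / np.linalg.norm(pore_axis)
    axis = _principal_axis(coords[np.asarray(substrate_beads, dtype=int)])
    theta = _angle_deg(pore_axis, axis, fold=True)

    def project(v):
        return v - np.dot(v, pore_axis) * pore_axis

    p1, p2 = project(axis), project(np.asarray(ring_subunit_com, dtype=float))
    if np.linalg.norm(p1) < 1e-9 or np.linalg.norm(p2) < 1e-9:
        raise ValueError("degenerate projection for azimuthal angle")
    phi = _angle_deg(p1, p2, fold=False)
    return theta, phi


# ---------------------------------------------------------------------------
# Translocation metrics
# ---------------------------------------------------------------------------


def translocation_metrics(
    frames: np.ndarray,
    order: np.ndarray,
    z_trans: float = 12.0,
    z_lumen: float = -8.0,
    frame_dt: float = 1.0,
    ratchet: bool = True,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-frame translocated fraction x(t), translocation line I(t), and
    per-residue waiting time w(I).

    ``order`` lists substrate bead indices in threading order (first pulled
    first); sequence positions are 1-based along that order. x(t) is the
    fraction of listed beads with z > ``z_trans``; I(t) the highest
    sequence position translocated (non-decreasing when ``ratchet``, the
    raw per-frame maximum otherwise); w(I) the total residence time of
    residue I at the pore entrance (z ≥ ``z_lumen``) before its first
    translocation.
    """
    frames = np.asarray(frames, dtype=float)
    order = np.asarray(order, dtype=int)
    z = frames[:, order, 2]  # (T, n)
    over = z > z_trans

    x = over.mean(axis=1)
    per_frame_line = np.where(
        over.any(axis=1), over.shape[1] - np.argmax(over[:, ::-1], axis=1), 0
    )
    line = np.maximum.accumulate(per_frame_line) if ratchet else per_frame_line

    first_cross = np.full(len(order), frames.shape[0], dtype=int)
    for k in range(len(order)):
        hits = np.flatnonzero(over[:, k])
        if len(hits):
            first_cross[k] = hits[0]
    t_idx = np.arange(frames.shape[0])[:, None]
    in_lumen = (z >= z_lumen) & (t_idx < first_cross[None, :])
    w = in_lumen.sum(axis=0) * frame_dt
    return x, line, w


# ---------------------------------------------------------------------------
# Free-energy landscape
# ---------------------------------------------------------------------------


def free_energy_landscape(
    obs1: np.ndarray,
    obs2: np.ndarray,
    kBT: float = 0.6,
    bins: int | tuple = 30,
    ranges=None,
):
    """2-D Boltzmann-inverted landscape −kBT·ln P, minimum shifted to zero.

    Returns ``(fel, xedges, yedges)``; bins with no samples are NaN
    (undefined), never an infinite sentinel that could contaminate minima.
    """
    obs1 = np.asarray(obs1, dtype=float)
    obs2 = np.asarray(obs2, dtype=float)
    if obs1.size == 0:
        raise ValueError("need at least one sample")
    hist, xe, ye = np.histogram2d(obs1, obs2, bins=bins, range=ranges)
    p = hist / hist.sum()
    with np.errstate(divide="ignore"):
        fel = -kBT * np.log(p)
    fel[p == 0] = np.nan
    fel -= np.nanmin(fel)
    return fel, xe, ye
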