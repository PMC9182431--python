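"""Analysis observables against hand-computed oracles and closed forms."""

import numpy as np
import pytest

import sopsim as s
from sopsim.brownian import ForceTrace
from sopsim.observables import free_energy_landscape, translocation_metrics
from sopsim.structures import BeadModel
from sopsim.topology import SOPTopology


def pair_topology(r0s, n_beads=None, classes=None):
    """Disjoint two-bead contacts at given native distances (oracle system)."""
    n_pairs = len(r0s)
    n = n_beads or 2 * n_pairs
    i = np.arange(0, 2 * n_pairs, 2)
    j = i + 1
    return SOPTopology(
        n_beads=n,
        bond_i=[], bond_j=[], bond_r0=[],
        contact_i=i, contact_j=j,
        contact_r0=np.asarray(r0s, dtype=float),
        contact_eps=np.ones(n_pairs),
        contact_class=np.array(classes or ["substrate"] * n_pairs, dtype=object),
        chain_index=np.arange(n),
    )


def pair_coords(dists, n_beads=None):
    n_pairs = len(dists)
    n = n_beads or 2 * n_pairs
    coords = np.zeros((n, 3))
    for k, d in enumerate(dists):
        coords[2 * k] = [0.0, 50.0 * k, 0.0]
        coords[2 * k + 1] = [d, 50.0 * k, 0.0]
    return coords


class TestFractionNativeContacts:
    def test_native_configuration_is_one(self):
        m = s.make_toy_lattice(3, 2, 3, seed=0)
        topo = s.build_native_contacts(m, s.InteractionTable())
        assert s.fraction_native_contacts(m.coords, topo) == 1.0

    def test_all_perturbed_past_tolerance_is_zero(self):
        topo = pair_topology([5.0, 5.0, 5.0])
        coords = pair_coords([8.0, 8.0, 8.0])  # all +3 Å > η = 2
        assert s.fraction_native_contacts(coords, topo) == 0.0

    def test_hand_counted_half(self):
        # perturbations {0.5, 1.9, 2.1, 5.0}: two inside η = 2 → QN = 0.5
        topo = pair_topology([5.0] * 4)
        coords = pair_coords([5.5, 6.9, 7.1, 10.0])
        assert s.fraction_native_contacts(coords, topo) == 0.5

    def test_class_subset_filter(self):
        topo = pair_topology([5.0, 5.0], classes=["lateral", "longitudinal"])
        coords = pair_coords([5.0, 10.0])
        assert s.fraction_native_contacts(coords, topo, subset="lateral") == 1.0
        assert s.fraction_native_contacts(coords, topo, subset="longitudinal") == 0.0
        with pytest.raises(ValueError, match="no contacts"):
            s.fraction_native_contacts(coords, topo, subset="seam")


class TestFractionNonnative:
    def test_two_bead_native_system_is_zero(self):
        topo = pair_topology([5.0])
        assert s.fraction_nonnative(pair_coords([5.0]), topo) == 0.0

    def test_collapsed_cloud_combinatorial_count(self):
        # 5 single-bead chains in a line at 4 Å: natives = pairs <= 13 Å (9 of 10)
        coords = np.column_stack([np.arange(5) * 4.0, np.zeros(5), np.zeros(5)])
        m = BeadModel(coords, [f"c{k}" for k in range(5)], np.ones(5, int),
                      ["pf0.d0.a"] * 5, ["none"] * 5, np.zeros(5, bool))
        topo = s.build_native_contacts(m, s.InteractionTable())
        assert topo.n_contacts == 9
        collapsed = coords * 0.3  # every pair now within 6 Å
        assert s.fraction_nonnative(collapsed, topo, cutoff=6.0) == pytest.approx((10 - 9) / 9)

    def test_equal_counts_give_one(self):
        # one native pair; bring a third bead within cutoff of one bead only
        topo = pair_topology([5.0], n_beads=3)
        coords = np.array([[0.0, 0, 0], [5.0, 0, 0], [-4.0, 0, 0]])
        assert s.fraction_nonnative(coords, topo, cutoff=4.5) == 1.0


class TestDetectBreakingForces:
    def _trace(self, values):
        t = np.arange(len(values), dtype=float)
        return ForceTrace(t, np.zeros_like(t), np.asarray(values, dtype=float))

    def test_two_peak_trace(self):
        up1 = np.linspace(0, 300, 31)
        down1 = np.linspace(300, 100, 21)[1:]
        up2 = np.linspace(100, 500, 41)[1:]
        down2 = np.linspace(500, 50, 46)[1:]
        fbf, cbf, events = s.detect_breaking_forces(
            self._trace(np.concatenate([up1, down1, up2, down2])), smooth_window=1, min_drop=50.0
        )
        assert fbf == pytest.approx(300.0)
        assert cbf == pytest.approx(500.0)
        assert len(events) == 2

    def test_monotone_ramp_has_no_events(self):
        fbf, cbf, events = s.detect_breaking_forces(
            self._trace(np.linspace(0, 400, 100)), smooth_window=1, min_drop=50.0
        )
        assert fbf is None
        assert cbf == pytest.approx(400.0)
        assert len(events) == 0

    def test_flat_zero_trace(self):
        fbf, cbf, events = s.detect_breaking_forces(self._trace(np.zeros(100)))
        assert fbf is None and cbf == 0.0 and len(events) == 0


class TestFragmentCensus:
    def test_intact_lattice_single_component(self):
        m = s.make_toy_lattice(3, 3, 4, seed=0)
        topo = s.build_native_contacts(m, s.InteractionTable())
        rep = s.fragment_census(m.coords, topo, m)
        assert len(rep.fragments) == 1
        assert rep.pathway_label == "0"
        assert rep.oligomers == "0"

    def test_displaced_monomer_detaches(self):
        m = s.make_toy_lattice(3, 3, 4, seed=0)
        topo = s.build_native_contacts(m, s.InteractionTable())
        coords = m.coords.copy()
        sel = m.select(subunit="pf1.d1.b")
        coords[sel] += np.array([0.0, 0.0, 100.0])
        rep = s.fragment_census(coords, topo, m)
        assert len(rep.fragments) == 2
        assert (1, ["pf1.d1.b"]) in [(n, list(c)) for n, c in rep.fragments]
        assert rep.pathway_label == "1"

    def test_protofilament_run_erased_labels_dimer_count(self):
        # displace one full 3-dimer protofilament: the anchored component is
        # chosen via the fixed beads, the detached PF counts 3 dimers
        m = s.make_toy_lattice(3, 3, 4, seed=0)
        anchors = m.select(subunit="pf0.d0.a")[:1]
        m = m.with_fixed(anchors)
        topo = s.build_native_contacts(m, s.InteractionTable())
        coords = m.coords.copy()
        subs = m.subunit_id.astype(str)
        pf2 = np.flatnonzero(np.char.startswith(subs.astype(str), "pf2."))
        coords[pf2] += np.array([0.0, 500.0, 0.0])
        rep = s.fragment_census(coords, topo, m)
        assert rep.pathway_label == "3"

    def test_components_partition_subunits(self):
        m = s.make_toy_lattice(3, 3, 4, seed=1)
        topo = s.build_native_contacts(m, s.InteractionTable())
        coords = m.coords + np.random.default_rng(0).normal(0, 3.0, m.coords.shape)
        rep = s.fragment_census(coords, topo, m)
        all_subs = [x for _, c in rep.fragments for x in c]
        assert sorted(all_subs) == sorted(set(m.subunit_id.astype(str)))
        assert sum(n for n, _ in rep.fragments) == len(set(m.subunit_id.astype(str)))


class TestOrientationAngles:
    def _rod_model(self, direction, n=8):
        direction = np.asarray(direction, dtype=float)
        direction /= np.linalg.norm(direction)
        coords = np.outer(np.arange(n) * 3.8, direction)
        # slight transverse spread so the gyration tensor is non-degenerate
        coords[:, (0, 1)] += np.random.default_rng(0).normal(0, 0.05, (n, 2))
        tags = ["pore_loop", "NBD", "NBD", "NBD", "NBD", "NBD", "NBD", "NBD"]
        return BeadModel(coords, ["A"] * n, range(1, n + 1), ["A"] * n, tags, [False] * n)

    @pytest.mark.parametrize(
        "rod_dir,pf_axis,expected",
        [((0, 0, 1), (0, 0, 1), 0.0), ((1, 0, 0), (0, 0, 1), 90.0),
         ((1, 0, 1), (0, 0, 1), 45.0)],
    )
    def test_closed_form_angles(self, rod_dir, pf_axis, expected):
        m = self._rod_model(rod_dir)
        theta, phi, psi = s.orientation_angles(
            m.coords, m, np.asarray(pf_axis, float), loop_pair=(0, 7)
        )
        assert theta == pytest.approx(expected, abs=1.0)
        assert phi == pytest.approx(expected, abs=1.0)
        assert psi == pytest.approx(expected, abs=1.0)

    def test_joint_rotation_invariance(self):
        from scipy.spatial.transform import Rotation

        m = self._rod_model((1, 1, 0.3))
        pf = np.array([0.2, -1.0, 0.5])
        base = s.orientation_angles(m.coords, m, pf, loop_pair=(0, 7))
        R = Rotation.from_rotvec([0.4, -1.1, 0.7]).as_matrix()
        rotated = s.orientation_angles(m.coords @ R.T, m, R @ pf, loop_pair=(0, 7))
        assert np.allclose(base, rotated, atol=1e-6)

    def test_degenerate_axis_raises(self):
        m = self._rod_model((0, 0, 1))
        with pytest.raises(ValueError, match="degenerate|zero-length"):
            s.orientation_angles(m.coords, m, np.zeros(3), loop_pair=(0, 7))


class TestSpOrientation:
    def _rod(self, direction, n=10):
        d = np.asarray(direction, float)
        d /= np.linalg.norm(d)
        coords = np.outer(np.arange(n) * 3.8, d)
        coords += np.random.default_rng(1).normal(0, 0.03, coords.shape)
        return coords

    def test_rod_along_pore_axis(self):
        theta, _ = s.sp_orientation(self._rod((0, 0, 1)), np.arange(10), [10.0, 0, 0])
        assert theta == pytest.approx(0.0, abs=1.0)

    def test_rod_perpendicular(self):
        theta, _ = s.sp_orientation(self._rod((0, 1, 0)), np.arange(10), [10.0, 0, 0])
        assert theta == pytest.approx(90.0, abs=1.0)

    def test_projections_at_right_angles(self):
        _, phi = s.sp_orientation(self._rod((0, 1, 0.3)), np.arange(10), [10.0, 0, 0])
        assert phi == pytest.approx(90.0, abs=2.0)


class TestTranslocationMetrics:
    def test_direct_fraction_count(self):
        frames = np.zeros((1, 100, 3))
        frames[0, :30, 2] = 15.0
        x, line, w = translocation_metrics(frames, np.arange(100), z_trans=12.0)
        assert x[0] == pytest.approx(0.30)

    def test_waiting_time_hand_count(self):
        # residue held at z = −7.5 (inside the lumen window) for 50 frames,
        # then translocated: w = 50 × frame interval
        frames = np.zeros((60, 1, 3))
        frames[:50, 0, 2] = -7.5
        frames[50:, 0, 2] = 15.0
        x, line, w = translocation_metrics(frames, [0], frame_dt=2.0)
        assert w[0] == pytest.approx(100.0)
        assert line[-1] == 1

    def test_fully_translocated_chain(self):
        frames = np.full((3, 10, 3), 20.0)
        x, line, w = translocation_metrics(frames, np.arange(10))
        assert np.all(x == 1.0)
        assert line[-1] == 10

    def test_ratchet_is_non_decreasing(self):
        rng = np.random.default_rng(0)
        frames = np.zeros((40, 5, 3))
        frames[:, :, 2] = rng.normal(12.0, 5.0, (40, 5))
        _, line, _ = translocation_metrics(frames, np.arange(5))
        assert np.all(np.diff(line) >= 0)


class TestFreeEnergyLandscape:
    def test_single_occupied_bin(self):
        fel, _, _ = free_energy_landscape(np.zeros(10), np.zeros(10), bins=5,
                                          ranges=[[-1, 1], [-1, 1]])
        assert np.nanmin(fel) == 0.0
        assert np.sum(~np.isnan(fel)) == 1

    def test_uniform_samples_are_flat(self):
        rng = np.random.default_rng(0)
        fel, _, _ = free_energy_landscape(rng.uniform(0, 1, 200_000),
                                          rng.uniform(0, 1, 200_000), kBT=0.6, bins=5,
                                          ranges=[[0, 1], [0, 1]])
        assert np.nanmax(fel) < 0.05

    def test_gaussian_well_curvature(self):
        rng = np.random.default_rng(1)
        kbt = 0.6
        s1, s2 = 1.0, 2.0
        a = rng.normal(0, s1, 100_000)
        b = rng.normal(0, s2, 100_000)
        fel, xe, ye = free_energy_landscape(a, b, kBT=kbt, bins=41,
                                            ranges=[[-4, 4], [-8, 8]])
        xc = 0.5 * (xe[:-1] + xe[1:])
        yc = 0.5 * (ye[:-1] + ye[1:])
        # quadratic fit along each axis through the central row/column
        mid = 20
        mx = ~np.isnan(fel[:, mid]) & (np.abs(xc) < 2.5)
        curv_x = 2 * np.polyfit(xc[mx], fel[mx, mid], 2)[0]
        my = ~np.isnan(fel[mid, :]) & (np.abs(yc) < 5.0)
        curv_y = 2 * np.polyfit(yc[my], fel[mid, my], 2)[0]
        assert curv_x == pytest.approx(kbt / s1**2, rel=0.10)
        assert curv_y == pytest.approx(kbt / s2**2, rel=0.10)
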