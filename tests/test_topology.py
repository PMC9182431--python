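"""Native-contact construction, interface classification, bookkeeping."""

import numpy as np
import pytest

import sopsim as s
from sopsim.structures import BeadModel
from sopsim.topology import repulsive_pairs


def cloud_model(n=50, seed=0, scale=25.0):
    """Random bead cloud, one chain per bead (no sequence exclusions)."""
    rng = np.random.default_rng(seed)
    coords = rng.uniform(0, scale, (n, 3))
    return BeadModel(
        coords,
        [f"c{i}" for i in range(n)],
        np.ones(n, int),
        ["pf0.d0.a"] * n,
        ["none"] * n,
        np.zeros(n, bool),
    )


class TestBuildNativeContacts:
    def test_two_distant_beads_no_contacts(self):
        m = BeadModel(
            [[0.0, 0, 0], [20.0, 0, 0]], ["a", "b"], [1, 1],
            ["pf0.d0.a", "pf0.d0.b"], ["none", "none"], [False, False],
        )
        topo = s.build_native_contacts(m, s.InteractionTable())
        assert topo.n_contacts == 0

    def test_chain_sequence_separation_rule(self):
        # linear 6-bead chain at 3.8 Å spacing: only |i−j| >= 3 pairs count
        coords = np.column_stack([np.arange(6) * 3.8, np.zeros(6), np.zeros(6)])
        m = BeadModel(coords, ["a"] * 6, range(1, 7), ["pf0.d0.a"] * 6, ["none"] * 6, [False] * 6)
        topo = s.build_native_contacts(m, s.InteractionTable())
        seps = topo.contact_j - topo.contact_i
        assert seps.min() >= 3
        assert set(zip(topo.contact_i.tolist(), topo.contact_j.tolist())) == {
            (0, 3), (1, 4), (2, 5),
        }  # |i−j|=3 at 11.4 Å < 13; |i−j|>=4 beyond cutoff

    def test_matches_brute_force_enumeration(self):
        m = cloud_model()
        cutoff = 13.0
        topo = s.build_native_contacts(m, s.InteractionTable(contact_cutoff=cutoff))
        expected = {
            (i, j)
            for i in range(m.n_beads)
            for j in range(i + 1, m.n_beads)
            if np.linalg.norm(m.coords[j] - m.coords[i]) <= cutoff
        }
        assert topo.contact_pair_set() == expected

    def test_cross_link_becomes_bond_not_contact(self):
        m = BeadModel(
            [[0.0, 0, 0], [4.0, 0, 0]], ["a", "b"], [1, 1],
            ["pf0.d0.a", "pf0.d0.b"], ["none", "none"], [False, False],
        )
        topo = s.build_native_contacts(m, s.InteractionTable(), cross_links=[(0, 1)])
        assert (0, 1) in topo.bond_pair_set()
        assert topo.n_contacts == 0

    def test_overstretched_cross_link_raises(self):
        m = BeadModel(
            [[0.0, 0, 0], [10.0, 0, 0]], ["a", "b"], [1, 1],
            ["pf0.d0.a", "pf0.d0.b"], ["none", "none"], [False, False],
        )
        with pytest.raises(ValueError, match="bond 0-1"):
            s.build_native_contacts(m, s.InteractionTable(), cross_links=[(0, 1)])


@pytest.fixture(scope="module")
def lattice():
    return s.make_toy_lattice(3, 3, 4, seed=1)


@pytest.fixture(scope="module")
def mounted_topology():
    from sopsim.experiments import mount_machine_on_lattice

    lat = s.make_toy_lattice(3, 3, 4, seed=0)
    ring = s.make_toy_hexamer(with_arms=True, linker_beads=3, seed=0)
    combo = mount_machine_on_lattice(lat, ring, "pf1.d1.b")
    return s.build_native_contacts(combo, s.InteractionTable())


class TestClassifyInterface:
    def _pair(self, model, sub_a, sub_b):
        ia = model.select(subunit=sub_a)[0]
        ib = model.select(subunit=sub_b)[0]
        return ia, ib

    @pytest.mark.parametrize(
        "sub_a,sub_b,expected,eps",
        [
            ("pf2.d1.a", "pf2.d1.b", "intra_dimer", 1.9),
            ("pf2.d1.b", "pf2.d2.a", "longitudinal", 1.0),
            ("pf2.d1.b", "pf1.d1.b", "lateral", 0.9),
            ("pf2.d1.a", "pf2.d1.a", "intra_monomer", 1.9),
        ],
    )
    def test_lattice_classes_and_strengths(self, lattice, sub_a, sub_b, expected, eps):
        ia, ib = self._pair(lattice, sub_a, sub_b)
        if sub_a == sub_b:
            ib = lattice.select(subunit=sub_b)[1]
        cls = s.classify_interface(ia, ib, lattice)
        assert cls == expected
        assert s.InteractionTable().eps_for(cls) == eps

    def test_symmetry(self, lattice):
        rng = np.random.default_rng(0)
        for _ in range(50):
            i, j = rng.integers(lattice.n_beads, size=2)
            if i == j:
                continue
            assert s.classify_interface(int(i), int(j), lattice) == s.classify_interface(
                int(j), int(i), lattice
            )

    def test_machine_and_mixed_classes(self):
        ring = s.make_toy_hexamer(with_arms=True, seed=0)
        a_loop = ring.select(chain="A", domain_tag="pore_loop")[0]
        a_nbd = ring.select(chain="A", domain_tag="NBD")[0]
        b_nbd = ring.select(chain="B", domain_tag="NBD")[0]
        assert s.classify_interface(int(a_loop), int(a_nbd), ring) == "intra_protomer"
        assert s.classify_interface(int(a_nbd), int(b_nbd), ring) == "inter_protomer"

        from sopsim.experiments import mount_machine_on_lattice

        lat = s.make_toy_lattice(3, 3, 4, seed=0)
        combo = mount_machine_on_lattice(lat, ring, "pf1.d1.b")
        tail = combo.select(subunit="pf1.d1.b", domain_tag="HBD_tail")[0]
        loop = combo.select(domain_tag="pore_loop")[0]
        mit = combo.select(domain_tag="MIT")[0]
        lat_bead = combo.select(subunit="pf0.d0.a")[0]
        assert s.classify_interface(int(tail), int(loop), combo) == "protomer_e15"
        assert s.classify_interface(int(mit), int(lat_bead), combo) == "mit_mt"
        nbd = combo.select(domain_tag="NBD")[0]
        assert s.classify_interface(int(nbd), int(lat_bead), combo) == "mt_protomer"

    def test_unannotated_bead_raises(self):
        m = BeadModel(
            [[0.0, 0, 0], [5.0, 0, 0]], ["a", "b"], [1, 1],
            ["none", "pf0.d0.a"], ["none", "none"], [False, False],
        )
        with pytest.raises(ValueError, match="no subunit annotation"):
            s.classify_interface(0, 1, m)


class TestSetMitInteraction:
    def test_sweep_changes_only_mit_contacts(self, mounted_topology):
        topo = mounted_topology
        assert topo.contact_mask("mit_mt").any()
        sweep = [1.0, 1.5, 2.0, 2.5, 3.0, 3.5, 4.0]
        for eps in sweep:
            t2 = s.set_mit_interaction(topo, eps)
            assert t2.n_contacts == topo.n_contacts
            m = t2.contact_mask("mit_mt")
            assert np.all(t2.contact_eps[m] == eps)
            assert np.array_equal(t2.contact_eps[~m], topo.contact_eps[~m])

    def test_identity_when_eps_unchanged(self, mounted_topology):
        t2 = s.set_mit_interaction(mounted_topology, 1.0)
        assert np.array_equal(t2.contact_eps, mounted_topology.contact_eps)


def test_pair_partition_exhaustive_and_exclusive():
    """Δij bookkeeping: natives + repulsives + bonds/short-range = all pairs."""
    m = s.make_toy_lattice(3, 2, 3, seed=2)
    topo = s.build_native_contacts(m, s.InteractionTable())
    i2, far = repulsive_pairs(topo)
    n = m.n_beads
    chain = topo.chain_index
    eligible = sum(
        1
        for i in range(n)
        for j in range(i + 1, n)
        if not (chain[i] == chain[j] and j - i < 3) and (i, j) not in topo.bond_pair_set()
    )
    # |i−j| >= 3 (or inter-chain) pairs split exactly into native + repulsive
    assert topo.n_contacts + len(far) == eligible
    # the (i, i+2) pairs are the separate short-range repulsive term
    assert len(i2) == sum(
        1 for i in range(n - 2) if chain[i] == chain[i + 2]
    )
    native = topo.contact_pair_set()
    rep = set(map(tuple, far.tolist())) | set(map(tuple, i2.tolist()))
    assert not (native & rep)


def test_interior_monomers_have_lateral_and_longitudinal_contacts():
    m = s.make_toy_lattice(3, 3, 4, seed=4)
    topo = s.build_native_contacts(m, s.InteractionTable())
    subs = m.subunit_id.astype(str)
    cls = topo.contact_class.astype(str)
    for mono in ("pf1.d1.a", "pf1.d1.b"):
        involved = (subs[topo.contact_i] == mono) | (subs[topo.contact_j] == mono)
        assert "lateral" in set(cls[involved])
        assert "longitudinal" in set(cls[involved])


def test_topology_serialization_roundtrip(tmp_path):
    m = s.make_toy_lattice(3, 2, 3, seed=0)
    topo = s.build_native_contacts(m, s.InteractionTable())
    topo.save(tmp_path / "topo")
    back = s.SOPTopology.load(tmp_path / "topo")
    assert back.n_beads == topo.n_beads
    assert np.array_equal(back.contact_i, topo.contact_i)
    assert np.allclose(back.contact_r0, topo.contact_r0)
    assert np.array_equal(back.contact_class.astype(str), topo.contact_class.astype(str))
    assert np.array_equal(back.chain_index, topo.chain_index)


def test_interaction_table_validation():
    with pytest.raises(ValueError, match="positive"):
        s.InteractionTable(eps_h_by_class={"lateral": -1.0})
    with pytest.raises(ValueError, match="exceed sigma"):
        s.InteractionTable(contact_cutoff=2.0)
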