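import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from axoxl.ensembles import (
    Ensemble, OligomerLattice, distance_heatmap, expand_lattice,
    reinterpret_intralinks, satisfiable_by_any,
)
from axoxl.io_formats import Structure
from axoxl.network import deduplicate
from axoxl.structmap import ca_distance, map_links

from helpers import make_chain, rec


def link(ga, ra, gb, rb):
    return deduplicate([rec(ga, ra, gb, rb)])[0]


def two_member_ensemble(coords0, coords1):
    return Ensemble(label="e", members=[
        Structure(id="m0", chains=[make_chain(coords0)]),
        Structure(id="m1", chains=[make_chain(coords1)]),
    ])


CHAIN_MAP = {"G": ["A"]}


class TestHeatmap:
    def test_identical_conformations_give_constant_rows(self):
        coords = [(0, 0, 0), (10, 0, 0), (0, 25, 0)]
        ens = two_member_ensemble(coords, coords)
        links = [link("G", 1, "G", 2), link("G", 1, "G", 3)]
        hm = distance_heatmap(links, ens, CHAIN_MAP)
        assert (hm.matrix["m0"] == hm.matrix["m1"]).all()
        assert hm.min_distance.tolist() == [10.0, 25.0]

    def test_unresolved_member_cell_is_nan_min_over_rest(self):
        ens = two_member_ensemble([(0, 0, 0), (10, 0, 0)],
                                  [(0, 0, 0), None])
        hm = distance_heatmap([link("G", 1, "G", 2)], ens, CHAIN_MAP)
        assert np.isnan(hm.matrix.iloc[0]["m1"])
        assert hm.min_distance.iloc[0] == 10.0
        assert hm.best_member.iloc[0] == "m0"
        assert not hm.all_unmappable.iloc[0]

    def test_matrix_equals_per_structure_recomputation(self, rng):
        coords0 = rng.normal(scale=20, size=(15, 3))
        coords1 = rng.normal(scale=20, size=(15, 3))
        ens = two_member_ensemble(coords0, coords1)
        links = [link("G", int(i), "G", int(j))
                 for i, j in rng.integers(1, 16, size=(10, 2)) if i != j]
        hm = distance_heatmap(links, ens, CHAIN_MAP)
        for col, member in zip(("m0", "m1"), ens.members):
            mapped = map_links(links, member, CHAIN_MAP)
            for row, m in zip(hm.matrix[col], mapped):
                assert row == pytest.approx(m.distance)

    def test_adding_a_conformation_never_increases_minima(self, rng):
        coords = [rng.normal(scale=20, size=(12, 3)) for _ in range(3)]
        links = [link("G", int(i), "G", int(j))
                 for i, j in rng.integers(1, 13, size=(8, 2)) if i != j]
        ens2 = Ensemble(label="e2", members=[
            Structure(id=f"m{k}", chains=[make_chain(coords[k])])
            for k in range(2)])
        ens3 = Ensemble(label="e3", members=[
            Structure(id=f"m{k}", chains=[make_chain(coords[k])])
            for k in range(3)])
        hm2 = distance_heatmap(links, ens2, CHAIN_MAP)
        hm3 = distance_heatmap(links, ens3, CHAIN_MAP)
        assert (hm3.min_distance <= hm2.min_distance + 1e-12).all()

    def test_members_must_share_chains(self):
        with pytest.raises(ValueError, match="chains"):
            Ensemble(label="bad", members=[
                Structure(id="a", chains=[make_chain([(0, 0, 0)], "A")]),
                Structure(id="b", chains=[make_chain([(0, 0, 0)], "B")]),
            ])


class TestSatisfiableByAny:
    def test_row_satisfied_by_second_conformation(self):
        ens = two_member_ensemble([(0, 0, 0), (45, 0, 0)],
                                  [(0, 0, 0), (28, 0, 0)])
        hm = distance_heatmap([link("G", 1, "G", 2)], ens, CHAIN_MAP)
        v = satisfiable_by_any(hm, cutoff=30.0)
        assert bool(v.satisfiable.iloc[0])
        assert v.best_member.iloc[0] == "m1"

    def test_row_satisfied_nowhere(self):
        ens = two_member_ensemble([(0, 0, 0), (45, 0, 0)],
                                  [(0, 0, 0), (50, 0, 0)])
        hm = distance_heatmap([link("G", 1, "G", 2)], ens, CHAIN_MAP)
        assert not satisfiable_by_any(hm, 30.0).satisfiable.iloc[0]

    def test_equals_brute_force_min_on_random_matrices(self, rng):
        for _ in range(20):
            n_members = int(rng.integers(2, 5))
            coords = [rng.normal(scale=25, size=(10, 3))
                      for _ in range(n_members)]
            links = [link("G", int(i), "G", int(j))
                     for i, j in rng.integers(1, 11, size=(6, 2)) if i != j]
            ens = Ensemble(label="e", members=[
                Structure(id=f"m{k}", chains=[make_chain(c)])
                for k, c in enumerate(coords)])
            hm = distance_heatmap(links, ens, CHAIN_MAP)
            v = satisfiable_by_any(hm, 30.0)
            brute = hm.matrix.to_numpy()
            assert np.allclose(v.min_distance, np.nanmin(brute, axis=1))
            assert (v.satisfiable == (np.nanmin(brute, axis=1) <= 30.0)).all()


class TestLattice:
    def base(self, coords):
        return Structure(id="b", chains=[make_chain(coords)])

    def test_pure_translation_shifts_z(self):
        lat = OligomerLattice(base=self.base([(0, 0, 0), (1, 2, 3)]),
                              rotation=np.eye(3),
                              translation=np.array([0, 0, 96.0]),
                              n_copies=2)
        ex = expand_lattice(lat)
        np.testing.assert_allclose(ex.chain("A@1").get(2).ca, [1, 2, 99.0])
        np.testing.assert_allclose(ex.chain("A@0").get(2).ca, [1, 2, 3.0])

    def test_identity_transform_superposes_copies(self):
        lat = OligomerLattice(base=self.base([(0, 0, 0), (5, 0, 0)]),
                              rotation=np.eye(3),
                              translation=np.zeros(3), n_copies=3)
        ex = expand_lattice(lat)
        assert ca_distance(ex, ("A@0", 1), ("A@2", 1)) == 0.0
        # inter-copy distance equals the intramolecular one
        assert ca_distance(ex, ("A@0", 1), ("A@1", 2)) == ca_distance(
            ex, ("A@0", 1), ("A@0", 2))

    def test_rotation_translation_matches_matrix_oracle(self, rng):
        R = Rotation.from_euler("z", 40, degrees=True).as_matrix()
        t = np.array([10.0, -4.0, 7.0])
        coords = rng.normal(scale=15, size=(8, 3))
        lat = OligomerLattice(base=self.base(coords), rotation=R,
                              translation=t, n_copies=3)
        ex = expand_lattice(lat)
        for k in range(3):
            expected = coords.copy()
            for _ in range(k):
                expected = expected @ R.T + t
            np.testing.assert_allclose(
                ex.chain(f"A@{k}").ca_array(), expected, atol=1e-9)

    def test_improper_rotation_rejected(self):
        refl = np.diag([1.0, 1.0, -1.0])
        with pytest.raises(ValueError, match="proper"):
            OligomerLattice(base=self.base([(0, 0, 0)]), rotation=refl,
                            translation=np.zeros(3))


class TestReinterpret:
    def test_constructed_head_to_tail_geometry(self):
        # monomer end-to-end 120 A; copies repeat at 140 A, so the head of
        # one copy lies 20 A from the tail of the next
        coords = [(0, 0, 0), (0, 0, 120.0)]
        lat = OligomerLattice(
            base=Structure(id="b", chains=[make_chain(coords)]),
            rotation=np.eye(3), translation=np.array([0, 0, 140.0]),
            n_copies=2)
        out = reinterpret_intralinks([link("G", 1, "G", 2)], lat, CHAIN_MAP,
                                     cutoff=30.0)
        assert out.satisfied.iloc[0]
        assert out.distance.iloc[0] == pytest.approx(20.0)

    def test_identity_lattice_reduces_to_intramolecular_distance(self):
        coords = [(0, 0, 0), (0, 0, 120.0)]
        st = Structure(id="b", chains=[make_chain(coords)])
        lat = OligomerLattice(base=st, rotation=np.eye(3),
                              translation=np.zeros(3), n_copies=2)
        out = reinterpret_intralinks([link("G", 1, "G", 2)], lat, CHAIN_MAP)
        assert out.distance.iloc[0] == pytest.approx(
            ca_distance(st, ("A", 1), ("A", 2)))

    def test_min_over_copy_pairs_equals_exhaustive_enumeration(self, rng):
        R = Rotation.from_euler("x", 15, degrees=True).as_matrix()
        t = np.array([3.0, 50.0, 20.0])
        coords = rng.normal(scale=30, size=(12, 3))
        st = Structure(id="b", chains=[make_chain(coords)])
        lat = OligomerLattice(base=st, rotation=R, translation=t, n_copies=3)
        ex = expand_lattice(lat)
        links = [link("G", int(i), "G", int(j))
                 for i, j in rng.integers(1, 13, size=(6, 2)) if i != j]
        out = reinterpret_intralinks(links, lat, CHAIN_MAP)
        for row, lk in zip(out.itertuples(), links):
            (_, ra), (_, rb) = lk.end_a, lk.end_b
            brute = min(
                ca_distance(ex, (f"A@{k}", ra), (f"A@{l}", rb))
                for k in range(3) for l in range(3) if k != l)
            assert row.distance == pytest.approx(brute)
            # lattice minimum never exceeds any individual evaluation
            assert row.distance <= ca_distance(
                ex, ("A@0", ra), ("A@1", rb)) + 1e-12
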