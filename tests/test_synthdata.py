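import numpy as np
import pytest
from scipy.spatial.distance import cdist

from axoxl.network import deduplicate
from axoxl.structmap import ca_distance
from axoxl.synthdata import (
    HELIX_RISE, HELIX_TURN, HELIX_RADIUS, MIN_CLEARANCE,
    HingeSpec, SynthSpec, make_complex, make_ensemble, make_hinge_testcase,
    make_oligomer_testcase, make_structure, sample_crosslinks, task_rng,
)
from axoxl.ensembles import reinterpret_intralinks


class TestMakeStructure:
    def test_random_walk_spacing_and_clearance(self):
        st, seq = make_structure(50, "random-walk-3.8", task_rng(1, "t"))
        cas = st.chains[0].ca_array()
        steps = np.linalg.norm(np.diff(cas, axis=0), axis=1)
        assert np.all((steps > 3.7) & (steps < 3.9))
        assert len(seq) == 50
        d = cdist(cas, cas)
        np.fill_diagonal(d, np.inf)
        # non-adjacent residues honour the self-avoidance radius
        off = np.abs(np.subtract.outer(np.arange(50), np.arange(50))) > 1
        assert d[off].min() >= MIN_CLEARANCE - 1e-9

    def test_same_seed_reproduces_coordinates(self):
        a, _ = make_structure(40, "random-walk-3.8", task_rng(7, "t"))
        b, _ = make_structure(40, "random-walk-3.8", task_rng(7, "t"))
        np.testing.assert_array_equal(a.chains[0].ca_array(),
                                      b.chains[0].ca_array())

    def test_helix_end_to_end_matches_rise_formula(self):
        n = 30
        st, _ = make_structure(n, "extended-helix", task_rng(1, "t"))
        cas = st.chains[0].ca_array()
        dtheta = np.deg2rad(HELIX_TURN * (n - 1))
        chord = 2 * HELIX_RADIUS * abs(np.sin(dtheta / 2))
        expected = np.hypot(HELIX_RISE * (n - 1), chord)
        assert np.linalg.norm(cas[-1] - cas[0]) == pytest.approx(expected)


class TestMakeEnsemble:
    def st(self):
        st, _ = make_structure(30, "random-walk-3.8", task_rng(3, "e"))
        return st

    def test_zero_angle_gives_identical_members(self):
        st = self.st()
        ens = make_ensemble(st, HingeSpec(pivot_author=15, angles=(0.0,)))
        np.testing.assert_allclose(ens.members[0].chains[0].ca_array(),
                                   ens.members[1].chains[0].ca_array())

    def test_pre_pivot_coordinates_identical_across_members(self):
        st = self.st()
        ens = make_ensemble(st, HingeSpec(pivot_author=15, angles=(120.0,)))
        a = ens.members[0].chains[0]
        b = ens.members[1].chains[0]
        for num in range(1, 16):
            np.testing.assert_array_equal(a.get(num).ca, b.get(num).ca)

    def test_180_degree_displacement_is_twice_distance_to_axis(self):
        st = self.st()
        axis = np.array([0.0, 0.0, 1.0])
        hinge = HingeSpec(pivot_author=15, angles=(180.0,), axis=(0, 0, 1))
        ens = make_ensemble(st, hinge)
        pivot = st.chains[0].get(15).ca
        last = st.chains[0].residues[-1]
        moved = ens.members[1].chains[0].get(last.author_number).ca
        rel = last.ca - pivot
        radial = rel - np.dot(rel, axis) * axis
        assert np.linalg.norm(moved - last.ca) == pytest.approx(
            2 * np.linalg.norm(radial))


class TestSampleCrosslinks:
    def test_zero_false_rate_only_short_links(self):
        spec = SynthSpec(seed=4, false_rate=0.0, n_true_links=60)
        cx = make_complex(spec)
        _, truth = sample_crosslinks(cx, spec)
        assert (truth.label == "true").all()
        assert (truth.true_distance <= spec.true_max_distance).all()

    def test_pure_false_links_follow_uniform_pair_null(self):
        """With false rate 1 the link distances match the all-pair
        distance distribution (two-sample KS test on a fixed seed)."""
        from scipy.stats import ks_2samp

        spec = SynthSpec(seed=5, false_rate=1.0, n_true_links=150)
        cx = make_complex(spec)
        _, truth = sample_crosslinks(cx, spec)
        assert (truth.label == "false").all()
        entries = []
        for ch in cx.structure.chains:
            for r in ch.resolved():
                entries.append((ch.chain_id, r.author_number, r.ca))
        coords = np.array([e[2] for e in entries])
        d = cdist(coords, coords)
        iu = np.triu_indices_from(d, k=1)
        pop = d[iu]
        stat = ks_2samp(truth.true_distance, pop)
        assert stat.pvalue > 0.01

    def test_duplicates_deduplicate_to_ground_truth_unique_set(self):
        spec = SynthSpec(seed=6, duplicate_rate=0.5, n_true_links=100,
                         false_rate=0.0)
        cx = make_complex(spec)
        records, truth = sample_crosslinks(cx, spec)
        assert len(records) > len(truth)  # duplicates were injected
        links = deduplicate(records)
        truth_keys = set()
        for row in truth.itertuples():
            a = (row.protein_a, row.residue_a)
            b = (row.protein_b, row.residue_b)
            truth_keys.add((a, b) if a <= b else (b, a))
        assert {lk.key for lk in links} == truth_keys

    def test_records_report_true_distance_on_structure(self):
        spec = SynthSpec(seed=7, false_rate=0.2, n_true_links=40)
        cx = make_complex(spec)
        _, truth = sample_crosslinks(cx, spec)
        chain_of = {v: k for k, v in cx.accession_of_chain.items()}
        for row in truth.sample(10, random_state=0).itertuples():
            d = ca_distance(cx.structure,
                            (chain_of[row.protein_a], row.residue_a),
                            (chain_of[row.protein_b], row.residue_b))
            assert d == pytest.approx(row.true_distance)


class TestOligomerTestcase:
    def test_planted_links_reinterpret_as_satisfied(self):
        tc = make_oligomer_testcase(seed=8)
        out = reinterpret_intralinks(tc.planted_links, tc.lattice,
                                     tc.chain_map, cutoff=30.0)
        assert out.satisfied.all()
        assert (out.distance <= 25.0).all()

    def test_planted_links_are_extreme_in_monomer(self):
        tc = make_oligomer_testcase(seed=8)
        for lk in tc.planted_links:
            (_, ra), (_, rb) = lk.end_a, lk.end_b
            d = ca_distance(tc.base, ("A", ra), ("A", rb))
            assert d > 100.0

    def test_shuffled_negatives_drop_to_background(self):
        tc = make_oligomer_testcase(seed=8)
        out = reinterpret_intralinks(tc.negative_links, tc.lattice,
                                     tc.chain_map, cutoff=30.0)
        pos = reinterpret_intralinks(tc.planted_links, tc.lattice,
                                     tc.chain_map, cutoff=30.0)
        assert out.satisfied.mean() < pos.satisfied.mean()
        assert out.satisfied.mean() < 0.5

    def test_deterministic_under_seed(self):
        a = make_oligomer_testcase(seed=9)
        b = make_oligomer_testcase(seed=9)
        assert [lk.key for lk in a.planted_links] == [
            lk.key for lk in b.planted_links]
        np.testing.assert_array_equal(a.base.chains[0].ca_array(),
                                      b.base.chains[0].ca_array())


class TestHingeTestcase:
    def test_planted_links_attributed_to_generating_state(self):
        from axoxl.ensembles import distance_heatmap, satisfiable_by_any

        tc = make_hinge_testcase(seed=10)
        assert len(tc.links) >= 8
        hm = distance_heatmap(tc.links, tc.ensemble, tc.chain_map)
        v = satisfiable_by_any(hm, cutoff=30.0)
        assert v.satisfiable.all()
        for label, member in tc.true_member.items():
            assert v.loc[label, "best_member"] == member


def test_false_link_violation_rate_matches_pair_geometry():
    """Unfiltered classification of false links violates the 30 A cutoff
    at least as often as the brute-force all-pair geometry predicts (up to
    three binomial standard errors of sampling noise)."""
    from axoxl.orthomap import collapse_to_orthogroups
    from axoxl.structmap import SATISFIED, map_links
    from axoxl.synthdata import _all_pairs

    spec = SynthSpec(seed=21, false_rate=0.5, n_true_links=200)
    cx = make_complex(spec)
    records, truth = sample_crosslinks(cx, spec)
    collapsed, _ = collapse_to_orthogroups(records, cx.orthomap)
    links = deduplicate(collapsed)
    mapped = map_links(links, cx.structure, cx.chain_map)
    category = {m.link.key: m.category for m in mapped}
    group_of = cx.orthomap.entries

    n = viol = 0
    for row in truth[truth.label == "false"].itertuples():
        a = (group_of[row.protein_a], row.residue_a)
        b = (group_of[row.protein_b], row.residue_b)
        cat = category.get((a, b) if a <= b else (b, a))
        assert cat is not None
        n += 1
        viol += cat != SATISFIED
    _, pairs = _all_pairs(cx, spec.min_seq_separation)
    dists = np.array([p[2] for p in pairs])
    expectation = float((dists > 30.0).mean())
    se = np.sqrt(expectation * (1 - expectation) / n)
    assert viol / n >= expectation - 3 * se


def test_named_generators_are_independent():
    """Adding or reordering sub-task generators never changes another
    sub-task's stream."""
    a = task_rng(3, "alpha").normal(size=5)
    _ = task_rng(3, "beta").normal(size=100)
    b = task_rng(3, "alpha").normal(size=5)
    np.testing.assert_array_equal(a, b)
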