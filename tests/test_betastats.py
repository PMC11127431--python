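import math
from io import StringIO

import numpy as np
import pytest
from scipy import stats as sps
from skbio import DistanceMatrix, TreeNode

from diazoscope import betastats
from diazoscope.errors import InputError
from diazoscope.place import Placement

import oracles


def _tree(newick):
    return TreeNode.read(StringIO(newick), convert_underscores=False)


def _random_tree_newick(rng, leaves):
    names = list(leaves)
    rng.shuffle(names)
    parts = [f"{n}:{rng.uniform(0.05, 1.0):.4f}" for n in names]
    while len(parts) > 2:
        a = parts.pop()
        b = parts.pop()
        parts.insert(0, f"({a},{b}):{rng.uniform(0.05, 1.0):.4f}")
    return f"({parts[0]},{parts[1]});"


class TestWeightedUnifrac:
    def test_identical_distributions_are_zero(self):
        tree = _tree("((a:1,b:1):1,c:2);")
        m = {"a": 0.5, "b": 0.3, "c": 0.2}
        assert betastats.weighted_unifrac(m, dict(m), tree) == 0.0

    def test_two_leaf_star_opposite_masses(self):
        tree = _tree("(a:1,b:1);")
        d = betastats.weighted_unifrac({"a": 1.0}, {"b": 1.0}, tree)
        assert d == pytest.approx(1.0)

    def test_zero_mass_rejected(self):
        tree = _tree("(a:1,b:1);")
        with pytest.raises(InputError):
            betastats.weighted_unifrac({}, {"b": 1.0}, tree)

    def test_matches_branch_enumeration_oracle(self):
        rng = np.random.default_rng(7)
        leaves = [f"L{i}" for i in range(10)]
        for _ in range(100):
            newick = _random_tree_newick(rng, leaves)
            tree = _tree(newick)
            wa = rng.dirichlet(np.ones(10))
            wb = rng.dirichlet(np.ones(10))
            a = dict(zip(leaves, wa))
            b = dict(zip(leaves, wb))
            mine = betastats.weighted_unifrac(a, b, tree)
            ref = oracles.unifrac_bruteforce(a, b, newick)
            assert mine == pytest.approx(ref, abs=1e-12)

    def test_metric_properties_on_random_triples(self):
        rng = np.random.default_rng(8)
        leaves = [f"L{i}" for i in range(8)]
        tree = _tree(_random_tree_newick(rng, leaves))
        for _ in range(1000):
            ms = [dict(zip(leaves, rng.dirichlet(np.ones(8))))
                  for _ in range(3)]
            d01 = betastats.weighted_unifrac(ms[0], ms[1], tree)
            d10 = betastats.weighted_unifrac(ms[1], ms[0], tree)
            d12 = betastats.weighted_unifrac(ms[1], ms[2], tree)
            d02 = betastats.weighted_unifrac(ms[0], ms[2], tree)
            assert d01 == pytest.approx(d10, abs=1e-12)
            assert 0.0 <= d01 <= 1.0
            assert d02 <= d01 + d12 + 1e-9

    def test_aggregate_placements(self):
        pls = [Placement("r1", {"a": 1.0}), Placement("r2", {"b": 1.0})]
        assert betastats.aggregate_placements(pls) == {"a": 0.5, "b": 0.5}


class TestAverageMarkerDistance:
    def test_elementwise_mean_and_symmetry(self):
        ids = ["s1", "s2", "s3"]
        d1 = DistanceMatrix([[0, 1, 1], [1, 0, 1], [1, 1, 0]], ids)
        d0 = DistanceMatrix(np.zeros((3, 3)), ids)
        avg = betastats.average_marker_distance(d1, d0)
        assert avg[("s1", "s2")] == pytest.approx(0.5)
        same = betastats.average_marker_distance(d1, d1)
        np.testing.assert_allclose(same.data, d1.data)

    def test_mismatched_ids_rejected(self):
        d1 = DistanceMatrix([[0, 1], [1, 0]], ["a", "b"])
        d2 = DistanceMatrix([[0, 1], [1, 0]], ["a", "c"])
        with pytest.raises(InputError):
            betastats.average_marker_distance(d1, d2)


class TestBrunnerMunzel:
    def test_symmetric_identical_groups(self):
        r = betastats.brunner_munzel([1, 2, 3], [1, 2, 3])
        assert r.statistic == pytest.approx(0.0)
        assert r.estimate == pytest.approx(0.5)

    def test_complete_separation_falls_back_to_permutation(self):
        with pytest.warns(UserWarning, match="degenerate"):
            r = betastats.brunner_munzel([1, 2, 3], [4, 5, 6])
        assert r.estimate == 1.0
        assert r.method == "permutation"
        assert 0 < r.pvalue <= 1

    def test_estimate_reversal_sums_to_one(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=15)
        y = rng.normal(1.0, 2.0, size=20)
        a = betastats.brunner_munzel(x, y)
        b = betastats.brunner_munzel(y, x)
        assert a.estimate + b.estimate == pytest.approx(1.0)

    def test_matches_scipy_reference(self):
        rng = np.random.default_rng(1)
        for _ in range(25):
            x = rng.normal(size=12)
            y = rng.normal(0.5, 1.8, size=17)
            mine = betastats.brunner_munzel(x, y)
            ref = sps.brunnermunzel(x, y)
            assert abs(mine.statistic) == pytest.approx(abs(ref.statistic),
                                                        rel=1e-9)
            assert mine.pvalue == pytest.approx(ref.pvalue, rel=1e-9)

    def test_type_one_error_calibrated(self):
        # Gaussian null, n = 30/30, 2,000 replicates, alpha = 0.05
        rng = np.random.default_rng(2)
        rejections = 0
        n_rep = 2000
        for _ in range(n_rep):
            x = rng.normal(size=30)
            y = rng.normal(size=30)
            rejections += betastats.brunner_munzel(x, y).pvalue < 0.05
        assert 0.04 <= rejections / n_rep <= 0.065

    def test_small_groups_rejected(self):
        with pytest.raises(InputError):
            betastats.brunner_munzel([1], [2, 3])


class TestPairwiseBonferroni:
    def test_identical_groups_share_a_letter(self):
        rng = np.random.default_rng(3)
        vals = list(rng.normal(size=15))
        letters, results = betastats.pairwise_bm_bonferroni(
            {"a": vals, "b": list(vals)})
        assert set(letters["a"]) & set(letters["b"])

    def test_shifted_groups_get_distinct_letters(self):
        rng = np.random.default_rng(4)
        x = list(rng.normal(0, 1, size=20))
        y = list(rng.normal(5, 1, size=20))
        z = list(rng.normal(10, 1, size=20))
        letters, results = betastats.pairwise_bm_bonferroni(
            {"g1": x, "g2": y, "g3": z})
        assert not (set(letters["g1"]) & set(letters["g2"]))
        assert not (set(letters["g2"]) & set(letters["g3"]))

    def test_bonferroni_arithmetic(self):
        rng = np.random.default_rng(5)
        groups = {k: list(rng.normal(size=10)) for k in "abc"}
        _, results = betastats.pairwise_bm_bonferroni(groups)
        for res in results.values():
            assert res.p_adj == pytest.approx(min(1.0, 3 * res.pvalue))

    def test_undersized_group_excluded_with_warning(self):
        rng = np.random.default_rng(6)
        with pytest.warns(UserWarning, match="excluded"):
            letters, _ = betastats.pairwise_bm_bonferroni(
                {"a": list(rng.normal(size=10)),
                 "b": list(rng.normal(size=10)), "tiny": [1.0]})
        assert "tiny" not in letters


class TestPermanova:
    @staticmethod
    def _two_block_dm():
        ids = [f"s{i}" for i in range(6)]
        mat = np.ones((6, 6))
        mat[:3, :3] = 0.0
        mat[3:, 3:] = 0.0
        np.fill_diagonal(mat, 0.0)
        return DistanceMatrix(mat, ids), ["A"] * 3 + ["B"] * 3

    def test_hand_computed_two_group_instance(self):
        dm, labels = self._two_block_dm()
        res = betastats.permanova(dm, labels, n_perm=99, seed=0)
        assert res.r2 == pytest.approx(1.0)

    def test_matches_skbio_pseudo_f(self):
        from skbio.stats.distance import permanova as skbio_permanova
        rng = np.random.default_rng(9)
        n = 12
        pts = rng.normal(size=(n, 3))
        pts[: n // 2] += 1.5
        d = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))
        dm = DistanceMatrix(d, [f"s{i}" for i in range(n)])
        labels = ["A"] * (n // 2) + ["B"] * (n // 2)
        mine = betastats.permanova(dm, labels, n_perm=99, seed=1)
        ref = skbio_permanova(dm, grouping=labels, permutations=99)
        assert mine.pseudo_f == pytest.approx(ref["test statistic"], rel=1e-9)

    def test_pvalue_uniform_under_null(self):
        rng = np.random.default_rng(10)
        n = 14
        pvals = []
        for _ in range(200):
            pts = rng.normal(size=(n, 2))
            d = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))
            dm = DistanceMatrix(d, [f"s{i}" for i in range(n)])
            labels = list(rng.permutation(["A"] * 7 + ["B"] * 7))
            pvals.append(betastats.permanova(dm, labels, n_perm=199,
                                             seed=int(rng.integers(2**31))
                                             ).pvalue)
        assert sps.kstest(pvals, "uniform").pvalue > 0.01

    def test_deterministic_under_seed(self):
        dm, labels = self._two_block_dm()
        a = betastats.permanova(dm, labels, n_perm=199, seed=5)
        b = betastats.permanova(dm, labels, n_perm=199, seed=5)
        assert a == b

    def test_invariant_to_co_permutation(self):
        rng = np.random.default_rng(11)
        n = 10
        d = rng.uniform(0.2, 1.0, size=(n, n))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0)
        ids = [f"s{i}" for i in range(n)]
        labels = np.array(["A"] * 5 + ["B"] * 5)
        base = betastats.permanova(DistanceMatrix(d, ids), labels,
                                   n_perm=9, seed=0)
        perm = rng.permutation(n)
        shuffled = betastats.permanova(
            DistanceMatrix(d[np.ix_(perm, perm)], [ids[i] for i in perm]),
            labels[perm], n_perm=9, seed=0)
        assert shuffled.r2 == pytest.approx(base.r2, rel=1e-12)
        assert shuffled.pseudo_f == pytest.approx(base.pseudo_f, rel=1e-12)


class TestNmds:
    def test_planar_configuration_recovers_low_stress(self):
        rng = np.random.default_rng(12)
        pts = rng.normal(size=(9, 2))
        d = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))
        dm = DistanceMatrix(d, [f"s{i}" for i in range(9)])
        res = betastats.nmds(dm, dims=2, n_restarts=3, seed=0)
        assert res.stress < 0.01

    def test_two_samples_have_zero_stress(self):
        dm = DistanceMatrix([[0, 0.7], [0.7, 0]], ["a", "b"])
        res = betastats.nmds(dm)
        assert res.stress == 0.0

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(13)
        d = rng.uniform(0.1, 1.0, size=(7, 7))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0)
        dm = DistanceMatrix(d, [f"s{i}" for i in range(7)])
        a = betastats.nmds(dm, seed=3)
        b = betastats.nmds(dm, seed=3)
        np.testing.assert_array_equal(a.coordinates, b.coordinates)
        assert a.stress == b.stress

    def test_stress_path_non_increasing(self):
        rng = np.random.default_rng(14)
        d = rng.uniform(0.1, 1.0, size=(8, 8))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0)
        res = betastats.nmds(DistanceMatrix(d, [f"s{i}" for i in range(8)]),
                             seed=1)
        assert all(a >= b - 1e-12 for a, b in zip(res.stress_path,
                                                  res.stress_path[1:]))

class TestSpearman:
    def test_monotone_pairs(self):
        assert betastats.spearman([1, 2, 3, 4], [10, 20, 30, 40])[0] \
            == pytest.approx(1.0)
        assert betastats.spearman([1, 2, 3, 4], [5, 4, 3, 2])[0] \
            == pytest.approx(-1.0)

    def test_tied_data_matches_midrank_definition(self):
        x = [1, 2, 2, 3, 5, 5, 5]
        y = [2, 1, 4, 4, 6, 7, 7]
        rho, _ = betastats.spearman(x, y)
        rx, ry = sps.rankdata(x), sps.rankdata(y)
        expected = np.corrcoef(rx, ry)[0, 1]
        assert rho == pytest.approx(expected, rel=1e-12)

    def test_constant_vector_rejected(self):
        with pytest.raises(InputError):
            betastats.spearman([1, 1, 1], [1, 2, 3])
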