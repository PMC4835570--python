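"""Tests for standardization, UPGMA, SIMPROF delineation, PCA and screens."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays
from scipy import stats
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist, squareform

from mfsoil import classify as cl
from mfsoil import synthetic as syn


# ---------------------------------------------------------- brute-force oracle

def brute_force_upgma(d: np.ndarray):
    """Average linkage straight from the definition: inter-cluster distance is
    the mean of all cross-pair original distances. Returns merge heights and
    the merged leaf sets, independent of the Lance-Williams recursion."""
    clusters = [frozenset([i]) for i in range(d.shape[0])]
    merges = []
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(clusters, 2):
            avg = np.mean([d[i, j] for i in a for j in b])
            if best is None or avg < best[0] - 1e-15:
                best = (avg, a, b)
        avg, a, b = best
        clusters.remove(a)
        clusters.remove(b)
        clusters.append(a | b)
        merges.append((avg, a | b))
    return merges


def collect_internal(node, out=None):
    if out is None:
        out = []
    if not node.is_leaf:
        out.append(node)
        for c in node.children:
            collect_internal(c, out)
    return out


class TestStandardize:
    def test_simple_column(self):
        z = cl.standardize_variables(pd.DataFrame({"x": [1.0, 2, 3],
                                                   "y": [2.0, 4, 9]}))
        assert np.allclose(z["x"], [-1, 0, 1])

    def test_idempotence(self, rng):
        table = pd.DataFrame(rng.normal(size=(10, 4)))
        z = cl.standardize_variables(table)
        z2 = cl.standardize_variables(z)
        assert np.allclose(z, z2, atol=1e-12)

    def test_oracle_recomputation(self, rng):
        table = pd.DataFrame(rng.normal(5, 3, size=(12, 5)))
        z = cl.standardize_variables(table).to_numpy()
        assert np.allclose(z.mean(axis=0), 0, atol=1e-12)
        assert np.allclose(z.std(axis=0, ddof=1), 1, atol=1e-12)

    def test_constant_variable_named(self):
        table = pd.DataFrame({"ok": [1.0, 2], "flat": [3.0, 3.0]})
        with pytest.raises(ValueError, match="flat"):
            cl.standardize_variables(table)


class TestEuclidean:
    def test_three_four_five(self):
        d = cl.euclidean_distances(np.array([[0.0, 0], [3, 4]]))
        assert d.iloc[0, 1] == pytest.approx(5.0)
        assert d.iloc[0, 0] == 0.0

    def test_brute_force_double_loop(self, rng):
        x = rng.normal(size=(7, 3))
        d = cl.euclidean_distances(x).to_numpy()
        for i in range(7):
            for j in range(7):
                assert d[i, j] == pytest.approx(
                    np.sqrt(((x[i] - x[j]) ** 2).sum()), abs=1e-12)


class TestUpgma:
    def test_two_samples(self):
        root = cl.upgma(np.array([[0.0, 3.2], [3.2, 0.0]]))
        assert root.height == pytest.approx(3.2)
        assert root.leaves == (0, 1)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.normal(size=(6, 3))
        d = squareform(pdist(pts))
        root = cl.upgma(d)
        ours = sorted((n.height, frozenset(n.leaves))
                      for n in collect_internal(root))
        oracle = sorted((h, s) for h, s in brute_force_upgma(d))
        assert len(ours) == len(oracle)
        for (h1, s1), (h2, s2) in zip(ours, oracle):
            assert h1 == pytest.approx(h2, abs=1e-9)
            assert s1 == s2

    def test_heights_match_scipy_average_linkage(self, rng):
        pts = rng.normal(size=(10, 4))
        d = squareform(pdist(pts))
        root = cl.upgma(d)
        ours = sorted(n.height for n in collect_internal(root))
        scipy_heights = sorted(linkage(pdist(pts), method="average")[:, 2])
        assert np.allclose(ours, scipy_heights, atol=1e-9)

    def test_equilateral_tie_is_deterministic(self):
        d = np.array([[0.0, 1, 1], [1, 0, 1], [1, 1, 0]])
        root = cl.upgma(d)
        # lexicographic tie-break: leaves 0 and 1 merge first
        first = min(collect_internal(root), key=lambda n: n.height)
        assert set(first.leaves) >= {0, 1} or first.leaves == (0, 1)
        assert root.height == pytest.approx(1.0)

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError):
            cl.upgma(np.zeros((1, 1)))

    @given(arrays(np.float64, (6, 2),
                  elements=st.floats(-10, 10, allow_nan=False)))
    def test_heights_monotone_rootward(self, pts):
        d = squareform(pdist(pts))
        root = cl.upgma(d)

        def check(node):
            for c in node.children:
                assert c.height <= node.height + 1e-9
                check(c)

        check(root)


class TestSimprof:
    def test_below_three_samples_untestable(self):
        pi, p = cl.simprof(np.zeros((2, 4)))
        assert p == 1.0 and np.isnan(pi)

    def test_deterministic_per_seed(self, rng):
        z = rng.normal(size=(8, 5))
        a = cl.simprof(z, 99, 99, seed=7)
        b = cl.simprof(z, 99, 99, seed=7)
        c = cl.simprof(z, 99, 99, seed=8)
        assert a == b
        assert a != c

    def test_planted_structure_detected(self):
        # two clusters separated by 10 within-cluster SDs
        rng = np.random.default_rng(0)
        rejections = 0
        for run in range(20):
            z = np.vstack([rng.normal(0, 1, size=(5, 4)),
                           rng.normal(10, 1, size=(5, 4))])
            _, p = cl.simprof(z, 199, 199, seed=run)
            rejections += p <= 0.05
        assert rejections >= 19

    def test_p_value_grid(self, rng):
        z = rng.normal(size=(6, 4))
        _, p = cl.simprof(z, 99, 99, seed=0)
        assert 0 < p <= 1
        assert (p * 100) == pytest.approx(round(p * 100))


class TestDelineate:
    def test_homogeneous_data_mostly_one_class(self):
        rng = np.random.default_rng(42)
        single = 0
        for run in range(10):
            z = pd.DataFrame(rng.normal(size=(12, 5)))
            tree = cl.upgma(cl.euclidean_distances(z))
            dendro = cl.delineate_classes(tree, z, n_perm=199, seed=run)
            single += dendro.labels.nunique() == 1
        assert single >= 8  # test level 0.05 per tree; a rare false split is fine

    def test_four_planted_clusters_recovered(self):
        # four well-separated clusters along orthogonal directions; the
        # per-node test operates at level 0.05, so recovery is a rate, not
        # a certainty, over seeds
        from sklearn.metrics import adjusted_rand_score
        exact = 0
        for seed in range(15):
            rng = np.random.default_rng(seed)
            offsets = syn.make_class_offsets(
                ("a", "b", "c", "d"), tuple("v" * 10), 3.0, seed,
                reference_class="a")
            centers = np.vstack([offsets[k] for k in ("a", "b", "c", "d")])
            z = np.vstack([rng.normal(c, 1.0, size=(4, 10)) for c in centers])
            zdf = pd.DataFrame(z, index=[f"s{i}" for i in range(16)])
            tree = cl.upgma(cl.euclidean_distances(zdf))
            dendro = cl.delineate_classes(tree, zdf, n_perm=499, seed=seed)
            truth = np.repeat(np.arange(4), 4)
            exact += (dendro.labels.nunique() == 4
                      and adjusted_rand_score(truth, dendro.labels) == 1.0)
        assert exact >= 12

    def test_study_shaped_partition_matches_planted(self, design,
                                                    class_assignment):
        # 1/2/3/9 planted class layout recovered on average across seeds
        from sklearn.metrics import adjusted_rand_score
        aris = []
        for seed in range(10):
            comp, truth = syn.generate_classed_biogeochem(
                design, class_assignment, seed=seed, reference_class="III")
            z = cl.standardize_variables(comp)
            tree = cl.upgma(cl.euclidean_distances(z))
            dendro = cl.delineate_classes(tree, z, n_perm=999, seed=seed)
            aris.append(adjusted_rand_score([truth[c] for c in z.index],
                                            dendro.labels))
        assert np.mean(aris) >= 0.9

    def test_partition_invariant_to_column_order_and_rescaling(
            self, design, class_assignment):
        comp, _ = syn.generate_classed_biogeochem(
            design, class_assignment, seed=2, reference_class="III")
        z = cl.standardize_variables(comp)
        tree = cl.upgma(cl.euclidean_distances(z))
        base = cl.delineate_classes(tree, z, n_perm=199, seed=4).labels
        rng = np.random.default_rng(0)
        for _ in range(5):
            cols = rng.permutation(comp.columns)
            scaled = comp[cols] * rng.uniform(0.5, 20, size=len(cols))
            z2 = cl.standardize_variables(scaled)[z.columns]
            tree2 = cl.upgma(cl.euclidean_distances(z2))
            labels2 = cl.delineate_classes(tree2, z2, n_perm=199, seed=4).labels
            pd.testing.assert_series_equal(base, labels2)


class TestRankClasses:
    def test_reference_class_distance_zero(self):
        z = pd.DataFrame(np.array([[0.0, 0], [0, 0], [3, 4], [3, 4]]),
                         index=list("abcd"))
        labels = pd.Series(["I", "I", "II", "II"], index=list("abcd"))
        ranks = cl.rank_classes(labels, z, [True, True, False, False])
        assert ranks.loc["I", "distance_to_reference"] == 0.0
        assert ranks.loc["II", "distance_to_reference"] == pytest.approx(5.0)
        assert ranks.loc["I", "disturbance_rank"] == 1

    def test_offset_class_distance_is_norm(self, rng):
        ref = rng.normal(size=(4, 3))
        v = np.array([1.0, 2.0, 2.0])  # norm 3
        z = pd.DataFrame(np.vstack([ref, ref + v]))
        labels = pd.Series(["A"] * 4 + ["B"] * 4)
        ranks = cl.rank_classes(labels, z, [True] * 4 + [False] * 4)
        assert ranks.loc["B", "distance_to_reference"] == pytest.approx(3.0)

    def test_no_reference_rejected(self):
        z = pd.DataFrame(np.zeros((2, 2)))
        with pytest.raises(ValueError, match="reference"):
            cl.rank_classes(pd.Series(["A", "B"]), z, [False, False])


class TestPca:
    def test_equilibrium_radius(self, rng):
        z = cl.standardize_variables(pd.DataFrame(rng.normal(size=(15, 10))))
        res = cl.pca(z, d=2)
        assert res.equilibrium_radius == pytest.approx(np.sqrt(0.2), abs=1e-12)
        plain = cl.pca(z, d=2, sqrt_radius=False)
        assert plain.equilibrium_radius == pytest.approx(0.2)

    def test_eigenvalue_sum_equals_p(self, rng):
        z = cl.standardize_variables(pd.DataFrame(rng.normal(size=(20, 7))))
        res = cl.pca(z)
        assert res.eigenvalues.sum() == pytest.approx(7.0, abs=1e-9)

    def test_axes_match_eigh_oracle_up_to_sign(self, rng):
        z = cl.standardize_variables(pd.DataFrame(rng.normal(size=(12, 4))))
        res = cl.pca(z)
        corr = np.corrcoef(z.to_numpy(), rowvar=False)
        w, v = np.linalg.eigh(corr)
        order = np.argsort(w)[::-1]
        assert np.allclose(res.eigenvalues, w[order], atol=1e-9)
        for k in range(4):
            dot = abs(np.dot(res.loadings.to_numpy()[:, k], v[:, order[k]]))
            assert dot == pytest.approx(1.0, abs=1e-9)

    def test_kaiser_guttman_retention(self, rng):
        z = cl.standardize_variables(pd.DataFrame(rng.normal(size=(30, 6))))
        res = cl.pca(z)
        assert np.array_equal(res.retained,
                              res.eigenvalues > res.eigenvalues.mean())

    def test_too_few_variables_rejected(self):
        with pytest.raises(ValueError):
            cl.pca(pd.DataFrame({"x": [1.0, 2, 3]}))


class TestCorrelations:
    def test_perfect_linear_r_one(self):
        table = pd.DataFrame({"x": [1.0, 2, 3, 4], "y": [2.0, 4, 6, 8]})
        out = cl.correlate_variables(table, transforms={})
        assert out["pearson_r"].iloc[0] == pytest.approx(1.0)

    def test_orthogonal_pair_r_zero(self):
        table = pd.DataFrame({"x": [-1.0, 0, 1], "y": [1.0, -2, 1]})
        out = cl.correlate_variables(table, transforms={})
        assert out["pearson_r"].iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_textbook_formula_oracle(self, rng):
        x, y = rng.normal(size=10), rng.normal(size=10)
        out = cl.correlate_variables(pd.DataFrame({"x": x, "y": y}),
                                     transforms={})
        xm, ym = x - x.mean(), y - y.mean()
        r_hand = (xm * ym).sum() / np.sqrt((xm**2).sum() * (ym**2).sum())
        assert out["pearson_r"].iloc[0] == pytest.approx(r_hand, abs=1e-12)

    def test_log_transform_applied(self, rng):
        x = rng.lognormal(size=20)
        y = x ** 1.7  # log-linear relation
        out = cl.correlate_variables(
            pd.DataFrame({"h2_uptake": x, "co_uptake": y}))
        assert out["pearson_r"].iloc[0] == pytest.approx(1.0, abs=1e-9)

    def test_constant_vector_rejected(self):
        table = pd.DataFrame({"x": [1.0, 1, 1], "y": [1.0, 2, 3]})
        with pytest.raises(ValueError, match="constant"):
            cl.correlate_variables(table, transforms={})


class TestAnova:
    def test_equal_group_means_f_zero(self):
        table = pd.DataFrame({"v": [1.0, 2, 3, 0, 2, 4]})
        groups = ["a"] * 3 + ["b"] * 3  # both means exactly 2
        summary, _ = cl.anova_screen(table, groups, transforms={})
        assert summary.loc["v", "F"] == pytest.approx(0.0, abs=1e-12)
        assert summary.loc["v", "p_value"] == pytest.approx(1.0)

    def test_f_matches_hand_computation(self):
        a, b = np.array([1.0, 2, 3]), np.array([4.0, 6, 8])
        table = pd.DataFrame({"v": np.concatenate([a, b])})
        groups = ["a"] * 3 + ["b"] * 3
        summary, posthoc = cl.anova_screen(table, groups, transforms={})
        grand = np.concatenate([a, b]).mean()
        ss_between = 3 * ((a.mean() - grand) ** 2 + (b.mean() - grand) ** 2)
        ss_within = ((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()
        f_hand = (ss_between / 1) / (ss_within / 4)
        assert summary.loc["v", "F"] == pytest.approx(f_hand, abs=1e-9)
        # single pair: Bonferroni factor 1, matches plain t-test
        assert posthoc["v"].loc["a", "b"] == pytest.approx(
            stats.ttest_ind(a, b).pvalue)

    def test_null_data_rarely_significant(self, design):
        # identical treatment means: per-variable rejections near alpha
        flat = {t: syn.DEFAULT_TREATMENT_PARAMS["unlogged"]
                for t in design.treatments}
        rates = []
        for seed in range(10):
            comp = syn.generate_biogeochem(design, flat, seed=seed)
            groups = [c.split("-")[0] for c in comp.index]
            summary, _ = cl.anova_screen(comp, groups)
            rates.append(summary["significant"].mean())
        assert np.mean(rates) < 0.12

    def test_degenerate_group_rejected(self):
        table = pd.DataFrame({"v": [1.0, 2, 3]})
        with pytest.raises(ValueError, match="fewer than 2"):
            cl.anova_screen(table, ["a", "a", "b"], transforms={})


def test_roman_labels():
    assert [cl.roman(k) for k in (1, 2, 3, 4, 9)] == ["I", "II", "III", "IV", "IX"]
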