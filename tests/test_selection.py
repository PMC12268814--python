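"""Silhouette scores, robustness tests and the three selection criteria."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.metrics import silhouette_score

from plexkit.selection import (
    FeatureSelectionReport,
    SelectionConfig,
    dunn_posthoc,
    feature_mss,
    kruskal_wallis_robustness,
    mean_silhouette,
    per_target_silhouette,
    select_features,
    silhouette_terms,
    singleplex_multiplex_correlation,
)


def brute_force_silhouette(points: np.ndarray, labels: np.ndarray) -> float:
    """Independent O(N^2) loop implementation of the mean silhouette."""
    points = np.asarray(points, dtype=float)
    if points.ndim == 1:
        points = points[:, None]
    n = len(points)
    s = []
    for i in range(n):
        same = [j for j in range(n) if labels[j] == labels[i] and j != i]
        a = np.mean([np.linalg.norm(points[i] - points[j]) for j in same])
        b = min(
            np.mean([np.linalg.norm(points[i] - points[j]) for j in range(n) if labels[j] == lab])
            for lab in set(labels) - {labels[i]}
        )
        s.append((b - a) / max(a, b))
    return float(np.mean(s))


class TestMeanSilhouette:
    def test_hand_example(self):
        pts = np.array([0.0, 1.0, 2.0, 3.0])
        labels = np.array([0, 0, 1, 1])
        assert mean_silhouette(pts, labels) == pytest.approx(7.0 / 15.0, abs=1e-12)

    def test_coincident_clusters_score_near_zero(self):
        # identical point multisets: b_i ~ a_i, so MSS -> 0 as clusters grow
        # (slightly negative at finite n because a_i excludes the point itself)
        pts = np.tile([0.0, 1.0], 40)
        labels = np.repeat([0, 1], 40)
        mss = mean_silhouette(pts, labels)
        assert mss == pytest.approx(0.0, abs=0.05)
        assert mss <= 0.0

    def test_well_separated_tight_clusters_near_one(self):
        pts = np.array([0.0, 0.001, 100.0, 100.001])
        labels = np.array([0, 0, 1, 1])
        assert mean_silhouette(pts, labels) > 0.999

    def test_matches_brute_force_on_random_sets(self, rng):
        for _ in range(100):
            n = rng.integers(8, 25)
            dim = rng.integers(1, 4)
            pts = rng.normal(size=(n, dim))
            labels = rng.integers(0, 3, size=n)
            # re-draw until every cluster has >= 2 members
            while np.unique(labels, return_counts=True)[1].min() < 2 or len(set(labels)) < 2:
                labels = rng.integers(0, 3, size=n)
            assert mean_silhouette(pts, labels) == pytest.approx(
                brute_force_silhouette(pts, labels), abs=1e-10
            )

    def test_matches_sklearn(self, rng):
        pts = rng.normal(size=(60, 2))
        labels = np.repeat([0, 1, 2], 20)
        pts[labels == 1] += 3.0
        pts[labels == 2] -= 3.0
        assert mean_silhouette(pts, labels) == pytest.approx(
            silhouette_score(pts, labels), abs=1e-10
        )

    def test_invariant_to_permutation_and_relabeling(self, rng):
        pts = rng.normal(size=(30, 2))
        labels = np.repeat(["a", "b", "c"], 10)
        base = mean_silhouette(pts, labels)
        perm = rng.permutation(30)
        assert mean_silhouette(pts[perm], labels[perm]) == pytest.approx(base, abs=1e-12)
        remap = np.array([{"a": "z", "b": "y", "c": "x"}[l] for l in labels])
        assert mean_silhouette(pts, remap) == pytest.approx(base, abs=1e-12)

    def test_singleton_cluster_rejected(self):
        with pytest.raises(ValueError, match="singleton"):
            mean_silhouette(np.array([0.0, 1.0, 2.0]), np.array([0, 0, 1]))

    def test_single_cluster_rejected(self):
        with pytest.raises(ValueError):
            mean_silhouette(np.array([0.0, 1.0]), np.array([0, 0]))

    def test_terms_bounded(self, rng):
        pts = rng.normal(size=(40, 3))
        labels = rng.integers(0, 2, size=40)
        while np.unique(labels, return_counts=True)[1].min() < 2:
            labels = rng.integers(0, 2, size=40)
        terms = silhouette_terms(pts, labels)
        assert np.all(terms.s_i >= -1.0) and np.all(terms.s_i <= 1.0)
        assert -1.0 <= terms.mss <= 1.0


class TestFeatureMss:
    def test_identical_feature_scores_zero(self):
        df = pd.DataFrame({"f": np.ones(30)})
        labels = np.repeat(["t1", "t2", "t3"], 10)
        assert feature_mss(df, labels, "f") == pytest.approx(0.0, abs=1e-12)

    def test_separated_feature_approaches_one(self, rng):
        labels = np.repeat([0, 1, 2], 15)
        df = pd.DataFrame({"f": labels + rng.normal(0, 1e-6, size=45)})
        assert feature_mss(df, labels, "f") > 0.999

    def test_per_target_decomposition_consistent(self, rng):
        pts = rng.normal(size=(30, 1))
        labels = np.repeat(["a", "b", "c"], 10)
        pts[labels == "b"] += 4
        per = per_target_silhouette(pts, labels)
        overall = mean_silhouette(pts, labels)
        assert np.mean(list(per.values())) == pytest.approx(overall, abs=1e-12)


class TestKruskalWallis:
    def test_identical_groups_give_h_zero_p_one(self):
        values = np.array([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
        labels = np.array(["a"] * 3 + ["b"] * 3)
        h, p, robust = kruskal_wallis_robustness(values, labels)
        assert h == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)
        assert robust

    def test_shifted_groups_detected(self):
        values = np.array([1.0, 2.0, 3.0, 101.0, 102.0, 103.0])
        labels = np.array(["a"] * 3 + ["b"] * 3)
        _, p, robust = kruskal_wallis_robustness(values, labels, alpha=0.1)
        # exact permutation oracle at n=3+3: most extreme split has p = 2/C(6,3) = 0.1
        assert p < 0.11
        assert not robust

    def test_invariant_to_monotone_transform(self, rng):
        values = rng.normal(size=60)
        labels = np.repeat(["a", "b", "c"], 20)
        h1, p1, _ = kruskal_wallis_robustness(values, labels)
        h2, p2, _ = kruskal_wallis_robustness(np.exp(values), labels)
        assert h1 == pytest.approx(h2, abs=1e-12)
        assert p1 == pytest.approx(p2, abs=1e-12)

    def test_null_simulation_false_rejection_rate(self, rng):
        # same distribution in 7 groups: p > 0.01 should hold ~99% of the time
        robust_count = 0
        reps = 200
        for _ in range(reps):
            values = rng.normal(size=7 * 50)
            labels = np.repeat(np.arange(7), 50)
            _, _, robust = kruskal_wallis_robustness(values, labels, alpha=0.01)
            robust_count += robust
        assert robust_count / reps >= 0.95

    def test_degenerate_grouping_rejected(self):
        with pytest.raises(ValueError):
            kruskal_wallis_robustness([1.0, 2.0, 3.0], ["a", "a", "a"])
        with pytest.raises(ValueError):
            kruskal_wallis_robustness([1.0, 2.0, 3.0], ["a", "a", "b"])


class TestDunnPosthoc:
    def test_identical_groups_all_p_one(self):
        values = np.tile([1.0, 2.0, 3.0, 4.0], 3)
        labels = np.repeat(["a", "b", "c"], 4)
        mat = dunn_posthoc(values, labels)
        np.testing.assert_allclose(mat.to_numpy(), 1.0)

    def test_matrix_symmetric_unit_diagonal(self, rng):
        values = rng.normal(size=40)
        labels = rng.choice(list("abcd"), size=40)
        mat = dunn_posthoc(values, labels)
        np.testing.assert_allclose(mat.to_numpy(), mat.to_numpy().T)
        np.testing.assert_allclose(np.diag(mat.to_numpy()), 1.0)

    def test_shifted_group_flagged_in_its_pairs(self, rng):
        labels = np.repeat([f"g{i}" for i in range(7)], 15)
        values = rng.normal(size=labels.size)
        values[labels == "g3"] += 5.0
        mat = dunn_posthoc(values, labels)
        off = mat.where(~np.eye(7, dtype=bool))
        smallest = off.stack().nsmallest(6)
        assert all("g3" in pair for pair in smallest.index)


class TestSpMpCorrelation:
    @staticmethod
    def _curve_sets(rng, attenuation=0.8, jitter=0.0, n_sets=5):
        from plexkit.curve_model import AmplificationCurve, SigmoidParams, eval_sigmoid

        t = np.arange(1.0, 46.0)
        sp, mp = {}, {}
        for k in range(n_sets):
            p = SigmoidParams(fm=800 + 200 * k, fb=100.0, sc=0.5 + 0.1 * k,
                              cs=24.0 + 0.5 * k, asym=1.0 + 0.3 * k)
            factor = attenuation * (1.0 + jitter * rng.standard_normal())
            pm = SigmoidParams(fm=p.fm * factor, fb=p.fb, sc=p.sc * factor,
                               cs=p.cs, asym=p.asym)
            sp[f"set{k}"] = [
                AmplificationCurve(f"sp{k}_{i}", t, eval_sigmoid(p, t)
                                   + rng.normal(0, 2.0, t.size)) for i in range(5)
            ]
            mp[f"set{k}"] = [
                AmplificationCurve(f"mp{k}_{i}", t, eval_sigmoid(pm, t)
                                   + rng.normal(0, 2.0, t.size)) for i in range(5)
            ]
        return sp, mp

    def test_linear_attenuation_gives_high_r(self, rng):
        sp, mp = self._curve_sets(rng, attenuation=0.8, jitter=0.0)
        r, paired = singleplex_multiplex_correlation(sp, mp, "slope_ms")
        assert r > 0.99
        assert len(paired) == 5

    def test_r_matches_textbook_formula(self, rng):
        sp, mp = self._curve_sets(rng, attenuation=0.8, jitter=0.05, n_sets=6)
        r, paired = singleplex_multiplex_correlation(sp, mp, "sc")
        x, y = paired["singleplex"].to_numpy(), paired["multiplex"].to_numpy()
        manual = np.sum((x - x.mean()) * (y - y.mean())) / np.sqrt(
            np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2)
        )
        assert r == pytest.approx(manual, abs=1e-12)

    def test_missing_set_excluded_with_warning(self, rng):
        sp, mp = self._curve_sets(rng, n_sets=4)
        del mp["set3"]
        with pytest.warns(UserWarning, match="set3"):
            r, paired = singleplex_multiplex_correlation(sp, mp, "sc")
        assert len(paired) == 3

    def test_too_few_pairs_rejected(self, rng):
        sp, mp = self._curve_sets(rng, n_sets=2)
        with pytest.raises(ValueError):
            singleplex_multiplex_correlation(sp, mp, "sc")


class TestSelectFeatures:
    @staticmethod
    def _report(name, mss, kw_p=0.5, r=0.95, per_target=0.2):
        return FeatureSelectionReport(
            feature=name, mss=mss, per_target_min_silhouette=per_target,
            kw_pvalue_per_efficiency={"all": kw_p}, dunn_pairs_flagged=[],
            sp_mp_pearson_r=r,
        )

    def test_constructed_fixture_selects_expected_set(self):
        # a few strong features among many weak ones, mirroring a realistic
        # candidate field: only the strong, robust, transferable ones pass
        reports = [
            self._report("slope_ms", 0.60),
            self._report("curv_p1", 0.55),
            self._report("neg_curv_p2", 0.50),
            self._report("sc", 0.45),
            self._report("span_p", 0.58, per_target=-0.3),  # fails one target
            self._report("span_exp", 0.20),
            self._report("asym_span", 0.18),
            self._report("asym_area", 0.15),
            self._report("asym_curv", 0.12),
            self._report("fm", 0.10),
            self._report("fb", 0.02),
            self._report("asym", 0.05),
            self._report("cs", 0.08, kw_p=1e-6),  # concentration-sensitive
        ]
        selected, _ = select_features(reports, SelectionConfig(mss_ratio=2.0))
        assert selected == ["slope_ms", "curv_p1", "neg_curv_p2", "sc"]

    def test_all_identical_features_error(self):
        reports = [self._report(f"f{i}", 0.0, kw_p=1.0, r=0.0) for i in range(5)]
        with pytest.raises(ValueError, match="no feature"):
            select_features(reports)

    def test_selection_grows_as_ratio_drops(self):
        reports = [self._report(f"f{i}", 0.1 * (i + 1)) for i in range(6)]
        sizes = []
        for ratio in (1.5, 1.0, 0.0):
            sel, _ = select_features(reports, SelectionConfig(mss_ratio=ratio))
            sizes.append(len(sel))
        assert sizes == sorted(sizes)
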