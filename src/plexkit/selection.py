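"""Feature scoring and selection.

A candidate kinetic feature is kept for distance scoring only if it passes
three criteria:

1. **Separability** — its mean silhouette score (MSS) across target labels
   is well above the field of candidates (default: at least twice the
   median MSS).  The silhouette of point *i* is
   ``s_i = (b_i - a_i) / max(a_i, b_i)`` with ``a_i`` the mean Euclidean
   distance to same-target points and ``b_i`` the mean distance to the
   nearest other target; MSS is the average over all points.
2. **Concentration robustness** — a Kruskal-Wallis test across template
   concentrations fails to reject distributional equality (p above alpha,
   default 0.01) in every reaction-efficiency group; Dunn's post-hoc test
   localizes any offending concentration pairs.  Non-significance is not
   equivalence, so this gate is a pragmatic screen, not a proof.
3. **Transferability** — the feature computed on per-primer-set median
   curves correlates linearly (Pearson r at least ``r_min``, default 0.85)
   between singleplex and multiplex reaction conditions, so distances
   simulated from singleplex data remain predictive of the multiplex assay.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from statsmodels.stats.multitest import multipletests

__all__ = [
    "SilhouetteTerms",
    "FeatureSelectionReport",
    "SelectionConfig",
    "mean_silhouette",
    "silhouette_terms",
    "feature_mss",
    "per_target_silhouette",
    "kruskal_wallis_robustness",
    "dunn_posthoc",
    "singleplex_multiplex_correlation",
    "select_features",
]


@dataclass
class SilhouetteTerms:
    """Per-point silhouette decomposition."""

    n: int
    a_i: np.ndarray
    b_i: np.ndarray
    s_i: np.ndarray
    labels: np.ndarray

    @property
    def mss(self) -> float:
        return float(np.mean(self.s_i))


@dataclass
class FeatureSelectionReport:
    feature: str
    mss: float
    per_target_min_silhouette: float
    kw_pvalue_per_efficiency: dict[str, float]
    dunn_pairs_flagged: list[tuple[str, str]]
    sp_mp_pearson_r: float | None
    passed_mss: bool = False
    passed_robustness: bool = False
    passed_correlation: bool = False
    passed_consistency: bool = False

    @property
    def passed(self) -> bool:
        return (self.passed_mss and self.passed_robustness
                and self.passed_correlation and self.passed_consistency)


@dataclass
class SelectionConfig:
    alpha: float = 0.01
    r_min: float = 0.85
    mss_ratio: float = 2.0
    per_target_floor: float = 0.0
    dunn_adjust: str = "holm"


def silhouette_terms(points: np.ndarray, labels: np.ndarray) -> SilhouetteTerms:
    """Compute a_i, b_i and s_i for every point (Euclidean metric).

    ``a_i`` excludes the point itself; ``b_i`` is the minimum over other
    labels of the mean distance to that label's points.  Requires at least
    two clusters and no singleton cluster.
    """
    x = np.asarray(points, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    labels = np.asarray(labels)
    uniq, counts = np.unique(labels, return_counts=True)
    if uniq.size < 2:
        raise ValueError("need at least 2 clusters")
    if np.any(counts < 2):
        bad = uniq[counts < 2].tolist()
        raise ValueError(f"singleton cluster(s) {bad}: a_i undefined")

    d = squareform(pdist(x))
    n = x.shape[0]
    # mean distance from every point to every cluster
    cluster_means = np.empty((n, uniq.size))
    for j, lab in enumerate(uniq):
        mask = labels == lab
        cluster_means[:, j] = d[:, mask].mean(axis=1)
    own = np.array([np.where(uniq == lab)[0][0] for lab in labels])
    counts_own = counts[own]
    # a_i: same-cluster mean excluding self (distance to self is 0)
    a_i = cluster_means[np.arange(n), own] * counts_own / (counts_own - 1)
    other = cluster_means.copy()
    other[np.arange(n), own] = np.inf
    b_i = other.min(axis=1)
    denom = np.maximum(a_i, b_i)
    s_i = np.where(denom == 0, 0.0, (b_i - a_i) / np.where(denom == 0, 1.0, denom))
    return SilhouetteTerms(n=n, a_i=a_i, b_i=b_i, s_i=s_i, labels=labels)


def mean_silhouette(points: np.ndarray, labels: np.ndarray) -> float:
    """Mean silhouette score (MSS) in [-1, 1]."""
    return silhouette_terms(points, labels).mss


def feature_mss(feature_matrix: pd.DataFrame, target_labels, feature_name: str) -> float:
    """MSS of a single feature column grouped by target label."""
    col = feature_matrix[feature_name].to_numpy(dtype=float)
    if not np.all(np.isfinite(col)):
        raise ValueError(f"feature {feature_name!r} contains non-finite values")
    return mean_silhouette(col[:, None], np.asarray(target_labels))


def per_target_silhouette(points: np.ndarray, labels: np.ndarray) -> dict:
    """Mean silhouette per target; the minimum flags targets a feature fails."""
    terms = silhouette_terms(points, labels)
    return {
        lab: float(np.mean(terms.s_i[terms.labels == lab]))
        for lab in np.unique(terms.labels)
    }


def kruskal_wallis_robustness(values, group_labels, alpha: float = 0.01):
    """Kruskal-Wallis H across groups; robust means p > alpha.

    Returns ``(H, p, robust)``.  Rank-based with tie correction
    (chi-squared reference with groups-1 df).  All-identical values are a
    degenerate all-tied case and return H=0, p=1.
    """
    values = np.asarray(values, dtype=float)
    group_labels = np.asarray(group_labels)
    groups = [values[group_labels == g] for g in np.unique(group_labels)]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 observations each")
    if np.all(values == values[0]):
        return 0.0, 1.0, True
    h, p = stats.kruskal(*groups)
    return float(h), float(p), bool(p > alpha)


def dunn_posthoc(values, group_labels, adjust: str = "holm") -> pd.DataFrame:
    """Dunn's pairwise post-hoc test after Kruskal-Wallis.

    Pairwise z-tests on mean ranks with tie correction, two-sided normal
    p-values, adjusted for multiple comparisons (default Holm step-down).
    Returns a symmetric p-value matrix with unit diagonal, indexed by group.
    """
    values = np.asarray(values, dtype=float)
    group_labels = np.asarray(group_labels)
    uniq = np.unique(group_labels)
    if uniq.size < 2:
        raise ValueError("need >= 2 groups")
    n = values.size
    ranks = stats.rankdata(values)
    mean_ranks = {g: ranks[group_labels == g].mean() for g in uniq}
    sizes = {g: int((group_labels == g).sum()) for g in uniq}
    _, tie_counts = np.unique(values, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    var_base = n * (n + 1) / 12.0 - tie_term / (12.0 * (n - 1))

    pairs = [(uniq[i], uniq[j]) for i in range(uniq.size) for j in range(i + 1, uniq.size)]
    raw = []
    for g1, g2 in pairs:
        se = np.sqrt(var_base * (1.0 / sizes[g1] + 1.0 / sizes[g2]))
        z = 0.0 if se == 0 else (mean_ranks[g1] - mean_ranks[g2]) / se
        raw.append(2.0 * stats.norm.sf(abs(z)))
    if adjust:
        adj = multipletests(raw, method=adjust)[1]
    else:
        adj = np.asarray(raw)

    mat = pd.DataFrame(np.ones((uniq.size, uniq.size)), index=uniq, columns=uniq)
    for (g1, g2), p in zip(pairs, adj):
        mat.loc[g1, g2] = mat.loc[g2, g1] = p
    return mat


def _median_curve_feature(curves: list, feature_name: str, feature_config=None) -> float:
    """Feature value of the per-cycle median curve of a set of curves."""
    from .curve_model import AmplificationCurve, fit_curve
    from .features import extract_features

    rows = pd.concat(
        [pd.DataFrame({"cycle": c.cycles, "fluorescence": c.fluorescence}) for c in curves]
    )
    med = rows.groupby("cycle")["fluorescence"].median()
    median_curve = AmplificationCurve(
        curve_id="__median__", cycles=med.index.to_numpy(), fluorescence=med.to_numpy()
    )
    fit = fit_curve(median_curve)
    if not fit.converged:
        raise RuntimeError("median-curve fit did not converge")
    return extract_features(fit.params, feature_config)[feature_name]


def singleplex_multiplex_correlation(
    singleplex_by_set: dict[str, list],
    multiplex_by_set: dict[str, list],
    feature_name: str,
    feature_config=None,
) -> tuple[float, pd.DataFrame]:
    """Pearson r between singleplex and multiplex median-curve features.

    For each primer set present in both conditions, the feature is computed
    on the per-cycle median curve of that set's curves in each condition.
    Primer sets missing in one condition are excluded with a warning; fewer
    than three pairs is an error.
    """
    common = sorted(set(singleplex_by_set) & set(multiplex_by_set))
    dropped = sorted(set(singleplex_by_set) ^ set(multiplex_by_set))
    if dropped:
        warnings.warn(f"primer set(s) missing in one condition, excluded: {dropped}")
    if len(common) < 3:
        raise ValueError(f"need >= 3 primer sets in both conditions, got {len(common)}")
    sp = [_median_curve_feature(singleplex_by_set[k], feature_name, feature_config) for k in common]
    mp = [_median_curve_feature(multiplex_by_set[k], feature_name, feature_config) for k in common]
    r, _ = stats.pearsonr(sp, mp)
    paired = pd.DataFrame({"primer_set": common, "singleplex": sp, "multiplex": mp})
    return float(r), paired


def select_features(
    reports: list[FeatureSelectionReport],
    config: SelectionConfig | None = None,
) -> tuple[list[str], list[FeatureSelectionReport]]:
    """Apply all three criteria plus the per-target consistency floor.

    A feature is selected iff its MSS is at least ``mss_ratio`` times the
    median MSS of all candidates, it is concentration-robust in every
    efficiency group, its singleplex-multiplex r reaches ``r_min``, and its
    worst per-target mean silhouette stays above ``per_target_floor``.
    The selected list is ordered by descending MSS (deterministic; ties by
    feature name).  An empty selection raises with advice.
    """
    config = config or SelectionConfig()
    median_mss = float(np.median([r.mss for r in reports]))
    for rep in reports:
        rep.passed_mss = rep.mss >= config.mss_ratio * median_mss
        rep.passed_robustness = all(
            p > config.alpha for p in rep.kw_pvalue_per_efficiency.values()
        )
        rep.passed_correlation = (
            rep.sp_mp_pearson_r is not None and rep.sp_mp_pearson_r >= config.r_min
        )
        rep.passed_consistency = rep.per_target_min_silhouette >= config.per_target_floor
    selected = sorted(
        (r for r in reports if r.passed),
        key=lambda r: (-r.mss, r.feature),
    )
    if not selected:
        raise ValueError(
            "no feature passed all selection gates; consider relaxing mss_ratio, "
            "alpha, r_min or per_target_floor"
        )
    return [r.feature for r in selected], reports
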