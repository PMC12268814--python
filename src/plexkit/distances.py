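"""Candidate primer-mix scoring: simulated multiplexes, distances, ranking.

A candidate assay assigns one primer set to each target.  Its multiplex
behaviour is simulated from singleplex data by pooling each assigned
primer set's feature vectors as that target's cluster (the kinetic
information of a well-chosen primer set transfers from singleplex to
multiplex up to a linear attenuation, which standardization absorbs).

Two inter-target distances are available:

* **median** — Euclidean distance between per-feature medians of the two
  clusters; blind to within-target spread.
* **clustering** — the mean silhouette score of the two clusters, in
  [-1, 1]; penalizes overlapping or high-variance clusters even when the
  medians sit far apart.

Each candidate receives an Average Distance Score (ADS, mean over all
target pairs) and a Minimum Distance Score (MDS, the worst pair).  Three
strategies are supported: S1 (the original single-feature approach — the
slope coefficient ``sc`` with median distances), S2 (selected feature
set, median distances) and S3 (selected feature set, clustering
distances).  Features are standardized ONCE over the pooled singleplex
dataset before any candidate is scored; this global affine map makes
scores comparable across candidates and leaves S1's ranking identical to
ranking on raw ``sc``, so S1 coincides exactly with S2 restricted to
``[sc]``.  Candidates are ranked by the sum of their ADS rank and MDS
rank; equal sums share a rank, so simultaneous third places are possible.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .features import DEFAULT_SELECTED_FEATURES, standardize_features
from .selection import mean_silhouette

__all__ = [
    "PrimerMixCandidate",
    "AssayScore",
    "StrategyConfig",
    "enumerate_candidates",
    "simulate_multiplex",
    "median_distance",
    "clustering_distance",
    "standardize_pool",
    "score_candidate",
    "rank_candidates",
    "distance_map",
]


@dataclass(frozen=True)
class PrimerMixCandidate:
    mix_id: str
    assignment: tuple[tuple[str, str], ...]  # ((target, primer_set), ...)

    @property
    def as_dict(self) -> dict[str, str]:
        return dict(self.assignment)

    def __post_init__(self) -> None:
        targets = [t for t, _ in self.assignment]
        if len(targets) != len(set(targets)):
            raise ValueError(f"{self.mix_id}: a target appears more than once")


@dataclass
class AssayScore:
    mix_id: str
    strategy: str
    ads: float
    mds: float
    rank: int | None = None

    def __post_init__(self) -> None:
        if self.mds > self.ads + 1e-12:
            raise ValueError(f"{self.mix_id}: MDS {self.mds} exceeds ADS {self.ads}")


@dataclass
class StrategyConfig:
    strategy: str = "S3"
    feature_set: tuple[str, ...] = DEFAULT_SELECTED_FEATURES
    distance_kind: str = "clustering"

    def __post_init__(self) -> None:
        if self.strategy not in ("S1", "S2", "S3"):
            raise ValueError(f"unknown strategy {self.strategy!r}")
        if self.strategy == "S1":
            self.feature_set = ("sc",)
            self.distance_kind = "median"
        elif self.strategy == "S2":
            self.distance_kind = "median"
        elif self.strategy == "S3":
            self.distance_kind = "clustering"
        if self.distance_kind not in ("median", "clustering"):
            raise ValueError(f"unknown distance kind {self.distance_kind!r}")


def enumerate_candidates(
    targets: list[str], primer_sets: dict[str, list[str]]
) -> list[PrimerMixCandidate]:
    """Full Cartesian product of per-target primer-set choices.

    Deterministic order (targets as given, primer sets as listed); mix ids
    are assigned sequentially as ``PM<n_targets>.<k>`` starting at 1.
    """
    for t in targets:
        if not primer_sets.get(t):
            raise ValueError(f"target {t!r} has no candidate primer set")
    combos = itertools.product(*(primer_sets[t] for t in targets))
    return [
        PrimerMixCandidate(
            mix_id=f"PM{len(targets)}.{k}",
            assignment=tuple(zip(targets, combo)),
        )
        for k, combo in enumerate(combos, start=1)
    ]


def simulate_multiplex(
    candidate: PrimerMixCandidate, singleplex_features: pd.DataFrame
) -> pd.DataFrame:
    """Pool singleplex feature vectors into one simulated multiplex dataset.

    ``singleplex_features`` must carry ``target`` and ``primer_set``
    columns; rows matching each (target, assigned primer set) pair become
    that target's cluster.  No resampling, no trace mixing.
    """
    parts = []
    for target, primer_set in candidate.assignment:
        rows = singleplex_features[
            (singleplex_features["target"] == target)
            & (singleplex_features["primer_set"] == primer_set)
        ]
        if rows.empty:
            raise ValueError(
                f"{candidate.mix_id}: no singleplex curves for target {target!r} "
                f"with primer set {primer_set!r}"
            )
        parts.append(rows)
    return pd.concat(parts, ignore_index=True)


def median_distance(cluster_a: np.ndarray, cluster_b: np.ndarray) -> float:
    """Euclidean distance between per-feature medians of two clusters."""
    a = np.atleast_2d(np.asarray(cluster_a, dtype=float).T).T
    b = np.atleast_2d(np.asarray(cluster_b, dtype=float).T).T
    if a.shape[1] != b.shape[1]:
        raise ValueError(f"feature dimension mismatch: {a.shape[1]} vs {b.shape[1]}")
    return float(np.linalg.norm(np.median(a, axis=0) - np.median(b, axis=0)))


def clustering_distance(cluster_a: np.ndarray, cluster_b: np.ndarray) -> float:
    """Mean silhouette score of the two clusters; in [-1, 1]."""
    a = np.atleast_2d(np.asarray(cluster_a, dtype=float).T).T
    b = np.atleast_2d(np.asarray(cluster_b, dtype=float).T).T
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError("clustering distance needs >= 2 points per cluster")
    points = np.vstack([a, b])
    labels = np.array([0] * a.shape[0] + [1] * b.shape[0])
    return mean_silhouette(points, labels)


def standardize_pool(features: pd.DataFrame, feature_set) -> pd.DataFrame:
    """Standardize the pooled feature table once, before candidate scoring.

    Returns a copy of ``features`` with the columns in ``feature_set``
    replaced by their standardized values (mean 0, population std 1 over
    the whole pool).
    """
    out = features.copy()
    std_cols, _, _ = standardize_features(features[list(feature_set)].astype(float))
    out[list(feature_set)] = std_cols
    return out


def score_candidate(
    dataset: pd.DataFrame, config: StrategyConfig, candidate_id: str = ""
) -> AssayScore:
    """ADS and MDS over all target pairs of one simulated multiplex dataset.

    The dataset is expected to be standardized already (see
    :func:`standardize_pool`); distances are computed as-is on the
    configured feature columns.
    """
    targets = sorted(dataset["target"].unique())
    if len(targets) < 2:
        raise ValueError("need >= 2 targets to score a candidate")
    x = dataset[list(config.feature_set)].astype(float).to_numpy()
    labels = dataset["target"].to_numpy()
    dist = median_distance if config.distance_kind == "median" else clustering_distance
    pair_d = [
        dist(x[labels == t1], x[labels == t2])
        for t1, t2 in itertools.combinations(targets, 2)
    ]
    return AssayScore(
        mix_id=candidate_id,
        strategy=config.strategy,
        ads=float(np.mean(pair_d)),
        mds=float(np.min(pair_d)),
    )


def rank_candidates(scores: list[AssayScore]) -> list[AssayScore]:
    """Rank by ascending sum of (descending-ADS rank) + (descending-MDS rank).

    Equal rank sums share a rank ("min" convention), so two candidates can
    occupy third place simultaneously.  Listing order is (rank, mix_id).
    """
    if len({s.strategy for s in scores}) > 1:
        raise ValueError("cannot rank scores from mixed strategies")
    ads = np.array([s.ads for s in scores])
    mds = np.array([s.mds for s in scores])
    rank_sum = rankdata(-ads, method="min") + rankdata(-mds, method="min")
    final = rankdata(rank_sum, method="min")
    for s, r in zip(scores, final):
        s.rank = int(r)
    return sorted(scores, key=lambda s: (s.rank, s.mix_id))


def distance_map(
    scores: list[AssayScore], accuracies: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Tidy table of (mix_id, strategy, ads, mds, rank[, accuracy]) for plotting."""
    table = pd.DataFrame(
        {
            "mix_id": [s.mix_id for s in scores],
            "strategy": [s.strategy for s in scores],
            "ads": [s.ads for s in scores],
            "mds": [s.mds for s in scores],
            "rank": [s.rank for s in scores],
        }
    )
    if accuracies is not None:
        table = table.merge(accuracies[["mix_id", "accuracy"]], on="mix_id", how="left")
    return table
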