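"""End-to-end pipeline: fit -> filter -> features -> select -> score -> rank -> classify.

Every stage writes its artifact to the output directory so runs are
resumable and auditable; with a fixed seed the whole run is reproducible
byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import aca, distances, io, preprocessing, selection, synthetic
from .curve_model import AmplificationCurve, FitConfig, FitResult, fit_curve
from .features import FeatureConfig, extract_features
from .preprocessing import FilterConfig
from .selection import SelectionConfig

logger = logging.getLogger("plexkit")

__all__ = ["RunConfig", "run_pipeline", "fit_all", "build_feature_table"]


def _strict(cls, data: dict, what: str):
    allowed = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - allowed
    if unknown:
        raise ValueError(f"unknown key(s) in {what}: {sorted(unknown)}")
    for key in ("selected_features", "feature_set"):
        if key in data and isinstance(data[key], list):
            data[key] = tuple(data[key])
    return cls(**data)


@dataclass
class RunConfig:
    """Fully YAML-serializable pipeline configuration; unknown keys rejected."""

    output_dir: str = "plexkit_out"
    curves: str | None = None
    metadata: str | None = None
    seed: int = 0
    log_level: str = "INFO"
    synth: dict | None = None  # {"preset": "7plex", "n_curves": int, "contamination": {...}}
    fit: FitConfig = field(default_factory=FitConfig)
    filter: FilterConfig = field(default_factory=FilterConfig)
    features: FeatureConfig = field(default_factory=FeatureConfig)
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    strategy: distances.StrategyConfig = field(default_factory=distances.StrategyConfig)
    classifier: aca.ClassifierConfig = field(default_factory=aca.ClassifierConfig)
    cv_folds: int = 30

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data)
        sections = {
            "fit": FitConfig,
            "filter": FilterConfig,
            "features": FeatureConfig,
            "selection": SelectionConfig,
            "strategy": distances.StrategyConfig,
            "classifier": aca.ClassifierConfig,
        }
        for name, section_cls in sections.items():
            if name in data and isinstance(data[name], dict):
                data[name] = _strict(section_cls, data[name], name)
        return _strict(cls, data, "run config")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


def fit_all(curves: list[AmplificationCurve], config: FitConfig | None = None) -> dict[str, FitResult]:
    return {c.curve_id: fit_curve(c, config) for c in curves}


def build_feature_table(
    curves: list[AmplificationCurve],
    fits: dict[str, FitResult],
    config: FeatureConfig | None = None,
) -> pd.DataFrame:
    """One row per converged curve: 13 features + a1/a2 + metadata columns."""
    rows = []
    for curve in curves:
        fit = fits[curve.curve_id]
        if not fit.converged:
            continue
        feats = extract_features(fit.params, config)
        feats.update(
            curve_id=curve.curve_id,
            target=curve.target,
            primer_set=curve.primer_set,
            concentration=curve.concentration,
            panel_id=curve.panel_id,
            reaction_type=curve.reaction_type,
        )
        rows.append(feats)
    return pd.DataFrame(rows)


def _stage(name: str):
    logger.info("stage: %s", name)
    return time.perf_counter()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full workflow; returns the in-memory artifacts.

    Stages: synthesize/load -> fit -> filter -> features -> feature scoring
    -> candidate enumeration -> simulated-multiplex scoring -> ranking ->
    ACA evaluation of the top-ranked candidate (k-fold and LOCO).
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=config.log_level)

    t0 = _stage("input")
    if config.synth is not None:
        preset = config.synth.get("preset", "7plex")
        if preset != "7plex":
            raise ValueError(f"unknown preset {preset!r}")
        scenario = synthetic.preset_7plex(
            seed=config.seed, n_curves=int(config.synth.get("n_curves", 10))
        )
        if "contamination" in config.synth:
            scenario.contamination = dict(config.synth["contamination"])
        curves, meta = synthetic.generate_singleplex(scenario)
        cont, cont_meta = synthetic.generate_contaminants(scenario)
        curves += cont
        meta = pd.concat([meta, cont_meta], ignore_index=True)
        io.write_curves(curves, out / "curves.csv")
        meta.to_csv(out / "metadata.csv", index=False)
    elif config.curves is not None:
        curves = io.read_curves(config.curves, config.metadata)
    else:
        raise ValueError("config needs either `synth` or `curves`")
    logger.info("input: %d curves (%.2fs)", len(curves), time.perf_counter() - t0)

    t0 = _stage("fit")
    try:
        fits = fit_all(curves, config.fit)
    except Exception as exc:  # pragma: no cover - stage context for the operator
        raise RuntimeError(f"stage 'fit' failed: {exc}") from exc
    io.write_fits(fits, out / "fits.csv")
    logger.info("fit: done (%.2fs)", time.perf_counter() - t0)

    t0 = _stage("filter")
    kept, report = preprocessing.filter_curves(curves, fits, config.filter)
    io.write_filter_report(report, out / "filter_report.csv")
    logger.info("filter: kept %d/%d (%.2fs)", report.n_kept, report.n_input,
                time.perf_counter() - t0)

    t0 = _stage("features")
    features_df = build_feature_table(kept, fits, config.features)
    features_df.to_csv(out / "features.csv", index=False)
    logger.info("features: %d rows (%.2fs)", len(features_df), time.perf_counter() - t0)

    sp = features_df[features_df["reaction_type"] == "singleplex"].reset_index(drop=True)
    if sp.empty:
        raise RuntimeError("stage 'features': no singleplex curves survived filtering")

    t0 = _stage("feature scoring")
    from .features import FEATURE_NAMES

    score_rows = []
    for name in FEATURE_NAMES:
        mss = selection.feature_mss(sp, sp["target"], name)
        _, kw_p, robust = selection.kruskal_wallis_robustness(
            sp[name].to_numpy(), sp["concentration"].to_numpy(), config.selection.alpha
        )
        per_t = selection.per_target_silhouette(
            sp[name].to_numpy()[:, None], sp["target"].to_numpy()
        )
        score_rows.append(
            {"feature": name, "mss": mss, "kw_pvalue": kw_p,
             "robust": robust, "per_target_min_silhouette": min(per_t.values())}
        )
    feature_scores = pd.DataFrame(score_rows)
    feature_scores.to_csv(out / "feature_scores.csv", index=False)
    logger.info("feature scoring: done (%.2fs)", time.perf_counter() - t0)

    t0 = _stage("rank")
    targets = sorted(sp["target"].unique())
    primer_sets = {
        t: sorted(sp.loc[sp["target"] == t, "primer_set"].unique()) for t in targets
    }
    candidates = distances.enumerate_candidates(targets, primer_sets)
    sp_std = distances.standardize_pool(sp, config.strategy.feature_set)
    scores = []
    for cand in candidates:
        dataset = distances.simulate_multiplex(cand, sp_std)
        scores.append(distances.score_candidate(dataset, config.strategy, cand.mix_id))
    ranked = distances.rank_candidates(scores)
    dmap = distances.distance_map(ranked)
    dmap.to_csv(out / "rankings.csv", index=False)
    logger.info("rank: %d candidates (%.2fs)", len(ranked), time.perf_counter() - t0)

    t0 = _stage("classify")
    top = ranked[0]
    top_candidate = next(c for c in candidates if c.mix_id == top.mix_id)
    dataset = distances.simulate_multiplex(top_candidate, sp)
    x = dataset[list(config.strategy.feature_set or config.features.selected_features)]
    y = dataset["target"].to_numpy()
    class_counts = pd.Series(y).value_counts()
    k = min(config.cv_folds, int(class_counts.min()))
    cv_report = aca.cross_validate(x.to_numpy(), y, k=k, seed=config.seed,
                                   config=config.classifier)
    loco_report = aca.loco_evaluate(
        x.to_numpy(), y, dataset["concentration"].to_numpy(),
        seed=config.seed, config=config.classifier,
    )
    cv_report.confusion.to_csv(out / "confusion_kfold.csv")
    loco_report.confusion.to_csv(out / "confusion_loco.csv")
    summary = pd.DataFrame(
        [
            {"scheme": "kfold", "mix_id": top.mix_id, "accuracy": cv_report.accuracy,
             "folds": k, "seed": config.seed, "embedding_mss": cv_report.embedding_mss},
            {"scheme": "loco", "mix_id": top.mix_id, "accuracy": loco_report.accuracy,
             "folds": len(loco_report.per_fold_accuracies), "seed": config.seed,
             "embedding_mss": loco_report.embedding_mss},
        ]
    )
    summary.to_csv(out / "classification_summary.csv", index=False)
    logger.info("classify: kfold %.3f, loco %.3f (%.2fs)",
                cv_report.accuracy, loco_report.accuracy, time.perf_counter() - t0)

    return {
        "curves": curves,
        "fits": fits,
        "filter_report": report,
        "features": features_df,
        "feature_scores": feature_scores,
        "candidates": candidates,
        "rankings": dmap,
        "cv_report": cv_report,
        "loco_report": loco_report,
    }
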