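"""End-to-end orchestration: simulate → featurize → split → resample →
train → calibrate → evaluate → importance → (optional) selection →
taxonomy, with provenance-stamped artifacts."""

from __future__ import annotations

import hashlib
import json
import logging
import time
from contextlib import contextmanager
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import io as lio
from .classifier import CalibratedClassifier, classify, save_model
from .config import PipelineConfig
from .evaluation import (
    SelectionLadder,
    TrainingRecipe,
    compute_metrics,
    feature_correlation,
    forward_selection,
    permutation_importance,
    wbt_threshold_classifier,
)
from .features import FEATURE_NAMES
from .sampling import SplitAssignment, temporal_split
from .synthetic_data import SyntheticCorpus, generate_corpus
from .taxonomy import taxonomy_table

__all__ = ["PipelineResult", "run_pipeline"]

log = logging.getLogger("lethalheat.pipeline")


@contextmanager
def _stage(name: str, **counts):
    t0 = time.perf_counter()
    log.info("stage=%s status=start %s", name,
             " ".join(f"{k}={v}" for k, v in counts.items()))
    try:
        yield
    except Exception as exc:
        log.error("stage=%s status=failed error=%r", name, exc)
        raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
    log.info("stage=%s status=done elapsed_s=%.2f", name, time.perf_counter() - t0)


@dataclass
class PipelineResult:
    config: PipelineConfig
    corpus: SyntheticCorpus
    split: SplitAssignment
    classifier: CalibratedClassifier
    metrics: dict
    importance: pd.DataFrame
    correlation: pd.DataFrame
    taxonomy: pd.DataFrame
    ladder: SelectionLadder | None = None

    @property
    def test_f1(self) -> float:
        return self.metrics["model"]["test"]["f1"]


def _config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(config.model_dump(mode="json"), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(config: PipelineConfig, out_dir: str | Path | None = None) -> PipelineResult:
    """Execute the full analysis on a synthetic corpus.

    When ``out_dir`` is given, every artifact is written there:
    series/demographics/events/features/split CSVs, the serialized model,
    metrics.json, importance.csv, correlation.csv, taxonomy.csv, an
    optional ladder.csv, and provenance.yaml (config hash + seeds).
    """
    cfg = config
    seed = cfg.seed

    with _stage("simulate", cities=cfg.generator.n_cities, years=cfg.generator.years):
        corpus = generate_corpus(
            cfg.generator.weather_params(seed),
            cfg.mechanism.mechanism(seed),
            percentile=cfg.extraction.percentile,
            min_duration=cfg.extraction.min_duration,
            adaptive_n=cfg.extraction.adaptive_n,
            m=cfg.extraction.m,
            min_history_years=cfg.extraction.min_history_years,
            cities_per_country=cfg.generator.cities_per_country,
            start_year=cfg.generator.start_year,
        )
    events_df = corpus.events_frame()
    feats = corpus.features
    X = feats[list(FEATURE_NAMES)]
    y = feats["lethal"]

    with _stage("split", events=len(events_df)):
        split = temporal_split(
            events_df,
            test_frac=cfg.split.test_frac,
            val_frac=cfg.split.val_frac,
            region_key=cfg.split.region_key,
            seed=seed,
        )
    part = split.assignment
    idx_train = part.index[part == "train"]
    idx_val = part.index[part == "validation"]
    idx_test = part.index[part == "test"]

    recipe = TrainingRecipe(
        X_train=X.loc[idx_train],
        y_train=y.loc[idx_train],
        X_val=X.loc[idx_val],
        y_val=y.loc[idx_val],
        resample=cfg.resample.spec(seed),
        hyperparams=cfg.classifier.hyperparams(),
        decision_threshold=cfg.classifier.decision_threshold,
        seed=seed,
    )
    with _stage("train", train=len(idx_train), val=len(idx_val)):
        clf = recipe.train()

    with _stage("evaluate", test=len(idx_test)):
        metrics: dict = {"model": {}, "wbt_baselines": {}}
        for name, idx in (("validation", idx_val), ("test", idx_test)):
            pred = classify(clf, X.loc[idx])
            metrics["model"][name] = compute_metrics(y.loc[idx], pred).to_dict()
        test_events = events_df.set_index("event_id").loc[idx_test].reset_index()
        for thr in cfg.wbt_baseline_thresholds:
            _, rep = wbt_threshold_classifier(test_events, thr)
            metrics["wbt_baselines"][f"{thr:g}C"] = rep.to_dict()
        prevalence = float(y.mean())
        metrics["corpus"] = {
            "n_events": int(len(y)),
            "n_lethal": int(y.sum()),
            "prevalence": prevalence,
        }

    with _stage("importance", repeats=cfg.importance_repeats):
        importance = permutation_importance(
            clf, X.loc[idx_test], y.loc[idx_test],
            n_repeats=cfg.importance_repeats, seed=seed,
        )
        correlation = feature_correlation(X)

    ladder = None
    if cfg.run_selection:
        with _stage("select"):
            ladder = forward_selection(
                recipe, X.loc[idx_test], y.loc[idx_test],
                max_steps=cfg.selection_max_steps,
            )

    with _stage("taxonomy"):
        taxonomy = taxonomy_table(events_df, shock_cutoff=cfg.shock_cutoff)
        pred_all = classify(clf, X)
        taxonomy_pred = taxonomy_table(
            events_df, lethal=pred_all, shock_cutoff=cfg.shock_cutoff, basis="predicted"
        )
        taxonomy = taxonomy.merge(
            taxonomy_pred[["event_id", "taxonomy"]].rename(
                columns={"taxonomy": "taxonomy_predicted"}
            ),
            on="event_id",
        )

    result = PipelineResult(
        config=cfg, corpus=corpus, split=split, classifier=clf,
        metrics=metrics, importance=importance, correlation=correlation,
        taxonomy=taxonomy, ladder=ladder,
    )

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with _stage("write", out=str(out)):
            lio.write_series_csv(corpus.series, out / "series.csv")
            lio.write_demographics_csv(corpus.demographics, out / "demographics.csv")
            lio.write_events_csv(corpus.events, out / "events.csv")
            feats.to_csv(out / "features.csv")
            split.to_frame().to_csv(out / "split.csv", index=False)
            save_model(clf, out / "model.joblib")
            (out / "metrics.json").write_text(json.dumps(metrics, indent=2, sort_keys=True))
            importance.to_csv(out / "importance.csv")
            correlation.to_csv(out / "correlation.csv")
            taxonomy.to_csv(out / "taxonomy.csv", index=False)
            if ladder is not None:
                ladder.to_frame().to_csv(out / "ladder.csv")
            provenance = {
                "config": cfg.model_dump(mode="json"),
                "config_hash": _config_hash(cfg),
                "seed": seed,
                "corpus_hash": corpus.content_hash(),
            }
            (out / "provenance.yaml").write_text(yaml.safe_dump(provenance, sort_keys=True))
    return result
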