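"""End-to-end mortality-prediction experiment.

Pipeline: obtain a cohort (synthetic exact, synthetic sampled, or a user
CSV) -> encode the six predictors -> stratified 80:20 train/test split ->
Bayesian optimization of the RVM kernel family and hyperparameters, with
the cross-validated classification error on the training split as the
objective -> refit the best configuration on the full training split ->
one evaluation on the held-out test split -> JSON report including the
descriptive chi-square battery.

The held-out test split is never touched by the BO objective. A single
master seed fans out (via a seed sequence) to the cohort generator, the
split, the RVM basis subsampling and the BO loop, so runs are reproducible
byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .bayesopt import BOConfig, BOResult, config_to_kernel_spec, kernel_search_space, optimize
from .cohort import (
    encode_features,
    load_printed_margins,
    plant_signal,
    read_cohort_csv,
    sample_cohort,
)
from .metrics import (
    chi_square_battery,
    classification_metrics,
    confusion_matrix,
    roc_auc,
)
from .rvm import TrainConfig, fitness, predict_proba, train_rvm

__all__ = [
    "ExperimentConfig",
    "ExperimentError",
    "split_stratified",
    "run_experiment",
    "validate_report",
]

log = logging.getLogger(__name__)


class ExperimentError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass(frozen=True)
class ExperimentConfig:
    """Everything needed to reproduce one experiment.

    ``cohort_source`` is 'synthetic-exact', 'synthetic-sampled' (with
    ``cohort_n`` records) or 'csv' (with ``cohort_path``).
    ``planted_signal`` optionally replaces the outcome with a known
    predictor rule plus ``planted_noise`` label noise, for pipeline
    validation runs.
    """

    cohort_source: str = "synthetic-exact"
    cohort_n: int | None = None
    cohort_path: str | None = None
    seed: int = 0
    split_ratio: float = 0.8
    scaling: str = "minmax"
    age_encoding: str = "years"
    cv_folds: int = 5
    planted_signal: bool = False
    planted_noise: float = 0.05
    train: TrainConfig = field(default_factory=TrainConfig)
    bo: BOConfig = field(default_factory=BOConfig)
    gamma_bounds: tuple[float, float] = (1e-3, 1e3)
    coef0_bounds: tuple[float, float] = (-5.0, 5.0)
    degree_bounds: tuple[int, int] = (1, 5)

    def __post_init__(self):
        if not 0 < self.split_ratio < 1:
            raise ValueError("split_ratio must be in (0, 1)")
        if self.cohort_source not in ("synthetic-exact", "synthetic-sampled", "csv"):
            raise ValueError(f"unknown cohort_source {self.cohort_source!r}")
        if self.cohort_source == "csv" and not self.cohort_path:
            raise ValueError("cohort_source 'csv' requires cohort_path")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be at least 2")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        if "train" in d and isinstance(d["train"], dict):
            d["train"] = TrainConfig(**d["train"])
        if "bo" in d and isinstance(d["bo"], dict):
            d["bo"] = BOConfig(**d["bo"])
        for key in ("gamma_bounds", "coef0_bounds", "degree_bounds"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def split_stratified(
    cohort: pd.DataFrame, ratio: float = 0.8, seed: int = 0, label_column: str = "outcome"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-outcome-class train/test split with largest-remainder rounding.

    Returns (train, test) with test fraction 1 - ratio; each class's test
    count is the floor of its exact share, with leftover records assigned by
    largest fractional remainder. Deterministic given ``seed``; the two
    parts partition the cohort.
    """
    if not 0 < ratio < 1:
        raise ValueError("ratio must be in (0, 1)")
    labels = cohort[label_column]
    classes = labels.unique()
    if len(classes) < 2:
        raise ValueError("both outcome classes must be present")
    counts = labels.value_counts()
    if (counts < 2).any():
        raise ValueError("every class needs at least 2 records to split")

    test_frac = 1.0 - ratio
    n_test_total = int(round(len(cohort) * test_frac))
    exact = {c: counts[c] * test_frac for c in classes}
    quota = {c: int(np.floor(exact[c])) for c in classes}
    leftover = n_test_total - sum(quota.values())
    by_remainder = sorted(classes, key=lambda c: exact[c] - quota[c], reverse=True)
    for c in by_remainder[: max(leftover, 0)]:
        quota[c] += 1

    rng = np.random.default_rng(seed)
    test_idx = []
    for c in classes:
        idx = cohort.index[labels == c].to_numpy()
        picked = rng.choice(idx, size=quota[c], replace=False)
        test_idx.append(picked)
    test_idx = np.concatenate(test_idx)
    mask = cohort.index.isin(test_idx)
    return cohort.loc[~mask].copy(), cohort.loc[mask].copy()


def _load_cohort(config: ExperimentConfig, seed: int) -> pd.DataFrame:
    if config.cohort_source == "csv":
        return read_cohort_csv(config.cohort_path)
    spec = load_printed_margins()
    mode = "exact" if config.cohort_source == "synthetic-exact" else "sampled"
    return sample_cohort(spec, mode=mode, n=config.cohort_n, seed=seed)


def run_experiment(config: ExperimentConfig, out_path=None) -> dict:
    """Execute the full BO-RVM pipeline and return (optionally write) the report."""
    ss = np.random.SeedSequence(config.seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(5)]
    seed_cohort, seed_plant, seed_split, seed_train, seed_bo = seeds

    stage = "cohort"
    try:
        cohort = _load_cohort(config, seed_cohort)
        if config.planted_signal:
            cohort = plant_signal(cohort, noise=config.planted_noise, seed=seed_plant)

        stage = "descriptive statistics"
        chi2 = chi_square_battery(cohort)

        stage = "encoding"
        X, y, feature_names = encode_features(
            cohort, scaling=config.scaling, age_encoding=config.age_encoding
        )

        stage = "split"
        frame = cohort.reset_index(drop=True)
        train_df, test_df = split_stratified(frame, config.split_ratio, seed_split)
        tr, te = train_df.index.to_numpy(), test_df.index.to_numpy()

        stage = "bayesian optimization"
        train_cfg = dataclasses.replace(config.train, rng_seed=seed_train)
        space = kernel_search_space(
            config.gamma_bounds, config.coef0_bounds, config.degree_bounds
        )

        def objective(cfg: dict) -> float:
            spec = config_to_kernel_spec(cfg)
            return fitness(spec, X[tr], y[tr], cv_folds=config.cv_folds, config=train_cfg)

        bo_cfg = dataclasses.replace(config.bo, seed=seed_bo)
        bo_result: BOResult = optimize(objective, space, bo_cfg)

        stage = "final fit"
        best_spec = config_to_kernel_spec(bo_result.best_config)
        model = train_rvm(X[tr], y[tr], best_spec, train_cfg)

        stage = "evaluation"
        proba = predict_proba(model, X[te])
        pred = (proba >= 0.5).astype(int)
        cm = confusion_matrix(y[te], pred, positive_label=1)
        report_metrics = classification_metrics(cm)
        auc = roc_auc(y[te], proba) if np.unique(y[te]).size == 2 else None
        metrics_dict = report_metrics.to_dict()
        metrics_dict["auc"] = auc
    except ExperimentError:
        raise
    except Exception as exc:
        raise ExperimentError(f"stage {stage!r} failed: {exc}") from exc

    report = {
        "config": config.to_dict(),
        "seed": config.seed,
        "cohort": {
            "n_records": int(len(cohort)),
            "n_died": int((cohort["outcome"] == "died").sum()),
            "n_train": int(tr.size),
            "n_test": int(te.size),
            "feature_order": feature_names,
        },
        "chi_square": chi2,
        "bo": bo_result.to_dict(),
        "best_kernel": best_spec.to_dict(),
        "n_relevance_vectors": model.n_relevance_vectors,
        "test_confusion_matrix": cm.to_dict(),
        "test_metrics": metrics_dict,
        "versions": {
            "borvm": __version__,
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    validate_report(report)
    if out_path is not None:
        Path(out_path).write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    return report


_REPORT_REQUIRED = {
    "config": dict,
    "seed": int,
    "cohort": dict,
    "chi_square": dict,
    "bo": dict,
    "best_kernel": dict,
    "test_confusion_matrix": dict,
    "test_metrics": dict,
    "versions": dict,
}


def validate_report(report: dict) -> None:
    """Check the report against the shipped schema's required keys and types."""
    for key, typ in _REPORT_REQUIRED.items():
        if key not in report:
            raise ValueError(f"report missing key {key!r}")
        if not isinstance(report[key], typ):
            raise ValueError(f"report key {key!r} has type {type(report[key]).__name__}")
    for key in ("tp", "fp", "fn", "tn"):
        if key not in report["test_confusion_matrix"]:
            raise ValueError(f"confusion matrix missing {key!r}")
    for key, value in report["test_metrics"].items():
        if value is not None and not 0.0 <= value <= 1.0:
            raise ValueError(f"metric {key!r}={value} outside [0, 1]")
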