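"""Imbalance-aware evaluation and the matched-privacy comparison runner.

Overall accuracy is close to meaningless under severe class imbalance — a
majority-class predictor scores the dominant-class share.  The metrics here
therefore centre on the multiclass Matthews correlation coefficient
(covariance form), macro-averaged F1/recall, and a per-group report that
averages class-conditional accuracy (per-class recall) separately over the
single dominant "large-shot" class and the minority "few-shot" classes.

:func:`run_comparison` is the experiment harness: for each algorithm and
privacy budget it calibrates the initial noise multiplier to the target
epsilon under that algorithm's schedule shape, trains over a seed set on
shared data splits, and aggregates validation metrics.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .accountant import PrivacyLedger, calibrate_sigma0, compose, to_dp
from .schedule import ScheduleConfig, build_table
from .synthetic_data import FEW_SHOT, LARGE_SHOT, LabelledDataset
from .trainer import TrainConfig, static_schedule, train

__all__ = [
    "confusion",
    "accuracy",
    "per_class_recall",
    "per_class_precision",
    "per_class_f1",
    "mcc_multiclass",
    "macro_f1",
    "macro_recall",
    "group_accuracy",
    "MetricsReport",
    "compute_metrics",
    "ComparisonTable",
    "run_comparison",
]

logger = logging.getLogger(__name__)


def confusion(y_true, y_pred, n_classes: int) -> np.ndarray:
    """K x K confusion matrix; rows are true classes, columns predictions."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    for name, y in (("y_true", y_true), ("y_pred", y_pred)):
        if y.size and (y.min() < 0 or y.max() >= n_classes):
            raise ValueError(f"{name} contains labels outside [0, {n_classes})")
    cm = np.zeros((n_classes, n_classes), dtype=int)
    np.add.at(cm, (y_true, y_pred), 1)
    return cm


def _check_cm(cm: np.ndarray) -> np.ndarray:
    cm = np.asarray(cm)
    if cm.ndim != 2 or cm.shape[0] != cm.shape[1]:
        raise ValueError("confusion matrix must be square")
    if cm.sum() == 0:
        raise ValueError("confusion matrix is empty")
    if (cm < 0).any():
        raise ValueError("confusion matrix entries must be non-negative")
    return cm


def accuracy(cm: np.ndarray) -> float:
    cm = _check_cm(cm)
    return float(np.trace(cm) / cm.sum())


def per_class_recall(cm: np.ndarray) -> np.ndarray:
    """Class-conditional accuracy; 0 for classes with no true samples."""
    cm = _check_cm(cm)
    support = cm.sum(axis=1)
    return np.divide(
        np.diag(cm), support, out=np.zeros(len(cm)), where=support > 0
    )


def per_class_precision(cm: np.ndarray) -> np.ndarray:
    cm = _check_cm(cm)
    predicted = cm.sum(axis=0)
    return np.divide(
        np.diag(cm), predicted, out=np.zeros(len(cm)), where=predicted > 0
    )


def per_class_f1(cm: np.ndarray) -> np.ndarray:
    """One-vs-rest F1 per class; 0 when precision + recall is 0."""
    p = per_class_precision(cm)
    r = per_class_recall(cm)
    denom = p + r
    return np.divide(2 * p * r, denom, out=np.zeros(len(p)), where=denom > 0)


def macro_recall(cm: np.ndarray) -> float:
    return float(per_class_recall(cm).mean())


def macro_f1(cm: np.ndarray) -> float:
    return float(per_class_f1(cm).mean())


def mcc_multiclass(cm: np.ndarray) -> float:
    """Multiclass Matthews correlation coefficient (covariance form).

    ``(c*s - sum_k p_k t_k) / sqrt((s^2 - sum p_k^2)(s^2 - sum t_k^2))`` with
    ``c`` the correct count, ``s`` the total, ``t_k``/``p_k`` the true and
    predicted counts of class k.  Returns 0 by convention when a marginal is
    degenerate (all-one-class truth or predictions).
    """
    cm = _check_cm(cm).astype(float)
    s = cm.sum()
    c = np.trace(cm)
    t = cm.sum(axis=1)
    p = cm.sum(axis=0)
    cov_tp = c * s - float(t @ p)
    cov_tt = s**2 - float(t @ t)
    cov_pp = s**2 - float(p @ p)
    denom = math.sqrt(cov_tt) * math.sqrt(cov_pp)
    if denom == 0.0:
        return 0.0
    return float(cov_tp / denom)


def group_accuracy(cm: np.ndarray, group_map: dict) -> dict:
    """Mean per-class recall within each class group (e.g. few-shot/large-shot)."""
    cm = _check_cm(cm)
    if set(group_map) != set(range(len(cm))):
        raise ValueError("group_map must cover every class exactly")
    recalls = per_class_recall(cm)
    out: dict = {}
    for group in sorted(set(group_map.values())):
        members = [k for k, g in group_map.items() if g == group]
        if not members:
            raise ValueError(f"group {group!r} has no member classes")
        out[group] = float(recalls[members].mean())
    return out


@dataclass(frozen=True)
class MetricsReport:
    """Confusion-matrix-derived metrics for one evaluated model."""

    accuracy: float
    mcc: float
    macro_f1: float
    macro_recall: float
    per_class_recall: tuple
    per_class_precision: tuple
    per_class_f1: tuple
    group_accuracy: dict

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "mcc": self.mcc,
            "macro_f1": self.macro_f1,
            "macro_recall": self.macro_recall,
            "per_class_recall": list(self.per_class_recall),
            "per_class_precision": list(self.per_class_precision),
            "per_class_f1": list(self.per_class_f1),
            "group_accuracy": dict(self.group_accuracy),
        }


def compute_metrics(y_true, y_pred, n_classes: int, group_map: dict | None = None) -> MetricsReport:
    cm = confusion(y_true, y_pred, n_classes)
    return MetricsReport(
        accuracy=accuracy(cm),
        mcc=mcc_multiclass(cm),
        macro_f1=macro_f1(cm),
        macro_recall=macro_recall(cm),
        per_class_recall=tuple(per_class_recall(cm)),
        per_class_precision=tuple(per_class_precision(cm)),
        per_class_f1=tuple(per_class_f1(cm)),
        group_accuracy=group_accuracy(cm, group_map) if group_map else {},
    )


@dataclass
class ComparisonTable:
    """Per-run metrics and seed-aggregated means/sds of a comparison."""

    runs: pd.DataFrame
    aggregate: pd.DataFrame

    def to_json(self) -> str:
        payload = {
            "runs": self.runs.to_dict(orient="records"),
            "aggregate": self.aggregate.to_dict(orient="records"),
        }
        return json.dumps(payload, indent=2)


_SCALAR_METRICS = ("accuracy", "mcc", "macro_f1", "macro_recall",
                   "large_shot_accuracy", "few_shot_accuracy")


def run_comparison(
    train_ds: LabelledDataset,
    val_ds: LabelledDataset,
    schedule: ScheduleConfig,
    train_template: TrainConfig,
    eps_targets,
    seeds,
    algorithms=("sdd", "static"),
    delta: float = 1e-3,
    mode: str = "plain",
    group_map: dict | None = None,
) -> ComparisonTable:
    """Matched-privacy comparison of schedules over a shared seed set.

    For each (algorithm, epsilon): the initial noise multiplier is calibrated
    to the target under that algorithm's schedule shape ("static" collapses
    the schedule to one constant stage), then one run per seed is trained on
    the same train split and evaluated on the same validation split.  Rows
    differ between algorithms only in the schedule and the noise/sampling
    randomness.
    """
    if not list(algorithms) or not list(seeds):
        raise ValueError("need at least one algorithm and one seed")
    group_map = group_map or train_ds.group_map
    q = train_template.batch_size / len(train_ds)
    rows = []
    for algo in algorithms:
        if algo == "sdd":
            shape = schedule
        elif algo == "static":
            shape = static_schedule(schedule)
        else:
            raise ValueError(f"unknown algorithm {algo!r}")
        for eps in eps_targets:
            try:
                sigma0 = calibrate_sigma0(eps, delta, shape, q=q, mode=mode)
            except Exception as exc:
                raise RuntimeError(
                    f"calibration failed for algorithm={algo}, eps={eps}: {exc}"
                ) from exc
            cfg_sched = dataclasses.replace(shape, sigma0=sigma0)
            ledger = PrivacyLedger.from_schedule(build_table(cfg_sched), q)
            eps_achieved = to_dp(compose(ledger, mode=mode), delta).epsilon
            logger.info(
                "%s at eps=%.3g: calibrated sigma0=%.6g (achieved eps=%.6g)",
                algo, eps, sigma0, eps_achieved,
            )
            for seed in seeds:
                cfg = dataclasses.replace(
                    train_template, schedule=cfg_sched, seed=int(seed)
                )
                result = train(train_ds, cfg)
                report = compute_metrics(
                    val_ds.labels,
                    result.predict(val_ds.features),
                    train_ds.n_classes,
                    group_map,
                )
                rows.append(
                    {
                        "algorithm": algo,
                        "eps_target": float(eps),
                        "eps_achieved": float(eps_achieved),
                        "sigma0": float(sigma0),
                        "seed": int(seed),
                        "accuracy": report.accuracy,
                        "mcc": report.mcc,
                        "macro_f1": report.macro_f1,
                        "macro_recall": report.macro_recall,
                        "large_shot_accuracy": report.group_accuracy.get(LARGE_SHOT),
                        "few_shot_accuracy": report.group_accuracy.get(FEW_SHOT),
                    }
                )
    runs = pd.DataFrame(rows)
    grouped = runs.groupby(["algorithm", "eps_target"], sort=False)
    aggregate = grouped[list(_SCALAR_METRICS)].agg(["mean", "std"])
    aggregate.columns = [f"{m}_{stat}" for m, stat in aggregate.columns]
    aggregate = aggregate.reset_index()
    return ComparisonTable(runs=runs, aggregate=aggregate)
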