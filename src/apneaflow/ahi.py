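"""Subject-level AHI estimation from per-segment predictions.

The per-segment event counts predicted by the CNN are averaged over a
subject's night and passed through a linear regression fitted on training
subjects. The regression absorbs both the segments-per-hour scaling
(60/segment_minutes) and the systematic overestimation of sleep time when
segments are cut from the total recording (TST < TRT), yielding an apnea-
hypopnea index in events per hour of sleep. Severity follows the pediatric
cutoffs: no OSA (<1), mild [1, 5), moderate [5, 10), severe (>=10 e/h).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .cnn import CNNRegressor, ModelConfig
from .preprocess import SegmentSet, build_segment_set
from .training import (
    TrainConfig,
    TrainedModel,
    default_batch_size,
    predict_segments,
    train_with_restarts,
)

__all__ = [
    "SEVERITY_CLASSES",
    "AHIEstimate",
    "CorrectionModel",
    "aggregate_subject",
    "fit_correction",
    "estimate_ahi",
    "classify_severity",
    "select_configuration",
]

logger = logging.getLogger(__name__)

SEVERITY_CLASSES = ("no_osa", "mild", "moderate", "severe")


@dataclass
class AHIEstimate:
    subject_id: str
    mean_segment_pred: float
    ahi: float
    severity: str


@dataclass(frozen=True)
class CorrectionModel:
    """Univariate OLS map from mean segment prediction to corrected AHI."""

    slope: float
    intercept: float
    fit_n: int

    def __post_init__(self) -> None:
        if self.fit_n < 2:
            raise ValueError("fit_n must be >= 2")

    def apply(self, mean_pred: float) -> float:
        return self.slope * mean_pred + self.intercept


def aggregate_subject(preds: Sequence[float]) -> float:
    """Arithmetic mean of the per-segment predictions of one subject."""
    preds = np.asarray(preds, dtype=float)
    if preds.size == 0:
        raise ValueError("cannot aggregate an empty prediction list")
    return float(preds.mean())


def fit_correction(
    train_means: Sequence[float], train_actual_ahi: Sequence[float]
) -> CorrectionModel:
    """OLS of the actual AHI on the mean segment prediction (train only)."""
    x = np.asarray(train_means, dtype=float)
    y = np.asarray(train_actual_ahi, dtype=float)
    if x.size != y.size or x.size < 2:
        raise ValueError("need equal-length inputs with at least 2 subjects")
    if np.ptp(x) < 1e-12 or x.std() < 1e-12:
        raise ValueError("degenerate predictor: mean predictions are all identical")
    xm, ym = x.mean(), y.mean()
    slope = float(np.sum((x - xm) * (y - ym)) / np.sum((x - xm) ** 2))
    intercept = float(ym - slope * xm)
    return CorrectionModel(slope=slope, intercept=intercept, fit_n=int(x.size))


def classify_severity(ahi: float) -> str:
    """Pediatric OSA severity class; boundaries 1, 5, 10 e/h are left-closed."""
    if ahi < 0:
        raise ValueError("AHI must be >= 0")
    if ahi < 1:
        return "no_osa"
    if ahi < 5:
        return "mild"
    if ahi < 10:
        return "moderate"
    return "severe"


def estimate_ahi(
    preds: Sequence[float], correction: CorrectionModel, subject_id: str = ""
) -> AHIEstimate:
    """Corrected subject AHI (clamped at 0) with its severity class."""
    mean_pred = aggregate_subject(preds)
    ahi = max(0.0, correction.apply(mean_pred))
    return AHIEstimate(
        subject_id=subject_id,
        mean_segment_pred=mean_pred,
        ahi=ahi,
        severity=classify_severity(ahi),
    )


def _cohort_sets(records, segment_minutes: int) -> list[SegmentSet]:
    return [build_segment_set(r, segment_minutes) for r in records]


def _stack(sets: Sequence[SegmentSet]) -> tuple[np.ndarray, np.ndarray]:
    X = np.concatenate([s.segments for s in sets])
    y = np.concatenate([s.labels for s in sets]).astype(float)
    return X, y


def fit_cohort_model(
    train_records,
    val_records,
    segment_minutes: int = 10,
    n_blocks: int = 4,
    n_filters: int = 16,
    r_drop: float = 0.1,
    max_epochs: int = 80,
    seed: int = 0,
) -> tuple[TrainedModel, CorrectionModel]:
    """Train CNN + correction on a cohort; correction fit on training only."""
    train_sets = _cohort_sets(train_records, segment_minutes)
    val_sets = _cohort_sets(val_records, segment_minutes)
    cfg = ModelConfig(
        n_blocks=n_blocks,
        n_filters=n_filters,
        r_drop=r_drop,
        input_length=int(segment_minutes * 240),
    )
    tc = TrainConfig(
        batch_size=default_batch_size(segment_minutes),
        max_epochs=max_epochs,
        seed=seed,
    )
    X_tr, y_tr = _stack(train_sets)
    X_va, y_va = _stack(val_sets)
    trained = train_with_restarts(
        lambda s: CNNRegressor(cfg, seed=s), X_tr, y_tr, X_va, y_va, tc
    )
    means = [aggregate_subject(predict_segments(trained, s)) for s in train_sets]
    actual = [r.true_ahi for r in train_records]
    correction = fit_correction(means, actual)
    return trained, correction


def estimate_cohort(
    trained: TrainedModel,
    correction: CorrectionModel,
    records,
    segment_minutes: int,
) -> list[AHIEstimate]:
    """Apply a trained model + fixed correction to a list of recordings."""
    out = []
    for r in records:
        s = build_segment_set(r, segment_minutes)
        preds = predict_segments(trained, s)
        out.append(estimate_ahi(preds, correction, subject_id=r.subject_id))
    return out


def select_configuration(
    grid: Sequence[tuple[int, int, float]],
    train_records,
    val_records,
    n_filters: int = 16,
    max_epochs: int = 80,
    seed: int = 0,
) -> tuple[tuple[int, int, float], list[dict]]:
    """Hyperparameter selection by 4-class validation kappa.

    ``grid`` lists ``(segment_minutes, n_blocks, r_drop)`` combinations; one
    model is trained per combination and the configuration with the highest
    validation kappa wins. Ties break toward fewer blocks, then shorter
    segments. Configurations that fail to train are excluded with a warning.
    """
    from .metrics import build_confusion_4, cohen_kappa

    if len(grid) == 0:
        raise ValueError("configuration grid is empty")
    results: list[dict] = []
    for segment_minutes, n_blocks, r_drop in grid:
        try:
            trained, correction = fit_cohort_model(
                train_records,
                val_records,
                segment_minutes=segment_minutes,
                n_blocks=n_blocks,
                n_filters=n_filters,
                r_drop=r_drop,
                max_epochs=max_epochs,
                seed=seed,
            )
            estimates = estimate_cohort(trained, correction, val_records, segment_minutes)
            actual = [classify_severity(r.true_ahi) for r in val_records]
            predicted = [e.severity for e in estimates]
            kappa = cohen_kappa(build_confusion_4(actual, predicted))
        except Exception as exc:  # noqa: BLE001 - failed configs are skipped
            logger.warning(
                "configuration (%s min, Nc=%s, r_drop=%s) failed: %s",
                segment_minutes, n_blocks, r_drop, exc,
            )
            results.append(
                {"segment_minutes": segment_minutes, "n_blocks": n_blocks,
                 "r_drop": r_drop, "kappa": None, "failed": True}
            )
            continue
        results.append(
            {"segment_minutes": segment_minutes, "n_blocks": n_blocks,
             "r_drop": r_drop, "kappa": kappa, "failed": False}
        )
    best = rank_configurations(results)[0]
    return (best["segment_minutes"], best["n_blocks"], best["r_drop"]), results


def rank_configurations(results: Sequence[dict]) -> list[dict]:
    """Order configuration results by validation kappa, breaking ties toward
    fewer blocks and then shorter segments; failed configurations excluded."""
    ok = [r for r in results if not r.get("failed")]
    if not ok:
        raise RuntimeError("every configuration in the grid failed to train")
    return sorted(ok, key=lambda r: (-r["kappa"], r["n_blocks"], r["segment_minutes"]))
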