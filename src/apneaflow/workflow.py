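"""End-to-end study orchestration on synthetic cohorts.

Ties the simulator, preprocessing, CNN training, AHI correction, diagnostic
evaluation, screening and attribution together into two reproducible
experiments:

* :func:`oracle_recovery` — feeds ground-truth per-segment event counts
  (bypassing the CNN) through the correction regression, verifying that the
  linear correction alone recovers the true AHI: the fitted slope must absorb
  the segments-per-hour factor (60/segment_minutes) inflated by the mean
  wake fraction, since events occur only in sleep but segments cover the
  whole recording.

* :func:`run_desk_study` — the scaled-down version of the full pipeline:
  simulate train/validation/test cohorts, train the desk-preset CNN with the
  full optimizer schedule, fit the correction on training subjects only,
  evaluate diagnostics on the held-out test cohort, run the screening
  protocol, and score event localization of Grad-CAM and Deep-SHAP maps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ahi import (
    AHIEstimate,
    CorrectionModel,
    aggregate_subject,
    estimate_cohort,
    fit_cohort_model,
    fit_correction,
)
from .explain import deep_shap, grad_cam_aggregate, localization_score
from .metrics import DiagnosticReport, diagnostic_report
from .preprocess import build_segment_set
from .screening import psg_reduction, screen_cohort
from .simulate import AirflowRecord, SimConfig, simulate_cohort
from .training import TrainedModel

__all__ = ["make_cohort", "oracle_recovery", "run_desk_study", "StudyResult"]


def make_cohort(
    n_subjects: int,
    seed: int,
    ahi_range: tuple[float, float] = (0.0, 20.0),
    duration: float = 3600.0,
    fs_out: float = 32.0,
) -> list[AirflowRecord]:
    """Cohort with target AHI levels drawn uniformly over ``ahi_range``."""
    rng = np.random.default_rng(seed)
    targets = rng.uniform(*ahi_range, n_subjects)
    base = SimConfig(fs_out=fs_out, duration=duration, seed=seed)
    return simulate_cohort(n_subjects, targets, base)


@dataclass
class OracleRecovery:
    r2: float
    mean_bias: float
    slope: float
    expected_slope: float
    correction: CorrectionModel


def oracle_recovery(
    seed: int,
    n_subjects: int = 100,
    segment_minutes: int = 10,
    duration: float = 3600.0,
) -> OracleRecovery:
    """Correction-regression sanity check with ground-truth segment counts.

    Uses the true per-segment labels as "predictions", fits the correction on
    the cohort and compares corrected to true AHI. The expected slope is
    ``(60 / segment_minutes) / (1 - mean wake fraction)``.
    """
    records = make_cohort(n_subjects, seed, duration=duration)
    means, actual, wake_fracs = [], [], []
    for r in records:
        s = build_segment_set(r, segment_minutes)
        means.append(aggregate_subject(s.labels.astype(float)))
        actual.append(r.true_ahi)
        wake_fracs.append(1.0 - r.sleep_time / r.duration)
    correction = fit_correction(means, actual)
    est = [max(0.0, correction.apply(m)) for m in means]
    actual = np.asarray(actual)
    est = np.asarray(est)
    ss_res = float(np.sum((actual - est) ** 2))
    ss_tot = float(np.sum((actual - actual.mean()) ** 2))
    return OracleRecovery(
        r2=1.0 - ss_res / ss_tot,
        mean_bias=float(np.mean(est - actual)),
        slope=correction.slope,
        expected_slope=(60.0 / segment_minutes) / (1.0 - float(np.mean(wake_fracs))),
        correction=correction,
    )


@dataclass
class StudyResult:
    trained: TrainedModel
    correction: CorrectionModel
    train_records: list[AirflowRecord]
    test_records: list[AirflowRecord]
    test_estimates: list[AHIEstimate]
    report: DiagnosticReport
    psg_reduction: float
    segment_minutes: int
    seed: int

    def shap_background(self, size: int = 50) -> np.ndarray:
        """Quiet-breathing reference set: training segments with zero events."""
        rows = []
        for r in self.train_records:
            s = build_segment_set(r, self.segment_minutes)
            rows.append(s.segments[s.labels == 0])
        pool = np.concatenate(rows)
        rng = np.random.default_rng(self.seed + 7919)
        idx = rng.choice(pool.shape[0], size=min(size, pool.shape[0]), replace=False)
        return pool[idx]

    def event_segments(self, max_segments: int = 30):
        """Event-bearing test segments with their records and start times."""
        out = []
        for r in self.test_records:
            s = build_segment_set(r, self.segment_minutes)
            for i in np.flatnonzero(s.labels > 0):
                out.append((r, s.segments[i], float(s.segment_start_times[i])))
                if len(out) >= max_segments:
                    return out
        return out


def run_desk_study(
    seed: int,
    n_train: int = 80,
    n_val: int = 20,
    n_test: int = 30,
    duration: float = 3600.0,
    segment_minutes: int = 10,
    n_blocks: int = 4,
    n_filters: int = 16,
    r_drop: float = 0.1,
    max_epochs: int = 80,
) -> StudyResult:
    """Simulate, train, correct, evaluate and screen — one reproducible run."""
    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, 2**30, size=4)
    train_records = make_cohort(n_train, int(seeds[0]), duration=duration)
    val_records = make_cohort(n_val, int(seeds[1]), duration=duration)
    test_records = make_cohort(n_test, int(seeds[2]), duration=duration)

    trained, correction = fit_cohort_model(
        train_records,
        val_records,
        segment_minutes=segment_minutes,
        n_blocks=n_blocks,
        n_filters=n_filters,
        r_drop=r_drop,
        max_epochs=max_epochs,
        seed=int(seeds[3]),
    )
    estimates = estimate_cohort(trained, correction, test_records, segment_minutes)
    actual = [r.true_ahi for r in test_records]
    est = [e.ahi for e in estimates]
    report = diagnostic_report(actual, est)
    decisions = screen_cohort([e.subject_id for e in estimates], est)
    return StudyResult(
        trained=trained,
        correction=correction,
        train_records=train_records,
        test_records=test_records,
        test_estimates=estimates,
        report=report,
        psg_reduction=psg_reduction(decisions),
        segment_minutes=segment_minutes,
        seed=seed,
    )


def localization_summary(study: StudyResult, max_segments: int = 30,
                         background_size: int = 50) -> dict[str, float]:
    """Median inside/outside relevance ratio of both attribution methods
    over event-bearing test segments."""
    background = study.shap_background(background_size)
    ratios_cam, ratios_shap = [], []
    for record, segment, start in study.event_segments(max_segments):
        cam = grad_cam_aggregate(study.trained, segment)
        phi = deep_shap(study.trained, segment, background)
        sc = localization_score(
            cam, record.annotations, start, study.segment_minutes, kind="gradcam"
        )
        ss = localization_score(
            phi, record.annotations, start, study.segment_minutes, kind="shap"
        )
        ratios_cam.append(sc.ratio)
        ratios_shap.append(ss.ratio)
    return {
        "gradcam_median_ratio": float(np.median(ratios_cam)),
        "shap_median_ratio": float(np.median(ratios_shap)),
        "n_segments": len(ratios_cam),
    }
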