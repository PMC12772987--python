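"""Agreement and diagnostic statistics for AHI method comparison.

Implements the statistics used to compare a model-derived AHI against the
polysomnography reference: intraclass correlation (two-way, single-measure,
absolute agreement — the standard variant for method-comparison studies),
RMSE, Bland-Altman limits of agreement, unweighted Cohen's kappa over the
four severity classes, the 4x4 confusion matrix, and per-cutoff binary
diagnostics (Se, Sp, Acc, PPV, NPV, LR+, LR-) at 1, 5 and 10 e/h.

Ratios with zero denominators are reported as ``inf``/``nan`` together with
an ``undefined`` flag set, never silently as zero, so that cohort reports
always render.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .ahi import SEVERITY_CLASSES, classify_severity

__all__ = [
    "icc",
    "rmse",
    "bland_altman",
    "cohen_kappa",
    "binary_diagnostics",
    "build_confusion_4",
    "BinaryDiagnostics",
    "BlandAltman",
    "DiagnosticReport",
    "diagnostic_report",
]

CUTOFFS = (1.0, 5.0, 10.0)


def icc(actual: Sequence[float], estimated: Sequence[float]) -> float:
    """ICC(A,1): two-way single-measure absolute-agreement intraclass
    correlation of the n x 2 rating table ``[actual, estimated]``.

    Computed from the ANOVA mean squares:
    ``(MSR - MSE) / (MSR + (k-1) MSE + (k/n)(MSC - MSE))`` with k = 2.
    """
    a = np.asarray(actual, dtype=float)
    b = np.asarray(estimated, dtype=float)
    if a.size != b.size or a.size < 3:
        raise ValueError("need equal-length vectors with n >= 3")
    table = np.column_stack([a, b])
    n, k = table.shape
    grand = table.mean()
    row_means = table.mean(axis=1)
    col_means = table.mean(axis=0)
    ss_total = np.sum((table - grand) ** 2)
    if ss_total < 1e-15:
        raise ValueError("zero total variance: ICC undefined")
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    return float((msr - mse) / (msr + (k - 1) * mse + (k / n) * (msc - mse)))


def rmse(actual: Sequence[float], estimated: Sequence[float]) -> float:
    a = np.asarray(actual, dtype=float)
    b = np.asarray(estimated, dtype=float)
    if a.size != b.size or a.size < 1:
        raise ValueError("need equal-length non-empty vectors")
    return float(np.sqrt(np.mean((a - b) ** 2)))


@dataclass(frozen=True)
class BlandAltman:
    mean_diff: float
    loa_low: float
    loa_high: float
    diffs: np.ndarray
    within_limits: float  # fraction of points inside the limits


def bland_altman(actual: Sequence[float], estimated: Sequence[float]) -> BlandAltman:
    """Limits of agreement: mean difference +/- 1.96 SD (SD with n-1).

    Differences are ``estimated - actual``, so a positive mean difference
    means the model overestimates.
    """
    a = np.asarray(actual, dtype=float)
    b = np.asarray(estimated, dtype=float)
    if a.size != b.size or a.size < 2:
        raise ValueError("need equal-length vectors with n >= 2")
    d = b - a
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    lo, hi = mean - 1.96 * sd, mean + 1.96 * sd
    within = float(np.mean((d >= lo) & (d <= hi)))
    return BlandAltman(mean, lo, hi, d, within)


def cohen_kappa(confusion: np.ndarray) -> float:
    """Unweighted Cohen's kappa from a k x k confusion-count matrix."""
    c = np.asarray(confusion, dtype=float)
    if c.ndim != 2 or c.shape[0] != c.shape[1]:
        raise ValueError("confusion matrix must be square")
    if np.any(c < 0):
        raise ValueError("counts must be non-negative")
    total = c.sum()
    if total <= 0:
        raise ValueError("confusion matrix total must be positive")
    po = np.trace(c) / total
    pe = float(np.sum(c.sum(axis=0) * c.sum(axis=1)) / total**2)
    if pe >= 1.0 - 1e-15:
        if po >= 1.0 - 1e-15:
            return 1.0
        raise ValueError("chance agreement is 1 with imperfect observed agreement")
    return float((po - pe) / (1 - pe))


@dataclass(frozen=True)
class BinaryDiagnostics:
    """Percent-scale Se/Sp/Acc/PPV/NPV plus ratio-scale likelihood ratios."""

    cutoff: float
    tp: int
    fn: int
    tn: int
    fp: int
    se: float
    sp: float
    acc: float
    ppv: float
    npv: float
    lr_pos: float
    lr_neg: float
    undefined: frozenset[str] = field(default_factory=frozenset)


def _from_counts(cutoff: float, tp: int, fn: int, tn: int, fp: int) -> BinaryDiagnostics:
    undefined = set()

    def ratio(num, den, name):
        if den == 0:
            undefined.add(name)
            return np.nan
        return num / den

    se = ratio(tp, tp + fn, "se")
    sp = ratio(tn, tn + fp, "sp")
    ppv = ratio(tp, tp + fp, "ppv")
    npv = ratio(tn, tn + fn, "npv")
    acc = (tp + tn) / (tp + fn + tn + fp)
    if "se" in undefined or "sp" in undefined:
        undefined.update({"lr_pos", "lr_neg"})
        lrp = lrn = np.nan
    else:
        if sp == 1.0:  # no false positives: LR+ unbounded
            lrp = np.inf if se > 0 else np.nan
            undefined.add("lr_pos")
        else:
            lrp = se / (1 - sp)
        if sp == 0.0:  # no true negatives: LR- unbounded (0/0 when Se = 1)
            lrn = np.inf if se < 1 else np.nan
            undefined.add("lr_neg")
        else:
            lrn = (1 - se) / sp
    return BinaryDiagnostics(
        cutoff=cutoff,
        tp=tp, fn=fn, tn=tn, fp=fp,
        se=100 * se, sp=100 * sp, acc=100 * acc,
        ppv=100 * ppv, npv=100 * npv,
        lr_pos=lrp, lr_neg=lrn,
        undefined=frozenset(undefined),
    )


def binary_diagnostics(
    actual_ahi: Sequence[float], estimated_ahi: Sequence[float], cutoff: float
) -> BinaryDiagnostics:
    """Binary screening metrics at one AHI cutoff (positive = AHI >= cutoff).

    If the reference contains no positives (or no negatives) the affected
    metrics carry the ``undefined`` flag rather than a silent zero.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    a = np.asarray(actual_ahi, dtype=float)
    e = np.asarray(estimated_ahi, dtype=float)
    if a.size != e.size:
        raise ValueError("need equal-length vectors")
    pos_a = a >= cutoff
    pos_e = e >= cutoff
    tp = int(np.sum(pos_a & pos_e))
    fn = int(np.sum(pos_a & ~pos_e))
    tn = int(np.sum(~pos_a & ~pos_e))
    fp = int(np.sum(~pos_a & pos_e))
    return _from_counts(cutoff, tp, fn, tn, fp)


def build_confusion_4(
    actual_severity: Sequence[str], predicted_severity: Sequence[str]
) -> np.ndarray:
    """4x4 count matrix; rows actual, columns predicted, order
    no_osa/mild/moderate/severe."""
    if len(actual_severity) != len(predicted_severity):
        raise ValueError("need equal-length lists")
    index = {c: i for i, c in enumerate(SEVERITY_CLASSES)}
    out = np.zeros((4, 4), dtype=int)
    for a, p in zip(actual_severity, predicted_severity):
        out[index[a], index[p]] += 1
    return out


@dataclass
class DiagnosticReport:
    """Everything computed when comparing estimated to actual AHI."""

    n: int
    icc: float
    rmse: float
    bland_altman: BlandAltman
    confusion: np.ndarray
    kappa: float
    acc4: float  # percent
    per_cutoff: dict[float, BinaryDiagnostics]


def diagnostic_report(
    actual_ahi: Sequence[float], estimated_ahi: Sequence[float]
) -> DiagnosticReport:
    """Full agreement + diagnostic evaluation of a cohort of AHI estimates."""
    a = np.asarray(actual_ahi, dtype=float)
    e = np.asarray(estimated_ahi, dtype=float)
    confusion = build_confusion_4(
        [classify_severity(v) for v in a], [classify_severity(v) for v in e]
    )
    return DiagnosticReport(
        n=int(a.size),
        icc=icc(a, e),
        rmse=rmse(a, e),
        bland_altman=bland_altman(a, e),
        confusion=confusion,
        kappa=cohen_kappa(confusion),
        acc4=100.0 * np.trace(confusion) / confusion.sum(),
        per_cutoff={c: binary_diagnostics(a, e, c) for c in CUTOFFS},
    )
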