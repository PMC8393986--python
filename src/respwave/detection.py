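"""Threshold classification, ROC sweep, Welch's t-test, spectral statistics.

A segment whose NCC falls below a threshold is called low-functional.
Sweeping the threshold from 0.8 to 1.0 in 0.001 ticks traces the ROC curve
of the detector; Welch's unequal-variance t-test compares the NCC
populations of the two conditions; and per-frequency mean/std of the
scalogram summarize spectral stability per condition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .segments import NCCSeries, SpectrumSegment
from .signal import LOW_FUNCTIONAL, NORMAL

logger = logging.getLogger(__name__)

__all__ = [
    "ROCResult",
    "WelchResult",
    "SpectrumStats",
    "classify",
    "roc_sweep",
    "welch_test",
    "spectrum_statistics",
    "DEFAULT_THRESHOLDS",
]

# 0.800, 0.801, ..., 1.000 — endpoints inclusive, 201 ticks
DEFAULT_THRESHOLDS = np.round(np.arange(800, 1001)) / 1000.0


@dataclass
class ROCResult:
    thresholds: np.ndarray
    sensitivity: np.ndarray
    one_minus_specificity: np.ndarray
    auc: float

    def operating_point(self, threshold: float) -> tuple[float, float]:
        """(1 - specificity, sensitivity) at the tick nearest ``threshold``."""
        i = int(np.argmin(np.abs(self.thresholds - threshold)))
        return float(self.one_minus_specificity[i]), float(self.sensitivity[i])


@dataclass
class WelchResult:
    t_statistic: float
    p_value: float
    n_a: int
    n_b: int
    significance_band: str


@dataclass
class SpectrumStats:
    frequencies: np.ndarray
    mean_power: np.ndarray
    std_power: np.ndarray
    condition: str | None = None

    def peak_index(self) -> int:
        return int(np.argmax(self.mean_power))

    def peak_frequency(self) -> float:
        return float(self.frequencies[self.peak_index()])


def classify(series: NCCSeries, threshold: float) -> list[str | None]:
    """Predict a condition label for every series entry.

    A segment is called low-functional iff its NCC is strictly below the
    threshold; ties are called normal.  NaN (degenerate-segment) entries get
    ``None`` and are reported in the log.
    """
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    predictions: list[str | None] = []
    n_nan = 0
    for _, value, _ in series.entries:
        if not np.isfinite(value):
            predictions.append(None)
            n_nan += 1
        else:
            predictions.append(LOW_FUNCTIONAL if value < threshold else NORMAL)
    if n_nan:
        logger.info("classify: excluded %d NaN NCC entries", n_nan)
    return predictions


def roc_sweep(series: NCCSeries, thresholds: np.ndarray | None = None) -> ROCResult:
    """ROC curve of the NCC threshold detector for low-functional breathing.

    For each threshold, sensitivity is the fraction of truly low-functional
    segments called low-functional and 1-specificity the fraction of normal
    segments called low-functional.  AUC is the trapezoid integral over the
    sorted operating points with the (0,0) and (1,1) corners appended.
    """
    if thresholds is None:
        thresholds = DEFAULT_THRESHOLDS
    scores, truths = [], []
    for _, value, label in series.entries:
        if np.isfinite(value) and label in (NORMAL, LOW_FUNCTIONAL):
            scores.append(value)
            truths.append(label)
    scores_arr = np.array(scores)
    truth_lf = np.array([t == LOW_FUNCTIONAL for t in truths])
    n_lf = int(truth_lf.sum())
    n_nor = int((~truth_lf).sum())
    if n_lf == 0 or n_nor == 0:
        raise ValueError("ROC needs at least one segment of each true condition")
    sens = np.empty(len(thresholds))
    fpr = np.empty(len(thresholds))
    for i, thr in enumerate(thresholds):
        called_lf = scores_arr < thr
        sens[i] = np.count_nonzero(called_lf & truth_lf) / n_lf
        fpr[i] = np.count_nonzero(called_lf & ~truth_lf) / n_nor
    pts = np.vstack([np.append(fpr, [0.0, 1.0]), np.append(sens, [0.0, 1.0])]).T
    order = np.lexsort((pts[:, 1], pts[:, 0]))
    pts = pts[order]
    auc = float(np.trapezoid(pts[:, 1], pts[:, 0]))
    return ROCResult(
        thresholds=np.asarray(thresholds, dtype=float),
        sensitivity=sens,
        one_minus_specificity=fpr,
        auc=auc,
    )


def _significance_band(p: float) -> str:
    if p <= 0.001:
        return "p<=0.001"
    if p <= 0.01:
        return "p<=0.01"
    if p <= 0.05:
        return "p<=0.05"
    return "ns"


def welch_test(a, b) -> WelchResult:
    """Two-sided Welch's t-test (unequal variances) between two NCC samples."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least 2 values")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("samples must be finite")
    if np.var(a) == 0.0 and np.var(b) == 0.0:
        raise ValueError("both samples have zero variance; t undefined")
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return WelchResult(
        t_statistic=float(t),
        p_value=float(p),
        n_a=int(a.size),
        n_b=int(b.size),
        significance_band=_significance_band(float(p)),
    )


def spectrum_statistics(
    segments: list[SpectrumSegment],
    frequencies: np.ndarray | None = None,
    condition: str | None = None,
) -> SpectrumStats:
    """Per-frequency mean and standard deviation of scalogram power.

    Pools every within-segment time column of every supplied segment (all of
    one condition) and reduces over the pooled time axis.  ``frequencies``
    is the analysis grid the segment rows were computed on; when omitted the
    row index stands in for it.
    """
    if len(segments) < 2:
        raise ValueError("need at least 2 segments for spectral statistics")
    pooled = np.concatenate([np.abs(seg.values) for seg in segments], axis=1)
    if frequencies is None:
        frequencies = np.arange(pooled.shape[0], dtype=float)
    frequencies = np.asarray(frequencies, dtype=float)
    if frequencies.size != pooled.shape[0]:
        raise ValueError("frequencies length must match the segment row count")
    return SpectrumStats(
        frequencies=frequencies,
        mean_power=pooled.mean(axis=1),
        std_power=pooled.std(axis=1),
        condition=condition,
    )
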