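"""Fixed-duration segmentation of wavelet spectrograms and NCC scoring.

The spectrogram is cut into consecutive non-overlapping blocks of a chosen
duration ``td`` (seconds), the blocks are averaged elementwise, and each
block is scored by its normalized correlation coefficient (NCC) against the
average.  A stable breathing pattern yields near-identical blocks and NCC
close to 1; time-varying (low-functional) breathing decorrelates the blocks
and pulls the NCC down.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .signal import ConditionPeriod
from .wavelet import WaveletSpectrogram

logger = logging.getLogger(__name__)

__all__ = [
    "SpectrumSegment",
    "AveragedSegment",
    "NCCSeries",
    "segment_spectrogram",
    "average_segments",
    "ncc",
    "score_series",
]


@dataclass
class SpectrumSegment:
    """One fixed-duration block of the spectrogram feature matrix."""

    values: np.ndarray  # (frequency, within-segment time)
    start_time: float
    duration: float
    source_label: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("segment values must be 2-D")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("segment values must be finite")


@dataclass
class AveragedSegment:
    """Elementwise mean of equally shaped segments."""

    values: np.ndarray
    duration: float
    n_segments: int


@dataclass
class NCCSeries:
    """Per-segment NCC values, ordered by segment start time."""

    entries: list[tuple[float, float, str | None]] = field(default_factory=list)
    duration: float = float("nan")

    def start_times(self) -> np.ndarray:
        return np.array([e[0] for e in self.entries])

    def values(self, label: str | None = ...) -> np.ndarray:
        """Finite NCC values, optionally restricted to one condition label."""
        vals = [v for _, v, lab in self.entries if (label is ... or lab == label)]
        arr = np.array(vals, dtype=float)
        return arr[np.isfinite(arr)]

    def labels(self) -> list[str | None]:
        return [lab for _, _, lab in self.entries]


def _label_for_midpoint(t: float, periods: list[ConditionPeriod]) -> str | None:
    for p in periods:
        if p.contains(t):
            return p.label
    return None


def segment_spectrogram(
    spectrogram: WaveletSpectrogram,
    td: float,
    feature: str = "modulus",
) -> list[SpectrumSegment]:
    """Cut the spectrogram into consecutive blocks of duration ``td``.

    Blocks are ``floor(td / dt)`` columns wide, start at the spectrogram
    origin, and do not overlap; an incomplete trailing block is discarded.
    ``feature`` selects the modulus |W| (default) or the raw complex
    coefficients.  Each block inherits the label of the condition period
    containing its midpoint, when labels are attached.
    """
    dt = spectrogram.sampling_period
    if td < 2 * dt:
        raise ValueError(f"td ({td} s) must be at least two sampling periods ({2 * dt} s)")
    if feature not in ("modulus", "complex"):
        raise ValueError(f"feature must be 'modulus' or 'complex', got {feature!r}")
    block = int(np.floor(td / dt))
    n_cols = spectrogram.n_times
    n_blocks = n_cols // block
    if n_blocks == 0:
        logger.warning(
            "spectrogram (%d columns) shorter than one %g-s block (%d columns); no segments",
            n_cols, td, block,
        )
        return []
    data = spectrogram.modulus() if feature == "modulus" else spectrogram.values
    dropped = n_cols - n_blocks * block
    if dropped:
        logger.debug("dropping %d trailing columns (< one %g-s block)", dropped, td)
    segments = []
    for b in range(n_blocks):
        start = spectrogram.start_time + b * block * dt
        mid = start + 0.5 * block * dt
        segments.append(
            SpectrumSegment(
                values=data[:, b * block : (b + 1) * block],
                start_time=start,
                duration=td,
                source_label=_label_for_midpoint(mid, spectrogram.periods),
            )
        )
    return segments


def average_segments(segments: list[SpectrumSegment]) -> AveragedSegment:
    """Elementwise arithmetic mean of equally shaped segments."""
    if not segments:
        raise ValueError("cannot average an empty segment list")
    shape = segments[0].values.shape
    for seg in segments[1:]:
        if seg.values.shape != shape:
            raise ValueError(f"segment shape mismatch: {seg.values.shape} vs {shape}")
    stacked = np.stack([seg.values for seg in segments])
    return AveragedSegment(
        values=stacked.mean(axis=0),
        duration=segments[0].duration,
        n_segments=len(segments),
    )


def ncc(
    segment: SpectrumSegment,
    average: AveragedSegment,
    normalization: str = "pearson",
) -> float:
    """Normalized correlation coefficient between a segment and the average.

    Both matrices are flattened over (frequency, within-segment time).  With
    ``pearson`` normalization (default) each vector is mean-centered and
    scaled to unit Euclidean norm before the dot product, so the result lies
    in [-1, 1] and is invariant to constant offsets and positive rescaling
    of either matrix.  ``unitnorm`` skips the centering.  For complex
    features the real part of the Hermitian inner product is returned.  A
    matrix that is constant (zero variance after centering) has no defined
    correlation: NaN is returned and a warning logged.
    """
    a = np.asarray(segment.values).ravel()
    b = np.asarray(average.values).ravel()
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {segment.values.shape} vs {average.values.shape}")
    if normalization not in ("pearson", "unitnorm"):
        raise ValueError(f"unknown normalization {normalization!r}")
    if normalization == "pearson":
        a = a - a.mean()
        b = b - b.mean()
    na = np.linalg.norm(a)
    nb = np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        logger.warning("degenerate (constant) segment at t=%g s: NCC undefined", segment.start_time)
        return float("nan")
    value = float(np.real(np.vdot(a / na, b / nb)))
    # clamp the last-ulp excursions so the contract |ncc| <= 1 holds exactly
    return float(np.clip(value, -1.0, 1.0))


def score_series(
    spectrogram: WaveletSpectrogram,
    td: float,
    grouping: str = "per_period",
    feature: str = "modulus",
    normalization: str = "pearson",
) -> NCCSeries:
    """NCC of every segment against its group's average segment.

    ``grouping='per_period'`` segments each labeled condition period
    independently (blocks align to the period start) and averages within
    that period, mirroring a per-phase evaluation; ``'global'`` segments and
    averages the whole record at once.  Periods too short to hold one block
    contribute no entries and are skipped with a warning.
    """
    if grouping not in ("per_period", "global"):
        raise ValueError(f"grouping must be 'per_period' or 'global', got {grouping!r}")
    entries: list[tuple[float, float, str | None]] = []
    if grouping == "global":
        groups = [spectrogram]
    else:
        if not spectrogram.periods:
            raise ValueError("per_period grouping requires condition-period labels")
        groups = []
        for p in spectrogram.periods:
            try:
                sub = spectrogram.slice_time(p.start, p.end)
            except ValueError:
                logger.warning("period [%g, %g) has no spectrogram columns; skipped", p.start, p.end)
                continue
            sub.periods = [p]
            groups.append(sub)
    for group in groups:
        segments = segment_spectrogram(group, td, feature=feature)
        if not segments:
            logger.warning(
                "group starting at %g s too short for td=%g s; skipped", group.start_time, td
            )
            continue
        avg = average_segments(segments)
        for seg in segments:
            entries.append((seg.start_time, ncc(seg, avg, normalization), seg.source_label))
    entries.sort(key=lambda e: e[0])
    return NCCSeries(entries=entries, duration=td)
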