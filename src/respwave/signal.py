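"""Respiration signal container and condition-period labels.

A respiration record is a uniformly sampled 1-D displacement series (the
inter-rib distance reported by a chest stretch sensor, in arbitrary sensor
units), optionally annotated with labeled time periods of "normal" or
"low_functional" breathing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

NORMAL = "normal"
LOW_FUNCTIONAL = "low_functional"
CONDITION_LABELS = (NORMAL, LOW_FUNCTIONAL)


@dataclass(frozen=True)
class ConditionPeriod:
    """A labeled time interval [start, end) in seconds."""

    start: float
    end: float
    label: str

    def __post_init__(self) -> None:
        if not (np.isfinite(self.start) and np.isfinite(self.end)):
            raise ValueError("period bounds must be finite")
        if self.end <= self.start:
            raise ValueError(f"period end ({self.end}) must exceed start ({self.start})")
        if self.label not in CONDITION_LABELS:
            raise ValueError(f"label must be one of {CONDITION_LABELS}, got {self.label!r}")

    @property
    def duration(self) -> float:
        return self.end - self.start

    def contains(self, t: float) -> bool:
        return self.start <= t < self.end


@dataclass
class RespirationSignal:
    """Uniformly sampled displacement series.

    Parameters
    ----------
    samples
        Displacement values, one per tick (arbitrary sensor units).
    sampling_period
        Tick spacing in seconds (default 0.1 s, i.e. 10 Hz sampling).
    start_time
        Time of the first sample, seconds.
    periods
        Optional non-overlapping :class:`ConditionPeriod` labels lying within
        the signal's time span.
    """

    samples: np.ndarray
    sampling_period: float = 0.1
    start_time: float = 0.0
    periods: list[ConditionPeriod] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size < 1:
            raise ValueError("samples must be a non-empty 1-D array")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")
        if not (self.sampling_period > 0):
            raise ValueError("sampling_period must be positive")
        self.periods = sorted(self.periods, key=lambda p: p.start)
        t0, t1 = self.start_time, self.end_time
        prev_end = -np.inf
        for p in self.periods:
            if p.start < t0 - 1e-9 or p.end > t1 + self.sampling_period + 1e-9:
                raise ValueError(f"period [{p.start}, {p.end}) outside signal span [{t0}, {t1}]")
            if p.start < prev_end - 1e-9:
                raise ValueError("condition periods overlap")
            prev_end = p.end

    @property
    def sampling_rate(self) -> float:
        return 1.0 / self.sampling_period

    @property
    def n_samples(self) -> int:
        return int(self.samples.size)

    @property
    def duration(self) -> float:
        return self.n_samples * self.sampling_period

    @property
    def end_time(self) -> float:
        return self.start_time + (self.n_samples - 1) * self.sampling_period

    @property
    def times(self) -> np.ndarray:
        return self.start_time + np.arange(self.n_samples) * self.sampling_period

    def label_at(self, t: float) -> str | None:
        """Condition label of the period containing time ``t``, if any."""
        for p in self.periods:
            if p.contains(t):
                return p.label
        return None
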