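"""CSV readers and writers for signals, labels, NCC series and statistics.

All formats are plain UTF-8 comma-separated text:

* signal:          ``time_s,displacement``
* period labels:   ``start_s,end_s,label``
* NCC series:      ``start_s,duration_s,ncc,label``
* ROC curve:       ``threshold,sensitivity,one_minus_specificity``
* spectrum stats:  ``frequency_hz,mean_power,std_power,condition``
* scalogram:       wide CSV, rows = frequencies (first column), columns = times
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .detection import ROCResult, SpectrumStats
from .segments import NCCSeries
from .signal import CONDITION_LABELS, ConditionPeriod, RespirationSignal
from .wavelet import WaveletSpectrogram

__all__ = [
    "read_signal_csv",
    "write_signal_csv",
    "read_labels_csv",
    "write_labels_csv",
    "write_ncc_csv",
    "read_ncc_csv",
    "write_roc_csv",
    "write_spectrum_stats_csv",
    "write_spectrogram_csv",
]

TIME_UNIFORMITY_TOL = 1e-6  # seconds


class FormatError(ValueError):
    """Raised when an input file violates the expected dialect."""


def read_signal_csv(path, labels_path=None) -> RespirationSignal:
    """Parse a ``time_s,displacement`` CSV into a RespirationSignal.

    The time column must be strictly increasing and uniform within 1e-6 s;
    the sampling period is inferred from it.  If ``labels_path`` is given,
    condition periods are attached from that file.
    """
    df = pd.read_csv(path)
    for col in ("time_s", "displacement"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    t = df["time_s"].to_numpy(dtype=float)
    if t.size < 2:
        raise FormatError(f"{path}: need at least 2 rows to infer the sampling period")
    steps = np.diff(t)
    dt = steps[0]
    bad = np.flatnonzero(np.abs(steps - dt) > TIME_UNIFORMITY_TOL)
    if dt <= 0 or bad.size:
        row = int(bad[0]) + 1 if bad.size else 1
        raise FormatError(
            f"{path}: non-uniform or non-increasing timestamps at data row {row} "
            f"(step {steps[row - 1]:g} s, expected {dt:g} s)"
        )
    periods = read_labels_csv(labels_path) if labels_path is not None else []
    return RespirationSignal(
        samples=df["displacement"].to_numpy(dtype=float),
        sampling_period=float(dt),
        start_time=float(t[0]),
        periods=periods,
    )


def write_signal_csv(path, signal: RespirationSignal) -> None:
    pd.DataFrame({"time_s": signal.times, "displacement": signal.samples}).to_csv(
        path, index=False, float_format="%.9g"
    )


def read_labels_csv(path) -> list[ConditionPeriod]:
    df = pd.read_csv(path)
    for col in ("start_s", "end_s", "label"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    periods = []
    for i, row in df.iterrows():
        label = str(row["label"])
        if label not in CONDITION_LABELS:
            raise FormatError(f"{path}: unknown label {label!r} at data row {i + 1}")
        periods.append(ConditionPeriod(float(row["start_s"]), float(row["end_s"]), label))
    return periods


def write_labels_csv(path, periods: list[ConditionPeriod]) -> None:
    pd.DataFrame(
        {
            "start_s": [p.start for p in periods],
            "end_s": [p.end for p in periods],
            "label": [p.label for p in periods],
        }
    ).to_csv(path, index=False, float_format="%.9g")


def write_ncc_csv(path, series: NCCSeries) -> None:
    pd.DataFrame(
        {
            "start_s": [e[0] for e in series.entries],
            "duration_s": series.duration,
            "ncc": [e[1] for e in series.entries],
            "label": [e[2] if e[2] is not None else "" for e in series.entries],
        }
    ).to_csv(path, index=False, float_format="%.12g")


def read_ncc_csv(path) -> NCCSeries:
    df = pd.read_csv(path, keep_default_na=False)
    entries = [
        (float(r["start_s"]), float(r["ncc"]), (str(r["label"]) or None))
        for _, r in df.iterrows()
    ]
    duration = float(df["duration_s"].iloc[0]) if len(df) else float("nan")
    return NCCSeries(entries=entries, duration=duration)


def write_roc_csv(path, roc: ROCResult) -> None:
    pd.DataFrame(
        {
            "threshold": roc.thresholds,
            "sensitivity": roc.sensitivity,
            "one_minus_specificity": roc.one_minus_specificity,
        }
    ).to_csv(path, index=False, float_format="%.6g")


def write_spectrum_stats_csv(path, stats_list: list[SpectrumStats]) -> None:
    frames = [
        pd.DataFrame(
            {
                "frequency_hz": s.frequencies,
                "mean_power": s.mean_power,
                "std_power": s.std_power,
                "condition": s.condition or "",
            }
        )
        for s in stats_list
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.9g")


def write_spectrogram_csv(path, spectrogram: WaveletSpectrogram) -> None:
    """Write the scalogram (|W|) as a wide CSV with the grid as first column."""
    df = pd.DataFrame(
        spectrogram.modulus(),
        index=pd.Index(spectrogram.grid.frequencies, name="frequency_hz"),
        columns=[f"{t:.3f}" for t in spectrogram.times],
    )
    df.to_csv(path, float_format="%.6g")

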