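"""End-to-end analysis pipeline and its configuration.

`run_pipeline` ties the stages together: (simulated or loaded) signals →
Morlet spectrograms → fixed-duration segmentation and NCC scoring for each
configured duration → per-duration Welch test and spectral statistics →
one pooled ROC sweep.  Every run writes a manifest recording the resolved
configuration, its hash, the seed, and the package version, so any output
file is re-derivable from the manifest alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .detection import roc_sweep, spectrum_statistics, welch_test
from .io import read_signal_csv, write_labels_csv, write_ncc_csv, write_roc_csv, \
    write_signal_csv, write_spectrum_stats_csv
from .segments import NCCSeries, segment_spectrogram, score_series
from .signal import LOW_FUNCTIONAL, NORMAL, RespirationSignal
from .simulate import SimulationConfig, simulate_cohort
from .wavelet import MorletParams, cwt, make_frequency_grid

logger = logging.getLogger(__name__)

# the eight standard segment durations, seconds
DEFAULT_TD_LIST = (1.0, 3.0, 5.0, 10.0, 20.0, 30.0, 60.0, 90.0)


@dataclass
class PipelineConfig:
    """Union of all stage parameters; validated before any computation."""

    omega0: float = 6.0
    fmin_hz: float = 0.01
    fmax_hz: float = 5.0
    voices_per_octave: int = 12
    td_seconds: tuple[float, ...] = DEFAULT_TD_LIST
    feature: str = "modulus"
    normalization: str = "pearson"
    grouping: str = "per_period"
    threshold_min: float = 0.8
    threshold_max: float = 1.0
    threshold_step: float = 0.001
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    out_dir: str = "respwave_out"
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        MorletParams(self.omega0)
        make_frequency_grid(self.fmin_hz, self.fmax_hz, self.voices_per_octave)
        if not self.td_seconds:
            raise ValueError("td_seconds must be non-empty")
        if any(td <= 0 for td in self.td_seconds):
            raise ValueError("every td must be positive")
        if self.feature not in ("modulus", "complex"):
            raise ValueError(f"unknown feature {self.feature!r}")
        if self.normalization not in ("pearson", "unitnorm"):
            raise ValueError(f"unknown normalization {self.normalization!r}")
        if self.grouping not in ("per_period", "global"):
            raise ValueError(f"unknown grouping {self.grouping!r}")
        if not (self.threshold_min < self.threshold_max and self.threshold_step > 0):
            raise ValueError("invalid threshold grid")

    def thresholds(self) -> np.ndarray:
        n = int(round((self.threshold_max - self.threshold_min) / self.threshold_step))
        return self.threshold_min + np.arange(n + 1) * self.threshold_step

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["td_seconds"] = list(self.td_seconds)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        sim = d.pop("simulation", {})
        if isinstance(sim, dict):
            for key in ("subject_freq_range_hz", "lf_slow_period_s", "lf_shallow_depth",
                        "lf_shallow_duration_s"):
                if key in sim:
                    sim[key] = tuple(sim[key])
            sim = SimulationConfig(**sim)
        if "td_seconds" in d:
            d["td_seconds"] = tuple(d["td_seconds"])
        return cls(simulation=sim, **d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def _config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def analyze_signals(
    signals: list[RespirationSignal], config: PipelineConfig
) -> dict:
    """Run the analysis stages in memory and return all intermediate results.

    Returns a dict with per-td NCC series (pooled over signals), per-td
    Welch results, per-condition spectral statistics at the longest td, and
    the pooled ROC at the longest td.
    """
    params = MorletParams(config.omega0)
    grid = make_frequency_grid(config.fmin_hz, config.fmax_hz, config.voices_per_octave)
    spectrograms = [cwt(sig, grid, params) for sig in signals]

    series_by_td: dict[float, NCCSeries] = {}
    welch_by_td: dict[float, object] = {}
    for td in config.td_seconds:
        entries = []
        for spec in spectrograms:
            s = score_series(spec, td, grouping=config.grouping,
                             feature=config.feature, normalization=config.normalization)
            entries.extend(s.entries)
        entries.sort(key=lambda e: e[0])
        series = NCCSeries(entries=entries, duration=td)
        series_by_td[td] = series
        nor, lf = series.values(NORMAL), series.values(LOW_FUNCTIONAL)
        if nor.size >= 2 and lf.size >= 2:
            welch_by_td[td] = welch_test(nor, lf)
        else:
            logger.warning("td=%g s: not enough labeled segments for a Welch test", td)

    td_star = max(config.td_seconds)
    stats = []
    for label in (NORMAL, LOW_FUNCTIONAL):
        segs = []
        for spec in spectrograms:
            segs.extend(
                s for s in segment_spectrogram(spec, td_star, feature="modulus")
                if s.source_label == label
            )
        if len(segs) >= 2:
            stats.append(spectrum_statistics(segs, grid.frequencies, condition=label))
    roc = None
    series_star = series_by_td[td_star]
    if series_star.values(NORMAL).size and series_star.values(LOW_FUNCTIONAL).size:
        roc = roc_sweep(series_star, config.thresholds())
    return {
        "grid": grid,
        "spectrograms": spectrograms,
        "series_by_td": series_by_td,
        "welch_by_td": welch_by_td,
        "spectrum_stats": stats,
        "roc": roc,
        "roc_td": td_star,
    }


def run_pipeline(
    config: PipelineConfig, input_signals: list[RespirationSignal] | None = None
) -> Path:
    """Run the full pipeline and write artifacts; returns the output dir.

    Without ``input_signals`` a cohort is simulated from the embedded
    SimulationConfig (seed included), making the run fully reproducible.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "package": "respwave",
        "version": __version__,
        "config": config.to_dict(),
        "config_hash": _config_hash(config),
        "seed": config.simulation.seed,
        "simulated_input": input_signals is None,
        "outputs": [],
        "complete": False,
    }
    manifest_path = out / "manifest.json"

    def _save_manifest():
        manifest_path.write_text(json.dumps(manifest, indent=2))

    _save_manifest()
    try:
        if input_signals is None:
            signals = simulate_cohort(config.simulation)
            for i, sig in enumerate(signals):
                write_signal_csv(out / f"subject{i:02d}_signal.csv", sig)
                write_labels_csv(out / f"subject{i:02d}_labels.csv", sig.periods)
                manifest["outputs"] += [f"subject{i:02d}_signal.csv", f"subject{i:02d}_labels.csv"]
        else:
            signals = input_signals
        results = analyze_signals(signals, config)
    except Exception as exc:
        manifest["error"] = f"{type(exc).__name__}: {exc}"
        _save_manifest()
        raise
    for td, series in results["series_by_td"].items():
        name = f"ncc_td{td:g}s.csv"
        write_ncc_csv(out / name, series)
        manifest["outputs"].append(name)
    if results["spectrum_stats"]:
        write_spectrum_stats_csv(out / "spectrum_stats.csv", results["spectrum_stats"])
        manifest["outputs"].append("spectrum_stats.csv")
    summary = {
        "welch": {
            f"{td:g}": {"t": w.t_statistic, "p": w.p_value, "band": w.significance_band,
                        "n_normal": w.n_a, "n_low_functional": w.n_b}
            for td, w in results["welch_by_td"].items()
        }
    }
    if results["roc"] is not None:
        roc = results["roc"]
        write_roc_csv(out / "roc.csv", roc)
        manifest["outputs"].append("roc.csv")
        summary["roc"] = {
            "td": results["roc_td"],
            "auc": roc.auc,
            "operating_points": {
                f"{thr:g}": roc.operating_point(thr) for thr in (0.9973, 0.9960, 0.9946)
            },
        }
    (out / "summary.json").write_text(json.dumps(summary, indent=2))
    manifest["outputs"].append("summary.json")
    manifest["complete"] = True
    _save_manifest()
    return out


def load_signals(paths: list[str]) -> list[RespirationSignal]:
    """Read signal CSVs, attaching a sibling ``*_labels.csv`` when present."""
    signals = []
    for p in paths:
        path = Path(p)
        labels = path.with_name(path.name.replace("_signal", "_labels"))
        signals.append(
            read_signal_csv(path, labels if labels != path and labels.exists() else None)
        )
    return signals
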