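"""ERP derivation: filtering, baseline, averaging, difference waves, peaks.

Epochs are low-pass filtered at 30 Hz (zero-phase 4th-order Butterworth,
forward-backward) and baseline-corrected to the 100 ms pre-stimulus window.
ERPs are arithmetic trial means; mismatch waves subtract the standard from
the deviant ERP and ORN waves subtract across conditions. Peak measures come
from the unweighted frontocentral ROI trace: MMN latency is the most negative
sample in 70-250 ms, P3a the most positive in 150-400 ms, and each mean
amplitude averages the 50-ms window centered at the peak (clipped at epoch
edges and flagged). P2 mean amplitude averages a fixed window around the
grand-average P2 latency of 141 ms.

The continuous-data 0.2 Hz high-pass of a real-recording workflow has no
epoched-data equivalent here; `highpass_placeholder` documents the no-op for
adapters that ingest real recordings.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import butter, sosfiltfilt

from .montage import DEFAULT_ROI
from .simulate import EpochSet

__all__ = [
    "AnalysisConfig",
    "Erp",
    "PeakMeasure",
    "lowpass_epochs",
    "baseline_correct",
    "average_erp",
    "difference_wave",
    "roi_trace",
    "peak_and_mean_amplitude",
    "p2_mean_amplitude",
    "highpass_placeholder",
]


@dataclass(frozen=True)
class AnalysisConfig:
    lowpass_hz: float = 30.0
    filter_order: int = 4
    baseline_ms: tuple[float, float] = (-100.0, 0.0)
    mmn_window_ms: tuple[float, float] = (70.0, 250.0)
    p3a_window_ms: tuple[float, float] = (150.0, 400.0)
    mean_amp_halfwidth_ms: float = 25.0  # 50-ms window centered at the peak
    p2_latency_ms: float = 141.0
    p2_halfwidth_ms: float = 25.0
    roi: tuple[str, ...] = DEFAULT_ROI

    def component_window(self, component: str) -> tuple[float, float]:
        if component == "MMN":
            return self.mmn_window_ms
        if component == "P3a":
            return self.p3a_window_ms
        raise KeyError(component)


@dataclass
class Erp:
    data: np.ndarray  # (n_channels, n_times), trial mean in uV
    times_ms: np.ndarray
    channels: tuple[str, ...]
    n_trials: int
    label: dict = field(default_factory=dict)

    def __sub__(self, other: "Erp") -> "Erp":
        return difference_wave(self, other)


@dataclass(frozen=True)
class PeakMeasure:
    component: str
    latency_ms: float
    mean_amplitude: float
    window_clipped: bool = False


def highpass_placeholder(epochs: EpochSet) -> EpochSet:
    """No-op: the raw-data high-pass applies before epoching, upstream of
    everything this package simulates."""
    return epochs


def lowpass_epochs(epochs: EpochSet, cfg: AnalysisConfig | None = None) -> EpochSet:
    """Zero-phase Butterworth low-pass along time; DC preserved."""
    cfg = cfg or AnalysisConfig()
    dt = np.diff(epochs.times_ms[:2])[0] / 1000.0
    fs = 1.0 / dt
    if cfg.lowpass_hz >= fs / 2:
        raise ValueError("cutoff must be below Nyquist")
    sos = butter(cfg.filter_order, cfg.lowpass_hz, fs=fs, output="sos")
    data = sosfiltfilt(sos, epochs.data, axis=-1).astype(epochs.data.dtype)
    return dataclasses.replace(epochs, data=data)


def baseline_correct(epochs: EpochSet, cfg: AnalysisConfig | None = None) -> EpochSet:
    """Subtract the per-trial, per-channel mean over the baseline window."""
    cfg = cfg or AnalysisConfig()
    lo, hi = cfg.baseline_ms
    mask = (epochs.times_ms >= lo) & (epochs.times_ms <= hi)
    if not mask.any():
        raise ValueError("baseline window outside epoch")
    base = epochs.data[..., mask].mean(axis=-1, keepdims=True)
    return dataclasses.replace(epochs, data=epochs.data - base)


def average_erp(epochs: EpochSet, **selector) -> Erp:
    """Arithmetic trial mean over the trials matching ``selector``."""
    mask = epochs.select(**selector)
    n = int(mask.sum())
    if n == 0:
        raise ValueError(f"no trials match selector {selector!r}")
    return Erp(
        data=epochs.data[mask].mean(axis=0).astype(float),
        times_ms=epochs.times_ms,
        channels=epochs.montage.names,
        n_trials=n,
        label=dict(selector),
    )


def difference_wave(a: Erp, b: Erp) -> Erp:
    """Elementwise a - b (mismatch: deviant - standard; ORN: cross-condition)."""
    if a.channels != b.channels or not np.array_equal(a.times_ms, b.times_ms):
        raise ValueError("operands have mismatching axes")
    return Erp(
        data=a.data - b.data,
        times_ms=a.times_ms,
        channels=a.channels,
        n_trials=min(a.n_trials, b.n_trials),
        label={"difference": (a.label, b.label)},
    )


def roi_trace(erp: Erp, roi: tuple[str, ...] | None = None) -> np.ndarray:
    """Unweighted mean over ROI channels."""
    roi = roi or DEFAULT_ROI
    idx = []
    for name in roi:
        if name not in erp.channels:
            raise KeyError(f"unknown channel {name!r}")
        idx.append(erp.channels.index(name))
    return erp.data[idx].mean(axis=0)


def _window_mean(
    trace: np.ndarray, times_ms: np.ndarray, center_ms: float, halfwidth_ms: float
) -> tuple[float, bool]:
    lo, hi = center_ms - halfwidth_ms, center_ms + halfwidth_ms
    clipped = lo < times_ms[0] or hi > times_ms[-1]
    mask = (times_ms >= lo) & (times_ms <= hi)
    return float(trace[mask].mean()), clipped


def peak_and_mean_amplitude(
    trace: np.ndarray,
    times_ms: np.ndarray,
    component: str,
    cfg: AnalysisConfig | None = None,
) -> PeakMeasure:
    """Peak latency (argmin for MMN, argmax for P3a) and windowed mean amplitude.

    Ties break toward the earliest sample (np.argmin/argmax semantics).
    """
    cfg = cfg or AnalysisConfig()
    lo, hi = cfg.component_window(component)
    mask = (times_ms >= lo) & (times_ms <= hi)
    if not mask.any():
        raise ValueError("component window outside trace")
    seg = trace[mask]
    seg_times = times_ms[mask]
    pick = np.argmin(seg) if component == "MMN" else np.argmax(seg)
    latency = float(seg_times[pick])
    mean_amp, clipped = _window_mean(trace, times_ms, latency, cfg.mean_amp_halfwidth_ms)
    return PeakMeasure(
        component=component,
        latency_ms=latency,
        mean_amplitude=mean_amp,
        window_clipped=clipped,
    )


def p2_mean_amplitude(
    trace: np.ndarray, times_ms: np.ndarray, cfg: AnalysisConfig | None = None
) -> float:
    """Mean amplitude around the fixed grand-average P2 latency (141 ms)."""
    cfg = cfg or AnalysisConfig()
    value, _ = _window_mean(trace, times_ms, cfg.p2_latency_ms, cfg.p2_halfwidth_ms)
    return value
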