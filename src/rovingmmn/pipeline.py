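"""End-to-end helpers: simulate subjects, reduce to ERPs and peak measures.

These drive the full analysis chain subject by subject so that only
subject-level ERPs (not raw epochs) are held in memory, which is what the
group-level cluster tests and repeated-measures models consume.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .erp import (
    AnalysisConfig,
    average_erp,
    baseline_correct,
    difference_wave,
    lowpass_epochs,
    p2_mean_amplitude,
    peak_and_mean_amplitude,
    roi_trace,
)
from .montage import Montage, default_montage
from .simulate import CONDITIONS, SimulationDesign, simulate_subject

__all__ = ["SubjectLevelData", "reduce_dataset", "familywise_error_rate"]


@dataclass
class SubjectLevelData:
    """Group-stacked subject-level ERP arrays and tidy peak measures.

    ``diff_erps[cond]`` and ``std_erps[cond]``/``dev_erps[cond]`` are
    (n_subjects, n_channels, n_times); ``measures`` has one row per
    (subject, condition, component) with peak latency and mean amplitude, and
    ``p2_measures`` one row per (subject, condition, deviance) with the
    fixed-window P2 mean amplitude.
    """

    std_erps: dict[str, np.ndarray]
    dev_erps: dict[str, np.ndarray]
    diff_erps: dict[str, np.ndarray]
    measures: pd.DataFrame
    p2_measures: pd.DataFrame
    times_ms: np.ndarray
    montage: Montage


def reduce_dataset(
    design: SimulationDesign,
    analysis: AnalysisConfig | None = None,
    montage: Montage | None = None,
    deviant_order: int = 1,
) -> SubjectLevelData:
    """Simulate every subject and reduce to subject-level ERPs and measures.

    Filtering and baseline correction run per subject before averaging;
    mismatch waves use the requested deviant order against the condition's
    standards.
    """
    analysis = analysis or AnalysisConfig()
    montage = montage or default_montage()
    std_erps: dict[str, list] = {c: [] for c in CONDITIONS}
    dev_erps: dict[str, list] = {c: [] for c in CONDITIONS}
    diff_erps: dict[str, list] = {c: [] for c in CONDITIONS}
    rows = []
    p2_rows = []
    times_ms = design.times_ms

    for sid in range(design.n_subjects):
        epochs = simulate_subject(design, sid, montage=montage)
        epochs = baseline_correct(lowpass_epochs(epochs, analysis), analysis)
        for cond in CONDITIONS:
            std = average_erp(epochs, condition=cond, role="standard")
            dev = average_erp(
                epochs, condition=cond, role="deviant", deviant_order=deviant_order
            )
            diff = difference_wave(dev, std)
            std_erps[cond].append(std.data)
            dev_erps[cond].append(dev.data)
            diff_erps[cond].append(diff.data)
            trace = roi_trace(diff, analysis.roi)
            for comp in ("MMN", "P3a"):
                m = peak_and_mean_amplitude(trace, times_ms, comp, analysis)
                rows.append(
                    (sid, cond, comp, m.latency_ms, m.mean_amplitude, deviant_order)
                )
            for role_name, erp_obj in (("standard", std), ("deviant", dev)):
                p2 = p2_mean_amplitude(roi_trace(erp_obj, analysis.roi), times_ms,
                                       analysis)
                p2_rows.append((sid, cond, role_name, p2))

    measures = pd.DataFrame(
        rows,
        columns=[
            "subject", "condition", "component", "latency_ms", "mean_amp_uv",
            "deviant_order",
        ],
    )
    p2_measures = pd.DataFrame(
        p2_rows, columns=["subject", "condition", "deviance", "value"]
    )
    return SubjectLevelData(
        std_erps={c: np.stack(v) for c, v in std_erps.items()},
        dev_erps={c: np.stack(v) for c, v in dev_erps.items()},
        diff_erps={c: np.stack(v) for c, v in diff_erps.items()},
        measures=measures,
        p2_measures=p2_measures,
        times_ms=times_ms,
        montage=montage,
    )


def familywise_error_rate(
    n_datasets: int = 500,
    n_subjects: int = 20,
    channel_names: tuple[str, ...] = ("F3", "Fz", "F4", "FC1", "FC2", "Cz"),
    n_permutations: int = 200,
    design: SimulationDesign | None = None,
    analysis: AnalysisConfig | None = None,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Fraction of null datasets yielding any significant cluster.

    Each null dataset holds subject-level difference ERPs containing only the
    generator's noise (pink + white at ERP scale, low-pass filtered and
    baseline-corrected) on a sub-montage -- exchangeable under sign flips, so
    the paired-t cluster test's familywise error should sit at ``alpha``.
    """
    from .cluster import ClusterTestConfig, channel_adjacency, permutation_test
    from .simulate import _pink_noise

    design = design or SimulationDesign()
    analysis = analysis or AnalysisConfig()
    sub = default_montage().subset(channel_names)
    adj = channel_adjacency(sub)
    times = design.times_ms
    n_t = len(times)
    rng = np.random.default_rng(seed)
    # ERP-scale noise: trial noise shrunk by the default deviant/standard
    # trial counts (the scale is irrelevant to the error rate, only
    # exchangeability matters)
    scale = np.sqrt(1.0 / design.max_deviants + 1.0 / design.max_standards)

    from scipy.signal import butter, sosfiltfilt

    dt = np.diff(times[:2])[0] / 1000.0
    sos = butter(analysis.filter_order, analysis.lowpass_hz, fs=1.0 / dt,
                 output="sos")
    base_mask = (times >= analysis.baseline_ms[0]) & (times <= analysis.baseline_ms[1])

    n_hits = 0
    for i in range(n_datasets):
        noise = design.noise_pink_sd * _pink_noise(
            rng, (n_subjects, len(channel_names), n_t), design.sfreq
        )
        noise += design.noise_white_sd * rng.standard_normal(noise.shape)
        noise *= scale
        noise = sosfiltfilt(sos, noise, axis=-1)
        noise -= noise[..., base_mask].mean(axis=-1, keepdims=True)
        cfg = ClusterTestConfig(
            n_permutations=n_permutations, seed=int(rng.integers(2**31))
        )
        res = permutation_test(noise, adj, cfg)
        if res.min_p() < alpha:
            n_hits += 1
    return n_hits / n_datasets
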