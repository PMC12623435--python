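"""Synthetic multi-subject epoched EEG with a roving-oddball effect structure.

Each trial is a superposition of Gaussian-bump ERP components (N1 and P2 on
every tone, MMN and P3a on deviants with condition-dependent amplitudes, an
ORN-like P2-range negativity on every inharmonic/changing tone), scaled by a
frontocentral topography, plus per-channel 1/f ("pink") and white noise.
Component amplitudes carry subject-level random intercepts, giving the
between-subject variance that the repeated-measures models downstream rely
on. Epochs span -100..450 ms at 1000 Hz (551 samples) in microvolts, with the
mastoid reference treated as already applied.

Trial labels come from roving-oddball event tables, so deviant order and
frequency-shift magnitude are carried through to the analysis stage.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .montage import Montage, default_montage
from .paradigm import ParadigmConfig, generate_block

__all__ = [
    "ErpComponent",
    "EffectTable",
    "default_effect_table",
    "SimulationDesign",
    "EpochSet",
    "simulate_subject",
    "simulate_dataset",
]

CONDITIONS = ("harmonic", "inharmonic", "changing")

# Topography: isotropic Gaussian falloff on the unit disc, centered between
# Fz and FCz; every component in this study peaks frontocentrally.
TOPO_CENTER = (0.0, 0.34)
TOPO_SIGMA = 0.55


@dataclass(frozen=True)
class ErpComponent:
    """One ERP component template: a Gaussian bump in time.

    ``width_ms`` is the Gaussian SD. Amplitudes are supplied separately (they
    depend on condition and deviance role).
    """

    name: str
    latency_ms: float
    width_ms: float

    def __post_init__(self) -> None:
        if self.width_ms <= 0:
            raise ValueError("width must be positive")

    def time_course(self, times_ms: np.ndarray) -> np.ndarray:
        return np.exp(-0.5 * ((times_ms - self.latency_ms) / self.width_ms) ** 2)


# Latencies seeded from the reported component windows: MMN negativity
# 120-180 ms, P3a positivity 216-286 ms, grand-average P2 peak at 141 ms.
DEFAULT_COMPONENTS = {
    "N1": ErpComponent("N1", latency_ms=100.0, width_ms=25.0),
    "P2": ErpComponent("P2", latency_ms=141.0, width_ms=40.0),
    "MMN": ErpComponent("MMN", latency_ms=150.0, width_ms=25.0),
    "P3a": ErpComponent("P3a", latency_ms=250.0, width_ms=40.0),
    "ORN": ErpComponent("ORN", latency_ms=141.0, width_ms=25.0),
}


@dataclass(frozen=True)
class EffectTable:
    """Component amplitudes (microvolts) per condition.

    ``mmn`` and ``p3a`` apply to deviants only; ``orn`` applies to every tone
    of its condition; ``n1`` and ``p2`` apply to every tone of every
    condition.
    """

    mmn: dict[str, float]
    p3a: dict[str, float]
    orn: dict[str, float]
    n1: float = -2.0
    p2: float = 2.0

    def amplitude(self, component: str, condition: str, is_deviant: bool) -> float:
        if component == "N1":
            return self.n1
        if component == "P2":
            return self.p2
        if component == "ORN":
            return self.orn[condition]
        if component == "MMN":
            return self.mmn[condition] if is_deviant else 0.0
        if component == "P3a":
            return self.p3a[condition] if is_deviant else 0.0
        raise KeyError(component)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "EffectTable":
        return cls(**d)


def default_effect_table() -> EffectTable:
    """Deviance effects mirroring the observed qualitative pattern.

    MMN present for harmonic and inharmonic deviants, absent for changing;
    P3a largest for inharmonic; ORN on every inharmonic/changing tone.
    """
    return EffectTable(
        mmn={"harmonic": -1.0, "inharmonic": -0.7, "changing": 0.0},
        p3a={"harmonic": 0.8, "inharmonic": 2.0, "changing": 0.7},
        orn={"harmonic": 0.0, "inharmonic": -1.0, "changing": -1.0},
    )


@dataclass(frozen=True)
class SimulationDesign:
    """Study-scale defaults with documented simulation-size reductions.

    The study presented two 600-tone blocks per condition to 35 participants;
    the default simulation keeps the 35 subjects and the two-block roving
    structure (about 200 first-order deviants per condition) and retains up
    to ``max_standards``/``max_deviants`` epochs per condition (the ERP
    averages downstream only need stable subject-level means).
    ``include_deviant_orders`` defaults to first-order deviants, the focus of
    the main analysis.
    """

    n_subjects: int = 35
    n_blocks_per_condition: int = 2
    max_standards: int = 200
    max_deviants: int = 250
    include_deviant_orders: tuple[int, ...] = (1,)
    subject_sd: float = 0.75  # uV, per-component random intercept SD
    noise_white_sd: float = 3.0  # uV per channel per trial
    noise_pink_sd: float = 3.0  # uV per channel per trial
    tmin_ms: float = -100.0
    tmax_ms: float = 450.0
    sfreq: float = 1000.0
    seed: int = 0
    effects: EffectTable = field(default_factory=default_effect_table)
    paradigm: ParadigmConfig = field(default_factory=ParadigmConfig)

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("need at least 2 subjects")

    @property
    def times_ms(self) -> np.ndarray:
        step = 1000.0 / self.sfreq
        return np.arange(self.tmin_ms, self.tmax_ms + step / 2, step)


@dataclass
class EpochSet:
    """Trials x channels x time (microvolts) with per-trial labels."""

    data: np.ndarray
    times_ms: np.ndarray
    labels: pd.DataFrame  # condition, role, deviant_order, shift_hz
    subject_id: int
    montage: Montage

    def __post_init__(self) -> None:
        n_tr, n_ch, n_t = self.data.shape
        if n_ch != self.montage.n_channels or n_t != len(self.times_ms):
            raise ValueError("data shape inconsistent with montage/times")
        if len(self.labels) != n_tr:
            raise ValueError("labels length inconsistent with data")

    def select(self, **criteria) -> np.ndarray:
        """Boolean trial mask, e.g. ``select(condition='harmonic', role='deviant')``."""
        mask = np.ones(len(self.labels), dtype=bool)
        for key, value in criteria.items():
            mask &= (
                (self.labels[key] == value).fillna(False).to_numpy(dtype=bool)
            )
        return mask

    def save(self, path: Path | str) -> None:
        path = Path(path)
        np.savez_compressed(
            path,
            data=self.data.astype(np.float32),
            times_ms=self.times_ms,
            positions=self.montage.positions,
        )
        meta = {
            "subject_id": self.subject_id,
            "channels": list(self.montage.names),
            "roi": list(self.montage.roi),
            "labels": self.labels.to_dict(orient="list"),
        }
        path.with_suffix(".json").write_text(json.dumps(meta))

    @classmethod
    def load(cls, path: Path | str) -> "EpochSet":
        path = Path(path)
        with np.load(path.with_suffix(".npz")) as arr:
            data = arr["data"]
            times_ms = arr["times_ms"]
            positions = arr["positions"]
        meta = json.loads(path.with_suffix(".json").read_text())
        labels = pd.DataFrame(meta["labels"])
        if "deviant_order" in labels:
            labels["deviant_order"] = labels["deviant_order"].astype("Int64")
        mont = Montage(
            names=tuple(meta["channels"]),
            positions=positions,
            roi=tuple(meta["roi"]),
        )
        return cls(
            data=data,
            times_ms=times_ms,
            labels=labels,
            subject_id=meta["subject_id"],
            montage=mont,
        )


def _topography(montage: Montage) -> np.ndarray:
    d = np.linalg.norm(montage.positions - np.asarray(TOPO_CENTER), axis=1)
    return np.exp(-0.5 * (d / TOPO_SIGMA) ** 2)


def _pink_noise(rng: np.random.Generator, shape: tuple, sfreq: float) -> np.ndarray:
    """Unit-SD 1/f noise along the last axis."""
    n_t = shape[-1]
    white = rng.standard_normal(shape)
    spec = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(n_t, d=1.0 / sfreq)
    scale = np.zeros_like(freqs)
    scale[1:] = 1.0 / np.sqrt(freqs[1:])
    pink = np.fft.irfft(spec * scale, n=n_t, axis=-1)
    sd = pink.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return pink / sd


def _subject_rng(seed: int, subject_id: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((seed, subject_id)))


def _select_trials(
    table: pd.DataFrame, design: SimulationDesign, rng: np.random.Generator
) -> pd.DataFrame:
    std = table[table["role"] == "standard"]
    if len(std) > design.max_standards:
        std = std.iloc[np.sort(rng.choice(len(std), design.max_standards, replace=False))]
    parts = [std]
    for order in design.include_deviant_orders:
        dev = table[
            (table["role"] == "deviant") & (table["deviant_order"] == order)
        ]
        if len(dev) > design.max_deviants:
            dev = dev.iloc[
                np.sort(rng.choice(len(dev), design.max_deviants, replace=False))
            ]
        parts.append(dev)
    return pd.concat(parts, ignore_index=True)


def simulate_subject(
    design: SimulationDesign,
    subject_id: int,
    event_tables: dict[str, pd.DataFrame] | None = None,
    montage: Montage | None = None,
) -> EpochSet:
    """One subject's epochs; deterministic per (design.seed, subject_id)."""
    montage = montage or default_montage()
    rng = _subject_rng(design.seed, subject_id)
    times = design.times_ms
    topo = _topography(montage)

    if event_tables is None:
        event_tables = {}
        for cond in CONDITIONS:
            blocks = [
                generate_block(cond, rng, design.paradigm)
                for _ in range(design.n_blocks_per_condition)
            ]
            event_tables[cond] = pd.concat(blocks, ignore_index=True)
    missing = set(CONDITIONS) - set(event_tables)
    if missing:
        raise ValueError(f"event tables missing conditions: {sorted(missing)}")

    # Independent subject intercept per amplitude-table cell (component x
    # condition), shared across trials and roles: this is the subject-by-
    # condition variance that gives the downstream repeated-measures models
    # their error term.
    intercepts = {
        (name, cond): rng.normal(0.0, design.subject_sd)
        for name in DEFAULT_COMPONENTS
        for cond in CONDITIONS
    }

    label_parts = []
    for cond in CONDITIONS:
        sel = _select_trials(event_tables[cond], design, rng)
        label_parts.append(
            sel[["condition", "role", "deviant_order", "shift_hz"]]
        )
    labels = pd.concat(label_parts, ignore_index=True)

    # Noise-free templates per (condition, is_deviant) cell.
    courses = {n: c.time_course(times) for n, c in DEFAULT_COMPONENTS.items()}
    templates: dict[tuple[str, bool], np.ndarray] = {}
    for cond in CONDITIONS:
        for is_dev in (False, True):
            tmpl = np.zeros((montage.n_channels, len(times)))
            for name in DEFAULT_COMPONENTS:
                amp = design.effects.amplitude(name, cond, is_dev)
                if _intercept_applies(name, is_dev):
                    amp += intercepts[(name, cond)]
                if amp != 0.0:
                    tmpl += amp * np.outer(topo, courses[name])
            templates[(cond, is_dev)] = tmpl

    n_trials = len(labels)
    data = np.empty((n_trials, montage.n_channels, len(times)), dtype=np.float32)
    is_deviant = (labels["role"] == "deviant").to_numpy()
    conds = labels["condition"].to_numpy()
    for i in range(n_trials):
        data[i] = templates[(conds[i], bool(is_deviant[i]))]
    if design.noise_pink_sd > 0:
        data += design.noise_pink_sd * _pink_noise(
            rng, (n_trials, montage.n_channels, len(times)), design.sfreq
        ).astype(np.float32)
    if design.noise_white_sd > 0:
        data += design.noise_white_sd * rng.standard_normal(
            (n_trials, montage.n_channels, len(times))
        ).astype(np.float32)

    return EpochSet(
        data=data,
        times_ms=times,
        labels=labels,
        subject_id=subject_id,
        montage=montage,
    )


def _intercept_applies(name: str, is_deviant: bool) -> bool:
    """Subject intercepts ride on a component wherever that component can occur:
    N1/P2/ORN on every tone, MMN/P3a on deviants only."""
    if name in ("N1", "P2", "ORN"):
        return True
    return is_deviant


def simulate_dataset(
    design: SimulationDesign, montage: Montage | None = None
) -> list[EpochSet]:
    """Independent subjects sharing one design. For large designs prefer
    iterating ``simulate_subject`` and reducing to ERPs subject by subject."""
    return [
        simulate_subject(design, sid, montage=montage)
        for sid in range(design.n_subjects)
    ]
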