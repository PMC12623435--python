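"""Complex-tone synthesis: harmonic and frequency-jittered stimuli.

Tones are sums of equal-amplitude sine-phase partials. Harmonic tones contain
every integer multiple of the fundamental (F0) strictly below the Nyquist
frequency. Inharmonic tones multiply each partial above the F0 by
``1 + u_n`` with ``u_n ~ U(-0.5, 0.5)``; patterns producing any pair of
partials closer than 30 Hz at any F0 of the roving grid are rejected and
redrawn, which avoids audible beating. All tones are 70 ms, linearly ramped
over 5 ms at onset and offset, and loudness-normalized to -12 LUFS
(ITU-R BS.1770 K-weighting, un-gated: the clips are shorter than the 400 ms
gating block).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.io import wavfile
from scipy.signal import lfilter

__all__ = [
    "SynthConfig",
    "JitterPattern",
    "ToneSpec",
    "Waveform",
    "make_harmonic_partials",
    "draw_jitter_pattern",
    "apply_jitter",
    "harmonic_tone_spec",
    "synthesize_tone",
    "measure_loudness",
    "normalize_loudness",
    "build_sound_pool",
    "load_waveform",
    "ResamplingExhausted",
]

DEFAULT_F0_GRID = (500.0, 550.0, 600.0, 650.0, 700.0, 750.0, 800.0)


class ResamplingExhausted(RuntimeError):
    """Rejection sampling failed to find a valid jitter pattern."""


@dataclass(frozen=True)
class SynthConfig:
    """Synthesis constants.

    ``f0_grid`` is the roving grid in Hz; ``min_spacing`` is the smallest
    allowed gap between any two partials of an accepted jittered tone, for
    every F0 on the grid.
    """

    sample_rate: float = 48_000.0
    duration: float = 0.070
    ramp: float = 0.005
    target_loudness: float = -12.0
    bit_depth: int = 16
    f0_grid: tuple[float, ...] = DEFAULT_F0_GRID
    jitter_low: float = -0.5
    jitter_high: float = 0.5
    min_spacing: float = 30.0
    ramp_shape: str = "linear"  # or "cosine"
    max_pattern_draws: int = 10_000

    def __post_init__(self) -> None:
        if not 0 < 2 * self.ramp <= self.duration:
            raise ValueError("need 0 < 2*ramp <= duration")
        if any(f <= 0 for f in self.f0_grid):
            raise ValueError("f0_grid values must be positive")
        if list(self.f0_grid) != sorted(set(self.f0_grid)):
            raise ValueError("f0_grid must be strictly increasing")
        if not self.jitter_low < self.jitter_high:
            raise ValueError("jitter_low must be < jitter_high")
        if self.min_spacing <= 0:
            raise ValueError("min_spacing must be positive")
        if self.ramp_shape not in ("linear", "cosine"):
            raise ValueError("ramp_shape must be 'linear' or 'cosine'")

    @property
    def nyquist(self) -> float:
        return self.sample_rate / 2.0

    @property
    def n_samples(self) -> int:
        return int(round(self.duration * self.sample_rate))


@dataclass(frozen=True)
class JitterPattern:
    """Per-partial multiplicative jitter, indexed by harmonic number.

    ``values[0]`` corresponds to the F0 and is always 0 (the F0 is never
    jittered); ``values[n-1]`` multiplies harmonic ``n`` as ``n*f0*(1+u_n)``.
    Because values are indexed by harmonic number, one pattern transfers
    across all F0s of the grid.
    """

    values: tuple[float, ...]
    pattern_id: str = ""
    rng_seed: int | None = None

    def __post_init__(self) -> None:
        if len(self.values) < 1:
            raise ValueError("pattern needs at least one value")
        if self.values[0] != 0.0:
            raise ValueError("F0 jitter must be 0")


@dataclass(frozen=True)
class ToneSpec:
    """A single complex tone: sorted partial frequencies, equal amplitudes."""

    f0: float
    partial_freqs: tuple[float, ...]
    condition: str = "harmonic"
    pattern_id: str | None = None

    def __post_init__(self) -> None:
        freqs = np.asarray(self.partial_freqs)
        if len(freqs) == 0:
            raise ValueError("empty partial list")
        if np.any(np.diff(freqs) <= 0):
            raise ValueError("partial_freqs must be strictly increasing")
        if freqs[0] != self.f0:
            raise ValueError("first partial must equal f0")


@dataclass(frozen=True)
class Waveform:
    samples: np.ndarray
    sample_rate: float

    @property
    def n_samples(self) -> int:
        return len(self.samples)


def make_harmonic_partials(f0: float, cfg: SynthConfig) -> np.ndarray:
    """All integer multiples of ``f0`` strictly below the Nyquist frequency.

    A component at exactly Nyquist is unrepresentable in sine phase, so the
    inequality is strict.
    """
    if f0 <= 0 or f0 >= cfg.nyquist:
        raise ValueError(f"f0 must be in (0, {cfg.nyquist}) Hz, got {f0}")
    n_max = int(np.ceil(cfg.nyquist / f0)) - 1
    return f0 * np.arange(1, n_max + 1)


def _jittered_partials(f0: float, values: np.ndarray, cfg: SynthConfig) -> np.ndarray:
    """Jitter the harmonic series of ``f0``, drop >= Nyquist, sort ascending."""
    harm = make_harmonic_partials(f0, cfg)
    if len(values) < len(harm):
        raise ValueError(
            f"pattern has {len(values)} values but f0={f0} has {len(harm)} partials"
        )
    freqs = harm * (1.0 + values[: len(harm)])
    freqs = freqs[freqs < cfg.nyquist]
    return np.sort(freqs)


def _pattern_valid(values: np.ndarray, cfg: SynthConfig) -> bool:
    for f0 in cfg.f0_grid:
        freqs = _jittered_partials(f0, values, cfg)
        if len(freqs) == 0:
            return False
        if len(freqs) > 1 and np.min(np.diff(freqs)) < cfg.min_spacing:
            return False
    return True


def max_grid_partials(cfg: SynthConfig) -> int:
    """Largest harmonic count over the F0 grid (pattern length needed)."""
    return max(len(make_harmonic_partials(f0, cfg)) for f0 in cfg.f0_grid)


def draw_jitter_pattern(
    rng: np.random.Generator,
    cfg: SynthConfig,
    n_partials: int | None = None,
    pattern_id: str = "",
    rng_seed: int | None = None,
) -> JitterPattern:
    """Rejection-sample a jitter pattern valid at every F0 of the grid.

    Whole patterns are redrawn on any spacing conflict at any grid F0: in the
    inharmonic condition one pattern must serve all F0s of a block.
    """
    if n_partials is None:
        n_partials = max_grid_partials(cfg)
    if n_partials < 1:
        raise ValueError("n_partials must be >= 1")
    values = np.zeros(n_partials)
    for _ in range(cfg.max_pattern_draws):
        values[1:] = rng.uniform(cfg.jitter_low, cfg.jitter_high, n_partials - 1)
        if n_partials == 1 or _pattern_valid(values, cfg):
            return JitterPattern(tuple(values), pattern_id=pattern_id, rng_seed=rng_seed)
    raise ResamplingExhausted(
        f"no valid pattern in {cfg.max_pattern_draws} draws"
    )


def apply_jitter(f0: float, pattern: JitterPattern, cfg: SynthConfig) -> ToneSpec:
    """Jittered tone spec for ``f0``: partial ``n`` at ``n*f0*(1+u_n)``."""
    freqs = _jittered_partials(f0, np.asarray(pattern.values), cfg)
    if len(freqs) > 1 and np.min(np.diff(freqs)) < cfg.min_spacing:
        raise ValueError("jittered partials violate min_spacing")
    return ToneSpec(
        f0=f0,
        partial_freqs=tuple(freqs),
        condition="inharmonic",
        pattern_id=pattern.pattern_id or None,
    )


def harmonic_tone_spec(f0: float, cfg: SynthConfig) -> ToneSpec:
    return ToneSpec(
        f0=f0,
        partial_freqs=tuple(make_harmonic_partials(f0, cfg)),
        condition="harmonic",
    )


def _envelope(cfg: SynthConfig) -> np.ndarray:
    n = cfg.n_samples
    n_ramp = int(round(cfg.ramp * cfg.sample_rate))
    env = np.ones(n)
    if n_ramp > 0:
        x = np.arange(n_ramp) / n_ramp
        ramp = x if cfg.ramp_shape == "linear" else 0.5 * (1 - np.cos(np.pi * x))
        env[:n_ramp] = ramp
        env[-n_ramp:] = ramp[::-1]
    return env


def synthesize_tone(spec: ToneSpec, cfg: SynthConfig) -> Waveform:
    """Sum of zero-phase sines over partials, ramped. Deterministic."""
    t = np.arange(cfg.n_samples) / cfg.sample_rate
    freqs = np.asarray(spec.partial_freqs)
    samples = np.sin(2.0 * np.pi * np.outer(freqs, t)).sum(axis=0)
    samples *= _envelope(cfg)
    return Waveform(samples=samples, sample_rate=cfg.sample_rate)


# ITU-R BS.1770-4 K-weighting pre-filters, digital coefficients at 48 kHz:
# stage 1 models the acoustic effect of the head (high shelf, +4 dB),
# stage 2 is the revised low-frequency B-curve high-pass.
_KW_SHELF_B = (1.53512485958697, -2.69169618940638, 1.19839281085285)
_KW_SHELF_A = (1.0, -1.69065929318241, 0.73248077421585)
_KW_HP_B = (1.0, -2.0, 1.0)
_KW_HP_A = (1.0, -1.99004745483398, 0.99007225036621)


def _k_weight(samples: np.ndarray, sample_rate: float) -> np.ndarray:
    if abs(sample_rate - 48_000.0) > 1e-6:
        raise ValueError("K-weighting coefficients are defined for 48 kHz only")
    y = lfilter(_KW_SHELF_B, _KW_SHELF_A, samples)
    return lfilter(_KW_HP_B, _KW_HP_A, y)


def measure_loudness(w: Waveform) -> float:
    """Integrated loudness in LUFS, K-weighted, un-gated (mono, weight 1).

    Gating is undefined for clips shorter than the 400 ms gating block, so the
    mean square runs over the whole clip.
    """
    y = _k_weight(np.asarray(w.samples, dtype=float), w.sample_rate)
    ms = np.mean(y**2)
    if ms <= 0:
        raise ValueError("silent waveform has no defined loudness")
    return -0.691 + 10.0 * np.log10(ms)


def normalize_loudness(w: Waveform, target: float) -> Waveform:
    """Pure-gain normalization to ``target`` LUFS, then a [-1, 1] headroom clamp.

    The clamp only engages for high-crest signals (sine-phase harmonic stacks);
    it mirrors what happens when a float signal is written to 16-bit PCM.
    """
    loudness = measure_loudness(w)
    gain = 10.0 ** ((target - loudness) / 20.0)
    samples = np.clip(w.samples * gain, -1.0, 1.0)
    return Waveform(samples=samples, sample_rate=w.sample_rate)


def _write_wav_16bit(path: Path, w: Waveform) -> None:
    pcm = np.round(np.clip(w.samples, -1.0, 1.0) * 32767.0).astype(np.int16)
    wavfile.write(path, int(w.sample_rate), pcm)


def load_waveform(path: Path | str) -> Waveform:
    rate, data = wavfile.read(path)
    if data.dtype == np.int16:
        samples = data.astype(float) / 32768.0
    else:
        samples = data.astype(float)
    return Waveform(samples=samples, sample_rate=float(rate))


def build_sound_pool(
    cfg: SynthConfig,
    n_inharmonic_per_f0: int,
    seed: int,
    out_dir: Path | str,
) -> pd.DataFrame:
    """Write the per-F0 sound pool and its manifest.

    One harmonic WAV per grid F0 plus ``n_inharmonic_per_f0`` jittered WAVs per
    F0. Jitter patterns are drawn once (valid across the whole grid) and each
    pattern is rendered at every F0, carrying the jitter recipe across
    fundamentals. Deterministic under ``seed``.
    """
    if n_inharmonic_per_f0 < 1:
        raise ValueError("n_inharmonic_per_f0 must be >= 1")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    pattern_seeds = np.random.default_rng(seed).integers(
        0, 2**31 - 1, size=n_inharmonic_per_f0
    )
    patterns = []
    for i, pseed in enumerate(pattern_seeds):
        rng = np.random.default_rng(int(pseed))
        patterns.append(
            draw_jitter_pattern(
                rng, cfg, pattern_id=f"jp{i:05d}", rng_seed=int(pseed)
            )
        )

    rows = []
    for f0 in cfg.f0_grid:
        spec = harmonic_tone_spec(f0, cfg)
        w = normalize_loudness(synthesize_tone(spec, cfg), cfg.target_loudness)
        fname = f"harmonic_f{int(f0)}.wav"
        _write_wav_16bit(out / fname, w)
        rows.append((fname, f0, "harmonic", "", -1))
        for pat in patterns:
            spec = apply_jitter(f0, pat, cfg)
            w = normalize_loudness(synthesize_tone(spec, cfg), cfg.target_loudness)
            fname = f"inharmonic_f{int(f0)}_{pat.pattern_id}.wav"
            _write_wav_16bit(out / fname, w)
            rows.append((fname, f0, "inharmonic", pat.pattern_id, pat.rng_seed))

    manifest = pd.DataFrame(
        rows, columns=["file", "f0_hz", "condition", "pattern_id", "seed"]
    )
    manifest.to_csv(out / "manifest.csv", index=False)
    return manifest
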