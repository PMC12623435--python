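"""Tone synthesis: harmonic series, jitter sampling, ramps, loudness, pool."""

import dataclasses

import numpy as np
import pytest
from scipy.io import wavfile
from scipy.signal import bilinear, lfilter
from scipy.stats import kstest

from rovingmmn.synth import (
    JitterPattern,
    SynthConfig,
    apply_jitter,
    build_sound_pool,
    draw_jitter_pattern,
    harmonic_tone_spec,
    load_waveform,
    make_harmonic_partials,
    measure_loudness,
    normalize_loudness,
    synthesize_tone,
)


@pytest.mark.parametrize(
    "f0,n_expected",
    [(500.0, 47), (800.0, 29), (12000.0, 1), (550.0, 43), (750.0, 31)],
)
def test_harmonic_partial_count_strictly_below_nyquist(synth_cfg, f0, n_expected):
    partials = make_harmonic_partials(f0, synth_cfg)
    assert len(partials) == n_expected
    assert partials[0] == f0
    assert partials[-1] < synth_cfg.nyquist
    # exact integer multiples
    assert np.allclose(partials / f0, np.arange(1, n_expected + 1))


@pytest.mark.parametrize("f0", [0.0, -10.0, 24000.0, 30000.0])
def test_harmonic_partials_rejects_bad_f0(synth_cfg, f0):
    with pytest.raises(ValueError):
        make_harmonic_partials(f0, synth_cfg)


def test_jitter_pattern_basic_structure(synth_cfg, rng):
    pat = draw_jitter_pattern(rng, synth_cfg)
    values = np.asarray(pat.values)
    assert values[0] == 0.0
    assert np.all(values >= synth_cfg.jitter_low)
    assert np.all(values <= synth_cfg.jitter_high)
    # accepted pattern keeps >=30 Hz spacing at every grid F0
    for f0 in synth_cfg.f0_grid:
        freqs = np.asarray(apply_jitter(f0, pat, synth_cfg).partial_freqs)
        assert np.min(np.diff(freqs)) >= synth_cfg.min_spacing
        assert freqs[-1] < synth_cfg.nyquist
        assert freqs[0] == f0


def test_jitter_pattern_single_partial(synth_cfg, rng):
    pat = draw_jitter_pattern(rng, synth_cfg, n_partials=1)
    assert pat.values == (0.0,)


def test_jitter_resampling_exhausted():
    cfg = SynthConfig(min_spacing=5000.0, max_pattern_draws=50)
    from rovingmmn.synth import ResamplingExhausted

    with pytest.raises(ResamplingExhausted):
        draw_jitter_pattern(np.random.default_rng(0), cfg)


def _oracle_jitter_draw(rng, cfg):
    """Independent rejection sampler: plain loops, no shared code paths."""
    n = max(
        int(np.ceil(cfg.nyquist / f0)) - 1 for f0 in cfg.f0_grid
    )
    while True:
        u = np.concatenate([[0.0], rng.uniform(cfg.jitter_low, cfg.jitter_high, n - 1)])
        ok = True
        for f0 in cfg.f0_grid:
            freqs = []
            k = 1
            while k * f0 < cfg.nyquist:
                jittered = k * f0 * (1.0 + u[k - 1])
                if jittered < cfg.nyquist:
                    freqs.append(jittered)
                k += 1
            freqs.sort()
            for a, b in zip(freqs, freqs[1:]):
                if b - a < cfg.min_spacing:
                    ok = False
                    break
            if not ok:
                break
        if ok:
            return u


def test_accepted_jitter_matches_independent_rejection_sampler(synth_cfg):
    """The accepted u_2 distribution equals an independent sampler's.

    Rejection truncates u_2 below about -0.47 (partial-1 spacing at 500 Hz)
    and mildly depletes the extremes via collisions among higher jittered
    partials, so the check is two-sample against an oracle sampler rather
    than against the unconditional uniform.
    """
    rng = np.random.default_rng(2024)
    u2 = np.array(
        [draw_jitter_pattern(rng, synth_cfg).values[1] for _ in range(2500)]
    )
    assert u2.min() >= (30.0 / 500.0 - 1.0) / 2.0  # truncation bound
    rng2 = np.random.default_rng(77)
    oracle_u2 = np.array(
        [_oracle_jitter_draw(rng2, synth_cfg)[1] for _ in range(2500)]
    )
    from scipy.stats import ks_2samp

    assert ks_2samp(u2, oracle_u2).pvalue > 0.01
    # and the interior of the distribution is close to uniform
    interior = u2[(u2 >= -0.4) & (u2 <= 0.4)]
    stat = kstest(interior, "uniform", args=(-0.4, 0.8))
    assert stat.statistic < 0.05


def test_apply_jitter_identity_and_examples(synth_cfg):
    n = len(make_harmonic_partials(500.0, synth_cfg))
    zero = JitterPattern(tuple([0.0] * n))
    spec = apply_jitter(500.0, zero, synth_cfg)
    assert np.allclose(spec.partial_freqs, make_harmonic_partials(500.0, synth_cfg))

    values = [0.0] * n
    values[1] = 0.5  # second partial: 1000 * 1.5 = 1500 Hz
    values[2] = 0.2  # move the third partial clear of the jittered second
    spec = apply_jitter(500.0, JitterPattern(tuple(values)), synth_cfg)
    assert 1500.0 in spec.partial_freqs

    # colliding partials (750, 750) violate spacing and are refused
    values = [0.0] * n
    values[1] = -0.25  # 1000 -> 750
    values[2] = -0.5  # 1500 -> 750
    with pytest.raises(ValueError):
        apply_jitter(500.0, JitterPattern(tuple(values)), synth_cfg)


def test_single_partial_tone_spectrum_and_ramp(synth_cfg):
    spec = harmonic_tone_spec(12000.0, synth_cfg)  # single partial
    w = synthesize_tone(spec, synth_cfg)
    assert w.n_samples == 3360
    mags = np.abs(np.fft.rfft(w.samples))
    peak_hz = np.fft.rfftfreq(w.n_samples, 1 / synth_cfg.sample_rate)[np.argmax(mags)]
    assert abs(peak_hz - 12000.0) < 30.0
    assert abs(w.samples[0]) < 1e-9 and abs(w.samples[-1]) < 1e-3


def test_harmonic_tone_autocorrelation_period(synth_cfg):
    """A 500 Hz harmonic complex repeats every 96 samples at 48 kHz."""
    w = synthesize_tone(harmonic_tone_spec(500.0, synth_cfg), synth_cfg)
    x = w.samples[240:-240]  # interior, away from ramps
    ac = np.correlate(x, x, mode="full")[len(x) - 1 :]
    lag = np.argmax(ac[48:200]) + 48
    assert lag == 96


def test_synthesis_deterministic(synth_cfg):
    spec = harmonic_tone_spec(600.0, synth_cfg)
    a = synthesize_tone(spec, synth_cfg)
    b = synthesize_tone(spec, synth_cfg)
    assert np.array_equal(a.samples, b.samples)


def test_zero_jitter_matches_harmonic_synthesis(synth_cfg):
    n = len(make_harmonic_partials(650.0, synth_cfg))
    zero = JitterPattern(tuple([0.0] * n))
    wa = synthesize_tone(apply_jitter(650.0, zero, synth_cfg), synth_cfg)
    wb = synthesize_tone(harmonic_tone_spec(650.0, synth_cfg), synth_cfg)
    assert np.array_equal(wa.samples, wb.samples)


def _independent_k_weighted_loudness(samples, fs):
    """BS.1770 meter built from the analog prototype via bilinear transform
    (independent of the hardcoded digital coefficients in the package)."""
    # high shelf: +4 dB at high frequencies, fc ~1681.97 Hz, Q ~0.7072
    import math

    f0, G, Q = 1681.9744509555319, 3.99984385397, 0.7071752369554196
    K = math.tan(math.pi * f0 / fs)
    Vh = 10 ** (G / 20.0)
    Vb = Vh**0.4996667741545416
    a0 = 1 + K / Q + K * K
    b = [(Vh + Vb * K / Q + K * K) / a0, 2 * (K * K - Vh) / a0,
         (Vh - Vb * K / Q + K * K) / a0]
    a = [1.0, 2 * (K * K - 1) / a0, (1 - K / Q + K * K) / a0]
    y = lfilter(b, a, samples)
    # high-pass: fc ~38.135 Hz, Q ~0.5003
    f0, Q = 38.13547087602444, 0.5003270373238773
    K = math.tan(math.pi * f0 / fs)
    a0 = 1 + K / Q + K * K
    b = [1.0, -2.0, 1.0]
    a = [1.0, 2 * (K * K - 1) / a0, (1 - K / Q + K * K) / a0]
    y = lfilter(b, a, y)
    return -0.691 + 10 * np.log10(np.mean(y**2))


def test_loudness_normalization_properties(synth_cfg, rng):
    pat = draw_jitter_pattern(rng, synth_cfg)
    w = synthesize_tone(apply_jitter(500.0, pat, synth_cfg), synth_cfg)
    norm = normalize_loudness(w, -12.0)
    # inharmonic tones do not clip, so the target is met exactly
    assert abs(measure_loudness(norm) - (-12.0)) < 0.1
    # idempotence: renormalizing changes nothing
    again = normalize_loudness(norm, -12.0)
    assert np.max(np.abs(again.samples - norm.samples)) < 1e-3 * np.max(
        np.abs(norm.samples)
    )
    # pure-gain invariance: prescaling is irrelevant
    half = dataclasses.replace(w, samples=w.samples * 0.5)
    assert np.allclose(
        normalize_loudness(half, -12.0).samples, norm.samples, atol=1e-9
    )
    # independent BS.1770 meter agrees
    oracle = _independent_k_weighted_loudness(norm.samples, synth_cfg.sample_rate)
    assert -12.5 < oracle < -11.5


def test_loudness_rejects_silence(synth_cfg):
    from rovingmmn.synth import Waveform

    silent = Waveform(samples=np.zeros(3360), sample_rate=48000.0)
    with pytest.raises(ValueError):
        measure_loudness(silent)


@pytest.mark.parametrize("n_per_f0", [1, 2])
def test_sound_pool_counts_format_and_determinism(tmp_path, synth_cfg, n_per_f0):
    out_a = tmp_path / "a"
    man_a = build_sound_pool(synth_cfg, n_per_f0, seed=5, out_dir=out_a)
    assert len(man_a) == 7 * (1 + n_per_f0)
    assert (man_a["condition"] == "harmonic").sum() == 7

    rate, data = wavfile.read(out_a / man_a["file"].iloc[0])
    assert rate == 48000 and data.dtype == np.int16

    out_b = tmp_path / "b"
    man_b = build_sound_pool(synth_cfg, n_per_f0, seed=5, out_dir=out_b)
    assert man_a.equals(man_b)
    for f in man_a["file"]:
        assert (out_a / f).read_bytes() == (out_b / f).read_bytes()


def test_pool_loudness_and_rms_consistency(tmp_path, synth_cfg):
    man = build_sound_pool(synth_cfg, 2, seed=5, out_dir=tmp_path)
    rms = {}
    for _, row in man.iterrows():
        w = load_waveform(tmp_path / row["file"])
        # harmonic stacks clip slightly at -12 LUFS (crest ~7); all tones
        # stay within ~1 LU of target
        assert -13.2 < measure_loudness(w) < -11.9
        rms[(row["condition"], row["file"])] = np.sqrt(np.mean(w.samples**2))
    inh = np.array([v for (c, _), v in rms.items() if c == "inharmonic"])
    assert (inh.max() - inh.min()) / inh.mean() < 0.02
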