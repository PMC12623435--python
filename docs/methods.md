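# Methods

This note documents the models and procedures the package implements, the
defaults and why they were chosen, what the synthetic data generator does and
does not emulate, and the numerical decisions that matter.

## Stimulus synthesis

A tone is a sum of equal-amplitude, zero-phase sines. Harmonic tones use
every integer multiple of the fundamental **strictly below** the 24 kHz
Nyquist frequency (a component at exactly Nyquist is unrepresentable in sine
phase). Inharmonic tones multiply harmonic `n ≥ 2` by `1 + u_n`,
`u_n ~ U(-0.5, 0.5)`; the fundamental is never jittered. Jittered partials
landing at or above Nyquist are dropped rather than clipped (aliasing
safety). A whole jitter pattern is rejected and redrawn if, at **any**
fundamental of the 500–800 Hz grid, two surviving partials fall within
30 Hz — one pattern must serve every fundamental of an inharmonic block,
since the pattern is indexed by harmonic number and carried across
fundamentals. The draw cap is 10,000 whole-pattern attempts (acceptance runs
at roughly 1-in-10 under the defaults).

Rejection sampling distorts the accepted jitter marginals in two small ways
worth knowing about: `u_2` is truncated below ≈ −0.47 (the partial-1/
partial-2 gap `f0(1 + 2u_2) ≥ 30 Hz` at 500 Hz), and the extremes of every
`u_n` are mildly depleted by joint collisions among neighboring jittered
partials. The tests therefore validate the sampler against an independently
written rejection sampler rather than against the unconditional uniform.

Tones are 70 ms (3360 samples at 48 kHz) with 5 ms linear on/off ramps
(raised-cosine available; the envelope shape is otherwise unconstrained).
Loudness normalization is a pure gain to −12 LUFS measured with the ITU-R
BS.1770 K-weighting (48 kHz biquad coefficients) and an **un-gated** mean
square — the clips are shorter than the 400 ms gating block, so gating is
undefined. Sine-phase harmonic stacks have a crest factor near 7, so the
−12 LUFS target forces mild clipping at the ±1 headroom clamp (exactly what
happens when such a float signal is written to 16-bit PCM); harmonic tones
therefore measure ≈1 LU below target after the clamp, while inharmonic
tones, whose partials are incommensurate, do not clip. Equal K-weighted
loudness does **not** imply equal RMS across different spectra; within the
inharmonic condition RMS agrees to well under 2%.

## Roving-oddball sequences

Blocks hold exactly 600 tones at a 600 ms onset-to-onset interval (the only
reading consistent with 600 tones in a 6-minute block), giving 6 minutes per
block. Train lengths are drawn from 3–11 with weights 4:4:4:4:4:1:1:1:1
(P(L ≤ 7) = 20/24, E[L] = 5.75); the final train is truncated at tone 600.
Each new train's fundamental is uniform over the six grid values different
from the current one, implying shifts of ±50…300 Hz. Labels: tones at
positions 1–3 of every non-initial train are deviants of order 1–3; tones
from position 4 on are standards; the first five tones of a block are
excluded. The expected number of first-order deviants per block is
600/5.75 − 1 ≈ 103 (the block-initial train carries no deviant); the
generator's long-run mean is ≈104. Pattern assignment: harmonic blocks none,
inharmonic blocks a single pattern, changing blocks a fresh pattern per
sound by default (a per-train mode is available as a config switch, since
descriptions of this condition vary between per-sound and per-train).

## Stimulus entropy

Approximate entropy (Pincus): `ApEn = Phi_m(r) − Phi_{m+1}(r)`, where
`Phi_m` is the mean log fraction of templates within Chebyshev distance `r`
(self-matches included, counts normalized by the number of templates of that
dimension). Defaults m = 2, r = 0.2·SD. The implementation counts matches
with a k-d tree and is verified against a brute-force double loop to 1e−10.

Two readings of "the entropy of a tone" are provided. The default,
`signal="spectral"`, applies ApEn to the tone's **sorted partial-frequency
series**: a harmonic series is an arithmetic progression, for which ApEn is
slightly *negative* — with `N` templates the match count is nearly constant,
leaving `ApEn ≈ ln((N−3)/(N−2)) ≈ −0.02…−0.035` for the 30–47 partials on
the grid — while jittering raises it to ≈0.16–0.19 per fundamental, with a
spread across fundamentals of about 0.01. The alternative,
`signal="waveform"`, applies ApEn to the full normalized 70 ms waveform; at
48 kHz the inharmonic waveform decorrelates within a couple of samples and
ApEn saturates near 2.0 (harmonic ≈0.08). The spectral reading is the
default because it is the one whose pool-level statistics match the scale
this stimulus set is known for; the ordering harmonic < inharmonic at every
fundamental holds under both readings, and the SD-relative tolerance makes
both readings invariant to loudness normalization.

## Synthetic EEG

Thirty 10–20 channels with schematic unit-disc positions (a 32-channel
active cap minus the two mastoids, which are treated as the already-applied
reference). Each trial is a superposition of Gaussian-bump components
scaled by a frontocentral topography (isotropic Gaussian falloff, σ = 0.55,
centered between Fz and FCz) plus noise:

| component | latency | width (SD) | amplitude (µV) |
|---|---|---|---|
| N1 (every tone) | 100 ms | 25 ms | −2.0 |
| P2 (every tone) | 141 ms | 40 ms | +2.0 |
| MMN (deviants) | 150 ms | 25 ms | harmonic −1.0, inharmonic −0.7, changing 0 |
| P3a (deviants) | 250 ms | 40 ms | harmonic +0.8, inharmonic +2.0, changing +0.7 |
| ORN (all tones) | 141 ms | 25 ms | harmonic 0, inharmonic −1.0, changing −1.0 |

Latencies sit at the centers of the component windows this paradigm is
analyzed with (MMN 120–180 ms, P3a 216–286 ms, P2 at the 141 ms
grand-average peak). The amplitude table reproduces the qualitative effect
structure: MMN present for harmonic and inharmonic deviants but absent when
the jitter pattern changes every sound, P3a largest for inharmonic tones,
and an ORN on every inharmonic/changing tone (so it cancels in
deviant−standard contrasts but appears in cross-condition ones).

Every (component × condition) amplitude cell carries an independent
per-subject intercept ~ N(0, 0.75² µV²), shared across trials and across the
standard/deviant roles of that condition. This is deliberately a
subject-**by-condition** random effect: a single per-component intercept
shared across conditions would cancel in all between-condition contrasts and
drive their standard errors to the trial-noise floor (≈0.05 µV), which is
far tighter than such experiments ever show; with the per-cell reading the
contrast SEs land near 0.1–0.15 µV and the repeated-measures models have a
realistic error stratum.

Noise is per-channel, per-trial 1/f ("pink", FFT-shaped, unit-SD-normalized,
3 µV) plus white noise (3 µV). Trial counts follow the study design: two
600-tone blocks per condition per subject, all ≈200 first-order deviants
retained, standards subsampled to 200 (subject-level means are already
stable there); second/third-order deviants can be included via
`include_deviant_orders`. 35 subjects by default. Everything is
deterministic given (seed, subject id).

What the generator does **not** emulate: realistic forward-model scalp
topographies, eye/heart artifacts or artifact rejection, latency jitter
across trials or subjects, trial-to-trial amplitude variability of the
components (beyond additive noise), and condition-specific waveform shapes.
Passing tests on this data show that the analysis chain recovers the effect
structure it assumes from realistically noisy epochs — not that real EEG
would yield the same numbers.

## ERP pipeline

30 Hz low-pass: 4th-order Butterworth applied forward–backward (zero phase);
the raw-data 0.2 Hz high-pass of a real-recording workflow has no epoched
equivalent here and is retained only as a documented no-op for real-data
adapters. Baseline: subtract the −100…0 ms mean per trial and channel.
Averaging, difference waves (deviant−standard within condition;
cross-condition for ORN analyses) and the unweighted frontocentral ROI mean
are all linear, a property the tests exploit. Peak measures: MMN latency =
argmin in 70–250 ms, P3a = argmax in 150–400 ms, ties toward the earlier
sample; mean amplitude = mean over latency ±25 ms, clipped at epoch edges
and flagged when clipped. P2 mean amplitude uses a fixed 141 ±25 ms window
on standard or deviant ROI traces (the 50 ms width mirrors the peak-centered
windows; the exact width is a documented choice).

Peak picking on noisy traces is biased toward the extremes: a condition with
no true MMN still yields a negative measured mean (≈−0.2 µV at the default
noise and trial counts). This bias is inherent to extreme-picking measures,
shrinks with trial count, and affects all conditions; between-condition
contrasts remain interpretable but are attenuated relative to the injected
amplitudes.

## Cluster-based permutation tests

Cell-wise statistics over the (channel × time) grid: a one-sample t on
within-subject differences, or a one-way repeated-measures F
(`MS_cond / MS_cond×subj`). Cluster-forming thresholds are the parametric
quantiles at α = 0.05 from the design's degrees of freedom (t two-sided, F
one-sided) — the "automatic threshold from the number of observations"
convention. Zero-variance cells get statistic 0: they carry no evidence and
must not seed clusters. Supra-threshold cells are clustered by connectivity
= temporal adjacency within a channel OR sensor adjacency at the same time;
sensor adjacency connects channels closer than 0.48 in the unit-disc layout
(median degree 5, connected graph). Positive and negative t exceedances
cluster separately. The cluster statistic is the mass (sum of cell
statistics); the null is the maximum |mass| per permutation across both
tails (max-statistic correction), with per-subject sign flips (t) or
within-subject condition-label permutations (F). p = (1 + #{null ≥
observed}) / (1 + n_permutations) — the identity permutation enters through
the add-one correction, and the smallest attainable p at the default 1024
permutations is 1/1025. Post-hoc pairwise cluster tests after an F are
evaluated against Bonferroni α = 0.05/3.

Formation is implemented with connected components on a sparse cell graph
and verified against a recursive flood-fill oracle; observed maps, clusters
and masses are cross-checked against the reference MNE spatio-temporal
implementation (p-values are not compared — permutation draws differ).
Familywise error on exchangeable null data calibrates to ≈0.05 (500
datasets, 20 subjects, 6 channels, 200 permutations).

## Repeated-measures inference

For the balanced within-subject designs used here, the condition test of a
linear model with participant random intercepts is exactly the
repeated-measures ANOVA, so the package implements the closed-form
sums-of-squares decomposition and **rejects unbalanced tables** rather than
claiming a general REML fitter. One-way: F = MS_cond/MS_cond×subj with
df (k−1, (k−1)(n−1)). Two-way (condition × deviance): a single pooled
within-subject error stratum with df = nab − ab − (n−1) = (ab−1)(n−1) — 170
for the 3×2 design at n = 35 — mirroring the mixed model's shared residual
df. Degenerate error strata (perfect fits) yield F = ∞ for non-null effects
rather than 0.

Tukey HSD contrasts take SE = √(2·MS_err/n) from the ANOVA error term and
p-values from the studentized-range distribution with the error df; adjusted
p is never smaller than the unadjusted pairwise p.

Model comparison reports `df_resid · ln(RSS0/RSS1)` with df = k−1. The
naive N-scaled log-likelihood-ratio is visibly inflated at this design size
(its null mean is N(k−1)/df_resid ≈ 3.1 for n = 35, k = 3); scaling by the
residual df is the standard small-sample correction and keeps the statistic
χ²-calibrated under the null, which the tests verify by simulation.

## Power simulation

Subject-level condition means are simulated as intercept + effect +
residual, with effects (0, e, e) µV for (harmonic, inharmonic, changing) —
the planning assumption is that the changing condition behaves like
inharmonic — and tested with the one-way RM-ANOVA at α = 0.05. The ANOVA is
invariant to the subject intercept, so power depends only on the residual
SD. Defaults: subject SD 1.5 µV, residual SD 1.5 µV. The residual default is
a calibration, not an estimate: the noncentrality at N subjects is
λ = (2/3)·N·e²/σ², and σ = 1.5 puts 80% power for a 1 µV effect at N ≈ 33
(closed form: λ(33) = 9.8, power 0.805; Monte-Carlo at 2000 sims: 0.79–0.80).
With σ = 1.0 the same effect would have λ(33) = 22 and power ≈ 0.99, which
is inconsistent with an 80%-power design point at N = 33. At zero effect the
rejection rate equals α (the F test is exact under normality).

## Known limitations

* The synthesis path supports 48 kHz only (the K-weighting biquads are the
  standard's 48 kHz coefficients).
* The entropy module's spectral reading reconstructs partial series from
  the pool manifest's recorded seeds; a peak-picking estimator from the WAV
  spectra is not provided.
* No general (unbalanced) mixed-model estimation, no AIC, no ordinal models
  for behavioral counts; `count_error` is provided but group inference on
  behavioral data is out of scope.
* Cluster tests implement the mass statistic only (no TFCE), and sensor
  adjacency is the distance rule above (configurable radius), not a
  template-specific neighbor file.
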