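# Methods

This note documents the models, estimators and numerical choices behind
`specratio`, and what the synthetic-data experiments do and do not show.

## Spectral model and band powers

Band powers are estimated with Welch's method: segments of `window_s`
seconds (Hamming taper, 50% overlap, per-segment mean removal), each
zero-padded to an FFT length of `steps_per_hz × fs` samples so that the
one-sided density lives on a grid of `1/steps_per_hz` Hz. "Steps per Hz"
is therefore realized as zero-padding; at 500 Hz the three standard
parameterizations decompose into window/FFT/overlap sample counts
1000/5000/500 (2 s/10), 1000/2500/500 (2 s/5) and 500/5000/250 (1 s/10).
The density is Parseval-consistent: its sum times the grid spacing equals
the tapered signal's mean power (checked to 5% on long stationary noise).
The implementation batches all segments through a single FFT call and is
verified against `scipy.signal.welch` to machine precision; a useful exact
identity (also tested) is that the 2 s/5 spectrum equals every second bin
of the 2 s/10 spectrum, which the multi-parameterization driver exploits.

Band edges are half-open, `(low, high]`, with the first band closed below:
δ [0.5, 4], θ (4, 8], α (8, 13], β (13, 30], γ (30, 45] Hz. This keeps
every grid point in exactly one band; where a convention had to be chosen
the explicit "greater-than" readings of the β/γ edges were honored. The
band power is the *mean* density over the in-band grid points (an "absolute
average" power, μV²/Hz-scaled), the lobar power the mean of the lobe's
electrode band powers (frontal: Fp1, Fp2, F3, F4, F7, F8, Fz; temporal:
T3, T4, T5, T6 — legacy 10–20 names are canonical internally, with
T7/T8/P7/P8 mapped on input). Averaging powers before ratioing (rather
than ratioing per electrode) follows the "frontal power / temporal power"
reading; by linearity the order of power averaging itself is immaterial.
Ratios with a zero denominator become missing values and are dropped per
feature downstream.

## Referencing

Average reference subtracts the instantaneous channel mean. REST
(reference electrode standardization technique) maps average-referenced
data toward an infinity reference via `V_rest = G · pinv(G_avg) · V_avg`,
where `G` is the lead field of an equivalent source layer referenced at
infinity and `G_avg` its column-centered version. The volume conductor is
the classical three-concentric-sphere head: relative radii 0.87/0.92/1.0,
relative conductivities 1/0.0125/1, with 300 radial unit dipoles evenly
spread (golden-spiral lattice) at radius 0.86. The forward solution is the
analytic Legendre series; per degree n the five layered boundary
conditions give a 5×5 linear system, truncated at n = 80 (terms decay like
0.86ⁿ ≈ 3·10⁻⁷ at the cutoff). With equal conductivities the solver
reproduces the homogeneous-sphere closed form to machine precision, and a
radial dipole's largest lead-field entry falls on its nearest electrode.
The pseudo-inverse truncates singular values below 1e−6 of the largest
(G_avg is rank-deficient by one, by construction). Electrode coordinates
come from the standard 10–20 spherical layout, radially projected onto the
unit sphere.

**Known limitation.** With only 19 electrodes, REST recovers the
average-reference offset imperfectly: re-referencing data forward-simulated
from the model's own source layer leaves a relative error of roughly 10%
(sources under the cap) to 19% (whole layer), falling below ~5% only for
the best-covered sources. This electrode-density dependence is a property
of the method, not of the implementation (it is insensitive to the
pseudo-inverse threshold, source-layer depth and density, dipole
orientations, and skull conductivity); the test suite pins the measured
behavior, including one intentionally strict 5% recovery bound that fails
at this montage density and is kept as documentation of the target. What
REST is used for here — checking that group contrasts survive the
reference choice — does not require offset-perfect reconstruction.

## Synthetic cohorts

Each channel is a sum over bands of `a(lobe, band) × unit-RMS band-limited
noise`, plus a 1/f^β background floor. Band noise is built in the
frequency domain (i.i.d. complex Gaussian coefficients inside the band,
zero outside, Parseval-normalized to exactly unit sample RMS), so adjacent
half-open bands occupy disjoint bins and channel RMS is exactly the root
sum of squared amplitudes. Defaults, chosen once as a plausible
eyes-closed adult resting profile: δ/θ/α/β/γ base amplitudes
10/7/12/5/2 μV RMS in all lobes; background β = 1 with RMS scale
0.1 × mean base amplitude (no power below 0.5 Hz, matching band-passed
preprocessed clinical data).

Group structure is multiplicative on amplitudes, patient (FTD) group only:
frontal θ ×1.3, frontal α ×0.75, temporal α ×0.7, temporal γ ×1.25, all
else 1; non-frontal/temporal channels always keep the control profile.
Between-subject variability is one log-normal factor (σ = 0.2) per
(subject, lobe, band), shared across a lobe's electrodes. These effect
sizes are calibration choices reproducing the intended *directions* and an
AUC regime around 0.75–0.95 for the headline ratios at n = 23/29; no
quantitative per-band effect sizes were available to copy. Demographics:
age ~ N(63.6, 8.2²) FTD / N(67.9, 5.4²) CTL, female proportion 0.39/0.38,
MMSE ~ N(22.17, 8.22²) clipped to [0, 30] for FTD and fixed 30 for CTL.

What the generator does *not* emulate: artifacts (blinks, EMG, line
noise), nonstationarity, channel-specific noise, volume-conduction
correlation between channels (band noise is channel-independent), or any
preprocessing chain. Passing tests therefore demonstrate the statistical
machinery under clean, stationary, within-lobe-exchangeable signals — not
robustness to real clinical recordings.

Recordings serialize to EDF (16-bit, 1-second records, per-channel
physical range; quantization error ≤ range/2¹⁵) in a flat or BIDS-style
layout. The EDF writer is local to this package (validated by round-trip
through mne's EDF reader); EDF and EEGLAB SET reading go through mne
(continuous, scipy-readable SET files only; MATLAB v7.3 SET files are
rejected).

## Screening statistics

Every feature (10 lobar powers + 65 ratios = 75) is compared FTD vs CTL
with a two-sided Mann–Whitney U test: exact null enumeration for combined
n ≤ 20 without ties, otherwise the tie-corrected normal approximation with
continuity correction (at the study's 23/29 sizes the screen runs the
vectorized asymptotic path; it matches the scalar API exactly).
Benjamini–Hochberg adjustment is applied across all 75 features *within*
one (FFT × reference) configuration and re-run per configuration — the
family had to be chosen, and per-configuration adjustment matches the
per-configuration presentation of the screening results. A feature is
"tier-consistent" (at 0.05 or 0.01) when its adjusted p is below the tier
with the same direction in every configuration. Demographics use the
rank-sum test (age, MMSE; data are non-normal) and the 2×2 Pearson
chi-square without continuity correction (sex).

## Diagnostic accuracy

Markers are auto-oriented so AUC ≥ 0.5; the recorded orientation sets the
cutoff inequality ("> c" vs "≤ c"). The ROC AUC uses the Mann–Whitney
kernel (½ for ties) with DeLong structural-component variance; the paired
test uses the component covariance. PR curves interpolate nonlinearly
between achievable points — linearly in (TP, FP) space, which is the
correct hyperbolic path in (recall, precision) space — with the area in
closed form per segment; the 95% CI is computed on the logit scale with
SE = 1/√(n_pos·A(1−A)). Its empirical coverage at the study's 23/29 split
is ~97% (tested).

The Youden-optimal cutoff maximizes sens + spec − 1 over midpoints between
adjacent distinct scores (ties broken toward higher specificity — a
deterministic rule had to be fixed). Sensitivity/specificity get
Clopper–Pearson intervals; PPV/NPV are standardized to 50% prevalence with
their CIs obtained by propagating the binomial limits through the
prevalence formulas (both are monotone in sens and spec). Cutoff and
maximal J get stratified percentile-bootstrap intervals (5000 draws, seed
978 — the seed value reading of the ambiguous "5000 iterations and 978
seeds" phrasing), implemented by class-wise multinomial reweighting and
verified against a naive resampling loop. Percentile intervals for a
maximal statistic undercover for continuous markers (the max is biased
upward; this is a known property of the estimator, not a bug); the
coverage acceptance check therefore uses a discrete 0–10 marker with a
finite threshold set, where coverage at n = 52 is ~93%.

The sample-size routine inverts the Hanley–McNeil variance
(Q1 = A/(2−A), Q2 = 2A²/(1+A)): smallest equal n with
z_{α/2}·SE₀(n) + z_β·SE₁(n) ≤ A₁ − A₀, two-sided α (z = 2.576 at
α = 0.01), reproducing n = 20 per group for AUC 0.8 vs 0.5 at power 0.8.

## Logistic modeling

Stepwise selection over the four headline ratios plus age and sex (all
subject to the same rules — the covariates are candidates, not forced):
forward entry of the smallest likelihood-ratio p < 0.05, backward Wald
removal at p > 0.1, iterated to stability; ties resolve by column order.
Fits are maximum likelihood (Newton) on internally standardized
predictors, with coefficients and covariance back-transformed to the
original scale; complete or quasi-complete separation is flagged (and
separating candidates skipped with a note) rather than reported as a
diverged fit. Reported per variable: Wald χ² = (β/SE)², odds ratio
exp(β) with exp(β ± 1.96·SE) CI, plus in-sample classification accuracy at
probability 0.5.

## Problem sizes in the test suite

Simulation-based checks run at deliberately chosen scales: effect-recovery
uses 50 cohorts of 23 + 29 subjects with 60 s recordings (float32
synthesis — the precision does not affect any decision boundary) across
all four configurations; null-calibration uses 50 null cohorts at 30 s
under one configuration (FDR calibration does not depend on record
length); bootstrap and CI coverage use 500 simulated markers. Unit tests
use seconds-long recordings. All randomness is seeded; rerunning the suite
or the pipeline with fixed seeds reproduces outputs byte-identically.

## Known limitations

- REST offset recovery at 19 electrodes (above).
- The synthetic cohort omits inter-channel correlation and artifacts, so
  absolute AUC levels on synthetic data say nothing about clinical
  performance; only the machinery and the direction logic are validated.
- In-sample classification accuracy and Youden-point operating
  characteristics are optimistic relative to out-of-sample use; no
  cross-validation is implemented (out of scope).
- PPV/NPV at 50% prevalence are a standardization for comparability, far
  from realistic FTD prevalence.
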