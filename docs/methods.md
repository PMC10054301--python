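# Methods

## Approximate entropy

ApEn(m, r) = φ^m(r) − φ^(m+1)(r) with φ^m(r) the mean over the N − m + 1
template vectors of the natural log of the matched fraction Cᵢ^m(r).
Conventions, chosen once and fixed:

* **Tolerance.** r = `r_factor` × population SD (ddof = 0) of the exact
  sequence handed to `apen`, computed once per call. Windowed callers
  therefore get a *per-window* r: each window is judged against its own
  amplitude, which makes the statistic invariant to slow gain or amplitude
  changes between windows (and, exactly, to any affine map x → ax + b,
  a > 0). Default `r_factor` 0.2, embedding dimension m = 2 — the standard
  parameterization for micro-voltage electrome series.
* **Metric.** Chebyshev (max-norm) by default, which is Pincus's original
  formulation and what R's `pracma::approx_entropy` implements; Euclidean
  is a first-class option because parts of the electrophysiology
  literature phrase the match rule in Euclidean distance. Both are
  test-covered; at m = 1 they coincide.
* **Match rule.** Inclusive: distance exactly equal to r counts.
  Self-matches are included by default, which bounds every Cᵢ below by
  1/(N − m + 1), keeps all logarithms finite, and makes ApEn ≥ 0. With
  `self_match=False` an unmatched template raises an error naming its
  index rather than producing −inf.
* **Degenerate input.** A constant series has SD 0, hence r = 0; identical
  vectors still match at distance 0 ≤ 0 and ApEn is exactly 0 — no error.
  Non-finite samples are rejected outright: silently dropping them would
  change which samples are temporally adjacent and corrupt the embedding.
* **Length.** Hard error below N = m + 3 (both φ terms need ≥ 2 vectors);
  a `ShortSeriesWarning` below N = 50, where the statistic's small-sample
  bias is substantial.

The fast path counts matches from chunked `scipy` distance matrices
(memory-bounded at ~2048 × N entries). `apen_oracle` is a deliberate
template-by-template transliteration of the definition, size-guarded at
N ≤ 2000; the suite checks agreement to 1e-10 across seeded series under
both metrics, and one test cross-checks the Chebyshev path against
`pracma::approx_entropy` through `Rscript` at the same absolute r.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes for
ripening tomato fruit, not the biophysics. Each fruit passes through
mature green (MG) → breaker (B) → light red (LR); each simulated day
yields one acquisition at 62.5 Hz.

* **Regularity backbone: MIX(p).** out_j = (1 − z_j)·√2 sin(2πj/12) +
  z_j·U(−√3, √3), z_j ~ Bernoulli(p). Expected ApEn rises monotonically
  with p while the marginal variance stays ≈ 1 for every p, so stages
  differ in temporal structure rather than amplitude. Stage irregularity
  defaults: **MG 0.6, B 0.2, LR 0.5** — chosen to reproduce the observed
  ripening pattern qualitatively (complexity drop at breaker, partial
  recovery at light red). Only the ordering MG > B and LR > B is treated
  as ground truth; absolute entropy levels of real fruit are not reported
  anywhere and are not emulated.
* **Amplitude, drift, spikes.** The unit-variance backbone is scaled to
  50 µV, plus a linear baseline drift of 30 µV/h and Poisson-timed
  biphasic spikes (2/h, ±200 µV, one positive sample immediately followed
  by one negative) emulating transient depolarization-like events. These
  magnitudes are order-of-magnitude placeholders — real recordings'
  amplitude statistics are unpublished — and the analysis is insensitive
  to them by construction (per-window r). Spike rate is stage-independent:
  the entropy dip is modelled as a regularity change, not an event-rate
  change.
* **Stage durations.** Truncated-positive normal draws per fruit, rounded
  to whole days ≥ 1: MG 4 ± 1, B 3 ± 1, LR 2 ± 0.5 days. The values are
  plausible for detached cherry tomato ripening at room temperature and
  give every fruit its own transition days; no published per-stage day
  counts exist to calibrate against.
* **Seeding.** All randomness flows from one master seed through
  `numpy.random.SeedSequence` spawning keyed on (seed, fruit, day):
  cohorts regenerate byte-identically, fruits and days get independent
  streams, and trajectories are independent of the per-day sample count.
* **Day compression.** Acquisition *d* starts at t₀ = d × 86400 s so
  window times map onto calendar days, but contains `seconds_per_day` of
  samples (default 1200 s = 20 min; 86400 s behind `--full-day`). Tests
  and the acceptance script use 120 s per day with 512-sample windows —
  enough for ≥ 14 windows per acquisition and stable per-stage means —
  while the library's analysis default stays at 2048 samples (~33 s),
  non-overlapping, so pooled windows are statistically independent.

What passing tests on these cohorts do **not** show: robustness to
nonstationary noise floors, electrode drift and contact artifacts, diurnal
or temperature rhythms, true action/variation-potential waveforms, or
inter-channel structure. The generator's stages differ *only* in MIX
irregularity, which is exactly the contrast the pipeline is designed to
detect; results on real recordings depend on that contrast actually
dominating.

## Profiling and dip detection

Windows are fixed-length, trailing partial windows dropped
(n = ⌊(N − w)/step⌋ + 1). Stage summaries assign each window to the stage
covering its midpoint at day resolution; unassignable windows are counted
and reported, never silently dropped. Dip detection smooths a fruit's
profile with a running median (window 5, edge-truncated — medians resist
the occasional spike-inflated window), takes the global minimum (the
observed per-fruit pattern is a single broad trough, so no local-minimum
logic), breaks ties toward the earliest window, and reports medians of the
smoothed curve before and after the dip (None for an empty side, e.g. a
monotone profile). Because dip value and flanking medians come from the
same smoothed curve, dip ≤ both medians holds by construction.

## Features and classification

Six per-window features: ApEn plus population SD, standardized skewness
and excess kurtosis, mean |successive difference|, and lag-1 Pearson
autocorrelation (constant windows take 0 for the standardized quantities).
The classifier is deliberately minimal and fully specified: per-feature
robust standardization (global median/IQR; zero-IQR features get scale 1
and are flagged), per-stage centroids of standardized features, nearest
centroid by Euclidean distance, ties broken by canonical stage order.
Determinism and affine-invariance to raw-feature rescaling follow
directly. Evaluation splits are **by fruit**, never by window — adjacent
windows of one recording are strongly dependent and window-level splits
would leak. Note that because the synthetic stages differ only in MIX
irregularity, *every* regularity-sensitive feature (ApEn, successive
differences, lag-1 autocorrelation) separates MG from B to some degree;
ApEn is the cleanest, and the suite asserts its removal lowers mean
accuracy across seeded cohorts rather than on a single split where both
models can saturate at 100%.

## Numerical and interface choices

* Series files store absolute time in seconds; f_s is re-derived from the
  median time step on read and each step must agree to relative jitter
  ≤ 1e-6. Files are written at 17 significant digits and parsed with
  pandas' round-trip parser, so write→read is bit-exact for doubles.
* The acquisition hardware's 1.5 kHz low-pass is far above the 31.25 Hz
  Nyquist frequency of the stored signal and is a documented no-op; the
  0.5 Hz high-pass has a software analogue in `preprocess`'s
  moving-average detrend. With the centered, edge-truncated moving mean, a
  detrend window ≥ N leaves ~25% of a linear ramp at the edges; windows
  ≲ N/3 remove it to < 10%. Decimation is plain keep-every-k (no
  anti-alias filter) and refuses to leave < 64 samples.
* Every CLI run writes a `manifest.json` of effective parameters and
  seeds; `electrome replay` re-executes it and reproduces artifacts
  byte-identically.

## Known limitations

Single-channel model; no hypothesis testing across stages (deliberately —
the pipeline reports descriptive summaries and localizations); the
transition-day recovery check is a 2σ bound and so fails at a
few-percent rate per cohort by construction (the suite evaluates its
coverage across seeded cohorts); ApEn alone is a biased estimator at
small N and windows below ~50 samples are refused practical use via the
short-series warning rather than a hard error.
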