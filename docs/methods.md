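# Methods

This note documents the models, parameters and numerical choices behind the
package, in the spirit of a statistical-software methods appendix.  It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Task protocols and the boxcar reference

Two block-design protocols are built in:

| task    | blocks | block (s) | pause (s) | stimulation total (s) | window (s) |
|---------|--------|-----------|-----------|------------------------|------------|
| flanker | 7      | 58.8      | 30.6      | 595.2                  | 605.2 computed / 610 reported |
| nback   | 10     | 45.2      | 27.0      | 695                    | 705 |

The analysis window runs from 5 s before the first block to 5 s after the
last.  For the Flanker task the computed window (605.2 s) and the reported
analysis period (610 s) disagree by 4.8 s; the package exposes both
(`analysis_window()` vs `TaskProtocol.reported_window_s`) and deliberately
does not reconcile them.  Window extraction and the synthetic generator use
the reported period, so the per-task sample counts that the analysis is
defined on (6208 ± 2 for Flanker, 7173 for N-back) are reproducible; the
surplus time is absorbed as extra trailing padding.

The effective sampling rate is always derived from the data at hand
(`fs = n_samples / window`).  The counts above imply fs ≈ 10.1745 Hz, a
little below the nominal 10.2 Hz multiplexing rate of the acquisition
hardware; the generator default is `7173/705` so that in-window counts come
out exact.

The boxcar reference maps segment boundaries to `round(onset * fs)`; it is
binary (1 during blocks), not HRF-convolved — the simplest reading of a
signal "directly following" the stimulation sequence.  Its sample entropy
at the study parameters is 0.00518 on 7173 samples (the acceptance script
reports 0.005 at three decimals; the one-significant-digit reference value
is 0.006, and the ±0.001 band covers both readings of the unstated
construction).

## Sample entropy

SampEn(m, r) = −ln(A/B) with m = 2 and r = 0.2 times the sample SD
(n−1 denominator) of the analysed window of the individual channel.
Conventions, fixed so the fast path and the brute-force oracle cannot
drift apart:

* template indices run over 1..N−m for **both** the m- and (m+1)-length
  counts (Richman–Moorman), self-matches excluded, pairs counted once
  (i < j);
* the Chebyshev tolerance is inclusive (distance ≤ r);
* r is relative to the channel's own SD, making the statistic invariant to
  affine rescaling (asserted to 1e−12);
* degenerate outcomes — zero SD (including constant series carrying only
  rounding noise, detected as SD ≤ 1e−12·max|x|) or zero match counts —
  yield an explicit undefined marker with a warning; undefined channels are
  excluded from the participant mean and CV and reported, never silently
  dropped.

The production path is an O(N²) counting kernel (numba-compiled when
available, otherwise an exact lag-vectorised numpy equivalent).  A literal
double-loop oracle (`sample_entropy_oracle`, N ≤ 2000) verifies integer
match-count equality on randomised inputs in the test suite.

Participant-level metrics: mean SampEn over defined long channels
(temporal variability) and CV = sample SD / mean (spatial variability),
requiring at least two defined channels and a non-zero mean.

## Preprocessing chain

Order: intensity → ΔOD → wavelet motion correction → band-pass →
Beer–Lambert → short-channel GLM → baseline correction → window extraction.
All steps are length-preserving except the final extraction; provenance is
recorded per recording.

* **ΔOD** = −log10(I / geometric mean(I)); zero-mean-log by construction,
  making the forward/inverse optical loop exact for zero-mean concentration
  inputs (round trip ≤ 1e−9 µmol/l, tested).
* **Motion correction** — discrete wavelet decomposition (Daubechies-5);
  per detail level, coefficients are centred on the median with a robust
  scale IQR/1.349 and zeroed when their two-sided Gaussian tail probability
  falls below α.  Default α = 0.02.  The α = 0.1 setting often quoted for
  this family of methods zeroes ~10 % of detail coefficients at every
  level; on clean synthetic physiology this inflates the entropy floor of
  artifact-free channels from 0.0167 to 0.0246 while improving spike
  suppression not at all (96.9 % amplitude reduction at α ∈ {0.1, 0.05,
  0.02}).  α = 0.02 removes spikes equally and leaves smooth physiology
  untouched; α remains exposed in `PreprocessConfig`.
* **Band-pass** — zero-phase (forward–backward) Butterworth, order 3 per
  pass, pass band 0.005–0.05 Hz (the physically sensible ordering of the
  stated corner frequencies).  DC rejection and ≥ 20 dB attenuation at 1 Hz
  are asserted against the designed frequency response.
* **Beer–Lambert** — per-sample 2×2 solve of
  ΔOD(λ) = [ε_HbO(λ)·ΔHbO + ε_HbR(λ)·ΔHbR]·d·DPF(λ).  Extinction
  coefficients at 760/850 nm are compiled from the Gratzer/Prahl
  tabulation as distributed with the HOMER `GetExtinctions` table
  (760 nm: 586.0 / 1548.52; 850 nm: 1058.0 / 691.32 cm⁻¹ M⁻¹); DPF
  defaults to 6.0 at both wavelengths.  Both are explicit and overridable
  in `ChannelLayout`.
* **Short-channel GLM** — design = HRF-convolved block regressor +
  Legendre polynomials up to order 3 + the single short channel with the
  highest Pearson correlation to the long channel.  Only the nuisance
  contributions (short channel + polynomials) are subtracted; the
  task-locked variance stays in, because the entropy analysis targets
  task-related blood-flow fluctuation, not residuals of a response fit.
  Rank deficiency (condition number > 1e10) is rejected with diagnostics.
* **Baseline** — mean over the 5 s before the first block onset.
* **HRF** — canonical double-gamma (peak 6 s, undershoot 16 s, ratio 1/6),
  peak-normalised; the field-standard shape, used both in the GLM design
  and in the forward generator.

Whether the original processing chain ran motion correction on OD or on
concentrations, and whether filtering preceded conversion, is not stated at
this granularity in the source description; the order above is this
package's declared choice.

## Synthetic cohorts

The generator emulates the structure the analysis is sensitive to, not the
biophysics.  Per long channel:

* HRF-convolved block response, gain ~0.2–0.3 µmol/l with mild channel
  jitter;
* a vasomotor process inside the analysis band: unit-RMS 0.005–0.05 Hz
  noise gated by a two-state Markov on/off envelope (smoothed ~2 s).  The
  archetype's `intermittency_level` scales the symmetric switching rate
  (base 0.05 s⁻¹) and the burst amplitude; per-channel multipliers are
  drawn log-normally with CV = `spatial_heterogeneity`, the direct handle
  on CV(SampEn);
* a "rigidity" complement: channels with low vasomotor level receive a
  smooth 0.005–0.012 Hz perfusion ramp and a shrunken response gain,
  mimicking patches that show almost no response or a gradual perfusion
  drift — this is what lets per-channel entropy sink below the
  response-dominated floor, as required for realistic spatial CVs;
* shared systemic physiology (Mayer ~0.1 Hz, respiration ~0.25 Hz, cardiac
  ~1 Hz, 1/f background) coupled into long and short channels, slow
  polynomial drift, white measurement noise.  Short channels carry only the
  systemic components, so the GLM stage has honest work to do.
* motion spikes in the optical domain (Poisson 0.2 min⁻¹, 0.01 OD,
  exponential decay 1 s), shared across wavelengths.

Behaviour: ex-Gaussian reaction times per group and task with anticipation
(< 100 ms) and lapse contamination; Bernoulli errors; a per-participant
latent severity draw shifts reaction times and scales channel
heterogeneity, coupling behaviour to haemodynamics.  Sleepiness: integer
1–7 pre-scores around 3, with configured mean post-pre shifts of +1.75
(PCS), +1.0 (CAD) and +0.75 (CTRL), clamped to the scale.

Archetype defaults were calibrated **once** so that cohort summaries land
near the study's reported ranges (mean SampEn ≈ 0.024–0.030, CV(SampEn)
≈ 0.17–0.26, N-back reaction times ≈ 550–780 ms) with the reported group
orderings — temporal intermittency CAD > CTRL > PCS, spatial heterogeneity
PCS > CAD > CTRL:

| group | intermittency | heterogeneity | vaso amp (µmol/l) |
|-------|---------------|---------------|---------------------|
| PCS   | 0.75          | 0.42          | 0.18 |
| CAD   | 1.00          | 0.22          | 0.18 |
| CTRL  | 0.85          | 0.08          | 0.13 |

Under these defaults the simulated PCS spatial CV runs slightly above the
reported group mean (≈ 0.25–0.33 across seeds vs 0.263) but inside the
range observed for individual participants (up to 0.355); the orderings the
acceptance tests check are stable across seeds.  These constants live in
the config dataclasses, not in generator code, and are not re-tuned.

What the generator does **not** model: pericyte-level vascular dynamics and
capillary transit-time heterogeneity itself, pulse-level optics, cap or
optode mechanics, learning or fatigue trends within a task.  Passing tests
therefore demonstrate that the pipeline recovers the configured signal
structure — not that real PCS cortex behaves like the generator.

## Statistics

* One-way between-subjects ANOVA by direct sums of squares; partial
  η² = SS_between/(SS_between+SS_within); post-hoc power from the
  noncentral F distribution with λ = N·η²/(1−η²) at α = 0.05 (the α used
  throughout).  Missing values are dropped per measure, reproducing designs
  where behavioural and haemodynamic analyses have different complete-case
  counts.
* Tukey HSD via the studentized range (scipy), Tukey–Kramer under unequal
  n; cross-checked against the statsmodels implementation in the tests.
* Wilcoxon signed-rank with zero-difference exclusion and midranks; exact
  null distribution by dynamic programming for n ≤ 25 (verified against
  literal 2^n sign enumeration at n = 12), normal approximation with tie
  correction beyond.  The switch point is reported in the result object.
* OLS regressions with intercept; adjusted R² = 1−(1−R²)(n−1)/(n−p−1).
* Bonferroni adjustment min(1, m·p); the family size m is a mandatory
  caller argument because the number of tests is a reporting decision.

Calibration checks in the suite: the ANOVA type-I error at α = 0.05 over
2000 null replicates stays inside the 99 % binomial interval, and the
regression F-test holds its nominal level on independent data.

## Problem sizes and determinism

Cohort-level tests run 12 participants per group on the N-back arm
(17 long + 8 short channels, 7173 samples each) through the full
optical loop — the package's standard working size, completing in a couple
of minutes on one core.  Every random stream derives from
(seed, participant, task, stage) via `numpy.random.SeedSequence`, so any
single participant's data is independent of cohort size and every table is
byte-identical under a fixed (config, seed).

## Known limitations

* The sample-entropy floor of a cleaned channel is set by the residual
  in-band noise of the whole chain, not by the entropy stage itself;
  comparisons across preprocessing settings (especially the wavelet α and
  the band edges) shift absolute SampEn values and should hold settings
  fixed.
* CV(SampEn) is a ratio statistic; with few defined channels or a mean near
  zero it is unstable, which is why the summary refuses < 2 defined
  channels and flags undefined ones.
* The SNIRF-style reader/writer round-trips this package's own recordings;
  it is not a general SNIRF validator.
* Flanker congruency contrasts and multiscale/fuzzy entropy variants are
  out of scope.
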