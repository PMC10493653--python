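# Methods

## Transfer function analysis of dynamic cerebral autoregulation

The ABP→CBFV relation is modelled as a single-input linear system observed
in additive noise. Both channels are trimmed to their overlapping time span,
linearly interpolated onto a common grid at 10 Hz (configurable), and, under
the default percent normalization, CBFV is rescaled to percent of its own
mean so the gain reads %/mmHg and is invariant to Doppler probe calibration.
Linear detrending removes drift outside the analysis band.

Welch auto- and cross-spectra are computed with Hann tapers at 50% overlap.
The segment length is derived from the recording so that exactly five
windows fit: `nperseg = floor(N / (1 + (w−1)(1−overlap)))`, i.e. 200-s
segments for a 600-s recording, giving 0.005 Hz resolution and 13 bins in
the 0.06–0.12 Hz band. The window count is the one quantity the analysis
convention fixes; taper, overlap and detrending follow common TFA practice
and are configurable. Segments shorter than one period of the lower band
edge are rejected (`recording too short`).

The per-bin transfer function is H(f) = S_xy/S_xx, with the cross-spectrum
oriented so that a positive phase means CBFV leads ABP. Band reduction:

* **phase** — per-bin phase angles are unwrapped within the (narrow) band,
  then averaged over bins whose magnitude-squared coherence is ≥ 0.34, the
  critical value for five half-overlapping windows at the 5% significance
  level. 0.34 is stored as a cited constant; its derivation is out of scope
  here. The result is wrapped to (−180°, 180°] and reported raw; values
  outside the physiologically expected [0°, 90°] range set a quality flag
  rather than being clamped, so systems like a pure delay remain testable.
* **gain** — mean |H| over the same valid bins.
* **coherence** — mean γ² over *all* band bins (it is the validity metric,
  so it is not itself gated).
* a recording with zero valid bins is marked invalid (NaN phase/gain).
  Bin-level exclusion is the stricter of the two readings of "coherence
  cutoff" and is the documented choice.

Whole-brain ("overall") values are the per-subject arithmetic mean of the
two hemisphere results; if either hemisphere is invalid the overall result
is invalid. Averaging the two per-subject results (rather than running TFA
on averaged signals) is the documented choice.

Known estimator behaviour, visible in the oracle tests: (i) at coherence γ²
the per-bin phase standard deviation is ≈ sqrt((1−γ²)/(2γ²ν)) — at γ² just
above 0.9 with ~9 effective segments this approaches the 5° scale, so
per-bin closed-form comparisons are made on strongly coherent fixtures;
(ii) when in-band excitation is a single dominant Mayer tone, leakage makes
bins adjacent to the tone inherit H(f_tone), biasing per-bin gains by a few
percent — per-bin oracle fixtures therefore use broadband in-band
excitation; (iii) averaging arctan-shaped phase curves over the band
compresses a first-order lead's band mean ~1–2° below its value at the
0.09 Hz band centre.

## Heart-rate variability

Cleaning: an interval deviating more than 20% from the running median of
the last five accepted intervals is flagged and replaced by linear
interpolation between its clean neighbours. The reference is seeded with
the median of the first five raw intervals so an ectopic first beat cannot
anchor the detector and cascade. Recordings with a flagged fraction above
20% are marked excluded, and the index calculators refuse them; the
threshold, memory and exclusion fraction are configurable. The detector is
deliberately simple and is validated against the generator's ground-truth
injected positions.

Time domain: mean NN, SDNN (sample SD, n−1), RMSSD = sqrt(mean(ΔNN²)).
Frequency domain: the NN series is placed on its cumulative-time axis,
cubic-spline interpolated to 4 Hz, mean-removed, and a Hann/50%-overlap
Welch PSD with 120-s segments is integrated over half-open bands
[0, 0.04), [0.04, 0.15), [0.15, 0.40) Hz, so no bin is double-counted.

Conventions this package fixes because the field's software differs:
total power is defined as VLF + LF + HF over 0–0.40 Hz, which makes
nLF + nHF = 100 an exact algebraic identity of the normalized-unit formula
nLF = LF/(TP−VLF)×100; logarithms are base 10 (a SDNN of tens of ms gives
log-SDNN ≈ 1.5–1.6, the scale published HRV tables show). Mean-shift
invariance of SDNN/RMSSD is exact; the spectral indices are invariant only
up to the change of the cumulative-time axis that a mean shift implies.

## Group statistics

One-way ANOVA is computed in closed form from per-group (n, mean, SD)
summaries with the n-weighted grand mean; `anova_raw` is definitionally the
same formula applied to each sample's own summaries, and the two agree
exactly. All published "± SD" values are taken as sample (n−1) SDs. Since
printed summaries are rounded to two decimals, recomputed F and χ² values
are compared to printed ones at a ±0.02 reproduction scale.

Pearson χ² uses expected counts from the margin products; zero margins
raise an error recommending Fisher's exact test, which sums hypergeometric
probabilities of all tables no more probable than the observed one.

Mann–Whitney and Wilcoxon signed-rank use mid-ranks for ties and switch
between an exact enumeration mode (all C(n₁+n₂, n₁) labelings / all 2ⁿ sign
patterns, two-sided p as the probability of a statistic at least as far
from its null mean) and tie-corrected normal approximations; the automatic
switch points are ≤8 per side and n ≤ 15 respectively, and either mode can
be forced. Zero differences are dropped before signed-ranking.

The repeated-measures layer is a one-way within-subject ANOVA
(subject-blocked decomposition, no sphericity correction — the analysis
convention is not specified beyond "general linear model", so the plain
form is implemented and cross-checked against pingouin), followed by the
three pairwise paired t-tests with Bonferroni-multiplied p capped at 1.

Normality screening uses the one-sample Kolmogorov–Smirnov statistic
against a normal with the sample's own mean and SD and the asymptotic
p-value, deliberately without a small-sample (Lilliefors) correction — the
legacy statistical-package convention this analysis chain mirrors.

## Synthetic generators

ABP = mean + cardiac sinusoid (1.1 Hz, 15 mmHg) + Mayer sinusoid (0.10 Hz,
3 mmHg) + slow drift sinusoid (0.01 Hz, 1.5 mmHg) + white Gaussian noise
(0.8 mmHg), sampled at 10 Hz for 600 s with uniformly random component
phases. Amplitudes are plausible resting-recording magnitudes; noise is
white by design (the simplest model with controllable coherence), which is
the generator's main departure from real ABP, whose broadband power is
1/f-like. The cardiac component is far above the analysis band and mainly
exercises resampling.

CBFV is produced by applying a closed-form H(f) in the frequency domain
(circular convolution; edge effects are negligible at band frequencies for
10-min records): identity, pure delay (phase −360·f·τ), or first-order lead
K(1 + i2πfT) whose phase arctan(2πfT) is positive — CBFV leading ABP, the
phenomenology of intact autoregulation. `lead_for_phase` solves T for any
target phase at a chosen frequency. Independent white output noise sets the
achievable coherence: at the cohort default of 0.6 cm/s the in-band
coherence is ≈ 0.75, typical of good-quality recordings.

NN series: mean period plus two sinusoidal modulations evaluated on the
(approximate) cumulative-time axis so their frequencies are true Hz, plus
white noise. A modulation of amplitude A carries band power A²/2, so the
generated LF/HF power ratio is (lf_amp/hf_amp)², the basis of the recovery
tests. Injected ectopics shorten chosen intervals to 55% of their value —
premature-beat-like and guaranteed ≥40% away from any sane local median —
with ground-truth positions recorded.

All generators take explicit integer seeds and are bitwise deterministic.

## Cohort simulation

Three groups (default 45/50/50) with per-subject phase targets drawn from
group normals truncated to (5°, 85°) — defaults (46, 54, 54)° ± 5°, the
published group contrast — plus ±2° hemisphere jitter; per-subject NN
parameters jittered around group means; a fixed number of subjects per
group (default 2/1/1) carry a 25% ectopic rate and the rest 2%, so the
>20% exclusion rule removes exactly the constructed subjects. Subjects
excluded from HRV are retained for TFA, so the two group tables have
different ns, as in the study shape being emulated. The shunt group also
gets two extra NN recordings per subject (immediately post-procedure with
variability scaled to 60% and mean to 95%, and a fully recovered 1-month
recording) to exercise the repeated-measures layer. Demographics (age,
sex, comorbidities) are simulated independently of the signals and only
feed the χ²/ANOVA demographics table.

With these defaults, per-subject phase estimates carry ~5° estimator noise
on top of the 5° between-subject SD; the resulting ~6.5° total SD is below
the published 9–14° SDs, so the simulated three-group contrast has power
near 1 rather than the published F ≈ 6.7 — the cohort layer validates
recovery and calibration, not effect-size realism.

Problem sizes used by the drivers and the acceptance script: full-size
cohorts for single study runs; 12 seeded end-to-end runs for power and 30
for the null rejection rate; 2000 null simulations for test-level type-I
calibration (binomial SE ≈ 0.005).

## Printed-table reconstruction

The packaged CSVs carry the published per-group summaries and counts. All
F/χ² rows of the demographics, autoregulation and HRV tables are
recomputed; 15 of 24 agree within ±0.02 as expected from input rounding.
The remaining rows (the three gain rows and six of the log-scale HRV rows)
differ by up to ~0.2 in F — at two-decimal input precision those printed
statistics are not exactly reproducible from their own printed summaries,
a discrepancy the reconstruction report surfaces rather than hides. The
demographic, phase-difference and non-log HRV rows all reproduce.

## Limitations

* The generators make no attempt at physiological realism beyond spectral
  placement: no baroreflex loop, no CO₂ reactivity, no respiratory
  modulation of ABP, white rather than 1/f noise. Passing tests show the
  estimators recover known linear systems and band powers under these
  conditions; they do not certify behaviour on pathological recordings.
* Patient-level published values (biomarker medians, individual phase
  trajectories) are not reproducible without the clinical data; the
  pipeline covers them only through property-based surrogates.
* The exact enumeration modes are O(C(n₁+n₂, n₁)) and O(2ⁿ) and are
  practical to roughly 12 per group / n = 20 pairs.
* TFA assumes a stationary linear relation over the full recording; no
  time-varying or multivariate (CO₂-adjusted) extension is provided.
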