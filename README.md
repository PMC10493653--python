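# dcahrv

Transfer-function analysis of dynamic cerebral autoregulation, beat-to-beat
heart-rate-variability (HRV) analysis, and the group-comparison statistics of
a three-group clinical cohort — with a synthetic signal generator whose
ground truth is known in closed form, so every estimator in the pipeline can
be validated without patient recordings.

## Who this is for

Researchers in cerebral hemodynamics and autonomic physiology who analyse
paired arterial-blood-pressure (ABP, mmHg) / cerebral-blood-flow-velocity
(CBFV, cm/s) recordings and beat-interval (NN) series, and who want a tested,
scriptable implementation of the standard analysis chain:

1. **Transfer function analysis (TFA).** The ABP→CBFV relation is estimated
   by Welch cross-spectral analysis and reduced over the 0.06–0.12 Hz band to
   the phase difference φ = arg H(f) (degrees; positive = CBFV leads ABP,
   the signature of active autoregulation), the gain |H| (by default with
   CBFV in percent of its own mean, giving %/mmHg), and the magnitude-squared
   coherence γ²(f) = |S_xy|²/(S_xx·S_yy). Band bins with γ² < 0.34 (the
   critical value for 5 windows at the 5% level) are excluded; a recording
   with no valid bin is flagged invalid.
2. **HRV.** Ectopic beats are detected against a running local median,
   corrected by linear interpolation, and recordings with >20% ectopics are
   excluded. Time-domain indices (mean NN, SDNN, RMSSD) and Welch spectral
   band powers (VLF <0.04, LF 0.04–0.15, HF 0.15–0.40 Hz) are computed on the
   cubic-spline-resampled series, with normalized units
   nLF = LF/(TP−VLF)×100 (so nLF + nHF = 100) and base-10 log transforms.
3. **Group statistics.** One-way ANOVA computed in closed form from per-group
   (n, mean, SD) summaries —
   F = [Σ nᵢ(mᵢ−m̄)²/(k−1)] / [Σ (nᵢ−1)sᵢ²/(N−k)] —
   Pearson χ², Fisher's exact test, exact/approximate Mann–Whitney and
   Wilcoxon signed-rank tests, repeated-measures ANOVA with Bonferroni
   post-hocs, and one-sample Kolmogorov–Smirnov normality checks. Because the
   summary-form ANOVA needs only printed table values, published F statistics
   can be recomputed exactly from the paper trail they leave.

The synthetic layer generates ABP with a cardiac pulse, a ~0.1 Hz Mayer wave,
drift and noise; CBFV through a linear system with analytic H(f) (identity,
pure delay, or a first-order lead tuned to any target phase); and NN series
with sinusoidal LF/HF modulations of known power plus injectable ectopics.

## Worked example

```python
import dcahrv as d

abp = d.generate_abp(d.ABPSpec(seed=1))                      # 10 min at 10 Hz
filt = d.AutoregFilterSpec.lead_for_phase(50.0, 0.09,        # true phase 50°
                                          dc_gain=0.65, noise_sd=0.6,
                                          noise_seed=2)
cbfv = d.apply_autoreg_filter(abp, filt)
res = d.analyze_pair(abp, cbfv)
print(f"phase {res.phase_deg:.1f} deg, coherence {res.mean_coherence:.2f}, "
      f"valid bins {res.n_valid_bins}")
```

prints

```
phase 52.2 deg, coherence 0.67, valid bins 11
```

— the band-averaged phase recovers the 50° ground truth to within the
single-recording estimator noise (a few degrees at this coherence); 11 of 13
band bins pass the 0.34 coherence cutoff.

Reconstructing a published F statistic from its printed summaries:

```python
groups = [d.GroupSummary("shunt", 45, 46.25, 13.02),
          d.GroupSummary("migraine", 50, 54.19, 8.95),
          d.GroupSummary("control", 50, 54.46, 14.28)]
r = d.anova_from_summary(groups)
print(f"F = {r.statistic:.3f}, p = {r.p:.4f}")
```

prints `F = 6.728, p = 0.0016`.

The numbered drivers under `analysis/` run the full study shape:
`01_simulate_cohort.py` (three-group cohort with group-specific phase
targets), `02_run_study.py` (per-subject TFA + HRV, exclusion bookkeeping,
group tables), `03_reconstruct_printed_stats.py` (closed-form recomputation
of the published F/χ² values), `04_calibration.py` (type-I error and power).
Tables land in `results/`.

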