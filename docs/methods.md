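# Methods and conventions

This document records the quantitative conventions, the synthetic-generator
defaults, the statistical choices, and the known limitations of `fetpwi`.

## PET kinetics

- **SUV.** SUV = concentration × body weight / injected dose. TBR divides a
  lesion value by the corresponding reference (mirror-region) value.
- **Frame schedule.** The default dynamic acquisition is 4 × 60 s followed by
  12 × 180 s (40 min total). Each frame is represented by its midpoint; all
  time-resolved statistics operate on midpoints.
- **Late window.** Static metrics (mean, max) and the linear fit use frames
  whose midpoints fall in [1200 s, 2400 s], inclusive at both ends.
- **Slope and intercept.** Ordinary least squares of value against midpoint
  time in hours, so the slope is in units/hour. The intercept is the fitted
  line evaluated at t = 0 (the injection time), not at the window start. A
  late-window plateau of height p with slope s centered at 1800 s therefore
  round-trips to intercept p − s·0.5.
- **TBR_max** is lesion SUV_max over the window divided by the window-mean
  reference SUV (not a frame-wise ratio maximum).
- **Time-to-peak.** Midpoint of the global-maximum frame over the whole
  acquisition; ties resolve to the earliest frame.

## DSC-MRI

- ΔR2\*(t) = −ln(S(t)/S₀)/TE with S₀ the mean over the pre-bolus baseline
  frames and TE the echo time (default 30 ms, 2.02 s temporal resolution).
- rCBV is the ratio of trapezoid-integrated ΔR2\* areas, lesion over
  reference, over the full acquisition unless a window is given. No
  leakage-correction or gamma-variate refitting is applied; the simulator's
  shared bolus shape makes the noiseless area ratio exactly the generating
  amplitude ratio.

## DCE-MRI (Tofts model)

- Standard Kety/Tofts model: C_t(t) = K^trans ∫ C_p(u) e^(−k_ep (t−u)) du with
  k_ep = K^trans / v_e, K^trans in 1/min.
- The population arterial input function is biexponential,
  C_p(t) = D (a₁ e^(−m₁ t) + a₂ e^(−m₂ t)) with D = 0.1 mmol/kg,
  a₁ = 3.99, a₂ = 4.78 kg/L, m₁ = 0.144, m₂ = 0.0111 min⁻¹. For this AIF the
  convolution has a closed form (each exponential term contributes
  a (e^(−m τ) − e^(−k_ep τ))/(k_ep − m), with the degenerate limit
  a τ e^(−m τ) when k_ep ≈ m). Arbitrary AIFs use an exponential-integrator
  fallback with exact per-step decay.
- Fitting is bounded nonlinear least squares (K^trans ∈ [0, 5] min⁻¹,
  v_e ∈ (10⁻⁶, 1]) from four fixed starts; the best residual wins. An all-zero
  curve returns K^trans = 0 with v_e undefined (NaN).
- **Non-monotonicity note.** C_t is *not* monotone in K^trans at every fixed
  time: raising K^trans at fixed v_e also raises k_ep, so late-time curves can
  cross. The true invariants — monotonicity for a constant plasma level and
  exact linearity in K^trans at fixed k_ep — are what the tests assert.

## Diagnostics

- **Orientation.** Metrics where *lower* values indicate tumor (suv_slope,
  tbr_slope, ttp_s) are sign-flipped internally so every ROC is computed in a
  higher-indicates-POD frame; reported cutoffs are on the original scale with
  the correct inequality direction.
- **AUC** is the Mann–Whitney statistic (ties get half credit); the standard
  error and 95% CI follow Hanley & McNeil (1982), with a one-sided test of
  AUC > 0.5.
- **Cutoffs** maximize the geometric mean of sensitivity and specificity over
  midpoints between adjacent distinct scores plus ±∞ sentinels; ties resolve
  to the smallest transformed threshold.
- **Paired AUC comparison** uses the Hanley & McNeil (1983) correlated-ROC
  z test. The correlation input r is taken as the mean of the within-class
  Pearson correlations between the two scores directly, rather than mapped
  through the published lookup table (which has no closed form and is close
  to identity in its mid-range). A within-patient permutation test in the
  test suite bounds the approximation error; an explicit `r` override is
  available. As with any normal-theory tail probability, agreement with a
  resampling p-value is tight in the moderate-p regime and loosens to a few
  thousandths in the far tail.
- **Multiplicity.** Benjamini–Hochberg adjustment (via statsmodels). Note BH
  is *not* idempotent — re-adjusting adjusted p-values can inflate them
  further; the guaranteed properties are elementwise inflation (adjusted ≥
  raw) and monotonicity in the input.
- **Rounding.** Formatted performance uses decimal half-up rounding:
  percentages to integers, positive likelihood ratio to one decimal, negative
  likelihood ratio to two. All reported values are derived from the
  contingency counts; published clinical tables can be internally
  inconsistent between printed percentages and their own counts, and this
  package always reports the count-derived value.
- **Institutional rules.** PET calls POD when TBR_max > 2.5 (strict); MRI
  calls POD when rCBV > 3.0 or K^trans > 0.26 (strict); on PET/MRI
  discordance the hybrid call follows PET. Boundary values therefore call
  TRC. Concordance analysis reports accuracy among concordant cases and which
  modality was correct among discordant ones.

## Synthetic cohort generator

Labels are Bernoulli with prevalence 42/80 (POD); tumor origin is Bernoulli
with mix 42/80 (astrocytoma vs brain metastasis) independent of label. Each
patient draws a kinetic profile conditionally on label:

| parameter | POD | TRC | family |
|---|---|---|---|
| TBR plateau | median 3.0 | median 1.8 | lognormal, σ = 0.25 |
| washout slope (/h) | −1.0 | +0.4 | normal, sd = 0.9 |
| time-to-peak (s) | 900 | 2100 | normal, sd = 600, clipped [120, 2340] |
| rCBV | 4.5 | 2.5 | lognormal, σ = 0.45 |
| K^trans (/min) | 0.8 | 0.4 | lognormal, σ = 0.55 |
| v_e | 0.45 ± 0.15 | 0.30 ± 0.10 | normal, clipped [0.05, 0.95] |
| volume change (%) | 25 ± 20 | 5 ± 15 | normal |

Reference SUV is lognormal (median 1.0, σ = 0.2). Noise defaults: 0.05 SUV on
PET frames, sd 1.0 on DSC signal, 5%-of-peak on DCE concentration. The
medians place the class centers where the clinical operating points sit (PET
TBR cutoffs near 2.2–2.7, rCBV near 3, K^trans near 0.26–0.5); the spreads
were fixed once so that noiseless between-class separation yields AUCs in the
high-but-imperfect range typical of these modalities, and were not revisited
afterwards.

The TBR truth curve is min(wash-in ramp to the TTP center, late line
p + s·(t − 1800)/3600), clipped at 0; a guard shrinks extreme slopes so the
curve stays positive over the late window. **TTP caveat:** for TRC-like
profiles with positive late slope the global maximum of the generated curve
sits at the scan end, so extracted TTP equals the last frame midpoint rather
than the drawn TTP center; exact TTP round trips hold only for profiles whose
peak precedes the late window.

DSC uses one gamma-variate bolus shape (t₀ = 12 s, α = 3, β = 4.5 s) for
lesion and reference with the lesion amplitude scaled by the true rCBV, so
the noiseless area ratio is exact. DCE synthesizes concentration directly
from the Tofts forward model at 2.7 s resolution over 300 s.

## Numerical choices

- ROC computation is backed by scikit-learn after orientation transform; BH
  by statsmodels; the Tofts fit by scipy `least_squares` (tolerance 1e-8).
- rCBV integration uses the composite trapezoid rule on the acquired grid.
- All randomness flows from a single `numpy.random.default_rng(seed)` per
  cohort; pipelines are bit-reproducible given a config.

## Limitations

- The simulator is a validation harness, not a physiological model: no
  partial-volume effects, motion, T1/T2\* signal models for DCE (concentration
  is synthesized directly), contrast-leakage effects in DSC, or correlation
  structure between PET and perfusion parameters beyond the shared label.
- Threshold rules are fixed single-feature inequalities; no multivariable
  model is fitted.
- Hanley-style inference assumes binormal-like behavior; for very small
  samples or extreme AUCs prefer the permutation route demonstrated in the
  tests.
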