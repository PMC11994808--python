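# Methods

This note documents the models, parameter choices and numerical decisions
behind `mcir`, and what the synthetic-data experiments do and do not show.

## Digital twin

The twin is an auto-associative kernel regression (AAKR), the canonical
member of the similarity-based-modeling family: an exemplar memory of
baseline 5-vectors (HR, HRV, RR, activity, skin temperature; z-units) and a
similarity-weighted average as the estimator. We chose AAKR over
pseudo-inverse similarity-operator variants because it is parameter-light,
numerically stable (no matrix inversion at query time), and its estimates
provably stay inside the exemplar hull, which the test suite asserts. The
realization is intentionally swappable: the model object stores only the
memory, the normalization and a bandwidth.

Assumptions: baseline physiology is (quasi-)stationary over the pre-dose
wear period at the 1-minute scale once quality filters remove motion and
poor-signal minutes; the joint 5-channel pattern, not any single channel,
identifies "normal" states; deviations of interest are additive departures
from that joint pattern.

Parameters:

- **Exemplar count m = 250.** Large enough to tile 3–7 days of filtered
  baseline in 5 dimensions, small enough that scoring a 2-week record is
  milliseconds. Channel extremes (≤ 10 vectors) are always included so the
  hull covers the observed range; the rest are rank-uniform by vector norm,
  making selection deterministic in input order.
- **Bandwidth h = median pairwise exemplar distance.** A standard
  self-tuning scale; with the inverse-distance kernel k(d) = 1/(1 + d/h) a
  far exemplar leaks ~h into the estimate, so h also bounds the residual
  floor. The Mahalanobis/ECDF calibration downstream absorbs that floor.
- **Training gate: ≥ 2500 filtered minutes over ≥ 3 distinct calendar
  days,** with at least three days each holding ≥ 10 % of the samples so
  the day-span requirement cannot be met by token coverage. Days are
  calendar days of the (timezone-free) record clock.
- **Filters.** Scoring and training both require activity < 0.05 g
  (strict), skin temperature in [30, 40] °C and SQI ≥ 0.9; training
  additionally requires HR in [40, 250] bpm and RR in [8, 35] breaths/min
  (closed bounds). The looser scoring gate keeps post-dose tachycardia and
  tachypnea scoreable.

One twin is trained per dose from that dose's pre-dose data only; there is
no online updating and no pooling across individuals.

## MCIR fusion

The 15-minute Multivariate Change Index of Reactogenicity is computed as:
block-mean residual vectors (≥ 3 valid minutes per block, grid anchored at
the dose time so no block straddles the dose) → Mahalanobis distance d
against the pre-dose block-residual distribution → empirical CDF F̂ over
the pre-dose distances → `mcir = max(0, (F̂(d) − q)/(1 − q))` with
q = 0.95.

This fusion is a documented surrogate: it satisfies the defining behavioral
requirements of the production index — a multivariate combination of
residuals, 15-minute cadence, bounded to [0, 1] so the 72-h rectangular
area is well defined, and exactly zero with positive probability under
baseline conditions (the q-floor ties the null non-zero rate to ~5 %). No
numerical equivalence with the proprietary production index is claimed.

Numerical choices: covariance ridge ε·I with ε = 10⁻⁶·trace(Σ)/5 (falls
back to 10⁻¹² for an exactly zero trace) keeps degenerate baselines
invertible; F̂ uses the right-continuous convention (proportion of null
distances ≤ d), so a block exceeding every baseline block maps to exactly
1; missing blocks stay missing through fusion and are only zero-imputed by
the response metrics, where missing data must not create a response.
Calibration uses all pre-dose blocks, in-sample for the twin; the held-out
post-dose null non-zero rate was verified empirically to stay at ~5 %, so
no train/calibration split is used.

## Response metrics

AUC Total Response = Σ(mcir × 15 min)/(72 h × 1.0) over the 288 post-dose
blocks, missing blocks contributing zero, denominator fixed. Detectable
response = (some 24-block window with ≥ 12 blocks > 0.10) AND (a run of
≥ 5 consecutive blocks > 0 anywhere in the 72-h window). The "> 1 h"
persistence at 15-minute cadence excludes exactly-1-h runs, hence ≥ 5
blocks. The persistence run may fall anywhere in the 72-h window, not
necessarily inside the qualifying 6-h window; the two conditions are
logically independent screens. Window stride is one block. All threshold
comparisons are strict (> 0.10, > 0). Onset is the first above-threshold
block of the earliest qualifying window; offset is the end of the last
above-threshold block of the latest qualifying window.

## Statistical layer

- **Bootstrap performance.** Study-dose decisions are positive ground
  truth; random 72-h windows of control MCIR (window starts uniform over
  the block grid, 100 per control) are negative ground truth. Each of the
  1000 bootstrap replicates resamples the study decisions with replacement
  and draws one window decision per control individual, mirroring the
  "one decision per dose" resampling; point estimates are means over
  replicates, CIs the 2.5/97.5 percentiles. Percentile CI width converges
  with the number of replicates (it estimates a fixed sampling-distribution
  width); it does not shrink, and the tests assert convergence, not
  shrinkage.
- **Rank statistics.** KS, Wilcoxon and Spearman statistics are delegated
  to scipy and cross-checked against exhaustive enumeration at small n in
  the tests. p-values use the standard approximations: asymptotic
  Kolmogorov distribution with the effective-n correction
  λ = (√en + 0.12 + 0.11/√en)·D; normal approximation with continuity
  correction after dropping zero differences (≥ 5 non-zero pairs
  required); t-approximation with tie-averaged ranks, one-sided p taken in
  the direction of the observed sign.
- **Robust fits.** IRLS with scale s = MAD/0.6745 re-estimated per
  iteration and u = r/(tune·s), tune = 0.8 shared by both weight
  functions; the conventional per-function constants (Welsch 2.985,
  Andrews 1.339) are deliberately *not* folded in, so the single shared
  tune value governs both. Welsch w = exp(−u²); Andrews w = sin(u)/u for
  |u| < π, else 0, w(0) = 1. Convergence when the coefficient change is
  < 10⁻⁸; an exactly-fitting line (s = 0) converges immediately;
  non-convergence is flagged on the result, not raised.

## Synthetic-data generator

The generator emulates, at 1-minute cadence: a 24-h sinusoid in HR (peak
16:00) and skin temperature (amplitude 0.1 °C per bpm of HR amplitude);
daytime (08:00–22:00) activity bouts (Poisson, default 1.5/h, 5–20 min,
0.08–0.25 g) that raise HR (60 bpm/g above rest) and RR and depress HRV;
AR(1) noise (coefficient 0.9) per channel so 48-h baselines have realistic
autocorrelation and twin residuals are not trivially white; SQI dropout
episodes (10–60 min) at a per-profile rate; and ~1 short wear gap per day
removed outright. Vaccine responses are additive piecewise-linear
envelopes (default onset 6 h, peak 24 h, duration 72 h — deviations lasting
roughly three days) with per-channel peak deltas (+4 bpm HR, −0.01 s HRV,
+1.5 breaths/min RR, +0.5 °C skin temperature, activity unchanged) scaled
by a non-negative magnitude. Per-channel effect sizes are calibration
choices within physiologically plausible ranges, not published values.
Symptom labels are logistic in magnitude with an intercept giving ~20 %
positives at magnitude zero (the nocebo floor); immunogenicity is
100·exp(0.8·magnitude + ε), ε ~ N(0, 0.5²), a stated monotone link so rank
correlations are recoverable. Cohort wear-start times are staggered across
the day so dose clock times vary.

What the generator does **not** emulate: multi-day physiologic
nonstationarity (illness, travel, alcohol, shift work), sensor drift,
posture artifacts, medication effects, or the behavioral irregularity of
real free-living controls. Consequently the detectable-response false
positive rate on synthetic null windows is ~0, far below the rate observed
on real-world control cohorts; passing tests demonstrate correctness of
the pipeline and calibration, not real-world specificity. Likewise the
parameter-recovery correlations on synthetic cohorts (Spearman ≈ 0.97
between 72-h AUC and injected magnitude at n = 60) are upper bounds: real
responses are not a single shared waveform.

## Problem sizes

The test and acceptance runs use: single individuals of 7–9 days; a
60-person response cohort (magnitudes Uniform(0, 3), 5 baseline + 5 post
days) for parameter recovery; a 30-person null cohort (7 post days) with
100 random 72-h windows per individual and 1000 bootstrap replicates for
calibration and false-positive checks; 10⁴ random 288-block series for the
window-rule oracle; and n = 20 with one gross outlier for the robust-fit
benchmark. These sizes give stable statistics at interactive runtimes.

## Known limitations

- The fusion statistic and exemplar-selection strategy are this package's
  own explicit constructions; behavioral properties, not numerical
  equivalence with any deployed system, are what the tests guarantee.
- The inverse-distance kernel leaves a residual floor of order h even at a
  memorized state; applications needing near-interpolation should swap in
  a faster-decaying kernel.
- Null calibration is in-sample for the twin; with very short baselines
  (near the 2500-minute gate) the ~5 % null rate can drift upward.
- p-values at very small n use the stated approximations and should not be
  read as exact.
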