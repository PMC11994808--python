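# mcir — personalized digital-twin quantification of vaccine reactogenicity

`mcir` quantifies an individual's physiologic response to vaccination from
continuous wearable biosignals. Reactogenicity — the fever, fatigue and
malaise that follow a vaccine — is usually measured by self-report, which
is subjective and heavily confounded by the nocebo effect. Given 1-minute
multichannel data from a torso patch sensor (heart rate, heart-rate
variability, respiration rate, activity, skin temperature, plus an
ECG-derived signal-quality index), the package builds a *digital twin* of
each person's pre-dose physiology and converts post-dose deviations from
that twin into an objective, bounded biomarker. It is aimed at digital
medicine and biostatistics researchers working with dense wearable
time-series around an intervention.

## The method

**Digital twin (similarity-based modeling).** All pre-dose minutes passing
quality filters (activity < 0.05 g, skin temperature 30–40 °C, SQI ≥ 0.9,
and during training HR 40–250 bpm, RR 8–35 breaths/min; ≥ 2500 samples over
≥ 3 days required) form the training set. Channels are z-scored by their
training mean/SD, and an exemplar memory D (m = 250 vectors, always
containing each channel's extremes) is kept. A query x is estimated by
auto-associative kernel regression

    x̂ = Σᵢ wᵢ Dᵢ,   wᵢ ∝ k(‖x − Dᵢ‖₂),   k(d) = 1 / (1 + d/h),

with bandwidth h the median pairwise exemplar distance. The residual
r = x − x̂ is near zero under baseline behavior and carries the
vaccine-induced deviation afterwards.

**MCIR fusion.** Residual minutes are averaged into 15-minute blocks on a
grid anchored at the dose time (≥ 3 valid minutes per block). Each block's
Mahalanobis distance d from the pre-dose block-residual distribution
(mean μ, ridge-regularized covariance Σ) is passed through the empirical
CDF F̂ of the pre-dose block distances and zero-floored at quantile
q = 0.95:

    MCIR = max(0, (F̂(d) − q) / (1 − q)) ∈ [0, 1].

The index is exactly zero for a typical baseline block and saturates at 1
beyond every baseline block.

**Response metrics.** Over the fixed 72-h post-dose window (288 blocks),
the *AUC Total Response* is A_i/A_T — the accumulated MCIR area as a
fraction of the maximal rectangle. A *detectable response* requires a 6-h
sliding window with ≥ 50 % of its 15-min steps above 0.10 plus a > 1 h run
of non-zero MCIR; onset/offset bracket the above-threshold excursion.

**Validation layer.** Diagnostic performance (TPR/SPC/FPR/PPV/NPV/ACC with
bootstrap 95 % CIs) of the detectable rule against random 72-h windows of
non-vaccine control data, two-sample Kolmogorov–Smirnov and Wilcoxon
signed-rank tests, Spearman correlation, and robust IRLS line fits with
Welsch (`exp(−u²)`) or Andrews (`sin(u)/u`, cutoff π) weights at a shared
tune parameter 0.8, where u = r/(tune · MAD/0.6745).

**Synthetic cohorts.** Because the raw study data are not public, a
first-class generator produces realistic cohorts: circadian HR and skin
temperature, activity-coupled HR/HRV/RR, AR(1) sensor noise, SQI dropout,
wear gaps, and injectable post-dose perturbations with known magnitude,
linked symptom labels (logistic with a ~20 % nocebo floor) and
immunogenicity values (monotone log-link). Every downstream claim is
testable against this ground truth.

## Worked example

```python
import pandas as pd
from mcir import (IndividualProfile, ResponseParams, simulate_individual,
                  inject_vaccine_response, score_dose)

profile = IndividualProfile(participant_id="demo", rng_seed=7)
baseline = simulate_individual(profile, duration_days=9)
dose_time = baseline.data["timestamp"].iloc[0] + pd.Timedelta(days=5)
dosed, truth = inject_vaccine_response(
    baseline, dose_time, ResponseParams(magnitude_scale=2.0))
mcir, summary = score_dose(dosed, dose_time)
```

prints (via `python examples/score_single_dose.py`):

```
dose at 2021-01-09 00:00:00, injected magnitude 2.0
AUC Total Response : 0.551
detectable response: True
onset / offset     : 2021-01-09 11:30:00 / 2021-01-11 06:45:00
valid 15-min blocks: 267 of 288
```

The dose was injected with twice the default per-channel amplitudes; the
twin flags a sustained deviation starting ~11.5 h post dose that accumulates
55 % of the maximal possible 72-h MCIR area. On the same individual without
the injection the AUC is 0.028 and nothing is detectable. The other scripts
in `examples/` demonstrate cohort simulation, the uni-parametric 3-h screen,
bootstrap performance estimation and the robust/rank statistics.

A thin CLI wraps the same functions:

```bash
mcir simulate --n 20 --seed 1 --null-fraction 0.5 --out cohort/
mcir score    --series-dir cohort/ --doses cohort/doses.csv --out scored/
mcir validate --cohort cohort/ --out performance.json --seed 1
mcir stats    --cohort cohort/ --doses cohort/doses.csv --out population.csv
```

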