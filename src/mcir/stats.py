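"""Statistical validation layer.

Bootstrap diagnostic performance of the detectable-response rule against
control (non-vaccine) MCIR windows, confusion-matrix arithmetic,
distribution comparisons (two-sample KS), paired pre/post tests (Wilcoxon
signed rank), rank correlation (Spearman), robust IRLS line fits with
Welsch/Andrews weights, and the population-level pre/post daily summary.
Distributional p-values come from scipy's implementations of the standard
approximations; the statistics themselves are verified against exhaustive
enumeration in the test suite.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.special
import scipy.stats

from mcir.index import BLOCK_MINUTES, MCIRSeries
from mcir.metrics import WINDOW_H, detectable_response
from mcir.preprocess import BASELINE_HOURS
from mcir.types import BiosignalSeries, CHANNELS, DoseEvent

log = logging.getLogger(__name__)


@dataclass
class PerformanceEstimate:
    """Confusion-matrix rates, optionally with bootstrap 95% CIs."""

    tpr: float
    spc: float
    fpr: float
    ppv: float
    npv: float
    acc: float
    ci95: dict[str, tuple[float, float]] = field(default_factory=dict)
    n_boot: int = 0

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in ("tpr", "spc", "fpr", "ppv", "npv", "acc")}
        d["ci95"] = {k: list(v) for k, v in self.ci95.items()}
        d["n_boot"] = self.n_boot
        return d


def confusion_metrics(tpr: float, spc: float, n_pos: int, n_neg: int
                      ) -> PerformanceEstimate:
    """Reconstruct all confusion-matrix rates from TPR, SPC and class sizes."""
    if n_pos <= 0 or n_neg <= 0:
        raise ValueError("n_pos and n_neg must be positive")
    if not (0 <= tpr <= 1 and 0 <= spc <= 1):
        raise ValueError("rates must lie in [0, 1]")
    tp = tpr * n_pos
    fn = (1 - tpr) * n_pos
    tn = spc * n_neg
    fp = (1 - spc) * n_neg
    if tp + fp == 0:
        raise ValueError("PPV undefined: no predicted positives")
    if tn + fn == 0:
        raise ValueError("NPV undefined: no predicted negatives")
    return PerformanceEstimate(
        tpr=tpr, spc=spc, fpr=1 - spc,
        ppv=tp / (tp + fp), npv=tn / (tn + fn),
        acc=(tp + tn) / (n_pos + n_neg),
    )


def classify_control_windows(control_mcir: Sequence[MCIRSeries],
                             windows_per_control: int = 100,
                             rng: np.random.Generator | None = None
                             ) -> list[np.ndarray]:
    """Classify random 72-h windows of control MCIR as detectable or not.

    Returns one boolean decision array per usable control series.  Window
    starts are drawn uniformly over block positions leaving full 72-h
    coverage; series shorter than 72 h are skipped with a warning.
    """
    rng = rng or np.random.default_rng()
    n_blocks_needed = WINDOW_H * 60 // BLOCK_MINUTES
    out: list[np.ndarray] = []
    for s in control_mcir:
        n_start = len(s) - n_blocks_needed
        if n_start < 1:
            log.warning("%s: control MCIR shorter than 72 h; skipped",
                        s.participant_id)
            continue
        starts = rng.integers(0, n_start + 1, size=windows_per_control)
        decisions = np.array([
            detectable_response(s, s.block_start[int(i)])[0] for i in starts
        ])
        out.append(decisions)
    if not out:
        raise ValueError("no control series covers a full 72-h window")
    return out


def bootstrap_performance(study_decisions: Sequence[bool],
                          control_mcir: Sequence[MCIRSeries],
                          windows_per_control: int = 100,
                          n_boot: int = 1000,
                          seed: int | None = None) -> PerformanceEstimate:
    """Bootstrap the detectable-response rule's diagnostic performance.

    Study dose decisions are treated as positive ground truth; random
    72-h control windows as negative ground truth.  Each bootstrap draws
    one window decision per control individual and resamples the study
    decisions with replacement; point estimates are the means over
    bootstrap replicates, CIs the 2.5/97.5 percentiles.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    study = np.asarray(study_decisions, dtype=bool)
    if len(study) == 0:
        raise ValueError("no study decisions supplied")
    rng = np.random.default_rng(seed)
    per_control = classify_control_windows(control_mcir, windows_per_control, rng)
    ctrl_matrix = np.stack(per_control)          # (n_controls, windows)
    n_pos, n_neg = len(study), len(per_control)

    reps = {k: np.empty(n_boot) for k in ("tpr", "spc", "fpr", "ppv", "npv", "acc")}
    for b in range(n_boot):
        s = study[rng.integers(0, n_pos, size=n_pos)]
        cols = rng.integers(0, ctrl_matrix.shape[1], size=n_neg)
        c = ctrl_matrix[np.arange(n_neg), cols]  # one decision per control
        tp, fn = s.sum(), (~s).sum()
        fp, tn = c.sum(), (~c).sum()
        reps["tpr"][b] = tp / n_pos
        reps["spc"][b] = tn / n_neg
        reps["fpr"][b] = fp / n_neg
        reps["ppv"][b] = tp / (tp + fp) if tp + fp else np.nan
        reps["npv"][b] = tn / (tn + fn) if tn + fn else np.nan
        reps["acc"][b] = (tp + tn) / (n_pos + n_neg)
    point = {k: float(np.nanmean(v)) for k, v in reps.items()}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        ci = {k: (float(np.nanpercentile(v, 2.5)), float(np.nanpercentile(v, 97.5)))
              for k, v in reps.items()}
    return PerformanceEstimate(**point, ci95=ci, n_boot=n_boot)


def ks_two_sample(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Two-sample KS test: D = sup |ECDF_a - ECDF_b|, asymptotic p."""
    a, b = np.asarray(a, dtype=float), np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be non-empty")
    d = float(scipy.stats.ks_2samp(a, b, method="asymp").statistic)
    en = np.sqrt(len(a) * len(b) / (len(a) + len(b)))
    lam = (en + 0.12 + 0.11 / en) * d  # small-sample effective-n correction
    p = float(scipy.special.kolmogorov(lam))
    return d, min(max(p, 0.0), 1.0)


def wilcoxon_signed_rank(pre: Sequence[float], post: Sequence[float]
                         ) -> tuple[float, float]:
    """Paired Wilcoxon signed-rank test (normal approximation, corrected).

    Zero differences are dropped; at least 5 non-zero pairs are required.
    The statistic is the smaller of the positive/negative rank sums.
    """
    pre, post = np.asarray(pre, dtype=float), np.asarray(post, dtype=float)
    if len(pre) != len(post):
        raise ValueError("pre and post must be paired (equal length)")
    diffs = post - pre
    nz = diffs[diffs != 0]
    if len(nz) == 0:
        raise ValueError("all paired differences are zero")
    if len(nz) < 5:
        raise ValueError(f"only {len(nz)} non-zero pairs; need >= 5")
    res = scipy.stats.wilcoxon(nz, zero_method="wilcox", correction=True,
                               method="approx")
    return float(res.statistic), float(res.pvalue)


def spearman(x: Sequence[float], y: Sequence[float],
             alternative: str = "two_sided") -> tuple[float, float]:
    """Spearman rank correlation with tie-averaged ranks; t-approximation p.

    ``alternative='one_sided'`` tests in the direction of the observed
    correlation's sign.
    """
    x, y = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 4:
        raise ValueError("need paired samples with n >= 4")
    if np.isnan(x).any() or np.isnan(y).any():
        raise ValueError("missing values are not allowed")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("correlation undefined for constant input")
    rho = float(scipy.stats.spearmanr(x, y).statistic)
    if alternative == "two_sided":
        alt = "two-sided"
    elif alternative == "one_sided":
        alt = "greater" if rho >= 0 else "less"
    else:
        raise ValueError("alternative must be 'one_sided' or 'two_sided'")
    p = float(scipy.stats.spearmanr(x, y, alternative=alt).pvalue)
    return rho, p


@dataclass
class RobustFitResult:
    """Robust line fit y = intercept + slope * x via IRLS."""

    slope: float
    intercept: float
    weight_function: str
    tune: float
    final_weights: np.ndarray
    n_iter: int
    converged: bool


def _irls_weights(u: np.ndarray, weight_function: str) -> np.ndarray:
    if weight_function == "welsch":
        return np.exp(-u ** 2)
    if weight_function == "andrews":
        w = np.ones_like(u)
        nz = u != 0
        w[nz] = np.where(np.abs(u[nz]) < np.pi, np.sin(u[nz]) / u[nz], 0.0)
        return np.clip(w, 0.0, 1.0)
    raise ValueError("weight_function must be 'welsch' or 'andrews'")


def robust_fit(x: Sequence[float], y: Sequence[float],
               weight_function: str = "welsch", tune: float = 0.8,
               tol: float = 1e-8, max_iter: int = 200) -> RobustFitResult:
    """Iteratively reweighted least-squares line fit.

    Residual scale is re-estimated each iteration as MAD/0.6745; the
    standardized residual is ``u = r / (tune * s)`` (the tune value is the
    single shared multiplier; no weight-function-specific constant is
    folded in).  Welsch weights decay as exp(-u^2); Andrews weights are
    sin(u)/u inside |u| < pi and zero beyond.  Non-convergence is flagged,
    not raised.
    """
    x, y = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need paired samples with n >= 3")
    if np.all(x == x[0]):
        raise ValueError("x must not be constant")
    if tune <= 0:
        raise ValueError("tune must be positive")
    A = np.column_stack([np.ones_like(x), x])
    beta, *_ = np.linalg.lstsq(A, y, rcond=None)
    w = np.ones_like(x)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        r = y - A @ beta
        med = np.median(r)
        s = np.median(np.abs(r - med)) / 0.6745
        if s <= 0 or not np.isfinite(s):
            converged = True  # residuals numerically exact
            break
        u = r / (tune * s)
        w = _irls_weights(u, weight_function)
        if w.sum() == 0 or np.count_nonzero(w) < 2:
            break
        sw = np.sqrt(w)
        beta_new, *_ = np.linalg.lstsq(A * sw[:, None], y * sw, rcond=None)
        if np.max(np.abs(beta_new - beta)) < tol:
            beta = beta_new
            converged = True
            break
        beta = beta_new
    return RobustFitResult(slope=float(beta[1]), intercept=float(beta[0]),
                           weight_function=weight_function, tune=tune,
                           final_weights=w, n_iter=it, converged=converged)


def population_daily_summary(cohort: Sequence[BiosignalSeries],
                             dose_events: Sequence[DoseEvent],
                             n_post_days: int = 5) -> pd.DataFrame:
    """Population-level pre/post daily medians with Wilcoxon tests.

    For each individual and channel, the median over all pre-dose data is
    subtracted from the median of each post-dose day 1..n, giving per-day
    deltas relative to the individual's own baseline.  Across individuals,
    the population median delta and a Wilcoxon signed-rank p-value are
    reported per channel per day.
    """
    doses = {e.participant_id: e for e in dose_events}
    per_individual: dict[str, dict[tuple[str, int], float]] = {}
    for s in cohort:
        e = doses.get(s.participant_id)
        if e is None:
            continue
        df = s.data
        pre = df[df["timestamp"] < e.dose_time]
        deltas: dict[tuple[str, int], float] = {}
        for ch in CHANNELS:
            base = pre[ch].median()
            if not np.isfinite(base):
                continue
            for day in range(1, n_post_days + 1):
                lo = e.dose_time + pd.Timedelta(days=day - 1)
                hi = e.dose_time + pd.Timedelta(days=day)
                vals = df.loc[(df["timestamp"] >= lo)
                              & (df["timestamp"] < hi), ch].dropna()
                if len(vals):
                    deltas[(ch, day)] = float(vals.median() - base)
        if deltas:
            per_individual[s.participant_id] = deltas
    if len(per_individual) < 5:
        raise ValueError("need >= 5 individuals with pre and post data")
    rows = []
    for ch in CHANNELS:
        for day in range(1, n_post_days + 1):
            d = np.array([v[(ch, day)] for v in per_individual.values()
                          if (ch, day) in v])
            if len(d) < 5:
                continue
            try:
                _, p = wilcoxon_signed_rank(np.zeros_like(d), d)
            except ValueError:
                p = 1.0
            rows.append({"channel": ch, "post_day": day, "n": len(d),
                         "median_delta": float(np.median(d)), "wilcoxon_p": p})
    return pd.DataFrame(rows)
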