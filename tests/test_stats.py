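"""Confusion arithmetic, bootstrap performance, rank statistics, robust fits."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mcir import (bootstrap_performance, confusion_metrics, ks_two_sample,
                  population_daily_summary, robust_fit, spearman,
                  wilcoxon_signed_rank)
from mcir.synthetic import simulate_cohort
from mcir.types import DoseEvent
from conftest import EPOCH, make_mcir


# ---------------------------------------------------------------- oracles

def ks_statistic_oracle(a, b):
    """sup |ECDF_a - ECDF_b| over the pooled support."""
    grid = np.unique(np.concatenate([a, b]))
    fa = np.array([(np.asarray(a) <= g).mean() for g in grid])
    fb = np.array([(np.asarray(b) <= g).mean() for g in grid])
    return np.max(np.abs(fa - fb))


def average_ranks(v):
    v = np.asarray(v, dtype=float)
    order = np.argsort(v, kind="stable")
    ranks = np.empty(len(v))
    i = 0
    sorted_v = v[order]
    while i < len(v):
        j = i
        while j + 1 < len(v) and sorted_v[j + 1] == sorted_v[i]:
            j += 1
        ranks[order[i:j + 1]] = 0.5 * (i + j) + 1.0
        i = j + 1
    return ranks


def spearman_oracle(x, y):
    rx, ry = average_ranks(x), average_ranks(y)
    return np.corrcoef(rx, ry)[0, 1]


def wilcoxon_statistic_oracle(pre, post):
    d = np.asarray(post, dtype=float) - np.asarray(pre, dtype=float)
    d = d[d != 0]
    r = average_ranks(np.abs(d))
    return min(r[d > 0].sum(), r[d < 0].sum())


# ------------------------------------------------------ confusion metrics

class TestConfusionMetrics:
    def test_published_operating_point_reconstruction(self):
        est = confusion_metrics(1.0, 0.677, n_pos=66, n_neg=76)
        assert round(100 * est.acc, 1) == 82.7
        assert est.npv == 1.0
        assert est.fpr == pytest.approx(0.323)
        assert round(100 * est.ppv, 1) == 72.9

    def test_perfect_tpr_forces_perfect_npv(self):
        for spc in (0.3, 0.7, 0.99):
            assert confusion_metrics(1.0, spc, 10, 33).npv == 1.0

    def test_perfect_classifier(self):
        est = confusion_metrics(1.0, 1.0, 5, 5)
        assert (est.tpr, est.spc, est.ppv, est.npv, est.acc) == (1, 1, 1, 1, 1)

    def test_degenerate_ppv_raises(self):
        with pytest.raises(ValueError, match="PPV"):
            confusion_metrics(0.0, 1.0, 10, 10)

    @given(st.floats(0.01, 1.0), st.floats(0.01, 1.0),
           st.integers(1, 500), st.integers(1, 500))
    @settings(max_examples=100, deadline=None)
    def test_accuracy_identity(self, tpr, spc, n_pos, n_neg):
        est = confusion_metrics(tpr, spc, n_pos, n_neg)
        expect = (tpr * n_pos + spc * n_neg) / (n_pos + n_neg)
        assert est.acc == pytest.approx(expect, rel=1e-12)
        assert est.fpr == pytest.approx(1 - est.spc, abs=1e-12)


# ---------------------------------------------------------- rank statistics

class TestKS:
    def test_identical_samples_zero(self):
        d, _ = ks_two_sample([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert d == 0.0

    def test_disjoint_supports_one(self):
        d, p = ks_two_sample([1, 2, 3], [4, 5, 6])
        assert d == 1.0 and 0 < p < 1

    def test_statistic_matches_oracle_small_n(self):
        rng = np.random.default_rng(0)
        for _ in range(300):
            n, m = rng.integers(1, 7), rng.integers(1, 7)
            a = rng.integers(0, 5, size=n).astype(float)  # ties likely
            b = rng.integers(0, 5, size=m).astype(float)
            d, _ = ks_two_sample(a, b)
            assert d == pytest.approx(ks_statistic_oracle(a, b), abs=1e-12)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            ks_two_sample([], [1.0])


class TestWilcoxon:
    def test_uniform_shift_gives_zero_statistic(self):
        pre = np.arange(8, dtype=float)
        w, p = wilcoxon_signed_rank(pre, pre + 2.0)
        assert w == 0.0 and p < 0.05

    def test_statistic_matches_oracle_small_n(self):
        rng = np.random.default_rng(1)
        checked = 0
        while checked < 200:
            n = int(rng.integers(5, 7))
            pre = rng.integers(0, 6, size=n).astype(float)
            post = rng.integers(0, 6, size=n).astype(float)
            if (post - pre != 0).sum() < 5:
                continue
            w, _ = wilcoxon_signed_rank(pre, post)
            assert w == pytest.approx(wilcoxon_statistic_oracle(pre, post))
            checked += 1

    def test_symmetric_permutation_statistic_near_center(self):
        rng = np.random.default_rng(2)
        pre = np.arange(1.0, 13.0)
        ws = []
        for _ in range(50):
            post = rng.permutation(pre)
            if (post - pre != 0).sum() < 5:
                continue
            nz = (post - pre) != 0
            n = nz.sum()
            w, _ = wilcoxon_signed_rank(pre[nz], post[nz])
            ws.append(w / (n * (n + 1) / 4.0))
        assert 0.5 < np.mean(ws) <= 1.0  # min-side statistic <= center

    def test_guards(self):
        with pytest.raises(ValueError):
            wilcoxon_signed_rank([1.0] * 6, [1.0] * 6)  # all zero diffs
        with pytest.raises(ValueError):
            wilcoxon_signed_rank([1, 2, 3, 4, 5, 6], [1, 2, 3, 4, 5, 7.0])


class TestSpearman:
    def test_monotone_extremes(self):
        x = np.arange(10.0)
        assert spearman(x, np.exp(x))[0] == pytest.approx(1.0)
        assert spearman(x, -x ** 3)[0] == pytest.approx(-1.0)

    def test_hand_ranked_example(self):
        # sum of squared rank differences = 4 -> rho = 1 - 6*4/(5*24) = 0.8
        rho, _ = spearman([1, 2, 3, 4, 5], [2, 1, 4, 3, 5])
        assert rho == pytest.approx(0.8)

    def test_matches_oracle_small_n_with_ties(self):
        rng = np.random.default_rng(3)
        for _ in range(300):
            n = int(rng.integers(4, 7))
            x = rng.integers(0, 4, size=n).astype(float)
            y = rng.integers(0, 4, size=n).astype(float)
            if np.all(x == x[0]) or np.all(y == y[0]):
                continue
            rho, _ = spearman(x, y)
            assert rho == pytest.approx(spearman_oracle(x, y), abs=1e-12)

    def test_one_sided_p_halves_two_sided(self):
        x = [1.0, 2, 3, 4, 5, 6]
        y = [2.0, 1, 4, 3, 6, 5]
        rho, p2 = spearman(x, y, "two_sided")
        _, p1 = spearman(x, y, "one_sided")
        assert p1 == pytest.approx(p2 / 2)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            spearman([1.0, 1, 1, 1], [1.0, 2, 3, 4])


# ---------------------------------------------------------------- robust fit

class TestRobustFit:
    def test_exact_line_recovered(self):
        x = np.linspace(0, 10, 15)
        fit = robust_fit(x, 2 * x + 1)
        assert fit.slope == pytest.approx(2.0, abs=1e-8)
        assert fit.intercept == pytest.approx(1.0, abs=1e-8)
        assert fit.converged

    @pytest.mark.parametrize("wf", ["welsch", "andrews"])
    def test_huge_tune_matches_ols(self, wf):
        rng = np.random.default_rng(4)
        x = rng.uniform(0, 10, 30)
        y = 1.5 * x - 2 + rng.normal(0, 1, 30)
        fit = robust_fit(x, y, weight_function=wf, tune=1e9)
        ols = np.polyfit(x, y, 1)
        assert fit.slope == pytest.approx(ols[0], abs=1e-6)
        assert fit.intercept == pytest.approx(ols[1], abs=1e-6)

    @pytest.mark.parametrize("wf", ["welsch", "andrews"])
    def test_gross_outlier_downweighted(self, wf):
        rng = np.random.default_rng(5)
        x = np.linspace(0, 10, 20)
        y = 2 * x + 1 + rng.normal(0, 0.1, 20)
        y[7] += 40.0  # gross outlier
        fit = robust_fit(x, y, weight_function=wf)
        ols_slope = np.polyfit(x, y, 1)[0]
        assert abs(fit.slope - 2.0) < 0.05
        assert abs(ols_slope - 2.0) > 0.2
        assert fit.final_weights[7] < 0.05

    def test_weights_in_unit_interval(self):
        rng = np.random.default_rng(6)
        x = rng.uniform(0, 5, 25)
        y = x + rng.standard_t(3, size=25)
        for wf in ("welsch", "andrews"):
            fit = robust_fit(x, y, weight_function=wf)
            assert ((fit.final_weights >= 0) & (fit.final_weights <= 1)).all()

    def test_constant_x_rejected(self):
        with pytest.raises(ValueError):
            robust_fit([1.0, 1, 1, 1], [1.0, 2, 3, 4])


# ------------------------------------------------------------- bootstrap

def _mcir_noise(rng, n_blocks, rate=0.05):
    v = np.zeros(n_blocks)
    hot = rng.uniform(size=n_blocks) < rate
    v[hot] = rng.uniform(0.05, 0.6, size=hot.sum())
    return make_mcir(v)


class TestBootstrapPerformance:
    def test_perfect_separation_has_degenerate_ci(self):
        rng = np.random.default_rng(7)
        controls = [make_mcir(np.zeros(2000)) for _ in range(4)]
        est = bootstrap_performance([True] * 10, controls,
                                    windows_per_control=20, n_boot=100, seed=1)
        assert est.tpr == 1.0 and est.fpr == 0.0
        assert est.ci95["tpr"] == (1.0, 1.0)
        assert est.ci95["fpr"] == (0.0, 0.0)
        assert est.npv == 1.0

    def test_seed_reproducibility(self):
        rng = np.random.default_rng(8)
        controls = [_mcir_noise(rng, 1500) for _ in range(6)]
        kw = dict(windows_per_control=30, n_boot=200, seed=42)
        e1 = bootstrap_performance([True, True, False, True], controls, **kw)
        e2 = bootstrap_performance([True, True, False, True], controls, **kw)
        assert e1.to_dict() == e2.to_dict()

    def test_ci_covers_direct_window_rate(self):
        rng = np.random.default_rng(9)
        controls = [_mcir_noise(rng, 2000, rate=0.12) for _ in range(12)]
        from mcir.stats import classify_control_windows
        direct = np.concatenate(classify_control_windows(
            controls, 200, np.random.default_rng(0))).mean()
        est = bootstrap_performance([True] * 20, controls,
                                    windows_per_control=100, n_boot=400, seed=3)
        lo, hi = est.ci95["fpr"]
        assert lo - 0.05 <= direct <= hi + 0.05

    def test_short_controls_skipped_all_short_raises(self):
        short = [make_mcir(np.zeros(10))]
        with pytest.raises(ValueError):
            bootstrap_performance([True], short, n_boot=10, seed=0)

    def test_ci_width_converges_with_more_bootstraps(self):
        # Percentile CIs estimate a fixed sampling-distribution width: more
        # replicates stabilize that estimate (lower seed-to-seed variance)
        # and the mean widths agree closely.
        rng = np.random.default_rng(10)
        controls = [_mcir_noise(rng, 1500, rate=0.10) for _ in range(8)]
        study = [True] * 15 + [False] * 5
        w_small, w_big = [], []
        for rep in range(10):
            e_small = bootstrap_performance(study, controls, 50, n_boot=250,
                                            seed=rep)
            e_big = bootstrap_performance(study, controls, 50, n_boot=4000,
                                          seed=rep)
            w_small.append(e_small.ci95["acc"][1] - e_small.ci95["acc"][0])
            w_big.append(e_big.ci95["acc"][1] - e_big.ci95["acc"][0])
        assert np.std(w_big) < np.std(w_small)
        assert np.mean(w_big) == pytest.approx(np.mean(w_small), rel=0.15)


# ------------------------------------------------- population daily summary

class TestPopulationDailySummary:
    @pytest.fixture(scope="class")
    def cohort(self):
        series, truths = simulate_cohort(
            8, magnitude_distribution=2.0, seed=13,
            baseline_days=3.0, post_days=4.0)
        events = [DoseEvent(t.participant_id, t.dose_time) for t in truths]
        return series, events

    def test_injected_hr_shift_recovered_on_day_one(self, cohort):
        series, events = cohort
        table = population_daily_summary(series, events, n_post_days=3)
        day1 = table[(table["channel"] == "hr") & (table["post_day"] == 1)]
        # magnitude 2 x 4 bpm peak with ramp envelope: day-1 median shift
        # lands well above zero but below the 8 bpm peak
        assert 1.0 < day1["median_delta"].iloc[0] < 8.0
        assert day1["wilcoxon_p"].iloc[0] < 0.05

    def test_null_cohort_shows_no_shift(self):
        series, truths = simulate_cohort(
            6, magnitude_distribution=0.0, seed=14,
            baseline_days=3.0, post_days=3.0)
        events = [DoseEvent(t.participant_id, t.dose_time) for t in truths]
        table = population_daily_summary(series, events, n_post_days=2)
        hr = table[table["channel"] == "hr"]
        assert hr["median_delta"].abs().max() < 1.5

    def test_too_few_individuals_rejected(self, cohort):
        series, events = cohort
        with pytest.raises(ValueError):
            population_daily_summary(series[:1], events[:1])
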