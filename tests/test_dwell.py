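"""Residence-time mixture fitting, BIC, bootstrap, Z-test."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from chromodwell import (
    DwellDataset,
    DwellTimeModel,
    SurvivalCurve,
    bic,
    compare_conditions,
    exponential_mixture_mle,
    fit_exponential_mixture,
    select_dwell_model,
    simulate_dwell_times,
    survival_curve,
)

TWO_POP = [(0.88, 2.4), (0.12, 28.8)]


class TestBic:
    def test_direct_arithmetic_oracle(self):
        # independent evaluation of ln[n](p+1) + n(ln[2 pi RSS / n] + 1)
        n, p, rss = 100, 3, 1.0
        expected = np.log(100) * 4 + 100 * (np.log(2 * np.pi * 1.0 / 100) + 1)
        assert bic(n, p, rss) == pytest.approx(expected, rel=1e-12)

    @given(st.floats(0.01, 10.0), st.floats(0.01, 10.0))
    def test_monotone_in_rss(self, rss1, rss2):
        lo, hi = sorted((rss1, rss2))
        if hi / lo < 1 + 1e-9:
            return
        assert bic(50, 3, lo) < bic(50, 3, hi)

    def test_textbook_penalty_flag(self):
        n, p, rss = 200, 3, 0.5
        assert bic(n, p, rss) - bic(n, p, rss, textbook=True) == pytest.approx(
            np.log(n) * (p + 1) - p * np.log(n))

    def test_degenerate_rss_raises(self):
        with pytest.raises(ValueError):
            bic(10, 2, 0.0)


class TestSurvivalCurve:
    def test_hand_counted_example(self):
        ds = DwellDataset(dwells=np.array([1.0, 2.0, 3.0]), frame_interval=1.0)
        with pytest.warns(UserWarning):
            curve = survival_curve(ds)
        np.testing.assert_allclose(curve.t, [1.0, 2.0, 3.0])
        np.testing.assert_allclose(curve.survival, [1.0, 2 / 3, 1 / 3])

    def test_single_value_is_step(self):
        ds = DwellDataset(dwells=np.full(20, 2.0), frame_interval=0.5)
        curve = survival_curve(ds)
        np.testing.assert_allclose(curve.survival, [1, 1, 1, 1])

    def test_censored_excluded_and_counted(self):
        ds = DwellDataset(dwells=np.array([1.0] * 15 + [9.0] * 5),
                          frame_interval=1.0,
                          censored=np.array([False] * 15 + [True] * 5))
        curve = survival_curve(ds)
        assert curve.n == 15
        assert curve.n_censored_excluded == 5
        assert curve.t.max() == pytest.approx(1.0)

    def test_all_censored_raises(self):
        ds = DwellDataset(dwells=np.ones(5), frame_interval=1.0,
                          censored=np.ones(5, dtype=bool))
        with pytest.raises(ValueError):
            survival_curve(ds)

    def test_survival_non_increasing_invariant(self):
        ds = simulate_dwell_times(TWO_POP, 2000, seed=3)
        curve = survival_curve(ds)
        assert np.all(np.diff(curve.survival) <= 1e-12)
        assert curve.survival[0] <= 1.0


class TestFitting:
    def test_exact_single_exponential_recovered(self):
        t = np.arange(1, 80) * 0.5
        curve = SurvivalCurve(t=t, survival=np.exp(-t / 5.0), n=1000,
                              frame_interval=0.5)
        res = fit_exponential_mixture(curve, n_components=1)
        assert res.taus[0] == pytest.approx(5.0, rel=1e-6)

    def test_two_population_recovery(self):
        # 2.4 s / 28.8 s mixture at n=5000: slow tau within 15%, fast within
        # 10%, slow fraction within 3 points
        ds = simulate_dwell_times(TWO_POP, 5000, seed=21, frame_interval=0.5)
        res = fit_exponential_mixture(survival_curve(ds), n_components=2)
        assert res.fast_tau == pytest.approx(2.4, rel=0.10)
        assert res.slow_tau == pytest.approx(28.8, rel=0.15)
        assert abs(res.fractions[-1] - 0.12) < 0.03

    def test_components_sorted_and_normalised(self):
        ds = simulate_dwell_times(TWO_POP, 3000, seed=5)
        res = fit_exponential_mixture(survival_curve(ds), 2)
        assert res.taus[0] < res.taus[1]
        assert res.fractions.sum() == pytest.approx(1.0, abs=1e-6)

    def test_two_mixture_beats_single_fit_on_rss(self):
        ds = simulate_dwell_times(TWO_POP, 5000, seed=9)
        curve = survival_curve(ds)
        rss1 = fit_exponential_mixture(curve, 1).rss
        rss2 = fit_exponential_mixture(curve, 2).rss
        assert rss2 < rss1

    def test_mle_cross_check_agrees(self):
        ds = simulate_dwell_times(TWO_POP, 5000, seed=17)
        res = fit_exponential_mixture(survival_curve(ds), 2)
        taus, fracs = exponential_mixture_mle(ds.dwells, 2, seed=0)
        np.testing.assert_allclose(res.taus, taus, rtol=0.15)
        np.testing.assert_allclose(res.fractions, fracs, atol=0.05)


class TestModelSelection:
    def test_single_exponential_prefers_one_component(self):
        wins = 0
        for seed in range(10):
            ds = simulate_dwell_times([(1.0, 5.0)], 3000, seed=seed)
            res = select_dwell_model(survival_curve(ds))
            wins += res.n_components == 1
        assert wins >= 9

    def test_separated_mixture_selects_two(self):
        ds = simulate_dwell_times(TWO_POP, 5000, seed=31)
        res = select_dwell_model(survival_curve(ds))
        assert res.n_components == 2

    def test_vanishing_third_component_is_dropped(self):
        comps = [(0.595, 2.4), (0.4, 28.8), (0.005, 200.0)]
        ds = simulate_dwell_times(comps, 5000, seed=41)
        res = select_dwell_model(survival_curve(ds))
        assert res.n_components == 2

    def test_bic_table_attached(self):
        ds = simulate_dwell_times(TWO_POP, 2000, seed=2)
        res = select_dwell_model(survival_curve(ds))
        assert res.bic_table is not None
        assert (res.n_components, res.bic, res.rss) in res.bic_table


class TestBootstrap:
    def test_mean_consistent_with_base_fit(self):
        ds = simulate_dwell_times([(1.0, 10.0)], 5000, seed=51)
        res = fit_exponential_mixture(survival_curve(ds), 1)
        res.parametric_bootstrap(n_boot=200, seed=52)
        assert abs(res.bootstrap_mean[0] - res.taus[0]) < res.bootstrap_sd[0]

    def test_sd_tracks_analytic_standard_error(self):
        # single exponential, n=500: SE(tau_hat) ~ tau / sqrt(n)
        ds = simulate_dwell_times([(1.0, 10.0)], 500, seed=61)
        res = fit_exponential_mixture(survival_curve(ds), 1)
        res.parametric_bootstrap(n_boot=400, seed=62)
        analytic = res.taus[0] / np.sqrt(500)
        assert res.bootstrap_sd[0] == pytest.approx(analytic, rel=0.30)

    def test_bit_reproducible_under_seed(self):
        ds = simulate_dwell_times(TWO_POP, 1000, seed=71)
        a = fit_exponential_mixture(survival_curve(ds), 2)
        b = fit_exponential_mixture(survival_curve(ds), 2)
        a.parametric_bootstrap(n_boot=50, seed=72)
        b.parametric_bootstrap(n_boot=50, seed=72)
        np.testing.assert_array_equal(a.bootstrap_mean, b.bootstrap_mean)
        np.testing.assert_array_equal(a.bootstrap_sd, b.bootstrap_sd)

    def test_summary_reports_bootstrap(self):
        ds = simulate_dwell_times([(1.0, 5.0)], 1000, seed=81)
        res = fit_exponential_mixture(survival_curve(ds), 1)
        res.parametric_bootstrap(n_boot=50, seed=82)
        assert "boot" in res.summary()

    def test_plot_shows_log_survival(self):
        import matplotlib
        matplotlib.use("Agg")
        ds = simulate_dwell_times([(1.0, 5.0)], 500, seed=83)
        res = fit_exponential_mixture(survival_curve(ds), 1)
        ax = res.plot()
        assert ax.get_yscale() == "log"


class TestZTest:
    def test_identical_means_give_z_zero_p_one(self):
        z, p = compare_conditions([5.0, 5.0, 5.0], [5.0, 5.0, 5.0])
        assert z == 0.0 and p == 1.0

    def test_against_normal_cdf_oracle(self):
        # replicate-level specific residence times, WT vs mutant style
        a = np.array([45.0, 38.2, 64.4])   # mean ~49.2
        b = np.array([31.1, 25.5, 31.9])   # mean ~29.5
        z, p = compare_conditions(a, b)
        se = np.hypot(a.std(ddof=1) / np.sqrt(3), b.std(ddof=1) / np.sqrt(3))
        z_expected = (a.mean() - b.mean()) / se
        assert z == pytest.approx(z_expected, rel=1e-12)
        assert p == pytest.approx(2 * (1 - stats.norm.cdf(abs(z_expected))),
                                  rel=1e-9)

    def test_needs_two_replicates(self):
        with pytest.raises(ValueError):
            compare_conditions([1.0], [2.0, 3.0])


def test_recovery_over_seeds_fig6a_regime():
    """Median recovery at n=5000 over several datasets: tau1 within 10%,
    tau2 within 15%, slow fraction within 0.03."""
    t1, t2, f2 = [], [], []
    for seed in range(8):
        ds = simulate_dwell_times(TWO_POP, 5000, seed=900 + seed,
                                  frame_interval=0.5)
        res = DwellTimeModel(ds).fit(2)
        t1.append(res.fast_tau)
        t2.append(res.slow_tau)
        f2.append(res.fractions[-1])
    assert np.median(t1) == pytest.approx(2.4, rel=0.10)
    assert np.median(t2) == pytest.approx(28.8, rel=0.15)
    assert abs(np.median(f2) - 0.12) < 0.03
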