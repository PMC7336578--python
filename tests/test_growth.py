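"""OD correction, lag times, Richards fitting and the variance decomposition."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import least_squares

from ssu1_checkup.growth import (
    DEFAULT_OD_CORRECTION,
    GrowthCurve,
    anova_lm1,
    correct_od,
    fit_richards,
    lag_time,
    mu_max_of_fit,
    richards_od,
)
from ssu1_checkup.simulate import SimConfig, gen_growth_curves, richards_truth

GRID = np.linspace(0, 96, 25)
BASE = dict(K=1.4, nu=1.0, k=0.28, t_m=10.0)


class TestCorrectOd:
    def test_constant_term_at_zero(self):
        assert correct_od([0.0])[0] == pytest.approx(0.0386)

    def test_sum_of_coefficients_at_one(self):
        assert correct_od([1.0])[0] == pytest.approx(0.9589)

    def test_monotone_increasing_on_operating_range(self):
        x = np.arange(0.0, 2.0001, 0.01)
        y = correct_od(x)
        assert np.all(np.diff(y) > 0)

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            correct_od([-0.1])


class TestLagTime:
    def curve(self, times, ods):
        return GrowthCurve("s", np.asarray(times), np.asarray(ods))

    def test_flat_curve_censored(self):
        c = self.curve([0, 4, 8, 12], [0.1, 0.1, 0.1, 0.1])
        t, censored = lag_time(c, inoculum_od=correct_od([0.1])[0])
        assert censored and t == 12.0

    def test_linear_interpolation(self):
        c = self.curve([0, 2, 4, 6, 8], [0.10, 0.12, 0.18, 0.26, 0.40])
        t, censored = lag_time(c, inoculum_od=0.1, use_corrected=False)
        # threshold 0.20 crossed between 4 h (0.18) and 6 h (0.26)
        assert not censored
        assert t == pytest.approx(4 + 2 * (0.20 - 0.18) / (0.26 - 0.18))

    def test_curve_starting_above_threshold(self):
        c = self.curve([0, 2, 4], [0.5, 0.6, 0.7])
        t, censored = lag_time(c, inoculum_od=0.1, use_corrected=False)
        assert (t, censored) == (0.0, False)

    def test_monotone_under_pointwise_decrease(self):
        times = np.arange(0, 40, 2.0)
        y = richards_od(times, **BASE)
        c_hi = self.curve(times, y)
        c_lo = self.curve(times, y * 0.8)
        t_hi, _ = lag_time(c_hi, 0.1, use_corrected=False)
        t_lo, _ = lag_time(c_lo, 0.1, use_corrected=False)
        assert t_lo >= t_hi

    def test_bad_inoculum_rejected(self):
        with pytest.raises(ValueError):
            lag_time(self.curve([0, 1], [0.1, 0.2]), 0.0)


class TestFitRichards:
    def test_noiseless_self_consistency(self):
        y = richards_od(GRID, **BASE)
        p = fit_richards(GrowthCurve("s", GRID, y), already_corrected=True)
        truth = richards_truth(BASE["K"], BASE["nu"], BASE["k"], BASE["t_m"], GRID)
        assert p.converged
        assert p.mu_max == pytest.approx(truth.mu_max, rel=0.01)
        assert p.lag_time_h == pytest.approx(truth.lag_time_h, abs=0.1)

    def test_logistic_closed_form_limit(self):
        # nu = 1 reduces to the logistic; max d(ln y)/dt on the window is
        # k * (1 - y(t0)/K) evaluated at the first time point
        y = richards_od(GRID, 1.2, 1.0, 0.3, 12.0)
        p = fit_richards(GrowthCurve("s", GRID, y), already_corrected=True)
        closed_form = p.k * (1 - richards_od(GRID[0], p.K, 1.0, p.k, p.t_m) / p.K)
        assert p.nu == pytest.approx(1.0, rel=0.05)
        assert p.mu_max == pytest.approx(closed_form, rel=0.01)

    def test_noisy_recovery_simulation(self):
        """Mean recovered mu_max within 5% of the generating value and every
        lag within one sampling interval, over 100 noise replicates."""
        truth = richards_truth(BASE["K"], BASE["nu"], BASE["k"], BASE["t_m"], GRID)
        y0 = richards_od(GRID, **BASE)
        interval = GRID[1] - GRID[0]
        mus, lag_err = [], []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            y = np.clip(y0 + rng.normal(0, 0.01, GRID.shape), 1e-4, None)
            p = fit_richards(GrowthCurve("s", GRID, y), already_corrected=True, seed=seed)
            mus.append(p.mu_max)
            lag_err.append(abs(p.lag_time_h - truth.lag_time_h))
        assert abs(np.mean(mus) - truth.mu_max) / truth.mu_max < 0.05
        assert max(lag_err) < interval

    def test_richards_rss_not_worse_than_logistic(self):
        rng = np.random.default_rng(5)
        y0 = richards_od(GRID, 1.4, 2.5, 0.5, 14.0)  # distinctly non-logistic
        y = y0 + rng.normal(0, 0.005, GRID.shape)
        p = fit_richards(GrowthCurve("s", GRID, np.clip(y, 1e-4, None)),
                         already_corrected=True)

        def logistic_resid(theta):
            K, k, t_m = theta
            return richards_od(GRID, K, 1.0, k, t_m) - y

        sol = least_squares(
            logistic_resid, [y.max(), 0.3, 14.0],
            bounds=([1e-6, 1e-4, 1e-6], [14.0, 10.0, 960.0]),
        )
        rss_logistic = float(np.sum(sol.fun**2))
        assert p.rss <= rss_logistic + 1e-10

    def test_degenerate_curve_flagged(self):
        y = np.full_like(GRID, 0.2)
        p = fit_richards(GrowthCurve("s", GRID, y), already_corrected=True)
        assert not p.converged
        assert p.mu_max == 0.0

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_richards(GrowthCurve("s", GRID[:4], np.ones(4)))


def fit_design(curves):
    rows = []
    for c in curves:
        p = fit_richards(c, already_corrected=True, seed=0)
        rows.append(
            {"chr16_config": c.chr16_config, "so2": c.so2_mg_per_l,
             "mu_max": p.mu_max, "lag_time_h": p.lag_time_h,
             "lag_censored": p.lag_censored}
        )
    return pd.DataFrame(rows)


class TestAnova:
    def null_table(self, seed, reps=4):
        rng = np.random.default_rng(seed)
        rows = []
        for cfg in ("a", "b", "c", "d", "e", "f"):
            for so2 in (0, 25, 50, 75):
                for _ in range(reps):
                    rows.append({"chr16_config": cfg, "so2": so2,
                                 "value": rng.normal()})
        return pd.DataFrame(rows)

    def test_percent_variance_sums_to_100(self):
        res = anova_lm1(self.null_table(0))
        assert sum(res.pct_variance.values()) == pytest.approx(100.0, abs=0.1)

    def test_null_simulation_calibration(self):
        """With no factor effects, each factor stays non-significant in at
        least 90% of seeded runs."""
        ok = {"chr16": 0, "so2": 0}
        n = 100
        for seed in range(n):
            res = anova_lm1(self.null_table(seed))
            for term in ok:
                ok[term] += res.p_values[term] > 0.05
        assert ok["chr16"] >= 0.9 * n
        assert ok["so2"] >= 0.9 * n

    def test_strong_so2_effect_dominates(self):
        """A configured SO2 effect on lag must surface as the largest
        non-residual variance share."""
        cfg = SimConfig(seed=3, n_strains_per_config=2, n_replicates=2)
        sens = {c: (5.0, 0.0) for c in
                ("XVI-wt", "VIII-t-XVI^388", "VIII-t-XVI^478",
                 "VIII-t-XVI^555", "XV-t-XVI", "inv-XVI")}
        curves, _ = gen_growth_curves(cfg, sensitivity=sens)
        df = fit_design(curves)
        res = anova_lm1(df, trait="lag_time_h", censored_col="lag_censored")
        shares = {k: v for k, v in res.pct_variance.items() if k != "residual"}
        assert max(shares, key=shares.get) == "so2"
        assert res.p_values["so2"] < 1e-6

    def test_balanced_design_order_invariance(self):
        df = self.null_table(7)
        res1 = anova_lm1(df)
        swapped = df.rename(columns={"chr16_config": "so2", "so2": "chr16_config"})
        res2 = anova_lm1(swapped)
        assert res1.pct_variance["chr16"] == pytest.approx(res2.pct_variance["so2"])
        assert res1.pct_variance["so2"] == pytest.approx(res2.pct_variance["chr16"])

    def test_empty_cells_named(self):
        df = self.null_table(1)
        df = df[~((df["chr16_config"] == "a") & (df["so2"] == 75))]
        with pytest.raises(ValueError, match="empty design cells"):
            anova_lm1(df)

    def test_single_level_factor_rejected(self):
        df = self.null_table(1)
        df = df[df["so2"] == 0]
        with pytest.raises(ValueError, match="levels"):
            anova_lm1(df)
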