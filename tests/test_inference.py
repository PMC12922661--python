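import math
from types import SimpleNamespace

import numpy as np
import pandas as pd
import pytest
import scipy.stats as sps

from metaprl.inference import (
    average_marginal_effect,
    bootstrap_contrast,
    breusch_pagan,
    fit_moderation,
    group_compare,
    lrt,
    odds_ratio,
    predicted_wsr,
    zscore,
)


def _table(mu3, m_bar, verbosity, gcog, switches, wins):
    return pd.DataFrame(
        {
            "mu3_0": mu3,
            "m_bar": m_bar,
            "verbosity": verbosity,
            "gcog": gcog,
            "n_win_switches": switches,
            "n_win_trials": wins,
        }
    )


def _null_table(rng, n=200, denom=40, base_p=0.3, beta=None):
    """Participant table generated from a known-coefficient binomial model
    (all-zero slopes by default)."""
    # standardise the draws so the generating design equals the fitted one
    z = {k: zscore(rng.normal(size=n)) for k in ("mu3", "mp", "verb", "gcog")}
    eta = np.full(n, math.log(base_p / (1 - base_p)))
    if beta:
        eta = eta + sum(b * z[k] for k, b in beta.items() if k != "mu3xmp")
        if "mu3xmp" in beta:
            eta = eta + beta["mu3xmp"] * z["mu3"] * z["mp"]
    p = 1 / (1 + np.exp(-eta))
    wins = np.full(n, denom)
    switches = rng.binomial(denom, p)
    return _table(z["mu3"], z["mp"], z["verb"], z["gcog"], switches, wins)


class TestZscore:
    def test_hand_example(self):
        np.testing.assert_allclose(zscore([1, 2, 3]), [-1, 0, 1])

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        x = zscore(rng.normal(size=50))
        np.testing.assert_allclose(zscore(x), x, atol=1e-12)

    def test_constant_rejected(self):
        with pytest.raises(ValueError):
            zscore([2.0, 2.0, 2.0])


class TestFitModeration:
    def test_matches_closed_form_two_by_two(self):
        """Balanced binary design: slope must equal the 2x2 log-odds ratio
        log(3.5) and the intercept the baseline log-odds log(3/7)."""
        mu3 = [0.0] * 10 + [1.0] * 10
        m_bar = ([0.0, 1.0] * 10)  # balanced, orthogonal to mu3
        switches = [3] * 10 + [6] * 10
        tab = _table(mu3, m_bar, np.tile([1.0, 2.0], 10), np.tile([1.0, 2.0], 10), switches, [10] * 20)
        fit = fit_moderation(tab, include_interaction=False, include_controls=False)
        sd_x = np.std(mu3, ddof=1)
        slope_raw = fit.params["z_mu3"] / sd_x
        assert slope_raw == pytest.approx(math.log(3.5), abs=1e-6)
        # intercept at x=0: const - beta_z * mean/sd
        eta_at_A = fit.params["const"] - fit.params["z_mu3"] * 0.5 / sd_x
        assert eta_at_A == pytest.approx(math.log(3 / 7), abs=1e-6)
        # odds ratio on the raw binary scale equals the cross-product ratio
        assert math.exp(slope_raw) == pytest.approx(3.5, abs=1e-6)

    def test_null_generator_small_coefficients(self):
        rng = np.random.default_rng(1)
        pvals = []
        for _ in range(200):
            fit = fit_moderation(_null_table(rng, n=200), include_controls=False)
            assert np.max(np.abs(fit.params[1:])) < 0.5
            i = fit.terms.index("z_mu3")
            z = fit.result.params[i] / fit.result.bse[i]
            pvals.append(2 * sps.norm.sf(abs(z)))
        # Wald p-values approximately uniform under the null
        assert sps.kstest(pvals, "uniform").pvalue > 0.01

    def test_coverage_of_known_coefficients(self):
        beta = {"mu3": 0.5, "mp": -0.3, "verb": 0.2, "gcog": 0.0, "mu3xmp": -0.2}
        rng = np.random.default_rng(2)
        hits = total = 0
        for _ in range(200):
            tab = _null_table(rng, n=300, denom=60, beta=beta)
            fit = fit_moderation(tab)
            truth = {
                "z_mu3": 0.5, "z_mp": -0.3, "z_mu3:z_mp": -0.2,
                "z_verbosity": 0.2, "z_gcog": 0.0,
            }
            for term, true_b in truth.items():
                i = fit.terms.index(term)
                total += 1
                if abs(fit.result.params[i] - true_b) < 2 * fit.result.bse[i]:
                    hits += 1
        assert hits / total >= 0.93

    def test_minimum_sample_enforced(self):
        tab = _table([1, 2, 3], [1, 2, 3], [1, 2, 3], [1, 2, 3], [1, 1, 1], [5, 5, 5])
        with pytest.raises(ValueError):
            fit_moderation(tab)


class TestLRT:
    def test_identical_models_give_zero(self):
        rng = np.random.default_rng(3)
        tab = _null_table(rng)
        fit = fit_moderation(tab)
        stat, df, p = lrt(fit, fit)
        assert stat == 0.0 and df == 0 and p == 1.0

    def test_non_nested_rejected(self):
        rng = np.random.default_rng(3)
        tab = _null_table(rng)
        full = fit_moderation(tab, include_controls=False)
        other = fit_moderation(tab, include_interaction=False)
        with pytest.raises(ValueError):
            lrt(full, other)

    def test_null_statistic_is_chi_square_one(self):
        """Under no interaction the LRT statistic has mean ~ 1 (chi2(1))."""
        rng = np.random.default_rng(4)
        stats = []
        for _ in range(500):
            tab = _null_table(rng, n=150, denom=30)
            full = fit_moderation(tab, include_controls=False)
            reduced = fit_moderation(tab, include_interaction=False, include_controls=False)
            stats.append(lrt(full, reduced)[0])
        assert abs(np.mean(stats) - 1.0) <= 0.2

    def test_power_against_strong_interaction(self):
        beta = {"mu3": 0.6, "mp": -0.3, "mu3xmp": -0.4}
        rng = np.random.default_rng(5)
        rejections = 0
        n_sims = 50
        for _ in range(n_sims):
            tab = _null_table(rng, n=480, denom=40, beta=beta)
            full = fit_moderation(tab, include_controls=False)
            reduced = fit_moderation(tab, include_interaction=False, include_controls=False)
            if lrt(full, reduced)[2] < 0.05:
                rejections += 1
        assert rejections >= 0.8 * n_sims


class TestEffects:
    @pytest.fixture(scope="class")
    def fit(self):
        rng = np.random.default_rng(6)
        return fit_moderation(_null_table(rng, n=150, beta={"mu3": 0.8, "mp": -0.4}))

    def test_odds_ratio_inverse_mapping(self, fit):
        orv, (lo, hi) = odds_ratio(fit, "z_mu3")
        i = fit.terms.index("z_mu3")
        assert orv == pytest.approx(math.exp(fit.result.params[i]))
        assert lo < orv < hi

    def test_ame_matches_finite_difference(self, fit):
        """AME must agree with a central finite difference of the mean
        predicted probability along the design column."""
        for term in ("z_mu3", "z_mp"):
            ame = average_marginal_effect(fit, term)
            i = fit.terms.index(term)
            h = 1e-5
            up, down = fit.exog.copy(), fit.exog.copy()
            up[:, i] += h
            down[:, i] -= h
            # the product column is a separate regressor: the AME of a term
            # is the derivative along its own design column only
            fd = (
                np.mean(fit.result.predict(up)) - np.mean(fit.result.predict(down))
            ) / (2 * h)
            assert ame == pytest.approx(fd, abs=1e-6)

    def test_zero_slope_gives_zero_ame(self):
        rng = np.random.default_rng(7)
        fit = fit_moderation(_null_table(rng, n=400, denom=200), include_controls=False)
        assert abs(average_marginal_effect(fit, "z_mp")) < 0.02


class TestPredictedWSR:
    def _hand_fit(self, params, terms):
        return SimpleNamespace(result=SimpleNamespace(params=np.array(params)), terms=terms)

    def test_intercept_only(self):
        fit = self._hand_fit([-1.0, 0.0, 0.0, 0.0], ("const", "z_mu3", "z_mp", "z_mu3:z_mp"))
        expected = 1 / (1 + math.exp(1.0))
        for g in ((-1, -1), (1, 1), (-1, 1)):
            assert predicted_wsr(fit, *g) == pytest.approx(expected)

    def test_hand_computed_grid(self):
        fit = self._hand_fit([-2.0, 0.5, 0.0, 0.0], ("const", "z_mu3", "z_mp", "z_mu3:z_mp"))
        assert predicted_wsr(fit, 1.0, -1.0) == pytest.approx(1 / (1 + math.exp(1.5)))
        assert predicted_wsr(fit, -1.0, 1.0) == pytest.approx(1 / (1 + math.exp(2.5)))

    def test_probability_scale_bend_without_interaction(self):
        """With beta3=0 the logit-scale slope is identical at low and high
        MP, yet the probability-scale contrast differs — the bend near the
        floor that motivates contrast-based reporting."""
        fit = self._hand_fit([-2.0, 0.8, -0.8, 0.0], ("const", "z_mu3", "z_mp", "z_mu3:z_mp"))

        def eta(mu3, mp):
            return -2.0 + 0.8 * mu3 - 0.8 * mp

        # identical link-scale slope
        assert eta(1, -1) - eta(-1, -1) == pytest.approx(eta(1, 1) - eta(-1, 1))
        pp_low = predicted_wsr(fit, 1, -1) - predicted_wsr(fit, -1, -1)
        pp_high = predicted_wsr(fit, 1, 1) - predicted_wsr(fit, -1, 1)
        assert pp_low != pytest.approx(pp_high, abs=1e-6)


class TestBootstrapContrast:
    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(8)
        tab = _null_table(rng, n=80)
        a = bootstrap_contrast(tab, n_boot=50, seed=11)
        b = bootstrap_contrast(tab, n_boot=50, seed=11)
        assert a == b

    def test_percentile_interval_brackets_median(self):
        rng = np.random.default_rng(9)
        tab = _null_table(rng, n=120, beta={"mu3": 0.5, "mu3xmp": -0.3})
        res = bootstrap_contrast(tab, n_boot=200, seed=0)
        assert res.ci_low <= res.ci_high

    def test_detects_strong_negative_interaction(self):
        beta = {"mu3": 0.8, "mp": -0.3, "mu3xmp": -0.5}
        rng = np.random.default_rng(10)
        hits = 0
        n_meta = 30
        for _ in range(n_meta):
            tab = _null_table(rng, n=250, denom=60, beta=beta)
            res = bootstrap_contrast(tab, n_boot=200, seed=int(rng.integers(2**31)))
            if res.delta < 0 and res.ci_high < 0:
                hits += 1
        assert hits >= 0.8 * n_meta


class TestBreuschPagan:
    def test_perfect_fit_gives_zero_statistic(self):
        x = np.linspace(0, 1, 50)
        res = breusch_pagan(2 * x + 1, x)
        assert res.lm_stat == 0.0 and res.lm_p == 1.0

    def test_null_p_values_uniform(self):
        rng = np.random.default_rng(11)
        pvals = []
        for _ in range(200):
            X = rng.normal(size=(500, 3))
            y = X @ [1.0, -0.5, 0.2] + rng.normal(size=500)
            pvals.append(breusch_pagan(y, X).lm_p)
        assert sps.kstest(pvals, "uniform").pvalue > 0.01

    def test_power_against_variance_trend(self):
        rng = np.random.default_rng(12)
        rejections = 0
        for _ in range(100):
            x = rng.uniform(0.5, 3.0, size=500)
            y = x + rng.normal(size=500) * x
            if breusch_pagan(y, x).lm_p < 0.05:
                rejections += 1
        assert rejections >= 90


class TestGroupCompare:
    def test_identical_groups(self):
        vals = np.r_[np.arange(10.0), np.arange(10.0)]
        groups = ["a"] * 10 + ["b"] * 10
        res = group_compare(vals, groups)
        assert res.cohen_d == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)

    def test_unit_effect_recovered(self):
        rng = np.random.default_rng(13)
        vals = np.r_[rng.normal(0, 1, 1000), rng.normal(1, 1, 1000)]
        groups = ["a"] * 1000 + ["b"] * 1000
        res = group_compare(vals, groups)
        assert 0.85 <= abs(res.cohen_d) <= 1.15

    def test_two_group_welch_anova_equals_squared_welch_t(self):
        rng = np.random.default_rng(14)
        vals = np.r_[rng.normal(0, 1, 40), rng.normal(0.8, 2, 30), rng.normal(1.5, 1, 25)]
        groups = np.array(["a"] * 40 + ["b"] * 30 + ["c"] * 25)
        sub = groups != "c"
        t_res = group_compare(vals[sub], groups[sub])
        df = pd.DataFrame({"value": vals[sub], "group": groups[sub]})
        import pingouin as pg

        f = float(pg.welch_anova(data=df, dv="value", between="group")["F"].iloc[0])
        assert f == pytest.approx(t_res.stat**2, rel=1e-9)
        # three groups route through Welch ANOVA
        res3 = group_compare(vals, groups)
        assert res3.kind == "welch_anova" and res3.p < 0.05

    def test_tiny_group_rejected(self):
        with pytest.raises(ValueError):
            group_compare([1, 2, 3], ["a", "a", "b"])
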