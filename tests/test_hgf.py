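import math
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from metaprl.behavior import win_switch_rate
from metaprl.hgf import (
    HGFParams,
    ParamPrior,
    default_priors,
    filter_beliefs,
    fit_map,
    response_probabilities,
    simulate_agent,
)
from metaprl.prl import SessionData, TaskConfig, TrialRecord

from tests._hgf_reference import reference_filter


def _random_session(seed: int, n_trials: int = 20) -> SessionData:
    rng = np.random.default_rng(seed)
    records = [
        TrialRecord(
            t=t,
            choice=int(rng.integers(1, 4)),
            outcome=int(rng.integers(0, 2)),
            assigned_probs=(0.9, 0.5, 0.1),
        )
        for t in range(1, n_trials + 1)
    ]
    return SessionData(participant_id="x", records=records)


class TestFiltering:
    @pytest.mark.parametrize("seed", range(5))
    def test_matches_independent_reference_implementation(self, seed):
        """The filter must agree with a straight-line re-implementation of
        the written update equations to near machine precision."""
        rng = np.random.default_rng(100 + seed)
        params = HGFParams(
            mu3_0=float(rng.normal(-2.5, 1.0)),
            sigma3_0=float(rng.uniform(0.5, 2.0)),
            sigma2_0=float(rng.uniform(0.5, 2.0)),
            kappa=float(rng.uniform(0.05, 0.6)),
            omega=float(rng.uniform(-2.0, 0.0)),
            theta=float(rng.uniform(0.01, 0.3)),
            phi2=float(rng.uniform(0.0, 0.2)),
            phi3=float(rng.uniform(0.0, 0.2)),
            m3=float(rng.normal(-2.5, 1.0)),
        )
        session = _random_session(seed)
        traj = filter_beliefs(session, params)
        ref = reference_filter(session.choices, session.outcomes, params)
        for name in ("xhat2", "xhat3", "mu2", "mu3", "sigma2", "sigma3", "mhat", "delta1", "delta2"):
            np.testing.assert_allclose(
                getattr(traj, name), ref[name], rtol=0, atol=1e-10, err_msg=name
            )

    def test_decoupled_level3_relaxes_to_attractor(self):
        """With kappa=0 level 3 ignores outcomes entirely and its mean decays
        geometrically toward m3 at rate phi3."""
        params = HGFParams(kappa=0.0, phi3=0.2, mu3_0=1.0, m3=-1.0)
        t1 = filter_beliefs(_random_session(1), params)
        t2 = filter_beliefs(_random_session(2), params)
        np.testing.assert_array_equal(t1.mu3, t2.mu3)
        expected = [-1.0 + (1 - 0.2) ** t * (1.0 - (-1.0)) for t in range(1, 21)]
        np.testing.assert_allclose(t1.mu3, expected, atol=1e-12)

    def test_static_levels_leave_unchosen_options_constant(self):
        """phi2=phi3=0 and kappa=0: unchosen options neither drift nor update."""
        params = HGFParams(kappa=0.0, phi2=0.0, phi3=0.0)
        session = _random_session(3)
        traj = filter_beliefs(session, params)
        mu2_prev = np.full(3, params.mu2_0)
        for t, rec in enumerate(session.records):
            for j in range(3):
                if j != rec.choice - 1:
                    assert traj.mu2[t, j] == mu2_prev[j]
            mu2_prev = traj.mu2[t]

    def test_zero_prediction_error_means_no_level2_innovation(self):
        """mu2 of the chosen option differs from its prediction by exactly
        delta1/pi2, so the innovation vanishes with the prediction error."""
        params = HGFParams()
        session = _random_session(4)
        traj = filter_beliefs(session, params)
        for t, rec in enumerate(session.records):
            c = rec.choice - 1
            innovation = traj.mu2[t, c] - traj.xhat2[t, c]
            assert innovation == 0 if traj.delta1[t] == 0 else np.sign(innovation) == np.sign(traj.delta1[t])

    def test_deterministic_and_variances_positive(self):
        params = HGFParams()
        session = _random_session(5, n_trials=160)
        a = filter_beliefs(session, params)
        b = filter_beliefs(session, params)
        np.testing.assert_array_equal(a.mu3, b.mu3)
        assert (a.sigma2 > 0).all() and (a.sigma3 > 0).all()
        assert ((a.mhat > 0) & (a.mhat < 1)).all()


class TestResponseModel:
    def test_equal_predictions_give_uniform_choice(self):
        assert response_probabilities([0.4, 0.4, 0.4], 0.0) == pytest.approx([1 / 3] * 3)

    def test_high_volatility_flattens_choice(self):
        probs = response_probabilities([0.9, 0.5, 0.1], 50.0)
        assert probs == pytest.approx([1 / 3] * 3, abs=1e-6)

    def test_unit_beta_matches_hand_softmax(self):
        probs = response_probabilities([0.9, 0.5, 0.1], 0.0)
        expected = np.exp([0.9, 0.5, 0.1])
        expected /= expected.sum()
        np.testing.assert_allclose(probs, expected, atol=1e-12)

    @given(
        m=st.lists(st.floats(0.001, 0.999), min_size=3, max_size=3),
        x3=st.floats(-5, 5),
        bump=st.floats(0.0001, 0.3),
    )
    @settings(max_examples=200, deadline=None)
    def test_simplex_and_monotonicity(self, m, x3, bump):
        probs = response_probabilities(m, x3)
        assert all(p > 0 for p in probs)
        assert sum(probs) == pytest.approx(1.0, abs=1e-9)
        m2 = list(m)
        m2[0] = min(m2[0] + bump, 1.0)
        probs2 = response_probabilities(m2, x3)
        assert probs2[0] >= probs[0] - 1e-12

    def test_extreme_volatility_is_numerically_safe(self):
        for x3 in (-700.0, 700.0):
            probs = response_probabilities([0.9, 0.5, 0.1], x3)
            assert all(p > 0 for p in probs)
            assert sum(probs) == pytest.approx(1.0, abs=1e-9)


class TestSimulation:
    def test_deterministic_given_seed(self, config):
        a, ta = simulate_agent(HGFParams(), config, 42)
        b, tb = simulate_agent(HGFParams(), config, 42)
        assert a.records == b.records
        np.testing.assert_array_equal(ta.mu3, tb.mu3)

    def test_single_option_config_is_trivial(self):
        cfg = TaskConfig(
            n_trials=10, n_options=1, probs_pre=(0.7,), probs_post=(0.7,),
            shift_trial=6, scheduled_period=40,
        )
        session, _ = simulate_agent(HGFParams(), cfg, 0)
        assert all(r.choice == 1 for r in session.records)

    def test_higher_volatility_prior_means_more_win_switching(self, config):
        """The direction the mapping experiment relies on: raising mu3_0
        alone raises the expected win-switch rate."""
        def mean_wsr(mu3, seeds):
            p = HGFParams(mu3_0=mu3, m3=mu3)
            vals = []
            for s in seeds:
                session, _ = simulate_agent(p, config, s, record=False)
                w = win_switch_rate(session).wsr
                if w is not None:
                    vals.append(w)
            return np.mean(vals)

        low = mean_wsr(-3.4, range(100))
        high = mean_wsr(-1.6, range(100, 200))
        assert high > low


class TestFitting:
    def test_all_fixed_returns_prior_means(self, config):
        priors = default_priors()
        fixed = ParamPrior(
            means=dict(priors.means),
            variances={k: 0.0 for k in priors.variances},
            tie_m3=True,
        )
        session, _ = simulate_agent(HGFParams(), config, 1)
        fit = fit_map(session, fixed)
        assert fit.params == fixed.mean_params()
        assert math.isfinite(fit.neg_log_joint)
        assert fit.n_restarts_used == 0

    def test_map_log_joint_beats_prior_mean(self, config, priors):
        from metaprl.hgf import _neg_log_joint

        session, _ = simulate_agent(HGFParams(mu3_0=-1.6, m3=-1.6), config, 3)
        fit = fit_map(session, priors, n_restarts=3, seed=0)
        choices = [int(c) for c in session.choices]
        outcomes = [int(y) for y in session.outcomes]
        at_mean = _neg_log_joint(
            np.array([priors.means[n] for n in priors.free_names]),
            choices, outcomes, priors, 3,
        )
        assert fit.neg_log_joint <= at_mean + 1e-9

    def test_long_session_pulls_estimate_toward_truth(self, config, priors):
        """Simulate 3 concatenated runs (480 trials) from a known mu3_0 well
        away from the prior mean; the MAP estimate should land closer to the
        truth than the prior mean does in most replicates."""
        truth = -4.1  # 1.5 prior SDs below the prior mean
        prior_mean = priors.means["mu3_0"]
        p = HGFParams(mu3_0=truth, m3=truth)
        wins = 0
        n_seeds = 20
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            records = []
            for run in range(3):
                s, _ = simulate_agent(p, config, rng, record=False)
                records.extend(s.records)
            long_session = SessionData(
                "cat",
                [replace(r, t=i + 1) for i, r in enumerate(records)],
            )
            fit = fit_map(long_session, priors, n_restarts=2, seed=seed)
            if abs(fit.params.mu3_0 - truth) < abs(prior_mean - truth):
                wins += 1
        assert wins >= 0.8 * n_seeds

    def test_too_short_session_rejected(self, priors):
        session = SessionData("x", [TrialRecord(1, 1, 1, (0.9, 0.5, 0.1))])
        with pytest.raises(ValueError):
            fit_map(session, priors)
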