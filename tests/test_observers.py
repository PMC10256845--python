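"""Learner models: update algebra, reductions, and response mapping."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st_hyp

from hexlearn import observers as obs
from hexlearn import schedule as sched
from hexlearn.errors import ConfigurationError
from hexlearn.observers import (Hgf2Params, Hgf3Params, K1Params, KalmanParams,
                                RwParams, hgf2_filter, hgf2_step, hgf3_filter,
                                k1_filter, kalman_filter, response_prob,
                                rw_filter, sigmoid, simulate_agent)

# hand-computed two-step unroll: start (mu2, sigma2) = (0, 1), omega = 0, u = (1, 1)
STEP1 = dict(mu1_hat=0.5, delta=0.5, pi2_hat=0.5, pi2=0.75,
             epsilon=2 / 3, mu2=2 / 3, sigma2=4 / 3)
STEP2 = dict(mu1_hat=0.660756368766, delta=0.339243631234, pi2_hat=3 / 7,
             pi2=0.652728818473, epsilon=0.519731351877,
             mu2=1.186398018544, sigma2=1.532029798133)


class TestSigmoid:
    def test_symmetry_point(self):
        assert sigmoid(0.0) == 0.5

    def test_monotone_to_limits(self):
        xs = np.linspace(-30, 30, 101)
        ys = sigmoid(xs)
        assert (np.diff(ys) >= 0).all()
        assert ys[-1] > 1 - 1e-9 and ys[0] < 1e-9

    @given(st_hyp.floats(-50, 50))
    @settings(deadline=None)
    def test_complement_identity(self, x):
        assert sigmoid(x) + sigmoid(-x) == pytest.approx(1.0, abs=1e-12)


class TestHgf2Step:
    @pytest.mark.parametrize("u,sign", [(1, 1.0), (0, -1.0)])
    def test_hand_computed_first_step(self, u, sign):
        rec = hgf2_step(0.0, 1.0, u, 0.0)
        assert rec["mu1_hat"] == pytest.approx(0.5)
        assert rec["delta"] == pytest.approx(sign * 0.5)
        assert rec["pi2_hat"] == pytest.approx(0.5)
        assert rec["pi2"] == pytest.approx(0.75)
        assert rec["epsilon"] == pytest.approx(sign * 2 / 3)
        assert rec["mu2"] == pytest.approx(sign * 2 / 3)
        assert rec["sigma2"] == pytest.approx(4 / 3)

    def test_two_step_unroll(self):
        traj = hgf2_filter([1, 1], Hgf2Params(omega=0.0, zeta=1.0))
        for key, expect in STEP1.items():
            assert getattr(traj, key)[0] == pytest.approx(expect, abs=1e-9)
        for key, expect in STEP2.items():
            assert getattr(traj, key)[1] == pytest.approx(expect, abs=1e-9)

    def test_repeated_hostile_outcomes_drive_belief_up(self):
        traj = hgf2_filter(np.ones(500, dtype=int), Hgf2Params(omega=-1.0, zeta=1.0))
        assert (np.diff(traj.mu2) > 0).all()
        assert traj.mu1_hat[-1] > 0.99

    def test_frozen_environment_limit(self):
        # omega -> -inf: step variance vanishes, uncertainty shrinks monotonically
        traj = hgf2_filter(np.ones(50, dtype=int), Hgf2Params(omega=-40.0, zeta=1.0))
        assert (np.diff(traj.sigma2) < 0).all()
        assert abs(traj.mu2[-1]) < np.log(50)  # updates stay bounded


class TestTrajectoryIdentities:
    @pytest.mark.parametrize("seed", range(5))
    def test_update_algebra_conserved(self, seed):
        rng = np.random.default_rng(seed)
        u = (rng.random(400) < rng.uniform(0.2, 0.8)).astype(int)
        params = Hgf2Params(omega=rng.uniform(-6, 0), zeta=1.0,
                            mu2_0=rng.normal(), sigma2_0=rng.uniform(0.5, 2))
        traj = hgf2_filter(u, params)
        mu2_prev = np.r_[params.mu2_0, traj.mu2[:-1]]
        assert np.allclose(traj.mu2 - mu2_prev, traj.epsilon, atol=1e-10)
        w = traj.mu1_hat * (1 - traj.mu1_hat)
        assert np.allclose(traj.pi2, traj.pi2_hat + w, atol=1e-10)
        assert np.allclose(traj.pi2, traj.pi2_hat + 1 / traj.pi1_hat, atol=1e-10)
        assert ((traj.delta > -1) & (traj.delta < 1)).all()
        assert np.array_equal(np.sign(traj.delta), np.where(u == 1, 1, -1))
        assert (traj.sigma2 > 0).all()
        assert ((traj.mu1_hat > 0) & (traj.mu1_hat < 1)).all()

    def test_empty_sequence(self):
        traj = hgf2_filter([], Hgf2Params())
        assert len(traj) == 0


class TestHgf3:
    def test_decoupled_limit_reproduces_two_level(self):
        u = (np.random.default_rng(0).random(200) < 0.7).astype(int)
        t3 = hgf3_filter(u, Hgf3Params(omega2=-2.5, kappa=1e-10, theta=-4.0, zeta=1.0))
        t2 = hgf2_filter(u, Hgf2Params(omega=-2.5, zeta=1.0))
        assert np.allclose(t3.mu2, t2.mu2, atol=1e-8)
        assert np.allclose(t3.sigma2, t2.sigma2, atol=1e-8)

    def test_frozen_level3_shifts_omega(self):
        u = (np.random.default_rng(1).random(200) < 0.6).astype(int)
        kappa, mu3_0, omega2 = 0.8, 1.5, -4.0
        t3 = hgf3_filter(u, Hgf3Params(omega2=omega2, kappa=kappa, theta=-60.0,
                                       zeta=1.0, mu3_0=mu3_0, sigma3_0=1e-12))
        t2 = hgf2_filter(u, Hgf2Params(omega=kappa * mu3_0 + omega2, zeta=1.0))
        assert np.allclose(t3.mu2, t2.mu2, atol=1e-6)

    def test_volatility_belief_tracks_regime(self):
        rng = np.random.default_rng(2)
        params = Hgf3Params(omega2=-4.0, kappa=1.0, theta=-2.0, zeta=1.0)
        m_stable, m_volatile = [], []
        for _ in range(20):
            stable = (rng.random(400) < 0.85).astype(int)
            p = np.where((np.arange(400) // 20) % 2 == 0, 0.85, 0.15)
            volatile = (rng.random(400) < p).astype(int)
            m_stable.append(hgf3_filter(stable, params).mu3.mean())
            m_volatile.append(hgf3_filter(volatile, params).mu3.mean())
        assert np.mean(m_volatile) > np.mean(m_stable)


class TestValueModels:
    def test_rw_full_updating(self):
        u = np.array([1, 0, 1, 1, 0])
        traj = rw_filter(u, RwParams(alpha=1.0, zeta=1.0))
        assert np.array_equal(traj.v, u)

    def test_rw_single_step(self):
        traj = rw_filter([1], RwParams(alpha=0.1, zeta=1.0, v0=0.5))
        assert traj.v[0] == pytest.approx(0.55)

    def test_rw_closed_form_constant_input(self):
        alpha, v0, n = 0.23, 0.4, 60
        traj = rw_filter(np.ones(n, dtype=int), RwParams(alpha=alpha, zeta=1.0, v0=v0))
        t = np.arange(1, n + 1)
        closed = 1 - (1 - alpha) ** t * (1 - v0)
        assert np.allclose(traj.v, closed, atol=1e-12)

    def test_k1_reduces_to_rw_without_meta_learning(self):
        u = (np.random.default_rng(3).random(100) < 0.7).astype(int)
        beta0 = -1.2
        t_k1 = k1_filter(u, K1Params(mu_meta=0.0, beta0=beta0, zeta=1.0))
        t_rw = rw_filter(u, RwParams(alpha=math.exp(beta0), zeta=1.0))
        assert np.allclose(t_k1.v, t_rw.v, atol=1e-12)

    def test_k1_first_step_trace(self):
        traj = k1_filter([1], K1Params(mu_meta=0.05, beta0=-1.0, zeta=1.0, v0=0.5))
        a1 = traj.alpha[0]
        # h0 = 0 so beta is unchanged on trial 1 and h1 = alpha1 * delta1
        assert a1 == pytest.approx(math.exp(-1.0))
        assert traj.v[0] == pytest.approx(0.5 + a1 * 0.5)

    def test_k1_learning_rate_shrinks_under_alternating_errors(self):
        u = np.tile([1, 0], 100)
        traj = k1_filter(u, K1Params(mu_meta=0.2, beta0=-1.0, zeta=1.0, v0=0.5))
        assert traj.alpha[-1] < traj.alpha[0]

    def test_kalman_noiseless_observation_limit(self):
        u = np.array([1, 0, 0, 1])
        traj = kalman_filter(u, KalmanParams(q=0.1, r_obs=1e-12, zeta=1.0))
        assert np.allclose(traj.v, u, atol=1e-6)

    def test_kalman_static_world_limit(self):
        u = (np.random.default_rng(4).random(50) < 0.5).astype(int)
        traj = kalman_filter(u, KalmanParams(q=0.0, r_obs=0.3, zeta=1.0))
        assert (np.diff(traj.s) < 0).all()
        assert traj.gain[-1] < traj.gain[0]

    def test_kalman_steady_state_fixed_point(self):
        q, r = 0.05, 0.3
        traj = kalman_filter(np.zeros(2000, dtype=int),
                             KalmanParams(q=q, r_obs=r, zeta=1.0))
        s_star = traj.s[-1]
        k_star = (s_star + q) / (s_star + q + r)
        assert s_star == pytest.approx((1 - k_star) * (s_star + q), rel=1e-6)


class TestResponseModel:
    def test_probability_matching_at_unit_zeta(self):
        for m in (0.1, 0.35, 0.8):
            assert response_prob(m, 1.0) == pytest.approx(m, abs=1e-9)

    def test_indifference_point(self):
        for z in (0.5, 1.0, 5.0, 100.0):
            assert response_prob(0.5, z) == pytest.approx(0.5, abs=1e-9)

    def test_hand_computed_value(self):
        assert response_prob(0.8, 2.0) == pytest.approx(0.64 / 0.68, abs=1e-9)

    @given(st_hyp.floats(0.01, 0.99), st_hyp.floats(0.1, 50))
    @settings(deadline=None)
    def test_complement_identity(self, m, z):
        assert response_prob(m, z) + response_prob(1 - m, z) == pytest.approx(1.0, abs=1e-9)

    def test_monotone_in_belief_and_sharpness(self):
        ms = np.linspace(0.05, 0.95, 50)
        p = response_prob(ms, 3.0)
        assert (np.diff(p) > 0).all()
        zs = np.linspace(0.2, 20, 30)
        p2 = np.array([response_prob(0.7, z) for z in zs])
        assert (np.diff(p2) > 0).all()

    def test_rejects_nonpositive_zeta(self):
        with pytest.raises(ConfigurationError):
            response_prob(0.5, 0.0)


class TestSimulateAgent:
    def test_seed_determinism(self, default_schedule, default_outcomes):
        params = Hgf2Params(omega=-3, zeta=2)
        a = simulate_agent(default_schedule, default_outcomes, "hgf2", params, seed=5)
        b = simulate_agent(default_schedule, default_outcomes, "hgf2", params, seed=5)
        assert np.array_equal(a.response, b.response)

    def test_noiseless_decision_limit(self, default_schedule, default_outcomes):
        params = Hgf2Params(omega=-3, zeta=1000.0)
        rs = simulate_agent(default_schedule, default_outcomes, "hgf2", params, seed=0)
        pred, _ = obs.filter_predictions("hgf2", params, default_outcomes,
                                         opponents=default_schedule.opponent)
        decidable = np.abs(pred - 0.5) > 1e-3
        assert np.array_equal(rs.response[decidable], (pred > 0.5).astype(int)[decidable])

    def test_unknown_model_rejected(self, default_schedule, default_outcomes):
        with pytest.raises(ConfigurationError):
            simulate_agent(default_schedule, default_outcomes, "q_learner",
                           Hgf2Params(), seed=0)

    def test_shoot_rate_tracks_gun_probability(self, default_schedule):
        params = Hgf2Params(omega=-3, zeta=2)
        diffs = []
        high = default_schedule.p_gun > 0.5
        for i in range(300):
            u = sched.sample_outcomes(default_schedule, seed=5000 + i).u
            rs = simulate_agent(default_schedule, u, "hgf2", params, seed=6000 + i)
            diffs.append(rs.response[high].mean() - rs.response[~high].mean())
        assert np.mean(diffs) > 0

    def test_missingness_injection(self, default_schedule, default_outcomes):
        rs = simulate_agent(default_schedule, default_outcomes, "hgf2",
                            Hgf2Params(), seed=1, missing_rate=0.3)
        frac = (rs.response == obs.MISSING).mean()
        assert 0.15 < frac < 0.45
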