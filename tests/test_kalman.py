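import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from patchkf.kalman import (
    EnsembleState,
    ObservationModel,
    correct,
    filter_trace,
    init_state,
    innovation,
    loglik_traceset,
    observation_covariance,
    predict,
    process_noise,
)
from patchkf.schemes import build_rate_matrix, ccco, transition_matrix
from patchkf.simulate import (
    NoiseParams,
    TraceSet,
    sample_generalized_multinomial,
)

from ._oracles import multinomial_cov, state_dependent_marginal_moments


def scalar_obs(H=1.0, var=1.0):
    """Single-observable model with constant noise variance."""
    return ObservationModel(
        H=np.array([[H]]),
        base_var=np.array([var]),
        var_slope=np.array([[0.0]]),
        var_floor=np.array([0.0]),
        labels=("current",),
    )


def random_stochastic(rng, M):
    T = rng.uniform(0, 1, size=(M, M))
    return T / T.sum(axis=0)


class TestInitState:
    def test_two_state_symmetric_four_channels(self):
        K = np.array([[-1.0, 1.0], [1.0, -1.0]])
        st_ = init_state(K, 4)
        assert np.allclose(st_.nbar, [2, 2])
        assert np.allclose(st_.P, [[1, -1], [-1, 1]])

    def test_degenerate_equilibrium_has_zero_covariance(self):
        s = ccco()
        K = build_rate_matrix(s, s.default_rates, 0.0)
        st_ = init_state(K, 100)
        assert np.allclose(st_.P, 0.0)
        assert np.allclose(st_.nbar, [100, 0, 0, 0])

    def test_trace_identity(self, rng):
        p = rng.dirichlet(np.ones(5))
        K = None  # bypass: construct the multinomial moments directly
        state = EnsembleState(nbar=200 * p, P=multinomial_cov(200, p))
        assert np.trace(state.P) == pytest.approx(200 * (1 - np.sum(p**2)))


class TestPredict:
    def test_identity_propagator_is_noop(self, rng):
        p = rng.dirichlet(np.ones(3))
        state = EnsembleState(nbar=50 * p, P=multinomial_cov(50, p))
        out = predict(state, np.eye(3))
        assert np.allclose(out.nbar, state.nbar)
        assert np.allclose(out.P, state.P)

    def test_single_certain_channel_gives_multinomial_cov(self, rng):
        T = random_stochastic(rng, 4)
        state = EnsembleState(nbar=np.eye(4)[1], P=np.zeros((4, 4)))
        out = predict(state, T)
        Te = T[:, 1]
        assert np.allclose(out.nbar, Te)
        assert np.allclose(out.P, np.diag(Te) - np.outer(Te, Te))

    def test_mean_channel_count_is_conserved(self, rng):
        T = random_stochastic(rng, 5)
        p = rng.dirichlet(np.ones(5))
        state = EnsembleState(nbar=123 * p, P=multinomial_cov(123, p))
        out = predict(state, T)
        assert out.nbar.sum() == pytest.approx(123.0, abs=1e-9)

    def test_moments_match_monte_carlo(self, rng):
        """predict() vs empirical moments of generalized-multinomial draws."""
        M, Nch, S = 3, 100, 30000
        T = random_stochastic(rng, M)
        p0 = rng.dirichlet(np.ones(M))
        n0 = rng.multinomial(Nch, p0, size=S)
        draws = np.empty((S, M), dtype=np.int64)
        for i in range(S):
            draws[i] = sample_generalized_multinomial(n0[i], T, rng)
        state = EnsembleState(nbar=Nch * p0, P=multinomial_cov(Nch, p0))
        out = predict(state, T)
        se_mean = np.sqrt(np.diag(out.P) / S)
        assert np.all(np.abs(draws.mean(axis=0) - out.nbar) < 4 * se_mean)
        C = np.cov(draws, rowvar=False)
        se_cov = np.sqrt(
            (np.outer(np.diag(out.P), np.diag(out.P)) + out.P**2) / S
        )
        assert np.all(np.abs(C - out.P) < 4 * se_cov)

    @settings(max_examples=50, deadline=None)
    @given(seed=st.integers(0, 10_000), M=st.integers(2, 5))
    def test_process_noise_is_psd(self, seed, M):
        r = np.random.default_rng(seed)
        T = random_stochastic(r, M)
        nbar = r.uniform(0, 100, size=M)
        Q = process_noise(T, nbar)
        assert np.linalg.eigvalsh(0.5 * (Q + Q.T)).min() > -1e-9 * max(
            np.trace(Q), 1.0
        )


class TestObservationCovariance:
    def test_constant_noise_limit(self):
        s = ccco()
        noise = NoiseParams(sigma_m=1.3, sigma_op=0.0, lambda_b=0.0, sigma_back=2.0)
        obs = ObservationModel.from_scheme(s, noise)
        state = EnsembleState(nbar=np.array([10.0, 5, 5, 80]), P=np.zeros((4, 4)))
        sig = observation_covariance(state, obs)
        assert np.allclose(sig, np.diag([2.0**2, 1.3**2]))

    def test_open_channel_term_arithmetic(self):
        s = ccco()
        noise = NoiseParams(sigma_m=1.0, sigma_op=np.sqrt(0.1), lambda_b=0.0,
                            sigma_back=1.0)
        obs = ObservationModel.from_scheme(s, noise)
        state = EnsembleState(nbar=np.array([0.0, 0, 0, 10.0]), P=np.zeros((4, 4)))
        sig = observation_covariance(state, obs)
        assert sig[1, 1] == pytest.approx(1.0 + 0.1 * 10.0)

    def test_ccco_fluorescence_mean_stoichiometry(self):
        s = ccco()
        noise = NoiseParams(lambda_b=0.375)
        obs = ObservationModel.from_scheme(s, noise)
        n = np.array([7.0, 11.0, 13.0, 17.0])
        mean_flu = (obs.H @ n)[0]
        assert mean_flu == pytest.approx(0.375 * (n[1] + 2 * (n[2] + n[3])))

    def test_count_floor_applies_at_zero_occupancy(self):
        s = ccco()
        obs = ObservationModel.from_scheme(s, NoiseParams(lambda_b=0.375, sigma_back=0))
        state = EnsembleState(nbar=np.array([5.0, 0, 0, 0]), P=np.zeros((4, 4)))
        sig = observation_covariance(state, obs)
        assert sig[0, 0] == pytest.approx(1.0 / 12.0)


class TestInnovation:
    def test_zero_residual_normalization_constant(self):
        state = EnsembleState(nbar=np.array([3.0]), P=np.array([[2.0]]))
        obs = scalar_obs(H=1.0, var=1.0)
        inn = innovation(state, obs, np.array([3.0]))
        S = 2.0 + 1.0
        assert inn.residual == pytest.approx(0.0)
        assert inn.loglik == pytest.approx(-0.5 * np.log(2 * np.pi * S))

    def test_zero_prior_covariance_reduces_to_plain_gaussian(self):
        state = EnsembleState(nbar=np.array([3.0]), P=np.array([[0.0]]))
        obs = scalar_obs(H=1.0, var=4.0)
        inn = innovation(state, obs, np.array([5.0]))
        expect = -0.5 * (np.log(2 * np.pi * 4.0) + (5 - 3) ** 2 / 4.0)
        assert inn.loglik == pytest.approx(expect)
        assert inn.S[0, 0] == pytest.approx(4.0)

    def test_rejects_non_finite_observation(self):
        state = EnsembleState(nbar=np.array([3.0]), P=np.array([[1.0]]))
        with pytest.raises(ValueError):
            innovation(state, scalar_obs(), np.array([np.nan]))

    def test_moment_matching_of_state_dependent_marginal(self):
        """Quadrature moments of the exact state-dependent-noise marginal.

        The marginal int N(y|n, sm^2 + n sop^2) N(n|nbar, P) dn has mean
        nbar and variance P + sm^2 + sop^2*E[max(n,0)] ~ P + Sigma(nbar);
        the filter's moment-matched normal must agree.
        """
        nbar, P, sm, sop = 40.0, 9.0, 1.0, 0.5
        m_exact, v_exact = state_dependent_marginal_moments(nbar, P, sm, sop)
        obs = ObservationModel(
            H=np.array([[1.0]]),
            base_var=np.array([sm**2]),
            var_slope=np.array([[sop**2]]),
            var_floor=np.array([0.0]),
            labels=("current",),
        )
        state = EnsembleState(nbar=np.array([nbar]), P=np.array([[P]]))
        inn = innovation(state, obs, np.array([nbar]))
        assert m_exact == pytest.approx(nbar, rel=1e-6)
        assert inn.S[0, 0] == pytest.approx(v_exact, rel=1e-4)


class TestCorrect:
    def test_infinite_noise_keeps_prior(self):
        state = EnsembleState(nbar=np.array([3.0, 7.0]), P=np.eye(2))
        obs = ObservationModel(
            H=np.array([[1.0, 0.0]]),
            base_var=np.array([1e12]),
            var_slope=np.zeros((1, 2)),
            var_floor=np.array([0.0]),
            labels=("current",),
        )
        out = correct(state, obs, np.array([100.0]))
        assert np.allclose(out.nbar, state.nbar, atol=1e-6)
        assert np.allclose(out.P, state.P, atol=1e-6)

    def test_conjugate_normal_closed_form(self):
        state = EnsembleState(nbar=np.array([0.0]), P=np.array([[1.0]]))
        out = correct(state, scalar_obs(H=1.0, var=1.0), np.array([1.0]))
        assert out.nbar[0] == pytest.approx(0.5)
        assert out.P[0, 0] == pytest.approx(0.5)

    def test_zero_observation_row_changes_nothing(self):
        state = EnsembleState(
            nbar=np.array([3.0, 7.0]), P=np.array([[2.0, 0.3], [0.3, 1.0]])
        )
        obs1 = ObservationModel(
            H=np.array([[1.0, 0.5]]),
            base_var=np.array([1.0]),
            var_slope=np.zeros((1, 2)),
            var_floor=np.array([0.0]),
            labels=("current",),
        )
        obs2 = ObservationModel(
            H=np.array([[1.0, 0.5], [0.0, 0.0]]),
            base_var=np.array([1.0, 1.0]),
            var_slope=np.zeros((2, 2)),
            var_floor=np.array([0.0, 0.0]),
            labels=("current", "aux"),
        )
        a = correct(state, obs1, np.array([5.0]))
        b = correct(state, obs2, np.array([5.0, 0.123]))
        assert np.allclose(a.nbar, b.nbar)
        assert np.allclose(a.P, b.P)


class TestLoglikTraceset:
    def test_sum_over_independent_traces(self, toy2, toy2_traces):
        full = loglik_traceset(
            toy2, toy2.default_rates, toy2_traces.noise, 1000, toy2_traces
        )
        total = 0.0
        for c in range(toy2_traces.n_traces):
            single = TraceSet(
                times=toy2_traces.times,
                concentrations=[toy2_traces.concentrations[c]],
                current=toy2_traces.current[:, c : c + 1],
                fluorescence=toy2_traces.fluorescence[:, c : c + 1],
                f_ana=toy2_traces.f_ana,
                noise=toy2_traces.noise,
                t_on=toy2_traces.t_on,
            )
            total += loglik_traceset(
                toy2, toy2.default_rates, toy2_traces.noise, 1000, single
            ).loglik
        assert total == pytest.approx(full.loglik, rel=1e-12)

    def test_fast_core_matches_stepwise_filter(self, toy2, toy2_traces):
        """The jitted whole-trace core equals the documented step functions."""
        from patchkf.kalman import ObservationModel, _trace_inputs

        y = toy2_traces.y(1)[:40]
        times = toy2_traces.times[:40]
        obs = ObservationModel.from_scheme(toy2, toy2_traces.noise)
        T_stack, seg_idx, K0 = _trace_inputs(
            toy2, toy2.default_rates, 4.0, 250.0, times, 0.6
        )
        state = init_state(K0, 1000)
        ll = 0.0
        for t in range(len(times)):
            if t > 0:
                state = predict(state, T_stack[seg_idx[t]])
            ll += innovation(state, obs, y[t]).loglik
            state = correct(state, obs, y[t])
        ll_fast, _ = filter_trace(
            toy2, toy2.default_rates, toy2_traces.noise, 1000, y, times, 4.0,
            0.6, 250.0,
        )
        assert ll_fast == pytest.approx(ll, rel=1e-8)

    def test_observable_ordering_invariance(self, toy2, toy2_traces):
        y = toy2_traces.y(0)
        args = (toy2, toy2.default_rates, toy2_traces.noise, 1000)
        ll_a, _ = filter_trace(
            *args, y, toy2_traces.times, 0.0625 * 16, 0.6, 250.0,
            observables=("fluorescence", "current"),
        )
        ll_b, _ = filter_trace(
            *args, y[:, ::-1], toy2_traces.times, 0.0625 * 16, 0.6, 250.0,
            observables=("current", "fluorescence"),
        )
        assert ll_a == pytest.approx(ll_b, rel=1e-10)

    def test_deterministic_for_fixed_inputs(self, toy2, toy2_traces):
        a = loglik_traceset(toy2, toy2.default_rates, toy2_traces.noise, 1000, toy2_traces)
        b = loglik_traceset(toy2, toy2.default_rates, toy2_traces.noise, 1000, toy2_traces)
        assert a.loglik == b.loglik

    def test_failure_carries_trace_index(self, toy2, toy2_traces):
        bad = {"k12": np.inf, "k21": 50.0}
        with pytest.raises(RuntimeError, match="trace 0"):
            loglik_traceset(toy2, bad, toy2_traces.noise, 1000, toy2_traces)
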