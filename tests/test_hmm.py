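"""The two-state truncated-normal HMM: initialization, EM, decoding."""

import numpy as np
import pytest
from scipy.integrate import quad

from methylstates import (
    HIGH,
    LOW,
    HmmConfig,
    HmmParams,
    InitializationError,
    ValidationError,
    baum_welch,
    estimate_emissions,
    estimate_transitions,
    initial_params,
    initialize_states,
    log_joint,
    posteriors,
    tnorm_pdf,
    viterbi,
)

from conftest import brute_force_paths, random_params


def simulate_chain(rng, n, params: HmmParams):
    """Direct simulation from the generative model (truncated-normal emissions)."""
    from scipy.stats import truncnorm

    states = np.empty(n, dtype=int)
    states[0] = rng.choice(2, p=params.pi)
    for i in range(1, n):
        states[i] = rng.choice(2, p=params.A[states[i - 1]])
    mu, sd = params.means[states], params.sds[states]
    obs = truncnorm.rvs(
        (0.0 - mu) / sd, (1.0 - mu) / sd, loc=mu, scale=sd, random_state=rng
    )
    return obs, states


class TestInitialization:
    def test_threshold_split(self):
        [s] = initialize_states([np.array([0.05, 0.95, 0.50])], cutoff=0.6)
        assert s.tolist() == [LOW, HIGH, LOW]

    def test_boundary_is_low_and_all_high(self):
        [s] = initialize_states([np.array([0.6])], cutoff=0.6)
        assert s.tolist() == [LOW]
        [s] = initialize_states([np.array([0.9, 0.9])], cutoff=0.6)
        assert s.tolist() == [HIGH, HIGH]

    def test_inverted_orientation_flag(self):
        [s] = initialize_states([np.array([0.1, 0.9])], cutoff=0.6, invert=True)
        assert s.tolist() == [HIGH, LOW]

    def test_empty_chain_raises(self):
        with pytest.raises(ValidationError):
            initialize_states([np.array([])])

    def test_transition_hand_count(self):
        # pairs L->L:1, L->H:1, H->H:2
        A, pi = estimate_transitions([np.array([0, 0, 1, 1, 1])], pseudocount=0)
        assert np.allclose(A, [[0.5, 0.5], [0.0, 1.0]])
        assert np.allclose(pi, [1.0, 0.0])

    def test_transition_alternating(self):
        A, _ = estimate_transitions([np.array([0, 1, 0, 1])], pseudocount=0)
        assert np.allclose(A, [[0, 1], [1, 0]])

    def test_unobserved_state_uniform_fallback(self):
        A, _ = estimate_transitions([np.zeros(5, dtype=int)], pseudocount=0.5)
        assert np.allclose(A[HIGH], [0.5, 0.5])

    def test_emission_moments_and_floor(self):
        chains = [np.array([0.1, 0.2, 0.3, 0.8, 0.8])]
        states = [np.array([0, 0, 0, 1, 1])]
        means, sds = estimate_emissions(chains, states, sigma_floor=1e-3)
        assert means[LOW] == pytest.approx(0.2)
        assert sds[LOW] ** 2 == pytest.approx(0.01)  # ddof=1 variance
        assert sds[HIGH] == 1e-3  # identical values -> floor

    def test_single_member_group_uses_floor(self):
        means, sds = estimate_emissions(
            [np.array([0.5, 0.9, 0.8])], [np.array([0, 1, 1])], sigma_floor=0.01
        )
        assert means[LOW] == pytest.approx(0.5)
        assert sds[LOW] == 0.01

    def test_empty_state_raises_initialization_error(self):
        with pytest.raises(InitializationError, match="cutoff"):
            initial_params([np.array([0.1, 0.2, 0.3])], HmmConfig())


class TestTruncatedNormal:
    @pytest.mark.parametrize("mu,sigma", [(0.1, 0.05), (0.5, 0.2), (0.9, 0.01), (0.3, 2.0)])
    def test_integrates_to_one(self, mu, sigma):
        val, _ = quad(tnorm_pdf, 0, 1, args=(mu, sigma), limit=200)
        assert val == pytest.approx(1.0, abs=1e-6)

    def test_symmetry_at_half(self):
        for d in (0.1, 0.3, 0.49):
            assert tnorm_pdf(0.5 - d, 0.5, 0.2) == pytest.approx(
                tnorm_pdf(0.5 + d, 0.5, 0.2)
            )

    def test_flat_limit_is_uniform(self):
        x = np.linspace(0, 1, 11)
        assert np.allclose(tnorm_pdf(x, 0.5, 10.0), 1.0, atol=2e-3)

    def test_zero_outside_support(self):
        assert tnorm_pdf(-0.1, 0.5, 0.1) == 0.0
        assert tnorm_pdf(1.1, 0.5, 0.1) == 0.0

    def test_invalid_sigma(self):
        with pytest.raises(ValidationError):
            tnorm_pdf(0.5, 0.5, 0.0)


@pytest.fixture
def simple_params():
    return HmmParams(
        pi=[0.6, 0.4],
        A=[[0.9, 0.1], [0.2, 0.8]],
        means=[0.1, 0.9],
        sds=[0.08, 0.08],
    )


class TestLogJoint:
    def test_length_one(self, simple_params):
        val = log_joint([0.2], [LOW], simple_params)
        expected = np.log(0.6) + np.log(tnorm_pdf(0.2, 0.1, 0.08))
        assert val == pytest.approx(expected)

    def test_term_by_term_oracle(self, simple_params, rng):
        obs = rng.uniform(size=8)
        states = rng.integers(0, 2, size=8)
        expected = np.log(simple_params.pi[states[0]]) + np.log(
            tnorm_pdf(obs[0], simple_params.means[states[0]], simple_params.sds[states[0]])
        )
        for t in range(1, 8):
            expected += np.log(simple_params.A[states[t - 1], states[t]])
            expected += np.log(
                tnorm_pdf(obs[t], simple_params.means[states[t]], simple_params.sds[states[t]])
            )
        assert log_joint(obs, states, simple_params) == pytest.approx(expected)

    def test_zero_probability_transition(self):
        p = HmmParams(pi=[1.0, 0.0], A=[[1.0, 0.0], [0.5, 0.5]],
                      means=[0.1, 0.9], sds=[0.1, 0.1])
        assert log_joint([0.1, 0.9], [LOW, HIGH], p) == -np.inf

    def test_length_mismatch(self, simple_params):
        with pytest.raises(ValidationError):
            log_joint([0.1, 0.2], [LOW], simple_params)


class TestPosteriors:
    def test_sum_to_one_everywhere(self, simple_params, rng):
        chains = [rng.uniform(size=50), rng.uniform(size=7)]
        gammas, ll = posteriors(chains, simple_params)
        assert np.isfinite(ll)
        for g in gammas:
            assert np.allclose(g.sum(axis=1), 1.0, atol=1e-9)


class TestBaumWelch:
    def test_monotone_loglik_and_stochastic_rows(self, rng):
        true = HmmParams(pi=[0.5, 0.5], A=[[0.9, 0.1], [0.1, 0.9]],
                         means=[0.1, 0.9], sds=[0.05, 0.05])
        obs, _ = simulate_chain(rng, 400, true)
        init = initial_params([obs], HmmConfig())
        fit = baum_welch([obs], init, tol=1e-6, max_iter=40)
        tr = np.array(fit.log_likelihood_trace)
        assert (np.diff(tr) >= -1e-8).all()
        assert np.allclose(fit.params.A.sum(axis=1), 1.0, atol=1e-9)
        assert fit.params.pi.sum() == pytest.approx(1.0, abs=1e-9)

    def test_max_iter_zero_returns_init(self, simple_params):
        fit = baum_welch([np.array([0.1, 0.9])], simple_params, max_iter=0)
        assert fit.log_likelihood_trace == []
        assert np.allclose(fit.params.A, simple_params.A)

    def test_parameter_recovery(self):
        rng = np.random.default_rng(42)
        true = HmmParams(pi=[0.5, 0.5], A=[[0.9, 0.1], [0.1, 0.9]],
                         means=[0.1, 0.9], sds=[0.05, 0.05])
        obs, states = simulate_chain(rng, 5000, true)
        fit = baum_welch([obs], initial_params([obs], HmmConfig()), tol=1e-4, max_iter=100)
        assert np.abs(fit.params.means - true.means).max() < 0.02
        assert abs(fit.params.A[0, 0] - 0.9) < 0.05
        assert abs(fit.params.A[1, 1] - 0.9) < 0.05
        [path] = viterbi([obs], fit.params)
        assert (path == states).mean() >= 0.95

    def test_cross_check_against_hmmlearn(self, rng):
        # far from the [0,1] edges the truncated-normal model coincides
        # with a plain Gaussian HMM to ~1e-7; compare likelihood + path
        hmmlearn = pytest.importorskip("hmmlearn.hmm")
        params = HmmParams(pi=[0.4, 0.6], A=[[0.85, 0.15], [0.1, 0.9]],
                           means=[0.35, 0.65], sds=[0.05, 0.04])
        obs, _ = simulate_chain(rng, 300, params)
        m = hmmlearn.GaussianHMM(n_components=2, covariance_type="diag", init_params="")
        m.startprob_ = np.asarray(params.pi)
        m.transmat_ = np.asarray(params.A)
        m.means_ = params.means.reshape(-1, 1)
        m.covars_ = (params.sds ** 2).reshape(-1, 1)
        X = obs.reshape(-1, 1)
        _, ll = posteriors([obs], params)
        assert ll == pytest.approx(m.score(X), abs=1e-4)
        [mine] = viterbi([obs], params)
        theirs = m.predict(X)
        assert (mine == theirs).mean() == 1.0


class TestViterbi:
    def test_length_one(self, simple_params):
        [p] = viterbi([np.array([0.95])], simple_params)
        assert p.tolist() == [HIGH]

    def test_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(7)
        for _ in range(60):
            k = int(rng.integers(1, 13))
            params = random_params(rng)
            obs = rng.uniform(size=k)
            [path] = viterbi([obs], params)
            paths, scores = brute_force_paths(obs, params)
            assert log_joint(obs, path, params) == pytest.approx(
                float(scores.max()), abs=1e-9
            )

    def test_identical_emissions_follow_pi(self):
        p = HmmParams(pi=[0.3, 0.7], A=np.eye(2), means=[0.5, 0.5], sds=[0.1, 0.1])
        [path] = viterbi([np.full(6, 0.4)], p)
        assert (path == HIGH).all()

    def test_tie_broken_toward_low(self):
        p = HmmParams(pi=[0.5, 0.5], A=[[0.5, 0.5], [0.5, 0.5]],
                      means=[0.5, 0.5], sds=[0.1, 0.1])
        [path] = viterbi([np.array([0.2, 0.8, 0.5])], p)
        assert (path == LOW).all()
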