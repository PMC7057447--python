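"""Two-state hidden Markov model with truncated-normal emissions.

The model behind both layers of the methylation-state caller.  Hidden
states are ``LOW`` (low-methyl) and ``HIGH`` (high-methyl); the observed
sequence is the per-CpG beta-value (or per-region mean beta) along one
chromosome, so one observation chain per chromosome and a single shared
parameter set across chains.

Emissions are normal densities truncated and renormalized to the
beta-value support [0, 1].  Initialization follows the hard-threshold
recipe (sites split at a beta cutoff, transition frequencies and group
moments estimated from that split); training is Baum-Welch (EM) with the
E-step in log space, and decoding is Viterbi.

The joint probability being maximized is

    P(O, H) = P(h_1) P(o_1 | h_1) * prod_i P(h_i | h_{i-1}) P(o_i | h_i)

with truncated-normal P(o | h).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.special import ndtr

from .errors import InitializationError, ValidationError

LOW, HIGH = 0, 1
STATE_NAMES = ("LOW", "HIGH")

_LOG_SQRT_2PI = 0.5 * math.log(2.0 * math.pi)


@dataclass(frozen=True)
class HmmConfig:
    """Settings for initialization and training of one HMM layer.

    Parameters
    ----------
    init_cutoff : float
        Beta threshold splitting sites into the two starting groups
        (default 0.6, the empirical valley between the unmethylated and
        methylated modes of array beta distributions).
    invert_init : bool
        If True, use the inverted orientation (LOW above the cutoff).
        Off by default; exists only for comparing conventions.
    pseudocount : float
        Laplace-style count added when estimating starting transition
        frequencies, guarding against unobserved states on small inputs.
    sigma_floor : float
        Lower bound on emission standard deviations; prevents variance
        collapse during EM.
    tol : float
        Convergence tolerance on the change in total log-likelihood.
    max_iter : int
        Maximum number of Baum-Welch iterations.
    """

    init_cutoff: float = 0.6
    invert_init: bool = False
    pseudocount: float = 0.5
    sigma_floor: float = 1e-3
    tol: float = 1e-4
    max_iter: int = 100

    def __post_init__(self) -> None:
        if not (0.0 < self.init_cutoff < 1.0):
            raise ValidationError("init_cutoff must be in (0, 1)")
        if self.sigma_floor <= 0 or self.tol <= 0 or self.max_iter < 0:
            raise ValidationError("sigma_floor, tol must be > 0 and max_iter >= 0")


@dataclass
class HmmParams:
    """Parameter set of the two-state HMM.

    pi : (2,) initial state distribution.
    A : (2, 2) row-stochastic transition matrix, rows/cols (LOW, HIGH).
    means, sds : (2,) truncated-normal emission mean and sd per state.
    """

    pi: np.ndarray
    A: np.ndarray
    means: np.ndarray
    sds: np.ndarray

    def __post_init__(self) -> None:
        self.pi = np.asarray(self.pi, dtype=float).reshape(2)
        self.A = np.asarray(self.A, dtype=float).reshape(2, 2)
        self.means = np.asarray(self.means, dtype=float).reshape(2)
        self.sds = np.asarray(self.sds, dtype=float).reshape(2)
        self.validate()

    def validate(self, tol: float = 1e-9) -> None:
        if abs(self.pi.sum() - 1.0) > tol or (self.pi < 0).any():
            raise ValidationError("pi must be a probability vector")
        if (np.abs(self.A.sum(axis=1) - 1.0) > tol).any() or (self.A < 0).any():
            raise ValidationError("A must be row-stochastic")
        if (self.sds <= 0).any():
            raise ValidationError("emission sds must be > 0")

    def to_dict(self) -> dict:
        return {
            "pi": self.pi.tolist(),
            "A": self.A.tolist(),
            "means": self.means.tolist(),
            "sds": self.sds.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "HmmParams":
        return cls(pi=d["pi"], A=d["A"], means=d["means"], sds=d["sds"])


@dataclass
class FitResult:
    """Outcome of one Baum-Welch run."""

    params: HmmParams
    log_likelihood_trace: list[float] = field(default_factory=list)
    n_iter: int = 0
    converged: bool = False

    def to_dict(self) -> dict:
        return {
            "params": self.params.to_dict(),
            "log_likelihood_trace": list(self.log_likelihood_trace),
            "n_iter": self.n_iter,
            "converged": self.converged,
        }


# ---------------------------------------------------------------------------
# truncated normal on [0, 1]


def tnorm_logpdf(x, mu: float, sigma: float):
    """Log-density of N(mu, sigma^2) truncated to [0, 1]; -inf outside."""
    if sigma <= 0:
        raise ValidationError("sigma must be > 0")
    x = np.asarray(x, dtype=float)
    z = (x - mu) / sigma
    log_mass = math.log(ndtr((1.0 - mu) / sigma) - ndtr((0.0 - mu) / sigma))
    out = -0.5 * z * z - _LOG_SQRT_2PI - math.log(sigma) - log_mass
    out = np.where((x < 0.0) | (x > 1.0), -np.inf, out)
    return out if out.ndim else float(out)


def tnorm_pdf(x, mu: float, sigma: float):
    """Density of N(mu, sigma^2) truncated and renormalized to [0, 1]."""
    return np.exp(tnorm_logpdf(x, mu, sigma))


# ---------------------------------------------------------------------------
# initialization


def _check_chains(chains: Sequence[np.ndarray]) -> list[np.ndarray]:
    if not chains:
        raise ValidationError("no observation chains given")
    out = []
    for c in chains:
        arr = np.asarray(c, dtype=float).ravel()
        if arr.size == 0:
            raise ValidationError("empty observation chain")
        if (arr < 0).any() or (arr > 1).any() or not np.isfinite(arr).all():
            raise ValidationError("observations must be finite and within [0, 1]")
        out.append(arr)
    return out


def initialize_states(
    chains: Sequence[np.ndarray], cutoff: float = 0.6, invert: bool = False
) -> list[np.ndarray]:
    """Hard-threshold starting split: LOW iff o <= cutoff, HIGH otherwise.

    ``invert`` flips the orientation (provided for convention comparisons
    only; the default matches the semantics of the emission model, where
    the LOW state carries the smaller mean).
    """
    chains = _check_chains(chains)
    if not (0.0 < cutoff < 1.0):
        raise ValidationError("cutoff must be in (0, 1)")
    out = []
    for arr in chains:
        low = arr <= cutoff
        if invert:
            low = ~low
        out.append(np.where(low, LOW, HIGH).astype(np.int8))
    return out


def estimate_transitions(
    state_chains: Sequence[np.ndarray], pseudocount: float = 0.5
) -> tuple[np.ndarray, np.ndarray]:
    """Frequency estimates of (A, pi) from hard state assignments.

    A[s, t] = (#(s -> t adjacent pairs, pooled over chains) + pc)
              / (#pairs leaving s + 2 pc);
    pi is the pseudocounted frequency of states at chain starts.
    """
    counts = np.zeros((2, 2))
    starts = np.zeros(2)
    for sc in state_chains:
        sc = np.asarray(sc)
        if sc.size == 0:
            raise ValidationError("empty state chain")
        starts[sc[0]] += 1
        if sc.size >= 2:
            np.add.at(counts, (sc[:-1], sc[1:]), 1)
    A = (counts + pseudocount) / (counts.sum(axis=1, keepdims=True) + 2 * pseudocount)
    pi = (starts + pseudocount) / (starts.sum() + 2 * pseudocount)
    return A, pi


def estimate_emissions(
    chains: Sequence[np.ndarray],
    state_chains: Sequence[np.ndarray],
    sigma_floor: float = 1e-3,
) -> tuple[np.ndarray, np.ndarray]:
    """Group mean and sample sd (ddof=1) per hard-assigned state.

    A state with fewer than two members gets sd = sigma_floor; a state
    with no members at all raises :class:`InitializationError`, since no
    moment can be formed — move the initialization cutoff instead.
    """
    obs = np.concatenate([np.asarray(c, float).ravel() for c in chains])
    states = np.concatenate([np.asarray(s).ravel() for s in state_chains])
    if obs.shape != states.shape:
        raise ValidationError("observation/state chain lengths differ")
    means = np.empty(2)
    sds = np.empty(2)
    for s in (LOW, HIGH):
        grp = obs[states == s]
        if grp.size == 0:
            raise InitializationError(
                f"state {STATE_NAMES[s]} received no observations at the "
                "initialization cutoff; choose a different cutoff"
            )
        means[s] = grp.mean()
        sds[s] = max(grp.std(ddof=1), sigma_floor) if grp.size >= 2 else sigma_floor
    return means, sds


def initial_params(chains: Sequence[np.ndarray], config: HmmConfig = HmmConfig()) -> HmmParams:
    """Full initialization: threshold split -> transition + emission moments."""
    chains = _check_chains(chains)
    states = initialize_states(chains, config.init_cutoff, config.invert_init)
    A, pi = estimate_transitions(states, config.pseudocount)
    means, sds = estimate_emissions(chains, states, config.sigma_floor)
    return HmmParams(pi=pi, A=A, means=means, sds=sds)


# ---------------------------------------------------------------------------
# likelihood, forward-backward, EM, Viterbi


def _emission_logs(obs: np.ndarray, params: HmmParams) -> np.ndarray:
    """(T, 2) matrix of per-state emission log-densities."""
    return np.column_stack(
        [tnorm_logpdf(obs, params.means[s], params.sds[s]) for s in (LOW, HIGH)]
    )


def log_joint(obs: np.ndarray, states: np.ndarray, params: HmmParams) -> float:
    """Log of the joint path probability P(O, H) under ``params``."""
    obs = np.asarray(obs, dtype=float).ravel()
    states = np.asarray(states).ravel()
    if obs.size != states.size:
        raise ValidationError("observation/state length mismatch")
    if obs.size == 0:
        raise ValidationError("empty chain")
    logB = _emission_logs(obs, params)
    with np.errstate(divide="ignore"):
        lpi = np.log(params.pi)
        lA = np.log(params.A)
    total = lpi[states[0]] + logB[0, states[0]]
    total += lA[states[:-1], states[1:]].sum() + logB[np.arange(1, obs.size), states[1:]].sum()
    return float(total)


def _forward_backward_chain(
    logB: np.ndarray, lpi: np.ndarray, lA: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Log-space forward-backward for one chain.

    Returns (log_alpha, log_beta, log_likelihood); 2-state log-sum-exp is
    spelled out with np.logaddexp.
    """
    T = logB.shape[0]
    la = np.empty((T, 2))
    lb = np.empty((T, 2))
    la[0] = lpi + logB[0]
    for t in range(1, T):
        la[t, 0] = np.logaddexp(la[t - 1, 0] + lA[0, 0], la[t - 1, 1] + lA[1, 0]) + logB[t, 0]
        la[t, 1] = np.logaddexp(la[t - 1, 0] + lA[0, 1], la[t - 1, 1] + lA[1, 1]) + logB[t, 1]
    lb[T - 1] = 0.0
    for t in range(T - 2, -1, -1):
        b0 = lb[t + 1, 0] + logB[t + 1, 0]
        b1 = lb[t + 1, 1] + logB[t + 1, 1]
        lb[t, 0] = np.logaddexp(lA[0, 0] + b0, lA[0, 1] + b1)
        lb[t, 1] = np.logaddexp(lA[1, 0] + b0, lA[1, 1] + b1)
    ll = float(np.logaddexp(la[T - 1, 0], la[T - 1, 1]))
    return la, lb, ll


def posteriors(
    chains: Sequence[np.ndarray], params: HmmParams
) -> tuple[list[np.ndarray], float]:
    """Per-chain (T, 2) state posteriors and the total log-likelihood."""
    chains = _check_chains(chains)
    with np.errstate(divide="ignore"):
        lpi = np.log(params.pi)
        lA = np.log(params.A)
    gammas = []
    total = 0.0
    for obs in chains:
        logB = _emission_logs(obs, params)
        la, lb, ll = _forward_backward_chain(logB, lpi, lA)
        lg = la + lb - ll
        gammas.append(np.exp(lg))
        total += ll
    return gammas, total


def baum_welch(
    chains: Sequence[np.ndarray],
    init: HmmParams,
    tol: float = 1e-4,
    max_iter: int = 100,
    sigma_floor: float = 1e-3,
) -> FitResult:
    """Baum-Welch EM over multiple chains sharing one parameter set.

    E-step is the log-space forward-backward above.  M-step: pi from the
    chain-start posteriors, A from expected transition counts, and the
    emission (mean, sd) by maximizing the responsibility-weighted
    truncated-normal log-likelihood (a 2-parameter problem with
    closed-form sufficient statistics, solved numerically and
    warm-started at the weighted moments; the incumbent parameters are
    kept whenever they score better, so the EM ascent property holds
    exactly).  sd is floored at ``sigma_floor``.

    Stops when the total log-likelihood improves by less than ``tol``,
    or after ``max_iter`` iterations.  The trace records the E-step
    likelihood of each visited parameter set and is non-decreasing by EM
    theory (asserted to 1e-8 slack in the tests, not here).
    """
    chains = _check_chains(chains)
    params = HmmParams(init.pi.copy(), init.A.copy(), init.means.copy(), init.sds.copy())
    trace: list[float] = []
    if max_iter == 0:
        return FitResult(params=params, log_likelihood_trace=[], n_iter=0, converged=False)

    prev_ll = -np.inf
    converged = False
    n_iter = 0
    obs_all = np.concatenate(chains)
    for n_iter in range(1, max_iter + 1):
        with np.errstate(divide="ignore"):
            lpi = np.log(params.pi)
            lA = np.log(params.A)
        xi_sum = np.zeros((2, 2))
        start_post = np.zeros(2)
        gamma_all = np.empty((obs_all.size, 2))
        ll = 0.0
        off = 0
        for obs in chains:
            logB = _emission_logs(obs, params)
            la, lb, ll_c = _forward_backward_chain(logB, lpi, lA)
            ll += ll_c
            lg = la + lb - ll_c
            g = np.exp(lg)
            gamma_all[off : off + obs.size] = g
            off += obs.size
            start_post += g[0]
            if obs.size >= 2:
                # xi[t, i, j] = alpha_t(i) A_ij B_{t+1}(j) beta_{t+1}(j) / L
                lxi = (
                    la[:-1, :, None]
                    + lA[None, :, :]
                    + (logB[1:] + lb[1:])[:, None, :]
                    - ll_c
                )
                xi_sum += np.exp(lxi).sum(axis=0)
        if not np.isfinite(ll):
            raise ValidationError("non-finite log-likelihood during Baum-Welch")
        trace.append(ll)
        if abs(ll - prev_ll) < tol:
            converged = True
            break
        prev_ll = ll

        # M-step
        pi = start_post / start_post.sum()
        denom = xi_sum.sum(axis=1, keepdims=True)
        A = params.A.copy()
        rows = denom[:, 0] > 0
        A[rows] = xi_sum[rows] / denom[rows]
        w = gamma_all.sum(axis=0)
        means = params.means.copy()
        sds = params.sds.copy()
        for s in (LOW, HIGH):
            if w[s] > 0:
                means[s], sds[s] = _emission_mstep(
                    gamma_all[:, s], obs_all, means[s], sds[s], sigma_floor
                )
        params = HmmParams(pi=pi, A=A, means=means, sds=sds)
    return FitResult(params=params, log_likelihood_trace=trace, n_iter=n_iter, converged=converged)


def _tnorm_weighted_nll(mu: float, sigma: float, W: float, S1: float, S2: float) -> float:
    """Negative weighted truncated-normal log-likelihood from sufficient
    statistics W = sum w, S1 = sum w*o, S2 = sum w*o^2."""
    mass = ndtr((1.0 - mu) / sigma) - ndtr((0.0 - mu) / sigma)
    if mass <= 0.0:
        return math.inf
    return (
        0.5 * (S2 - 2.0 * mu * S1 + mu * mu * W) / (sigma * sigma)
        + W * (math.log(sigma) + math.log(mass) + _LOG_SQRT_2PI)
    )


def _emission_mstep(
    w: np.ndarray, obs: np.ndarray, mu0: float, sigma0: float, sigma_floor: float
) -> tuple[float, float]:
    """Exact M-step for one state's truncated-normal emission.

    Maximizes the responsibility-weighted log-likelihood over (mu, sd)
    numerically (Nelder-Mead on (mu, log sd), warm-started at the
    weighted moments).  The incumbent and the moment-matched candidates
    are retained, so the returned pair never scores worse than the
    current parameters — preserving the EM ascent guarantee even if the
    optimizer stalls.
    """
    W = float(w.sum())
    S1 = float(w @ obs)
    S2 = float(w @ (obs * obs))
    m_mm = S1 / W
    v_mm = max(S2 / W - m_mm * m_mm, 0.0)
    sd_mm = max(math.sqrt(v_mm), sigma_floor)

    def score(mu: float, sd: float) -> float:
        if not (0.0 <= mu <= 1.0) or sd < sigma_floor:
            return math.inf
        return _tnorm_weighted_nll(mu, sd, W, S1, S2)

    candidates = [(mu0, sigma0), (float(np.clip(m_mm, 0.0, 1.0)), sd_mm)]
    res = minimize(
        lambda t: score(float(np.clip(t[0], 0.0, 1.0)), max(math.exp(t[1]), sigma_floor)),
        x0=[float(np.clip(m_mm, 0.0, 1.0)), math.log(sd_mm)],
        method="Nelder-Mead",
        options={"xatol": 1e-7, "fatol": 1e-10, "maxiter": 200},
    )
    candidates.append(
        (float(np.clip(res.x[0], 0.0, 1.0)), max(math.exp(res.x[1]), sigma_floor))
    )
    return min(candidates, key=lambda c: score(*c))


def viterbi(chains: Sequence[np.ndarray], params: HmmParams) -> list[np.ndarray]:
    """Most probable state path per chain (log-space dynamic program).

    Ties are broken toward LOW (and toward the LOW predecessor), making
    the decoder deterministic on degenerate inputs.
    """
    chains = _check_chains(chains)
    with np.errstate(divide="ignore"):
        lpi = np.log(params.pi)
        lA = np.log(params.A)
    paths = []
    for obs in chains:
        logB = _emission_logs(obs, params)
        T = obs.size
        delta = np.empty((T, 2))
        back = np.zeros((T, 2), dtype=np.int8)
        delta[0] = lpi + logB[0]
        for t in range(1, T):
            for s in (LOW, HIGH):
                cand = delta[t - 1] + lA[:, s]
                b = int(np.argmax(cand))  # argmax prefers LOW on ties
                back[t, s] = b
                delta[t, s] = cand[b] + logB[t, s]
        path = np.empty(T, dtype=np.int8)
        path[T - 1] = int(np.argmax(delta[T - 1]))
        for t in range(T - 2, -1, -1):
            path[t] = back[t + 1, path[t + 1]]
        paths.append(path)
    return paths


def fit_and_decode(
    chains: Sequence[np.ndarray], config: HmmConfig = HmmConfig()
) -> tuple[FitResult, list[np.ndarray]]:
    """Initialize -> Baum-Welch -> Viterbi, the standard one-layer run."""
    init = initial_params(chains, config)
    fit = baum_welch(
        chains, init, tol=config.tol, max_iter=config.max_iter, sigma_floor=config.sigma_floor
    )
    return fit, viterbi(chains, fit.params)
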