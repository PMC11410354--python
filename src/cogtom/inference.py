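"""Posterior inference of internal models from response times.

The subjective internal model is an infinite HMM (HDP-HMM) whose
parameters must explain both the stimulus sequence it filters and, through
the LATER response model, the observed RTs.  Inference mixes two kinds of
MCMC moves per sweep:

* a *beam* (slice) move — auxiliary slice variables truncate the infinite
  state set so an exact forward-filter/backward-sample step on the latent
  path applies; transition rows, the shared stick-breaking weights and the
  two DP concentrations are then resampled from their (path-conditional)
  conjugate forms;
* a block of Hamiltonian Monte Carlo updates on the continuous parameters
  (transition and emission rows, softmax-reparameterised; LATER ``mu``,
  ``sigma``, ``theta0`` in log space) targeting
  ``log p(model) + stim_weight * log p(stimuli, states | model)
  + rt_weight * sum_n log p(RT_n | p_n)``
  where ``p_n`` is the forward-filtered predictive probability of the
  realised stimulus.  Gradients flow through the filtering recursion by
  reverse-mode accumulation (see :mod:`cogtom._kernels`).

``stim_weight`` defaults to zero: the internal model is inferred from the
response times alone, with the stimulus sequence acting only as the
filtering input — a subjective model may deviate arbitrarily from the true
task statistics, which is the point of the method.  The beam move still
conditions on the stimuli; it provides the state-count adaptivity and the
HDP bookkeeping, and is an approximation once the HMC block has moved the
transition rows (documented in the methods note).

The Markov baseline reuses the same HMC machinery with the latent
structure fixed to the observed stimulus chain.
"""

from __future__ import annotations

import hashlib
import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .models import (DEFAULT_EPS_FLOOR, HMMInternalModel, MarkovInternalModel,
                     PredictiveTrace, forward_filter, markov_predict)
from .response import LATERParams
from .task import N_STIMULI


class InferenceError(RuntimeError):
    pass


@dataclass(frozen=True)
class SamplerConfig:
    """Sampler bookkeeping; ``paper`` scale is the full production
    configuration (1600 sweeps, 30 HMC per sweep, 4 chains, last 30
    samples retained), ``desk`` a scaled-down setting for interactive use
    and testing."""

    n_chains: int = 4
    n_sweeps: int = 1600
    hmc_updates_per_sweep: int = 30
    retained_tail: int = 30
    n_leapfrog: int = 10
    step_size: float = 0.02
    adapt_fraction: float = 0.5
    target_accept: float = 0.65
    alpha0_a: float = 1.0       # Gamma hyperprior on the DP concentration
    alpha0_b: float = 1.0
    gamma_a: float = 1.0        # Gamma hyperprior on the top-level DP
    gamma_b: float = 1.0
    emission_alpha: float = 1.0  # symmetric Dirichlet base measure over stimuli
    later_prior: tuple = ((math.log(8.0), 1.0), (0.0, 1.0), (0.0, 1.0))
    rt_weight: float = 1.0
    stim_weight: float = 0.0     # weight of the stimulus/path likelihood
    eps_floor: float = DEFAULT_EPS_FLOOR
    init_states: int = 8
    max_states: int = 12
    warm_start_rounds: int = 3   # beam + gradient-ascent rounds before MCMC
    warm_start_iters: int = 150
    gauge: float = 0.01          # Gaussian gauge fixing for softmax logits

    def __post_init__(self) -> None:
        if min(self.n_chains, self.n_sweeps, self.hmc_updates_per_sweep,
               self.retained_tail, self.n_leapfrog) < 1:
            raise InferenceError("all sampler counts must be >= 1")
        if self.retained_tail > self.n_sweeps:
            raise InferenceError("retained_tail cannot exceed n_sweeps")

    @classmethod
    def paper(cls, **kw) -> "SamplerConfig":
        return cls(**kw)

    @classmethod
    def desk(cls, **kw) -> "SamplerConfig":
        defaults = dict(n_chains=2, n_sweeps=200, hmc_updates_per_sweep=10,
                        retained_tail=20)
        defaults.update(kw)
        return cls(**defaults)


@dataclass
class PosteriorSample:
    model: HMMInternalModel | MarkovInternalModel
    later: LATERParams
    alpha0: float = np.nan
    gamma: float = np.nan


@dataclass
class CTPosterior:
    """Retained posterior samples from all chains, with provenance."""

    samples: list            # flat list of PosteriorSample
    config: SamplerConfig
    seed: int
    data_hash: str
    kind: str = "ct"         # "ct" or "markov"
    diagnostics: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.samples)


def data_fingerprint(stimuli, rt_s, rt_mask) -> str:
    h = hashlib.sha256()
    for arr in (np.asarray(stimuli, dtype=np.int64),
                np.asarray(rt_s, dtype=float),
                np.asarray(rt_mask, dtype=bool)):
        h.update(np.ascontiguousarray(arr).tobytes())
    return h.hexdigest()[:16]


# ---------------------------------------------------------------------------
# generic HMC

def hmc_update(theta, logp_and_grad, rng, step_size, n_leapfrog,
               inv_mass=None):
    """One Hamiltonian Monte Carlo update with leapfrog integration.

    ``inv_mass`` is an optional diagonal inverse mass (per-coordinate
    step preconditioner); identity when omitted.  Returns
    ``(theta, accepted, accept_prob, logp)``.  Divergent (non-finite)
    trajectories are rejected with accept probability 0.
    """
    lp0, g0 = logp_and_grad(theta)
    if not np.isfinite(lp0):
        raise InferenceError("non-finite log posterior at current point")
    if inv_mass is None:
        inv_mass = np.ones(theta.size)
    p = rng.standard_normal(theta.size) / np.sqrt(inv_mass)
    H0 = -lp0 + 0.5 * float(p * inv_mass @ p)
    th = theta.copy()
    g = g0
    p = p + 0.5 * step_size * g
    lp = lp0
    for i in range(n_leapfrog):
        th = th + step_size * inv_mass * p
        lp, g = logp_and_grad(th)
        if not np.all(np.isfinite(g)) or not np.isfinite(lp):
            return theta, False, 0.0, lp0
        if i < n_leapfrog - 1:
            p = p + step_size * g
    p = p + 0.5 * step_size * g
    H1 = -lp + 0.5 * float(p * inv_mass @ p)
    accept_prob = min(1.0, math.exp(min(0.0, H0 - H1)))
    if rng.random() < accept_prob:
        return th, True, accept_prob, lp
    return theta, False, accept_prob, lp0


def _softmax_rows(eta):
    z = eta - eta.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def _dirichlet(rng, alpha):
    g = rng.gamma(np.maximum(np.asarray(alpha, dtype=float), 1e-8))
    s = g.sum()
    if s <= 0:
        return np.full(g.shape, 1.0 / g.size)
    return g / s


# ---------------------------------------------------------------------------
# beam sampler chain state

@dataclass
class ChainState:
    """Mutable state of one HDP-HMM chain.

    ``beta`` has K+1 entries (last = unrepresented stick mass); ``pi`` is
    (K, K+1) with the remainder column last; ``pi0`` is the initial-state
    DP draw with the same layout.
    """

    beta: np.ndarray
    pi: np.ndarray
    pi0: np.ndarray
    emis: np.ndarray
    s: np.ndarray
    later_log: np.ndarray
    alpha0: float
    gamma: float
    step_size: float

    @property
    def n_states(self) -> int:
        return self.pi.shape[0]


def _init_chain(y, rt_s, rt_mask, cfg: SamplerConfig, rng) -> ChainState:
    alpha0 = gamma = 1.0
    K = cfg.init_states
    beta = _dirichlet(rng, np.ones(K + 1))
    pi = np.stack([_dirichlet(rng, alpha0 * beta) for _ in range(K)])
    pi0 = _dirichlet(rng, alpha0 * beta)
    emis = np.stack([_dirichlet(rng, np.full(N_STIMULI, cfg.emission_alpha))
                     for _ in range(K)])
    s = rng.integers(0, K, size=len(y))
    rts = rt_s[rt_mask]
    r = (1.0 + math.log(N_STIMULI)) / np.maximum(rts, 1e-3)
    mu = float(np.clip(r.mean(), 0.5, 100.0))
    sigma = float(np.clip(r.std(), 0.05, 50.0))
    later_log = np.log(np.array([mu, sigma, 1.0]))
    return ChainState(beta=beta, pi=pi, pi0=pi0, emis=emis, s=s,
                      later_log=later_log, alpha0=alpha0, gamma=gamma,
                      step_size=cfg.step_size)


def _add_state(state: ChainState, rng) -> None:
    """Break one new state off the unrepresented mass (stick-breaking)."""
    b = rng.beta(1.0, max(state.gamma, 1e-6))
    beta_new = state.beta[-1] * b
    beta_rem = state.beta[-1] * (1.0 - b)
    state.beta = np.concatenate([state.beta[:-1], [beta_new, beta_rem]])
    a_new = max(state.alpha0 * beta_new, 1e-8)
    a_rem = max(state.alpha0 * beta_rem, 1e-8)

    def split(row):
        v = rng.beta(a_new, a_rem)
        return np.concatenate([row[:-1], [row[-1] * v, row[-1] * (1.0 - v)]])

    state.pi = np.vstack([np.stack([split(r) for r in state.pi]),
                          _dirichlet(rng, state.alpha0 * state.beta)])
    state.pi0 = split(state.pi0)
    state.emis = np.vstack([state.emis,
                            _dirichlet(rng, np.full(N_STIMULI, 1.0))])


def _sample_tables(rng, count, a) -> int:
    """Number of tables in a Chinese-restaurant process with ``count``
    customers and concentration ``a`` (antithetic-free direct simulation)."""
    if count <= 0:
        return 0
    i = np.arange(count, dtype=float)
    return int(np.sum(rng.random(count) < a / (a + i)))


def _resample_concentrations(state: ChainState, n_rows, total_tables,
                             n_dishes, cfg: SamplerConfig, rng) -> None:
    """Auxiliary-variable updates for the DP concentrations (Teh et al.
    style for alpha0, Escobar-West for the top-level gamma)."""
    valid = n_rows[n_rows > 0]
    if valid.size and total_tables > 0:
        w = rng.beta(state.alpha0 + 1.0, valid)
        s_aux = rng.random(valid.size) < valid / (valid + state.alpha0)
        shape = cfg.alpha0_a + total_tables - s_aux.sum()
        rate = cfg.alpha0_b - np.log(np.maximum(w, 1e-300)).sum()
        state.alpha0 = float(np.clip(rng.gamma(max(shape, 1e-3)) / rate,
                                     1e-3, 1e3))
    if total_tables > 0:
        eta = rng.beta(state.gamma + 1.0, total_tables)
        log_eta = math.log(max(eta, 1e-300))
        odds = ((cfg.gamma_a + n_dishes - 1)
                / max(total_tables * (cfg.gamma_b - log_eta), 1e-12))
        shape = cfg.gamma_a + n_dishes - (0 if rng.random() < odds / (1 + odds)
                                          else 1)
        state.gamma = float(np.clip(rng.gamma(max(shape, 1e-3))
                                    / (cfg.gamma_b - log_eta), 1e-3, 1e3))


def beam_sweep(state: ChainState, y, cfg: SamplerConfig, rng) -> ChainState:
    """One beam (slice) move: resample the latent path over the
    slice-truncated state set, prune unused states, and refresh sticks,
    transition rows and DP concentrations from their conjugate forms."""
    T = len(y)
    s = state.s
    for attempt in range(5):
        u = np.empty(T)
        u[0] = rng.random() * state.pi0[s[0]]
        u[1:] = rng.random(T - 1) * state.pi[s[:-1], s[1:]]
        u_min = u.min()
        while (max(state.pi[:, -1].max(), state.pi0[-1]) > u_min
               and state.n_states < cfg.max_states):
            _add_state(state, rng)
        K = state.n_states
        path, ok = _kernels.beam_ffbs(
            np.ascontiguousarray(state.pi0[:K]),
            np.ascontiguousarray(state.pi[:, :K]),
            np.maximum(state.emis, 1e-300), y, u, rng.random(T))
        if ok:
            break
    else:
        warnings.warn("beam sweep: slice truncation kept emptying the "
                      "candidate set; keeping previous path")
        path = s.copy()

    used = np.unique(path)
    remap = np.full(state.n_states, -1, dtype=np.int64)
    remap[used] = np.arange(used.size)
    path = remap[path]
    K = used.size
    emis = state.emis[used]
    beta_used = state.beta[used]

    trans_counts, _ = _kernels.path_counts(path, y, K, N_STIMULI)
    # tables: one CRP per transition row plus the initial-state draw
    m = np.zeros((K, K), dtype=np.int64)
    for j in range(K):
        for k in range(K):
            m[j, k] = _sample_tables(rng, trans_counts[j, k],
                                     state.alpha0 * max(beta_used[k], 1e-12))
    m_cols = m.sum(axis=0).astype(float)
    m_cols[path[0]] += 1.0       # table opened by the initial state
    total_tables = float(m_cols.sum())

    beta = _dirichlet(rng, np.concatenate([m_cols, [max(state.gamma, 1e-3)]]))
    pi = np.stack([
        _dirichlet(rng, np.concatenate([
            state.alpha0 * beta[:K] + trans_counts[j],
            [state.alpha0 * beta[-1]]]))
        for j in range(K)])
    e0 = np.zeros(K)
    e0[path[0]] = 1.0
    pi0 = _dirichlet(rng, np.concatenate([
        state.alpha0 * beta[:K] + e0, [state.alpha0 * beta[-1]]]))

    state.beta, state.pi, state.pi0, state.emis, state.s = beta, pi, pi0, emis, path
    n_rows = np.concatenate([trans_counts.sum(axis=1), [1]]).astype(float)
    _resample_concentrations(state, n_rows, total_tables, K, cfg, rng)
    return state


# ---------------------------------------------------------------------------
# joint-target construction

def _later_prior_logp_grad(later_log, cfg: SamplerConfig):
    lp = 0.0
    g = np.zeros(3)
    for i, (m, sd) in enumerate(cfg.later_prior):
        z = (later_log[i] - m) / sd
        lp += -0.5 * z * z
        g[i] = -z / sd
    return lp, g


def _make_ct_target(y, rt_s, rt_mask, pi0_trunk, trans_counts, emis_counts,
                    trans_prior_rows, cfg: SamplerConfig):
    """Joint HMC target over (transition logits, emission logits, LATER
    log-parameters) for one sweep's fixed latent path and sticks.

    ``trans_prior_rows`` carries the HDP row prior (alpha0 * beta) so the
    sampled transition rows stay tied to the shared sticks.
    """
    K = emis_counts.shape[0]
    n_trans = K * K
    n_emis = K * N_STIMULI
    # softmax-reparameterised Dirichlet exponents (the Jacobian adds one
    # power of each entry)
    a_trans = cfg.stim_weight * trans_counts + trans_prior_rows
    a_emis = cfg.stim_weight * emis_counts + cfg.emission_alpha

    def logp_and_grad(theta):
        eta_t = theta[:n_trans].reshape(K, K)
        eta_e = theta[n_trans:n_trans + n_emis].reshape(K, N_STIMULI)
        later_log = np.clip(theta[n_trans + n_emis:], -10.0, 10.0)
        Tm = _softmax_rows(eta_t)
        B = _softmax_rows(eta_e)
        mu, sigma, theta0 = np.exp(later_log)
        ll_rt, dT_rt, dB_rt, dmu, dsig, dth = _kernels.rt_loglik_grad_hmm(
            pi0_trunk, Tm, B, y, rt_s, rt_mask, mu, sigma, theta0,
            cfg.eps_floor)
        dT = cfg.rt_weight * dT_rt + a_trans / Tm
        dB = cfg.rt_weight * dB_rt + a_emis / B
        lp = (cfg.rt_weight * ll_rt
              + float(np.sum(a_trans * np.log(Tm)))
              + float(np.sum(a_emis * np.log(B)))
              - 0.5 * cfg.gauge * float(np.sum(eta_t * eta_t)
                                        + np.sum(eta_e * eta_e)))
        g_t = Tm * (dT - np.sum(dT * Tm, axis=1, keepdims=True)) - cfg.gauge * eta_t
        g_e = B * (dB - np.sum(dB * B, axis=1, keepdims=True)) - cfg.gauge * eta_e
        lp_prior, g_prior = _later_prior_logp_grad(later_log, cfg)
        lp += lp_prior
        g_later = (cfg.rt_weight * np.array([dmu * mu, dsig * sigma, dth * theta0])
                   + g_prior)
        return lp, np.concatenate([g_t.ravel(), g_e.ravel(), g_later])

    return logp_and_grad


def _ascend(theta, logp_and_grad, n_iters, lr=0.02):
    """Adam ascent to (near) the posterior mode — used only to warm-start
    chains, so slow MCMC burn-in does not eat the sweep budget.  Also
    returns the second-moment gradient estimate, which doubles as a cheap
    diagonal preconditioner for the subsequent HMC."""
    m = np.zeros_like(theta)
    v = np.zeros_like(theta)
    best, best_lp = theta, -np.inf
    for i in range(n_iters):
        lp, g = logp_and_grad(theta)
        if not np.isfinite(lp):
            break
        if lp > best_lp:
            best, best_lp = theta, lp
        m = 0.9 * m + 0.1 * g
        v = 0.999 * v + 0.001 * g * g
        mhat = m / (1 - 0.9 ** (i + 1))
        vhat = v / (1 - 0.999 ** (i + 1))
        theta = theta + lr * mhat / (np.sqrt(vhat) + 1e-8)
    return best, v


def _block_inv_mass(vhat, K, n_obs=N_STIMULI):
    """Three block-scalar inverse masses (transition logits, emission
    logits, LATER logs) from the warm-start gradient second moments,
    normalised to geometric mean one."""
    n_trans = K * K
    n_emis = K * n_obs
    blocks = [vhat[:n_trans], vhat[n_trans:n_trans + n_emis],
              vhat[n_trans + n_emis:]]
    scales = np.array([1.0 / math.sqrt(np.median(b) + 1e-8) for b in blocks])
    scales /= np.exp(np.mean(np.log(np.maximum(scales, 1e-12))))
    return np.clip(scales, 0.05, 20.0)


def _trunk_normalised(mat):
    mat = np.asarray(mat, dtype=float)
    rows = mat.sum(axis=-1, keepdims=True) if mat.ndim > 1 else mat.sum()
    return mat / rows


# ---------------------------------------------------------------------------
# fitting front-ends

def _prepare_ct_target(state: ChainState, y, rt_s, rt_mask, cfg: SamplerConfig):
    K = state.n_states
    trans_counts, emis_counts = _kernels.path_counts(state.s, y, K, N_STIMULI)
    pi0_trunk = _trunk_normalised(state.pi0[:K])
    trans_prior_rows = np.tile(
        np.maximum(state.alpha0 * state.beta[:K], 1e-3), (K, 1))
    target = _make_ct_target(y, rt_s, rt_mask, pi0_trunk, trans_counts,
                             emis_counts, trans_prior_rows, cfg)
    theta = np.concatenate([
        np.log(np.maximum(_trunk_normalised(state.pi[:, :K]), 1e-12)).ravel(),
        np.log(np.maximum(state.emis, 1e-12)).ravel(),
        state.later_log])
    return target, theta, K


def _write_back_ct(state: ChainState, theta, K) -> None:
    trans_new = _softmax_rows(theta[:K * K].reshape(K, K))
    # write the sampled rows back into the trunk, preserving each row's
    # unrepresented remainder mass
    state.pi[:, :K] = trans_new * (1.0 - state.pi[:, -1:])
    state.emis = _softmax_rows(
        theta[K * K:K * K + K * N_STIMULI].reshape(K, N_STIMULI))
    state.later_log = np.clip(theta[K * K + K * N_STIMULI:], -10.0, 10.0)


def fit_ct(stimuli, rt_s, rt_mask, config: SamplerConfig | None = None,
           seed: int = 0) -> CTPosterior:
    """Fit the Cognitive Tomography model (infinite HMM + LATER) to one
    participant-session.

    ``stimuli`` is the full trial sequence (excluded trials included, so
    they keep conditioning predictions); ``rt_mask`` marks trials whose RT
    enters the likelihood; ``rt_s`` are RTs in seconds (ignored where the
    mask is False).
    """
    cfg = config or SamplerConfig()
    y = np.asarray(stimuli, dtype=np.int64)
    rt_mask = np.asarray(rt_mask, dtype=bool)
    rt_raw = np.asarray(rt_s, dtype=float)
    if y.size != rt_raw.size or y.size != rt_mask.size:
        raise InferenceError("stimuli, rt_s and rt_mask must be aligned")
    rt_s = np.where(rt_mask, rt_raw, 1.0)
    if rt_mask.sum() < 1:
        raise InferenceError("need at least one surviving RT")

    samples: list[PosteriorSample] = []
    diagnostics = {"n_states": [], "accept": [], "logp": [], "failed_chains": 0}
    adapt_until = int(cfg.adapt_fraction * cfg.n_sweeps)
    for chain in range(cfg.n_chains):
        rng = np.random.default_rng([seed, chain])
        try:
            state = _init_chain(y, rt_s, rt_mask, cfg, rng)
            block_scales = np.ones(3)
            for _ in range(cfg.warm_start_rounds):
                beam_sweep(state, y, cfg, rng)
                target, theta, K = _prepare_ct_target(state, y, rt_s,
                                                      rt_mask, cfg)
                theta, vhat = _ascend(theta, target, cfg.warm_start_iters)
                _write_back_ct(state, theta, K)
                block_scales = _block_inv_mass(vhat, K)
            k_trace, acc_trace, lp_last = [], [], np.nan
            for sweep in range(cfg.n_sweeps):
                beam_sweep(state, y, cfg, rng)
                target, theta, K = _prepare_ct_target(state, y, rt_s,
                                                      rt_mask, cfg)
                inv_mass = np.concatenate([
                    np.full(K * K, block_scales[0]),
                    np.full(K * N_STIMULI, block_scales[1]),
                    np.full(3, block_scales[2])])
                for _ in range(cfg.hmc_updates_per_sweep):
                    theta, _, aprob, lp_last = hmc_update(
                        theta, target, rng, state.step_size, cfg.n_leapfrog,
                        inv_mass)
                    acc_trace.append(aprob)
                    if sweep < adapt_until:
                        state.step_size = float(np.clip(
                            state.step_size
                            * math.exp(0.05 * (aprob - cfg.target_accept)),
                            1e-5, 1.0))
                _write_back_ct(state, theta, K)
                k_trace.append(K)
                if sweep >= cfg.n_sweeps - cfg.retained_tail:
                    mu, sigma, theta0 = np.exp(state.later_log)
                    samples.append(PosteriorSample(
                        model=HMMInternalModel(
                            initial=_trunk_normalised(state.pi0[:K]).copy(),
                            transition=_trunk_normalised(state.pi[:, :K]).copy(),
                            emission=state.emis.copy()),
                        later=LATERParams(mu, sigma, theta0),
                        alpha0=state.alpha0, gamma=state.gamma))
            diagnostics["n_states"].append(k_trace)
            diagnostics["accept"].append(float(np.mean(acc_trace)))
            diagnostics["logp"].append(float(lp_last))
        except InferenceError:
            diagnostics["failed_chains"] += 1
            warnings.warn(f"chain {chain} aborted with non-finite posterior")
    if not samples:
        raise InferenceError("all chains failed")
    return CTPosterior(samples=samples, config=cfg, seed=seed,
                       data_hash=data_fingerprint(y, rt_s, rt_mask),
                       kind="ct", diagnostics=diagnostics)


def fit_markov(stimuli, rt_s, rt_mask, config: SamplerConfig | None = None,
               seed: int = 0) -> CTPosterior:
    """Fit the first-order Markov baseline with the same Gibbs+HMC
    machinery, the latent structure fixed to the stimulus-indexed chain.

    Transition rows carry a symmetric Dirichlet(1) prior and are informed
    by both the observed bigram counts and the RT likelihood.
    """
    cfg = config or SamplerConfig()
    y = np.asarray(stimuli, dtype=np.int64)
    rt_mask = np.asarray(rt_mask, dtype=bool)
    rt_raw = np.asarray(rt_s, dtype=float)
    if y.size != rt_raw.size or y.size != rt_mask.size:
        raise InferenceError("stimuli, rt_s and rt_mask must be aligned")
    rt_s = np.where(rt_mask, rt_raw, 1.0)
    if rt_mask.sum() < 1:
        raise InferenceError("need at least one surviving RT")
    bigram = np.zeros((N_STIMULI, N_STIMULI))
    np.add.at(bigram, (y[:-1], y[1:]), 1.0)
    init_marginal = np.full(N_STIMULI, 1.0 / N_STIMULI)

    def make_target():
        def logp_and_grad(theta):
            eta = theta[:16].reshape(N_STIMULI, N_STIMULI)
            later_log = np.clip(theta[16:], -10.0, 10.0)
            M = _softmax_rows(eta)
            mu, sigma, theta0 = np.exp(later_log)
            ll_rt, dM_rt, dmu, dsig, dth = _kernels.rt_loglik_grad_markov(
                M, init_marginal, y, rt_s, rt_mask, mu, sigma, theta0,
                cfg.eps_floor)
            a_rows = cfg.stim_weight * bigram + 1.0
            dM = cfg.rt_weight * dM_rt + a_rows / M
            lp = (cfg.rt_weight * ll_rt
                  + float(np.sum(a_rows * np.log(M)))
                  - 0.5 * cfg.gauge * float(np.sum(eta * eta)))
            g_eta = M * (dM - np.sum(dM * M, axis=1, keepdims=True))
            g_eta -= cfg.gauge * eta
            lp_prior, g_prior = _later_prior_logp_grad(later_log, cfg)
            lp += lp_prior
            g_later = (cfg.rt_weight
                       * np.array([dmu * mu, dsig * sigma, dth * theta0])
                       + g_prior)
            return lp, np.concatenate([g_eta.ravel(), g_later])
        return logp_and_grad

    samples: list[PosteriorSample] = []
    diagnostics = {"accept": [], "failed_chains": 0}
    adapt_until = int(cfg.adapt_fraction * cfg.n_sweeps)
    target = make_target()
    for chain in range(cfg.n_chains):
        rng = np.random.default_rng([seed, 1000 + chain])
        rts = rt_s[rt_mask]
        r = (1.0 + math.log(N_STIMULI)) / np.maximum(rts, 1e-3)
        theta = np.concatenate([
            np.log(_dirichlet(rng, np.ones((N_STIMULI, N_STIMULI)) * 2)
                   .reshape(N_STIMULI, N_STIMULI)).ravel(),
            np.log([np.clip(r.mean(), 0.5, 100.0),
                    np.clip(r.std(), 0.05, 50.0), 1.0])])
        step = cfg.step_size
        acc_trace = []
        theta, vhat = _ascend(theta, target,
                              cfg.warm_start_rounds * cfg.warm_start_iters)
        inv_mass = 1.0 / np.sqrt(vhat + 1e-8)
        inv_mass /= np.exp(np.mean(np.log(np.maximum(inv_mass, 1e-12))))
        inv_mass = np.clip(inv_mass, 0.05, 20.0)
        for sweep in range(cfg.n_sweeps):
            for _ in range(cfg.hmc_updates_per_sweep):
                theta, _, aprob, _ = hmc_update(theta, target, rng, step,
                                                cfg.n_leapfrog, inv_mass)
                acc_trace.append(aprob)
                if sweep < adapt_until:
                    step = float(np.clip(
                        step * math.exp(0.05 * (aprob - cfg.target_accept)),
                        1e-5, 1.0))
            if sweep >= cfg.n_sweeps - cfg.retained_tail:
                M = _softmax_rows(theta[:16].reshape(N_STIMULI, N_STIMULI))
                mu, sigma, theta0 = np.exp(np.clip(theta[16:], -10, 10))
                samples.append(PosteriorSample(
                    model=MarkovInternalModel(transition=M,
                                              initial=init_marginal.copy()),
                    later=LATERParams(mu, sigma, theta0)))
        diagnostics["accept"].append(float(np.mean(acc_trace)))
    return CTPosterior(samples=samples, config=cfg, seed=seed,
                       data_hash=data_fingerprint(y, rt_s, rt_mask),
                       kind="markov", diagnostics=diagnostics)


def posterior_predictive(posterior: CTPosterior, stimuli,
                         eps_floor: float = DEFAULT_EPS_FLOOR) -> PredictiveTrace:
    """Monte Carlo posterior-predictive trace: the forward-filtered
    predictive vectors averaged over all retained samples with equal
    weights on the probability scale."""
    if not posterior.samples:
        raise InferenceError("empty posterior")
    y = np.asarray(stimuli, dtype=np.int64)
    acc = np.zeros((y.size, N_STIMULI))
    for sample in posterior.samples:
        if isinstance(sample.model, MarkovInternalModel):
            trace = markov_predict(sample.model, y)
        else:
            trace = forward_filter(sample.model, y, eps_floor=eps_floor)
        acc += trace.probs
    acc /= len(posterior.samples)
    realized = np.maximum(acc[np.arange(y.size), y], eps_floor)
    return PredictiveTrace(probs=acc, realized=realized)


def posterior_mean_later(posterior: CTPosterior) -> LATERParams:
    """Posterior-mean LATER parameters across retained samples."""
    arr = np.array([[s.later.mu, s.later.sigma, s.later.theta0]
                    for s in posterior.samples])
    m = arr.mean(axis=0)
    return LATERParams(*m)
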