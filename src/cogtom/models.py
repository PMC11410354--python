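"""Internal sequence models: ground-truth HMM, Markov baseline, filtering.

An internal model is the (possibly subjective) probabilistic model a
participant entertains about the stimulus sequence.  Three families are
used throughout the package:

* :class:`HMMInternalModel` — a finite-state HMM over the four stimuli;
  posterior samples of the infinite HMM are represented this way too.
* :class:`MarkovInternalModel` — a first-order model on stimuli,
  ``p(y_{t+1} | y_t)``; the initial inductive bias.
* The *Ground Truth* model — an 8-state HMM that generates the ASRT
  sequence exactly at zero noise, with two mixing parameters that blur the
  dynamics and the deterministic emissions.

:func:`forward_filter` produces the one-step-ahead predictive
probabilities (a :class:`PredictiveTrace`) that drive both response-time
prediction and every evaluation metric.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .task import N_STIMULI, StimulusPermutation, TaskRule

DEFAULT_EPS_FLOOR = 1e-6
_ROW_TOL = 1e-9


class ModelError(ValueError):
    pass


def _check_stochastic(mat, name):
    mat = np.asarray(mat, dtype=float)
    if np.any(mat < -1e-15):
        raise ModelError(f"{name} has negative entries")
    rows = mat.sum(axis=-1)
    if not np.allclose(rows, 1.0, atol=_ROW_TOL):
        raise ModelError(f"{name} rows must sum to 1 (got {rows})")
    return np.clip(mat, 0.0, None)


@dataclass
class HMMInternalModel:
    """Finite-state hidden Markov model over the four ASRT stimuli."""

    initial: np.ndarray      # (K,)
    transition: np.ndarray   # (K, K) row-stochastic
    emission: np.ndarray     # (K, 4) row-stochastic

    def __post_init__(self) -> None:
        self.initial = _check_stochastic(np.atleast_1d(self.initial), "initial")
        self.transition = _check_stochastic(self.transition, "transition")
        self.emission = _check_stochastic(self.emission, "emission")
        K = self.initial.shape[0]
        if self.transition.shape != (K, K) or self.emission.shape[0] != K:
            raise ModelError("inconsistent state dimensions")
        if self.emission.shape[1] != N_STIMULI:
            raise ModelError("emission must have 4 observation columns")

    @property
    def n_states(self) -> int:
        return self.initial.shape[0]

    def to_json(self, path=None):
        payload = {
            "schema": "cogtom-hmm-v1",
            "n_states": int(self.n_states),
            "initial": self.initial.tolist(),
            "transition": self.transition.tolist(),
            "emission": self.emission.tolist(),
        }
        if path is None:
            return json.dumps(payload)
        with open(path, "w") as fh:
            json.dump(payload, fh)
        return None

    @classmethod
    def from_json(cls, source) -> "HMMInternalModel":
        if isinstance(source, (str, bytes)) and str(source).lstrip().startswith("{"):
            payload = json.loads(source)
        else:
            with open(source) as fh:
                payload = json.load(fh)
        if payload.get("schema") != "cogtom-hmm-v1":
            raise ModelError(f"unknown model schema: {payload.get('schema')!r}")
        return cls(initial=np.array(payload["initial"]),
                   transition=np.array(payload["transition"]),
                   emission=np.array(payload["emission"]))


@dataclass
class MarkovInternalModel:
    """First-order model on stimuli: prediction is a row of ``transition``."""

    transition: np.ndarray                  # (4, 4)
    initial: np.ndarray = field(
        default_factory=lambda: np.full(N_STIMULI, 1.0 / N_STIMULI))

    def __post_init__(self) -> None:
        self.transition = _check_stochastic(self.transition, "transition")
        self.initial = _check_stochastic(np.atleast_1d(self.initial), "initial")
        if self.transition.shape != (N_STIMULI, N_STIMULI):
            raise ModelError("Markov transition must be 4x4")


@dataclass
class PredictiveTrace:
    """Per-trial predictive distributions and realized-stimulus probability."""

    probs: np.ndarray      # (T, 4)
    realized: np.ndarray   # (T,) = probs[t, y_t] floored away from 0

    def __len__(self) -> int:
        return self.probs.shape[0]


# ---------------------------------------------------------------------------
# ground truth model

def build_ground_truth(rule: TaskRule, dyn_noise: float = 0.0,
                       emis_noise: float = 0.0) -> HMMInternalModel:
    """The 8-state generative model of the ASRT sequence.

    States alternate pattern and random: P1, R1, P2, R2, P3, R3, P4, R4.
    At zero noise P_k emits ``rule[k]`` with probability one and steps to
    R_k, which emits uniformly and steps to P_{k+1}.  ``dyn_noise`` mixes
    every transition row with the uniform distribution over the 8 states;
    ``emis_noise`` mixes the deterministic emission rows with the uniform
    distribution over the 4 stimuli.  The initial state is uniform.
    """
    for name, eps in (("dyn_noise", dyn_noise), ("emis_noise", emis_noise)):
        if not 0.0 <= eps < 1.0:
            raise ModelError(f"{name} must lie in [0, 1)")
    K = 2 * N_STIMULI
    trans = np.zeros((K, K))
    emis = np.zeros((K, N_STIMULI))
    for k in range(N_STIMULI):
        p_state, r_state = 2 * k, 2 * k + 1
        trans[p_state, r_state] = 1.0
        trans[r_state, (2 * (k + 1)) % K] = 1.0
        emis[p_state, rule[k]] = 1.0
        emis[r_state, :] = 1.0 / N_STIMULI
    trans = (1 - dyn_noise) * trans + dyn_noise / K
    pattern_rows = np.arange(0, K, 2)
    emis[pattern_rows] = ((1 - emis_noise) * emis[pattern_rows]
                          + emis_noise / N_STIMULI)
    return HMMInternalModel(initial=np.full(K, 1.0 / K),
                            transition=trans, emission=emis)


GROUND_TRUTH_PATTERN_STATES = tuple(range(0, 2 * N_STIMULI, 2))
GROUND_TRUTH_RANDOM_STATES = tuple(range(1, 2 * N_STIMULI, 2))


# ---------------------------------------------------------------------------
# filtering and prediction

def forward_filter(model: HMMInternalModel, stimuli,
                   eps_floor: float = DEFAULT_EPS_FLOOR) -> PredictiveTrace:
    """Exact HMM forward filtering of a stimulus sequence.

    ``probs[t]`` is the predictive distribution over the four stimuli
    before observing ``stimuli[t]``; ``realized[t]`` is the probability
    assigned to the stimulus that actually occurred, floored at
    ``eps_floor`` so deterministic models stay defined on off-pattern
    observations (a warning is emitted when the floor engages).
    """
    y = np.asarray(stimuli, dtype=np.int64)
    if y.size == 0:
        raise ModelError("empty stimulus sequence")
    if np.any((y < 0) | (y >= N_STIMULI)):
        raise ModelError("stimulus ids must lie in 0..3")
    probs, realized, _, n_floored = _kernels.forward_filter_kernel(
        model.initial, model.transition, model.emission, y, eps_floor)
    if n_floored:
        warnings.warn(
            f"forward_filter: {n_floored} zero-likelihood observations "
            f"floored at {eps_floor}")
    return PredictiveTrace(probs=probs, realized=realized)


def markov_predict(model: MarkovInternalModel, stimuli) -> PredictiveTrace:
    """Predictive trace of the first-order Markov model."""
    y = np.asarray(stimuli, dtype=np.int64)
    if y.size == 0:
        raise ModelError("empty stimulus sequence")
    probs = np.empty((y.size, N_STIMULI))
    probs[0] = model.initial
    probs[1:] = model.transition[y[:-1]]
    realized = probs[np.arange(y.size), y]
    return PredictiveTrace(probs=probs, realized=realized)


def markov_to_hmm(model: MarkovInternalModel) -> HMMInternalModel:
    """Embed the Markov model as a 4-state HMM (state = last stimulus,
    one-hot emissions)."""
    return HMMInternalModel(initial=model.initial.copy(),
                            transition=model.transition.copy(),
                            emission=np.eye(N_STIMULI))


def permute_observations(model: HMMInternalModel,
                         sigma: StimulusPermutation) -> HMMInternalModel:
    """Relabel the observation channels of an HMM by a stimulus permutation.

    ``emission'[k, sigma(y)] = emission[k, y]``; dynamics and initial
    distribution are untouched, so latent structure (and its entropy) is
    preserved exactly.
    """
    new_emis = np.empty_like(model.emission)
    new_emis[:, list(sigma.mapping)] = model.emission
    return HMMInternalModel(initial=model.initial.copy(),
                            transition=model.transition.copy(),
                            emission=new_emis)


def synthesize_from_model(model: HMMInternalModel, n_trials: int, rng=None):
    """Ancestral sampling of ``(states, stimuli)`` from an internal model."""
    if n_trials < 1:
        raise ModelError("n_trials must be >= 1")
    rng = np.random.default_rng(rng)
    K = model.n_states
    states = np.empty(n_trials, dtype=np.int64)
    # vectorized categorical draws via the inverse-CDF trick
    cum_trans = np.cumsum(model.transition, axis=1)
    cum_emis = np.cumsum(model.emission, axis=1)
    u_state = rng.random(n_trials)
    u_obs = rng.random(n_trials)
    states[0] = np.searchsorted(np.cumsum(model.initial), u_state[0], side="right")
    for t in range(1, n_trials):
        states[t] = np.searchsorted(cum_trans[states[t - 1]], u_state[t],
                                    side="right")
    states = np.minimum(states, K - 1)
    stimuli = (u_obs[:, None] > cum_emis[states]).sum(axis=1)
    return states, stimuli.astype(np.int64)


def stationary_distribution(transition) -> np.ndarray:
    """Left stationary distribution of a row-stochastic matrix (leading
    eigenvector, renormalised)."""
    vals, vecs = np.linalg.eig(np.asarray(transition, dtype=float).T)
    idx = np.argmin(np.abs(vals - 1.0))
    v = np.real(vecs[:, idx])
    v = np.abs(v)
    return v / v.sum()
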