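import itertools

import numpy as np
import pytest

from cogtom import make_task_rule
from cogtom.models import HMMInternalModel


@pytest.fixture(scope="session")
def rule_pair():
    return make_task_rule((0, 1, 2, 3)), make_task_rule((1, 3, 0, 2))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_hmm(rng, n_states, n_obs=4) -> HMMInternalModel:
    """A fully supported random HMM (no zero entries)."""
    return HMMInternalModel(
        initial=rng.dirichlet(np.ones(n_states) * 2),
        transition=rng.dirichlet(np.ones(n_states) * 2, size=n_states),
        emission=rng.dirichlet(np.ones(n_obs) * 2, size=n_states))


def brute_force_predictives(model: HMMInternalModel, stimuli) -> np.ndarray:
    """Predictive stimulus probabilities by exhaustive state-path
    enumeration: p(y_t = c | y_{1:t-1}) computed from joint marginals
    summed over every path in K^t.  Exponential — tiny inputs only."""
    y = list(stimuli)
    K = model.n_states
    T = len(y)
    out = np.zeros((T, model.emission.shape[1]))
    for t in range(T):
        # joint probability of observing y_1..y_{t-1} then candidate c
        for c in range(model.emission.shape[1]):
            total = 0.0
            for path in itertools.product(range(K), repeat=t + 1):
                p = model.initial[path[0]]
                for i in range(1, t + 1):
                    p *= model.transition[path[i - 1], path[i]]
                for i in range(t):
                    p *= model.emission[path[i], y[i]]
                p *= model.emission[path[t], c]
                total += p
        # normalise by p(y_1..y_{t-1})
            out[t, c] = total
        out[t] /= out[t].sum()
    return out
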