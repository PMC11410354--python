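"""Sampler machinery: HMC, beam sweeps, posterior bookkeeping."""

import numpy as np
import pytest

from cogtom import _kernels
from cogtom.inference import (CTPosterior, InferenceError,
                              PosteriorSample, SamplerConfig, _init_chain,
                              beam_sweep, fit_ct, fit_markov, hmc_update,
                              posterior_predictive)
from cogtom.models import (MarkovInternalModel, forward_filter,
                           markov_predict, synthesize_from_model)
from cogtom.response import LATERParams, later_sample

from conftest import random_hmm

TINY = SamplerConfig.desk(n_sweeps=25, retained_tail=5, n_chains=1,
                          hmc_updates_per_sweep=4, warm_start_rounds=1,
                          warm_start_iters=50)


class TestConfig:
    def test_paper_scale_bookkeeping(self):
        cfg = SamplerConfig.paper()
        assert (cfg.n_chains, cfg.n_sweeps, cfg.hmc_updates_per_sweep,
                cfg.retained_tail) == (4, 1600, 30, 30)
        # four chains times the last 30 samples each
        assert cfg.n_chains * cfg.retained_tail == 120

    def test_desk_scale(self):
        cfg = SamplerConfig.desk()
        assert (cfg.n_chains, cfg.n_sweeps, cfg.hmc_updates_per_sweep,
                cfg.retained_tail) == (2, 200, 10, 20)

    def test_invalid_tail_rejected(self):
        with pytest.raises(InferenceError):
            SamplerConfig(n_sweeps=10, retained_tail=20)


class TestHMC:
    def test_flat_target_always_accepts(self, rng):
        def flat(theta):
            return 0.0, np.zeros_like(theta)
        theta = np.zeros(3)
        probs = []
        for _ in range(50):
            theta, accepted, aprob, _ = hmc_update(theta, flat, rng, 0.1, 5)
            probs.append(aprob)
        assert np.allclose(probs, 1.0)

    def test_gaussian_target_moments(self, rng):
        """Analytic oracle: samples from a standard normal target have
        mean 0 and variance 1 within 3 (autocorrelation-inflated) SEs."""
        def gauss(theta):
            return -0.5 * float(theta @ theta), -theta
        theta = np.zeros(1)
        draws = []
        for _ in range(10_000):
            theta, _, _, _ = hmc_update(theta, gauss, rng, 0.5, 8)
            draws.append(theta[0])
        draws = np.array(draws[500:])
        n_eff = draws.size / 5.0          # conservative ESS bound
        assert abs(draws.mean()) < 3 / np.sqrt(n_eff)
        assert abs(draws.var() - 1.0) < 3 * np.sqrt(2 / n_eff)

    def test_energy_conservation_on_gaussian(self, rng):
        """Leapfrog keeps the Hamiltonian error small at a stable step."""
        def gauss(theta):
            return -0.5 * float(theta @ theta), -theta
        theta = rng.standard_normal(4)
        errors = []
        for _ in range(200):
            lp0, _ = gauss(theta)
            new, accepted, aprob, lp = hmc_update(theta, gauss, rng, 0.1, 10)
            errors.append(-np.log(max(aprob, 1e-12)))
            theta = new
        assert np.mean(errors) < 0.05

    def test_divergent_trajectory_rejected(self, rng):
        def unstable(theta):
            if abs(theta[0]) > 2.0:
                return np.nan, theta
            return -0.5 * float(theta @ theta), -theta
        theta = np.array([1.9])
        out, accepted, aprob, _ = hmc_update(theta, unstable, rng, 5.0, 10)
        assert not accepted and aprob == 0.0
        assert np.array_equal(out, theta)


class TestBeamSweep:
    def _data(self, rng, T=300):
        model = random_hmm(rng, 2)
        _, y = synthesize_from_model(model, T, rng=5)
        return y

    def test_preserves_row_stochastic_invariants(self, rng):
        y = self._data(rng)
        cfg = SamplerConfig.desk()
        state = _init_chain(y, np.full(len(y), 0.3), np.ones(len(y), bool),
                            cfg, rng)
        for _ in range(10):
            beam_sweep(state, y, cfg, rng)
            K = state.n_states
            assert np.allclose(state.pi.sum(axis=1), 1.0, atol=1e-9)
            assert np.allclose(state.beta.sum(), 1.0, atol=1e-9)
            assert state.s.max() < K
            assert state.emis.shape == (K, 4)

    def test_state_count_stays_small_on_two_state_data(self, rng):
        """Data from a fixed 2-state model keeps the sampled state count
        concentrated at small K over repeated sweeps."""
        y = self._data(rng, T=400)
        cfg = SamplerConfig.desk()
        state = _init_chain(y, np.full(len(y), 0.3), np.ones(len(y), bool),
                            cfg, rng)
        ks = []
        for _ in range(200):
            beam_sweep(state, y, cfg, rng)
            ks.append(state.n_states)
        mode = np.bincount(ks).argmax()
        assert mode <= cfg.max_states
        assert np.median(ks[100:]) <= 8

    def test_identical_seeds_identical_fit(self):
        rng = np.random.default_rng(0)
        model = random_hmm(rng, 2)
        _, y = synthesize_from_model(model, 200, rng=2)
        trace = forward_filter(model, y)
        rt = later_sample(trace.realized, LATERParams(8, 1, 1), rng)
        mask = np.ones(len(y), bool)
        a = fit_ct(y, rt, mask, TINY, seed=7)
        b = fit_ct(y, rt, mask, TINY, seed=7)
        for sa, sb in zip(a.samples, b.samples):
            assert np.array_equal(sa.model.transition, sb.model.transition)
            assert np.array_equal(sa.model.emission, sb.model.emission)
            assert sa.later == sb.later


class TestFitCT:
    def test_sample_bookkeeping_and_validity(self, rng):
        model = random_hmm(rng, 2)
        _, y = synthesize_from_model(model, 300, rng=3)
        trace = forward_filter(model, y)
        rt = later_sample(trace.realized, LATERParams(8, 1, 1), rng)
        post = fit_ct(y, rt, np.ones(len(y), bool), TINY, seed=1)
        assert len(post.samples) == TINY.n_chains * TINY.retained_tail
        for s in post.samples[:5]:
            assert np.allclose(s.model.transition.sum(axis=1), 1.0)
            assert np.allclose(s.model.emission.sum(axis=1), 1.0)
            assert s.later.mu > 0 and s.later.sigma > 0

    def test_recovers_two_state_predictives(self, rng):
        """Scaled-down recovery: posterior-predictive probabilities track
        the generative ones on data from a known 2-state model."""
        model = random_hmm(rng, 2)
        _, y = synthesize_from_model(model, 600, rng=4)
        gen = forward_filter(model, y)
        rt = later_sample(gen.realized, LATERParams(8, 1, 1), rng)
        cfg = SamplerConfig.desk(n_chains=1, n_sweeps=60, retained_tail=10)
        post = fit_ct(y, rt, np.ones(len(y), bool), cfg, seed=2)
        pp = posterior_predictive(post, y)
        corr = np.corrcoef(pp.realized, gen.realized)[0, 1]
        assert corr ** 2 > 0.5

    def test_misaligned_inputs_rejected(self, rng):
        with pytest.raises(InferenceError):
            fit_ct(np.zeros(10, dtype=int), np.ones(9), np.ones(10, bool),
                   TINY, seed=0)


class TestFitMarkov:
    def test_uniform_rt_null_concentrates_near_uniform(self, rng):
        """RTs carrying no sequence information leave the posterior rows
        near the uniform inductive bias."""
        y = rng.integers(0, 4, 800)
        rt = rng.uniform(0.25, 0.35, 800)
        post = fit_markov(y, rt, np.ones(800, bool), TINY, seed=3)
        mean_T = np.mean([s.model.transition for s in post.samples], axis=0)
        assert np.abs(mean_T - 0.25).max() < 0.1

    def test_retained_sample_contract_matches_ct(self, rng):
        y = rng.integers(0, 4, 200)
        rt = rng.uniform(0.2, 0.4, 200)
        post = fit_markov(y, rt, np.ones(200, bool), TINY, seed=0)
        assert len(post.samples) == TINY.n_chains * TINY.retained_tail
        assert post.kind == "markov"


class TestPosteriorPredictive:
    def test_single_sample_equals_forward_filter(self, rng):
        model = random_hmm(rng, 3)
        y = rng.integers(0, 4, 100)
        post = CTPosterior(samples=[PosteriorSample(model, LATERParams(8, 1, 1))],
                           config=TINY, seed=0, data_hash="x")
        pp = posterior_predictive(post, y)
        direct = forward_filter(model, y)
        assert np.allclose(pp.probs, direct.probs)

    def test_duplicate_samples_change_nothing(self, rng):
        model = random_hmm(rng, 3)
        y = rng.integers(0, 4, 100)
        one = CTPosterior(samples=[PosteriorSample(model, LATERParams(8, 1, 1))],
                          config=TINY, seed=0, data_hash="x")
        two = CTPosterior(samples=one.samples * 2, config=TINY, seed=0,
                          data_hash="x")
        assert np.allclose(posterior_predictive(one, y).probs,
                           posterior_predictive(two, y).probs)

    def test_two_component_mixture_oracle(self, rng):
        """Averaging over two model samples equals the hand-computed
        mixture of their individual traces."""
        m1, m2 = random_hmm(rng, 2), random_hmm(rng, 4)
        y = rng.integers(0, 4, 150)
        post = CTPosterior(
            samples=[PosteriorSample(m1, LATERParams(8, 1, 1)),
                     PosteriorSample(m2, LATERParams(8, 1, 1))],
            config=TINY, seed=0, data_hash="x")
        pp = posterior_predictive(post, y)
        expected = 0.5 * (forward_filter(m1, y).probs
                          + forward_filter(m2, y).probs)
        assert np.abs(pp.probs - expected).max() < 1e-12

    def test_markov_samples_dispatch(self, rng):
        model = MarkovInternalModel(rng.dirichlet(np.ones(4), 4))
        y = rng.integers(0, 4, 80)
        post = CTPosterior(samples=[PosteriorSample(model, LATERParams(8, 1, 1))],
                           config=TINY, seed=0, data_hash="x", kind="markov")
        assert np.allclose(posterior_predictive(post, y).probs,
                           markov_predict(model, y).probs)

    def test_empty_posterior_rejected(self):
        post = CTPosterior(samples=[], config=TINY, seed=0, data_hash="x")
        with pytest.raises(InferenceError):
            posterior_predictive(post, [0, 1])


class TestKernelGradients:
    def test_hmm_rt_gradient_matches_central_differences(self, rng):
        model = random_hmm(rng, 3)
        T = 40
        y = rng.integers(0, 4, T)
        rt = rng.uniform(0.2, 0.6, T)
        mask = rng.random(T) < 0.8
        args = (model.initial, model.transition, model.emission, y, rt, mask)
        ll, dT, dB, dmu, dsig, dth = _kernels.rt_loglik_grad_hmm(
            *args, 7.0, 1.1, 0.9, 1e-6)
        eps = 1e-5

        def f(trans, emis, mu=7.0, sig=1.1, th=0.9):
            return _kernels.rt_loglik_grad_hmm(
                model.initial, trans, emis, y, rt, mask, mu, sig, th, 1e-6)[0]

        for j in range(3):
            for k in range(3):
                t1 = model.transition.copy(); t1[j, k] += eps
                t2 = model.transition.copy(); t2[j, k] -= eps
                fd = (f(t1, model.emission) - f(t2, model.emission)) / (2 * eps)
                assert dT[j, k] == pytest.approx(fd, rel=1e-5, abs=1e-6)
            for c in range(4):
                e1 = model.emission.copy(); e1[j, c] += eps
                e2 = model.emission.copy(); e2[j, c] -= eps
                fd = (f(model.transition, e1)
                      - f(model.transition, e2)) / (2 * eps)
                assert dB[j, c] == pytest.approx(fd, rel=1e-5, abs=1e-6)
        fd_mu = (f(model.transition, model.emission, mu=7.0 + eps)
                 - f(model.transition, model.emission, mu=7.0 - eps)) / (2 * eps)
        assert dmu == pytest.approx(fd_mu, rel=1e-5)

    def test_markov_rt_gradient_matches_central_differences(self, rng):
        M = rng.dirichlet(np.ones(4), 4)
        T = 50
        y = rng.integers(0, 4, T)
        rt = rng.uniform(0.2, 0.6, T)
        mask = np.ones(T, bool)
        init = np.full(4, 0.25)
        ll, dM, *_ = _kernels.rt_loglik_grad_markov(M, init, y, rt, mask,
                                                    7.0, 1.1, 0.9, 1e-6)
        eps = 1e-5
        for j in range(4):
            for k in range(4):
                m1 = M.copy(); m1[j, k] += eps
                m2 = M.copy(); m2[j, k] -= eps
                fd = (_kernels.rt_loglik_grad_markov(
                          m1, init, y, rt, mask, 7.0, 1.1, 0.9, 1e-6)[0]
                      - _kernels.rt_loglik_grad_markov(
                          m2, init, y, rt, mask, 7.0, 1.1, 0.9, 1e-6)[0]) / (2 * eps)
                assert dM[j, k] == pytest.approx(fd, rel=1e-5, abs=1e-6)
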