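"""Evaluation measures: r^2, learning strength, entropies, permutation
transfer."""

import numpy as np
import pytest

from cogtom.inference import CTPosterior, PosteriorSample, SamplerConfig
from cogtom.metrics import (MetricsError, latent_state_entropy,
                            learning_strength, model_cross_entropy,
                            predictive_performance, relative_performance,
                            training_phase_learning_strength,
                            transfer_permutation_analysis)
from cogtom.models import (HMMInternalModel, PredictiveTrace,
                           build_ground_truth, forward_filter,
                           permute_observations, stationary_distribution,
                           synthesize_from_model)
from cogtom.response import LATERParams, later_sample
from cogtom.task import make_task_rule, normative_permutation

from conftest import random_hmm


def _trace_from_realized(p):
    p = np.asarray(p, dtype=float)
    probs = np.tile((1 - p)[:, None] / 3, (1, 4))
    probs[:, 0] = p
    return PredictiveTrace(probs=probs, realized=p)


class TestPredictivePerformance:
    def test_affine_rts_give_one(self):
        p = np.linspace(0.1, 0.9, 20)
        trace = _trace_from_realized(p)
        rt = 0.1 + 0.05 * (-np.log(p))
        assert predictive_performance(trace, rt) == pytest.approx(1.0)

    def test_matches_direct_pearson_formula(self):
        """Hand-computable fixture checked against the closed-form
        Pearson correlation."""
        p = np.array([0.9, 0.5, 0.2, 0.4, 0.7, 0.3, 0.6, 0.8, 0.25, 0.35])
        rt = np.array([0.21, 0.33, 0.49, 0.40, 0.27,
                       0.43, 0.30, 0.24, 0.45, 0.41])
        x = -np.log(p)
        num = np.sum((x - x.mean()) * (rt - rt.mean()))
        den = np.sqrt(np.sum((x - x.mean()) ** 2) * np.sum((rt - rt.mean()) ** 2))
        expected = (num / den) ** 2
        assert predictive_performance(_trace_from_realized(p), rt) == \
            pytest.approx(expected, abs=1e-12)

    def test_constant_predictor_returns_sentinel_zero(self):
        trace = _trace_from_realized(np.full(20, 0.25))
        with pytest.warns(UserWarning, match="degenerate"):
            assert predictive_performance(trace, np.linspace(0.2, 0.5, 20)) == 0.0

    def test_invariant_to_affine_prediction_transforms(self, rng):
        p = rng.uniform(0.05, 0.95, 50)
        rt = rng.uniform(0.2, 0.6, 50)
        trace = _trace_from_realized(p)
        base = predictive_performance(trace, rt)
        # r^2 is computed from p alone, so any LATER params give the same
        for params in [LATERParams(5, 1, 1), LATERParams(12, 2, 0.3)]:
            assert predictive_performance(trace, rt, params=params) == \
                pytest.approx(base)

    def test_too_few_trials_rejected(self):
        with pytest.raises(MetricsError):
            predictive_performance(_trace_from_realized([0.5] * 5),
                                   np.ones(5))


class TestLearningStrength:
    def test_subtraction(self):
        assert learning_strength(0.3, 0.1) == pytest.approx(0.2)
        assert learning_strength(0.2, 0.2) == 0.0

    def test_training_summary_averages_days_5_to_8(self):
        per_day = {d: 0.01 * d for d in range(1, 9)}
        assert training_phase_learning_strength(per_day) == \
            pytest.approx(0.01 * (5 + 6 + 7 + 8) / 4)

    def test_training_summary_requires_all_days(self):
        with pytest.raises(MetricsError):
            training_phase_learning_strength({5: 0.1, 6: 0.1})


class TestCrossEntropy:
    def test_self_cross_entropy_is_entropy(self, rng):
        probs = rng.dirichlet(np.ones(4), 30)
        trace = PredictiveTrace(probs=probs, realized=probs[:, 0])
        expected = float(np.mean(-np.sum(probs * np.log(probs), axis=1)))
        assert model_cross_entropy(trace, trace) == pytest.approx(expected)

    def test_uniform_reference_gives_log4(self, rng):
        p = PredictiveTrace(probs=rng.dirichlet(np.ones(4), 10),
                            realized=np.full(10, 0.25))
        q = PredictiveTrace(probs=np.full((10, 4), 0.25),
                            realized=np.full(10, 0.25))
        assert model_cross_entropy(p, q) == pytest.approx(np.log(4))

    def test_two_trial_fixture_hand_summed(self):
        p = PredictiveTrace(probs=np.array([[0.7, 0.1, 0.1, 0.1],
                                            [0.25, 0.25, 0.25, 0.25]]),
                            realized=np.array([0.7, 0.25]))
        q = PredictiveTrace(probs=np.array([[0.4, 0.2, 0.2, 0.2],
                                            [0.1, 0.3, 0.3, 0.3]]),
                            realized=np.array([0.4, 0.1]))
        t1 = -(0.7 * np.log(0.4) + 0.3 * np.log(0.2))
        t2 = -(0.25 * np.log(0.1) + 0.75 * np.log(0.3))
        assert model_cross_entropy(p, q) == pytest.approx((t1 + t2) / 2)

    def test_gibbs_inequality(self, rng):
        for _ in range(20):
            probs_p = rng.dirichlet(np.ones(4), 15)
            probs_q = rng.dirichlet(np.ones(4), 15)
            p = PredictiveTrace(probs=probs_p, realized=probs_p[:, 0])
            q = PredictiveTrace(probs=probs_q, realized=probs_q[:, 0])
            assert model_cross_entropy(p, q) >= model_cross_entropy(p, p) - 1e-12


class TestLatentEntropy:
    def test_single_state_is_zero(self):
        model = HMMInternalModel(np.ones(1), np.ones((1, 1)),
                                 np.full((1, 4), 0.25))
        assert latent_state_entropy(model, 2000, rng=0) == 0.0

    def test_uniform_eight_state_cycle_is_three_bits(self):
        gt = build_ground_truth(make_task_rule((0, 1, 2, 3)))
        ent = latent_state_entropy(gt, 100_000, rng=0)
        assert ent == pytest.approx(3.0, abs=0.01)

    def test_two_state_analytic(self, rng):
        trans = np.array([[0.95, 0.05], [0.45, 0.55]])
        model = HMMInternalModel(np.array([0.5, 0.5]), trans,
                                 rng.dirichlet(np.ones(4), 2))
        pi = stationary_distribution(trans)
        expected = -np.sum(pi * np.log2(pi))
        ent = latent_state_entropy(model, 100_000, rng=1)
        assert ent == pytest.approx(expected, abs=0.05)

    def test_invariant_under_observation_permutation(self, rng):
        model = random_hmm(rng, 4)
        sigma = normative_permutation(make_task_rule((0, 1, 2, 3)),
                                      make_task_rule((2, 3, 1, 0)))
        a = latent_state_entropy(model, 20_000, rng=7)
        b = latent_state_entropy(permute_observations(model, sigma),
                                 20_000, rng=7)
        assert a == pytest.approx(b, abs=1e-12)


class TestRelativePerformance:
    def test_identical_models_give_zero(self):
        assert relative_performance(0.25, 0.25) == 0.0

    def test_sign_convention(self):
        assert relative_performance(0.3, 0.1) > 0


def _posterior_from_models(models, later=None):
    later = later or LATERParams(8.0, 1.0, 1.0)
    return CTPosterior(
        samples=[PosteriorSample(model=m, later=later) for m in models],
        config=SamplerConfig.desk(), seed=0, data_hash="test")


class TestTransferPermutation:
    def test_identity_only_reduces_to_plain_evaluation(self, rng, rule_pair):
        r1, r2 = rule_pair
        model = random_hmm(rng, 4)
        y = rng.integers(0, 4, 300)
        rt = rng.uniform(0.2, 0.5, 300)
        post = _posterior_from_models([model])
        from cogtom.task import IDENTITY_PERMUTATION
        table = transfer_permutation_analysis(
            post, build_ground_truth(r2), {"identity": IDENTITY_PERMUTATION},
            y, rt, np.ones(300, bool))
        direct = predictive_performance(forward_filter(model, y), rt)
        row = table[table.label == "identity"].iloc[0]
        assert row.r2 == pytest.approx(direct)

    def test_permuted_ground_truth_self_consistency(self, rule_pair):
        """Equivariance oracle: sigma*-permuted zero-noise ground truth
        scored on its own synthesized data equals the unpermuted model on
        untransformed data."""
        r1, r2 = rule_pair
        sigma = normative_permutation(r1, r2)
        gt1 = build_ground_truth(r1, 0.02, 0.02)
        gt2 = permute_observations(gt1, sigma)
        params = LATERParams(8.0, 1.0, 1.0)
        rng = np.random.default_rng(5)
        _, y1 = synthesize_from_model(gt1, 600, rng=3)
        rt1 = later_sample(forward_filter(gt1, y1).realized, params, rng)
        r2_base = predictive_performance(forward_filter(gt1, y1), rt1)
        # permuted model, permuted stimuli, same RTs
        y2 = sigma(y1)
        r2_perm = predictive_performance(forward_filter(gt2, y2), rt1)
        assert r2_perm == pytest.approx(r2_base, abs=1e-12)

    def test_empty_permutation_set_rejected(self, rng, rule_pair):
        _, r2 = rule_pair
        post = _posterior_from_models([random_hmm(rng, 3)])
        with pytest.raises(MetricsError):
            transfer_permutation_analysis(post, build_ground_truth(r2), {},
                                          rng.integers(0, 4, 50),
                                          np.ones(50), np.ones(50, bool))
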