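"""Evaluation measures: predictive performance, learning strength,
cross-entropy, latent-state entropy, relative performance and the
permutation-transfer analysis.

Predictive performance is the trial-by-trial variance explained
(Pearson's r^2) between measured RTs and the LATER point predictions of a
model's predictive trace.  Because the point prediction is affine in
``-log p_n``, the r^2 is invariant to the LATER parameters; they are
accepted for interface completeness only.

Learning strength — the r^2 of the subjective (CT) model minus that of the
first-order Markov model on the same held-out trials — quantifies acquired
sequence knowledge beyond the initial Markovian inductive bias.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .models import (DEFAULT_EPS_FLOOR, HMMInternalModel, PredictiveTrace,
                     forward_filter, permute_observations,
                     synthesize_from_model)
from .inference import CTPosterior, posterior_predictive
from .response import LATERParams


class MetricsError(ValueError):
    pass


@dataclass
class MetricsRecord:
    """One evaluated (participant, day, model) cell; tidy-table friendly."""

    participant: object
    day: int
    model: str
    metrics: dict = field(default_factory=dict)

    def rows(self):
        for metric, value in self.metrics.items():
            yield {"participant": self.participant, "day": self.day,
                   "model": self.model, "metric": metric, "value": value}


def records_to_frame(records) -> pd.DataFrame:
    rows = [row for rec in records for row in rec.rows()]
    return pd.DataFrame(rows, columns=["participant", "day", "model",
                                       "metric", "value"])


def predictive_performance(trace: PredictiveTrace, rt_s, rt_mask=None,
                           params: LATERParams | None = None) -> float:
    """Variance explained (Pearson r^2) in held-out RTs, trial by trial.

    Computed as ``corr(RT, -log p_n)^2`` over surviving trials, which by
    affine invariance equals the correlation with the LATER point
    prediction for any parameter values.
    """
    rt = np.asarray(rt_s, dtype=float)
    if rt_mask is None:
        rt_mask = np.isfinite(rt)
    rt_mask = np.asarray(rt_mask, dtype=bool)
    if len(trace) != rt.size:
        raise MetricsError("trace and RTs must be aligned")
    x = -np.log(trace.realized[rt_mask])
    r = rt[rt_mask]
    if r.size < 10:
        raise MetricsError("need at least 10 surviving trials")
    if np.std(x) < 1e-12 or np.std(r) < 1e-12:
        warnings.warn("degenerate predictor or RTs; returning r^2 = 0")
        return 0.0
    c = np.corrcoef(x, r)[0, 1]
    return float(c * c)


def learning_strength(r2_ct: float, r2_markov: float) -> float:
    """CT minus Markov variance explained on the same held-out trials."""
    return float(r2_ct) - float(r2_markov)


TRAINING_SUMMARY_DAYS = (5, 6, 7, 8)


def training_phase_learning_strength(per_day: dict) -> float:
    """Training-phase summary: learning strength averaged over days 5-8."""
    missing = [d for d in TRAINING_SUMMARY_DAYS if d not in per_day]
    if missing:
        raise MetricsError(f"missing days for the D5-D8 summary: {missing}")
    return float(np.mean([per_day[d] for d in TRAINING_SUMMARY_DAYS]))


def model_cross_entropy(trace_p: PredictiveTrace, trace_q: PredictiveTrace,
                        eps_floor: float = DEFAULT_EPS_FLOOR) -> float:
    """Mean cross-entropy (nats/trial) between two predictive traces
    computed on the same stimulus sequence; the first argument is the
    reference distribution (CT, by the package's convention)."""
    if len(trace_p) != len(trace_q):
        raise MetricsError("traces must cover the same trials")
    q = trace_q.probs
    if np.any((q <= 0) & (trace_p.probs > 0)):
        warnings.warn("zero probabilities in the comparison trace; flooring")
    q = np.maximum(q, eps_floor)
    q = q / q.sum(axis=1, keepdims=True)
    return float(np.mean(-np.sum(trace_p.probs * np.log(q), axis=1)))


def latent_state_entropy(model: HMMInternalModel, n_synth: int = 100_000,
                         rng=None) -> float:
    """Shannon entropy (bits) of latent-state occupancies under data
    synthesized from the model — a complexity measure of the internal
    model that is invariant under observation permutations."""
    if n_synth < 1000:
        raise MetricsError("n_synth must be >= 1000")
    states, _ = synthesize_from_model(model, n_synth, rng)
    occ = np.bincount(states, minlength=model.n_states).astype(float)
    occ /= occ.sum()
    nz = occ[occ > 0]
    return float(-np.sum(nz * np.log2(nz)))


def relative_performance(r2_corresponding: float,
                         r2_noncorresponding: float) -> float:
    """Difference in variance explained between the corresponding model
    (within-day, or within-task on alternation blocks) and the
    non-corresponding one.  Positive values favour the corresponding
    model, i.e. distinct internal models / successful switching."""
    return float(r2_corresponding) - float(r2_noncorresponding)


def transfer_permutation_analysis(ct_posterior_task1: CTPosterior,
                                  gt_task2: HMMInternalModel,
                                  permutations: dict,
                                  stimuli, rt_s, rt_mask,
                                  eps_floor: float = DEFAULT_EPS_FLOOR) -> pd.DataFrame:
    """Score permuted Task-1 internal models on Transfer-phase data.

    For each permutation sigma, every retained Task-1 posterior sample is
    observation-permuted, the posterior-predictive trace recomputed on the
    Transfer-phase stimuli and scored (r^2) against the Transfer-phase
    RTs.  The Task-2 Ground Truth model (the normatively permuted Task-1
    Ground Truth) is scored alongside.

    Returns a tidy frame with one row per model: columns ``label``,
    ``kind`` ("subjective" / "ground_truth") and ``r2``, plus the two
    headline contrasts as attrs: ``normative_minus_best_alternative`` and
    ``subjective_minus_ground_truth``.
    """
    if not permutations:
        raise MetricsError("empty permutation set")
    y = np.asarray(stimuli, dtype=np.int64)
    rows = []
    for label, sigma in permutations.items():
        permuted = CTPosterior(
            samples=[type(s)(model=permute_observations(s.model, sigma),
                             later=s.later)
                     for s in ct_posterior_task1.samples],
            config=ct_posterior_task1.config,
            seed=ct_posterior_task1.seed,
            data_hash=ct_posterior_task1.data_hash,
            kind=ct_posterior_task1.kind)
        trace = posterior_predictive(permuted, y, eps_floor=eps_floor)
        rows.append({"label": label, "kind": "subjective",
                     "r2": predictive_performance(trace, rt_s, rt_mask)})
    gt_trace = forward_filter(gt_task2, y, eps_floor=eps_floor)
    rows.append({"label": "ground_truth_task2", "kind": "ground_truth",
                 "r2": predictive_performance(gt_trace, rt_s, rt_mask)})
    out = pd.DataFrame(rows)
    subj = out[out.kind == "subjective"].set_index("label")["r2"]
    if "sigma*" in subj.index:
        alts = subj.drop("sigma*")
        out.attrs["normative_minus_best_alternative"] = float(
            subj["sigma*"] - (alts.max() if len(alts) else np.nan))
        out.attrs["subjective_minus_ground_truth"] = float(
            subj["sigma*"] - out[out.kind == "ground_truth"]["r2"].iloc[0])
    return out
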