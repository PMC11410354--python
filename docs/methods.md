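# Methods

`cogtom` infers the *subjective internal model* a participant entertains
about a stimulus sequence — the probabilistic model whose one-step-ahead
predictions best explain that participant's response times — and uses it
to quantify how structural knowledge transfers between related tasks.
This note documents the models, the inference machinery, the synthetic
cohort generator, and the numerical and design choices behind them.

## Task model

The Alternating Serial Response Times (ASRT) task presents one of four
stimuli per trial. After five uniform warm-up trials, each 85-trial block
repeats an eight-element cycle `d-r-d-r-d-r-d-r` ten times: deterministic
(`d`) trials follow a fixed four-element rule, random (`r`) trials are
uniform. The full design spans ten sessions: eight days on one rule
(Training), one day on a permuted rule (Transfer), and a final day
alternating the two rules in five-block runs (Alternation). A session has
25 blocks (20 on the last day).

Because each rule uses all four stimuli, the second rule is the image of
the first under a stimulus bijection; the one aligning the k-th elements
of the rules is the *normative permutation* σ\*. Applying σ\* to an
internal model's observation channels is the operational meaning of
"transferring the structure while relabelling the surface".

Two underdetermined details are configurable: the deterministic phase
restarts at each block's sixth trial (`ScheduleConfig.continue_phase`
carries it across blocks instead), and the Alternation day starts with
the first task (`alternation_starts_with`). The comparison set for the
permutation analysis defaults to σ\* plus four alternatives mapping
Task 1's cycle onto each deterministic cycle that is cyclically distinct
from both rules' cycles. Cyclic shifts of the target rule would be
near-useless alternatives — a shifted rule generates the same recurring
sequence with relabelled phases, which filtering infers from data, so a
shift-permuted model is predictively almost equivalent to the normative
one; the four remaining cyclic classes give genuinely different sequence
structures. The set is fully configurable.

## Response model

Response times follow the LATER (Linear Approach to Threshold with
Ergodic Rate) model: a decision signal starts `-log p` below a baseline
threshold θ₀ and rises at rate `r ~ Normal(μ, σ)` truncated to `r > 0`,
so `RT = (θ0 − log p)/r` seconds, where `p` is the subjective predictive
probability of the realised stimulus. The implied RT density is a scaled
reciprocal truncated normal; `later_log_density` is exact (quadrature
checks integrate it to 1 ± 1e-6). All three parameters are estimated per
participant and session; the `−log p` term anchors the scale so the
triple is identifiable. Natural logarithms throughout; seconds
internally, milliseconds at the CSV boundary.

Preprocessing applies the standard exclusion rules in a fixed precedence:
warm-up trials, incorrect responses, missing RTs, RTs above 5000 ms, RTs
above the participant's session mean + 3 SD (computed after the previous
rules), and RTs below 180 ms last. Excluded trials stay in the sequence —
they condition the sequence model; only their RT likelihood terms drop.
The mean+3sd statistic is computed per participant-session over trials
surviving the earlier rules; on well-behaved data a second pass removes
nothing (idempotence is tested on a synthetic session).

## Internal models

* **Markov** — first-order: the prediction is a row of a 4×4 transition
  matrix indexed by the previous stimulus. This is the initial inductive
  bias humans bring to sequential tasks.
* **Ground Truth** — the true 8-state generative HMM of the ASRT
  sequence (pattern and random states alternating), with two mixing
  parameters ε_d, ε_e that blur the dynamics and the deterministic
  emissions toward uniform. The noise enters as uniform mixing
  (`(1−ε)·pure + ε·uniform`); a Dirichlet-smoothing formulation would be
  an alternative, but mixing is transparent and two-parameter. Per
  participant, (ε_d, ε_e) are fitted by grid search (default 0–0.5, step
  0.01 in the library; 0.05 in the desk pipeline) maximising the
  filtered-RT likelihood with LATER parameters profiled out at each grid
  point (normal MLE of the implied rates plus a bounded scalar search
  over θ₀; the truncation correction is evaluated at the optimum, exact
  whenever μ/σ is large, which holds in the response-time regime).
* **Cognitive Tomography (CT)** — an HDP-HMM (infinite HMM) over the
  four stimuli whose parameters are constrained by the RT likelihood.
  Posterior samples are finite HMMs; predictive probabilities come from
  exact forward filtering, numerically stabilised by per-step
  normalisation. A configurable emission floor (1e-6) keeps filtering
  defined when a deterministic model meets an off-pattern stimulus; the
  realised predictive probability is floored at the same value.

The initial state distribution of constructed models is uniform; sampled
models carry their own initial-distribution draw.

## Inference

The posterior over internal models is sampled by chains that interleave
two move types per sweep:

1. **Beam (slice) move.** Auxiliary slice variables truncate the
   infinite transition structure so an exact forward-filter /
   backward-sample step updates the latent state path; stick weights,
   transition pseudocounts (Chinese-restaurant tables) and the two DP
   concentrations (Gamma(1,1) hyperpriors, standard auxiliary-variable
   updates) are then refreshed. Unused states are pruned each sweep. The
   represented state set is capped (default 12; the true ASRT structure
   has 8 states) — at small sweep budgets an uncapped sampler
   accumulates weakly-constrained states whose wandering emissions add
   noise to the predictive trace.
2. **HMC block.** Hamiltonian Monte Carlo (default 10 leapfrog steps,
   step size adapted toward 0.65 acceptance during the first half of the
   run) updates the transition rows and emission rows
   (softmax-reparameterised, with a small Gaussian gauge term pinning
   the redundant direction) and the LATER parameters (log space,
   weakly-informative log-normal priors). The target is

       log p(model) + stim_weight · log p(stimuli, states | model)
                    + rt_weight · Σ_n log p(RT_n | p_n)

   with gradients backpropagated through the filtering recursion
   (verified against central differences to 1e-8 relative error).

**The stimulus-likelihood weight defaults to zero**: internal models are
inferred from response times alone, with the stimulus sequence acting
only as the filtering input. This is deliberate. A subjective model may
deviate arbitrarily from the true task statistics — that deviation is
the object of measurement — and with the stimulus likelihood at full
weight the posterior provably prefers the task-structure model over the
generative subjective model on first-order synthetic data (the stimulus
term's advantage, ~0.6 nats/trial, outweighs the RT term's). The beam
move still conditions on the stimuli; it serves as the scaffolding that
adapts the state count, and is an approximation once HMC has moved the
transition rows. Setting `stim_weight > 0` recovers a joint-likelihood
sampler.

Two warm-up devices keep desk-scale runs honest rather than
burn-in-dominated, both validated by parameter-recovery measurements:
chains start with a few rounds of beam moves plus short Adam ascents to
the posterior mode, and HMC uses a diagonal block inverse-mass
(transition / emission / LATER blocks) estimated from the warm-start
gradient second moments. Without the preconditioner the CT fit trails a
dedicated first-order fit by ~0.03 in held-out r² on first-order data;
with it the gap is below 0.01.

The **Markov baseline** is fitted with the same HMC machinery, the
latent structure fixed to the observed stimulus chain (Dirichlet(1) rows,
bigram counts entering at `stim_weight`).

Two built-in scales share one code path: `paper` (4 chains × 1600 sweeps
× 30 HMC updates, last 30 samples per chain retained — 120 samples) and
`desk` (2 × 200 × 10, tail 20 — 40 samples). All shipped tests run at
desk scale. Posterior predictive probabilities are equal-weight averages
of the per-sample forward-filtered predictive vectors on the probability
scale. Every fit is reproducible from (config, seed, data); all
randomness flows from one `numpy` generator per chain, and the numba
kernels draw nothing themselves.

No convergence diagnostics gate the pipeline (fixed sweep counts);
acceptance rates, state counts and final log-posteriors are recorded in
the posterior's diagnostics for inspection.

## Evaluation measures

* **Predictive performance** — trial-by-trial variance explained:
  squared Pearson correlation between held-out RTs and the LATER point
  prediction, equivalently `corr(RT, −log p_n)²` by affine invariance.
  Degenerate cases (constant predictor or RTs) return 0 with a warning.
  The default protocol fits on the last 13 blocks of a 25-block session
  and evaluates on the first 12; the Alternation day is scored per
  five-block run.
* **Learning strength** — CT r² minus Markov r² on the same held-out
  trials; the Training-phase summary averages days 5–8.
* **Cross-entropy** between two models' predictive traces, in nats per
  trial, with the CT trace as the reference distribution (the direction
  and units are a package convention, recorded in output metadata).
* **Latent-state entropy** — Shannon entropy (bits) of state occupancies
  under data synthesized from the model (default 10⁵ trials; the desk
  pipeline uses 2×10⁴ over a posterior-sample subset). Invariant under
  observation permutations, which the tests assert exactly.
* **Relative performance** — within-day minus across-days (or
  within-task minus across-tasks) r², positive when the corresponding
  model wins.
* **Permutation-transfer analysis** — every retained Task-1 posterior
  sample is observation-permuted by each candidate σ, re-filtered on the
  Transfer-day stimuli and scored against the Transfer-day RTs; the
  σ\*-permuted Ground Truth is scored alongside.

## Synthetic cohorts

The generator produces trial tables with known generative internal
models so the whole pipeline is testable by parameter recovery. Its
defaults are the study conditions: 85-trial blocks, 25/20-block
sessions, 11% incorrect responses, and 1% + 1% long/short contaminant
RTs (uniform on 1–6 s and 50–180 ms) to exercise both threshold filters.

Each participant owns a LATER parameter triple, an idiosyncratic
first-order bias (transition rows Dirichlet(20) around uniform,
calibrated so the Day-1 first-order model explains ~0.1–0.2 of RT
variance, the low end of plausible day-one performance), a noisy Ground
Truth component (ε ~ U(0.02, 0.10)), and a logistic learning trajectory
`w(d) = w_max / (1 + exp(−(d − d₀)/τ))` giving the Ground-Truth
component's weight on day `d` — any monotone two-parameter family would
do. The LATER ranges (θ₀ ∈ 1.2–1.45, μ ∈ 7.2–9.5 s⁻¹) are pinned by two
facts about adult ASRT performance: first-order-driven sessions average
≈370 ms and fully-learned sessions ≈280 ms. A consequence worth knowing:
well-predicted trials brush the 180 ms exclusion floor, so later
sessions lose a few percent of genuinely fast trials to that filter —
real cohorts show the same.

A participant's per-trial predictive probability is the fixed-weight
mixture of the components' forward-filtered predictions. (The
block-diagonal single-HMM composition `blend_models` realises the same
first-trial mixture and is what the rest of the package consumes as a
model object, but *filtering* it lets the posterior drift to the better
component within a block — a w=0.2 learner would look fully trained by
mid-block. Mixing the traces keeps the blend weight pinned at `w(d)`,
which is what partial learning means here.)

Transfer types: `transfer` (Day-9 components are the σ\*-permuted Day-8
components), `retainer` (Day-9 model identical to Day-8), `non-learner`
(first-order model throughout). Day 10 uses the Day-8 mixture on Task-1
runs and the Day-9 mixture on Task-2 runs.

What the generator does **not** emulate: fatigue and reactive
inhibition, error-trial RT dynamics (errors are flagged at a constant
rate, their RTs drawn from the same model), session-break consolidation,
and any drift of the internal model *within* a day. Passing recovery
tests therefore show that the inference machinery recovers the models
this generative family produces — not that human data satisfy the
family's assumptions.

## Problem sizes in the shipped tests

The test suite runs everything at desk scale: recovery uses 2000-trial
sessions (a day's 25 blocks) and 13-block fits, six σ\*-transfer
participants plus two no-switch controls for the switching and
permutation analyses, and three seeds for the stochastic recovery
checks. The no-switch control compares fits of consecutive same-task
days (7 and 8) of retainer-type participants, whose internal model is
essentially unchanged between those days; its bound (|mean relative
performance| < 0.05) is three times the r²-difference sampling noise at
these sizes. Inferring a *retained* rule-1 model from rule-2 data (the
literal Day-9 retainer scenario) is close to unidentifiable at desk
scale — Day-9 stimuli rarely exercise the retained structure — and is
not used as a control.

## Known limitations

* The beam scaffolding conditions on stimuli while the HMC target may
  not (stim_weight = 0); the combined kernel is a pragmatic hybrid, not
  an exact Gibbs sampler for either target. Recovery studies, not
  detailed balance, justify it.
* Conjugate HDP bookkeeping treats the HMC-updated transition rows as if
  they were the conjugate draw; concentrations α₀, γ are therefore
  calibrated only approximately.
* The ground-truth ε grid search profiles LATER parameters with an
  untruncated-normal approximation, exact only for μ/σ ≫ 1.
* `fit_later_mle` and the ε grid are point estimates; no uncertainty is
  propagated for the Ground Truth baseline.
* Desk-scale CT retains 40 posterior samples; r² estimates carry ~0.02
  Monte-Carlo noise, visible in per-participant learning strengths.
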