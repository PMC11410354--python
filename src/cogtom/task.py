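"""ASRT task structure: rules, blocks, training schedules, stimulus permutations.

The Alternating Serial Response Times (ASRT) task presents one of four
stimuli per trial.  After five warm-up trials, each block cycles through an
eight-element template ``d-r-d-r-d-r-d-r``: deterministic (``pattern``)
trials carry the next element of a fixed four-element rule, random trials
are drawn uniformly from the four stimuli.  A ten-day design exposes
participants to one rule for eight days (Training), a permuted rule on day
nine (Transfer) and both rules in alternating five-block runs on day ten
(Alternation).

Trial tables are plain :class:`pandas.DataFrame` objects with the columns
listed in :data:`TRIAL_COLUMNS`; they round-trip through CSV via
:func:`write_trials` / :func:`read_trials`.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

N_STIMULI = 4
TRIALS_PER_BLOCK = 85
N_WARMUP = 5
CYCLE_LENGTH = 8          # d-r-d-r-d-r-d-r
CYCLES_PER_BLOCK = 10

TRIAL_COLUMNS = [
    "participant", "day", "block", "trial", "stimulus",
    "trial_type", "task_label", "rt_ms", "correct",
]


class TaskError(ValueError):
    """Invalid task rule, permutation or schedule configuration."""


@dataclass(frozen=True)
class TaskRule:
    """Deterministic component of an ASRT sequence: an ordered 4-tuple of
    distinct stimulus ids (``d1..d4``)."""

    pattern: tuple[int, int, int, int]

    def __post_init__(self) -> None:
        pat = tuple(int(p) for p in self.pattern)
        object.__setattr__(self, "pattern", pat)
        if len(pat) != N_STIMULI or sorted(pat) != list(range(N_STIMULI)):
            raise TaskError(
                f"task rule must be an ordering of 0..3, got {pat!r}")

    def __getitem__(self, k: int) -> int:
        return self.pattern[k % N_STIMULI]


def make_task_rule(pattern) -> TaskRule:
    """Validate and build a :class:`TaskRule` from any 4-sequence of ids."""
    return TaskRule(tuple(pattern))


@dataclass(frozen=True)
class StimulusPermutation:
    """A bijection on stimulus ids; ``mapping[y]`` is the image of ``y``."""

    mapping: tuple[int, int, int, int]

    def __post_init__(self) -> None:
        m = tuple(int(v) for v in self.mapping)
        object.__setattr__(self, "mapping", m)
        if sorted(m) != list(range(N_STIMULI)):
            raise TaskError(f"not a bijection on 0..3: {m!r}")

    def __call__(self, y):
        arr = np.asarray(self.mapping)
        return arr[y] if np.ndim(y) else int(arr[y])

    def inverse(self) -> "StimulusPermutation":
        inv = np.empty(N_STIMULI, dtype=int)
        inv[list(self.mapping)] = np.arange(N_STIMULI)
        return StimulusPermutation(tuple(inv))

    def compose(self, other: "StimulusPermutation") -> "StimulusPermutation":
        """Return ``self ∘ other`` (apply ``other`` first)."""
        return StimulusPermutation(tuple(self(other(y)) for y in range(N_STIMULI)))

    @property
    def is_identity(self) -> bool:
        return self.mapping == tuple(range(N_STIMULI))

    def apply_to_rule(self, rule: TaskRule) -> TaskRule:
        return TaskRule(tuple(self(y) for y in rule.pattern))


IDENTITY_PERMUTATION = StimulusPermutation((0, 1, 2, 3))


def normative_permutation(rule1: TaskRule, rule2: TaskRule,
                          offset: int = 0) -> StimulusPermutation:
    """Stimulus relabelling mapping ``rule1`` onto ``rule2``.

    ``offset=0`` gives the normative permutation sigma*, which sends the
    k-th element of the first rule onto the k-th element of the second
    (``sigma(rule1[k]) = rule2[k]``); nonzero offsets cyclically shift the
    target rule first.  Because each rule uses all four ids, the result is
    always a bijection.
    """
    mapping = np.empty(N_STIMULI, dtype=int)
    for k in range(N_STIMULI):
        mapping[rule1.pattern[k]] = rule2.pattern[(k + offset) % N_STIMULI]
    return StimulusPermutation(tuple(mapping))


def _cyclic_class(pattern: tuple) -> frozenset:
    return frozenset(tuple(pattern[i:] + pattern[:i]) for i in range(len(pattern)))


def alternative_permutations(rule1: TaskRule, rule2: TaskRule) -> dict[str, StimulusPermutation]:
    """Default comparison set for the permutation-transfer analysis.

    The normative permutation (``sigma*``) plus four alternatives that map
    the first rule's deterministic cycle onto deterministic cycles which
    are *cyclically distinct* from both rules' cycles.  Cyclic shifts of
    the target rule would be near-equivalent to ``sigma*`` — a shifted
    rule generates the same recurring sequence with relabelled phases,
    which filtering infers anyway — so they make degenerate alternatives;
    the four remaining cyclic classes of 4-element cycles give genuinely
    different sequence structures.
    """
    perms = {"sigma*": normative_permutation(rule1, rule2, 0)}
    excluded = {_cyclic_class(rule1.pattern), _cyclic_class(rule2.pattern)}
    for cand in itertools.permutations(range(N_STIMULI)):
        if cand[0] != 0:                      # one representative per class
            continue
        if _cyclic_class(cand) in excluded:
            continue
        label = "alt" + "".join(map(str, cand))
        perms[label] = normative_permutation(rule1, TaskRule(cand), 0)
        if len(perms) == 5:
            break
    return perms


@dataclass(frozen=True)
class ScheduleConfig:
    """Block/session structure of the ten-day design."""

    n_days: int = 10
    blocks_per_day: int = 25        # days 1..9
    day10_blocks: int = 20
    transfer_day: int = 9           # first (only) day on rule2 before alternation
    run_length: int = 5             # alternation run length on the last day
    alternation_starts_with: str = "task1"
    continue_phase: bool = False    # carry the pattern phase across blocks

    def __post_init__(self) -> None:
        if self.alternation_starts_with not in ("task1", "task2"):
            raise TaskError("alternation_starts_with must be 'task1' or 'task2'")
        if self.run_length < 1:
            raise TaskError("run_length must be >= 1")


@dataclass
class ExperimentSchedule:
    """Per-block task assignment plus the generated trial table."""

    config: ScheduleConfig
    rule1: TaskRule
    rule2: TaskRule
    blocks: pd.DataFrame     # columns: day, block, task_label
    trials: pd.DataFrame     # TRIAL_COLUMNS

    @property
    def n_blocks(self) -> int:
        return len(self.blocks)


def generate_block(rule: TaskRule, rng, start_phase: int = 0):
    """Generate one 85-trial block.

    Returns ``(stimuli, trial_types, next_phase)`` where ``stimuli`` is an
    int array of length 85, ``trial_types`` the matching array of
    ``{"warmup", "pattern", "random"}`` labels and ``next_phase`` the pattern
    phase to use if the phase continues into the following block.

    The first five trials are uniform random warm-up; trials 6, 8, ..., 84
    (1-based) are pattern trials carrying the rule's elements in order, the
    interleaved trials are uniform random.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    if not isinstance(rule, TaskRule):
        rule = make_task_rule(rule)
    stimuli = np.empty(TRIALS_PER_BLOCK, dtype=np.int64)
    types = np.empty(TRIALS_PER_BLOCK, dtype=object)
    stimuli[:N_WARMUP] = rng.integers(0, N_STIMULI, size=N_WARMUP)
    types[:N_WARMUP] = "warmup"
    phase = start_phase % N_STIMULI
    for i in range(N_WARMUP, TRIALS_PER_BLOCK):
        # post-warmup position 0,1,2,... : even = deterministic, odd = random
        if (i - N_WARMUP) % 2 == 0:
            stimuli[i] = rule[phase]
            types[i] = "pattern"
            phase = (phase + 1) % N_STIMULI
        else:
            stimuli[i] = rng.integers(0, N_STIMULI)
            types[i] = "random"
    return stimuli, types, phase


def generate_schedule(rule1: TaskRule, rule2: TaskRule,
                      config: ScheduleConfig | None = None,
                      rng=None, participant=0) -> ExperimentSchedule:
    """Generate the full experiment: stimuli for every block of every day.

    Days ``1..transfer_day-1`` use ``rule1`` (task1), the transfer day uses
    ``rule2`` (task2), and the final day alternates the two rules in runs of
    ``config.run_length`` blocks.  ``rt_ms`` and ``correct`` are left empty;
    they are filled by a behaving agent (human or synthetic).
    """
    config = config or ScheduleConfig()
    if not isinstance(rule1, TaskRule):
        rule1 = make_task_rule(rule1)
    if not isinstance(rule2, TaskRule):
        rule2 = make_task_rule(rule2)
    if rule1 == rule2:
        raise TaskError("rule1 and rule2 must differ (transfer undefined)")
    rng = np.random.default_rng(rng)

    block_rows = []
    trial_frames = []
    phase = {"task1": 0, "task2": 0}
    first, second = (("task1", "task2")
                     if config.alternation_starts_with == "task1"
                     else ("task2", "task1"))
    for day in range(1, config.n_days + 1):
        if day == config.n_days:
            n_blocks = config.day10_blocks
            labels = [first if (b // config.run_length) % 2 == 0 else second
                      for b in range(n_blocks)]
        else:
            n_blocks = config.blocks_per_day
            labels = ["task2" if day == config.transfer_day else "task1"] * n_blocks
        for b, label in enumerate(labels, start=1):
            rule = rule1 if label == "task1" else rule2
            start = phase[label] if config.continue_phase else 0
            stimuli, types, next_phase = generate_block(rule, rng, start)
            phase[label] = next_phase
            block_rows.append({"day": day, "block": b, "task_label": label})
            trial_frames.append(pd.DataFrame({
                "participant": participant,
                "day": day,
                "block": b,
                "trial": np.arange(1, TRIALS_PER_BLOCK + 1),
                "stimulus": stimuli,
                "trial_type": types,
                "task_label": label,
                "rt_ms": np.nan,
                "correct": pd.array([pd.NA] * TRIALS_PER_BLOCK, dtype="boolean"),
            }))
    blocks = pd.DataFrame(block_rows)
    trials = pd.concat(trial_frames, ignore_index=True)[TRIAL_COLUMNS]
    return ExperimentSchedule(config=config, rule1=rule1, rule2=rule2,
                              blocks=blocks, trials=trials)


def write_trials(trials: pd.DataFrame, path) -> None:
    """Write a trial table to CSV; missing rt/correct become empty fields."""
    out = trials.copy()
    if "correct" in out:
        out["correct"] = out["correct"].map(
            lambda v: "" if pd.isna(v) else int(bool(v)))
    out.to_csv(path, index=False, columns=TRIAL_COLUMNS)


def read_trials(path) -> pd.DataFrame:
    """Read a trial table written by :func:`write_trials`."""
    df = pd.read_csv(path, dtype={"trial_type": str, "task_label": str})
    df["correct"] = pd.array(
        [pd.NA if pd.isna(v) else bool(v) for v in df["correct"]], dtype="boolean")
    return df[TRIAL_COLUMNS]
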