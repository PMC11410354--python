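"""Orchestration: named analysis stages over a cohort directory.

Each stage reproduces one of the package's headline analyses over a
directory of trial CSVs (real or synthetic): per-day learning curves,
transfer-phase learning strength, within/across-day model switching,
alternation-phase switching, and the permutation-transfer analysis.  A
stage preprocesses RTs, fits the required models per participant and day,
computes its metrics and writes a tidy CSV plus a JSON run manifest from
which the run is auditable and reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import pathlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .inference import (CTPosterior, PosteriorSample, SamplerConfig, fit_ct,
                        fit_markov, posterior_predictive)
from .metrics import (MetricsRecord, latent_state_entropy, learning_strength,
                      model_cross_entropy, predictive_performance,
                      records_to_frame, relative_performance,
                      transfer_permutation_analysis)
from .models import (HMMInternalModel, MarkovInternalModel,
                     build_ground_truth, forward_filter)
from .response import LATERParams, fit_later_mle, later_log_density, preprocess_rts
from .task import TaskRule, alternative_permutations, read_trials

log = logging.getLogger("cogtom")

STAGES = ("training_curves", "transfer", "model_switch", "alternation",
          "permutation_transfer")

SCHEMA_VERSION = 1


class PipelineError(RuntimeError):
    pass


class ManifestError(PipelineError):
    pass


# ---------------------------------------------------------------------------
# ground-truth noise fitting

def fit_ground_truth_noise(rule: TaskRule, stimuli, rt_s, rt_mask,
                           grid_max: float = 0.5, grid_step: float = 0.01):
    """Fit the Ground Truth model's two noise parameters to a participant.

    Grid search over (dyn_noise, emis_noise) maximising the filtered-RT
    likelihood, with LATER parameters profiled out at each grid point.
    Returns ``(model, later_params, best_loglik)``.
    """
    y = np.asarray(stimuli, dtype=np.int64)
    rt = np.asarray(rt_s, dtype=float)
    mask = np.asarray(rt_mask, dtype=bool)
    grid = np.arange(0.0, grid_max + 1e-9, grid_step)
    best = (-np.inf, None, None)
    for eps_d in grid:
        for eps_e in grid:
            model = build_ground_truth(rule, float(eps_d), float(eps_e))
            trace = forward_filter(model, y)
            later = fit_later_mle(rt[mask], trace.realized[mask])
            ll = float(np.sum(later_log_density(rt[mask],
                                                trace.realized[mask], later)))
            if ll > best[0]:
                best = (ll, model, later)
    return best[1], best[2], best[0]


# ---------------------------------------------------------------------------
# serialization round-trips

def save_model(model, path) -> None:
    model.to_json(path)


def load_model(path) -> HMMInternalModel:
    return HMMInternalModel.from_json(path)


def save_posterior(posterior: CTPosterior, path) -> None:
    """Serialize a posterior to a single ``.npz`` archive (arrays plus a
    JSON manifest); round-trips preserve every matrix bit-exactly."""
    arrays = {}
    meta = {"schema": SCHEMA_VERSION, "kind": posterior.kind,
            "seed": posterior.seed, "data_hash": posterior.data_hash,
            "n_samples": len(posterior.samples),
            "config": dataclasses.asdict(posterior.config)}
    for i, s in enumerate(posterior.samples):
        if isinstance(s.model, MarkovInternalModel):
            arrays[f"s{i}_transition"] = s.model.transition
            arrays[f"s{i}_initial"] = s.model.initial
        else:
            arrays[f"s{i}_initial"] = s.model.initial
            arrays[f"s{i}_transition"] = s.model.transition
            arrays[f"s{i}_emission"] = s.model.emission
        arrays[f"s{i}_later"] = np.array([s.later.mu, s.later.sigma,
                                          s.later.theta0])
        arrays[f"s{i}_hyper"] = np.array([s.alpha0, s.gamma])
    arrays["_meta"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_posterior(path) -> CTPosterior:
    with np.load(path) as data:
        meta = json.loads(bytes(data["_meta"]).decode())
        if meta.get("schema") != SCHEMA_VERSION:
            raise ManifestError(
                f"posterior schema {meta.get('schema')!r} != {SCHEMA_VERSION}")
        samples = []
        for i in range(meta["n_samples"]):
            later = LATERParams(*data[f"s{i}_later"])
            alpha0, gamma = data[f"s{i}_hyper"]
            if meta["kind"] == "markov":
                model = MarkovInternalModel(
                    transition=data[f"s{i}_transition"],
                    initial=data[f"s{i}_initial"])
            else:
                model = HMMInternalModel(
                    initial=data[f"s{i}_initial"],
                    transition=data[f"s{i}_transition"],
                    emission=data[f"s{i}_emission"])
            samples.append(PosteriorSample(model=model, later=later,
                                           alpha0=float(alpha0),
                                           gamma=float(gamma)))
    cfg = SamplerConfig(**{k: (tuple(tuple(x) if isinstance(x, list) else x
                                     for x in v) if isinstance(v, list) else v)
                           for k, v in meta["config"].items()})
    return CTPosterior(samples=samples, config=cfg, seed=meta["seed"],
                       data_hash=meta["data_hash"], kind=meta["kind"])


@dataclass
class RunManifest:
    """Audit record of a stage run; rerunning an identical manifest
    reproduces identical outputs for deterministic stages."""

    stage: str
    seed: int
    config: dict
    inputs: dict = field(default_factory=dict)    # path -> sha256
    outputs: list = field(default_factory=list)
    schema: int = SCHEMA_VERSION
    version: str = __version__

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def load(cls, path) -> "RunManifest":
        try:
            with open(path) as fh:
                payload = json.load(fh)
        except (OSError, json.JSONDecodeError) as exc:
            raise ManifestError(f"unreadable manifest {path}: {exc}") from exc
        if payload.get("schema") != SCHEMA_VERSION:
            raise ManifestError(
                f"manifest schema {payload.get('schema')!r} != {SCHEMA_VERSION}")
        return cls(**payload)


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


# ---------------------------------------------------------------------------
# stage machinery

@dataclass(frozen=True)
class PipelineConfig:
    """Knobs shared by all stages."""

    scale: str = "desk"                 # "desk" or "paper"
    seed: int = 0
    sampler: SamplerConfig | None = None  # overrides scale when given
    rule1: TaskRule | None = None       # read from the cohort manifest if None
    rule2: TaskRule | None = None
    eval_blocks: int = 12               # early blocks used for evaluation
    days: tuple | None = None           # restrict per-day stages
    participants: tuple | None = None
    gt_grid_step: float = 0.05          # ground-truth noise grid
    gt_grid_max: float = 0.5
    entropy_synth: int = 20_000
    entropy_samples: int = 8            # posterior samples entering entropy

    def sampler_config(self) -> SamplerConfig:
        if self.sampler is not None:
            return self.sampler
        return (SamplerConfig.paper() if self.scale == "paper"
                else SamplerConfig.desk())


def _load_cohort(cohort_dir, config: PipelineConfig):
    cohort_dir = pathlib.Path(cohort_dir)
    csvs = sorted(p for p in cohort_dir.glob("*.csv"))
    if not csvs:
        raise PipelineError(f"no trial CSVs in {cohort_dir}")
    tables, hashes = {}, {}
    for p in csvs:
        df = read_trials(p)
        pid = df["participant"].iloc[0]
        if config.participants and str(pid) not in set(map(str, config.participants)):
            continue
        tables[pid] = df
        hashes[str(p)] = _sha256(p)
    manifest_path = cohort_dir / "ground_truth.json"
    rules = (config.rule1, config.rule2)
    if (rules[0] is None or rules[1] is None) and manifest_path.exists():
        with open(manifest_path) as fh:
            gt = json.load(fh)
        rules = (TaskRule(tuple(gt["rule1"])), TaskRule(tuple(gt["rule2"])))
        hashes[str(manifest_path)] = _sha256(manifest_path)
    return tables, rules, hashes


def _day_arrays(df: pd.DataFrame, day: int, blocks=None):
    """Stimuli, RTs (s) and likelihood mask for one session (or a block
    subset); excluded trials stay in the sequence with mask False."""
    sub = df[df["day"] == day]
    if blocks is not None:
        sub = sub[sub["block"].isin(list(blocks))]
    if len(sub) == 0:
        raise PipelineError(f"no trials for day {day}")
    sub = sub.sort_values(["block", "trial"])
    y = sub["stimulus"].to_numpy(dtype=np.int64)
    rt_s = pd.to_numeric(sub["rt_ms"], errors="coerce").to_numpy() / 1000.0
    mask = sub["rt_keep"].to_numpy(dtype=bool)
    return y, np.where(mask, rt_s, 1.0), mask


def _require_days(df, days, stage):
    have = set(df["day"].unique())
    missing = sorted(set(days) - have)
    if missing:
        raise PipelineError(
            f"stage {stage} needs day(s) {missing} which are absent")


def _split_blocks(df, day, eval_blocks):
    blocks = sorted(df.loc[df["day"] == day, "block"].unique())
    return blocks[:eval_blocks], blocks[eval_blocks:]


def _fit_day(df, day, blocks, kind, cfg: PipelineConfig, seed_tag: int):
    y, rt, mask = _day_arrays(df, day, blocks)
    fitter = fit_ct if kind == "ct" else fit_markov
    return fitter(y, rt, mask, cfg.sampler_config(),
                  seed=int((cfg.seed * 1009 + seed_tag) % (2 ** 31)))


def _score(posterior, df, day, blocks):
    y, rt, mask = _day_arrays(df, day, blocks)
    trace = posterior_predictive(posterior, y)
    return predictive_performance(trace, rt, mask), trace


def run_stage(stage: str, cohort_dir, config: PipelineConfig | None = None,
              out_dir=None):
    """Execute one named analysis stage over a cohort directory.

    Writes ``<stage>_metrics.csv`` and ``<stage>_manifest.json`` into
    ``out_dir`` (defaults to ``<cohort_dir>/results``) and returns the
    tidy metrics frame.
    """
    if stage not in STAGES:
        raise PipelineError(f"unknown stage {stage!r}; choose from {STAGES}")
    config = config or PipelineConfig()
    cohort_dir = pathlib.Path(cohort_dir)
    out_dir = pathlib.Path(out_dir) if out_dir else cohort_dir / "results"
    out_dir.mkdir(parents=True, exist_ok=True)
    tables, (rule1, rule2), hashes = _load_cohort(cohort_dir, config)
    log.info("stage %s: %d participants, scale=%s seed=%d",
             stage, len(tables), config.scale, config.seed)

    records = []
    for pidx, (pid, raw) in enumerate(sorted(tables.items(),
                                             key=lambda kv: str(kv[0]))):
        df, report = preprocess_rts(raw)
        log.info("participant %s: %d/%d trials survive filtering (%s)",
                 pid, report.n_surviving, report.n_total, report.counts)
        if stage == "training_curves":
            days = config.days or tuple(
                d for d in sorted(df["day"].unique()) if d <= 8)
            records += _stage_training_curves(pid, pidx, df, rule1, config, days)
        elif stage == "transfer":
            days = config.days or (1, 9)
            _require_days(df, days, stage)
            records += _stage_transfer(pid, pidx, df, config, days)
        elif stage == "model_switch":
            _require_days(df, (8, 9), stage)
            records += _stage_model_switch(pid, pidx, df, config)
        elif stage == "alternation":
            _require_days(df, (8, 9, 10), stage)
            records += _stage_alternation(pid, pidx, df, config)
        elif stage == "permutation_transfer":
            _require_days(df, (8, 9), stage)
            records += _stage_permutation_transfer(pid, pidx, df, rule1,
                                                   rule2, config)
    frame = records_to_frame(records)
    csv_path = out_dir / f"{stage}_metrics.csv"
    frame.to_csv(csv_path, index=False)
    manifest = RunManifest(stage=stage, seed=config.seed,
                           config=_config_snapshot(config),
                           inputs=hashes, outputs=[str(csv_path)])
    manifest.save(out_dir / f"{stage}_manifest.json")
    return frame


def _config_snapshot(config: PipelineConfig) -> dict:
    snap = dataclasses.asdict(config)
    for key in ("rule1", "rule2"):
        if snap[key] is not None:
            snap[key] = list(snap[key]["pattern"])
    return snap


def _stage_training_curves(pid, pidx, df, rule1, config, days):
    records = []
    for day in days:
        eval_blocks, fit_blocks = _split_blocks(df, day, config.eval_blocks)
        ct = _fit_day(df, day, fit_blocks, "ct", config, 10 * pidx + day)
        mk = _fit_day(df, day, fit_blocks, "markov", config, 10 * pidx + day)
        r2_ct, ct_trace = _score(ct, df, day, eval_blocks)
        r2_mk, mk_trace = _score(mk, df, day, eval_blocks)
        y_fit, rt_fit, mask_fit = _day_arrays(df, day, fit_blocks)
        gt_model, _, _ = fit_ground_truth_noise(
            rule1, y_fit, rt_fit, mask_fit,
            grid_max=config.gt_grid_max, grid_step=config.gt_grid_step)
        y_ev, rt_ev, mask_ev = _day_arrays(df, day, eval_blocks)
        r2_gt = predictive_performance(forward_filter(gt_model, y_ev),
                                       rt_ev, mask_ev)
        ent_rng = np.random.default_rng([config.seed, pidx, day])
        thin = max(1, len(ct.samples) // config.entropy_samples)
        ent = float(np.mean([
            latent_state_entropy(s.model, config.entropy_synth, ent_rng)
            for s in ct.samples[::thin]]))
        records.append(MetricsRecord(pid, day, "ct", {
            "r2": r2_ct,
            "learning_strength": learning_strength(r2_ct, r2_mk),
            "cross_entropy_vs_markov": model_cross_entropy(ct_trace, mk_trace),
            "latent_entropy_bits": ent}))
        records.append(MetricsRecord(pid, day, "markov", {"r2": r2_mk}))
        records.append(MetricsRecord(pid, day, "ground_truth", {"r2": r2_gt}))
    return records


def _stage_transfer(pid, pidx, df, config, days):
    records = []
    for day in days:
        eval_blocks, fit_blocks = _split_blocks(df, day, config.eval_blocks)
        ct = _fit_day(df, day, fit_blocks, "ct", config, 100 * pidx + day)
        mk = _fit_day(df, day, fit_blocks, "markov", config, 100 * pidx + day)
        r2_ct, _ = _score(ct, df, day, eval_blocks)
        r2_mk, _ = _score(mk, df, day, eval_blocks)
        records.append(MetricsRecord(pid, day, "ct", {
            "r2": r2_ct, "learning_strength": learning_strength(r2_ct, r2_mk)}))
        records.append(MetricsRecord(pid, day, "markov", {"r2": r2_mk}))
    return records


def _stage_model_switch(pid, pidx, df, config):
    fits, evals = {}, {}
    for day in (8, 9):
        eval_blocks, fit_blocks = _split_blocks(df, day, config.eval_blocks)
        fits[day] = _fit_day(df, day, fit_blocks, "ct", config,
                             200 * pidx + day)
        evals[day] = eval_blocks
    records = []
    for eval_day in (8, 9):
        other = 9 if eval_day == 8 else 8
        r2_within, _ = _score(fits[eval_day], df, eval_day, evals[eval_day])
        r2_across, _ = _score(fits[other], df, eval_day, evals[eval_day])
        records.append(MetricsRecord(pid, eval_day, "ct", {
            "r2_within_day": r2_within,
            "r2_across_days": r2_across,
            "relative_performance": relative_performance(r2_within, r2_across),
        }))
    return records


def _stage_alternation(pid, pidx, df, config):
    fits = {}
    for day in (8, 9):
        _, fit_blocks = _split_blocks(df, day, config.eval_blocks)
        fits[day] = _fit_day(df, day, fit_blocks, "ct", config,
                             300 * pidx + day)
    day10 = df[df["day"] == 10]
    records = []
    for label, sub in day10.groupby("task_label"):
        blocks = sorted(sub["block"].unique())
        # runs of consecutive blocks under one rule
        runs, current = [], [blocks[0]]
        for b in blocks[1:]:
            if b == current[-1] + 1:
                current.append(b)
            else:
                runs.append(current)
                current = [b]
        runs.append(current)
        for run in runs:
            r2_task1, _ = _score(fits[8], df, 10, run)
            r2_task2, _ = _score(fits[9], df, 10, run)
            corresponding = r2_task1 if label == "task1" else r2_task2
            other = r2_task2 if label == "task1" else r2_task1
            records.append(MetricsRecord(pid, 10, "ct", {
                f"switch_score_{label}_b{run[0]}":
                    relative_performance(corresponding, other)}))
    return records


def _stage_permutation_transfer(pid, pidx, df, rule1, rule2, config):
    _, fit_blocks = _split_blocks(df, 8, config.eval_blocks)
    ct8 = _fit_day(df, 8, fit_blocks, "ct", config, 400 * pidx + 8)
    y9, rt9, mask9 = _day_arrays(df, 9)
    perms = alternative_permutations(rule1, rule2)
    gt2 = build_ground_truth(rule2, 0.0, 0.0)
    table = transfer_permutation_analysis(ct8, gt2, perms, y9, rt9, mask9)
    metrics = {f"r2_{row.label}": row.r2 for row in table.itertuples()}
    metrics.update({k: v for k, v in table.attrs.items()})
    return [MetricsRecord(pid, 9, "ct", metrics)]
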