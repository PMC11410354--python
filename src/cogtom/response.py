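"""LATER response-time model and trial-level RT preprocessing.

The LATER (Linear Approach to Threshold with Ergodic Rate) model links the
subjective predictive probability ``p`` of the upcoming stimulus to the
response time: a decision signal rises from ``-log p`` below a baseline
threshold ``theta0`` at a rate ``r ~ Normal(mu, sigma)`` truncated to
positive values, so

    RT = (theta0 - log p) / r        [seconds]

Larger predictive probability shortens the distance to threshold and hence
the response.  The implied RT distribution is a scaled reciprocal
(truncated) normal.

Preprocessing applies the standard ASRT exclusion rules in a fixed
precedence order: warm-up trials, incorrect responses, RTs above 5000 ms,
RTs above the participant's session mean + 3 SD, and RTs below 180 ms.
Excluded trials keep conditioning the sequence model; only their RT
likelihood terms are dropped.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .task import N_WARMUP

MS_PER_S = 1000.0

# exclusion rules in precedence order (a trial is attributed to the first
# rule it violates)
FILTER_RULES = ("warmup", "incorrect", "rt_missing",
                "rt_over_max", "rt_over_mean3sd", "rt_under_min")


class ResponseModelError(ValueError):
    pass


@dataclass(frozen=True)
class LATERParams:
    """Individual response-model parameters.

    mu : mean rate of rise (1/s)
    sigma : SD of the rate of rise (1/s); the rate is truncated to r > 0
    theta0 : baseline threshold (dimensionless)
    """

    mu: float
    sigma: float
    theta0: float

    def __post_init__(self) -> None:
        for name in ("mu", "sigma", "theta0"):
            if not np.isfinite(getattr(self, name)) or getattr(self, name) <= 0:
                raise ResponseModelError(f"{name} must be strictly positive")


def _check_p(p):
    p = np.asarray(p, dtype=float)
    if np.any(p <= 0) or np.any(p > 1):
        raise ResponseModelError("predictive probability must lie in (0, 1]")
    return p


def later_point_prediction(p, params: LATERParams):
    """Deterministic RT prediction (seconds) at the mean rate of rise.

    Strictly decreasing in ``p``; affine in ``-log p``.
    """
    p = _check_p(p)
    out = (params.theta0 - np.log(p)) / params.mu
    return float(out) if out.ndim == 0 else out


def _truncated_rate(params: LATERParams):
    a = (0.0 - params.mu) / params.sigma
    return stats.truncnorm(a, np.inf, loc=params.mu, scale=params.sigma)


def later_sample(p, params: LATERParams, rng=None):
    """Sample RTs (seconds): rise distance divided by a truncated-normal rate."""
    p = _check_p(p)
    rng = np.random.default_rng(rng)
    r = _truncated_rate(params).rvs(size=np.shape(p) or 1, random_state=rng)
    out = (params.theta0 - np.log(p)) / r
    return float(out[0]) if np.ndim(p) == 0 else out


def later_log_density(rt_s, p, params: LATERParams):
    """Log density of an RT (seconds) under the LATER model.

    Change of variables r = (theta0 - log p)/rt gives
    ``f(rt) = TruncNormal(r; mu, sigma, r>0) * (theta0 - log p) / rt**2``.
    """
    p = _check_p(p)
    rt_s = np.asarray(rt_s, dtype=float)
    if np.any(rt_s <= 0):
        raise ResponseModelError("rt must be strictly positive")
    x = params.theta0 - np.log(p)
    r = x / rt_s
    z = (r - params.mu) / params.sigma
    log_norm = stats.norm.logpdf(z) - np.log(params.sigma)
    log_trunc = stats.norm.logcdf(params.mu / params.sigma)
    out = log_norm - log_trunc + np.log(x) - 2.0 * np.log(rt_s)
    return float(out) if out.ndim == 0 else out


def fit_later_mle(rt_s, p, theta0_bounds=(1e-2, 10.0)) -> LATERParams:
    """Approximate maximum-likelihood LATER parameters for paired (RT, p).

    For a fixed ``theta0`` the implied rates ``r_n = (theta0 - log p_n)/rt_n``
    have (untruncated) normal MLE given by their sample mean and SD; the
    truncation correction is evaluated at that point.  The resulting profile
    likelihood is maximised over ``theta0`` with a bounded scalar search.
    Exact when the truncation mass is negligible (mu/sigma large), which
    holds for realistic response-time regimes.
    """
    rt_s = np.asarray(rt_s, dtype=float)
    p = _check_p(p)
    lp = np.log(p)
    if rt_s.size < 3:
        raise ResponseModelError("need at least 3 trials to fit LATER")

    def neg_profile(theta0):
        x = theta0 - lp
        r = x / rt_s
        mu, sig = r.mean(), r.std()
        if sig <= 0 or not np.isfinite(sig):
            return np.inf
        ll = np.sum(stats.norm.logpdf(r, mu, sig) + np.log(x) - 2 * np.log(rt_s))
        ll -= r.size * stats.norm.logcdf(mu / sig)
        return -ll

    res = optimize.minimize_scalar(neg_profile, bounds=theta0_bounds,
                                   method="bounded")
    theta0 = float(res.x)
    r = (theta0 - lp) / rt_s
    return LATERParams(mu=float(r.mean()), sigma=float(max(r.std(), 1e-6)),
                       theta0=theta0)


@dataclass
class FilterReport:
    """Bookkeeping for the RT exclusion rules.

    ``counts`` maps each rule to the number of trials attributed to it
    (first matching rule wins); ``thresholds`` records the per-session
    mean+3sd cut-offs in ms, keyed by (participant, day).
    """

    n_total: int
    n_surviving: int
    counts: dict = field(default_factory=dict)
    thresholds: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        payload = {
            "n_total": self.n_total,
            "n_surviving": self.n_surviving,
            "counts": self.counts,
            "thresholds": {f"{k[0]}|{k[1]}": v for k, v in self.thresholds.items()},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def preprocess_rts(trials: pd.DataFrame, rt_max_ms: float = 5000.0,
                   rt_min_ms: float = 180.0, sd_mult: float = 3.0):
    """Apply the RT exclusion rules per participant and session (day).

    Returns ``(trials, report)`` where ``trials`` is a copy with two added
    columns: ``rt_keep`` (bool; RT enters the likelihood / evaluation) and
    ``rt_excluded_by`` (name of the first violated rule, empty if kept).
    All rows are retained so excluded trials still condition sequence
    predictions.

    The mean+3sd statistic is computed per participant-session over trials
    that already survived the warm-up, correctness and 5000 ms rules; the
    180 ms floor is applied last.
    """
    if len(trials) == 0:
        raise ResponseModelError("empty trial table")
    df = trials.copy()
    rt = pd.to_numeric(df["rt_ms"], errors="coerce").to_numpy(dtype=float)
    correct = df["correct"]
    excluded_by = np.full(len(df), "", dtype=object)

    warm = df["trial"].to_numpy() <= N_WARMUP
    incorrect = np.array([(not pd.isna(c)) and (not bool(c)) for c in correct])
    missing = np.isnan(rt)
    over_max = rt > rt_max_ms

    def attribute(mask, rule):
        fresh = mask & (excluded_by == "")
        excluded_by[fresh] = rule

    attribute(warm, "warmup")
    attribute(incorrect, "incorrect")
    attribute(missing & ~warm, "rt_missing")
    attribute(over_max, "rt_over_max")

    thresholds = {}
    over_3sd = np.zeros(len(df), dtype=bool)
    for (part, day), idx in df.groupby(["participant", "day"]).indices.items():
        base = idx[(excluded_by[idx] == "")]
        if base.size == 0:
            continue
        m, s = np.nanmean(rt[base]), np.nanstd(rt[base])
        cut = m + sd_mult * s
        thresholds[(part, day)] = float(cut)
        over_3sd[base[rt[base] > cut]] = True
    attribute(over_3sd, "rt_over_mean3sd")
    attribute(rt < rt_min_ms, "rt_under_min")

    keep = excluded_by == ""
    df["rt_keep"] = keep
    df["rt_excluded_by"] = excluded_by
    counts = {rule: int(np.sum(excluded_by == rule)) for rule in FILTER_RULES}
    report = FilterReport(n_total=len(df), n_surviving=int(keep.sum()),
                          counts=counts, thresholds=thresholds)
    if report.n_surviving == 0:
        warnings.warn("all trials excluded by RT preprocessing")
    return df, report
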