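"""Synthetic cohorts of daily log-in trajectories, covariates and outcomes.

The generator emulates the statistical structure the trajectory analysis
assumes: each user belongs to one of a small number of engagement
archetypes, each defined by a 52-week profile of expected log-in days per
week. Given the archetype, log-ins follow a quasi-regular renewal scheme:
the user's weekly quota is the archetype target scaled by a bounded mean-1
uniform multiplier (between-user overdispersion), a log-in occurs at every
integer crossing of the cumulative quota with a random phase, and active
days are placed uniformly within each week — so weekly targets are met
exactly in expectation and group membership stays behaviorally coherent.
Week 12 gets an additive quota bump emulating the spike triggered by a
12-week assessment invitation. Baseline covariates are drawn from
configurable marginals (tobacco-trial-like defaults), independent of the
archetype unless explicit archetype shifts are requested, so every
association test has a known truth. The binary cessation outcome follows a
logistic model with per-archetype log-odds-ratios and optional covariate
effects, with missing-at-random outcome masking.

Two arm presets are provided whose archetype profiles and mixing
proportions mirror the published trajectory groups of a two-arm smoking
cessation website trial: a treatment-like arm ("webquit") with 1-week
(55%), 5-week (32%) and 52-week (13%) users, and a control-like arm
("smokefree") with 1-week (49%), 4-week (30%) and 5-week (21%) users.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import DailyEngagementMatrix

__all__ = [
    "ArchetypeSpec",
    "CohortConfig",
    "SyntheticCohort",
    "default_archetypes",
    "simulate_engagement",
    "simulate_covariates",
    "simulate_outcome",
    "simulate_cohort",
    "cohort_to_events",
]

_SPORADIC = 0.1  # "almost no log-ins": expected days per week
_MONTHLY = 0.25  # "about once a month": expected days per week


@dataclass(frozen=True)
class ArchetypeSpec:
    """An engagement archetype: expected log-in days for each of 52 weeks."""

    name: str
    weekly_mean_logins: tuple  # 52 values in [0, 7]
    proportion: float

    def __post_init__(self) -> None:
        if len(self.weekly_mean_logins) != 52:
            raise ValueError("weekly_mean_logins must have 52 entries")
        if not all(0.0 <= v <= 7.0 for v in self.weekly_mean_logins):
            raise ValueError("weekly targets must lie in [0, 7]")
        if not 0.0 <= self.proportion <= 1.0:
            raise ValueError("proportion must lie in [0, 1]")


def _profile(head: list[float], tail: float = _SPORADIC) -> tuple:
    return tuple(head + [tail] * (52 - len(head)))


def default_archetypes(arm: str) -> list[ArchetypeSpec]:
    """Three archetypes per arm, with week-level targets taken from the
    published cluster descriptions (sporadic tails set to 0.1 days/week,
    monthly use to 0.25 days/week)."""
    arm = arm.lower()
    if arm == "webquit":
        return [
            ArchetypeSpec("1-week", _profile([1.0]), 0.55),
            ArchetypeSpec("5-week", _profile([1.8, 0.8, 1 / 3, 1 / 3, 1 / 3]), 0.32),
            ArchetypeSpec(
                "52-week", _profile([3.7, 3.3, 2.7, 2.4, 1.6, 1.0], tail=_MONTHLY), 0.13
            ),
        ]
    if arm == "smokefree":
        return [
            ArchetypeSpec("1-week", _profile([0.8]), 0.49),
            ArchetypeSpec("4-week", _profile([1.0, 0.5, 0.5, 0.5]), 0.30),
            ArchetypeSpec("5-week", _profile([1.5, 1.5, 1.0, 0.5, 0.5]), 0.21),
        ]
    raise ValueError(f"unknown arm {arm!r}; expected 'webquit' or 'smokefree'")


# Observed 1-week-user abstinence 116/562 and unadjusted cross-product odds
# ratios 1.424 (5-week) and 2.001 (52-week) define the default outcome model.
_DEFAULT_ALPHA = float(np.log((116 / 562) / (1 - 116 / 562)))
_DEFAULT_GROUP_OR = (1.0, (100 * 446) / (270 * 116), (51 * 446) / (98 * 116))


@dataclass
class CohortConfig:
    """Everything the generator needs; defaults mirror the treatment-like arm."""

    n_users: int = 1240
    archetypes: list = field(default_factory=lambda: default_archetypes("webquit"))
    heterogeneity: float = 0.28  # half-width of the uniform per-user multiplier
    week12_spike: float = 0.05  # additive daily log-in probability, week 12 only
    horizon_days: int = 365
    outcome_intercept: float = _DEFAULT_ALPHA  # log-odds of abstinence, archetype 1
    group_log_or: tuple = tuple(float(np.log(r)) for r in _DEFAULT_GROUP_OR)
    covariate_effects: dict = field(default_factory=dict)  # covariate -> log-OR
    missingness: float = 1 - 2309 / 2637  # outcome missing-at-random rate
    seed: int = 0

    def __post_init__(self) -> None:
        props = [a.proportion for a in self.archetypes]
        if abs(sum(props) - 1.0) > 1e-9:
            raise ValueError(f"archetype proportions must sum to 1, got {sum(props)}")
        if not 0.0 <= self.missingness < 1.0:
            raise ValueError("missingness must lie in [0, 1)")
        if not 0.0 <= self.heterogeneity <= 1.0:
            raise ValueError("heterogeneity half-width must lie in [0, 1]")
        if len(self.group_log_or) != len(self.archetypes):
            raise ValueError("group_log_or must have one entry per archetype")


@dataclass
class SyntheticCohort:
    """A complete simulated dataset plus its generating truth."""

    matrix: DailyEngagementMatrix
    covariates: pd.DataFrame  # indexed 0..N-1, user_id column included
    outcome: np.ndarray  # float, NaN where missing
    missing: np.ndarray  # bool mask
    labels: np.ndarray  # true archetype labels, 1-based
    config: CohortConfig


def simulate_engagement(config: CohortConfig) -> tuple[DailyEngagementMatrix, np.ndarray]:
    """Draw the daily binary engagement matrix and true archetype labels.

    Log-ins follow a quasi-regular renewal ("quota-crossing") scheme: each
    user's weekly quota is the archetype's weekly target scaled by a mean-1
    uniform multiplier on [1 - a, 1 + a] (plus the week-12 spike, 7 x the
    daily bump), and a log-in occurs in week w for every integer crossed by
    the cumulative quota offset by a user-specific uniform phase. Active
    days are placed uniformly within the week. The scheme preserves every
    weekly target exactly in expectation while keeping trajectories
    behaviorally coherent — a quota of "once every 3 weeks" really does
    produce one log-in per 3 weeks rather than a thin scatter of
    independent daily coin flips.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_users
    props = np.array([a.proportion for a in config.archetypes])
    labels = rng.choice(len(config.archetypes), size=n, p=props) + 1
    targets = np.stack([np.asarray(a.weekly_mean_logins, float) for a in config.archetypes])
    quota = targets[labels - 1].astype(float)  # (N, 52)
    if config.heterogeneity > 0:
        a = config.heterogeneity
        mult = rng.uniform(1.0 - a, 1.0 + a, size=n)
        quota = quota * mult[:, None]
    if config.week12_spike > 0:
        quota[:, 11] += 7.0 * config.week12_spike
    quota = np.clip(quota, 0.0, 7.0)
    phase = rng.random(n)[:, None]
    cum = np.cumsum(quota, axis=1) + phase
    counts = np.diff(np.floor(np.concatenate([phase, cum], axis=1)), axis=1).astype(int)
    # place each week's count on distinct days, uniformly within the week
    ranks = rng.random((n, 52, 7)).argsort(axis=2).argsort(axis=2)
    weekly_days = (ranks < counts[:, :, None]).astype(np.int8)
    values = weekly_days.reshape(n, 364)
    if config.horizon_days <= 364:
        values = values[:, : config.horizon_days]
    else:
        # days beyond week 52 (day 365 by default) continue at the week-52 rate
        extra = config.horizon_days - 364
        p_tail = np.clip(quota[:, -1] / 7.0, 0.0, 1.0)
        tail = (rng.random((n, extra)) < p_tail[:, None]).astype(np.int8)
        values = np.concatenate([values, tail], axis=1)
    user_ids = [f"u{i + 1:05d}" for i in range(n)]
    return DailyEngagementMatrix(user_ids, values), labels


#: default covariate marginals, approximating the trial's overall baseline table
DEFAULT_MARGINALS: dict = {
    "age": ("truncnormal", 46.4, 13.3, 18.0, 80.0),
    "male": ("bernoulli", 0.20),
    "married": ("bernoulli", 0.38),
    "working": ("bernoulli", 0.52),
    "hs_or_less": ("bernoulli", 0.28),
    "half_pack_or_more": ("bernoulli", 0.79),
    "smoked_gt_10_years": ("bernoulli", 0.80),
    "partner_smokes": ("bernoulli", 0.70),
    "depression": ("bernoulli", 0.56),
    "anxiety": ("bernoulli", 0.34),
    "social_anxiety": ("bernoulli", 0.30),
    "panic": ("bernoulli", 0.48),
    "ptsd": ("bernoulli", 0.52),
    "hazardous_alcohol": ("bernoulli", 0.11),
    "commitment": ("truncnormal", 4.0, 0.76, 1.0, 5.0),
    "ftnd": ("truncnormal", 5.6, 2.2, 0.0, 10.0),
}


def _logit(p: float) -> float:
    return float(np.log(p / (1 - p)))


def simulate_covariates(
    n: int,
    seed: int,
    marginals: dict | None = None,
    labels: np.ndarray | None = None,
    archetype_shifts: dict | None = None,
) -> pd.DataFrame:
    """Draw baseline covariates from independent marginals.

    ``archetype_shifts`` maps a binary covariate name to a per-archetype
    log-odds-ratio sequence (entry g applies to archetype g+1; entry 0 is
    the reference and should be 0), inducing a known covariate-membership
    association for multinomial-model testing. Requires ``labels``.
    """
    rng = np.random.default_rng(seed)
    marginals = DEFAULT_MARGINALS if marginals is None else marginals
    archetype_shifts = archetype_shifts or {}
    if archetype_shifts and labels is None:
        raise ValueError("archetype_shifts requires true labels")
    out: dict[str, np.ndarray] = {}
    for name, spec in marginals.items():
        kind = spec[0]
        if kind == "bernoulli":
            p = np.full(n, float(spec[1]))
            if name in archetype_shifts:
                shift = np.asarray(archetype_shifts[name], dtype=float)
                eta = _logit(float(spec[1])) + shift[np.asarray(labels) - 1]
                p = 1.0 / (1.0 + np.exp(-eta))
            out[name] = (rng.random(n) < p).astype(float)
        elif kind == "truncnormal":
            _, mu, sd, lo, hi = spec
            draws = rng.normal(mu, sd, size=n)
            bad = (draws < lo) | (draws > hi)
            while bad.any():  # redraw out-of-range values
                draws[bad] = rng.normal(mu, sd, size=int(bad.sum()))
                bad = (draws < lo) | (draws > hi)
            out[name] = draws
        else:
            raise ValueError(f"unknown marginal kind {kind!r} for {name!r}")
    return pd.DataFrame(out)


def simulate_outcome(
    labels: np.ndarray,
    covariates: pd.DataFrame,
    config: CohortConfig,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw the binary outcome and its missingness mask from the logistic model.

    logit P(abstinent) = intercept + group log-OR + covariate effects; the
    mask is missing-completely-at-random at the configured rate. Returns
    (outcome with NaN where missing, boolean missing mask).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    labels = np.asarray(labels)
    eta = config.outcome_intercept + np.asarray(config.group_log_or)[labels - 1]
    for name, beta in config.covariate_effects.items():
        eta = eta + beta * covariates[name].to_numpy(dtype=float)
    p = 1.0 / (1.0 + np.exp(-eta))
    outcome = (rng.random(len(labels)) < p).astype(float)
    missing = rng.random(len(labels)) < config.missingness
    outcome[missing] = np.nan
    return outcome, missing


def simulate_cohort(
    arm: str = "webquit",
    n_users: int = 1240,
    seed: int = 0,
    **overrides,
) -> SyntheticCohort:
    """Generate a full synthetic cohort for one arm with a single seed."""
    config = CohortConfig(
        n_users=n_users, archetypes=default_archetypes(arm), seed=seed, **overrides
    )
    matrix, labels = simulate_engagement(config)
    covariates = simulate_covariates(config.n_users, seed + 2, labels=labels)
    covariates.insert(0, "user_id", matrix.user_ids)
    outcome, missing = simulate_outcome(labels, covariates, config)
    return SyntheticCohort(matrix, covariates, outcome, missing, labels, config)


def cohort_to_events(
    matrix: DailyEngagementMatrix,
    start_date: str = "2014-06-02",
    stagger_days: int = 180,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Reconstruct event and enrollment tables from a binary matrix.

    Enrollment dates are staggered uniformly over ``stagger_days`` from
    ``start_date``; each active day becomes a single noon-time event, so
    binarizing the returned tables reproduces the matrix exactly.
    """
    rng = np.random.default_rng(seed)
    base = pd.Timestamp(start_date)
    offsets = rng.integers(0, max(stagger_days, 1), size=matrix.n_users)
    enroll = pd.DataFrame(
        {
            "user_id": matrix.user_ids,
            "enrollment_date": [base + pd.Timedelta(days=int(o)) for o in offsets],
        }
    )
    rows, days = np.nonzero(matrix.values)
    times = [
        enroll["enrollment_date"].iloc[r] + pd.Timedelta(days=int(d), hours=12)
        for r, d in zip(rows, days)
    ]
    events = pd.DataFrame(
        {"user_id": [matrix.user_ids[r] for r in rows], "event_time": times}
    )
    return events, enroll
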