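"""Outcome and cluster-membership models reported as odds-ratio tables.

Two families of models link trajectory clusters to the data:

* logistic regression of the binary cessation outcome on trajectory-group
  indicators (reference = cluster 1, the largest group), optionally adjusted
  for baseline covariates chosen by bidirectional stepwise AIC with the
  trajectory indicators forced into every candidate model;
* baseline-category multinomial logistic regression of cluster membership on
  baseline characteristics, with candidates prefiltered by a univariate
  likelihood-ratio screen.

Maximum-likelihood fitting is by Newton iterations (via statsmodels) with
Wald standard errors from the inverse observed information; all odds ratios
carry 95% Wald intervals and two-sided normal p-values. A closed-form 2x2
cross-product odds ratio with a Woolf interval is provided as an independent
oracle for the one-binary-covariate logistic model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.tools.sm_exceptions import PerfectSeparationError, PerfectSeparationWarning

__all__ = [
    "DesignSpec",
    "LogisticFit",
    "MultinomialFit",
    "SeparationError",
    "RankDeficientError",
    "fit_logistic",
    "odds_ratios",
    "or_from_2x2",
    "stepwise_aic",
    "univariate_screen",
    "fit_multinomial",
]

_Z95 = 1.959963984540054  # standard-normal 97.5% quantile


class SeparationError(RuntimeError):
    """The likelihood has no finite maximum (perfect or quasi separation)."""


class RankDeficientError(ValueError):
    """Design matrix is rank deficient; names the collinear terms."""

    def __init__(self, terms: list[str]):
        self.terms = terms
        super().__init__(f"design matrix is rank deficient; collinear term(s): {terms}")


@dataclass(frozen=True)
class DesignSpec:
    """Model specification: outcome column, forced terms, stepwise candidates."""

    outcome: str
    forced: tuple[str, ...] = ()
    candidates: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        terms = list(self.forced) + list(self.candidates)
        dup = {t for t in terms if terms.count(t) > 1}
        if dup:
            raise ValueError(f"duplicate terms in design: {sorted(dup)}")


@dataclass
class LogisticFit:
    """Logistic MLE: coefficients, Wald SEs, log-likelihood, AIC, n."""

    params: pd.Series
    bse: pd.Series
    llf: float
    aic: float
    nobs: int
    terms: tuple[str, ...]


@dataclass
class MultinomialFit:
    """Baseline-category multinomial MLE; one coefficient vector per contrast."""

    params: pd.DataFrame  # rows = terms (incl. const), columns = nonreference classes
    bse: pd.DataFrame
    llf: float
    aic: float
    nobs: int
    classes: tuple
    reference: object

    def predict_proba(self, data: pd.DataFrame) -> np.ndarray:
        """Class-membership probabilities (columns ordered as ``classes``)."""
        terms = [t for t in self.params.index if t != "const"]
        x = np.column_stack([np.ones(len(data)), data[terms].astype(float).to_numpy()])
        eta = x @ self.params.to_numpy()  # (n, G-1)
        eta = np.column_stack([np.zeros(len(data)), eta])
        eta -= eta.max(axis=1, keepdims=True)
        p = np.exp(eta)
        return p / p.sum(axis=1, keepdims=True)


def _design_matrix(data: pd.DataFrame, terms: tuple[str, ...]) -> pd.DataFrame:
    x = data.loc[:, list(terms)].astype(float)
    x.insert(0, "const", 1.0)
    rank = np.linalg.matrix_rank(x.to_numpy())
    if rank < x.shape[1]:
        # identify offending columns by greedy rank growth
        bad, kept = [], x[["const"]].to_numpy()
        for c in x.columns[1:]:
            trial = np.column_stack([kept, x[c].to_numpy()])
            if np.linalg.matrix_rank(trial) == kept.shape[1]:
                bad.append(c)
            else:
                kept = trial
        raise RankDeficientError(bad)
    return x


def _complete_cases(data: pd.DataFrame, cols: list[str]) -> pd.DataFrame:
    return data.dropna(subset=[c for c in cols if c in data.columns])


def fit_logistic(
    design: DesignSpec,
    data: pd.DataFrame,
    terms: tuple[str, ...] | None = None,
) -> LogisticFit:
    """Fit a binary logistic model of ``design.outcome`` on the given terms.

    ``terms`` defaults to the design's forced terms. Rows with missing
    outcome or predictors are dropped (complete-case analysis). Newton
    iterations stop when the score is below 1e-8 or after 50 steps.
    """
    if terms is None:
        terms = design.forced
    sub = _complete_cases(data, [design.outcome, *terms])
    y = sub[design.outcome].astype(float)
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError(f"outcome {design.outcome!r} must be binary 0/1")
    x = _design_matrix(sub, tuple(terms))
    if len(sub) < x.shape[1] + 1:
        raise ValueError("too few complete cases for the requested model")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", PerfectSeparationWarning)
            res = sm.Logit(y, x).fit(method="newton", maxiter=50, tol=1e-8, disp=0)
    except (PerfectSeparationError, PerfectSeparationWarning) as exc:
        raise SeparationError(str(exc)) from exc
    if not res.mle_retvals.get("converged", False) or np.abs(res.params).max() > 30:
        raise SeparationError("logistic fit did not converge to a finite maximum")
    return LogisticFit(
        params=res.params,
        bse=res.bse,
        llf=float(res.llf),
        aic=float(res.aic),
        nobs=int(res.nobs),
        terms=tuple(terms),
    )


def odds_ratios(fit: LogisticFit) -> pd.DataFrame:
    """Per-term odds ratios with 95% Wald CIs and p-values (intercept omitted)."""
    rows = []
    for term in fit.terms:
        b, se = fit.params[term], fit.bse[term]
        z = b / se if se > 0 else np.inf * np.sign(b) if b else 0.0
        rows.append(
            {
                "term": term,
                "odds_ratio": np.exp(b),
                "ci_low": np.exp(b - _Z95 * se),
                "ci_high": np.exp(b + _Z95 * se),
                "p": 2 * stats.norm.sf(abs(z)),
            }
        )
    return pd.DataFrame(rows)


def or_from_2x2(a: float, b: float, c: float, d: float) -> tuple[float, tuple[float, float]]:
    """Closed-form odds ratio and Woolf CI from a 2x2 table.

    Convention: ``a`` = reference-group events, ``b`` = reference non-events,
    ``c`` = exposed-group events, ``d`` = exposed non-events, so
    OR = (c*b)/(d*a) — exposed events x reference non-events over exposed
    non-events x reference events. Zero cells get the Haldane-Anscombe 0.5
    correction (applied to all four cells).
    """
    cells = [a, b, c, d]
    if any(v < 0 for v in cells):
        raise ValueError("counts must be non-negative")
    if any(v == 0 for v in cells):
        a, b, c, d = (v + 0.5 for v in cells)
    or_ = (c * b) / (d * a)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return float(or_), (float(or_ * np.exp(-_Z95 * se)), float(or_ * np.exp(_Z95 * se)))


@dataclass
class StepwiseStep:
    action: str  # "add" or "drop"
    term: str
    aic_before: float
    aic_after: float


def stepwise_aic(
    design: DesignSpec,
    data: pd.DataFrame,
    direction: str = "both",
) -> tuple[LogisticFit, list[StepwiseStep]]:
    """Bidirectional stepwise AIC selection over the design's candidates.

    Starts from the forced-terms-only model and at each step evaluates every
    single addition (if direction allows) and single drop of a non-forced
    term, taking the move with the lowest AIC when it strictly improves the
    current one. Ties prefer the smaller model, then the alphabetically
    first term. Candidates that would make the design rank deficient are
    skipped with a warning. Complete cases are fixed up front over outcome,
    forced terms and all candidates so AICs are comparable across steps.
    """
    if direction not in {"both", "forward", "backward"}:
        raise ValueError(f"unknown direction {direction!r}")
    sub = _complete_cases(data, [design.outcome, *design.forced, *design.candidates])
    current = list(design.forced) if direction != "backward" else list(design.forced) + sorted(design.candidates)
    fit = fit_logistic(design, sub, tuple(current))
    trace: list[StepwiseStep] = []
    while True:
        moves = []  # (aic, prefer_drop_rank, term, action, terms)
        if direction in {"both", "backward"}:
            for t in sorted(set(current) - set(design.forced)):
                trial = tuple(u for u in current if u != t)
                try:
                    moves.append((fit_logistic(design, sub, trial).aic, 0, t, "drop", trial))
                except (SeparationError, RankDeficientError, ValueError):
                    continue
        if direction in {"both", "forward"}:
            for t in sorted(set(design.candidates) - set(current)):
                trial = tuple(current) + (t,)
                try:
                    moves.append((fit_logistic(design, sub, trial).aic, 1, t, "add", trial))
                except RankDeficientError:
                    warnings.warn(f"candidate {t!r} is collinear with the current model; skipped")
                    continue
                except (SeparationError, ValueError):
                    continue
        if not moves:
            return fit, trace
        moves.sort(key=lambda m: (m[0], m[1], m[2]))
        best = moves[0]
        if best[0] >= fit.aic - 1e-10:
            return fit, trace
        trace.append(StepwiseStep(best[3], best[2], fit.aic, best[0]))
        current = list(best[4])
        fit = fit_logistic(design, sub, tuple(current))


def _mnlogit(y_codes: np.ndarray, x: pd.DataFrame):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return sm.MNLogit(y_codes, x).fit(method="newton", maxiter=100, disp=0)


def univariate_screen(
    covariates: pd.DataFrame,
    labels: np.ndarray,
    alpha: float = 0.05,
) -> list[str]:
    """Likelihood-ratio screen of each covariate against cluster membership.

    Each covariate is fit alone in a multinomial model of the cluster label;
    covariates whose LR test against the intercept-only model has p < alpha
    are kept as stepwise candidates. Constant covariates are excluded with a
    warning; covariates whose fit fails (e.g. perfect separation — extreme
    evidence of association) are kept.
    """
    labels = np.asarray(labels)
    classes, y_codes = np.unique(labels, return_inverse=True)
    df_per_term = len(classes) - 1
    const = pd.DataFrame({"const": np.ones(len(labels))}, index=covariates.index)
    llf0 = _mnlogit(y_codes, const).llf
    kept: list[str] = []
    for name in covariates.columns:
        col = covariates[name].astype(float)
        if col.nunique(dropna=True) <= 1:
            warnings.warn(f"covariate {name!r} is constant; excluded from screening")
            continue
        x = const.copy()
        x[name] = col
        try:
            res = _mnlogit(y_codes, x)
            lr = 2 * (res.llf - llf0)
        except Exception:
            lr = np.nan
        if not np.isfinite(lr):
            # divergent likelihood = (quasi-)separation: extreme association
            warnings.warn(f"covariate {name!r}: separated multinomial fit; kept as candidate")
            kept.append(name)
            continue
        if stats.chi2.sf(max(lr, 0.0), df_per_term) < alpha:
            kept.append(name)
    return kept


def fit_multinomial(
    design: DesignSpec,
    labels: np.ndarray,
    data: pd.DataFrame,
    terms: tuple[str, ...] | None = None,
) -> tuple[MultinomialFit, dict]:
    """Baseline-category multinomial logit of cluster membership on covariates.

    The reference category is the lowest cluster label — cluster 1, the
    largest group under the size-based relabeling convention. Returns the
    fit plus a dict mapping each non-reference cluster to its odds-ratio
    table (95% Wald CIs, two-sided p-values).
    """
    if terms is None:
        terms = design.forced + design.candidates
    labels = np.asarray(labels)
    frame = data.copy()
    frame["_cluster"] = labels
    sub = _complete_cases(frame, ["_cluster", *terms])
    classes = np.unique(sub["_cluster"])
    if len(classes) < 2:
        raise ValueError("need at least 2 clusters")
    y_codes = np.searchsorted(classes, sub["_cluster"].to_numpy())
    x = _design_matrix(sub, tuple(terms))
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", PerfectSeparationWarning)
            res = _mnlogit(y_codes, x)
    except (PerfectSeparationError, PerfectSeparationWarning) as exc:
        raise SeparationError(str(exc)) from exc
    if np.abs(res.params.to_numpy()).max() > 30:
        raise SeparationError("multinomial fit did not converge to a finite maximum")
    nonref = [classes[j] for j in range(1, len(classes))]
    params = pd.DataFrame(res.params.to_numpy(), index=x.columns, columns=nonref)
    bse = pd.DataFrame(res.bse.to_numpy(), index=x.columns, columns=nonref)
    fit = MultinomialFit(
        params=params,
        bse=bse,
        llf=float(res.llf),
        aic=float(res.aic),
        nobs=int(res.nobs),
        classes=tuple(classes),
        reference=classes[0],
    )
    tables = {}
    for cls in nonref:
        rows = []
        for term in terms:
            b, se = params.loc[term, cls], bse.loc[term, cls]
            z = b / se if se > 0 else 0.0
            rows.append(
                {
                    "term": term,
                    "odds_ratio": np.exp(b),
                    "ci_low": np.exp(b - _Z95 * se),
                    "ci_high": np.exp(b + _Z95 * se),
                    "p": 2 * stats.norm.sf(abs(z)),
                }
            )
        tables[cls] = pd.DataFrame(rows)
    return fit, tables
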