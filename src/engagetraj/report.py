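"""Trial-report-style summaries and the end-to-end pipeline orchestrator.

Outputs follow the conventions of the trial reports this pipeline targets:
cluster proportions to 2 decimal places, abstinence rates to 1, odds ratios
to 2, all rounded half-up at the printed precision. The orchestrator wires
binarize -> presmooth -> FPCA -> prediction-strength k selection -> CLARA ->
size-based relabeling -> summaries -> association models, writes every
artifact as delimited text plus a JSON manifest, and is byte-reproducible
for a fixed (input, config, seed) triple.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .association import DesignSpec, fit_logistic, fit_multinomial, odds_ratios, stepwise_aic, univariate_screen
from .clustering import clara, prediction_strength, relabel_by_size
from .cohort import simulate_cohort
from .fpca import fit_fpca, presmooth
from .io import DailyEngagementMatrix, Dialect, binarize_daily, read_enrollment, read_login_events, weekly_counts

__all__ = [
    "round_half_up",
    "percent",
    "cluster_proportions",
    "weekly_profile",
    "abstinence_by_cluster",
    "run_pipeline",
]

logger = logging.getLogger("engagetraj")


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Decimal round-half-up (0.5 always rounds away from zero)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def percent(numerator: float, denominator: float, ndigits: int = 2) -> float:
    """100 * numerator / denominator, rounded half-up to ``ndigits``."""
    if denominator == 0:
        raise ZeroDivisionError("denominator is zero")
    return round_half_up(100.0 * numerator / denominator, ndigits)


def cluster_proportions(labels: np.ndarray) -> pd.DataFrame:
    """Per-cluster n and percentage of the sample (2 dp, half-up)."""
    labels = np.asarray(labels)
    if len(labels) == 0:
        raise ValueError("labels must be nonempty")
    clusters, counts = np.unique(labels, return_counts=True)
    return pd.DataFrame(
        {
            "cluster": clusters,
            "n": counts,
            "percent": [percent(c, len(labels), 2) for c in counts],
        }
    )


def weekly_profile(matrix: DailyEngagementMatrix, labels: np.ndarray) -> pd.DataFrame:
    """Mean weekly log-ins per cluster: one row per cluster, 52 week columns."""
    labels = np.asarray(labels)
    if len(labels) != matrix.n_users:
        raise ValueError("labels must align with matrix rows")
    weekly = weekly_counts(matrix)
    rows = {}
    for g in np.unique(labels):
        members = weekly[labels == g]
        if len(members) == 0:  # pragma: no cover - unique() precludes this
            warnings.warn(f"cluster {g} is empty; omitted from profile")
            continue
        rows[g] = members.mean(axis=0)
    out = pd.DataFrame.from_dict(rows, orient="index", columns=[f"week_{w}" for w in range(1, 53)])
    out.index.name = "cluster"
    return out


def abstinence_by_cluster(
    labels: np.ndarray,
    outcome: np.ndarray,
    missing: np.ndarray | None = None,
    mode: str = "complete_case",
) -> pd.DataFrame:
    """Abstinence count, denominator and rate (1 dp, half-up) per cluster.

    ``complete_case`` restricts the denominator to observed outcomes;
    ``missing_as_smoking`` counts every cluster member, treating missing
    outcomes as smoking.
    """
    if mode not in {"complete_case", "missing_as_smoking"}:
        raise ValueError(f"unknown mode {mode!r}")
    labels = np.asarray(labels)
    outcome = np.asarray(outcome, dtype=float)
    if missing is None:
        missing = np.isnan(outcome)
    missing = np.asarray(missing, dtype=bool)
    rows = []
    for g in np.unique(labels):
        in_g = labels == g
        events = int(np.nansum(outcome[in_g & ~missing]))
        denom = int((in_g & ~missing).sum()) if mode == "complete_case" else int(in_g.sum())
        rate = round_half_up(100.0 * events / denom, 1) if denom else 0.0
        rows.append({"cluster": g, "abstinent": events, "denominator": denom, "rate_pct": rate})
    return pd.DataFrame(rows)


_DEFAULT_CONFIG = {
    "seed": 0,
    "smoothing": {"bandwidth_days": 28.0},
    "fpca": {"fve_threshold": 0.90, "max_components": 10},
    "cluster": {"k": "auto", "k_max": 6, "threshold": 0.85, "n_splits": 20},
    "association": {"outcome": "abstinent", "candidates": [], "mode": "complete_case"},
}


def _merge(base: dict, override: dict) -> dict:
    merged = dict(base)
    for key, val in override.items():
        if isinstance(val, dict) and isinstance(merged.get(key), dict):
            merged[key] = _merge(merged[key], val)
        else:
            merged[key] = val
    return merged


def load_config(config: dict | str | Path) -> dict:
    if not isinstance(config, dict):
        with open(config) as fh:
            config = yaml.safe_load(fh) or {}
    return _merge(_DEFAULT_CONFIG, config)


def _load_inputs(cfg: dict, seed: int):
    """Either simulate a cohort or read events/enrollment/covariates from disk."""
    if "simulate" in cfg:
        sim = dict(cfg["simulate"])
        cohort = simulate_cohort(
            arm=sim.get("arm", "webquit"), n_users=int(sim.get("n_users", 1240)), seed=seed
        )
        covariates = cohort.covariates.set_index("user_id")
        covariates["abstinent"] = cohort.outcome
        return cohort.matrix, covariates, cohort.labels
    inputs = cfg["inputs"]
    dialect = Dialect(**inputs.get("dialect", {}))
    events = read_login_events(inputs["events"], dialect)
    enrollment = read_enrollment(inputs["enrollment"], dialect)
    matrix, diag = binarize_daily(events, enrollment, int(inputs.get("horizon_days", 365)))
    logger.info("binarize diagnostics: %s", diag.to_dict())
    covariates = pd.read_csv(inputs["covariates"]).set_index("user_id")
    covariates = covariates.loc[matrix.user_ids]
    return matrix, covariates, None


def run_pipeline(config: dict | str | Path, out_dir: str | Path | None = None) -> dict:
    """Execute the full analysis and write artifacts; returns the manifest."""
    cfg = load_config(config)
    out = Path(out_dir if out_dir is not None else cfg.get("out_dir", "engagetraj_out"))
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])

    logger.info("stage: inputs")
    matrix, covariates, true_labels = _load_inputs(cfg, seed)

    logger.info("stage: presmooth")
    smoothed = presmooth(matrix, float(cfg["smoothing"]["bandwidth_days"]))

    logger.info("stage: fpca")
    model = fit_fpca(
        smoothed,
        fve_threshold=float(cfg["fpca"]["fve_threshold"]),
        max_components=int(cfg["fpca"]["max_components"]),
    )
    logger.info("fpca retained %d components (fve %.4f)", model.n_components, model.fve[-1])

    logger.info("stage: cluster")
    ccfg = cfg["cluster"]
    ps = prediction_strength(
        model.scores,
        k_max=int(ccfg["k_max"]),
        n_splits=int(ccfg["n_splits"]),
        threshold=float(ccfg["threshold"]),
        seed=seed,
    )
    k = ps.selected_k if ccfg["k"] == "auto" else int(ccfg["k"])
    logger.info("prediction strength selected k=%d (using k=%d)", ps.selected_k, k)
    result = relabel_by_size(clara(model.scores, k, seed=seed))

    logger.info("stage: summaries")
    proportions = cluster_proportions(result.labels)
    profile = weekly_profile(matrix, result.labels)

    acfg = cfg["association"]
    outcome_col = acfg["outcome"]
    artifacts: dict[str, str] = {}
    tables: dict[str, pd.DataFrame] = {
        "labels": pd.DataFrame({"user_id": matrix.user_ids, "cluster": result.labels}),
        "prediction_strength": pd.DataFrame(
            {"k": ps.k_values, "ps_mean": ps.ps_mean, "ps_sd": ps.ps_sd}
        ),
        "cluster_summary": proportions,
        "weekly_profile": profile.reset_index(),
    }

    stepwise_summary = None
    if outcome_col in covariates.columns:
        logger.info("stage: association")
        data = covariates.copy()
        group_terms = []
        for g in range(2, k + 1):
            name = f"cluster_{g}"
            data[name] = (result.labels == g).astype(float)
            group_terms.append(name)
        if np.isnan(data[outcome_col].astype(float)).any() and acfg["mode"] == "missing_as_smoking":
            data[outcome_col] = data[outcome_col].fillna(0.0)
        tables["abstinence"] = abstinence_by_cluster(
            result.labels, covariates[outcome_col].to_numpy(float), mode=acfg["mode"]
        )
        design = DesignSpec(outcome_col, tuple(group_terms), tuple(acfg.get("candidates", ())))
        unadj = fit_logistic(design, data)
        tables["outcome_or_unadjusted"] = odds_ratios(unadj)
        if design.candidates:
            adj, trace = stepwise_aic(design, data)
            tables["outcome_or_adjusted"] = odds_ratios(adj)
            stepwise_summary = [
                {"action": s.action, "term": s.term, "aic_before": s.aic_before, "aic_after": s.aic_after}
                for s in trace
            ]
        if k >= 2:
            cand = univariate_screen(
                data[[c for c in acfg.get("candidates", ()) if c in data.columns]], result.labels
            ) if acfg.get("candidates") else []
            terms = tuple(cand) if cand else None
            if terms:
                _, or_tables = fit_multinomial(DesignSpec(outcome_col), result.labels, data, terms)
                for cls, tab in or_tables.items():
                    tables[f"membership_or_cluster_{cls}"] = tab

    for name, frame in tables.items():
        path = out / f"{name}.csv"
        frame.to_csv(path, index=False)
        artifacts[name] = path.name

    manifest = {
        "package_version": __version__,
        "seed": seed,
        "config": cfg,
        "config_sha256": hashlib.sha256(
            json.dumps(cfg, sort_keys=True, default=str).encode()
        ).hexdigest(),
        "n_users": matrix.n_users,
        "fpca_components": model.n_components,
        "selected_k": int(ps.selected_k),
        "k_used": int(k),
        "stepwise_trace": stepwise_summary,
        "artifacts": artifacts,
    }
    if true_labels is not None:
        manifest["simulated"] = True
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    logger.info("pipeline complete; artifacts in %s", out)
    return manifest
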