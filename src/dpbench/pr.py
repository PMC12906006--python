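"""Prognosis-related (PR) cell-type identification.

One Cox proportional-hazards model per cell type — hazard ~ proportion
(+ configured clinical covariates) — rather than a joint model over all
cell types, which would be singular on compositional covariates. The
proportion covariate is standardized (zero mean, unit variance) by default
so hazard ratios are per-SD and comparable across cell types; the sign and
p-value are unaffected. Wald p-values are BH-adjusted over the cell types
that were testable, and a cell type is only testable when at least
``event_floor`` death events (default 15) remain after the low-proportion
filtering shared with DP detection. Ties in the partial likelihood use
Efron's method.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.exceptions import ConvergenceError

from dpbench.dp import bh_adjust
from dpbench.filtering import FilterConfig
from dpbench.io import ProportionMatrix, SurvivalTable

__all__ = ["CoxConfig", "fit_cox_per_celltype", "detect_pr", "write_pr_results"]


@dataclass
class CoxConfig:
    """Per-cell-type Cox model settings.

    covariates
        Names of clinical adjuster columns in the survival table (default
        none; configure per cohort).
    standardize_proportion
        Standardize the proportion covariate before fitting (default on).
    event_floor
        Minimum number of death events among retained samples for the cell
        type to be testable (default 15).
    fdr_threshold
        BH threshold for calling a cell type PR (default 0.05; 0.10/0.15
        are common sensitivity settings).
    """

    covariates: list = field(default_factory=list)
    standardize_proportion: bool = True
    event_floor: int = 15
    fdr_threshold: float = 0.05

    def __post_init__(self):
        if self.event_floor < 1:
            raise ValueError("event_floor must be >= 1")


def _untested(cell_type: str, reason: str, n: int = 0, n_events: int = 0) -> dict:
    return {
        "cell_type": cell_type,
        "beta": np.nan,
        "hr": np.nan,
        "neg_ln_hr": np.nan,
        "p_value": np.nan,
        "q_value": np.nan,
        "n_samples": n,
        "n_events": n_events,
        "tested": False,
        "reason": reason,
    }


def fit_cox_per_celltype(
    pm: ProportionMatrix,
    surv: SurvivalTable,
    cell_type: str,
    cfg: Optional[CoxConfig] = None,
    filter_cfg: Optional[FilterConfig] = None,
) -> dict:
    """Fit hazard ~ proportion (+ covariates) for one cell type.

    Samples are those present in both the proportion matrix and the
    survival table whose proportion of this cell type is at least
    ``filter_cfg.min_proportion``. Returns an untested record (with a
    reason) when the event floor is not met, the proportion column has no
    variation, or the fit fails to converge.
    """
    cfg = cfg or CoxConfig()
    filter_cfg = filter_cfg or FilterConfig()
    if cell_type not in pm.cell_types:
        raise KeyError(f"cell type {cell_type!r} not in matrix")
    col = pm.column(cell_type)
    matched = surv.aligned_to(pm.samples)
    keep = matched["sample_id"].map(lambda s: col[s] >= filter_cfg.min_proportion)
    data = matched[keep].copy()
    n, n_events = len(data), int(data["event"].sum())
    if n_events < cfg.event_floor:
        return _untested(cell_type, "insufficient_events", n, n_events)
    x = col[data["sample_id"]].to_numpy(dtype=float)
    if np.ptp(x) == 0:
        return _untested(cell_type, "no_variation", n, n_events)
    if cfg.standardize_proportion:
        x = (x - x.mean()) / x.std(ddof=0)
    frame = pd.DataFrame({"time": data["time"].to_numpy(), "event": data["event"].to_numpy(), "proportion": x})
    for cov in cfg.covariates:
        if cov not in data.columns:
            raise KeyError(f"covariate {cov!r} not in survival table")
        frame[cov] = pd.to_numeric(data[cov], errors="ignore").to_numpy()
    try:
        fitter = CoxPHFitter()
        fitter.fit(frame, duration_col="time", event_col="event")
    except (ConvergenceError, np.linalg.LinAlgError, ValueError):
        return _untested(cell_type, "no_convergence", n, n_events)
    beta = float(fitter.params_["proportion"])
    p = float(fitter.summary.loc["proportion", "p"])
    return {
        "cell_type": cell_type,
        "beta": beta,
        "hr": float(np.exp(beta)),
        "neg_ln_hr": -beta,
        "p_value": p,
        "q_value": np.nan,
        "n_samples": n,
        "n_events": n_events,
        "tested": True,
        "reason": "",
    }


def detect_pr(
    pm: ProportionMatrix,
    surv: SurvivalTable,
    cfg: Optional[CoxConfig] = None,
    filter_cfg: Optional[FilterConfig] = None,
) -> tuple[pd.DataFrame, set]:
    """Per-cell-type Cox fits with BH-FDR; returns (results, PR set).

    The PR set contains (cell_type, sign(beta)) pairs with q below the
    configured threshold. The majority-removal rule from DP filtering
    applies with the whole survival cohort as a single group: a cell type
    is skipped when more than half of the matched samples fall below the
    proportion floor.
    """
    cfg = cfg or CoxConfig()
    filter_cfg = filter_cfg or FilterConfig()
    matched_ids = [s for s in pm.samples if s in set(surv.df["sample_id"])]
    rows = []
    for ct in pm.cell_types:
        col = pm.column(ct)
        n_total = len(matched_ids)
        n_kept = int(sum(col[s] >= filter_cfg.min_proportion for s in matched_ids))
        if n_total and (n_total - n_kept) > filter_cfg.majority_rule * n_total:
            rows.append(_untested(ct, "removed_by_filter", n_kept, 0))
            continue
        rows.append(fit_cox_per_celltype(pm, surv, ct, cfg, filter_cfg))
    results = pd.DataFrame(rows)
    tested = results["tested"].to_numpy()
    if tested.any():
        results.loc[tested, "q_value"] = bh_adjust(results.loc[tested, "p_value"].to_numpy())
    results["is_pr"] = results["tested"] & (results["q_value"] < cfg.fdr_threshold)
    pr_set = {
        (r.cell_type, int(np.sign(r.beta)))
        for r in results.itertuples()
        if r.is_pr and r.beta != 0
    }
    results = results.sort_values("cell_type", kind="mergesort").reset_index(drop=True)
    return results, pr_set


def write_pr_results(results: pd.DataFrame, path) -> None:
    cols = [
        "cell_type", "beta", "hr", "neg_ln_hr", "p_value", "q_value",
        "n_samples", "n_events", "tested", "is_pr", "reason",
    ]
    results[cols].to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_pr_results(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    df["tested"] = df["tested"].astype(bool)
    df["is_pr"] = df["is_pr"].astype(bool)
    df["reason"] = df.get("reason", pd.Series([""] * len(df))).fillna("")
    return df
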