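"""Pan-cancer prognostic-consistency analysis.

Assembles a cancer-entity x cell-subtype matrix of -ln(HR) values from
per-cohort Cox fits (positive = favorable prognosis, negative = adverse),
then asks, per subtype, whether the prognostic direction is consistent
across entities: a one-sided Wilcoxon signed-rank test of the -ln(HR)
values against zero, with the side taken from the sign of the observed
median and BH-FDR across subtypes. Because the side is chosen post hoc,
reports carry a warning flag and a two-sided option is available.

Also builds additive cell-proportion prognostic indicators (e.g. classical
monocyte % + matrix-CAF %) and evaluates them by Cox regression on the
continuous score with a median-split Kaplan-Meier stratification for
display.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from dpbench.dp import bh_adjust
from dpbench.filtering import FilterConfig
from dpbench.io import CohortBundle, ProportionMatrix, SurvivalTable
from dpbench.pr import CoxConfig, detect_pr

__all__ = [
    "HRMatrix",
    "IndicatorSpec",
    "IndicatorEvaluation",
    "build_hr_matrix",
    "consistency_test",
    "indicator_score",
    "evaluate_indicator",
]


@dataclass
class HRMatrix:
    """Entities x subtypes matrix of -ln(HR); NaN where untested.

    ``missing_reason`` mirrors the shape with the reason string
    (``insufficient_events``, ``removed_by_filter``, ...). Stored values
    are never clipped; ``clipped()`` applies the +/-1 display clamp used
    for heatmaps.
    """

    values: pd.DataFrame
    missing_reason: pd.DataFrame

    @property
    def entities(self) -> list[str]:
        return list(self.values.index)

    @property
    def subtypes(self) -> list[str]:
        return list(self.values.columns)

    def clipped(self, bound: float = 1.0) -> pd.DataFrame:
        return self.values.clip(-bound, bound)


@dataclass
class IndicatorSpec:
    """Additive proportion indicator: score = sum of named subtypes."""

    subtype_names: Sequence[str] = ("classical_mono", "mCAF")

    def __post_init__(self):
        if len(self.subtype_names) < 1:
            raise ValueError("indicator needs at least one subtype")


def build_hr_matrix(
    cohorts: Sequence[CohortBundle],
    cox_cfg: Optional[CoxConfig] = None,
    filter_cfg: Optional[FilterConfig] = None,
) -> HRMatrix:
    """Per-entity PR fits assembled into a -ln(HR) matrix.

    Each cohort must carry survival data; its row holds the fitted
    -ln(HR) (= -beta) per subtype, NaN with a reason where the event floor
    or filtering makes the subtype untestable.
    """
    cox_cfg = cox_cfg or CoxConfig()
    rows, reasons = {}, {}
    for cohort in sorted(cohorts, key=lambda c: c.name):
        if cohort.survival is None:
            raise ValueError(f"cohort {cohort.name!r} has no survival data")
        results, _ = detect_pr(cohort.proportions, cohort.survival, cox_cfg, filter_cfg)
        results = results.set_index("cell_type")
        rows[cohort.name] = results["neg_ln_hr"]
        reasons[cohort.name] = results["reason"].where(~results["tested"], "")
    values = pd.DataFrame(rows).T.sort_index()
    reason = pd.DataFrame(reasons).T.sort_index().fillna("untested")
    if values.notna().sum().sum() == 0:
        import warnings

        warnings.warn("no testable subtype in any entity; HR matrix is all-missing")
    return HRMatrix(values=values, missing_reason=reason)


def consistency_test(
    hrm: HRMatrix,
    entity_floor: int = 5,
    fdr_threshold: float = 0.05,
    two_sided: bool = False,
) -> pd.DataFrame:
    """Per-subtype sign-consistency of -ln(HR) across entities.

    One-sided Wilcoxon signed-rank against 0, side = sign of the observed
    median (post hoc — flagged in the output; set ``two_sided=True`` to
    avoid the selection). Subtypes with fewer than ``entity_floor``
    non-missing entities are reported untested. BH-FDR across tested
    subtypes.
    """
    rows = []
    for subtype in hrm.subtypes:
        vals = hrm.values[subtype].dropna().to_numpy()
        row = {
            "subtype": subtype,
            "n_entities": len(vals),
            "median": float(np.median(vals)) if len(vals) else np.nan,
            "direction": 0,
            "p_value": np.nan,
            "q_value": np.nan,
            "tested": False,
            "note": "",
        }
        if len(vals) < entity_floor:
            row["note"] = "below_entity_floor"
            rows.append(row)
            continue
        med = row["median"]
        direction = int(np.sign(med))
        nonzero = vals[vals != 0]
        if len(nonzero) == 0:
            row["note"] = "all_zero"
            rows.append(row)
            continue
        if two_sided or direction == 0:
            alternative = "two-sided"
        else:
            alternative = "greater" if direction > 0 else "less"
            row["note"] = "one_sided_alternative_chosen_post_hoc"
        res = stats.wilcoxon(vals, alternative=alternative)
        row["direction"] = direction
        row["p_value"] = float(res.pvalue)
        row["tested"] = True
        rows.append(row)
    out = pd.DataFrame(rows)
    tested = out["tested"].to_numpy()
    if tested.any():
        out.loc[tested, "q_value"] = bh_adjust(out.loc[tested, "p_value"].to_numpy())
    out["consistent"] = out["tested"] & (out["q_value"] < fdr_threshold)
    return out


def indicator_score(pm: ProportionMatrix, spec: IndicatorSpec) -> pd.Series:
    """Per-sample indicator: sum of the named subtype proportions."""
    missing = [s for s in spec.subtype_names if s not in pm.cell_types]
    if missing:
        raise KeyError(
            f"indicator subtypes {missing} not in matrix; available: {pm.cell_types}"
        )
    return pm.values[list(spec.subtype_names)].sum(axis=1)


@dataclass
class IndicatorEvaluation:
    beta: float
    hr: float
    p_value: float
    groups: pd.Series  # sample -> {"low", "high"} at the median split
    km_data: pd.DataFrame = field(repr=False)  # sample_id, group, time, event


def evaluate_indicator(
    score: pd.Series,
    surv: SurvivalTable,
    cox_cfg: Optional[CoxConfig] = None,
) -> IndicatorEvaluation:
    """Cox fit on the (standardized) indicator plus a median-split KM table.

    The headline statistic is the Cox p-value on the continuous score; the
    median split (ties to the low group) only feeds the KM display.
    """
    from lifelines import CoxPHFitter

    cox_cfg = cox_cfg or CoxConfig()
    if score.nunique() <= 1:
        raise ValueError("indicator score is constant; cannot evaluate")
    matched = surv.aligned_to(list(score.index))
    n_events = int(matched["event"].sum())
    if n_events < cox_cfg.event_floor:
        raise ValueError(
            f"only {n_events} events, below the floor of {cox_cfg.event_floor}"
        )
    x = score.loc[matched["sample_id"]].to_numpy(dtype=float)
    if cox_cfg.standardize_proportion:
        x = (x - x.mean()) / x.std(ddof=0)
    frame = pd.DataFrame(
        {
            "time": matched["time"].to_numpy(),
            "event": matched["event"].to_numpy(),
            "indicator": x,
        }
    )
    for cov in cox_cfg.covariates:
        frame[cov] = matched[cov].to_numpy()
    fitter = CoxPHFitter()
    fitter.fit(frame, duration_col="time", event_col="event")
    fit = {
        "beta": float(fitter.params_["indicator"]),
        "hr": float(np.exp(fitter.params_["indicator"])),
        "p_value": float(fitter.summary.loc["indicator", "p"]),
    }
    med = float(score.loc[matched["sample_id"]].median())
    groups = score.loc[matched["sample_id"]].map(lambda v: "low" if v <= med else "high")
    km = pd.DataFrame(
        {
            "sample_id": matched["sample_id"].to_numpy(),
            "group": groups.to_numpy(),
            "time": matched["time"].to_numpy(),
            "event": matched["event"].to_numpy(),
        }
    )
    return IndicatorEvaluation(
        beta=fit["beta"],
        hr=fit["hr"],
        p_value=fit["p_value"],
        groups=groups,
        km_data=km,
    )
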