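"""Differentially proportioned (DP) cell-type identification.

A cell type is DP when its per-sample proportion differs between the two
disease-contrast conditions: two-sided Wilcoxon rank-sum test per cell type
on filter-retained samples, Benjamini-Hochberg FDR over the cell types that
were actually testable, and a direction from the condition medians. The
default FDR threshold is 0.1 for scRNA-derived ground truth (small n per
condition) and 0.05 for deconvolution estimates.

The p-value is exact (full rank-assignment enumeration) whenever both
groups have at most 25 samples and the pooled data are tie-free; otherwise
the normal approximation with continuity correction is used. The switch is
fixed so printed p-values reproduce across platforms.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from dpbench.filtering import FilterConfig, FilterReport, drop_unstable_celltypes, filter_low_proportion
from dpbench.io import ProportionMatrix, merge_compartments

__all__ = ["DPSet", "rank_sum_test", "bh_adjust", "detect_dp", "DEFAULT_FDR"]

#: default FDR threshold by matrix source
DEFAULT_FDR = {"scRNA": 0.1, "deconvolution": 0.05}

EXACT_MAX_N = 25


@dataclass
class DPSet:
    """Directed DP calls: {(cell_type, direction)} with one direction each."""

    elements: set = field(default_factory=set)
    fdr_threshold: float = 0.05
    source: str = ""

    @property
    def cell_types(self) -> set:
        return {ct for ct, _ in self.elements}

    def direction_of(self, cell_type: str) -> Optional[int]:
        for ct, d in self.elements:
            if ct == cell_type:
                return d
        return None

    def to_json(self, path=None) -> str:
        payload = {
            "fdr_threshold": self.fdr_threshold,
            "source": self.source,
            "elements": sorted([ct, int(d)] for ct, d in self.elements),
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_json(cls, path) -> "DPSet":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            elements={(ct, int(d)) for ct, d in payload["elements"]},
            fdr_threshold=payload["fdr_threshold"],
            source=payload.get("source", ""),
        )


def rank_sum_test(x: Sequence[float], y: Sequence[float]) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value.

    Exact enumeration for tie-free groups of size <= 25 each; otherwise the
    normal approximation with continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    tie_free = len(np.unique(pooled)) == len(pooled)
    if tie_free and len(x) <= EXACT_MAX_N and len(y) <= EXACT_MAX_N:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=True
    )
    return float(min(res.pvalue, 1.0))


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([])
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _source_kind(pm: ProportionMatrix) -> str:
    return "scRNA" if pm.is_scrna else "deconvolution"


def detect_dp(
    pm: ProportionMatrix,
    cfg: Optional[FilterConfig] = None,
    fdr_threshold: Optional[float] = None,
    compartment_map: Optional[Mapping[str, str]] = None,
    minor_exclusion: bool = False,
    minor_reference: Optional[ProportionMatrix] = None,
    minor_threshold: float = 0.01,
    conditions: Optional[tuple[str, str]] = None,
) -> tuple[pd.DataFrame, DPSet]:
    """Full DP pipeline on a two-condition proportion matrix.

    Steps: optional compartment merging -> optional minor-cell-type
    exclusion -> per-cell-type low-proportion filtering and majority-removal
    -> rank-sum test on retained samples -> BH adjustment over tested cell
    types -> directed DP set at the FDR threshold.

    Returns
    -------
    (results, dp_set)
        ``results``: one row per cell type with columns cell_type, n1, n2,
        median1, median2, direction, p_value, q_value, tested, is_dp,
        reason. ``dp_set``: the directed calls.

    Notes
    -----
    * A cell type with fewer than two retained samples in either condition
      is reported untested (not an error).
    * Direction is sign(median1 - median2) over retained samples; an exact
      median tie gives direction 0 and the type cannot be called DP.
    * ``minor_exclusion`` drops cell types whose median abundance is below
      ``minor_threshold`` in either condition of ``minor_reference`` (the
      scRNA ground truth; defaults to ``pm`` itself) — a sensitivity mode.
    """
    cfg = cfg or FilterConfig()
    if compartment_map:
        pm = merge_compartments(pm, compartment_map)
    if conditions is None:
        conds = pm.conditions
        if len(conds) != 2:
            raise ValueError(f"DP analysis needs exactly two conditions, got {conds}")
        cond1, cond2 = conds
    else:
        cond1, cond2 = conditions
        present = set(pm.conditions)
        if not {cond1, cond2} <= present:
            raise ValueError(f"conditions {conditions} not all present in matrix")

    minor_dropped: set[str] = set()
    if minor_exclusion:
        ref = minor_reference if minor_reference is not None else pm
        for ct in pm.cell_types:
            if ct not in ref.cell_types:
                continue
            col = ref.column(ct)
            for cond in (cond1, cond2):
                ids = ref.samples_in_condition(cond)
                if ids and float(np.median(col[ids])) < minor_threshold:
                    minor_dropped.add(ct)
                    break

    report = FilterReport()
    retained_by_ct: dict[str, dict[str, list[str]]] = {}
    for ct in pm.cell_types:
        if ct in minor_dropped:
            continue
        retained_by_ct[ct] = filter_low_proportion(
            pm, cfg, ct, conditions=[cond1, cond2], report=report
        )
    removed = drop_unstable_celltypes(report, cfg)

    rows = []
    for ct in pm.cell_types:
        row = {
            "cell_type": ct,
            "n1": 0,
            "n2": 0,
            "median1": np.nan,
            "median2": np.nan,
            "direction": 0,
            "p_value": np.nan,
            "q_value": np.nan,
            "tested": False,
            "reason": "",
        }
        if ct in minor_dropped:
            row["reason"] = "minor_cell_type"
            rows.append(row)
            continue
        if ct in removed:
            row["reason"] = "removed_by_filter"
            rows.append(row)
            continue
        ids1 = retained_by_ct[ct][cond1]
        ids2 = retained_by_ct[ct][cond2]
        row["n1"], row["n2"] = len(ids1), len(ids2)
        if len(ids1) < 2 or len(ids2) < 2:
            row["reason"] = "too_few_retained"
            rows.append(row)
            continue
        col = pm.column(ct)
        x = col[ids1].to_numpy()
        y = col[ids2].to_numpy()
        m1, m2 = float(np.median(x)), float(np.median(y))
        row["median1"], row["median2"] = m1, m2
        row["direction"] = int(np.sign(m1 - m2))
        row["p_value"] = rank_sum_test(x, y)
        row["tested"] = True
        rows.append(row)

    results = pd.DataFrame(rows)
    tested_mask = results["tested"].to_numpy()
    if tested_mask.any():
        q = bh_adjust(results.loc[tested_mask, "p_value"].to_numpy())
        results.loc[tested_mask, "q_value"] = q

    if fdr_threshold is None:
        fdr_threshold = DEFAULT_FDR[_source_kind(pm)]
    results["is_dp"] = (
        results["tested"]
        & (results["q_value"] < fdr_threshold)
        & (results["direction"] != 0)
    )
    dp_set = DPSet(
        elements={
            (r.cell_type, int(r.direction))
            for r in results.itertuples()
            if r.is_dp
        },
        fdr_threshold=fdr_threshold,
        source=pm.source,
    )
    # stable output order regardless of input column order
    results = results.sort_values("cell_type", kind="mergesort").reset_index(drop=True)
    return results, dp_set


def write_dp_results(results: pd.DataFrame, path) -> None:
    cols = [
        "cell_type", "n1", "n2", "median1", "median2",
        "direction", "p_value", "q_value", "tested", "is_dp", "reason",
    ]
    results[cols].to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_dp_results(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    df["tested"] = df["tested"].astype(bool)
    df["is_dp"] = df["is_dp"].astype(bool)
    df["direction"] = df["direction"].astype(int)
    df["reason"] = df.get("reason", pd.Series([""] * len(df))).fillna("")
    return df
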