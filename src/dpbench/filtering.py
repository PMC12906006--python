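"""Low-proportion sample exclusion and cell-type removal.

Deconvolution methods sometimes assign (near-)zero proportions to a cell
type in many samples — an estimation failure, not biology — and scRNA-seq
samples can carry spuriously tiny fractions from sequencing artifacts.
Both inflate differential-proportion significance. The guard is applied per
cell type, before testing:

* samples whose proportion of the cell type is below ``min_proportion``
  (default 0.1%) are excluded from that cell type's test only;
* if, within either condition, more than half of the samples were excluded,
  the cell type is removed from identification altogether.

The same rules run before prognostic (Cox) testing; survival cohorts with a
single condition are treated as one group.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import pandas as pd

from dpbench.io import ProportionMatrix

__all__ = ["FilterConfig", "FilterReport", "filter_low_proportion", "drop_unstable_celltypes"]


@dataclass
class FilterConfig:
    """Exclusion thresholds.

    min_proportion
        Strict lower bound: samples with proportion < this are excluded
        from the cell type's test (0 disables filtering).
    majority_rule
        Fraction of a condition's samples whose exclusion removes the cell
        type; removal requires excluded > majority_rule * n (strict).
    """

    min_proportion: float = 0.001
    majority_rule: float = 0.5

    def __post_init__(self):
        if not 0 <= self.min_proportion < 1:
            raise ValueError("min_proportion must be in [0, 1)")


@dataclass
class FilterReport:
    """Per (cell_type, condition) exclusion bookkeeping."""

    entries: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["cell_type", "condition", "n_total", "n_excluded"]
        )
    )
    retained: dict = field(default_factory=dict)  # (cell_type, condition) -> [sample ids]
    removed_cell_types: dict = field(default_factory=dict)  # cell_type -> reason

    def add(self, cell_type: str, condition: str, total_ids, retained_ids) -> None:
        self.retained[(cell_type, condition)] = list(retained_ids)
        row = pd.DataFrame(
            [
                {
                    "cell_type": cell_type,
                    "condition": condition,
                    "n_total": len(total_ids),
                    "n_excluded": len(total_ids) - len(retained_ids),
                }
            ]
        )
        self.entries = pd.concat([self.entries, row], ignore_index=True)

    def to_frame(self) -> pd.DataFrame:
        df = self.entries.copy()
        df["removed_flag"] = df["cell_type"].isin(self.removed_cell_types)
        df["reason"] = df["cell_type"].map(self.removed_cell_types).fillna("")
        return df


def filter_low_proportion(
    pm: ProportionMatrix,
    cfg: FilterConfig,
    cell_type: str,
    conditions: Optional[list[str]] = None,
    report: Optional[FilterReport] = None,
) -> dict[str, list[str]]:
    """Retained sample ids per condition for one cell type.

    Exclusion is strict: proportion < ``min_proportion`` drops the sample
    from this cell type's comparison only. With ``conditions=None`` the
    matrix's own condition labels are used; pass a single pseudo-condition
    for survival cohorts without a disease contrast.
    """
    if cell_type not in pm.cell_types:
        raise KeyError(f"cell type {cell_type!r} not in matrix")
    col = pm.column(cell_type)
    if conditions is None:
        groups = {c: pm.samples_in_condition(c) for c in pm.conditions}
    else:
        groups = {c: pm.samples_in_condition(c) for c in conditions}
    out: dict[str, list[str]] = {}
    for cond, ids in groups.items():
        kept = [s for s in ids if col[s] >= cfg.min_proportion]
        out[cond] = kept
        if report is not None:
            report.add(cell_type, cond, ids, kept)
    return out


def drop_unstable_celltypes(report: FilterReport, cfg: FilterConfig) -> set[str]:
    """Cell types removed from identification: within any condition, more
    than ``majority_rule`` of the samples were excluded (strict >)."""
    removed: set[str] = set()
    for _, row in report.entries.iterrows():
        if row["n_excluded"] > cfg.majority_rule * row["n_total"]:
            removed.add(row["cell_type"])
            report.removed_cell_types.setdefault(
                row["cell_type"],
                f"excluded {row['n_excluded']}/{row['n_total']} samples in "
                f"condition {row['condition']!r}",
            )
    return removed
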