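"""Benchmark metrics for DP/PR set agreement.

Three scenarios, each scored under two criteria modes:

* Scenario 1 — consistency of deconvolution-called DP cell types with the
  scRNA-seq-defined reference (precision/recall/F1). Conservative precision
  counts calls confirmed as significant in scRNA-seq with matching
  direction; permissive precision also accepts calls whose scRNA-seq trend
  (direction of the median shift, regardless of significance) matches.
  Recall is identical in both modes.
* Scenario 2 — reproducibility of DP cell types across two bulk cohorts
  (Jaccard of shared vs union), plus an F1 of the shared set against the
  scRNA-seq reference. Conservative shared = significant in both cohorts
  with one direction; permissive shared additionally accepts significance
  in exactly one cohort with a direction-consistent trend in the other.
  The F1's precision is trend-consistency with scRNA-seq in BOTH modes;
  only the shared set itself changes between modes.
* Scenario 3 — reproducibility of PR cell types, pooled over cancer
  entities because single cohorts carry too few PR calls for a stable
  per-entity Jaccard.

Direction agreement is required for every notion of "validated", "shared"
or "recovered": a significance match with opposite direction would be a
false agreement. A flag disables this for ablation.

Also here: log2 fold-change MAE for magnitude comparisons, sample-level and
cell-type-level Pearson correlations against ground truth, and average-rank
aggregation across metrics.
"""

from __future__ import annotations

import decimal
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

__all__ = [
    "ScoreReport",
    "f1_score",
    "jaccard_index",
    "score_scenario1",
    "shared_dp",
    "shared_pr",
    "score_scenario2",
    "pooled_jaccard_scenario3",
    "log2fc",
    "log2fc_table",
    "mae_log2fc",
    "pcc_sample",
    "pcc_celltype",
    "aggregate_ranks",
    "round2",
]


def round2(x: Optional[float]) -> Optional[float]:
    """Round half-up to 2 decimals for display (0.435 -> 0.44)."""
    if x is None or (isinstance(x, float) and np.isnan(x)):
        return x
    return float(decimal.Decimal(repr(float(x))).quantize(
        decimal.Decimal("0.01"), rounding=decimal.ROUND_HALF_UP
    ))


@dataclass
class ScoreReport:
    """Precision/recall/F1 and/or Jaccard with the contributing sets.

    A metric is ``None`` when undefined (e.g. recall with an empty
    reference set); ``flags`` records why.
    """

    mode: str
    precision: Optional[float] = None
    recall: Optional[float] = None
    f1: Optional[float] = None
    jaccard: Optional[float] = None
    contributing_sets: dict = field(default_factory=dict)
    flags: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "mode": self.mode,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "jaccard": self.jaccard,
            "contributing_sets": {k: sorted(v) for k, v in self.contributing_sets.items()},
            "flags": list(self.flags),
        }


def f1_score(recall: float, precision: float) -> float:
    """Harmonic mean of precision and recall; 0 when their sum is 0."""
    for name, v in (("recall", recall), ("precision", precision)):
        if not 0 <= v <= 1:
            raise ValueError(f"{name} must be in [0, 1], got {v}")
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)


def jaccard_index(shared: Iterable, union_set: Iterable) -> Optional[float]:
    """|shared| / |union|; ``None`` when the union is empty."""
    shared, union_set = set(shared), set(union_set)
    if not shared <= union_set:
        raise ValueError(f"shared set is not a subset of the union: {shared - union_set}")
    if not union_set:
        return None
    return len(shared) / len(union_set)


# ----------------------------------------------------------------------
# canonical per-cell-type call records
# ----------------------------------------------------------------------

def _calls(table: pd.DataFrame, sig_col: str, direction_from_beta: bool = False) -> dict:
    """cell_type -> (tested, significant, direction) from a result table."""
    out = {}
    for r in table.itertuples():
        if direction_from_beta:
            d = int(np.sign(r.beta)) if r.tested and not np.isnan(r.beta) else 0
        else:
            d = int(r.direction) if r.tested else 0
        out[r.cell_type] = (bool(r.tested), bool(getattr(r, sig_col)), d)
    return out


def _dp_calls(table: pd.DataFrame) -> dict:
    return _calls(table, "is_dp")


def _pr_calls(table: pd.DataFrame) -> dict:
    return _calls(table, "is_pr", direction_from_beta=True)


def score_scenario1(
    deconv_dp: pd.DataFrame,
    scrna_dp: pd.DataFrame,
    mode: str = "conservative",
    require_direction: bool = True,
) -> ScoreReport:
    """Consistency of deconvolution DP calls with the scRNA-seq reference.

    Parameters
    ----------
    deconv_dp, scrna_dp
        DP result tables (as from :func:`dpbench.dp.detect_dp`) for the
        deconvolution matrix and the scRNA-derived ground truth.
    mode
        ``"conservative"`` (precision requires scRNA significance) or
        ``"permissive"`` (a direction-consistent scRNA trend suffices).
    """
    if mode not in ("conservative", "permissive"):
        raise ValueError(f"unknown mode {mode!r}")
    dec = _dp_calls(deconv_dp)
    ref = _dp_calls(scrna_dp)
    called = {ct for ct, (_, sig, _) in dec.items() if sig}
    reference = {ct for ct, (_, sig, _) in ref.items() if sig}

    def dir_match(ct: str, need_sig: bool) -> bool:
        if ct not in ref:
            return False
        tested, sig, d_ref = ref[ct]
        if need_sig and not sig:
            return False
        if not require_direction:
            return tested and (sig or not need_sig)
        return tested and d_ref != 0 and d_ref == dec[ct][2]

    validated = {ct for ct in called if dir_match(ct, need_sig=True)}
    trend_ok = {ct for ct in called if dir_match(ct, need_sig=False)}

    report = ScoreReport(mode=mode)
    report.contributing_sets = {
        "called": called,
        "reference": reference,
        "validated": validated,
        "trend_consistent": trend_ok,
    }
    if not reference:
        report.flags.append("empty_reference_dp_set:recall_undefined")
        return report
    report.recall = len(validated) / len(reference)
    if not called:
        report.flags.append("no_deconvolution_dp_calls:precision_undefined")
        report.f1 = 0.0
        return report
    numerator = validated if mode == "conservative" else trend_ok
    report.precision = len(numerator) / len(called)
    report.f1 = f1_score(report.recall, report.precision)
    return report


def _shared_union(calls_a: dict, calls_b: dict, mode: str) -> tuple[dict, set]:
    """Shared (cell_type -> direction) and union cell-type sets for two
    cohorts' call records."""
    union = {ct for ct, (_, sig, _) in calls_a.items() if sig}
    union |= {ct for ct, (_, sig, _) in calls_b.items() if sig}
    shared: dict[str, int] = {}
    for ct in union:
        ta, sa, da = calls_a.get(ct, (False, False, 0))
        tb, sb, db = calls_b.get(ct, (False, False, 0))
        if sa and sb and da != 0 and da == db:
            shared[ct] = da
        elif mode == "permissive" and (sa != sb):
            sig_dir = da if sa else db
            other_tested, other_dir = (tb, db) if sa else (ta, da)
            if other_tested and sig_dir != 0 and other_dir == sig_dir:
                shared[ct] = sig_dir
    return shared, union


def shared_dp(
    dp_a: pd.DataFrame, dp_b: pd.DataFrame, mode: str = "conservative"
) -> tuple[dict, set]:
    """Shared and union DP cell types for two cohorts of the same contrast.

    Returns ``(shared, union)`` where ``shared`` maps cell type to its
    direction and ``union`` is every cell type significant in at least one
    cohort. Types untested in the other cohort can enter the union but
    never the shared set.
    """
    if mode not in ("conservative", "permissive"):
        raise ValueError(f"unknown mode {mode!r}")
    return _shared_union(_dp_calls(dp_a), _dp_calls(dp_b), mode)


def shared_pr(
    pr_a: pd.DataFrame, pr_b: pd.DataFrame, mode: str = "conservative"
) -> tuple[dict, set]:
    """As :func:`shared_dp` but on PR tables, with sign(beta) as direction."""
    if mode not in ("conservative", "permissive"):
        raise ValueError(f"unknown mode {mode!r}")
    return _shared_union(_pr_calls(pr_a), _pr_calls(pr_b), mode)


def score_scenario2(
    shared: Mapping[str, int],
    union_set: Iterable,
    scrna_dp: pd.DataFrame,
    mode: str = "conservative",
) -> ScoreReport:
    """Jaccard of the shared DP set plus its F1 against the scRNA reference.

    ``shared``/``union_set`` come from :func:`shared_dp` at the same mode.
    Precision is the fraction of shared types whose scRNA trend (direction,
    regardless of significance) is consistent — in both modes; recall is
    the fraction of scRNA-DP types recovered in the shared set with
    matching direction.
    """
    ref = _dp_calls(scrna_dp)
    reference = {ct for ct, (_, sig, _) in ref.items() if sig}
    shared = dict(shared)
    report = ScoreReport(mode=mode)
    report.jaccard = jaccard_index(shared.keys(), union_set)

    def scrna_trend_match(ct: str, need_sig: bool) -> bool:
        if ct not in ref:
            return False
        tested, sig, d_ref = ref[ct]
        if need_sig and not sig:
            return False
        return tested and d_ref != 0 and d_ref == shared[ct]

    recovered = {ct for ct in shared if scrna_trend_match(ct, need_sig=True)}
    trend_ok = {ct for ct in shared if scrna_trend_match(ct, need_sig=False)}
    report.contributing_sets = {
        "shared": set(shared),
        "union": set(union_set),
        "reference": reference,
        "recovered": recovered,
        "trend_consistent": trend_ok,
    }
    if reference:
        report.recall = len(recovered) / len(reference)
    else:
        report.flags.append("empty_reference_dp_set:recall_undefined")
    if shared:
        report.precision = len(trend_ok) / len(shared)
    else:
        report.flags.append("empty_shared_set:precision_undefined")
    if report.recall is not None and report.precision is not None:
        report.f1 = f1_score(report.recall, report.precision)
    elif report.recall is not None and not shared:
        report.f1 = 0.0
        report.flags.append("f1_zero_by_empty_shared")
    return report


def pooled_jaccard_scenario3(
    per_entity: Sequence[tuple[pd.DataFrame, pd.DataFrame]],
    mode: str = "conservative",
) -> tuple[Optional[float], dict]:
    """Pooled PR reproducibility across cancer entities.

    Each element of ``per_entity`` is a (PR table cohort A, PR table cohort
    B) pair. Shared/union sets are computed per entity as in Scenario 2
    (significance = is_pr, direction = sign(beta)) and pooled:
    sum(|shared_e|) / sum(|union_e|). ``None`` when every union is empty.
    """
    if len(per_entity) == 0:
        raise ValueError("need at least one entity")
    n_shared = n_union = 0
    detail = {}
    for i, (pr_a, pr_b) in enumerate(per_entity):
        shared, union = shared_pr(pr_a, pr_b, mode)
        n_shared += len(shared)
        n_union += len(union)
        detail[i] = {"shared": set(shared), "union": union}
    if n_union == 0:
        warnings.warn("no PR cell types in any entity; pooled Jaccard undefined")
        return None, detail
    return n_shared / n_union, detail


def log2fc(median1: float, median2: float, eps: float = 1e-4) -> float:
    """log2((median1 + eps) / (median2 + eps)); NaN when both medians are 0
    and eps is 0 (undefined ratio)."""
    if median1 + eps == 0 and median2 + eps == 0:
        return float("nan")
    if median2 + eps == 0:
        return float("inf") if median1 + eps > 0 else float("nan")
    return float(np.log2((median1 + eps) / (median2 + eps)))


def log2fc_table(dp_results: pd.DataFrame, eps: float = 1e-4) -> pd.Series:
    """Per-tested-cell-type log2 fold change of condition medians."""
    tested = dp_results[dp_results["tested"]]
    return pd.Series(
        {r.cell_type: log2fc(r.median1, r.median2, eps) for r in tested.itertuples()},
        dtype=float,
    )


def mae_log2fc(fc_a: pd.Series, fc_b: pd.Series) -> Optional[float]:
    """Median absolute difference of paired log2 fold changes (shared,
    finite cell types only); ``None`` for an empty pairing."""
    common = fc_a.index.intersection(fc_b.index)
    diffs = (fc_a[common] - fc_b[common]).abs()
    diffs = diffs[np.isfinite(diffs)]
    if len(diffs) == 0:
        return None
    return float(np.median(diffs))


def _pcc(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("inputs must be 1-D and the same length")
    if len(a) < 2:
        raise ValueError("need at least two points")
    da, db = a - a.mean(), b - b.mean()
    denom = np.sqrt((da ** 2).sum()) * np.sqrt((db ** 2).sum())
    if denom == 0:
        return float("nan")
    return float((da * db).sum() / denom)


def pcc_sample(est: Sequence[float], truth: Sequence[float]) -> float:
    """Pearson correlation across cell types within one sample (estimated
    vs true composition); NaN when either vector has zero variance."""
    return _pcc(est, truth)


def pcc_celltype(est: Sequence[float], truth: Sequence[float]) -> float:
    """Pearson correlation across samples for one cell type."""
    return _pcc(est, truth)


def aggregate_ranks(
    metric_table: pd.DataFrame,
    higher_is_better: Union[bool, Mapping[str, bool]] = True,
) -> pd.Series:
    """Average rank per method across metrics (rank 1 = best).

    ``metric_table``: methods (rows) x metrics (columns). Ties get the mean
    of the tied ranks; an undefined (NaN) score ranks last in its metric —
    a method that produced no usable calls must not win by abstention.
    """
    if metric_table.shape[0] < 2:
        raise ValueError("need at least two methods to rank")
    if metric_table.shape[1] < 1:
        raise ValueError("need at least one metric")
    ranks = {}
    for col in metric_table.columns:
        hib = higher_is_better if isinstance(higher_is_better, bool) else higher_is_better[col]
        ranks[col] = metric_table[col].rank(
            ascending=not hib, method="average", na_option="bottom"
        )
    return pd.DataFrame(ranks).mean(axis=1)
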