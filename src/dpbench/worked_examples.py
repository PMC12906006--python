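"""Worked example call configurations for a colon-adenocarcinoma-style
benchmark.

These functions build small DP call tables whose counts match the worked
COAD example used throughout the documentation: five deconvolution methods
compared against an scRNA-seq reference with 12 DP cell types (Scenario 1)
and across a TCGA/GEO cohort pair (Scenario 2). They exist so the scoring
arithmetic can be exercised end to end on a configuration with known
published-scale numbers — e.g. a method calling 16 DP types of which 8 are
confirmed in scRNA-seq scores F1 = 2*(8/16)*(8/12)/((8/16)+(8/12)) ≈ 0.57.

Only the counts matter; cell-type names, p-values and medians are
synthetic placeholders consistent with the call pattern.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from dpbench.scoring import ScoreReport, score_scenario1, score_scenario2, shared_dp

__all__ = [
    "make_dp_table",
    "scenario1_configurations",
    "scenario2_configurations",
    "scenario1_worked_scores",
    "scenario2_worked_scores",
]


def make_dp_table(calls: dict) -> pd.DataFrame:
    """DP result table from {cell_type: (tested, is_dp, direction)}.

    Medians, p and q are filled with placeholder values consistent with
    the call: significant rows get q = 0.01, tested non-significant rows
    q = 0.5, untested rows NaN. Medians encode the direction.
    """
    rows = []
    for ct, (tested, is_dp, direction) in calls.items():
        if is_dp and (not tested or direction == 0):
            raise ValueError(f"{ct}: a DP call must be tested with a direction")
        m2 = 0.1
        m1 = m2 + 0.05 * direction
        rows.append(
            {
                "cell_type": ct,
                "n1": 20 if tested else 0,
                "n2": 20 if tested else 0,
                "median1": m1 if tested else np.nan,
                "median2": m2 if tested else np.nan,
                "direction": direction if tested else 0,
                "p_value": (0.001 if is_dp else 0.5) if tested else np.nan,
                "q_value": (0.01 if is_dp else 0.5) if tested else np.nan,
                "tested": tested,
                "is_dp": bool(is_dp),
                "reason": "" if tested else "too_few_retained",
            }
        )
    return pd.DataFrame(rows)


def _s1_config(n_calls, n_validated, n_trend, n_ref=12):
    """Deconvolution + scRNA tables: ``n_calls`` DP calls of which
    ``n_validated`` are scRNA-significant with matching direction and
    ``n_trend`` (>= n_validated) have a matching scRNA trend; the scRNA
    reference holds ``n_ref`` DP types in total."""
    deconv, scrna = {}, {}
    for i in range(n_calls):
        ct = f"T{i:02d}"
        deconv[ct] = (True, True, 1)
        if i < n_validated:
            scrna[ct] = (True, True, 1)
        elif i < n_trend:
            scrna[ct] = (True, False, 1)  # consistent trend, not significant
        else:
            scrna[ct] = (True, False, -1)  # opposite trend
    for j in range(n_ref - n_validated):  # scRNA DP types the method missed
        ct = f"R{j:02d}"
        scrna[ct] = (True, True, 1)
        deconv[ct] = (True, False, 1)
    return make_dp_table(deconv), make_dp_table(scrna)


def scenario1_configurations() -> dict:
    """Per-method (deconvolution table, scRNA table) pairs for the COAD
    worked example: calls / validated / trend-consistent out of a 12-type
    scRNA DP reference."""
    return {
        "BayesPrism": _s1_config(n_calls=16, n_validated=8, n_trend=11),
        "ReCIDE": _s1_config(n_calls=14, n_validated=7, n_trend=10),
        "MuSiC": _s1_config(n_calls=5, n_validated=1, n_trend=2),
    }


def scenario1_worked_scores() -> pd.DataFrame:
    """Scenario-1 precision/recall/F1 per method and mode."""
    rows = []
    for method, (deconv, scrna) in scenario1_configurations().items():
        for mode in ("conservative", "permissive"):
            rep = score_scenario1(deconv, scrna, mode)
            rows.append(
                {
                    "method": method,
                    "mode": mode,
                    "precision": rep.precision,
                    "recall": rep.recall,
                    "f1": rep.f1,
                }
            )
    return pd.DataFrame(rows)


def _s2_config(
    n_union,
    n_cons_shared,
    n_perm_extra,
    cons_trend,
    cons_sig,
    perm_trend,
    perm_sig,
    n_ref=12,
):
    """Two cohort tables plus an scRNA table with prescribed counts.

    n_union
        cell types significant in at least one cohort;
    n_cons_shared / n_perm_extra
        significant in both with one direction / significant in exactly
        one with a matching trend in the other;
    cons_trend, cons_sig
        of the conservative shared set: scRNA trend-consistent count and,
        among those, scRNA-significant count;
    perm_trend, perm_sig
        same counts for the permissive shared set (superset).
    """
    a, b, scrna = {}, {}, {}
    scrna_dp_used = 0

    def ref_entry(i, trend_ok, sig):
        nonlocal scrna_dp_used
        if sig:
            scrna_dp_used += 1
        if trend_ok:
            return (True, sig, 1)
        return (True, sig, -1) if sig else (True, False, -1)

    idx = 0
    for i in range(n_cons_shared):
        ct = f"S{idx:02d}"; idx += 1
        a[ct] = (True, True, 1)
        b[ct] = (True, True, 1)
        scrna[ct] = ref_entry(i, trend_ok=i < cons_trend, sig=i < cons_sig)
    extra_trend = perm_trend - cons_trend
    extra_sig = perm_sig - cons_sig
    for i in range(n_perm_extra):
        ct = f"P{idx:02d}"; idx += 1
        a[ct] = (True, True, 1)
        b[ct] = (True, False, 1)  # matching trend, not significant
        scrna[ct] = ref_entry(i, trend_ok=i < extra_trend, sig=i < extra_sig)
    for _ in range(n_union - n_cons_shared - n_perm_extra):
        ct = f"U{idx:02d}"; idx += 1
        a[ct] = (True, True, 1)
        b[ct] = (True, False, -1)  # opposite trend: never shared
        scrna[ct] = (True, False, -1)
    for _ in range(n_ref - scrna_dp_used):  # scRNA DP types outside the union
        ct = f"R{idx:02d}"; idx += 1
        scrna[ct] = (True, True, 1)
        a[ct] = (True, False, 1)
        b[ct] = (True, False, 1)
    return make_dp_table(a), make_dp_table(b), make_dp_table(scrna)


def scenario2_configurations() -> dict:
    """Per-method (cohort A, cohort B, scRNA) tables for the COAD
    cohort-pair worked example."""
    return {
        "ReCIDE": _s2_config(
            n_union=15, n_cons_shared=8, n_perm_extra=3,
            cons_trend=5, cons_sig=4, perm_trend=7, perm_sig=6,
        ),
        "BayesPrism": _s2_config(
            n_union=16, n_cons_shared=6, n_perm_extra=3,
            cons_trend=3, cons_sig=2, perm_trend=5, perm_sig=4,
        ),
        "CIBERSORT": _s2_config(
            n_union=8, n_cons_shared=2, n_perm_extra=2,
            cons_trend=0, cons_sig=0, perm_trend=0, perm_sig=0,
        ),
    }


def scenario2_worked_scores() -> pd.DataFrame:
    """Scenario-2 Jaccard and F1 per method and mode."""
    rows = []
    for method, (tab_a, tab_b, scrna) in scenario2_configurations().items():
        for mode in ("conservative", "permissive"):
            shared, union = shared_dp(tab_a, tab_b, mode)
            rep = score_scenario2(shared, union, scrna, mode)
            rows.append(
                {
                    "method": method,
                    "mode": mode,
                    "jaccard": rep.jaccard,
                    "precision": rep.precision,
                    "recall": rep.recall,
                    "f1": rep.f1,
                }
            )
    return pd.DataFrame(rows)
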