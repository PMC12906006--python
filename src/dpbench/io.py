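"""Data model and tabular readers/writers.

Proportion matrices are samples x cell types DataFrames of fractions in
[0, 1]. Deconvolution outputs are compositional (rows sum to 1); rows that
drift slightly are renormalized with a warning, larger drift is an error.
Condition labels attach to samples, not to the matrix, so the same matrix
can feed both the two-condition differential test and the survival model.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Union

import numpy as np
import pandas as pd

__all__ = [
    "CellAnnotationTable",
    "ProportionMatrix",
    "SurvivalTable",
    "CohortBundle",
    "read_proportions",
    "write_proportions",
    "proportions_from_annotations",
    "merge_compartments",
    "apply_alias_map",
    "read_survival",
    "write_survival",
    "read_alias_map",
]

#: Deconvolution rows whose sum deviates from 1 by at most this are
#: renormalized (with a warning); larger deviations raise.
DEFAULT_SUM_TOL = 1e-3


class CellAnnotationTable:
    """Per-cell annotations: (cell_id, sample_id, condition, cell_type).

    The ground-truth input: cell-type labels assigned to individual cells of
    an scRNA-seq experiment, from which per-sample proportions are tallied.
    """

    REQUIRED = ("cell_id", "sample_id", "condition", "cell_type")

    def __init__(self, df: pd.DataFrame):
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise ValueError(f"annotation table missing columns: {missing}")
        if len(df) == 0:
            raise ValueError("annotation table is empty")
        if df["cell_id"].duplicated().any():
            dups = df.loc[df["cell_id"].duplicated(), "cell_id"].head(3).tolist()
            raise ValueError(f"duplicate cell_id values, e.g. {dups}")
        cond_per_sample = df.groupby("sample_id", sort=False)["condition"].nunique()
        bad = cond_per_sample[cond_per_sample > 1]
        if len(bad):
            raise ValueError(
                f"samples mapped to multiple conditions: {bad.index.tolist()[:3]}"
            )
        self.df = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def samples(self) -> list[str]:
        return list(dict.fromkeys(self.df["sample_id"]))

    @property
    def cell_types(self) -> list[str]:
        return sorted(self.df["cell_type"].unique())


class ProportionMatrix:
    """Samples x cell types matrix of fractions with condition labels.

    Parameters
    ----------
    values
        DataFrame indexed by sample id, columns = cell-type names, entries
        fractions in [0, 1].
    condition_of
        Mapping / Series sample id -> condition label. May cover a superset
        of the samples present.
    source
        ``"scRNA"`` for ground truth derived from annotations, or
        ``"deconvolution:<method>"`` for an estimated matrix.
    """

    def __init__(
        self,
        values: pd.DataFrame,
        condition_of: Union[Mapping[str, str], pd.Series],
        source: str = "deconvolution:unknown",
    ):
        values = values.astype(float)
        if (values.values < 0).any() or (values.values > 1).any():
            bad = np.argwhere((values.values < 0) | (values.values > 1))[0]
            raise ValueError(
                f"proportion out of [0, 1] at sample {values.index[bad[0]]!r}, "
                f"cell type {values.columns[bad[1]]!r}"
            )
        if values.index.duplicated().any():
            raise ValueError("duplicate sample ids in proportion matrix")
        if values.columns.duplicated().any():
            raise ValueError("duplicate cell-type names in proportion matrix")
        cond = pd.Series(dict(condition_of)) if not isinstance(condition_of, pd.Series) else condition_of
        missing = [s for s in values.index if s not in cond.index]
        if missing:
            raise ValueError(f"no condition label for samples: {missing[:5]}")
        self.values = values
        self.condition_of = cond.loc[values.index]
        self.source = source

    # -- basic views ----------------------------------------------------
    @property
    def samples(self) -> list[str]:
        return list(self.values.index)

    @property
    def cell_types(self) -> list[str]:
        return list(self.values.columns)

    @property
    def conditions(self) -> list[str]:
        return list(pd.unique(self.condition_of))

    @property
    def is_scrna(self) -> bool:
        return self.source == "scRNA"

    def column(self, cell_type: str) -> pd.Series:
        return self.values[cell_type]

    def subset_samples(self, sample_ids) -> "ProportionMatrix":
        return ProportionMatrix(
            self.values.loc[list(sample_ids)], self.condition_of, self.source
        )

    def samples_in_condition(self, condition: str) -> list[str]:
        return list(self.condition_of.index[self.condition_of == condition])

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"ProportionMatrix({len(self.samples)} samples x "
            f"{len(self.cell_types)} cell types, source={self.source!r})"
        )


class SurvivalTable:
    """Right-censored survival data: (sample_id, time, event, covariates...)."""

    def __init__(self, df: pd.DataFrame):
        for col in ("sample_id", "time", "event"):
            if col not in df.columns:
                raise ValueError(f"survival table missing column {col!r}")
        df = df.copy()
        df["time"] = pd.to_numeric(df["time"])
        if (df["time"] < 0).any():
            bad = df.loc[df["time"] < 0, "sample_id"].head(3).tolist()
            raise ValueError(f"negative survival time for samples {bad}")
        ev = pd.to_numeric(df["event"])
        if not ev.isin([0, 1]).all():
            bad = df.loc[~ev.isin([0, 1]), "sample_id"].head(3).tolist()
            raise ValueError(f"event values must be 0/1; offending samples {bad}")
        df["event"] = ev.astype(int)
        if df["sample_id"].duplicated().any():
            raise ValueError("duplicate sample_id in survival table")
        self.df = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def covariate_columns(self) -> list[str]:
        return [c for c in self.df.columns if c not in ("sample_id", "time", "event")]

    def aligned_to(self, sample_ids) -> pd.DataFrame:
        """Rows for the given samples, in that order; missing ids are dropped."""
        sub = self.df.set_index("sample_id")
        keep = [s for s in sample_ids if s in sub.index]
        return sub.loc[keep].reset_index()


@dataclass
class CohortBundle:
    """One cohort: a proportion matrix plus optional survival data."""

    name: str
    proportions: ProportionMatrix
    survival: Optional[SurvivalTable] = None
    platform: str = "none"  # {rnaseq, microarray, none}


# ----------------------------------------------------------------------
# readers / writers
# ----------------------------------------------------------------------

def _sniff_sep(path: Path) -> str:
    with open(path) as fh:
        header = fh.readline()
    return "\t" if "\t" in header else ","


def read_proportions(
    path,
    condition_map: Union[Mapping[str, str], pd.Series],
    source: str = "deconvolution:unknown",
    renormalize: bool = False,
    sum_tol: float = DEFAULT_SUM_TOL,
) -> ProportionMatrix:
    """Read a delimited proportion matrix (header = cell types, first column
    = sample ids) and validate it.

    ``renormalize=True`` rescales every row to sum 1. Otherwise rows of a
    deconvolution matrix deviating from 1 by at most ``sum_tol`` are
    renormalized with a warning and larger deviations raise.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sniff_sep(path), index_col=0)
    df.index = df.index.astype(str).str.strip()
    df.columns = [str(c).strip() for c in df.columns]
    for col in df.columns:
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any():
            row = df.index[bad.argmax()]
            raise ValueError(f"non-numeric value at sample {row!r}, cell type {col!r}")
    df = df.astype(float)
    if (df.values < 0).any():
        i, j = np.argwhere(df.values < 0)[0]
        raise ValueError(
            f"negative proportion at sample {df.index[i]!r}, cell type {df.columns[j]!r}"
        )
    sums = df.sum(axis=1)
    if renormalize:
        df = df.div(sums, axis=0)
    elif source != "scRNA":
        off = (sums - 1.0).abs()
        if (off > sum_tol).any():
            worst = off.idxmax()
            raise ValueError(
                f"row sum {sums[worst]:.6f} for sample {worst!r} deviates from 1 "
                f"by more than {sum_tol}; pass renormalize=True to override"
            )
        if (off > 1e-6).any():
            warnings.warn(
                f"{int((off > 1e-6).sum())} rows renormalized (sum drift <= {sum_tol})"
            )
            df = df.div(sums, axis=0)
    return ProportionMatrix(df, condition_map, source=source)


def write_proportions(pm: ProportionMatrix, path) -> None:
    out = pm.values.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t", float_format="%.10g")


def proportions_from_annotations(ann: CellAnnotationTable) -> ProportionMatrix:
    """Ground-truth proportions: per sample, fraction of cells of each type.

    Rows sum to 1 exactly; the matrix carries ``source="scRNA"``.
    """
    counts = (
        ann.df.groupby(["sample_id", "cell_type"], sort=True)
        .size()
        .unstack(fill_value=0)
    )
    fractions = counts.div(counts.sum(axis=1), axis=0)
    cond = ann.df.drop_duplicates("sample_id").set_index("sample_id")["condition"]
    return ProportionMatrix(fractions, cond, source="scRNA")


def merge_compartments(
    pm: ProportionMatrix, mapping: Mapping[str, str]
) -> ProportionMatrix:
    """Sum mapped cell types into compartment columns (e.g. tumor + other
    epithelial cells into one epithelial compartment); unmapped types pass
    through unchanged. Row sums are conserved.
    """
    unknown = [k for k in mapping if k not in pm.cell_types]
    if unknown:
        raise ValueError(f"mapping keys not in matrix: {unknown}")
    if not mapping:
        return pm
    unmapped = [c for c in pm.cell_types if c not in mapping]
    collisions = set(mapping.values()) & set(unmapped)
    if collisions:
        raise ValueError(
            f"compartment name collides with unmapped cell type: {sorted(collisions)}"
        )
    target = {c: mapping.get(c, c) for c in pm.cell_types}
    merged = pm.values.T.groupby(pm.values.columns.map(target)).sum().T
    # keep a stable order: unmapped types first (original order), then new compartments
    new_cols = [c for c in pm.cell_types if c not in mapping]
    new_cols += [c for c in dict.fromkeys(mapping.values()) if c not in new_cols]
    merged = merged[new_cols]
    return ProportionMatrix(merged, pm.condition_of, pm.source)


def apply_alias_map(pm: ProportionMatrix, alias: Mapping[str, str]) -> ProportionMatrix:
    """Harmonize cell-type labels across cohorts via an alias map
    (old name -> canonical name). Aliases collapsing onto one canonical
    name are summed, like compartment merging."""
    relevant = {k: v for k, v in alias.items() if k in pm.cell_types}
    return merge_compartments(pm, relevant) if relevant else pm


def read_alias_map(path) -> dict[str, str]:
    with open(path) as fh:
        data = json.load(fh)
    if not isinstance(data, dict):
        raise ValueError("alias map must be a JSON object of old -> new names")
    return {str(k).strip(): str(v).strip() for k, v in data.items()}


def read_survival(
    path, time_col: str = "time", event_col: str = "event", sample_col: str = "sample_id"
) -> SurvivalTable:
    path = Path(path)
    df = pd.read_csv(path, sep=_sniff_sep(path))
    df = df.rename(columns={time_col: "time", event_col: "event", sample_col: "sample_id"})
    df["sample_id"] = df["sample_id"].astype(str).str.strip()
    return SurvivalTable(df)


def write_survival(surv: SurvivalTable, path) -> None:
    surv.df.to_csv(path, sep="\t", index=False, float_format="%.10g")
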