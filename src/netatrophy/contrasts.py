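"""Patient-subtype contrasts and clinical-table utilities.

Covers the subtype comparisons used for spinal- vs bulbar-onset analyses:
parcelwise two-sample t-tests of individual epicenter maps (FDR across
parcels), Mann-Whitney U contrasts of clinical measures computed on observed
values only (FDR across measures, sparsely observed measures excluded), and
median imputation of missing clinical entries for analyses that cannot drop
rows (e.g., PLS).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .nulls import fdr_bh

__all__ = [
    "ClinicalTable",
    "GroupedMaps",
    "impute_median",
    "parcelwise_ttest",
    "behavioral_contrast",
]


@dataclass
class ClinicalTable:
    """Subject x measure clinical data with NaN as the missing marker."""

    data: pd.DataFrame
    groups: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        if not isinstance(self.data, pd.DataFrame):
            self.data = pd.DataFrame(np.asarray(self.data, dtype=float))
        if self.data.columns.duplicated().any():
            raise ValueError("measure names must be unique")
        if self.groups is not None:
            self.groups = np.asarray(self.groups)
            if self.groups.size != len(self.data):
                raise ValueError("groups length does not match subjects")


@dataclass
class GroupedMaps:
    """Subject x parcel map stack with a per-subject group label."""

    maps: np.ndarray
    groups: np.ndarray

    def __post_init__(self) -> None:
        self.maps = np.atleast_2d(np.asarray(self.maps, dtype=float))
        self.groups = np.asarray(self.groups)
        if self.groups.size != self.maps.shape[0]:
            raise ValueError("groups length does not match map stack rows")


def impute_median(table: ClinicalTable) -> tuple[ClinicalTable, pd.DataFrame]:
    """Replace missing cells by the observed per-measure median.

    Returns the imputed table and a boolean mask of imputed cells.  A measure
    with no observed values cannot be imputed and raises.
    """
    df = table.data
    fully_missing = df.columns[df.isna().all()]
    if len(fully_missing):
        raise ValueError(
            f"measure(s) fully missing: {list(fully_missing)}"
        )
    mask = df.isna()
    imputed = df.fillna(df.median())
    return ClinicalTable(imputed, table.groups), mask


def parcelwise_ttest(
    maps: GroupedMaps,
    group_a,
    group_b,
    equal_var: bool = True,
) -> dict:
    """Independent two-sample t per parcel (a minus b), two-sided, BH-FDR.

    Pooled-variance (Student) t by default; ``equal_var=False`` gives Welch.
    Parcels with zero pooled variance return NaN.
    """
    a = maps.maps[maps.groups == group_a]
    b = maps.maps[maps.groups == group_b]
    if a.shape[0] < 3 or b.shape[0] < 3:
        raise ValueError("each group needs >= 3 subjects")
    with np.errstate(invalid="ignore", divide="ignore"):
        res = stats.ttest_ind(a, b, axis=0, equal_var=equal_var)
    t = np.asarray(res.statistic, dtype=float)
    p = np.asarray(res.pvalue, dtype=float)
    degenerate = (a.std(axis=0) == 0) & (b.std(axis=0) == 0)
    t[degenerate] = np.nan
    p[degenerate] = np.nan
    return {"t": t, "p": p, "p_fdr": fdr_bh(p)}


def behavioral_contrast(
    table: ClinicalTable,
    group_a,
    group_b,
    min_observed: int = 20,
    exact_max_n: int = 8,
) -> pd.DataFrame:
    """Two-sided Mann-Whitney U per measure on observed values only.

    Measures observed in fewer than ``min_observed`` subjects overall are
    excluded (reported with NaN statistics); the exact null distribution is
    used when both groups have at most ``exact_max_n`` observations, the
    tie-corrected normal approximation otherwise.  BH-FDR across the tested
    measures.
    """
    if table.groups is None:
        raise ValueError("table has no group labels")
    ga = table.groups == group_a
    gb = table.groups == group_b
    rows = []
    for m in table.data.columns:
        col = table.data[m].to_numpy(dtype=float)
        xa = col[ga]
        xb = col[gb]
        xa = xa[~np.isnan(xa)]
        xb = xb[~np.isnan(xb)]
        n_obs = int(np.sum(~np.isnan(col)))
        if n_obs < min_observed:
            rows.append((m, n_obs, np.nan, np.nan, "excluded"))
            continue
        if xa.size < 2 or xb.size < 2:
            raise ValueError(f"measure {m!r}: fewer than 2 observed per group")
        method = ("exact" if (xa.size <= exact_max_n and xb.size <= exact_max_n
                              and np.unique(np.r_[xa, xb]).size
                              == xa.size + xb.size)
                  else "asymptotic")
        res = stats.mannwhitneyu(xa, xb, alternative="two-sided",
                                 method=method)
        rows.append((m, n_obs, float(res.statistic), float(res.pvalue),
                     method))
    out = pd.DataFrame(rows, columns=["measure", "n_observed", "U", "p",
                                      "method"]).set_index("measure")
    out["p_fdr"] = fdr_bh(out["p"].to_numpy())
    return out
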