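"""Normative w-score atrophy maps and their parcel/tract/class aggregation.

Deformation-based morphometry (DBM) values are modelled, voxelwise and within
each imaging-site stratum, by an ordinary least squares fit on healthy
controls:

    expected = beta1 * age + beta2 * sex + beta3

The w-score of a subject at a voxel is the deviation of the observed value
from this normative expectation, standardized by the control residual SD, and
then sign-inverted so that larger values mean more atrophy:

    w = -(observed - expected) / std(control residuals)

Aggregation utilities reduce voxel maps to parcels (mean over member voxels),
test mean atrophy within white-matter tracts (one-sample t against 0, FDR),
and score cytoarchitectonic-class enrichment against spin surrogates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator

from .nulls import fdr_bh, nonparametric_p, spin_surrogates

__all__ = [
    "VoxelCohort",
    "NormativeModel",
    "WScoreMap",
    "fit_normative_model",
    "compute_wscores",
    "parcellate",
    "class_enrichment",
    "tract_atrophy_test",
]

CONTROL, PATIENT = 0, 1


@dataclass
class VoxelCohort:
    """Per-subject voxel morphometry values with demographic covariates.

    ``values`` is subjects x voxels (DBM Jacobian-determinant scale); ``sex``
    is 0/1 coded; ``site`` is a categorical site(-phase) stratum; ``group`` is
    0 for controls, 1 for patients.
    """

    values: np.ndarray
    age: np.ndarray
    sex: np.ndarray
    site: np.ndarray
    group: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        self.age = np.asarray(self.age, dtype=float)
        self.sex = np.asarray(self.sex)
        self.site = np.asarray(self.site)
        self.group = np.asarray(self.group)
        n = self.values.shape[0]
        for name in ("age", "sex", "site", "group"):
            arr = getattr(self, name)
            if arr.shape[0] != n:
                raise ValueError(f"{name} length {arr.shape[0]} != {n} subjects")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("voxel values contain non-finite entries")
        if np.any(np.isnan(self.age)):
            raise ValueError("missing age covariate")
        ctrl = self.group == CONTROL
        for s in np.unique(self.site):
            if np.sum(ctrl & (self.site == s)) < 3:
                raise ValueError(
                    f"site {s!r} has fewer than 3 controls; "
                    "normative model unfittable"
                )

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.values.shape[1]

    def subset(self, mask: np.ndarray) -> "VoxelCohort":
        c = object.__new__(VoxelCohort)
        c.values = self.values[mask]
        c.age = self.age[mask]
        c.sex = self.sex[mask]
        c.site = self.site[mask]
        c.group = self.group[mask]
        return c


@dataclass
class WScoreMap:
    """Sign-inverted w-scores (subjects x voxels or parcels; SD units)."""

    values: np.ndarray
    subjects: np.ndarray | None = field(default=None)


class NormativeModel(BaseEstimator):
    """Site-stratified voxelwise normative OLS model of morphometry.

    For each site stratum the control values at every voxel are regressed on
    [age, sex, 1]; the residual standard deviation (divisor ``ddof``, default
    n-1) standardizes subsequent deviations.  Voxels whose residual SD is zero
    to within a relative numerical tolerance are flagged degenerate and yield
    NaN w-scores.

    Fitted attributes
    -----------------
    coef_ : dict site -> (3, n_voxels) array of [beta_age, beta_sex, beta_intercept]
    residual_sd_ : dict site -> (n_voxels,) control residual SD
    degenerate_ : dict site -> boolean mask of zero-residual-SD voxels
    """

    def __init__(self, ddof: int = 1):
        self.ddof = ddof

    def fit(self, cohort: VoxelCohort) -> "NormativeModel":
        coef, sd, degen = {}, {}, {}
        ctrl = cohort.group == CONTROL
        for s in np.unique(cohort.site):
            m = ctrl & (cohort.site == s)
            X = np.column_stack([
                cohort.age[m],
                np.asarray(cohort.sex[m], dtype=float),
                np.ones(int(m.sum())),
            ])
            if np.linalg.matrix_rank(X) < X.shape[1]:
                raise ValueError(
                    f"rank-deficient design in site stratum {s!r} "
                    "(e.g., single-sex site)"
                )
            beta, *_ = np.linalg.lstsq(X, cohort.values[m], rcond=None)
            resid = cohort.values[m] - X @ beta
            n = int(m.sum())
            sd_s = np.sqrt((resid**2).sum(axis=0) / (n - self.ddof))
            coef[s] = beta
            sd[s] = sd_s
            scale = np.maximum(1.0, np.abs(cohort.values[m]).max(axis=0))
            degen[s] = sd_s <= 1e-8 * scale
        self.coef_ = coef
        self.residual_sd_ = sd
        self.degenerate_ = degen
        self.n_voxels_ = cohort.n_voxels
        return self

    def predict(self, cohort: VoxelCohort) -> np.ndarray:
        """Expected (normative) values per subject and voxel."""
        out = np.empty_like(cohort.values)
        for s in np.unique(cohort.site):
            if s not in self.coef_:
                raise ValueError(f"site {s!r} absent from fitted model")
            m = cohort.site == s
            X = np.column_stack([
                cohort.age[m],
                np.asarray(cohort.sex[m], dtype=float),
                np.ones(int(m.sum())),
            ])
            out[m] = X @ self.coef_[s]
        return out

    def transform(self, cohort: VoxelCohort, target_group=None) -> WScoreMap:
        """Sign-inverted w-scores for ``target_group`` (default: all subjects)."""
        if target_group is not None:
            cohort = cohort.subset(cohort.group == target_group)
        expected = self.predict(cohort)
        w = np.empty_like(cohort.values)
        for s in np.unique(cohort.site):
            m = cohort.site == s
            sd = self.residual_sd_[s]
            with np.errstate(invalid="ignore", divide="ignore"):
                w[m] = -(cohort.values[m] - expected[m]) / sd
            w[np.ix_(np.flatnonzero(m), np.flatnonzero(self.degenerate_[s]))] = np.nan
        return WScoreMap(w)


def fit_normative_model(cohort: VoxelCohort, ddof: int = 1) -> NormativeModel:
    """Fit the site-stratified normative OLS model on the cohort's controls."""
    return NormativeModel(ddof=ddof).fit(cohort)


def compute_wscores(
    cohort: VoxelCohort, model: NormativeModel, target_group=PATIENT
) -> WScoreMap:
    """Sign-inverted w-scores of ``target_group`` under a fitted model."""
    if cohort.n_voxels != model.n_voxels_:
        raise ValueError("model fitted on a different voxel space")
    return model.transform(cohort, target_group=target_group)


def parcellate(
    voxel_values: np.ndarray,
    labels: np.ndarray,
    reduction: str = "mean",
) -> np.ndarray:
    """Reduce voxel values to parcels given an integer label per voxel.

    Label 0 is background and never contributes.  Works on a single map
    (1-D) or a subjects x voxels stack; parcels with no member voxels are NaN.
    Parcel p occupies output index p-1.
    """
    labels = np.asarray(labels)
    if labels.ndim != 1 or np.any(labels < 0):
        raise ValueError("labels must be a 1-D array of nonnegative integers")
    v = np.asarray(voxel_values, dtype=float)
    single = v.ndim == 1
    v = np.atleast_2d(v)
    if v.shape[1] != labels.size:
        raise ValueError("labels length does not match voxel dimension")
    n_parcels = int(labels.max())
    if n_parcels == 0:
        raise ValueError("labels contain only background")
    reducers = {"mean": np.nanmean, "median": np.nanmedian, "sum": np.nansum}
    if reduction not in reducers:
        raise ValueError(f"unknown reduction {reduction!r}")
    red = reducers[reduction]
    out = np.full((v.shape[0], n_parcels), np.nan)
    for p in range(1, n_parcels + 1):
        m = labels == p
        if m.any():
            block = v[:, m]
            with np.errstate(invalid="ignore"):
                out[:, p - 1] = red(block, axis=1)
    return out[0] if single else out


def class_enrichment(
    parcel_map: np.ndarray,
    class_labels: np.ndarray,
    coordinates: np.ndarray,
    n_spin: int = 1000,
    rng: np.random.Generator | None = None,
) -> dict:
    """Mean atrophy per cytoarchitectonic class with one-sided spin p-values.

    Each class's statistic is the mean of the map over its member parcels; the
    null is the same statistic on spin surrogates; p = add-one probability that
    a surrogate class mean is at least the observed one; BH-FDR across classes.
    """
    if rng is None:
        raise ValueError("rng is required")
    if n_spin < 100:
        raise ValueError("need n_spin >= 100")
    parcel_map = np.asarray(parcel_map, dtype=float)
    class_labels = np.asarray(class_labels)
    classes = np.unique(class_labels)
    for c in classes:
        if not np.any(class_labels == c):
            raise ValueError(f"empty class {c!r}")
    surr = spin_surrogates(coordinates, parcel_map, n_spin, rng)
    means = np.empty(len(classes))
    ps = np.empty(len(classes))
    for k, c in enumerate(classes):
        m = class_labels == c
        means[k] = np.nanmean(parcel_map[m])
        null_means = np.nanmean(surr[:, m], axis=1)
        ps[k] = nonparametric_p(means[k], null_means,
                                sidedness="one_sided_greater").p_value
    return {
        "classes": classes,
        "mean": means,
        "p_spin": ps,
        "p_fdr": fdr_bh(ps),
    }


def tract_atrophy_test(
    wscores: WScoreMap,
    tract_labels: np.ndarray,
    two_sample_groups: np.ndarray | None = None,
) -> dict:
    """Tract-level atrophy test on subject mean w-scores.

    Default: one-sample two-sided t-test of per-subject tract-mean inverted
    w-scores against 0 (w-scores already encode deviation from the control
    norm).  Passing ``two_sample_groups`` (0/1 per subject) switches to an
    independent two-sample t-test between the groups.  BH-FDR across tracts.
    """
    w = np.atleast_2d(wscores.values)
    if w.shape[0] < 3:
        raise ValueError("need >= 3 subjects")
    tract_means = parcellate(w, tract_labels)  # subjects x tracts
    n_tracts = tract_means.shape[1]
    t = np.empty(n_tracts)
    p = np.empty(n_tracts)
    for k in range(n_tracts):
        col = tract_means[:, k]
        col = col[~np.isnan(col)]
        if two_sample_groups is None:
            if col.size and col.std() == 0:
                raise ValueError(f"zero variance across subjects in tract {k + 1}")
            res = stats.ttest_1samp(col, 0.0)
        else:
            g = np.asarray(two_sample_groups)[~np.isnan(tract_means[:, k])]
            res = stats.ttest_ind(col[g == 0], col[g == 1])
        t[k], p[k] = res.statistic, res.pvalue
    return {"t": t, "p": p, "p_fdr": fdr_bh(p)}
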