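"""Disease exposure and data-driven epicenter mapping on weighted networks.

The *disease exposure* of parcel i is the weighted mean atrophy of its directly
connected neighbours,

    D_i = (1 / C_i) * sum_{j != i} d_j * c_ij,      C_i = sum_{j != i} c_ij,

where d_j is neighbour atrophy and c_ij the edge weight.  A positive
correlation between a parcel's own atrophy and its exposure indicates that
pathology patterns itself on network connectivity.  The data-driven epicenter
likelihood of a parcel is its mean rank across two ascending rankings — own
atrophy and exposure — so that parcels that are both highly atrophied and
connected to highly atrophied neighbours score highest.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .network import WeightedNetwork
from .nulls import nonparametric_p, spin_surrogates

__all__ = [
    "ExposureMap",
    "EpicenterMap",
    "neighbour_exposure",
    "node_neighbour_correlation",
    "epicenter_rank",
    "joint_regression_gain",
]


@dataclass
class ExposureMap:
    """Per-parcel disease exposure D_i; NaN where the weighted degree is 0."""

    values: np.ndarray


@dataclass
class EpicenterMap:
    """Per-parcel epicenter likelihood.

    ``method="rank"`` values are mean ranks in [1, n]; ``method="sir"`` values
    are maximal simulated-vs-observed correlations in [-1, 1].  Larger values
    always mean more epicenter-like.
    """

    values: np.ndarray
    method: str


def _as_map(atrophy) -> np.ndarray:
    a = np.asarray(atrophy, dtype=float)
    if a.ndim != 1:
        raise ValueError("atrophy map must be 1-D")
    return a


def neighbour_exposure(network: WeightedNetwork, atrophy) -> ExposureMap:
    """Weighted mean atrophy of each parcel's neighbours (disease exposure)."""
    a = _as_map(atrophy)
    if a.size != network.n_parcels:
        raise ValueError("atrophy length does not match network size")
    C = network.strength
    with np.errstate(invalid="ignore", divide="ignore"):
        D = network.weights @ a / C
    D[C == 0] = np.nan
    return ExposureMap(D)


def node_neighbour_correlation(
    network: WeightedNetwork,
    atrophy,
    method: str = "pearson",
) -> tuple[float, np.ndarray, np.ndarray]:
    """Correlation between parcel atrophy and neighbour exposure.

    Parcels with undefined exposure (weighted degree 0) are excluded pairwise.
    Returns ``(r, atrophy_used, exposure_used)`` so callers can plot or feed
    null models.
    """
    a = _as_map(atrophy)
    D = neighbour_exposure(network, a).values
    ok = ~np.isnan(D) & ~np.isnan(a)
    if ok.sum() < 3:
        raise ValueError("fewer than 3 parcels with defined exposure")
    x, y = a[ok], D[ok]
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance; correlation undefined")
    if method == "pearson":
        r = stats.pearsonr(x, y).statistic
    elif method == "spearman":
        r = stats.spearmanr(x, y).statistic
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(r), x, y


def _ascending_rank(values: np.ndarray) -> np.ndarray:
    """Fractional ranks, ascending (largest value -> rank n); ties averaged."""
    return stats.rankdata(values, method="average", nan_policy="omit")


def epicenter_rank(network: WeightedNetwork, atrophy) -> EpicenterMap:
    """Data-driven epicenter likelihood by dual ranking.

    Parcels are ranked ascending by their own atrophy and, separately, by
    their neighbour exposure; the epicenter likelihood is the mean of the two
    ranks.  Parcels with undefined exposure are excluded (NaN).
    """
    a = _as_map(atrophy)
    D = neighbour_exposure(network, a).values
    ok = ~np.isnan(D) & ~np.isnan(a)
    if ok.sum() == 0:
        raise ValueError("no parcel has defined exposure")
    sub_a, sub_D = a[ok], D[ok]
    if np.unique(sub_a).size == 1 and np.unique(sub_D).size == 1:
        raise ValueError("all values tied in both rankings; epicenter undefined")
    mean_rank = 0.5 * (_ascending_rank(sub_a) + _ascending_rank(sub_D))
    out = np.full(a.shape, np.nan)
    out[ok] = mean_rank
    return EpicenterMap(out, method="rank")


def _adjusted_r2(y: np.ndarray, X: np.ndarray) -> float:
    """Adjusted R^2 of an OLS fit with intercept."""
    n, k = X.shape
    design = np.column_stack([np.ones(n), X])
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    ss_res = resid @ resid
    ss_tot = np.sum((y - y.mean()) ** 2)
    r2 = 1.0 - ss_res / ss_tot
    return float(1.0 - (1.0 - r2) * (n - 1) / (n - k - 1))


def joint_regression_gain(
    atrophy,
    network_a: WeightedNetwork,
    network_b: WeightedNetwork,
    coordinates: np.ndarray | None = None,
    n_spin: int = 1000,
    rng: np.random.Generator | None = None,
) -> dict:
    """Does a second similarity network add predictive value beyond the first?

    Atrophy is regressed on (1) its exposure under ``network_a`` (typically the
    structural connectome) and (2) its exposure under ``network_b`` (a
    biological similarity network).  Reported are the adjusted R^2 of the one-
    and two-regressor fits and a one-sided spin p-value for the adjusted-R^2
    gain: the null replaces the second regressor with exposure (under
    ``network_b``) of a spin-rotated atrophy map — a regressor with matched
    spatial autocorrelation but no alignment to the observed atrophy.
    """
    if rng is None:
        raise ValueError("rng is required")
    a = _as_map(atrophy)
    n = a.size
    if n < 10:
        raise ValueError("need >= 10 parcels")
    coords = coordinates if coordinates is not None else network_a.coordinates
    if coords is None:
        raise ValueError("coordinates required for the spin null")
    exp_a = neighbour_exposure(network_a, a).values
    exp_b = neighbour_exposure(network_b, a).values
    ok = ~np.isnan(exp_a) & ~np.isnan(exp_b) & ~np.isnan(a)
    if ok.sum() <= 3:
        raise ValueError("insufficient degrees of freedom for two regressors")
    collinear = False
    r_ab = np.corrcoef(exp_a[ok], exp_b[ok])[0, 1]
    if abs(r_ab) > 0.999:
        warnings.warn("regressors nearly collinear; gain reported as <= 0",
                      stacklevel=2)
        collinear = True
    adj_a = _adjusted_r2(a[ok], exp_a[ok, None])
    adj_ab = _adjusted_r2(a[ok], np.column_stack([exp_a[ok], exp_b[ok]]))
    gain = adj_ab - adj_a
    if collinear:
        gain = min(gain, 0.0)
    surr = spin_surrogates(coords, a, n_spin, rng)
    null_gain = np.empty(n_spin)
    for s in range(n_spin):
        exp_null = neighbour_exposure(network_b, surr[s]).values
        okn = ok & ~np.isnan(exp_null)
        adj2 = _adjusted_r2(
            a[okn], np.column_stack([exp_a[okn], exp_null[okn]])
        )
        null_gain[s] = adj2 - _adjusted_r2(a[okn], exp_a[okn, None])
    ens = nonparametric_p(gain, null_gain, sidedness="one_sided_greater",
                          method="spin")
    return {
        "adj_r2_a": adj_a,
        "adj_r2_ab": adj_ab,
        "gain": gain,
        "p_spin": ens.p_value,
        "null_gains": null_gain,
    }
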