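"""Null models: spin surrogates, network rewiring, nonparametric p-values, FDR.

Three families of nulls are used to benchmark spatial associations:

* **spin surrogates** — random SO(3) rotations of spherical parcel centroids
  with nearest-neighbour value reassignment; destroys the alignment between
  values and locations while preserving the map's spatial autocorrelation;
* **degree-preserving rewiring** — Maslov-Sneppen double-edge swaps that
  randomize topology while keeping the binary degree sequence (weights travel
  with their edges);
* **degree- and length-preserving rewiring** — double-edge swaps restricted to
  edges in the same Euclidean-distance bin, additionally preserving the edge
  length distribution.

Nonparametric p-values use the add-one convention p = (k+1)/(n+1), whose floor
at n = 1000 surrogates is 1/1001 ~ 9.99e-4.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation
from statsmodels.stats.multitest import multipletests

from .network import WeightedNetwork

__all__ = [
    "SurrogateEnsemble",
    "spin_surrogates",
    "spin_assignments",
    "rewire_degree_preserving",
    "rewire_distance_binned",
    "nonparametric_p",
    "fdr_bh",
]


@dataclass
class SurrogateEnsemble:
    """Observed statistic with its null distribution and add-one p-value."""

    observed: float
    nulls: np.ndarray
    method: str
    sidedness: str
    p_value: float


def _check_sphere(coordinates: np.ndarray, tol: float = 1e-6) -> np.ndarray:
    coords = np.asarray(coordinates, dtype=float)
    radii = np.linalg.norm(coords, axis=1)
    if radii.min() <= 0:
        raise ValueError("coordinates include the origin; cannot project to sphere")
    rel_spread = (radii.max() - radii.min()) / radii.mean()
    return coords, rel_spread, radii


def _assign_for_rotation(
    coords: np.ndarray, R: np.ndarray, donors: np.ndarray
) -> np.ndarray:
    """Nearest-donor index per parcel after rotating donor centroids by R."""
    rotated = coords[donors] @ R.T
    tree = cKDTree(rotated)
    _, idx = tree.query(coords)
    return donors[idx]


def spin_assignments(
    coordinates: np.ndarray,
    n: int,
    rng: np.random.Generator,
    mask: np.ndarray | None = None,
    hemispheres: np.ndarray | None = None,
    auto_project: bool = False,
    sphere_tol: float = 1e-6,
) -> np.ndarray:
    """Generate ``n`` spin reassignment index vectors.

    Each row ``a`` maps an original parcel ``i`` to the source parcel
    ``a[i]`` whose rotated centroid lies closest to centroid ``i``; a spun
    surrogate of a map ``v`` is then ``v[a]``.  Computing assignments once and
    reusing them across many maps with shared coordinates is the fast path for
    ensemble nulls.

    Parameters
    ----------
    mask : boolean array, optional
        Parcels marked True (e.g., medial wall) never donate values: when the
        nearest rotated parcel is masked, the next closest unmasked parcel is
        used instead.
    hemispheres : array of {0, 1}, optional
        Two-hemisphere mode: hemisphere 1 receives the x-mirrored rotation so
        left/right maps rotate in mirror symmetry.
    """
    coords, rel_spread, radii = _check_sphere(coordinates)
    if rel_spread > sphere_tol:
        if not auto_project:
            raise ValueError(
                "centroids are not on a sphere (relative radius spread "
                f"{rel_spread:.3g}); pass auto_project=True to project"
            )
        coords = coords / radii[:, None] * radii.mean()
    if n < 1:
        raise ValueError("need n >= 1 surrogates")
    n_parcels = coords.shape[0]
    mask = None if mask is None else np.asarray(mask, dtype=bool)
    donors = np.arange(n_parcels) if mask is None else np.flatnonzero(~mask)
    if mask is not None and donors.size == 0:
        raise ValueError("all parcels masked")
    rotations = Rotation.random(num=n, random_state=rng)
    mirror = np.diag([-1.0, 1.0, 1.0])
    out = np.empty((n, n_parcels), dtype=np.intp)
    for k in range(n):
        R = rotations[k].as_matrix()
        if hemispheres is None:
            out[k] = _assign_for_rotation(coords, R, donors)
        else:
            hemis = np.asarray(hemispheres)
            for h, Rh in ((0, R), (1, mirror @ R @ mirror)):
                sel = hemis == h
                don_h = donors[np.isin(donors, np.flatnonzero(sel))]
                rotated = coords[don_h] @ Rh.T
                tree = cKDTree(rotated)
                _, idx = tree.query(coords[sel])
                out[k, sel] = don_h[idx]
    return out


def spin_surrogates(
    coordinates: np.ndarray,
    values: np.ndarray,
    n: int,
    rng: np.random.Generator,
    mask: np.ndarray | None = None,
    hemispheres: np.ndarray | None = None,
    auto_project: bool = False,
) -> np.ndarray:
    """Spatial-autocorrelation-preserving spin surrogates of a parcel map.

    Returns an (n, n_parcels) stack; each row is the original map evaluated at
    randomly rotated centroid positions (nearest-assignment, so values may
    repeat or drop but are always drawn from the original multiset).
    """
    values = np.asarray(values, dtype=float)
    assign = spin_assignments(
        coordinates, n, rng, mask=mask, hemispheres=hemispheres,
        auto_project=auto_project,
    )
    return values[assign]


def rewire_degree_preserving(
    network: WeightedNetwork,
    rng: np.random.Generator,
    swaps_per_edge: int = 10,
) -> WeightedNetwork:
    """Maslov-Sneppen rewired network: same size, density, and degree sequence.

    Attempts ``swaps_per_edge * n_edges`` double-edge swaps
    (a-b, c-d) -> (a-d, c-b); a swap is rejected when it would create a
    self-loop or a multi-edge.  Weights travel with their edges.  Warns when no
    valid swap was ever achieved.
    """
    edges = network.edge_list()
    m = len(edges)
    if m < 2:
        raise ValueError("need at least 2 edges to rewire")
    w = network.weights
    weights = w[edges[:, 0], edges[:, 1]].copy()
    edges = edges.copy()
    adj = {tuple(e) for e in map(tuple, edges)}
    adj |= {(j, i) for i, j in adj}
    attempts = swaps_per_edge * m
    achieved = 0
    pick = rng.integers(0, m, size=(attempts, 2))
    flips = rng.random(attempts) < 0.5
    for t in range(attempts):
        e1, e2 = pick[t]
        if e1 == e2:
            continue
        a, b = edges[e1]
        c, d = edges[e2]
        if flips[t]:
            c, d = d, c
        # propose (a,d) and (c,b)
        if a == d or c == b:
            continue
        if (a, d) in adj or (c, b) in adj:
            continue
        adj -= {(a, b), (b, a), (c, d), (d, c)}
        adj |= {(a, d), (d, a), (c, b), (b, c)}
        edges[e1] = sorted((a, d))
        edges[e2] = sorted((c, b))
        achieved += 1
    if achieved == 0:
        warnings.warn("no valid swaps achieved; network returned unchanged",
                      stacklevel=2)
    new = np.zeros_like(w)
    new[edges[:, 0], edges[:, 1]] = weights
    new[edges[:, 1], edges[:, 0]] = weights
    return WeightedNetwork(new, coordinates=network.coordinates,
                           labels=network.labels)


def rewire_distance_binned(
    network: WeightedNetwork,
    coordinates: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
    n_bins: int = 10,
    swap_factor: int = 20,
    equal_width: bool = False,
) -> WeightedNetwork:
    """Degree- and edge-length-preserving rewired network.

    Edges are assigned to ``n_bins`` Euclidean-distance bins (equal-count by
    default); double-edge swaps are attempted only between edges of the same
    bin and accepted only when both replacement edges fall back inside the
    bin's distance range, so per-bin edge counts (and hence the edge length
    distribution up to bin resolution) are preserved exactly.  Total attempted
    swaps = n_regions * swap_factor, spread over bins proportionally to their
    edge counts.  Bins with fewer than 2 edges are skipped with a warning.
    """
    if rng is None:
        raise ValueError("rng is required")
    coords = coordinates if coordinates is not None else network.coordinates
    if coords is None:
        raise ValueError("coordinates required for distance binning")
    coords = np.asarray(coords, dtype=float)
    edges = network.edge_list()
    m = len(edges)
    if m < 2:
        raise ValueError("need at least 2 edges to rewire")
    w = network.weights
    weights = w[edges[:, 0], edges[:, 1]].copy()
    dist = np.linalg.norm(coords[edges[:, 0]] - coords[edges[:, 1]], axis=1)
    if equal_width:
        bounds = np.linspace(dist.min(), dist.max(), n_bins + 1)
    else:
        bounds = np.quantile(dist, np.linspace(0, 1, n_bins + 1))
    bounds[0] -= 1e-12
    bounds[-1] += 1e-12
    bin_of = np.clip(np.searchsorted(bounds, dist, side="right") - 1, 0,
                     n_bins - 1)

    adj = {tuple(e) for e in map(tuple, edges)}
    adj |= {(j, i) for i, j in adj}
    edges = edges.copy()
    total_attempts = network.n_parcels * swap_factor
    counts = np.bincount(bin_of, minlength=n_bins)
    usable = counts >= 2
    for b in np.flatnonzero(~usable & (counts > 0)):
        warnings.warn(f"distance bin {b} has <2 edges; skipped", stacklevel=2)
    if not usable.any():
        warnings.warn("no bin has >=2 edges; network returned unchanged",
                      stacklevel=2)
        return network.copy()
    probs = np.where(usable, counts, 0).astype(float)
    probs /= probs.sum()
    bin_members = [np.flatnonzero(bin_of == b) for b in range(n_bins)]
    chosen_bins = rng.choice(n_bins, size=total_attempts, p=probs)
    flips = rng.random(total_attempts) < 0.5

    def pair_dist(i, j):
        return np.linalg.norm(coords[i] - coords[j])

    for t in range(total_attempts):
        b = chosen_bins[t]
        members = bin_members[b]
        e1, e2 = rng.choice(members, size=2, replace=False)
        a, bb = edges[e1]
        c, d = edges[e2]
        if flips[t]:
            c, d = d, c
        if a == d or c == bb:
            continue
        if (a, d) in adj or (c, bb) in adj:
            continue
        lo, hi = bounds[b], bounds[b + 1]
        if not (lo < pair_dist(a, d) <= hi and lo < pair_dist(c, bb) <= hi):
            continue
        adj -= {(a, bb), (bb, a), (c, d), (d, c)}
        adj |= {(a, d), (d, a), (c, bb), (bb, c)}
        edges[e1] = sorted((a, d))
        edges[e2] = sorted((c, bb))
    new = np.zeros_like(w)
    new[edges[:, 0], edges[:, 1]] = weights
    new[edges[:, 1], edges[:, 0]] = weights
    return WeightedNetwork(new, coordinates=network.coordinates,
                           labels=network.labels)


def nonparametric_p(
    observed: float,
    nulls: np.ndarray,
    sidedness: str = "one_sided_greater",
    method: str = "spin",
    center: float = 0.0,
) -> SurrogateEnsemble:
    """Add-one nonparametric p-value of an observed statistic against nulls.

    One-sided (greater): k = #{null >= observed}.  Two-sided: k counts nulls at
    least as far from ``center`` as the observed value.  p = (k+1)/(n+1), so
    the smallest attainable p with 1000 nulls is 1/1001 ~ 9.99e-4.
    """
    nulls = np.asarray(nulls, dtype=float)
    if nulls.size == 0:
        raise ValueError("nulls must be non-empty")
    if np.any(np.isnan(nulls)) or np.isnan(observed):
        raise ValueError("NaN in observed statistic or nulls")
    if sidedness == "one_sided_greater":
        k = int(np.sum(nulls >= observed))
    elif sidedness == "two_sided":
        k = int(np.sum(np.abs(nulls - center) >= abs(observed - center)))
    else:
        raise ValueError(f"unknown sidedness {sidedness!r}")
    p = (k + 1) / (nulls.size + 1)
    return SurrogateEnsemble(float(observed), nulls, method, sidedness, p)


def fdr_bh(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1).

    NaN entries are passed through untouched and excluded from the correction.
    """
    p = np.asarray(p_values, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    if ok.any():
        if np.any((p[ok] < 0) | (p[ok] > 1)):
            raise ValueError("p-values must lie in [0, 1]")
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out
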