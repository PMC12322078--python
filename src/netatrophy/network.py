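"""Weighted brain networks: container, validation, and similarity-matrix construction.

A :class:`WeightedNetwork` holds a symmetric nonnegative parcel-by-parcel weight
matrix (streamline density or inter-regional similarity units), optional 3D
parcel centroid coordinates, and optional parcel labels.  All spreading,
epicenter, and null-model routines operate on this container.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = ["WeightedNetwork", "threshold_positive", "build_similarity"]

#: clip bound applied to correlations before Fisher's r-to-z so z stays finite
R_CLIP = 1.0 - 1e-7


@dataclass
class WeightedNetwork:
    """Symmetric weighted network over brain parcels.

    Parameters
    ----------
    weights : (n, n) ndarray
        Symmetric, nonnegative (after thresholding), zero-diagonal weights.
    coordinates : (n, 3) ndarray, optional
        Euclidean parcel centroid positions (needed for spin tests and
        distance-binned rewiring).
    labels : sequence of str, optional
        Parcel names.
    """

    weights: np.ndarray
    coordinates: np.ndarray | None = None
    labels: list[str] | None = field(default=None)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.coordinates is not None:
            self.coordinates = np.asarray(self.coordinates, dtype=float)
        self.validate()

    # -- contract ------------------------------------------------------------
    def validate(self, atol: float = 1e-10) -> None:
        """Check the network invariants; raise ``ValueError`` on violation."""
        w = self.weights
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError(f"weights must be square, got shape {w.shape}")
        if not np.all(np.isfinite(w)):
            raise ValueError("weights contain non-finite entries")
        if not np.allclose(w, w.T, atol=atol, rtol=0):
            raise ValueError("weights must be symmetric")
        if np.any(np.diag(w) != 0):
            raise ValueError("diagonal must be exactly zero")
        if np.any(w < 0):
            raise ValueError("negative weights; apply threshold_positive first")
        if self.coordinates is not None and (
            self.coordinates.shape != (w.shape[0], 3)
        ):
            raise ValueError(
                f"coordinates shape {self.coordinates.shape} does not match "
                f"{w.shape[0]} parcels"
            )
        if self.labels is not None and len(self.labels) != w.shape[0]:
            raise ValueError("labels length does not match parcel count")

    @property
    def n_parcels(self) -> int:
        return self.weights.shape[0]

    @property
    def strength(self) -> np.ndarray:
        """Weighted degree C_i = sum_j c_ij."""
        return self.weights.sum(axis=1)

    @property
    def degree(self) -> np.ndarray:
        """Binary degree (number of nonzero edges per parcel)."""
        return (self.weights > 0).sum(axis=1)

    def edge_list(self) -> np.ndarray:
        """Upper-triangular (i, j) index pairs of existing edges."""
        iu, ju = np.triu_indices(self.n_parcels, k=1)
        mask = self.weights[iu, ju] > 0
        return np.column_stack([iu[mask], ju[mask]])

    def is_connected(self) -> bool:
        """True when every parcel is reachable from parcel 0 over nonzero edges."""
        from scipy.sparse import csr_matrix
        from scipy.sparse.csgraph import connected_components

        n_comp, _ = connected_components(
            csr_matrix(self.weights > 0), directed=False
        )
        return n_comp == 1

    def copy(self) -> "WeightedNetwork":
        return WeightedNetwork(
            self.weights.copy(),
            None if self.coordinates is None else self.coordinates.copy(),
            None if self.labels is None else list(self.labels),
        )


def threshold_positive(
    similarity: np.ndarray,
    coordinates: np.ndarray | None = None,
    labels: list[str] | None = None,
    atol: float = 1e-8,
) -> WeightedNetwork:
    """Zero out negative entries of a similarity matrix and return a network.

    Negative-valued elements are excluded as edges; the diagonal is zeroed;
    positive entries pass through unchanged.

    Raises
    ------
    ValueError
        If the input is asymmetric beyond ``atol``.
    """
    s = np.asarray(similarity, dtype=float)
    if s.ndim != 2 or s.shape[0] != s.shape[1]:
        raise ValueError(f"similarity must be square, got {s.shape}")
    if not np.allclose(s, s.T, atol=atol, rtol=0):
        raise ValueError("similarity matrix asymmetric beyond tolerance")
    w = np.where(s > 0, s, 0.0)
    # symmetrize away roundoff asymmetry admitted by atol
    w = 0.5 * (w + w.T)
    np.fill_diagonal(w, 0.0)
    if not np.any(w > 0):
        warnings.warn("thresholded network has no edges", stacklevel=2)
    return WeightedNetwork(w, coordinates=coordinates, labels=labels)


def build_similarity(
    profiles: np.ndarray,
    method: str = "pearson",
    fisher: bool = True,
) -> np.ndarray:
    """Parcel-by-parcel similarity from feature profiles.

    Columns of ``profiles`` (feature x parcel) are correlated pairwise; by
    convention the result is Fisher r-to-z transformed (after clipping r to
    +/-(1 - 1e-7) so z stays finite) and the diagonal zeroed.

    Parcels with a constant profile have undefined correlations; their rows and
    columns are returned as NaN with a warning.
    """
    profiles = np.asarray(profiles, dtype=float)
    if profiles.ndim != 2 or profiles.shape[0] < 3:
        raise ValueError("need a feature x parcel matrix with >= 3 features")
    if method == "pearson":
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.corrcoef(profiles.T)
    elif method == "spearman":
        from scipy.stats import rankdata

        ranked = rankdata(profiles, axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.corrcoef(ranked.T)
    else:
        raise ValueError(f"unknown method {method!r}")
    const = profiles.std(axis=0) == 0
    if const.any():
        warnings.warn(
            f"{int(const.sum())} constant profile(s); rows/columns set to NaN",
            stacklevel=2,
        )
        r[const, :] = np.nan
        r[:, const] = np.nan
    if fisher:
        r = np.arctanh(np.clip(r, -R_CLIP, R_CLIP))
    np.fill_diagonal(r, 0.0)
    return r
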