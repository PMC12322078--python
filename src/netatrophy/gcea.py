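"""Ensemble-null gene category enrichment analysis (GCEA).

Each gene's parcellated expression map is correlated (Pearson, then Fisher
r-to-z) with a phenotype map (e.g., epicenter likelihood); a category's
c-score is the mean z of its member genes.  Significance is assessed against
an *ensemble null*: the same c-scores computed for spatially-autocorrelated
surrogate phenotypes (spin surrogates), which corrects for both gene-gene
co-expression and the phenotype's spatial autocorrelation.  Genes with low
differential stability (across-donor consistency, default threshold 0.1) are
excluded, as are genes with constant maps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .network import R_CLIP
from .nulls import fdr_bh, spin_surrogates

__all__ = [
    "ExpressionAtlas",
    "EnrichmentResult",
    "gene_map_correlations",
    "category_scores",
    "gcea_test",
]


@dataclass
class ExpressionAtlas:
    """Gene x parcel expression with per-gene differential stability."""

    expression: np.ndarray
    gene_symbols: list[str]
    differential_stability: np.ndarray

    def __post_init__(self) -> None:
        self.expression = np.atleast_2d(np.asarray(self.expression, dtype=float))
        self.differential_stability = np.asarray(
            self.differential_stability, dtype=float
        )
        g, _ = self.expression.shape
        if len(self.gene_symbols) != g:
            raise ValueError("gene_symbols length does not match expression rows")
        if self.differential_stability.size != g:
            raise ValueError("differential_stability length mismatch")
        if not np.all(np.isfinite(self.expression)):
            raise ValueError("expression contains non-finite values")

    def collapse_duplicates(self) -> "ExpressionAtlas":
        """Average rows sharing a gene symbol (deterministic, order-stable)."""
        seen: dict[str, list[int]] = {}
        for i, s in enumerate(self.gene_symbols):
            seen.setdefault(s, []).append(i)
        if all(len(v) == 1 for v in seen.values()):
            return self
        symbols = list(seen)
        expr = np.vstack([self.expression[idx].mean(axis=0)
                          for idx in seen.values()])
        ds = np.array([self.differential_stability[idx].mean()
                       for idx in seen.values()])
        return ExpressionAtlas(expr, symbols, ds)


@dataclass
class EnrichmentResult:
    """Per-category enrichment: c-scores, add-one p, FDR p, gene counts."""

    categories: list[str]
    c_scores: np.ndarray
    p_values: np.ndarray
    p_fdr: np.ndarray
    gene_counts: np.ndarray
    unmatched: dict[str, list[str]]


def _corr_z(expression: np.ndarray, phenotypes: np.ndarray) -> np.ndarray:
    """Fisher-z Pearson correlations of each gene row with each phenotype
    column; returns (n_genes, n_phenotypes)."""
    E = expression - expression.mean(axis=1, keepdims=True)
    En = np.linalg.norm(E, axis=1, keepdims=True)
    P = phenotypes - phenotypes.mean(axis=0, keepdims=True)
    Pn = np.linalg.norm(P, axis=0, keepdims=True)
    r = (E @ P) / (En * Pn)
    return np.arctanh(np.clip(r, -R_CLIP, R_CLIP))


def gene_map_correlations(
    atlas: ExpressionAtlas,
    phenotype: np.ndarray,
    ds_threshold: float = 0.1,
) -> tuple[np.ndarray, list[str]]:
    """Fisher-z Pearson correlation of each stable gene map with the phenotype.

    Genes with differential stability below ``ds_threshold`` are removed;
    genes with constant expression maps are dropped with a warning.  Returns
    ``(z, kept_symbols)``.
    """
    phenotype = np.asarray(phenotype, dtype=float)
    atlas = atlas.collapse_duplicates()
    if atlas.expression.shape[1] != phenotype.size:
        raise ValueError("parcel dimensions of atlas and phenotype differ")
    keep = atlas.differential_stability >= ds_threshold
    const = atlas.expression.std(axis=1) == 0
    if np.any(const & keep):
        warnings.warn(
            f"{int((const & keep).sum())} constant gene map(s) dropped",
            stacklevel=2,
        )
    keep &= ~const
    z = _corr_z(atlas.expression[keep], phenotype[:, None])[:, 0]
    symbols = [s for s, k in zip(atlas.gene_symbols, keep) if k]
    return z, symbols


def category_scores(
    gene_z: np.ndarray,
    gene_symbols: list[str],
    categories: dict[str, list[str]],
) -> tuple[dict[str, float], dict[str, list[str]]]:
    """Mean member-gene z per category (the c-score).

    Categories whose symbols all fail to match are excluded with a warning;
    unmatched symbols are reported per category.
    """
    index = {s: i for i, s in enumerate(gene_symbols)}
    scores: dict[str, float] = {}
    unmatched: dict[str, list[str]] = {}
    for cat, genes in categories.items():
        if not genes:
            raise ValueError(f"category {cat!r} is empty")
        hits = [index[g] for g in genes if g in index]
        unmatched[cat] = [g for g in genes if g not in index]
        if not hits:
            warnings.warn(f"category {cat!r} has no matched genes; excluded",
                          stacklevel=2)
            continue
        scores[cat] = float(np.mean(gene_z[hits]))
    return scores, unmatched


def gcea_test(
    atlas: ExpressionAtlas,
    phenotype: np.ndarray,
    categories: dict[str, list[str]],
    coordinates: np.ndarray,
    n_null: int = 1000,
    ds_threshold: float = 0.1,
    rng: np.random.Generator | None = None,
) -> EnrichmentResult:
    """Category enrichment of a phenotype map against an ensemble null.

    ``n_null`` spin surrogates of the phenotype give, per category, a null
    distribution of c-scores; p is the positive-sided add-one exceedance
    probability, FDR-corrected across categories.
    """
    if rng is None:
        raise ValueError("rng is required")
    if n_null < 100:
        raise ValueError("need n_null >= 100")
    phenotype = np.asarray(phenotype, dtype=float)
    z, symbols = gene_map_correlations(atlas, phenotype, ds_threshold)
    obs_scores, unmatched = category_scores(z, symbols, categories)
    cats = list(obs_scores)

    surr = spin_surrogates(coordinates, phenotype, n_null, rng)  # (n_null, p)
    atlas_c = atlas.collapse_duplicates()
    keep = np.array([s in set(symbols) for s in atlas_c.gene_symbols])
    null_z = _corr_z(atlas_c.expression[keep], surr.T)  # (n_genes, n_null)
    kept_symbols = [s for s, k in zip(atlas_c.gene_symbols, keep) if k]
    index = {s: i for i, s in enumerate(kept_symbols)}

    c_scores = np.array([obs_scores[c] for c in cats])
    counts = np.empty(len(cats), dtype=int)
    p = np.empty(len(cats))
    for k, cat in enumerate(cats):
        hits = [index[g] for g in categories[cat] if g in index]
        counts[k] = len(hits)
        null_c = null_z[hits].mean(axis=0)
        p[k] = (np.sum(null_c >= c_scores[k]) + 1) / (n_null + 1)
    return EnrichmentResult(cats, c_scores, p, fdr_bh(p), counts, unmatched)
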