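"""Delimited-file I/O for networks, parcel maps, cohorts, and atlases.

Everything round-trips through TSV with parcel/subject identifiers so the CLI
stages compose via plain files.  Voxel data can alternatively be read from
NIfTI volumes (values plus an integer label atlas) when nibabel is available.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .contrasts import ClinicalTable
from .gcea import ExpressionAtlas
from .morphometry import VoxelCohort
from .network import WeightedNetwork

__all__ = [
    "write_network", "read_network",
    "write_map", "read_map",
    "write_matrix", "read_matrix",
    "write_cohort", "read_cohort",
    "write_clinical", "read_clinical",
    "write_expression", "read_expression",
    "write_categories", "read_categories",
    "write_manifest",
    "read_nifti_pair",
]


def _parcel_ids(n: int) -> list[str]:
    return [f"parcel_{i:04d}" for i in range(n)]


def write_network(net: WeightedNetwork, weights_path, coords_path=None) -> None:
    ids = net.labels or _parcel_ids(net.n_parcels)
    pd.DataFrame(net.weights, index=ids, columns=ids).to_csv(
        weights_path, sep="\t"
    )
    if coords_path is not None and net.coordinates is not None:
        pd.DataFrame(net.coordinates, index=ids,
                     columns=["x", "y", "z"]).to_csv(coords_path, sep="\t")


def read_network(weights_path, coords_path=None) -> WeightedNetwork:
    w = pd.read_csv(weights_path, sep="\t", index_col=0)
    coords = None
    if coords_path is not None:
        coords = pd.read_csv(coords_path, sep="\t", index_col=0).to_numpy()
    return WeightedNetwork(w.to_numpy(), coordinates=coords,
                           labels=list(w.index))


def write_map(values: np.ndarray, path, name: str = "value") -> None:
    values = np.asarray(values, dtype=float)
    pd.DataFrame({name: values}, index=_parcel_ids(values.size)).to_csv(
        path, sep="\t"
    )


def read_map(path) -> np.ndarray:
    return pd.read_csv(path, sep="\t", index_col=0).iloc[:, 0].to_numpy()


def write_matrix(values: np.ndarray, path, prefix: str = "col") -> None:
    values = np.atleast_2d(np.asarray(values, dtype=float))
    cols = [f"{prefix}_{j:04d}" for j in range(values.shape[1])]
    pd.DataFrame(values, columns=cols).to_csv(path, sep="\t", index=False)


def read_matrix(path) -> np.ndarray:
    return pd.read_csv(path, sep="\t").to_numpy(dtype=float)


def write_cohort(cohort: VoxelCohort, meta_path, values_path) -> None:
    pd.DataFrame({
        "id": [f"sub_{i:04d}" for i in range(cohort.n_subjects)],
        "age": cohort.age,
        "sex": cohort.sex,
        "site": cohort.site,
        "group": cohort.group,
    }).to_csv(meta_path, sep="\t", index=False)
    write_matrix(cohort.values, values_path, prefix="voxel")


def read_cohort(meta_path, values_path) -> VoxelCohort:
    meta = pd.read_csv(meta_path, sep="\t")
    values = read_matrix(values_path)
    return VoxelCohort(values, meta["age"].to_numpy(),
                       meta["sex"].to_numpy(), meta["site"].to_numpy(),
                       meta["group"].to_numpy())


def write_clinical(table: ClinicalTable, path) -> None:
    df = table.data.copy()
    if table.groups is not None:
        df.insert(0, "group", table.groups)
    df.to_csv(path, sep="\t", index=False, na_rep="")


def read_clinical(path) -> ClinicalTable:
    df = pd.read_csv(path, sep="\t")
    groups = None
    if "group" in df.columns:
        groups = df.pop("group").to_numpy()
    return ClinicalTable(df.astype(float), groups)


def write_expression(atlas: ExpressionAtlas, expr_path, meta_path) -> None:
    pd.DataFrame(atlas.expression, index=atlas.gene_symbols,
                 columns=_parcel_ids(atlas.expression.shape[1])).to_csv(
        expr_path, sep="\t"
    )
    pd.DataFrame({
        "symbol": atlas.gene_symbols,
        "differential_stability": atlas.differential_stability,
    }).to_csv(meta_path, sep="\t", index=False)


def read_expression(expr_path, meta_path) -> ExpressionAtlas:
    expr = pd.read_csv(expr_path, sep="\t", index_col=0)
    meta = pd.read_csv(meta_path, sep="\t")
    return ExpressionAtlas(expr.to_numpy(), list(expr.index),
                           meta["differential_stability"].to_numpy())


def write_categories(categories: dict[str, list[str]], path) -> None:
    rows = [(cat, g) for cat, genes in categories.items() for g in genes]
    pd.DataFrame(rows, columns=["category", "gene"]).to_csv(
        path, sep="\t", index=False
    )


def read_categories(path) -> dict[str, list[str]]:
    path = Path(path)
    if path.suffix == ".gmt":
        out: dict[str, list[str]] = {}
        for line in path.read_text().splitlines():
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 3:
                out[parts[0]] = parts[2:]
        return out
    df = pd.read_csv(path, sep="\t")
    return {cat: sub["gene"].tolist()
            for cat, sub in df.groupby("category", sort=False)}


def write_manifest(path, **entries) -> None:
    def _clean(v):
        if isinstance(v, np.ndarray):
            return v.tolist()
        if isinstance(v, (np.integer, np.floating)):
            return v.item()
        if isinstance(v, dict):
            return {k: _clean(x) for k, x in v.items()}
        if isinstance(v, (list, tuple)):
            return [_clean(x) for x in v]
        return v

    Path(path).write_text(json.dumps(_clean(entries), indent=2))


def read_nifti_pair(values_paths, labels_path):
    """Load per-subject NIfTI value volumes and an integer label atlas.

    Returns (subjects x voxels values, flat labels); voxels outside the atlas
    (label 0) are retained so downstream parcellation handles background.
    """
    import nibabel as nib

    labels = np.asarray(nib.load(str(labels_path)).dataobj).astype(int).ravel()
    values = np.vstack([
        np.asarray(nib.load(str(p)).dataobj, dtype=float).ravel()
        for p in values_paths
    ])
    if values.shape[1] != labels.size:
        raise ValueError("value volumes and label atlas differ in voxel count")
    return values, labels
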