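"""Synthetic inputs with planted ground truth for every pipeline stage.

The generators emulate, at desk scale, the statistical structure of the
empirical inputs: a spatially embedded weighted connectome (parcels on a unit
sphere, edge probability decaying with distance), voxel morphometry with
age/sex/site covariates and a group atrophy effect, atrophy spreading from a
known seed parcel, clinical measures sharing a planted latent factor with the
brain maps, and spatially autocorrelated gene expression with one planted
enriched category.  Every generator is a pure function of its configuration
and seed: identical seeds give bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .contrasts import ClinicalTable
from .gcea import ExpressionAtlas
from .morphometry import VoxelCohort
from .network import WeightedNetwork

__all__ = [
    "SynthConfig",
    "PlantedTruth",
    "make_spatial_connectome",
    "make_planted_atrophy",
    "make_voxel_cohort",
    "make_clinical_latent",
    "make_expression_atlas",
    "sphere_points",
]


@dataclass
class SynthConfig:
    """Ground-truth configuration shared by the synthetic generators.

    ``distance_decay`` is the e-folding rate of edge probability per unit
    inter-centroid distance; ``spread_weight`` mixes the seed-diffusion
    profile against the plain seed indicator; ``latent_corr`` is the planted
    correlation between the brain and behavior latent scores.
    """

    n_parcels: int = 200
    density: float = 0.10
    distance_decay: float = 4.0
    seed_region: int = 0
    spread_weight: float = 0.7
    noise_sd: float = 0.1
    n_controls: int = 60
    n_patients: int = 60
    n_sites: int = 3
    n_measures: int = 12
    latent_corr: float = 0.6
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_parcels", "n_controls", "n_patients", "n_sites",
                     "n_measures"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not (0.0 < self.density <= 1.0):
            raise ValueError("density must lie in (0, 1]")
        if self.distance_decay < 0:
            raise ValueError("distance_decay must be nonnegative")
        if not (0.0 <= self.spread_weight <= 1.0):
            raise ValueError("spread_weight must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if not (0.0 <= self.latent_corr <= 1.0):
            raise ValueError("latent_corr must lie in [0, 1]")
        if not (0 <= self.seed_region < self.n_parcels):
            raise ValueError("seed_region must index a parcel")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class PlantedTruth:
    """Ground truth planted by a generator (fields unused by it are None)."""

    seed_region: int | None = None
    latent_brain_weights: np.ndarray | None = None
    latent_behavior_weights: np.ndarray | None = None
    planted_category: list[str] = field(default_factory=list)


def sphere_points(n: int, rng: np.random.Generator) -> np.ndarray:
    """``n`` points drawn uniformly on the unit sphere."""
    p = rng.standard_normal((n, 3))
    return p / np.linalg.norm(p, axis=1, keepdims=True)


def make_spatial_connectome(
    config: SynthConfig,
    max_retries: int = 50,
    weight_sigma: float = 0.5,
) -> WeightedNetwork:
    """Spatially embedded random connectome on the unit sphere.

    Edge presence probability is ``b * exp(-distance_decay * d_ij)`` with the
    base rate ``b`` solved so the expected density matches ``config.density``;
    weights are log-normal; the network must be connected and realize the
    target density within +/-20% (regenerated otherwise, bounded retries).
    """
    if config.n_parcels < 10:
        raise ValueError("need n_parcels >= 10")
    rng = np.random.default_rng(config.rng_seed)
    n = config.n_parcels
    iu, ju = np.triu_indices(n, k=1)
    for _ in range(max_retries):
        coords = sphere_points(n, rng)
        d = np.linalg.norm(coords[iu] - coords[ju], axis=1)
        kernel = np.exp(-config.distance_decay * d)
        base = config.density / kernel.mean()
        p = np.minimum(base * kernel, 1.0)
        present = rng.random(p.size) < p
        realized = present.mean()
        if abs(realized - config.density) > 0.2 * config.density:
            continue
        w = np.zeros((n, n))
        weights = rng.lognormal(mean=0.0, sigma=weight_sigma,
                                size=int(present.sum()))
        w[iu[present], ju[present]] = weights
        w += w.T
        net = WeightedNetwork(w, coordinates=coords)
        if net.is_connected():
            return net
    raise RuntimeError(
        f"could not realize a connected network at density={config.density}, "
        f"distance_decay={config.distance_decay}, n={n} after {max_retries} "
        "attempts"
    )


def make_planted_atrophy(
    network: WeightedNetwork,
    seed_region: int,
    spread_weight: float,
    noise_sd: float,
    rng: np.random.Generator,
    n_steps: int = 3,
    laziness: float = 0.5,
) -> tuple[np.ndarray, np.ndarray]:
    """Atrophy map spreading from a known seed parcel.

    A unit mass at the seed undergoes ``n_steps`` steps of a lazy random walk
    (operator ``laziness * I + (1 - laziness) * P`` with P the row-normalized
    weight matrix); the resulting profile, rescaled to unit maximum, is mixed
    with the plain seed indicator:

        truth = spread_weight * diffusion/max + (1 - spread_weight) * indicator

    Gaussian noise of ``noise_sd`` is added and the map clipped at 0.  Returns
    ``(observed, truth)``.
    """
    n = network.n_parcels
    if not 0 <= seed_region < n:
        raise ValueError("seed_region must index a parcel")
    if not (0.0 <= spread_weight <= 1.0) or noise_sd < 0:
        raise ValueError("spread_weight in [0,1] and noise_sd >= 0 required")
    C = network.strength
    if C[seed_region] == 0:
        raise ValueError("seed region is isolated; no spread possible")
    P = np.zeros_like(network.weights)
    nz = C > 0
    P[nz] = network.weights[nz] / C[nz, None]
    P[~nz, ~nz] = 1.0
    x = np.zeros(n)
    x[seed_region] = 1.0
    for _ in range(n_steps):
        x = laziness * x + (1.0 - laziness) * (x @ P)
    indicator = np.zeros(n)
    indicator[seed_region] = 1.0
    truth = spread_weight * (x / x.max()) + (1.0 - spread_weight) * indicator
    observed = truth + rng.normal(0.0, noise_sd, size=n)
    return np.clip(observed, 0.0, None), truth


def make_voxel_cohort(
    config: SynthConfig,
    effect_map: np.ndarray,
    parcel_labels: np.ndarray,
    effect_scale: float = 0.05,
    beta_age: float = -0.002,
    beta_sex: float = 0.02,
    noise_sd: float | None = None,
    mean_age: float = 57.0,
    sd_age: float = 10.0,
) -> VoxelCohort:
    """Voxel morphometry cohort with covariate structure and a group effect.

    Each subject's voxel value is

        site intercept + beta_age * age + beta_sex * sex
            - group * effect_map[parcel(voxel)] * effect_scale + noise,

    i.e., patients lose tissue in proportion to the parcel effect map (DBM
    scale, so atrophy means smaller values).  Ages ~ N(57, 10), sexes
    balanced, sites assigned round-robin within controls and patients.
    """
    effect_map = np.asarray(effect_map, dtype=float)
    labels = np.asarray(parcel_labels)
    if labels.max() > effect_map.size:
        raise ValueError("effect_map dimension does not match label set")
    if config.n_controls < 3 * config.n_sites:
        raise ValueError("need at least 3 controls per site")
    rng = np.random.default_rng([config.rng_seed, 1])
    noise_sd = config.noise_sd if noise_sd is None else noise_sd
    n = config.n_controls + config.n_patients
    group = np.r_[np.zeros(config.n_controls, dtype=int),
                  np.ones(config.n_patients, dtype=int)]
    age = rng.normal(mean_age, sd_age, size=n)
    sex = np.tile([0, 1], n // 2 + 1)[:n]
    site = np.concatenate([
        np.arange(config.n_controls) % config.n_sites,
        np.arange(config.n_patients) % config.n_sites,
    ])
    site_intercepts = rng.normal(1.0, 0.05, size=config.n_sites)
    voxel_effect = np.zeros(labels.size)
    fg = labels > 0
    voxel_effect[fg] = effect_map[labels[fg] - 1]
    values = (
        site_intercepts[site][:, None]
        + beta_age * age[:, None]
        + beta_sex * sex[:, None]
        - group[:, None] * voxel_effect[None, :] * effect_scale
        + rng.normal(0.0, noise_sd, size=(n, labels.size))
    )
    return VoxelCohort(values, age, sex, site, group)


def make_clinical_latent(
    config: SynthConfig,
    rng: np.random.Generator,
    brain_signal: float = 3.0,
    brain_noise_sd: float = 0.5,
    behavior_signal: float = 2.0,
    behavior_noise_sd: float = 0.3,
    missing_rate: float = 0.0,
) -> tuple[np.ndarray, ClinicalTable, PlantedTruth]:
    """Subject epicenter maps and clinical measures sharing one latent factor.

    One latent score z per subject drives both blocks: brain rows are
    ``z * w_brain * brain_signal + noise``; the behavior latent is
    ``latent_corr * z + sqrt(1 - latent_corr^2) * e`` (unit variance, planted
    correlation ``latent_corr`` with z) and behavior rows follow the same
    construction with ``w_behavior``.  Weight vectors are unit-norm.  Optional
    missingness is injected completely at random into the clinical table.
    """
    if config.n_patients < 20:
        raise ValueError("need n_patients >= 20")
    if not (0.0 <= missing_rate < 1.0):
        raise ValueError("missing_rate must lie in [0, 1)")
    n, p, q = config.n_patients, config.n_parcels, config.n_measures
    w_brain = rng.standard_normal(p)
    w_brain /= np.linalg.norm(w_brain)
    w_beh = rng.standard_normal(q)
    w_beh /= np.linalg.norm(w_beh)
    z = rng.standard_normal(n)
    rho = config.latent_corr
    y_lat = rho * z + np.sqrt(1.0 - rho**2) * rng.standard_normal(n)
    X = (np.outer(z, w_brain) * brain_signal
         + rng.normal(0.0, brain_noise_sd, size=(n, p)))
    Y = (np.outer(y_lat, w_beh) * behavior_signal
         + rng.normal(0.0, behavior_noise_sd, size=(n, q)))
    if missing_rate > 0:
        holes = rng.random(Y.shape) < missing_rate
        # never blank out an entire measure
        for j in range(q):
            if holes[:, j].all():
                holes[rng.integers(0, n), j] = False
        Y = np.where(holes, np.nan, Y)
    import pandas as pd

    table = ClinicalTable(pd.DataFrame(
        Y, columns=[f"measure_{j:02d}" for j in range(q)]
    ))
    truth = PlantedTruth(latent_brain_weights=w_brain,
                         latent_behavior_weights=w_beh)
    return X, table, truth


def _spatial_basis(coordinates: np.ndarray) -> np.ndarray:
    """Low-order smooth basis on the sphere (degree-1 and degree-2 real
    spherical harmonics, each normalized to unit L2 norm on the sphere, so a
    field with iid coefficients is statistically isotropic)."""
    x, y, z = coordinates.T
    s3 = np.sqrt(3.0)
    s15 = np.sqrt(15.0)
    cols = [
        s3 * x, s3 * y, s3 * z,
        s15 * x * y, s15 * x * z, s15 * y * z,
        (s15 / 2.0) * (x**2 - y**2),
        (np.sqrt(5.0) / 2.0) * (3 * z**2 - 1),
    ]
    return np.column_stack(cols)


def make_expression_atlas(
    config: SynthConfig,
    phenotype: np.ndarray,
    rng: np.random.Generator,
    coordinates: np.ndarray | None = None,
    n_genes: int = 200,
    n_planted: int = 15,
    planted_strength: float = 1.0,
    gene_noise_sd: float = 0.5,
    low_ds_fraction: float = 0.3,
    n_background_categories: int = 19,
    category_size: int = 15,
) -> tuple[ExpressionAtlas, dict[str, list[str]], PlantedTruth]:
    """Gene x parcel expression atlas with one planted enriched category.

    Background genes are spatially autocorrelated fields (random combinations
    of a shared low-rank spherical-harmonic basis plus noise); planted-category
    genes are ``planted_strength * standardized phenotype + noise``.
    Differential stability is assigned so that ``low_ds_fraction`` of the
    background genes falls below 0.1 (and would be dropped by the standard
    filter); planted genes are always stable.
    """
    phenotype = np.asarray(phenotype, dtype=float)
    if phenotype.size != config.n_parcels:
        raise ValueError("phenotype length must equal n_parcels")
    if n_planted > n_genes:
        raise ValueError("planted category larger than gene pool")
    if coordinates is None:
        coordinates = sphere_points(config.n_parcels, rng)
    basis = _spatial_basis(coordinates)
    n_background = n_genes - n_planted
    coefs = rng.standard_normal((n_background, basis.shape[1]))
    background = coefs @ basis.T
    background += rng.normal(0.0, gene_noise_sd, size=background.shape)
    pheno_std = (phenotype - phenotype.mean()) / phenotype.std()
    planted = (planted_strength * pheno_std[None, :]
               + rng.normal(0.0, gene_noise_sd,
                            size=(n_planted, config.n_parcels)))
    expression = np.vstack([background, planted])
    symbols = [f"G{i:04d}" for i in range(n_genes)]
    planted_symbols = symbols[n_background:]

    ds = np.empty(n_genes)
    n_low = int(round(low_ds_fraction * n_background))
    low_idx = rng.choice(n_background, size=n_low, replace=False)
    ds[:n_background] = rng.uniform(0.1, 1.0, size=n_background)
    ds[low_idx] = rng.uniform(0.0, 0.1, size=n_low)
    ds[n_background:] = rng.uniform(0.3, 0.9, size=n_planted)

    categories = {"planted": list(planted_symbols)}
    for k in range(n_background_categories):
        members = rng.choice(n_background, size=min(category_size,
                                                    n_background),
                             replace=False)
        categories[f"background_{k:02d}"] = [symbols[i] for i in members]
    atlas = ExpressionAtlas(expression, symbols, ds)
    truth = PlantedTruth(planted_category=list(planted_symbols))
    return atlas, categories, truth
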