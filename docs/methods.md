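# Methods

`netatrophy` implements a network-spreading analysis of neurodegenerative
atrophy: normative morphometry, connectome-based exposure and epicenter
mapping, an agent-based spreading simulation, spatial and topological null
models, brain–behavior partial least squares, gene category enrichment, and
patient-subtype contrasts. This note records the model definitions, the
parameter choices and their rationale, and the numerical conventions.

## 1. Normative w-scores (`morphometry`)

Deformation-based morphometry (DBM) values are modelled voxelwise, within each
imaging-site stratum, by OLS on healthy controls:

    expected = β1·age + β2·sex + β3

and each subject's deviation is standardized by the control residual SD and
sign-inverted so that larger values mean more atrophy:

    w = −(observed − expected) / SD(control residuals)

Choices:

- **Site stratification.** Separate coefficient sets and residual SDs per site
  stratum absorb scanner/protocol offsets without cross-site shrinkage.
- **ddof = 1** for the residual SD (sample SD). A direct consequence: within
  the controls the model was fitted on, w-scores have mean 0 and SD 1 per
  voxel — an exact invariant used in the tests.
- **Degenerate voxels.** Residual SD equal to zero up to a relative tolerance
  (`sd ≤ 1e-8 · max(1, |values|)`) marks a voxel degenerate; its w-scores are
  NaN rather than unbounded. The tolerance is relative because `lstsq` leaves
  O(1e−16) residuals even on exactly linear data.
- **Rank-deficient strata** (e.g., a single-sex site) raise immediately with
  the stratum named, instead of producing silently unstable coefficients.

`parcellate` reduces voxel maps to parcels (label 0 = background, parcel p at
output index p−1; mean by default). `tract_atrophy_test` applies a two-sided
one-sample t-test of per-subject tract means against 0 (w-scores already
encode deviation from the norm), `class_enrichment` compares class means
against spin surrogates; both BH-FDR corrected.

## 2. Exposure and rank epicenters (`spreading`)

Disease exposure of parcel i is the weighted mean atrophy of its neighbours:

    D_i = Σ_{j≠i} d_j c_ij / C_i,   C_i = Σ_{j≠i} c_ij

Parcels with zero weighted degree have undefined exposure (NaN) and are
excluded pairwise downstream. `node_neighbour_correlation` is the Pearson (or
Spearman) correlation between own atrophy and exposure; a positive value
indicates connectivity-patterned pathology.

The data-driven epicenter likelihood is the mean of two ascending fractional
ranks — own atrophy and exposure — so parcels that are both highly atrophied
and connected to highly atrophied neighbours score highest. Ties receive
average ranks; excluded parcels are NaN and the remaining ranks renumber.

`joint_regression_gain` asks whether a second (similarity) network improves
prediction of atrophy beyond the structural connectome: adjusted R² of
atrophy on exposure-under-A versus on both exposures. The null replaces the
second regressor with exposure (under B) of a *spin-rotated* atrophy map —
autocorrelation-matched but unaligned — giving a one-sided add-one p for the
gain. Near-collinear regressors (|r| > 0.999) warn and cap the gain at ≤ 0.

## 3. Agent-based SIR simulation (`sirspread`)

Normal protein agents are synthesized per region, misfold on contact with
misfolded agents, migrate along weighted edges, and are cleared. Per step,
with one seeded generator driving all draws in fixed order:

1. synthesis: Binomial(round(region size), `synthesis_rate`) new normal agents;
2. clearance: Binomial(N, `clearance_normal`), Binomial(M, `clearance_misfolded`);
3. conversion: each normal agent misfolds with probability
   1 − (1 − `trans_rate`)^(M/size) (density dependence);
4. migration: each agent leaves with probability `mobility`, choosing a
   neighbour proportionally to edge weight (isolated regions retain agents);
5. atrophy: Δa_i = k1·(misfolded fraction) + k2·(weight-normalized mean of
   neighbours' previous-step increment), accumulated and capped so cumulative
   atrophy stays in [0, 1].

The two atrophy terms model direct toxicity and deafferentation. Migration is
vectorized with a batched multinomial draw, which is what makes whole-map
epicenter scoring tractable.

**Defaults** (`SIRParams`): synthesis 0.4, clearance 0.05/0.05, transmission
0.25, mobility 0.05, injection 20 agents, k1 = k2 = 0.01, unit region sizes.
These are package choices calibrated so the infection wave traverses a
few-hundred-node synthetic connectome over a few hundred steps; they stand in
for an empirical parameter table and should be refit for real data.

`sir_epicenter_map` seeds each candidate region in turn (generator seeded by
`[rng_seed, seed]`, so seeds are independent and reproducible), correlates the
cumulative simulated atrophy with the observed map at every step, and records
the maximum over steps; larger maxima mean more epicenter-like.

## 4. Null models (`nulls`)

- **Spin surrogates.** Uniform SO(3) rotations of spherical parcel centroids;
  each parcel takes the value of the nearest rotated centroid (optionally
  excluding masked donors; optional mirrored rotations per hemisphere). This
  preserves spatial autocorrelation while destroying alignment. Centroids
  must lie on a sphere (or pass `auto_project=True`).
- **Degree-preserving rewiring.** Maslov–Sneppen double-edge swaps
  (a–b, c–d) → (a–d, c–b), rejecting self-loops and multi-edges; weights
  travel with their edges. Exactly preserves the binary degree sequence and
  the weight multiset.
- **Degree- and length-preserving rewiring.** Swaps restricted to edges of
  the same Euclidean-distance bin (equal-count bins by default) and accepted
  only if both replacement edges fall back inside the bin's range — per-bin
  edge counts are preserved exactly, so the edge-length distribution is
  preserved up to bin resolution.
- **p-values.** Add-one convention p = (k+1)/(n+1); with 1000 surrogates the
  smallest attainable p is 1/1001 ≈ 9.99×10⁻⁴. BH-FDR is delegated to
  statsmodels, with NaN passthrough.

### A note on spin-test calibration

The type-I calibration experiment generates pairs of independent
autocorrelated maps from a low-order spherical-harmonic basis. Each basis
function is normalized to unit L2 norm on the sphere: with unnormalized
polynomials, iid coefficients produce an *anisotropic* random field, the
rotation-orbit exchangeability argument behind the spin test fails, and the
empirical type-I rate inflates to ≈ 0.11 no matter how the surrogates are
built. With the normalized (isotropic) basis the rate is ≈ 0.05.

## 5. Behavioral PLS (`pls`)

The brain (subjects × parcels) and behavior (subjects × measures) matrices
are column z-scored and the cross-covariance decomposed, X′Y = U S V′.
Effect size of LV k is s_k²/Σs². Sign convention: the largest-|weight|
element of each brain vector is positive. Inference:

- **Permutation** (default 1000): rows of X permuted; null singular values
  collected per LV index; add-one p.
- **Bootstrap** (default 1000): subjects resampled with replacement
  (degenerate resamples retried); each resample's LVs sign-aligned to the
  original; bootstrap ratio = original weight / bootstrap SE.
- **Split-half CV** (default 100 splits): fit on a random half, project the
  held-out half on the train weights (train-half standardization applied to
  the test half), correlate the held-out LV1 brain and behavior scores.
  Significance by re-running the splits on row-shuffled X and comparing
  median correlations (add-one p).

## 6. Gene category enrichment (`gcea`)

Each gene's parcel expression map is Pearson-correlated with the phenotype
map and Fisher r-to-z transformed (r clipped to ±(1 − 1e−7) so z is finite).
Genes below the differential-stability threshold (default 0.1) or with
constant maps are excluded. A category's c-score is the mean z of its
matched member genes. The **ensemble null** recomputes all c-scores for spin
surrogates of the phenotype, which accounts jointly for gene–gene
co-expression and the phenotype's spatial autocorrelation; p is the one-sided
add-one exceedance, BH-FDR across categories. Duplicate gene symbols are
collapsed by averaging before any correlation.

## 7. Subtype contrasts (`contrasts`)

- `parcelwise_ttest`: independent two-sample t per parcel (Student by
  default, Welch optional), NaN at zero-variance parcels, BH-FDR across
  parcels.
- `behavioral_contrast`: two-sided Mann–Whitney U per clinical measure on
  observed values only; measures observed in fewer than `min_observed`
  (default 20) subjects are excluded and reported; the exact null is used
  when both groups have ≤ 8 untied observations, the tie-corrected normal
  approximation otherwise; BH-FDR across tested measures.
- `impute_median`: per-measure observed-median imputation with a mask of
  imputed cells, for analyses that cannot drop rows (e.g., PLS).

## 8. Synthetic generators and study conditions (`synthgen`)

All evaluation is on synthetic data with planted ground truth; the defaults
of `SynthConfig` *are* the study conditions:

- **Connectome**: 200 parcels uniform on the unit sphere; edge probability
  b·exp(−4·distance) with b solved for expected density 0.10; log-normal
  weights (σ = 0.5); regenerated until connected and within ±20% of target
  density. Steep decay at reachable density mimics the distance dependence
  of empirical connectomes; unreachable combinations (probability cap
  saturates) raise with the parameters named.
- **Planted atrophy**: a unit mass at the seed takes 3 steps of a lazy random
  walk (laziness 0.5), the profile is rescaled to unit maximum and mixed with
  the seed indicator at spread weight 0.7, plus N(0, 0.1) noise, clipped at
  0. The unit-maximum rescaling keeps the spreading signal on the same scale
  as the noise; without it the walk profile (summing to 1 over 200 parcels)
  would be undetectable at the stated noise level. Limits: spread weight 0 →
  exact indicator; zero noise → the seed attains the maximum.
- **Voxel cohort**: value = site intercept (N(1, 0.05)) − 0.002·age +
  0.02·sex − group·effect·0.05 + noise. The group effect is *subtracted*
  (DBM scale: atrophy = smaller values) so inverted w-scores are positive in
  atrophied tissue.
- **Clinical latent factor**: one latent z per subject drives the brain block;
  the behavior latent is ρz + √(1−ρ²)e with planted ρ = 0.6; unit-norm
  weight vectors; optional MCAR missingness that never blanks a full measure.
- **Expression atlas**: 185 background genes as random combinations of the
  normalized spherical-harmonic basis plus noise, 15 planted genes as
  standardized phenotype plus noise; 30% of background genes assigned
  differential stability < 0.1 (removed by the default filter); one planted
  category plus 19 random background categories of 15.

These parameters were fixed from the analysis design before the acceptance
experiments were run, and are not tuned against test outcomes.

## 9. Scope and limitations

- Everything is validated on synthetic data; the empirical numbers of the
  motivating analyses (specific r values, covariance percentages, tract
  t-statistics) require patient cohorts and tractography connectomes and are
  out of scope.
- The SIR defaults are placeholders calibrated on synthetic networks, not
  fitted biological rates.
- Spin surrogates use nearest-assignment (values may duplicate or drop);
  parcel sets far from spherical require `auto_project` and a judgement call.
- The normative model is linear in age and sex; no spline or interaction
  terms.
- Distance-binned rewiring preserves edge lengths only up to bin resolution,
  and very sparse bins are skipped (with a warning) rather than forced.
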