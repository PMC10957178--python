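# Methods

This note documents the statistical procedures, the synthetic data model,
the numerical choices, and the known limitations of `morphlink`.

## Data model and preprocessing

The pipeline consumes four subject-level tables (clinical risk factors
with variable-group labels, parcel-wise morphometry, confounds, cognition)
plus parcel geometry, weighted connectomes, and a parcels × genes
expression matrix with a gene → cell-category catalog, all as delimited
text. Preprocessing order is: k-NN imputation of the clinical block,
OLS residualization of both blocks against the confounds, column
z-scoring.

**k-NN imputation (k = 4).** A missing cell is replaced by the unweighted
mean of the k nearest subjects' observed values, with neighbours found by
Euclidean distance on the z-scored variables of the *same* variable group
(lipids are imputed from lipids, not from demographics). This is realized
with `sklearn.impute.KNNImputer` on the z-scored group block, which is
affine-equivalent to the mean-of-raw-values rule. A subject missing an
entire group falls back to all clinical columns, with a warning. Ties in
distance are broken by subject order through the stable underlying sort.

**Residualization.** Each column is replaced by its OLS residual against
`[1, confounds]`. Confounds (age in years, binary sex, ordinal education,
binary cohort) enter untransformed — slopes absorb scale — and the
operation is idempotent; residuals are exactly orthogonal to every
confound. Education enters as a numeric ordinal and cohort as a binary
indicator by default; both are ordinary design columns, so a caller can
dummy-code before passing if preferred.

**Cross-cohort harmonization.** Test scores measured with different
instruments per cohort are z-scored within cohort and then once more
pooled, making the result invariant to per-cohort affine rescalings.

**Case-control machinery (sensitivity analyses).** A binary
risk-composite label is computed from the consensus rule — central
obesity (sex-specific waist cut-off) plus at least two of {elevated
triglycerides, low HDL (sex-specific), elevated BP or antihypertensive
therapy, elevated glucose or antidiabetic therapy} — with all cut-offs in
an overridable config (defaults: waist ≥ 94/80 cm, TG ≥ 150 mg/dL,
HDL < 40/50 mg/dL, BP ≥ 130/85 mmHg, glucose ≥ 100 mg/dL). Matching is
greedy 1:1 nearest-neighbour without replacement on Mahalanobis distance
over (age, sex, education), in a seed-fixed random case order — chosen
over optimal matching for determinism and auditability; standardized mean
differences before/after are reported. Group contrasts are parcel-level
GLMs (morphometry ~ intercept + group + confounds) with BH-FDR across
parcels.

## PLS correlation

SVD of the cross-block Pearson correlation matrix `R` (regions ×
clinical). The number of latent variables equals min(regions, clinical) —
the rank dimension, i.e. the clinical-variable count in the typical
wide-morphometry case. Explained variance uses the total-sum denominator
`δ_j²/Σδ_k²` (so it sums to 1 across latent variables). Sign convention:
per latent variable, signs are flipped so the largest-magnitude clinical
loading is positive; latent directions are otherwise sign-indeterminate.

**Permutation test.** Only the rows of `X` are permuted; per-column
z-scores are permutation-invariant, so re-standardizing permuted data is
a no-op and the question of permuting before or after z-scoring is moot.
The default comparison is rank-for-rank against the *sorted* permuted
explained variances, which is exchangeable under the null and therefore
calibrated (measured LV1 type-I error 0.03 at α = 0.05 over 200 null
cohorts, KS-uniform p-values). An alternative that Procrustes-aligns each
permuted decomposition to the observed clinical loadings before reading
off per-LV variance is available (`align='procrustes'`) but off by
default: the observed LV1 explained variance is an extreme order
statistic while the aligned permuted value is not, which makes that
variant reject essentially always under the null (measured rate ≈ 0.99).
The add-one p-value formula avoids zero p.

**Bootstrap.** Subjects are resampled jointly from both blocks. Each
resample's decomposition is aligned to the original by orthogonal
Procrustes on the clinical side V (fewer columns, stabler), with the
rotation applied to both singular-vector matrices — this resolves the
sign/order indeterminacy of resampled latent variables. Bootstrap ratio =
original region weight / bootstrap SD of aligned weights; |BR| > 1.96
marks a region significant. Clinical CIs are percentile 2.5/97.5 of the
aligned loadings. Resamples producing a constant column are redrawn (max
10 retries, logged).

**Cross-validation.** k-fold (default 10): the decomposition is refit on
the training subjects and held-out subjects are projected with the
training vectors; out-of-sample Spearman score correlations are reported
per fold with their mean. Folds are *not* aligned to a reference fold:
aligning to fold 1's loadings leaks information (fold 1's decomposition
saw the other folds' test subjects) and was measured to inflate the null
out-of-sample correlation to ≈ +0.06 where the unaligned procedure sits
at 0.

## Mediation

Single-mediator path model on z-scored complete cases (listwise deletion
per outcome, mirroring batteries where not every subject takes every
test): a from `m ~ x + covs`, b and c′ from `y ~ x + m + covs`, c from
`y ~ x + covs`; ab = a·b and ab + c′ = c exactly. The covariate set
defaults to (age, sex, education) and is configurable. Significance of ab
comes from a subject-level percentile bootstrap with the sign-crossing
two-tailed p (add-one corrected); path p-values come from OLS t-tests.
Classification: *none* unless a, b and ab are all significant after FDR;
*full* if additionally c′ is non-significant; *partial* if c′ remains
significant with |c′| < |c| (same-direction shrinkage). In batch mode
(one model per cognition column) BH-FDR is applied within each path type
across outcomes, which matches reporting one corrected p per path per
test; correcting across all paths jointly is a trivial caller-side
variant.

## Synthetic cohorts

The generators plant exactly the structure the analysis assumes; their
defaults are the conditions under which the test suite and acceptance
script operate.

- **Latent coupling.** One clinical latent `t_clin ~ N(0,1)` per subject
  and an imaging latent `t_img = a·t_clin + √(1−a²)·e`, where `a` is the
  planted clinical→imaging mediation path. With the default `a = 1` the
  two blocks share a single latent, and the correlation between the
  planted latent scores has the closed form
  `coupling²/(coupling²+noise²)`. Blocks are
  `coupling·t·loadingᵀ + confounds·B + noise`, with unit-norm loading
  vectors, linear confound contamination (so perfect residualization
  removes it exactly), and an MCAR mask on the clinical block only
  (k-NN imputation presumes recoverability from observed covariates).
  Defaults: n = 500 subjects (2000 in recovery tests), 60 regions, 12
  clinical variables, coupling 0.8, noise SD 0.5, 5% missingness —
  chosen so the planted dimension is strong but far from noiseless,
  comparable to a dominant first latent variable in large cohort data.
- **Cognition.** `y = b·t_img + c′·t_clin + residual`, scaled to unit
  variance; the planted (a, b, c′) are standardized slopes, recovered by
  fitting the mediation model on the latent scores.
- **Geometry.** Each hemisphere is its own full unit sphere
  (Fibonacci lattice, right = mirror of left), as in surface
  registration. Volumetric centroids are the spheres scaled to 100 mm
  radius and offset ±210 mm along x so that every interhemispheric
  distance exceeds the intrahemispheric diameter — maps are generated
  independently per hemisphere, and distance-based machinery must not
  treat cross-hemisphere pairs as near neighbours (the analogue of
  per-hemisphere geodesic distances on real surfaces).
- **Smooth maps.** Gaussian-process draws with exponential kernel
  `exp(−d/ℓ)` per hemisphere, standardized; ℓ → 0 recovers white noise.
- **Connectomes.** Edge probability ∝ `exp(−d/decay)`, boosted within
  spatially contiguous modules (k-means on centroids), rescaled by
  bisection so the realized density matches the request even when
  short-range probabilities saturate at 1; weights Uniform(0, 1];
  disconnected realizations are flagged, not repaired.
- **Expression.** Each gene map is an independent smooth draw; genes in
  signal categories add `weight × signal_map`. The catalog maps each
  gene to exactly one category.

What the generators do *not* emulate: realistic marginal distributions of
risk factors, site/scanner batch effects beyond a linear cohort term,
non-linear confounding, MNAR missingness, hemispheric asymmetries, or
geodesic cortical distances. Passing recovery tests therefore demonstrates
correctness of the machinery under the planted model, not robustness to
those real-data complications.

## Spatial null models

All surrogate generators preserve the map's value multiset exactly (spin
by construction, variogram and spatial-lag via final rank-remapping), so
any distribution-only statistic is invariant across surrogates and the
nulls differ from the data only in spatial arrangement.

- **Spin.** One uniform SO(3) rotation per surrogate for the left
  hemisphere; its x-mirrored twin for the right. Values move to rotated
  positions by one-to-one greedy nearest-neighbour assignment with
  exclusion (random processing order), giving exact permutations — the
  duplicate-allowing variant was rejected for breaking multiset
  invariance. The identity rotation reproduces the original map.
- **Variogram-matched.** Permute, smooth with a bank of 8 exponential
  kernels (radii log-spaced from half the median nearest-neighbour
  spacing to the 25th distance percentile), and mix with white noise as
  `√b·smooth + √(1−b)·noise`, with the single mixing weight b fitted by
  least squares to the distance-binned empirical variogram — the
  unit-variance constraint matters because the subsequent rank-remap
  fixes the value distribution, which would silently rescale an
  unconstrained two-parameter fit. Matching is restricted to pairs below
  the 25th distance percentile: short-range autocorrelation is what
  inflates map-to-map correlations, and including the long tail dilutes
  the fit where it counts (with a full-range 5-kernel bank the measured
  false-positive rate was ≈ 0.20; with short-range matching it is ≈ 0.05
  at α = 0.05).
- **Spatial-lag.** `y = ρWy + ε` with `W` row-normalized `exp(−d/d0)`,
  zero diagonal. (d0, ρ) by profile maximum likelihood over a log-spaced
  short-range d0 grid and ρ ∈ [0, 0.995] (negative ρ is excluded: these
  nulls model positive autocorrelation, and for near-white maps the
  unconstrained MLE diverges to the negative boundary on the log-det
  term). Surrogates are `(I−ρW)⁻¹ε`, rank-remapped. ρ ≥ 1 is clipped to
  0.99 with a warning.
- **Rewiring.** Maslov–Sneppen double-edge swaps on the binarized
  topology, weights travelling with their edges; degree sequence and
  edge count are conserved exactly. Used as the null for
  neighborhood-abnormality correlations, where the statistic depends on
  topology rather than on map arrangement.

Empirical p-values are add-one two-tailed by default. The three map nulls
are reported side by side where applicable; no combined decision rule is
imposed when they disagree.

## Contextualization

**Degree centrality** is the row sum of connection weights, returned as
average-tie ascending ranks (scale-invariant). **Neighborhood
abnormality** `A_i = (1/N_i) Σ_{j∈N_i} C_j w_ij` normalizes by the count
of connections, not their weight sum; isolated nodes are NaN and excluded
downstream. **Connectivity gradients** come from diffusion-map embedding
of a cosine-similarity affinity on row-sparsified (top 10%) connectivity
profiles, with anisotropic normalization α = 0.5 and automatic diffusion
time (eigenvalue scaling λ/(1−λ)); a disconnected affinity graph is an
error naming the components.

**Ensemble gene-category enrichment (GCEA).** Per cell category, the
effect map is Spearman-correlated with each member gene's map; the
coefficients are Fisher-z transformed and averaged into Z(rsp). The null
recomputes Z with spatial-lag surrogates of the effect map (the
correlated-gene and autocorrelation problems of naive enrichment are both
absorbed by conditioning on the map's spatial structure), two-tailed
add-one p, BH-FDR across categories. The alternative aggregation —
average member-gene expression first, correlate once — is available via
`aggregation='category_mean'`; the per-gene Fisher-z aggregate is the
default statistic. A category needs ≥ 2 present genes; missing genes are
skipped with warnings.

A note on exact recovery under multiplicity: with calibrated p-values, a
null category clears the BH rank-3 bar (p ≤ 3α/m) with probability
≈ 1.5%, so with 8 null categories the probability that *only* the planted
categories are flagged is ≈ 0.886 per dataset. This ceiling is a property
of FDR control itself (BH bounds the expected false-discovery proportion,
not the per-family probability of zero false flags) and cannot be raised
without making the null deliberately conservative; the pooled surrogate
null here matches an independent true-null simulation within ~4% out to
the 99.5th percentile.

## Pipeline and determinism

`run_pipeline` executes preprocess → PLS → mediation (one model per
cognition column, predictor = clinical LV1 score, mediator = imaging LV1
score) → contextualization, writing delimited tables, JSON scalars, a
provenance block (library version, config hash, all numeric settings) and
a markdown report whose numbers are read back from the result files.
Per-stage seeds are derived as `sha256(master_seed:stage_name)` truncated
to 31 bits, so stages are independently reproducible and the whole output
tree is byte-identical under a fixed master seed. Analysis constants
(k = 4 neighbours, 5000 permutations, 5000 bootstrap resamples, 1000 spin
permutations, 10 CV folds, α = 0.05, BR cut 1.96) live in
`PipelineConfig`; unknown config keys are rejected.

Problem sizes in the test suite and acceptance script are scaled to
desk-top dimensions (e.g. 2000 subjects × 60 regions for recovery, 200
parcels for null calibration, 200 permutations × 200 cohorts for type-I
error, 100–200 surrogates where the default is 1000); each reported
quantity states the size used.

## Known limitations

- Euclidean centroid distances stand in for geodesic surface distances;
  vertex-level statistics, surface meshes and neuroimaging file formats
  are out of scope by design.
- The SAR surrogate family cannot perfectly reproduce an
  exponential-kernel Gaussian process; its extreme tail is measured a few
  percent thin, which is visible only in exact-recovery-style criteria.
- Mediation is cross-sectional path analysis, not causal inference; no
  sensitivity analysis for unmeasured confounding is provided.
- Single imputation only (no multiple imputation), greedy rather than
  optimal matching, and no propensity scores.
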