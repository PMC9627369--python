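# Methods

This note documents the models, conventions and numerical choices behind
`nacfc`, and what the synthetic validation does and does not establish.

## Synthetic study design

The generator (`nacfc.synthetic`) emulates the design the analysis chain
assumes, with ground truth recorded for validation:

**Cohort.** A PD/HC case-control table drawn per `SimulationSpec`. Default
sizes are 129 PD / 106 HC; clinical scores are Gaussian draws around
group-level means with group-appropriate directions (higher GDS, STAI,
apathy score, RBD-SQ and ESS in PD; lower MoCA and UPSIT), clipped to
instrument ranges (MoCA 0–30, GDS 0–15, STAI 20–80, ESS 0–24, UPSIT 0–40,
RBD-SQ 0–13, apathy item 0–4, QUIP 0–13). Controls have zero disease
duration, LEDD, UPDRS-III and H&Y, and several degenerate-at-zero scores
(GDS, QUIP), as real PD/HC tables do. Each PD subject carries a hidden
`latent_severity ~ Uniform(0, 1)`; each score adds
`loading × (severity − ½)` before noise. Default loadings (score units per
unit severity): GDS +3, STAI +12, apathy +1, RBD-SQ +3, ESS +5, MoCA −5,
UPSIT −10, QUIP +0.3 — a single rank-1 coupling, because one latent
dimension per seed is the structure the multivariate analysis is meant to
detect.

**Atlas.** Gaussian probability blobs (`p = exp(−d²/2σ²)`, truncated below
0.01, σ = 1.5 voxels by default) for left/right core and shell on a 24³
grid of 3 mm voxels, inside an ellipsoidal brain mask (≈6 300 in-mask
voxels). A 24³ grid keeps a full pipeline run at ~10 s on one CPU while
leaving the pipeline itself grid-agnostic. Neighboring blobs' tails may
overlap slightly below p = 0.5; this mildly mixes the extracted seed
references, as correlated anatomical seeds do in real data.

**BOLD.** Each seed carries a unit-variance AR(1) latent signal
(ρ = 0.3, the simplest process with BOLD-like smoothness). ROI-support
voxels observe `s(t) + ε`; each seed's designated target voxels observe
`a·s(t) + ε` with `a = coupling_hc − slope × severity` (defaults 0.6 and
0.4), all other in-mask voxels pure noise (`ε ~ N(0, 1)`, single
precision; out-of-mask voxels are zero and never analyzed). The population
seed-target correlation is `a/√(a² + σ²)`, so controls sit near z ≈ 0.57
and the most-affected patients near z ≈ 0.20. Targets are grown as three
compact blobs of ~67 voxels per effect seed (nearest-neighbour accretion
around random centers, disjoint across seeds, outside all ROI supports):
group differences in real maps are spatially clustered, and scattered
single-voxel targets would be erased by any extent threshold. The right
shell gets no targets by default, planting a null seed. Per-subject
streams derive from `(root seed, crc32(subject_id))`, so any subject can
be regenerated independently of iteration order.

**Site effects and QC.** Subject z-maps receive `z′ = δᵢ z + γᵢ` by site
(defaults: a large site with γ=0, δ=1 and a small one with γ=0.3, δ=1.2,
at 0.8/0.2 of each group). Mean framewise displacement is Gamma(3, 0.06)
(~0.18 mm); the QC filter accepts an explicit boolean flag column or a
mean-FD threshold (default 0.5 mm — the common convention; the flag column
permits reproducing any documented exclusion manifest exactly).

**What this does not emulate.** No hemodynamic response, physiological
noise, spatial autocorrelation of the noise field, motion artefacts in
image space, registration error, or MNI geometry. Passing tests therefore
demonstrate the *statistical* correctness and calibration of the chain
under its own assumptions — not robustness to the physics of real fMRI.

## Connectivity mapping

Seed references are probability-weighted means `Σ p_v x_v / Σ p_v`
(binarize-at-0.5 is available via thresholding the map before the call).
Voxelwise Pearson r is transformed with `z = atanh(r)`; |r| ≥ 1 − 10⁻⁷ is
clipped to that bound first (logged), keeping z finite (~8.4) without
affecting any realistic value. Out-of-mask and zero-variance voxels carry
NaN as an explicit missing marker and are excluded — never zero-filled —
by harmonization, the GLM and PLS alike.

## Harmonization

Parametric empirical-Bayes ComBat: `y = α + Xβ + γᵢ + δᵢ ε` per feature,
standardized by the pooled OLS fit (batch indicators plus preserved
covariates; variance pooled with denominator n); per-site additive effects
get a Normal prior and multiplicative effects an Inverse-Gamma prior, both
moment-matched across features, and the conditional posterior means are
iterated to a sup-norm tolerance of 10⁻⁴ (max 200 iterations; the toy
oracle comparisons tighten this to 10⁻¹²). Default preserved covariates in
the pipeline: group, age, sex, education — the downstream GLM terms;
preserving group is what stops harmonization from absorbing the effect of
interest. Features with missing values or zero variance pass through
unharmonized with a logged report. One caveat documented deliberately:
EB shrinkage leaves a small residual site difference (the shrunk part of
the per-site sampling noise), so harmonization is only approximately
idempotent — the second pass changes values by far less than the first,
but not by zero. The implementation agrees with Bioconductor's
`sva::ComBat` to ~10⁻⁵ on matrices with covariates and both location and
scale effects.

## Group inference

Per voxel, OLS of z on [intercept, group(PD=1), covariates] with the
group-coefficient t-test (two-sided — reduced FC is an empirical outcome,
not an assumption); default covariates sex, age, education, mean FD.
Benjamini–Hochberg FDR is applied within each seed's in-mask voxels
(four separate families, matching per-seed reporting), then connected
components smaller than 20 voxels are removed (26-neighbourhood by
default, configurable to 6 or 18). FDR-then-extent is the conventional
order for "FDR-corrected with an extent threshold". Seeds with empty
surviving networks are excluded from the multivariate stage with a logged
notice. ROI volumes are compared by ANCOVA (volume ~ group + age + sex +
education), reported as the partial F for group; with no covariates this
reduces exactly to one-way ANOVA.

## Behavioral PLS correlation

Both blocks are column z-scored (ddof = 1), making
`R = YᵀX/(n − 1)` a correlation matrix — consistent with reporting
behavior loadings as correlation coefficients. `R = U S Vᵀ`; per-LV sign
is fixed by making the largest-magnitude behavioral salience positive.
Scores are `X_z V` and `Y_z U`. The analysis runs on PD subjects only:
controls have degenerate symptom distributions (several scores identically
zero), so patient-only blocks are the meaningful pairing.

**Permutation.** Rows of Y are permuted jointly (X fixed), the fit is
recomputed, and permuted singular values are compared to observed ones by
LV position (no re-rotation — the canonical convention);
`p = (1 + #{s^perm ≥ s^obs})/(1 + N)` never returns 0.

**Bootstrap.** Subjects are resampled with replacement, rows paired. Each
resample's solution is aligned to the observed one by orthogonal
Procrustes in the behavioral space, and the bootstrap distribution is
formed over singular-value-weighted saliences `v·s`: the weighting carries
the LV-strength fluctuation into the SE, which is what makes the ratio
`BSR = v_obs s_obs / SD_boot(v s)` approximately standard normal under the
null (unit-norm saliences understate the SD and inflate the null
exceedance of |BSR| > 3.3 several-fold). Zero bootstrap SD (noise-free
degeneracy) caps the BSR at 10⁶. Behavior loadings are Pearson
correlations between each (resampled) behavior column and the resample's
LV imaging score; CIs are 95% percentile intervals (not bias-corrected —
simpler, and adequate for loading magnitudes here), significant when they
exclude zero. Resamples that collapse a column to zero variance are
redrawn (counted, at most 50).

**Nuisance control.** The two-pass protocol: a first PLS pass may include
nuisance variables in the behavior block; the definitive pass residualizes
age, education, duration, LEDD, UPDRS-III, H&Y, the seed's own volume,
TIV and gray-matter volume out of *both* blocks by OLS (residuals exactly
orthogonal to the nuisance span), then reruns with the eight symptom
scores. Removing nuisance from the association requires removing it from
both sides; a single-block mode is available by calling `residualize` on
one block only.

**Random streams.** One root seed; permutation and bootstrap use
independent `SeedSequence` substreams, so results do not depend on the
order in which the two are run, and per-seed analyses use further
substreams.

## Pipeline and reproducibility

`run_pipeline` executes simulate → fc → harmonize → glm → pls from a
single config and records a manifest of parameters plus SHA-256 hashes of
every numeric output (arrays are hashed directly, so the contract holds
with or without file output). The output directory is excluded from the
hashed config — location is not a parameter of the computation. Images are
written as uncompressed NIfTI-1 (diagonal affine from the voxel size,
0-based indices in tables) so reruns are byte-identical.

## Problem sizes used in validation

The test suite and acceptance script run the recovery checks at n =
100/group, 24³ grid, T = 200, 200 target voxels per effect seed, 500
permutations/bootstraps, and the plant–detect closure over 20 planted and
20 null replicates (~10 s per full pipeline replicate on one CPU). Null
calibration uses 200 permutation replicates, 5 000 null voxels for the
GLM error rate, and 100 bootstrap replicates for the BSR exceedance rate.

## Known limitations

- Single latent dimension in the generator; multi-LV recovery is untested.
- Parametric ComBat only (no non-parametric, GAM or longitudinal variants).
- No permutation-based cluster inference (TFCE, cluster-mass); the extent
  threshold is a fixed voxel count.
- PLS correlation only — no PLS regression (NIPALS), sparse PLS, or
  split-half stability analysis.
- The synthetic noise field is spatially white; FDR behaves differently
  under the smooth correlated noise of real fMRI.
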