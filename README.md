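# nacfc

Seed-based functional connectivity of nucleus accumbens (NAc) subregions
and its multivariate association with non-motor symptoms (NMS) of
Parkinson's disease — as a tested, reproducible analysis pipeline.

## The scientific problem

Non-motor symptoms — depression, anxiety, apathy, cognitive decline, REM
sleep behavior disorder, daytime sleepiness, hyposmia, impulse-control
problems — dominate quality of life in Parkinson's disease, and the ventral
striatum's core/shell subdivision of the NAc is a plausible hub for them.
Linking *which* network changes go with *which* symptom profile requires an
analysis chain that (1) maps each subject's seed-voxel connectivity,
(2) removes scanner/site effects from a multi-center cohort, (3) localizes
group differences with voxelwise inference, and (4) relates the surviving
network to the full symptom battery in one multivariate model rather than
one symptom at a time.

`nacfc` implements that chain for Python users:

- **`nacfc.synthetic`** — a generative model of the whole study: a
  probabilistic 4-ROI seed atlas (left/right core and shell), a two-site
  PD/HC cohort with instrument-ranged clinical scores, BOLD series with
  planted seed-target coupling that weakens with a hidden latent severity,
  site location/scale effects, and motion-QC bookkeeping. Ground truth is
  known, so every downstream claim is checkable.
- **`nacfc.fc`** — probability-weighted seed time courses, voxelwise
  Pearson correlation, Fisher r-to-z.
- **`nacfc.combat`** — parametric empirical-Bayes location/scale
  harmonization (ComBat) preserving chosen covariates.
- **`nacfc.glm`** — voxelwise PD−HC contrasts with nuisance covariates,
  Benjamini–Hochberg FDR, cluster-extent filtering, and ROI-volume ANCOVA.
- **`nacfc.plsc`** — behavioral partial least squares correlation:
  SVD of the cross-block correlation, permutation test on singular values,
  bootstrap ratios for voxels, percentile CIs for behavior loadings,
  nuisance residualization of both blocks.
- **`nacfc.pipeline`** / the `nacfc` CLI — orchestration with content-hash
  manifests; identical configuration ⇒ byte-identical results.

## The model at the core

For one seed, subject-level maps are `z = atanh(r)` with `r` the Pearson
correlation between the seed's probability-weighted mean time course and
each brain voxel. After harmonization and the voxelwise group contrast
(FDR `q < 0.05`, extent ≥ 20 voxels), the PD subjects' `z` values inside the
surviving network form `X` (subjects × voxels) and their clinical scores
form `Y` (subjects × behaviors). Both blocks are column z-scored and the
cross-block correlation is decomposed:

    R = Yᵀ X / (n − 1),      R = U S Vᵀ

Latent variable *i* pairs a behavioral salience `uᵢ` with an imaging
salience `vᵢ`; it explains `sᵢ² / Σⱼ sⱼ²` of the cross-block covariance and
is tested by permuting the rows of `Y` (`p = (1 + #{sᵢ^perm ≥ sᵢ}) / (1 + N)`).
Subject resampling with replacement, Procrustes-aligned to the observed
solution, gives each voxel a bootstrap ratio (weighted salience over its
bootstrap SE; `|BSR| > 3.3 ≈ p < 0.001`) and each behavior a loading — its
correlation with the LV imaging score — with a 95% percentile CI that must
exclude zero for significance.

## Worked example

`python examples/05_behavioral_plsc.py` plants one latent dimension that
lowers connectivity and drives four symptom scores, then runs the full
PLSC inference:

```
LV-I: 99% of cross-block covariance, permutation p = 0.000999
voxels with |BSR| > 3.3: 60/60
imaging-behavior score correlation r = 0.92

behavior   loading   95% CI          significant
MoCA       -0.77   [-0.84, -0.69]   True
GDS        +0.84   [+0.78, +0.89]   True
STAI       +0.75   [+0.67, +0.82]   True
apathy     +0.63   [+0.53, +0.73]   True
```

The single planted dimension is recovered as a dominant, significant LV-I;
cognition (MoCA) loads opposite to depression/anxiety/apathy because worse
severity lowers the one and raises the others; every planted voxel is
flagged bootstrap-stable. The other `examples/*.py` scripts walk through
cohort simulation, single-subject connectivity mapping, site
harmonization, voxelwise group inference, and the end-to-end pipeline
(`python examples/06_full_pipeline.py` prints the per-seed report,
including the null right-shell seed being excluded for having no surviving
voxels).

The same chain runs from the shell:

```bash
nacfc run --out out/ --seed 42 --n-perm 1000 --n-boot 1000
nacfc report --manifest out/manifest.json
```

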