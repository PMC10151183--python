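# Methods

This note documents the models implemented in `dsdkit`, the choices made
where the design was genuinely open, what the synthetic generator does and
does not emulate, and the package's numerical conventions.

## Disconnectome maps

A patient's structural disconnectome is computed against a normative
streamline set (one whole-brain tractogram per healthy subject, world-mm
coordinates in a common template space):

1. keep the streamlines with at least one point inside the lesion;
2. binarise the kept streamlines into a voxel visitation mask (1 wherever
   any streamline passes);
3. average the masks over subjects.

Voxel values are therefore exact rationals k/n — the fraction of normative
subjects disconnected at that voxel.

*Intersection convention.* Streamlines are resampled to at most half-voxel
spacing and tested point-in-voxel (half-up rounding of continuous voxel
indices, so boundary points resolve consistently); the constant
`disconnectome.INTERSECTION_MODE` records this.  Exact segment–voxel
clipping would change results only for streamlines that clip a voxel corner
between two sample points, an error bounded by the resampling density.
`NormativeSet` precomputes each streamline's visited voxels once so a whole
cohort can be mapped without re-filtering; it is contractually identical to
the direct path and tested against it.

Lesion masks are binarised at > 0.5 on read (upstream registration can
leave fractional values) and must already be on the template grid; the
package performs no registration.

The functional comparator correlates the mean signal time course inside the
lesion with every voxel's time course per normative subject (4-D signal
volumes) and averages the subject maps.  The brain mask is the set of
voxels with nonzero signal variance — no anatomical masks exist in the
synthetic world.  Subjects whose lesion time course is constant are skipped
with a warning.

## Morphospace

Disconnectome maps are vectorised and embedded with UMAP
(`n_neighbors=15`, `min_dist=0.1`, Euclidean metric, 2 components — the
embedding library's defaults for a 2-D embedding).  Coordinates are shifted
so the training cloud is positive with zero origin.  The fitted transform
is persisted and used to project unseen patients; no refitting.

Numerical choices worth knowing:

- **Feature mask.** Only voxels that *vary* across the training maps enter
  the embedding.  Constant features are inert under the Euclidean metric
  but change the embedding library's random-number consumption and induce
  cancellation error in its distance kernel; dropping them (plus
  subtracting the per-voxel training minimum) makes the embedding invariant
  to constant image offsets up to the library's stochastic tolerance.
- **Seed.** The embedding is seeded (default 42) and recorded in the model
  bundle; coordinates are reproducible within this tool but have no
  absolute meaning across tools or versions.
- **Training-point projection.** The library's out-of-sample transform does
  not return a training point's stored coordinate (observed deviations of
  order 1 embedding unit).  `embed()` therefore short-circuits queries that
  are exactly equal to a training map to the stored coordinate; everything
  else goes through the native transform.
- **Stochastic sensitivity.** The layout optimiser is chaotic at the level
  of 1-ulp feature perturbations: two runs on mathematically identical
  inputs that differ in floating representation can produce layouts that
  agree in cluster structure but not in coordinates.  Tests therefore
  assert structure (cluster segregation, rank-correlated distances), not
  coordinates, for such comparisons.

## Composite per-score models

Each embedded coordinate is rasterised onto a `grid_size x grid_size`
morphospace image (default 260 × 260 pixels of 0.05 mm — a 13 mm window)
as a unit impulse convolved with an isotropic Gaussian of sigma 1 mm
(20 pixels), truncated at 4 sigma and renormalised to sum exactly 1, giving
a probability-of-localization map.  Two coordinate-to-pixel mappings exist:

- `direct` (default config): morphospace units read as mm over the
  [0, 13 mm) window; coordinates outside are clipped to the border with a
  warning and counted.
- `autoscale`: the training coordinates are min-max scaled into the window
  with a 3-sigma margin, and the frozen mapping is applied to test
  patients.  The high-level model constructor uses this mode because UMAP
  coordinate ranges vary freely from cohort to cohort; the mapping is
  stored in the model bundle.

Per score, patients with a missing value are dropped (pairwise deletion,
never imputation).  The pipeline is then:

1. **Correlation map**: per-pixel Pearson correlation between localization
   probability and the score across patients.  Pixels with zero variance
   across patients (scale-relative tolerance) are set to r = 0 and flagged,
   keeping the connected-component step total.
2. **Territories**: 8-connected components of |R| > 0.2 (the medium
   effect-size convention).  Only components containing at least one
   training patient's peak pixel count; if more than three qualify, the
   three with most patients are kept (ties: larger area, then lower label
   index).  No qualifying component is an error — the score is recorded
   as unmodelable, not fitted.
3. **Spatial PCA**: column-centred, unscaled PCA of the patients ×
   territory-pixels matrix over the *union* of kept components (per-cluster
   PCA would break the fixed three-component contract).  A warning fires if
   the three components explain less than 80 % of the variance.  For the
   typical shape (n patients ≪ m pixels) the exact Gram-matrix
   eigendecomposition is used; directions with numerically zero variance
   are completed deterministically with canonical axes and contribute zero
   explained variance.  Component signs are fixed (largest-magnitude entry
   positive) for reproducibility.
4. **Regression**: ordinary least squares of the score on the three PCA
   scores (intercept + 3 weights).  Collinear predictors fall back to the
   minimum-norm solution with a warning.  At least 5 non-missing patients
   are required per score.

Predictions are *not* clipped to the score scale by default (the regression
is linear and MAE% is computed on raw predictions); a flag enables
clipping.

## Evaluation

- **MAE%** = mean |measured − predicted| / max(score scale) × 100; scale
  invariant and comparable across clinical instruments.
- **R²** is the squared Pearson correlation from regressing measured on
  predicted scores.  It is reported only for cohorts above 20 subjects; the
  gate is soft (an override flag with a warning) because synthetic tests
  need small cohorts.  A constant predictor has R² = 0 by contract, which
  pins the group-mean baseline to zero.
- **k-fold stability**: 100 random 70/30 splits on the fixed morphospace.
  Each iteration refits territories, PCA and regression on its training
  split — reusing full-cohort territories would leak information from the
  held-out patients; a flag restores the cheaper reuse variant.  Failed
  iterations (no territory) are recorded, not dropped.
- **Voxel-based comparators** (disconnectome, lesion or functional-map
  features): per-voxel association t statistic, voxels at or above the
  98th percentile of |t| selected, per-voxel R² = t²/(t² + df), and the
  *mean* over selected voxels reported (a `max` aggregation is available;
  the aggregator is a config choice).  Score-permutation nulls of the same
  statistic support calibration (p = (1 + #{null ≥ observed}) / (n + 1)).
- **Volume + age baseline**: OLS on standardised lesion volume and age;
  constant covariates are excluded with a warning.
- **Model comparison**: two-tailed paired t-test of the reference model's
  per-score R² against each comparator across shared scores, Bonferroni
  multiplied by the number of comparators and capped at 1.

## Effect-size atlas

For every modeled score, each of the three spatial-PCA patient scores is
regressed voxel-wise on disconnection values over a reference cohort.  The
slope t statistic (capped at |t| = 1e6 for perfect associations; zero-
variance voxels get t = 0) is converted to Cohen's f² = t²/df, equivalent
to R²/(1 − R²).  The voxel-wise maximum over the three components, with
provenance, is the score's effect-size map.  Across scores:

- **summary labels**: per voxel, the 1-based index of the score with the
  largest f², labelled only where it reaches the medium threshold 0.15
  (ties break to the lowest index);
- **versatility**: per voxel, the count of scores with f² ≥ 0.35.

The thresholds follow the conventional medium/large f² bands
(0.15 ≤ f² < 0.35 medium, ≥ 0.35 large).  Split-half reproducibility
derives the full atlas on two disjoint subject halves and reports the
Pearson correlation between the stacked per-score effect-size vectors over
voxels with nonzero disconnection variance in both halves (correlating the
continuous effect sizes rather than discrete label maps, which is the
stricter of the two readings).  Permutation p-values for the voxel-wise
GLM default to 500 permutations (desk scale; configurable upward).

## Synthetic cohorts

The generator plants a fully known ground truth on a miniature template —
40 × 48 × 40 voxels at 2 mm (≈ 77 k voxels), a desk-scale stand-in for a
2 mm whole-brain grid that keeps full-pipeline studies in minutes:

- **tracts**: mirrored left/right projection tracts plus a commissural arc
  (radius 6 mm), so hemispheric segregation of the embedding is testable.
  Each normative subject's fascicle consists of densified centerline copies
  displaced by per-streamline Gaussian offsets (sd = jitter, default 1 mm)
  truncated at the tract radius — truncation guarantees that a lesion
  covering the fascicle cross-section severs every streamline.
- **lesions**: axis-aligned ellipsoids (semi-axes 6.5–8 mm by default)
  centred on randomly chosen tract centerline points (or scattered over the
  grid), the simplest family with a controllable volume confound.
- **scores**: `clip(intercept + Σ_t w_t·load_t + confound·volume_z +
  N(0, sd), 0, max_scale)`, where the per-tract loads are computed by a
  brute-force streamline–lesion intersection implemented independently of
  the disconnectome module (a cross-module oracle).  Default max scale 100,
  intercept at mid-scale.  Ages are drawn at 54 ± 11 years (clipped to
  19–83), matching a typical 1-year stroke outcome cohort, for the
  volume + age comparator.

What the generator does *not* emulate: realistic vascular-territory lesion
shapes, anatomical tract geometry beyond three idealised fascicles,
score-score collinearity, floor/ceiling psychometrics, or diffusion signal.
Passing the simulation studies shows the pipeline recovers planted linear
disconnection–score structure under Gaussian noise at these geometries; it
does not certify performance on clinical data.

## Standard study conditions

The validation studies (tests and `scripts/acceptance.py`) use:

- parameter recovery: 200 patients (150 train / 50 test), 6 normative
  subjects, 3 tracts, noise sd = 10 % of each planted score's range,
  near-constant lesion volume so tract identity drives the scores; 10
  seeds.  Success = held-out R² ≥ 0.5 and MAE% ≤ 15 for all planted scores;
  the composite model must also beat the volume + age and group-mean
  baselines.
- k-fold stability: 150 patients, noiseless planted scores, 100 iterations
  of 70/30.
- split-half atlas reproducibility: 2 × 60 subjects, 10 seeds, threshold
  R ≥ 0.8.
- voxel-model null calibration: 20 seeds of 30 patients × 1000 voxels with
  permuted scores and 200-permutation nulls.

These sizes are the package's chosen desk-scale defaults; all are
parameters of the experiment functions in `dsdkit.experiments`.

## Reproducibility and serialisation

All randomness flows from one global seed fanned out per stage via a SHA-256
hash (`dsdkit._seeds.stage_seed`), so any stage can be re-run in isolation.
Model bundles are zip archives of `.npy` arrays plus a JSON manifest
(format version, library versions, config); the fitted UMAP estimator,
which has no array representation, is stored as a single declared pickle
entry inside the archive.  A load of a saved bundle reproduces predictions
bit-identically on the same platform (tested).  CLI artifacts carry
`.prov.json` sidecars (command, parameters, seed, input digests) and
reports contain no timestamps, so identical runs are byte-identical.

## Known limitations

- Coordinates of the morphospace are meaningful only relative to a stored
  model; there is no canonical embedding across library versions.
- The any-point intersection test can miss a streamline that clips a voxel
  corner between samples (bounded by the half-voxel resampling).
- The composite model is linear in three spatial-PCA scores; strongly
  non-linear score–territory relationships would be underfit by design.
- The n > 20 gate for R² reporting is a reporting convention, not a
  statistical guarantee; small-cohort R² values obtained via the override
  are noisy.
- With fewer than `n_neighbors` patients per cluster the embedding merges
  clusters; choose `n_neighbors` below the expected cluster size for small
  cohorts.
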