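# Methods

This note documents the models, conventions and numerical choices behind
`neolung`, and what the synthetic phantoms do and do not establish about
real neonatal MRI.

## Conventions

All 3D arrays are indexed `(AP, LR, CC)`: anteroposterior, left–right,
craniocaudal. The slice axis of an axial multisection acquisition is CC,
and its effective spacing is the **slice pitch** — section thickness plus
inter-section gap (default 4.0 + 0.4 = 4.4 mm), so the gap's tissue share
is attributed to the neighbouring sections rather than dropped. Default
in-plane spacing is 1.3 × 1.9 mm. World coordinates are
`index × spacing` in millimetres with the origin at the corner of voxel
(0, 0, 0); voxel centres sit at `(index + 0.5) × spacing`. Under the
radiological convention the subject's left lung has the smaller LR world
coordinate.

## Phantoms

A phantom is a torso-like bright ellipsoid containing two darker
ellipsoidal lungs. Because the lungs are analytic, their volume
(`4/3·π·abc`), centroid, and smooth-case surface area (Knud Thomsen's
approximation, `4π·((a^p b^p + a^p c^p + b^p c^p)/3)^{1/p}` with
p = 1.6075, relative error ≤ 1.06 %) provide ground truth for every
downstream stage. Knobs and defaults:

- `noise_sd` (4 a.u. against lung 40 / background 120) and
  `blur_sigma_mm` (1 mm): additive Gaussian noise and in-plane blur.
- `ap_gradient_slope` (0 by default): a linear anteroposterior intensity
  gradient inside the lungs, emulating the gravity-dependent signal of a
  supine neonate; it is the surrogate the intensity-displacement feature
  is validated against.
- `surface_perturbation_amplitude` (0 by default): a seeded radial
  modulation of the lung surface by real spherical harmonics of degrees
  8, 12 and 16, normalised so the radial displacement never exceeds the
  stated amplitude. Degrees in this range are deliberate: much lower
  degrees merely change the overall shape, which the convex hull follows,
  so the hull-based roughness ratio would not respond to the knob. The
  harmonics are evaluated only on the shell the perturbation can reach.
- `random_phantom_spec(seed)` draws per-subject lung sizes (±15 %) and
  positions (±4 mm in plane, ±1 mm along CC) around anatomically plausible
  proportions of the grid, with caps that keep every draw inside a
  2-voxel margin; segmentation experiments use these so the network must
  generalise rather than memorise one template.

Simulated raters displace the true surface by a smooth Gaussian random
field (8 mm correlation length, RMS amplitude = `boundary_jitter_mm`)
applied to the signed Euclidean distance transform: boundary bands are
randomly dilated and eroded, the deep interior and far exterior are
untouched, and zero jitter returns exact copies. Mean pairwise Dice
decreases monotonically in the jitter amplitude.

Synthetic cohorts draw a four-grade severity label, patient attributes
(gestational age, birth weight, body size, sex) and postnatal variables
(5-minute Apgar, early-onset infection, steroid treatment) with
grade-dependent distributions, respiratory-support day counts from
negative-binomial distributions (dispersion 2, grade-dependent means — so
the Poisson regression stage is exercised under overdispersion), and the
78 lung features as standard normal noise plus optional planted
standardised mean shifts per grade step. With no planted effects the
features are independent of the label by construction.

**What phantoms do not show:** realistic MR contrast (no T2 relaxation,
coil profiles, motion or ghosting), lobar anatomy, airways, or the
correlation structure of real lung features. Passing tests establish that
the *implementation* is correct against analytic geometry and planted
effects, not that clinical performance numbers transfer.

## Segmentation

One 2D U-Net per human rater, trained on that rater's masks, slice by
slice; binarised predictions (threshold 0.5 by default — the cutoff is a
config knob) are fused by strict pixelwise majority vote, the same rule
that forms the physician consensus. For an even member count, an
exactly-tied pixel is set to background and the tie count is reported.

The network is a symmetric encoder–decoder (depth = resolution levels,
channels doubling per level, 2×2 max-pooling, nearest-neighbour
upsampling + 1×1 channel-halving convolution, skip concatenation, 1×1
logit head) implemented directly in NumPy with im2col convolutions and
hand-written reverse-mode gradients; the gradients are checked against
central finite differences to ~1e-6 in the unit tests. Choices that
matter:

- **LeakyReLU (slope 0.1)** instead of plain ReLU: lung slices are ~4 %
  foreground, and with plain ReLU the first gradient steps can push every
  unit inactive at once, collapsing the network to a constant output (we
  observed this deterministically at several seeds). The leak keeps
  gradients alive.
- **Loss = soft-Dice + BCE over the batch**: the Dice term counters the
  class imbalance, BCE keeps per-pixel gradients informative.
- **Adam** (lr 1e-3 default; small-data demos use up to 1e-2), He
  initialisation, seeded; the training seed fully determines the weights.
- Model input is robustly scaled per volume to [0, 1] via the 1st/99th
  percentiles; morphologic features always read the **raw** intensities.
- In-plane sizes must be divisible by `2^depth`; the crop stage produces
  128 × 128 slices (window centred on the intensity centre of mass, one
  window per subject, recorded so masks crop congruently; smaller inputs
  are symmetrically zero-padded).

The volumetric Dice coefficient is computed over the whole 3D stack, never
slice-averaged; two empty masks raise instead of silently scoring 1.

Training-scale defaults in tests and the acceptance script — 8 subjects of
48×48×12 voxels at (2.5, 2.5, 4.4) mm, depth 3, 8 base channels, 20
epochs — are the package's desk-scale study conditions; a held-out phantom
reaches volumetric Dice well above 0.85 under them.

## Reconstruction

Connected components use 26-connectivity (the most permissive standard
choice; anisotropic slices would otherwise split thin apices). The two
largest components become the lungs, assigned left/right by LR centroid
order; smaller specks are discarded with a logged count, and an LR
centroid gap under one LR voxel raises an ambiguity error.

The canonical reference frame aligns the principal inertia axes of the
**combined** two-lung voxel cloud (a per-lung frame would destroy
cross-lung comparability of centroid features). Each eigenvector is
assigned to the anatomical axis it is most parallel to — considering all
permutations — so an already-aligned subject gets the identity and a
tilted subject the inverse tilt. (Mapping "longest axis → CC"
unconditionally would misbehave: the combined cloud's longest axis is
generically LR, dominated by the separation of the two lungs.) Signs are
fixed deterministically: LR so the left lung is at negative LR, CC keeps
the slice order, AP makes the determinant +1. A nearly isotropic cloud
(relative eigenvalue spread < 1e-6) falls back to the identity with a
warning.

The frame is stored as rotation + translation applied to voxel-centre
*coordinates*; the grid itself is never resampled. This makes volume and
intensity statistics exactly invariant under alignment and avoids
nearest-neighbour artefacts in the surface mesh; a resampled export
exists for visualisation only. Lung volume is voxel count × voxel volume
(with the slice pitch as CC spacing).

## Morphologic features

78 features = 2 lungs × (19 volumetric + 15 intensity + 5 surface); the
roster, ordering, units and formula strings are frozen in one manifest
module (`neolung.manifest`) and guarded by a hash regression test, so the
roster can be amended in one place without touching extraction code.

- Volumetric: volume; bounding-box extents, geometric centroid, and
  second central coordinate moments per canonical axis; principal inertia
  eigenvalues (per unit mass); equivalent-ellipsoid axis lengths
  `2·sqrt(5·λ)` from the coordinate-covariance eigenvalues λ (exact for a
  solid ellipsoid); elongation = major/minor axis length;
  equivalent-sphere diameter; extent fraction = volume / bounding-box
  volume. Bounding-box extents add the voxel footprint projected on each
  canonical axis to the voxel-centre span (exact for axis-aligned
  frames).
- Intensity: mean, SD, median, min, max, skewness, excess kurtosis, 10th
  and 90th percentiles, 64-bin Shannon entropy (bits); intensity-weighted
  centroid per axis (weights clipped at zero — MR magnitudes are
  non-negative, noise may dip below); and the AP and CC centroid
  displacements, `(weighted − geometric centroid) / axis extent`,
  normalised to be dimensionless and body-size free. A constant-intensity
  lung reports skewness/kurtosis 0 with an explicit flag.
- Surface: marching cubes at iso-level 0.5 with spacing-aware vertices on
  the binary label, after Gaussian pre-smoothing of 0.8 voxels — raw
  binary marching cubes produces a staircase mesh that overestimates a
  smooth surface's area by 6–9 %, while 0.8 voxels of smoothing brings a
  1 mm-grid sphere within 1 % of 4πr² without erasing mm-scale structure.
  Features: mesh area, area/volume, convex-hull area, roughness =
  mesh/hull area (floored at 1), solidity = voxel volume / hull volume
  (capped at 1); the caps absorb sub-percent discretisation noise in
  ratios whose mathematical range is one-sided.

## Severity models

Designs are built from group selectors (`GA`, `L`, `P`, `C`, `PC`, `PCL`,
…); subjects with missing values in selected columns are excluded with a
logged count and all-constant columns dropped with a warning. The design
is returned raw: standardisation, dimensionality reduction (ANOVA-F
univariate selection with inner-CV-chosen k, or PCA) and the estimator
live in one sklearn pipeline whose every stage is fitted on training
folds only.

Nested CV: stratified 5-fold outer and inner loops, 10 repetitions by
default, hyperparameters chosen by randomized search on the inner folds
(default budget 50 draws; tests and the acceptance script use 3–4 draws
to stay desk-scale). Outer-fold predicted probabilities are pooled per
repetition before computing the AUC — stable when a class has few
members — and results are reported as mean ± SD **across repetitions**
(the alternative, across outer folds, is noisier at small n; the choice
is labelled here). Multiclass AUC is one-vs-rest, both prevalence-weighted
("macro-weighted") and unweighted. Count regression (Poisson or random
forest) uses the same discipline with pooled outer-fold MAE, outer folds
stratified on response quartiles.

Leakage is guarded by a canary test: univariate selection fitted on the
full data before CV inflates the AUC of pure-noise data well above
chance (the classic selection bias); the nested pipeline, run on the same
data, must stay at chance.

One estimator note: chance-level checks on a *fixed* null cohort inherit
that dataset's sampling noise (~0.04 AUC at n = 200) no matter how many
CV repetitions are run, because repetitions only re-split the same rows.
The chance-level acceptance check therefore averages over five
independently generated null cohorts.

Exploratory statistics: pairwise Spearman correlations with Bonferroni
correction (adjusted α = 0.05 / number of tests; constant columns are
flagged, not crashed), Kruskal–Wallis across severity grades, and
pairwise Mann–Whitney U with Bonferroni correction.

## Known limitations

- The feature roster is this package's reconstruction from the category
  counts and exemplar names; the frame-alignment procedure is an
  inertia-axis method documented above, not a claimed replica of any
  specific clinical pipeline's frames.
- Phantom realism limits are listed above; clinical VDC/AUC levels are
  not reproducible from synthetic data and are not claimed.
- The NumPy U-Net is CPU-bound and desk-scale by design; it accepts
  arbitrary depth/width but is not meant for training on large clinical
  cohorts.
- Severity labels in the synthetic cohort are drawn independently of the
  image phantoms; the pipeline links them only through the planted
  feature shifts.
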