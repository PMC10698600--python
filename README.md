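# neolung

Quantitative analysis of neonatal lung MRI for preterm infants at risk of
bronchopulmonary dysplasia (BPD). The package implements the full
quantification chain a clinical-imaging group needs to turn an axial
T2-weighted slice stack into disease-relevant numbers:

1. **Segmentation** — per-rater 2D U-Net models trained on each human
   annotator's masks, fused by pixelwise majority voting into a model
   ensemble. Concordance is measured with the volumetric Dice coefficient
   `VDC(A, B) = 2|A∩B| / (|A| + |B|)` over the whole 3D stack.
2. **Reconstruction** — thresholding, 26-connected 3D components, a
   left/right lung split, and alignment of the combined-lung principal
   inertia axes to a canonical `(AP, LR, CC)` anatomical frame. Slice
   stacks are treated at their physical geometry (e.g. 1.3 × 1.9 mm in
   plane, 4.4 mm slice pitch = 4 mm section + 0.4 mm gap).
3. **Morphologic features** — 78 named features per subject (39 per lung:
   19 volumetric, 15 intensity, 5 surface), including lung elongation
   (major/minor equivalent-ellipsoid axis), the intensity anteroposterior
   centroid displacement (a ventilation-inhomogeneity proxy), and the
   volumetric surface roughness (mesh area / convex-hull area).
4. **Severity models** — nested cross-validated classification (elastic-net
   logistic regression, random forests; optional univariate selection or
   PCA) of BPD severity from feature groups L (lung features), P (patient
   attributes) and C (postnatal adaptation), scored by pooled-prediction
   AUC (macro prevalence-weighted one-vs-rest for the 4-class case), plus
   Poisson / random-forest regression of respiratory-support day counts,
   and Spearman/Bonferroni exploratory statistics.

Because clinical images cannot ship with the code, the package includes a
first-class **phantom module**: torso-like volumes with two ellipsoidal
lungs whose volume, centroid and surface area have closed forms, plus
simulated raters (boundary-jittered masks) and synthetic cohorts with
planted feature–severity effects. Every stage is tested against these
analytic oracles.

## Worked example

```python
from neolung import (PhantomSpec, generate_phantom, simulate_raters,
                     majority_vote, reconstruct, extract_features,
                     volumetric_dice)

vol, truth, analytic = generate_phantom(PhantomSpec(seed=7))
raters = simulate_raters(truth, n_raters=3, boundary_jitter_mm=1.5, seed=7)
consensus = majority_vote(raters)
print(round(volumetric_dice(consensus, truth), 3))

recon = reconstruct(truth, intensities=vol)
features = extract_features(recon)
print(len(features), features.category_counts())
print(round(features.values["left_vol_elongation"], 2),
      round(features.values["left_surf_roughness"], 3))
```

prints

```
0.987
78 {'volumetric': 38, 'intensity': 30, 'surface': 10}
2.42 1.0
```

— the three-rater consensus overlaps the true mask at VDC 0.987, the
feature vector has exactly 78 entries split 38/30/10 across categories,
and the left phantom lung is 2.42× elongated (its craniocaudal semi-axis
is the longest) with surface roughness at the smooth-convex limit of 1.

A command-line interface mirrors the stages
(`neolung phantom|segment|reconstruct|features|classify|regress|run`);
`neolung run --config cfg.json --out dir/` executes the whole chain and
writes a manifest with content hashes, seeds and timings.

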