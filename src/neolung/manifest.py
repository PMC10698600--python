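"""Frozen roster of the 78 morphologic lung features.

39 features per lung (19 volumetric, 15 intensity, 5 surface), duplicated
for the left and right lung: 38 volumetric + 30 intensity + 10 surface in
total.  The roster is frozen here, in one place, so it can be amended
without touching extraction code; feature ordering is part of the public
contract (left block first, then right, category order volumetric ->
intensity -> surface).
"""

from __future__ import annotations

# (short name, category, units, formula / meaning)
PER_LUNG_FEATURES: list[tuple[str, str, str, str]] = [
    # --- volumetric (19) ---
    ("vol_volume_mm3", "volumetric", "mm^3", "voxel count x voxel volume"),
    ("vol_bbox_extent_ap_mm", "volumetric", "mm", "bounding-box extent along AP in the canonical frame"),
    ("vol_bbox_extent_lr_mm", "volumetric", "mm", "bounding-box extent along LR in the canonical frame"),
    ("vol_bbox_extent_cc_mm", "volumetric", "mm", "bounding-box extent along CC in the canonical frame"),
    ("vol_centroid_ap_mm", "volumetric", "mm", "geometric centroid, AP coordinate, canonical frame"),
    ("vol_centroid_lr_mm", "volumetric", "mm", "geometric centroid, LR coordinate, canonical frame"),
    ("vol_centroid_cc_mm", "volumetric", "mm", "geometric centroid, CC coordinate, canonical frame"),
    ("vol_inertia_eig_major_mm2", "volumetric", "mm^2", "largest principal moment of inertia per unit mass"),
    ("vol_inertia_eig_mid_mm2", "volumetric", "mm^2", "middle principal moment of inertia per unit mass"),
    ("vol_inertia_eig_minor_mm2", "volumetric", "mm^2", "smallest principal moment of inertia per unit mass"),
    ("vol_axis_major_mm", "volumetric", "mm", "major axis length of the inertia-equivalent ellipsoid"),
    ("vol_axis_intermediate_mm", "volumetric", "mm", "intermediate axis length of the inertia-equivalent ellipsoid"),
    ("vol_axis_minor_mm", "volumetric", "mm", "minor axis length of the inertia-equivalent ellipsoid"),
    ("vol_elongation", "volumetric", "1", "major axis length / minor axis length (>= 1)"),
    ("vol_equiv_sphere_diameter_mm", "volumetric", "mm", "diameter of the sphere with the same volume"),
    ("vol_extent_fraction", "volumetric", "1", "volume / bounding-box volume"),
    ("vol_moment2_ap_mm2", "volumetric", "mm^2", "second central moment of voxel AP coordinates"),
    ("vol_moment2_lr_mm2", "volumetric", "mm^2", "second central moment of voxel LR coordinates"),
    ("vol_moment2_cc_mm2", "volumetric", "mm^2", "second central moment of voxel CC coordinates"),
    # --- intensity (15) ---
    ("int_mean", "intensity", "a.u.", "mean lung voxel intensity"),
    ("int_std", "intensity", "a.u.", "standard deviation of lung voxel intensities"),
    ("int_median", "intensity", "a.u.", "median lung voxel intensity"),
    ("int_min", "intensity", "a.u.", "minimum lung voxel intensity"),
    ("int_max", "intensity", "a.u.", "maximum lung voxel intensity"),
    ("int_skewness", "intensity", "1", "skewness of the intensity distribution (0 if constant)"),
    ("int_kurtosis", "intensity", "1", "excess kurtosis of the intensity distribution (0 if constant)"),
    ("int_p10", "intensity", "a.u.", "10th percentile intensity"),
    ("int_p90", "intensity", "a.u.", "90th percentile intensity"),
    ("int_entropy", "intensity", "bits", "Shannon entropy of a 64-bin intensity histogram"),
    ("int_wcentroid_ap_mm", "intensity", "mm", "intensity-weighted centroid, AP coordinate, canonical frame"),
    ("int_wcentroid_lr_mm", "intensity", "mm", "intensity-weighted centroid, LR coordinate, canonical frame"),
    ("int_wcentroid_cc_mm", "intensity", "mm", "intensity-weighted centroid, CC coordinate, canonical frame"),
    ("int_ap_centroid_displacement", "intensity", "1",
     "(intensity-weighted AP centroid - geometric AP centroid) / AP extent"),
    ("int_cc_centroid_displacement", "intensity", "1",
     "(intensity-weighted CC centroid - geometric CC centroid) / CC extent"),
    # --- surface (5) ---
    ("surf_area_mm2", "surface", "mm^2", "marching-cubes mesh surface area"),
    ("surf_area_to_volume_mm1", "surface", "1/mm", "mesh surface area / voxel volume"),
    ("surf_hull_area_mm2", "surface", "mm^2", "surface area of the convex hull of the mesh"),
    ("surf_roughness", "surface", "1", "mesh area / convex-hull area (>= 1, 1 for smooth convex shapes)"),
    ("surf_solidity", "surface", "1", "voxel volume / convex-hull volume (<= 1)"),
]

SIDES = ("left", "right")

FEATURE_NAMES: list[str] = [
    f"{side}_{name}" for side in SIDES for name, _, _, _ in PER_LUNG_FEATURES
]

FEATURE_CATEGORIES: dict[str, str] = {
    f"{side}_{name}": cat for side in SIDES for name, cat, _, _ in PER_LUNG_FEATURES
}

FEATURE_UNITS: dict[str, str] = {
    f"{side}_{name}": units for side in SIDES for name, _, units, _ in PER_LUNG_FEATURES
}

FEATURE_FORMULAS: dict[str, str] = {
    f"{side}_{name}": desc for side in SIDES for name, _, _, desc in PER_LUNG_FEATURES
}

N_FEATURES = len(FEATURE_NAMES)  # 78

CATEGORY_COUNTS = {
    cat: sum(1 for c in FEATURE_CATEGORIES.values() if c == cat)
    for cat in ("volumetric", "intensity", "surface")
}


def manifest_records() -> list[dict]:
    """The manifest as JSON-serialisable records (name, category, units, formula)."""
    return [
        {
            "name": name,
            "category": FEATURE_CATEGORIES[name],
            "units": FEATURE_UNITS[name],
            "formula": FEATURE_FORMULAS[name],
        }
        for name in FEATURE_NAMES
    ]
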