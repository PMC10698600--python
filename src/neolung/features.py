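"""Extraction of the 78 morphologic lung features.

For each lung, 19 volumetric, 15 intensity and 5 surface features are
computed from the reconstruction (39 per lung, 78 in total).  Positional
features (centroids, bounding boxes, axis moments) are evaluated on the
voxel-centre coordinates mapped into the canonical reference frame, so
they are comparable across subjects; rotation-invariant features (volume,
inertia eigenvalues, surface metrics, intensity statistics) are computed
on the exact voxel cloud / grid.

Two features deserve a word because they act as injury surrogates:

* ``int_ap_centroid_displacement`` — the offset between the
  intensity-weighted and geometric centroids along the anteroposterior
  axis, normalised by the lung's AP extent.  A posterior-to-anterior
  signal gradient (ventilation inhomogeneity in the supine neonate)
  pushes this value away from zero.
* ``surf_roughness`` — mesh surface area divided by the surface area of
  its convex hull; 1 for smooth convex lungs, increasing with surface
  irregularity.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import ConvexHull
from scipy.stats import kurtosis, skew
from skimage.measure import marching_cubes, mesh_surface_area

from .manifest import (
    CATEGORY_COUNTS,
    FEATURE_CATEGORIES,
    FEATURE_NAMES,
    FEATURE_UNITS,
    N_FEATURES,
    manifest_records,
)
from .reconstruction import LABELS, LungReconstruction


@dataclass
class LungFeatureSet:
    """The ordered 78-feature vector with category/unit metadata."""

    values: dict[str, float]
    subject_id: str = ""
    flags: list[str] = field(default_factory=list)

    def __post_init__(self):
        if list(self.values) != FEATURE_NAMES:
            missing = set(FEATURE_NAMES) - set(self.values)
            extra = set(self.values) - set(FEATURE_NAMES)
            raise ValueError(
                f"feature set must contain exactly the {N_FEATURES} manifest features "
                f"in order (missing {sorted(missing)[:3]}, extra {sorted(extra)[:3]})"
            )
        bad = [k for k, v in self.values.items() if not np.isfinite(v)]
        if bad:
            raise ValueError(f"non-finite feature values: {bad[:5]}")

    def __len__(self) -> int:
        return len(self.values)

    def to_series(self) -> pd.Series:
        return pd.Series(self.values, name=self.subject_id or None)

    def category_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for name in self.values:
            cat = FEATURE_CATEGORIES[name]
            out[cat] = out.get(cat, 0) + 1
        return out

    @staticmethod
    def manifest_json() -> str:
        return json.dumps(manifest_records(), indent=2)


def _canonical_extent(recon: LungReconstruction, coords: np.ndarray) -> np.ndarray:
    """Bounding-box extent per canonical axis: span of voxel centres plus
    the voxel footprint projected onto that axis (support function of the
    voxel box), exact for axis-aligned frames."""
    span = coords.max(axis=0) - coords.min(axis=0)
    foot = np.abs(recon.rotation) @ np.asarray(recon.spacing)
    return span + foot


def volumetric_features(recon: LungReconstruction, side: str) -> dict[str, float]:
    """19 volumetric features of one lung (volume, bounding box, centroid,
    inertia eigenvalues, equivalent-ellipsoid axes, elongation, equivalent
    diameter, extent fraction, per-axis second moments)."""
    coords = recon.canonical_coords(side)
    if coords.shape[0] == 0:
        raise ValueError(f"{side} lung is empty")
    volume = coords.shape[0] * recon.voxel_volume_mm3
    extent = _canonical_extent(recon, coords)
    centroid = coords.mean(axis=0)
    centered = coords - centroid
    cov = centered.T @ centered / coords.shape[0]  # second central moments, mm^2
    # inertia tensor per unit mass; for a solid ellipsoid its eigenvalues are
    # (b^2+c^2)/5 etc., so the equivalent semi-axes are sqrt(5 * cov eigenvalue)
    inertia = np.trace(cov) * np.eye(3) - cov
    inertia_evals = np.sort(np.linalg.eigvalsh(inertia))[::-1]
    cov_evals = np.sort(np.linalg.eigvalsh(cov))[::-1]
    cov_evals = np.maximum(cov_evals, 0.0)
    axes_lengths = 2.0 * np.sqrt(5.0 * cov_evals)  # major, intermediate, minor
    minor = max(axes_lengths[2], 1e-12)
    return {
        "vol_volume_mm3": volume,
        "vol_bbox_extent_ap_mm": float(extent[0]),
        "vol_bbox_extent_lr_mm": float(extent[1]),
        "vol_bbox_extent_cc_mm": float(extent[2]),
        "vol_centroid_ap_mm": float(centroid[0]),
        "vol_centroid_lr_mm": float(centroid[1]),
        "vol_centroid_cc_mm": float(centroid[2]),
        "vol_inertia_eig_major_mm2": float(inertia_evals[0]),
        "vol_inertia_eig_mid_mm2": float(inertia_evals[1]),
        "vol_inertia_eig_minor_mm2": float(inertia_evals[2]),
        "vol_axis_major_mm": float(axes_lengths[0]),
        "vol_axis_intermediate_mm": float(axes_lengths[1]),
        "vol_axis_minor_mm": float(axes_lengths[2]),
        "vol_elongation": float(axes_lengths[0] / minor),
        "vol_equiv_sphere_diameter_mm": float((6.0 * volume / np.pi) ** (1.0 / 3.0)),
        "vol_extent_fraction": float(volume / np.prod(extent)),
        "vol_moment2_ap_mm2": float(cov[0, 0]),
        "vol_moment2_lr_mm2": float(cov[1, 1]),
        "vol_moment2_cc_mm2": float(cov[2, 2]),
    }


def intensity_features(
    recon: LungReconstruction, side: str, n_entropy_bins: int = 64
) -> tuple[dict[str, float], list[str]]:
    """15 intensity features of one lung; returns (values, flags).

    Raw (unnormalised) intensities are used.  On a constant-intensity lung
    skewness and kurtosis are undefined; they are reported as 0 with a
    flag.  Intensity weights for the weighted centroid are clipped at 0
    (MR magnitudes are non-negative; noise may dip below).
    """
    vals = recon.side_intensities(side).astype(np.float64)
    coords = recon.canonical_coords(side)
    flags: list[str] = []
    std = float(vals.std())
    if std == 0.0:
        flags.append(f"{side}: constant intensity; skewness/kurtosis set to 0")
        skw, kur = 0.0, 0.0
        entropy = 0.0
    else:
        skw = float(skew(vals))
        kur = float(kurtosis(vals))  # excess kurtosis
        hist, _ = np.histogram(vals, bins=n_entropy_bins)
        p = hist[hist > 0] / vals.size
        entropy = float(-(p * np.log2(p)).sum())

    weights = np.clip(vals, 0.0, None)
    if weights.sum() == 0:
        weights = np.ones_like(vals)
        flags.append(f"{side}: non-positive intensities; uniform centroid weights")
    wcentroid = (weights[:, None] * coords).sum(axis=0) / weights.sum()
    centroid = coords.mean(axis=0)
    extent = _canonical_extent(recon, coords)

    return (
        {
            "int_mean": float(vals.mean()),
            "int_std": std,
            "int_median": float(np.median(vals)),
            "int_min": float(vals.min()),
            "int_max": float(vals.max()),
            "int_skewness": skw,
            "int_kurtosis": kur,
            "int_p10": float(np.percentile(vals, 10)),
            "int_p90": float(np.percentile(vals, 90)),
            "int_entropy": entropy,
            "int_wcentroid_ap_mm": float(wcentroid[0]),
            "int_wcentroid_lr_mm": float(wcentroid[1]),
            "int_wcentroid_cc_mm": float(wcentroid[2]),
            "int_ap_centroid_displacement": float((wcentroid[0] - centroid[0]) / extent[0]),
            "int_cc_centroid_displacement": float((wcentroid[2] - centroid[2]) / extent[2]),
        },
        flags,
    )


#: Gaussian pre-smoothing of the binary volume before surface extraction,
#: in voxel units.  Marching cubes on a raw {0,1} grid produces a staircase
#: mesh whose area overestimates a smooth surface by ~6-9 %; 0.8 voxels of
#: smoothing removes the staircase while leaving mm-scale surface structure
#: intact (sphere-area error < 1 % at a 1 mm grid).
SURFACE_SMOOTHING_VOXELS = 0.8


def surface_features(recon: LungReconstruction, side: str) -> dict[str, float]:
    """5 surface features of one lung from a spacing-aware marching-cubes
    mesh at iso-level 0.5 (area, area/volume, convex-hull area, roughness
    = mesh area / hull area, solidity = voxel volume / hull volume).

    The binary volume is lightly smoothed (``SURFACE_SMOOTHING_VOXELS``)
    before the iso-surface is taken, so the mesh tracks the underlying
    shape instead of the voxel staircase.  Roughness is floored at 1 and
    solidity capped at 1: both are ratio invariants that discretisation
    noise can cross by a fraction of a percent.
    """
    binary = (recon.labels == LABELS[side]).astype(np.float64)
    n_vox = int(binary.sum())
    if n_vox < 8:
        raise ValueError(
            f"{side} lung too small for a closed surface ({n_vox} voxel(s))"
        )
    padded = np.pad(binary, 2)  # guarantee a closed iso-surface at the borders
    smoothed = ndimage.gaussian_filter(padded, SURFACE_SMOOTHING_VOXELS)
    if smoothed.max() <= 0.5:  # lung thinner than the smoothing kernel
        smoothed = padded
    try:
        verts, faces, _, _ = marching_cubes(smoothed, level=0.5, spacing=recon.spacing)
    except (ValueError, RuntimeError) as exc:
        raise ValueError(f"degenerate mesh for {side} lung ({n_vox} voxels): {exc}") from exc
    area = float(mesh_surface_area(verts, faces))
    hull = ConvexHull(verts)
    volume = n_vox * recon.voxel_volume_mm3
    return {
        "surf_area_mm2": area,
        "surf_area_to_volume_mm1": area / volume,
        "surf_hull_area_mm2": float(hull.area),
        "surf_roughness": max(area / float(hull.area), 1.0),
        "surf_solidity": min(volume / float(hull.volume), 1.0),
    }


def extract_features(recon: LungReconstruction, subject_id: str = "") -> LungFeatureSet:
    """All 78 features (left block then right; volumetric, intensity,
    surface within each block), with units and category tags from the
    frozen manifest."""
    values: dict[str, float] = {}
    flags: list[str] = []
    for side in ("left", "right"):
        try:
            per_lung = dict(volumetric_features(recon, side))
            ints, f = intensity_features(recon, side)
            per_lung.update(ints)
            per_lung.update(surface_features(recon, side))
            flags.extend(f)
        except Exception as exc:
            raise type(exc)(f"{side} lung: {exc}") from exc
        for name, v in per_lung.items():
            values[f"{side}_{name}"] = v
    ordered = {name: values[name] for name in FEATURE_NAMES}
    return LungFeatureSet(values=ordered, subject_id=subject_id, flags=flags)


def features_to_frame(feature_sets: list[LungFeatureSet]) -> pd.DataFrame:
    """One row per subject, 78 feature columns in manifest order."""
    rows = [fs.to_series() for fs in feature_sets]
    frame = pd.DataFrame(rows)
    frame.index.name = "subject_id"
    return frame


__all__ = [
    "LungFeatureSet",
    "volumetric_features",
    "intensity_features",
    "surface_features",
    "extract_features",
    "features_to_frame",
    "FEATURE_NAMES",
    "FEATURE_CATEGORIES",
    "FEATURE_UNITS",
    "CATEGORY_COUNTS",
]
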