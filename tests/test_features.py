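"""The 78-feature contract, geometric oracles, symmetry and monotonicity."""

import hashlib

import numpy as np
import pytest

from neolung.core import MaskStack, MriVolume
from neolung.features import (
    extract_features,
    features_to_frame,
    intensity_features,
    surface_features,
    volumetric_features,
)
from neolung.manifest import CATEGORY_COUNTS, FEATURE_CATEGORIES, FEATURE_NAMES
from neolung.phantom import PhantomSpec, generate_phantom
from neolung.reconstruction import LungReconstruction, reconstruct


@pytest.fixture(scope="module")
def sphere_recon(sphere_phantom):
    _, vol, mask, _ = sphere_phantom
    return reconstruct(mask, intensities=vol)


@pytest.fixture(scope="module")
def ellipsoid_recon(ellipsoid_phantom):
    _, vol, mask, _ = ellipsoid_phantom
    return reconstruct(mask, intensities=vol)


class TestContract:
    def test_exactly_78_features_partitioned_38_30_10(self, sphere_recon):
        fs = extract_features(sphere_recon)
        assert len(fs) == 78
        assert fs.category_counts() == {"volumetric": 38, "intensity": 30, "surface": 10}
        assert CATEGORY_COUNTS == {"volumetric": 38, "intensity": 30, "surface": 10}

    def test_feature_roster_is_frozen(self):
        # regression guard: renaming or reordering features is a contract break
        digest = hashlib.sha256("\n".join(FEATURE_NAMES).encode()).hexdigest()
        assert digest == "531b47ee00c3e6e8a0d709b774851897ab7cbd68f0d73bad984b007cd35b831c"

    def test_all_values_finite_and_ordered(self, ellipsoid_recon):
        fs = extract_features(ellipsoid_recon)
        assert list(fs.values) == FEATURE_NAMES
        assert all(np.isfinite(v) for v in fs.values.values())

    def test_frame_round_trip(self, sphere_recon, ellipsoid_recon):
        frame = features_to_frame(
            [extract_features(sphere_recon, "a"), extract_features(ellipsoid_recon, "b")]
        )
        assert frame.shape == (2, 78)
        assert list(frame.columns) == FEATURE_NAMES


class TestVolumetric:
    def test_ellipsoid_elongation_is_two(self, ellipsoid_recon):
        for side in ("left", "right"):
            feats = volumetric_features(ellipsoid_recon, side)
            assert feats["vol_elongation"] == pytest.approx(2.0, rel=0.02)
            assert feats["vol_axis_major_mm"] == pytest.approx(60.0, rel=0.02)
            assert feats["vol_axis_minor_mm"] == pytest.approx(30.0, rel=0.02)

    def test_sphere_is_isotropic(self, sphere_recon):
        feats = volumetric_features(sphere_recon, "left")
        assert feats["vol_elongation"] == pytest.approx(1.0, abs=0.02)
        eigs = [feats[f"vol_inertia_eig_{k}_mm2"] for k in ("major", "mid", "minor")]
        assert max(eigs) == pytest.approx(min(eigs), rel=0.02)
        # closed-form sphere inertia per unit mass: 2/5 r^2
        assert eigs[0] == pytest.approx(0.4 * 20**2, rel=0.02)

    def test_extent_fraction_matches_ellipsoid_ratio(self, ellipsoid_recon):
        feats = volumetric_features(ellipsoid_recon, "left")
        assert feats["vol_extent_fraction"] == pytest.approx(np.pi / 6, rel=0.02)

    def test_second_moments_match_ellipsoid_closed_form(self, ellipsoid_recon):
        # coordinate variance of a solid ellipsoid along semi-axis a is a^2/5
        feats = volumetric_features(ellipsoid_recon, "left")
        assert feats["vol_moment2_ap_mm2"] == pytest.approx(15**2 / 5, rel=0.02)
        assert feats["vol_moment2_cc_mm2"] == pytest.approx(30**2 / 5, rel=0.02)

    def test_empty_lung_rejected(self):
        labels = np.zeros((6, 6, 6), dtype=np.uint8)
        labels[1:4, 1:4, 1:4] = 1
        recon = LungReconstruction(labels=labels, spacing=(1, 1, 1))
        with pytest.raises(ValueError, match="empty"):
            volumetric_features(recon, "right")


def _gradient_recon(slope: float):
    spec = PhantomSpec(
        grid_shape=(80, 110, 40),
        spacing=(1.5, 1.5, 2.0),
        noise_sd=0.0,
        blur_sigma_mm=0.0,
        ap_gradient_slope=slope,
        seed=11,
    )
    vol, mask, _ = generate_phantom(spec)
    return reconstruct(mask, intensities=vol)


class TestIntensity:
    def test_homogeneous_lung_has_zero_ap_displacement(self):
        recon = _gradient_recon(0.0)
        for side in ("left", "right"):
            feats, flags = intensity_features(recon, side)
            assert feats["int_ap_centroid_displacement"] == pytest.approx(0.0, abs=1e-9)
            assert feats["int_skewness"] == 0.0
            assert any("constant" in f for f in flags)

    def test_ap_displacement_increases_with_gradient_slope(self):
        values = []
        for slope in (0.2, 0.5, 1.0):
            feats, _ = intensity_features(_gradient_recon(slope), "left")
            values.append(feats["int_ap_centroid_displacement"])
        assert values[0] > 0
        assert values[0] < values[1] < values[2]

    def test_descriptive_statistics_on_known_distribution(self, sphere_phantom):
        spec, vol, mask, _ = sphere_phantom
        recon = reconstruct(mask, intensities=vol)
        feats, _ = intensity_features(recon, "left")
        assert feats["int_mean"] == pytest.approx(spec.lung_intensity)
        assert feats["int_std"] == 0.0
        assert feats["int_min"] == feats["int_max"] == spec.lung_intensity

    def test_weighted_centroid_matches_geometric_for_flat_intensity(self, sphere_recon):
        feats, _ = intensity_features(sphere_recon, "left")
        vols = volumetric_features(sphere_recon, "left")
        for ax in ("ap", "lr", "cc"):
            assert feats[f"int_wcentroid_{ax}_mm"] == pytest.approx(
                vols[f"vol_centroid_{ax}_mm"], abs=1e-9
            )


class TestSurface:
    def test_sphere_area_within_three_percent(self, sphere_recon):
        feats = surface_features(sphere_recon, "left")
        assert feats["surf_area_mm2"] == pytest.approx(4 * np.pi * 20**2, rel=0.03)

    def test_convex_shape_roughness_and_solidity(self, sphere_recon, ellipsoid_recon):
        for recon in (sphere_recon, ellipsoid_recon):
            for side in ("left", "right"):
                feats = surface_features(recon, side)
                assert 1.0 <= feats["surf_roughness"] <= 1.05
                assert 0.98 <= feats["surf_solidity"] <= 1.0

    def test_surface_to_volume_consistency(self, sphere_recon):
        feats = surface_features(sphere_recon, "left")
        vols = volumetric_features(sphere_recon, "left")
        assert feats["surf_area_to_volume_mm1"] == pytest.approx(
            feats["surf_area_mm2"] / vols["vol_volume_mm3"]
        )

    def test_tiny_lung_raises_with_voxel_count(self):
        labels = np.zeros((6, 6, 6), dtype=np.uint8)
        labels[2, 2, 2] = 1
        labels[1:5, 1:5, 1:5] = 0
        labels[2, 2, 2] = 1
        labels[3, 3, 3] = 2
        recon = LungReconstruction(labels=labels, spacing=(1, 1, 1))
        with pytest.raises(ValueError, match="voxel"):
            surface_features(recon, "left")


def _perturbed_features(amplitude: float):
    spec = PhantomSpec(
        grid_shape=(90, 130, 90),
        spacing=(1, 1, 1),
        left_semi_axes=(20, 16, 28),
        right_semi_axes=(20, 16, 28),
        left_center=(45, 32, 45),
        right_center=(45, 98, 45),
        noise_sd=0.0,
        blur_sigma_mm=0.0,
        surface_perturbation_amplitude=amplitude,
        seed=21,
    )
    _, mask, _ = generate_phantom(spec)
    return surface_features(reconstruct(mask), "left")


class TestInvariances:
    def test_surface_perturbation_monotone_roughness_and_solidity(self):
        rough, solid = [], []
        for amp in (0.0, 2.0, 4.0):
            feats = _perturbed_features(amp)
            rough.append(feats["surf_roughness"])
            solid.append(feats["surf_solidity"])
        assert rough[0] < rough[1] < rough[2]
        assert solid[0] > solid[1] > solid[2]

    def test_isotropic_scaling_laws(self):
        def build(scale):
            spec = PhantomSpec(
                grid_shape=(72, 104, 72),
                spacing=(scale, scale, scale),
                left_semi_axes=(20 * scale, 15 * scale, 25 * scale),
                right_semi_axes=(18 * scale, 14 * scale, 24 * scale),
                left_center=(36 * scale, 26 * scale, 36 * scale),
                right_center=(36 * scale, 78 * scale, 36 * scale),
                noise_sd=0.0,
                blur_sigma_mm=0.0,
                seed=5,
            )
            vol, mask, _ = generate_phantom(spec)
            return extract_features(reconstruct(mask, intensities=vol))

        base = build(1.0).values
        scaled = build(2.0).values
        s = 2.0
        assert scaled["left_vol_volume_mm3"] == pytest.approx(base["left_vol_volume_mm3"] * s**3, rel=0.03)
        assert scaled["left_surf_area_mm2"] == pytest.approx(base["left_surf_area_mm2"] * s**2, rel=0.03)
        assert scaled["left_vol_axis_major_mm"] == pytest.approx(base["left_vol_axis_major_mm"] * s, rel=0.03)
        for ratio in ("left_vol_elongation", "left_surf_roughness", "left_surf_solidity", "left_vol_extent_fraction"):
            assert scaled[ratio] == pytest.approx(base[ratio], rel=0.03)

    def test_mirroring_swaps_left_right_blocks(self, sphere_phantom):
        _, vol, mask, _ = sphere_phantom
        fs = extract_features(reconstruct(mask, intensities=vol))
        mirrored_mask = MaskStack(mask.values[:, ::-1, :], mask.spacing)
        mirrored_vol = MriVolume(vol.intensities[:, ::-1, :], vol.spacing)
        fm = extract_features(reconstruct(mirrored_mask, intensities=mirrored_vol))
        swap_invariant = [
            "vol_volume_mm3",
            "vol_elongation",
            "vol_equiv_sphere_diameter_mm",
            "surf_area_mm2",
            "surf_roughness",
            "surf_solidity",
            "int_mean",
            "int_entropy",
            "int_ap_centroid_displacement",
        ]
        for name in swap_invariant:
            assert fm.values[f"left_{name}"] == pytest.approx(
                fs.values[f"right_{name}"], rel=1e-6, abs=1e-9
            )
            assert fm.values[f"right_{name}"] == pytest.approx(
                fs.values[f"left_{name}"], rel=1e-6, abs=1e-9
            )

    def test_translation_changes_only_centroids(self, sphere_phantom):
        _, vol, mask, _ = sphere_phantom
        fs = extract_features(reconstruct(mask, intensities=vol))
        # pad 6 voxels at the AP front: whole scene translates by +6 mm AP
        pad = ((6, 0), (0, 0), (0, 0))
        shifted_mask = MaskStack(np.pad(mask.values, pad), mask.spacing)
        shifted_vol = MriVolume(np.pad(vol.intensities, pad), vol.spacing)
        ft = extract_features(reconstruct(shifted_mask, intensities=shifted_vol))
        # centroids are measured in the lung-centred canonical frame, so
        # every feature is translation-invariant
        for name in FEATURE_NAMES:
            assert ft.values[name] == pytest.approx(fs.values[name], rel=1e-6, abs=1e-8)
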