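"""Synthetic MRI-like phantoms with analytic ground truth.

The phantom emulates a neonatal chest acquisition: a torso-like ellipsoid
of bright tissue containing two darker, roughly ellipsoidal lungs, sampled
on an anisotropic grid (defaults: 1.3 x 1.9 mm in plane, 4.4 mm slice
pitch).  Optional knobs add Gaussian noise, in-plane blur, an
anteroposterior intensity gradient inside the lungs (a ventilation-
inhomogeneity surrogate), and a seeded spherical-harmonic surface
perturbation (a roughness surrogate).  Because the lungs are analytic
ellipsoids, volume, centroid and (smooth case) surface area have closed
forms that downstream modules are tested against.

The module also generates synthetic cohorts: per-subject clinical
covariates, a four-grade severity label, overdispersed respiratory-support
day counts, and a 78-feature vector with optional planted per-grade mean
shifts.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.special import sph_harm_y

from .core import DEFAULT_SPACING, MaskStack, MriVolume, voxel_centers_mm
from .manifest import FEATURE_NAMES

#: Knud Thomsen's exponent for the approximate ellipsoid surface area;
#: the approximation's worst-case relative error is 1.06 %.
KNUD_THOMSEN_P = 1.6075
KNUD_THOMSEN_REL_ERROR = 0.0106

SEVERITY_LABELS = ("none", "mild", "moderate", "severe")


def ellipsoid_volume(semi_axes) -> float:
    """Closed-form ellipsoid volume 4/3 * pi * a * b * c (mm^3)."""
    a, b, c = (float(x) for x in semi_axes)
    return 4.0 / 3.0 * np.pi * a * b * c


def ellipsoid_surface_area(semi_axes, p: float = KNUD_THOMSEN_P) -> float:
    """Approximate ellipsoid surface area (mm^2), Knud Thomsen's formula.

    ``S ~ 4*pi*((a^p b^p + a^p c^p + b^p c^p)/3)^(1/p)`` with p = 1.6075;
    relative error is at most 1.06 % over all axis ratios, and zero for a
    sphere.
    """
    a, b, c = (float(x) for x in semi_axes)
    return 4.0 * np.pi * (((a * b) ** p + (a * c) ** p + (b * c) ** p) / 3.0) ** (1.0 / p)


@dataclass
class PhantomSpec:
    """Geometry and signal parameters of a two-lung phantom.

    All lengths are millimetres in ``(AP, LR, CC)`` order; intensities are
    arbitrary units.  ``seed`` fully determines the generated volume.
    """

    grid_shape: tuple[int, int, int] = (96, 80, 28)
    spacing: tuple[float, float, float] = DEFAULT_SPACING
    left_semi_axes: tuple[float, float, float] = (22.0, 14.0, 34.0)
    right_semi_axes: tuple[float, float, float] = (24.0, 16.0, 36.0)
    left_center: tuple[float, float, float] | None = None
    right_center: tuple[float, float, float] | None = None
    lung_intensity: float = 40.0
    background_intensity: float = 120.0
    noise_sd: float = 4.0
    blur_sigma_mm: float = 1.0
    ap_gradient_slope: float = 0.0
    surface_perturbation_amplitude: float = 0.0
    seed: int = 0

    def __post_init__(self):
        self.grid_shape = tuple(int(n) for n in self.grid_shape)
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(n < 4 for n in self.grid_shape):
            raise ValueError("grid_shape axes must each have at least 4 voxels")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be strictly positive")
        for name in ("left_semi_axes", "right_semi_axes"):
            axes = tuple(float(x) for x in getattr(self, name))
            if any(a <= 0 for a in axes):
                raise ValueError(f"{name} must be strictly positive")
            setattr(self, name, axes)
        if self.noise_sd < 0 or self.blur_sigma_mm < 0:
            raise ValueError("noise_sd and blur_sigma_mm must be non-negative")
        if self.surface_perturbation_amplitude < 0:
            raise ValueError("surface_perturbation_amplitude must be non-negative")
        extent = self.extent_mm
        if self.left_center is None:
            self.left_center = (extent[0] / 2, extent[1] * 0.27, extent[2] / 2)
        if self.right_center is None:
            self.right_center = (extent[0] / 2, extent[1] * 0.73, extent[2] / 2)
        self.left_center = tuple(float(x) for x in self.left_center)
        self.right_center = tuple(float(x) for x in self.right_center)
        self._check_fits("left", self.left_center, self.left_semi_axes)
        self._check_fits("right", self.right_center, self.right_semi_axes)

    @property
    def extent_mm(self) -> tuple[float, float, float]:
        return tuple(n * s for n, s in zip(self.grid_shape, self.spacing))

    def _check_fits(self, side, center, semi_axes):
        """Each lung must fit inside the grid with a >= 2-voxel margin."""
        pad = self.surface_perturbation_amplitude
        for ax, (c, a, n, s, label) in enumerate(
            zip(center, semi_axes, self.grid_shape, self.spacing, ("AP", "LR", "CC"))
        ):
            lo, hi = c - a - pad, c + a + pad
            if lo < 2 * s or hi > (n - 2) * s:
                raise ValueError(
                    f"{side} lung exceeds the grid along the {label} axis: "
                    f"occupies [{lo:.1f}, {hi:.1f}] mm of [{2 * s:.1f}, {(n - 2) * s:.1f}] mm"
                )

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "PhantomSpec":
        return cls(**json.loads(text))


@dataclass
class AnalyticTruth:
    """Closed-form geometry of the smooth phantom lungs."""

    lungs: dict  # side -> {volume_mm3, surface_area_mm2, centroid_mm, semi_axes_mm}
    surface_area_rel_error_bound: float = KNUD_THOMSEN_REL_ERROR
    surface_area_formula: str = (
        "4*pi*((a^p*b^p + a^p*c^p + b^p*c^p)/3)^(1/p), p=1.6075"
    )
    perturbed: bool = False

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2)


#: spherical-harmonic degrees of the surface perturbation.  Wavelengths
#: must be short relative to the lung for the hull-based roughness ratio
#: to respond: very low degrees merely change the overall shape, which the
#: convex hull follows.
PERTURBATION_DEGREES = (8, 12, 16)


def _radial_perturbation(direction, amplitude_mm, mean_radius_mm, rng):
    """Seeded spherical-harmonic radial modulation of the unit radius.

    Returns a multiplicative factor field ``1 + amplitude/mean_radius * f``
    where ``f`` combines real harmonics of the degrees in
    :data:`PERTURBATION_DEGREES`, normalised to unit maximum so the radial
    displacement never exceeds ``amplitude_mm``.
    """
    x, y, z = direction
    r = np.sqrt(x * x + y * y + z * z)
    r = np.where(r == 0, 1.0, r)
    theta = np.arccos(np.clip(z / r, -1.0, 1.0))
    phi = np.arctan2(y, x)
    f = np.zeros_like(theta)
    for ell in PERTURBATION_DEGREES:
        for m in range(-ell, ell + 1):
            coeff = rng.normal()
            harm = sph_harm_y(ell, abs(m), theta, phi)
            f += coeff * (harm.real if m >= 0 else harm.imag)
    peak = np.max(np.abs(f))
    if peak > 0:
        f = f / peak
    return 1.0 + (amplitude_mm / mean_radius_mm) * f


def _lung_mask(spec: PhantomSpec, side: str, rng) -> np.ndarray:
    center = spec.left_center if side == "left" else spec.right_center
    semi = spec.left_semi_axes if side == "left" else spec.right_semi_axes
    ap, lr, cc = voxel_centers_mm(spec.grid_shape, spec.spacing)
    dx = (ap - center[0])[:, None, None]
    dy = (lr - center[1])[None, :, None]
    dz = (cc - center[2])[None, None, :]
    rho = np.sqrt((dx / semi[0]) ** 2 + (dy / semi[1]) ** 2 + (dz / semi[2]) ** 2)
    if spec.surface_perturbation_amplitude <= 0:
        return rho <= 1.0
    # evaluate the (expensive) harmonics only on the shell the perturbation
    # can reach; the deep interior/exterior is decided by rho alone
    reach = spec.surface_perturbation_amplitude / float(min(semi)) + 1e-9
    shell = np.abs(rho - 1.0) <= reach
    mask = rho < 1.0 - reach
    direction = (
        np.broadcast_to(dx / semi[0], rho.shape)[shell],
        np.broadcast_to(dy / semi[1], rho.shape)[shell],
        np.broadcast_to(dz / semi[2], rho.shape)[shell],
    )
    factor = _radial_perturbation(
        direction,
        spec.surface_perturbation_amplitude,
        float(np.mean(semi)),
        rng,
    )
    mask[shell] = rho[shell] <= factor
    return mask


def generate_phantom(spec: PhantomSpec) -> tuple[MriVolume, MaskStack, AnalyticTruth]:
    """Generate the intensity volume, exact lung mask and analytic truth.

    The mask is the exact voxelisation of the (possibly perturbed)
    ellipsoids; the analytic truth always refers to the *smooth* ellipsoids
    and is flagged ``perturbed`` when a surface perturbation was applied.
    """
    rng = np.random.default_rng(spec.seed)
    left = _lung_mask(spec, "left", rng)
    right = _lung_mask(spec, "right", rng)
    lungs = left | right

    # torso: bright ellipsoid enclosing both lungs
    extent = spec.extent_mm
    ap, lr, cc = voxel_centers_mm(spec.grid_shape, spec.spacing)
    tc = tuple(e / 2 for e in extent)
    tsemi = (extent[0] * 0.47, extent[1] * 0.47, extent[2] * 0.55)
    torso = (
        ((ap - tc[0])[:, None, None] / tsemi[0]) ** 2
        + ((lr - tc[1])[None, :, None] / tsemi[1]) ** 2
        + ((cc - tc[2])[None, None, :] / tsemi[2]) ** 2
    ) <= 1.0

    img = np.zeros(spec.grid_shape, dtype=np.float64)
    img[torso] = spec.background_intensity
    img[lungs] = spec.lung_intensity
    if spec.ap_gradient_slope != 0.0:
        # posterior (larger AP coordinate) gets brighter for positive slope,
        # emulating gravity-dependent signal in supine position
        ap_off = (ap - (spec.left_center[0] + spec.right_center[0]) / 2)[:, None, None]
        img[lungs] += (spec.ap_gradient_slope * np.broadcast_to(ap_off, img.shape))[lungs]
    if spec.blur_sigma_mm > 0:
        img = ndimage.gaussian_filter(
            img, sigma=[spec.blur_sigma_mm / s for s in spec.spacing]
        )
    if spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd, size=img.shape)

    volume = MriVolume(img, spec.spacing, subject_id=f"phantom-{spec.seed}")
    mask = MaskStack(lungs.astype(np.uint8), spec.spacing, rater_id="truth")
    truth = AnalyticTruth(
        lungs={
            side: {
                "volume_mm3": ellipsoid_volume(semi),
                "surface_area_mm2": ellipsoid_surface_area(semi),
                "centroid_mm": list(center),
                "semi_axes_mm": list(semi),
            }
            for side, center, semi in (
                ("left", spec.left_center, spec.left_semi_axes),
                ("right", spec.right_center, spec.right_semi_axes),
            )
        },
        perturbed=spec.surface_perturbation_amplitude > 0,
    )
    return volume, mask, truth


def random_phantom_spec(
    seed: int,
    grid_shape: tuple[int, int, int] = (48, 48, 12),
    spacing: tuple[float, float, float] = (2.5, 2.5, 4.4),
    size_jitter: float = 0.15,
    center_jitter_mm: float = 4.0,
    **overrides,
) -> PhantomSpec:
    """A per-subject phantom with randomised lung geometry.

    Lung semi-axes vary by ``+/- size_jitter`` (fractional) and centres by
    ``+/- center_jitter_mm`` around anatomically plausible defaults, so a
    cohort of these phantoms exercises actual segmentation rather than
    template matching.  The geometry draw is separate from the intensity
    noise draw, both controlled by ``seed``.
    """
    rng = np.random.default_rng(seed + 10_000)
    extent = np.array([n * s for n, s in zip(grid_shape, spacing)])
    spacing_arr = np.asarray(spacing, dtype=float)
    base_left = np.array([0.20 * extent[0], 0.13 * extent[1], 0.24 * extent[2]])
    base_right = np.array([0.22 * extent[0], 0.15 * extent[1], 0.26 * extent[2]])
    # CC slack is scarce (few thick sections), so jitter the slice axis least
    jitter_axis = center_jitter_mm * np.array([1.0, 1.0, 0.25])
    # cap semi-axes so size + centre jitter always fit the 2-voxel margin
    max_semi = (extent / 2 - 2 * spacing_arr - jitter_axis) / (1 + size_jitter) * 0.98
    # LR centres sit at 0.27/0.73 of the extent: the cap is set by the
    # nearer edge and by the two lungs never touching
    max_semi[1] = min(
        (0.27 * extent[1] - 2 * spacing_arr[1] - jitter_axis[1]) / (1 + size_jitter) * 0.98,
        0.46 * extent[1] / 2 / (1 + size_jitter) * 0.9,
    )
    base_left = np.minimum(base_left, max_semi)
    base_right = np.minimum(base_right, max_semi)
    jit = lambda base: tuple(base * (1 + rng.uniform(-size_jitter, size_jitter, 3)))
    off = lambda: rng.uniform(-1.0, 1.0, 3) * jitter_axis
    left_c = np.array([extent[0] / 2, 0.27 * extent[1], extent[2] / 2]) + off()
    right_c = np.array([extent[0] / 2, 0.73 * extent[1], extent[2] / 2]) + off()
    params = dict(
        grid_shape=grid_shape,
        spacing=spacing,
        left_semi_axes=jit(base_left),
        right_semi_axes=jit(base_right),
        left_center=tuple(left_c),
        right_center=tuple(right_c),
        noise_sd=6.0,
        blur_sigma_mm=1.0,
        seed=seed,
    )
    params.update(overrides)
    return PhantomSpec(**params)


def simulate_raters(
    mask: MaskStack, n_raters: int, boundary_jitter_mm: float, seed: int
) -> list[MaskStack]:
    """Simulate independent human raters by jittering the mask boundary.

    Each rater's mask is the original surface displaced by a smooth, seeded
    Gaussian random field with RMS amplitude ``boundary_jitter_mm`` (mm):
    the rater includes voxel x iff ``signed_distance(x) < field(x)``, which
    randomly dilates and erodes boundary bands while leaving the deep
    interior and far exterior untouched.  Zero jitter returns exact copies.
    """
    if n_raters < 1:
        raise ValueError("n_raters must be >= 1")
    if boundary_jitter_mm < 0:
        raise ValueError("boundary_jitter_mm must be >= 0")
    vals = mask.values.astype(bool)
    if not vals.any():
        raise ValueError("cannot simulate raters on an empty mask")

    inside = ndimage.distance_transform_edt(vals, sampling=mask.spacing)
    outside = ndimage.distance_transform_edt(~vals, sampling=mask.spacing)
    signed = outside - inside  # < 0 strictly inside, > 0 strictly outside

    rng = np.random.default_rng(seed)
    raters = []
    for i in range(n_raters):
        if boundary_jitter_mm == 0:
            jittered = vals.copy()
        else:
            noise = rng.normal(size=vals.shape)
            # ~8 mm correlation length: plausible scale of human boundary disagreement
            field_ = ndimage.gaussian_filter(noise, sigma=[8.0 / s for s in mask.spacing])
            sd = field_.std()
            if sd > 0:
                field_ = field_ / sd * boundary_jitter_mm
            jittered = signed < field_
            if not jittered.any():
                jittered = vals.copy()
        raters.append(
            MaskStack(jittered.astype(np.uint8), mask.spacing, rater_id=f"rater-{i + 1}")
        )
    return raters


@dataclass
class CohortSpec:
    """Parameters of a synthetic study cohort.

    ``effect_sizes`` maps feature names (see the feature manifest) to a
    standardised mean shift per severity-grade step; features not listed
    are pure noise, so an empty mapping yields labels independent of all
    lung features.
    """

    n_subjects: int = 200
    class_proportions: tuple[float, float, float, float] = (0.35, 0.30, 0.15, 0.20)
    effect_sizes: dict[str, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        props = tuple(float(p) for p in self.class_proportions)
        if len(props) != 4 or any(p < 0 for p in props):
            raise ValueError("class_proportions must be 4 non-negative fractions")
        if abs(sum(props) - 1.0) > 1e-9:
            raise ValueError(f"class_proportions must sum to 1, got {sum(props)}")
        self.class_proportions = props
        unknown = set(self.effect_sizes) - set(FEATURE_NAMES)
        if unknown:
            raise ValueError(f"effect_sizes name unknown features: {sorted(unknown)[:5]}")


def _negative_binomial(rng, mean, dispersion, size):
    """NB draws parameterised by mean and dispersion k (variance = m + m^2/k)."""
    mean = np.asarray(mean, dtype=float)
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p, size=size)


P_COLUMNS = ("gestational_age_wk", "birth_weight_g", "body_size_cm", "sex")
C_COLUMNS = ("apgar5", "early_onset_infection", "steroid_treatment")
INDICATOR_COLUMNS = ("ventilation_days", "oxygen_days")


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Generate the per-subject cohort table.

    Columns: ``subject_id``, severity ``grade`` (label and 0-3 code),
    patient attributes (gestational age, birth weight, body size, sex),
    postnatal adaptation variables (5-minute Apgar, early-onset infection,
    steroid treatment), two overdispersed respiratory-support day counts,
    and the 78 lung features with planted per-grade mean shifts.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_subjects
    grade = rng.choice(4, size=n, p=spec.class_proportions)

    # patient attributes: lower gestational age / weight with higher grade
    ga = np.clip(rng.normal(27.5 - 0.9 * grade, 1.8), 22.0, 34.0)
    bw = np.clip(rng.normal(600 + 170 * (ga - 24.0), 120), 300, 2500)
    size_cm = np.clip(rng.normal(30 + 1.1 * (ga - 24.0), 1.5), 24, 45)
    sex = rng.integers(0, 2, size=n)

    # postnatal adaptation
    apgar5 = np.clip(np.round(rng.normal(8.0 - 0.5 * grade, 1.4)), 0, 10).astype(int)
    infection = (rng.random(n) < 0.08 + 0.08 * grade).astype(int)
    steroids = (rng.random(n) < 0.05 + 0.15 * grade).astype(int)

    # respiratory support: overdispersed day counts, grade-dependent means
    vent_mean = np.array([1.5, 6.0, 18.0, 45.0])[grade]
    oxy_mean = np.array([3.0, 12.0, 35.0, 75.0])[grade]
    vent = _negative_binomial(rng, vent_mean, dispersion=2.0, size=n)
    oxy = _negative_binomial(rng, oxy_mean, dispersion=2.0, size=n)

    features = rng.normal(size=(n, len(FEATURE_NAMES)))
    for j, name in enumerate(FEATURE_NAMES):
        shift = spec.effect_sizes.get(name, 0.0)
        if shift:
            features[:, j] += shift * grade

    table = pd.DataFrame(
        {
            "subject_id": [f"S{i:04d}" for i in range(n)],
            "grade": grade,
            "severity": [SEVERITY_LABELS[g] for g in grade],
            "gestational_age_wk": ga,
            "birth_weight_g": bw,
            "body_size_cm": size_cm,
            "sex": sex,
            "apgar5": apgar5,
            "early_onset_infection": infection,
            "steroid_treatment": steroids,
            "ventilation_days": vent,
            "oxygen_days": oxy,
        }
    )
    table[FEATURE_NAMES] = features
    return table
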