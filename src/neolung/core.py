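"""Core containers and axis conventions.

Every 3D array in this package is indexed ``(AP, LR, CC)``:

* axis 0 — anteroposterior (front-to-back),
* axis 1 — left-right (radiological convention: the subject's left lung
  sits at *smaller* LR world coordinate),
* axis 2 — craniocaudal (head-to-foot); this is the slice axis of an
  axial multisection acquisition, so its spacing is the slice *pitch*
  (section thickness + inter-section gap).

World coordinates are ``index * spacing`` in millimetres, origin at the
corner of voxel (0, 0, 0); voxel centres sit at ``(index + 0.5) * spacing``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

AXIS_LABELS = ("AP", "LR", "CC")

#: in-plane resolution and slice pitch of the emulated acquisition, mm
DEFAULT_SPACING = (1.3, 1.9, 4.4)

SLICE_THICKNESS_MM = 4.0
SLICE_GAP_MM = 0.4


def _check_spacing(spacing) -> tuple[float, float, float]:
    spacing = tuple(float(s) for s in spacing)
    if len(spacing) != 3 or any(s <= 0 for s in spacing):
        raise ValueError(f"spacing must be 3 strictly positive values, got {spacing}")
    return spacing


@dataclass
class MriVolume:
    """A 3D intensity volume with physical spacing and semantic axes."""

    intensities: np.ndarray
    spacing: tuple[float, float, float]
    axis_labels: tuple[str, str, str] = AXIS_LABELS
    subject_id: str = ""

    def __post_init__(self):
        self.intensities = np.asarray(self.intensities, dtype=np.float64)
        if self.intensities.ndim != 3:
            raise ValueError("intensities must be a 3D array")
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("intensities contain NaN or Inf")
        self.spacing = _check_spacing(self.spacing)
        self.axis_labels = tuple(self.axis_labels)
        if self.axis_labels != AXIS_LABELS:
            raise ValueError(f"axis labels must be {AXIS_LABELS}, got {self.axis_labels}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensities.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def with_intensities(self, arr: np.ndarray) -> "MriVolume":
        return replace(self, intensities=np.asarray(arr, dtype=np.float64))


@dataclass
class MaskStack:
    """A binary (or probabilistic) mask congruent with an :class:`MriVolume`."""

    values: np.ndarray
    spacing: tuple[float, float, float]
    rater_id: str = ""
    binary: bool = True

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError("mask must be a 3D array")
        self.spacing = _check_spacing(self.spacing)
        vals = self.values
        if not np.all(np.isfinite(vals.astype(np.float64))):
            raise ValueError("mask contains NaN or Inf")
        if self.binary:
            uniq = np.unique(vals)
            if not np.all(np.isin(uniq, (0, 1))):
                raise ValueError(f"binary mask contains values outside {{0,1}}: {uniq[:10]}")
            self.values = vals.astype(np.uint8)
        else:
            vals = vals.astype(np.float64)
            if vals.min() < 0 or vals.max() > 1:
                raise ValueError("probabilistic mask values must lie in [0, 1]")
            self.values = vals

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def volume_mm3(self) -> float:
        """Physical volume of the foreground, voxel count x voxel volume."""
        return float(self.values.sum() * np.prod(self.spacing))

    def check_congruent(self, other) -> None:
        if self.shape != other.shape:
            raise ValueError(f"shape mismatch: {self.shape} vs {other.shape}")
        if not np.allclose(self.spacing, other.spacing):
            raise ValueError(f"spacing mismatch: {self.spacing} vs {other.spacing}")


def voxel_centers_mm(shape, spacing) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """World coordinates (mm) of voxel centres along each axis."""
    return tuple(
        (np.arange(n, dtype=np.float64) + 0.5) * s for n, s in zip(shape, spacing)
    )
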