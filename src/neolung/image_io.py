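"""NIfTI reading/writing, cropping and model-input normalisation.

Volumes and masks travel as NIfTI with the voxel spacing in the header
(zooms).  The crop applied before model training is recorded as a
:class:`CropWindow` so masks can be cropped congruently and the operation
is reversible in provenance.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage

from .core import MaskStack, MriVolume


@dataclass(frozen=True)
class CropWindow:
    """An in-plane crop/pad window shared by all slices of one subject.

    ``offset`` is the (AP, LR) index of the window origin in the source
    array; negative offsets mean the source was zero-padded.
    """

    offset: tuple[int, int]
    side: int

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self))

    @classmethod
    def from_json(cls, text: str) -> "CropWindow":
        d = json.loads(text)
        return cls(offset=tuple(d["offset"]), side=int(d["side"]))


def _apply_window(arr: np.ndarray, window: CropWindow) -> np.ndarray:
    """Crop/pad the first two axes of a 3D array to ``side x side``."""
    side = window.side
    out = np.zeros((side, side, arr.shape[2]), dtype=arr.dtype)
    src_lo = [max(o, 0) for o in window.offset]
    src_hi = [min(o + side, n) for o, n in zip(window.offset, arr.shape[:2])]
    dst_lo = [max(-o, 0) for o in window.offset]
    out[
        dst_lo[0] : dst_lo[0] + (src_hi[0] - src_lo[0]),
        dst_lo[1] : dst_lo[1] + (src_hi[1] - src_lo[1]),
        :,
    ] = arr[src_lo[0] : src_hi[0], src_lo[1] : src_hi[1], :]
    return out


def crop_to_model_grid(
    volume: MriVolume, side: int = 128, pad: bool = True
) -> tuple[MriVolume, CropWindow]:
    """Crop every axial slice to ``side x side``, centred on the intensity
    centre of mass.

    One window is computed from the whole stack and applied to all slices,
    so a congruent mask can be cropped with :func:`crop_mask`.  Inputs
    smaller than the window are symmetrically zero-padded when ``pad`` is
    true, otherwise rejected.
    """
    if side <= 0:
        raise ValueError("side must be positive")
    arr = volume.intensities
    if not pad and (arr.shape[0] < side or arr.shape[1] < side):
        raise ValueError(
            f"in-plane shape {arr.shape[:2]} smaller than {side} and padding disabled"
        )
    if arr.shape[0] == side and arr.shape[1] == side:
        window = CropWindow(offset=(0, 0), side=side)
        return volume, window

    weights = arr - arr.min()
    if weights.sum() > 0:
        com = ndimage.center_of_mass(weights)
    else:
        com = tuple((n - 1) / 2 for n in arr.shape)
    offset = []
    for ax in range(2):
        o = int(round(com[ax] - side / 2 + 0.5))
        if arr.shape[ax] >= side:
            o = min(max(o, 0), arr.shape[ax] - side)  # keep window inside the image
        else:
            o = -((side - arr.shape[ax]) // 2)  # symmetric padding
        offset.append(o)
    window = CropWindow(offset=tuple(offset), side=side)
    return volume.with_intensities(_apply_window(arr, window)), window


def crop_mask(mask: MaskStack, window: CropWindow) -> MaskStack:
    """Apply a previously recorded crop window to a congruent mask."""
    return MaskStack(
        _apply_window(mask.values, window),
        mask.spacing,
        rater_id=mask.rater_id,
        binary=mask.binary,
    )


def normalize_for_model(volume: MriVolume, p_lo: float = 1.0, p_hi: float = 99.0) -> MriVolume:
    """Robust per-volume scaling to [0, 1] via the 1st/99th percentiles.

    Used only as model input; morphologic features always read the raw
    intensities.
    """
    arr = volume.intensities
    lo, hi = np.percentile(arr, [p_lo, p_hi])
    if hi <= lo:
        return volume.with_intensities(np.zeros_like(arr))
    return volume.with_intensities(np.clip((arr - lo) / (hi - lo), 0.0, 1.0))


def _affine_from_spacing(spacing) -> np.ndarray:
    return np.diag(list(spacing) + [1.0])


def save_volume(volume: MriVolume, path) -> None:
    img = nib.Nifti1Image(volume.intensities.astype(np.float32), _affine_from_spacing(volume.spacing))
    img.header.set_zooms(volume.spacing)
    nib.save(img, str(path))


def load_volume(path, spacing=None, subject_id: str = "") -> MriVolume:
    """Load a NIfTI volume; ``spacing`` overrides the header zooms."""
    img = nib.load(str(path))
    arr = np.asarray(img.dataobj, dtype=np.float64)
    if arr.ndim != 3:
        raise ValueError(f"expected a 3D volume, got shape {arr.shape}")
    zooms = spacing if spacing is not None else img.header.get_zooms()[:3]
    if zooms is None or any(z <= 0 for z in zooms):
        raise ValueError(
            "volume has no valid spacing in its header; pass spacing explicitly "
            "(CLI: --spacing AP,LR,CC in mm)"
        )
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{path}: intensities contain NaN/Inf")
    return MriVolume(arr, tuple(float(z) for z in zooms), subject_id=subject_id or Path(str(path)).stem)


def save_mask(mask: MaskStack, path) -> None:
    dtype = np.uint8 if mask.binary else np.float32
    img = nib.Nifti1Image(mask.values.astype(dtype), _affine_from_spacing(mask.spacing))
    img.header.set_zooms(mask.spacing)
    nib.save(img, str(path))


def load_mask(path, spacing=None, binary: bool = True, rater_id: str = "") -> MaskStack:
    img = nib.load(str(path))
    arr = np.asarray(img.dataobj, dtype=np.float64)
    zooms = spacing if spacing is not None else img.header.get_zooms()[:3]
    if zooms is None or any(z <= 0 for z in zooms):
        raise ValueError(
            "mask has no valid spacing in its header; pass spacing explicitly"
        )
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{path}: mask contains NaN/Inf")
    return MaskStack(arr, tuple(float(z) for z in zooms), rater_id=rater_id, binary=binary)
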