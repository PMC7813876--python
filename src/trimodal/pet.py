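"""PET parametric quantification: frame averaging, SUV, BP_ND, smoothing.

SUV normalises the tissue activity concentration by the injected dose
per body weight (g/ml).  The non-displaceable binding potential uses a
reference region with negligible specific binding:
``BP_ND = (C_T - C_REF) / C_REF`` with ``C_REF`` the mean concentration
over the reference mask of the time-weighted frame average.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .types import ValidationError, Volume

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass
class PetFrameSet:
    """Dynamic PET frames (kBq/ml) with durations, dose and body weight."""

    frames: list
    durations_min: np.ndarray
    injected_MBq: float
    weight_kg: float

    def __post_init__(self) -> None:
        self.durations_min = np.atleast_1d(np.asarray(self.durations_min, float))
        if len(self.frames) != self.durations_min.size:
            raise ValidationError("one duration per frame required")
        if (self.durations_min <= 0).any():
            raise ValidationError("frame durations must be positive")
        if self.injected_MBq <= 0 or self.weight_kg <= 0:
            raise ValidationError("injected_MBq and weight_kg must be positive")
        for f in self.frames[1:]:
            self.frames[0].require_same_grid(f, "PET frames")

    @property
    def n_frames(self) -> int:
        return len(self.frames)


@dataclass
class ParametricMap:
    """A quantified volume with its physical quantity and unit tag."""

    volume: Volume
    quantity: str  # "SUV" or "BP_ND"
    unit: str = ""

    _UNITS = {"SUV": "g/ml", "BP_ND": "p.d.u."}

    def __post_init__(self) -> None:
        if not self.unit:
            self.unit = self._UNITS.get(self.quantity, "a.u.")


def frame_average(fs: PetFrameSet, frame_indices: list[int] | None = None) -> Volume:
    """Voxel-wise average of selected frames, weighted by frame duration."""
    if frame_indices is None:
        frame_indices = list(range(fs.n_frames))
    if len(frame_indices) == 0:
        raise ValidationError("empty frame selection")
    for i in frame_indices:
        if not (0 <= i < fs.n_frames):
            raise ValidationError(f"frame index {i} out of range")
    w = fs.durations_min[frame_indices]
    stack = np.stack([fs.frames[i].data for i in frame_indices], axis=-1)
    avg = (stack * w).sum(axis=-1) / w.sum()
    ref = fs.frames[frame_indices[0]]
    return Volume(data=avg, voxel_size_mm=ref.voxel_size_mm, offset_mm=ref.offset_mm)


def compute_suv(avg: Volume, injected_MBq: float, weight_kg: float) -> ParametricMap:
    """Standard uptake value in g/ml.

    SUV = C [Bq/ml] / (dose [Bq] / weight [g]); with C in kBq/ml, dose in
    MBq and weight in kg this reduces to ``C * weight_kg / injected_MBq``.
    """
    if injected_MBq <= 0 or weight_kg <= 0:
        raise ValidationError("injected_MBq and weight_kg must be positive")
    suv = avg.data * (weight_kg / injected_MBq)
    vol = Volume(data=suv, voxel_size_mm=avg.voxel_size_mm, offset_mm=avg.offset_mm)
    return ParametricMap(volume=vol, quantity="SUV")


def compute_bpnd(avg: Volume, ref_mask: Volume) -> ParametricMap:
    """Non-displaceable binding potential, (C_T - C_REF) / C_REF per voxel."""
    avg.require_same_grid(ref_mask, "average and reference mask")
    mask = ref_mask.data.astype(bool)
    if not mask.any():
        raise ValidationError("reference mask is empty")
    c_ref = float(avg.data[mask].mean())
    if c_ref <= 0:
        raise ValidationError(f"reference concentration must be positive, got {c_ref}")
    bp = (avg.data - c_ref) / c_ref
    vol = Volume(data=bp, voxel_size_mm=avg.voxel_size_mm, offset_mm=avg.offset_mm)
    return ParametricMap(volume=vol, quantity="BP_ND")


def gaussian_smooth(
    v: Volume,
    fwhm_mm: float,
    width_is_sigma: bool = False,
    boundary: str = "renormalize",
) -> Volume:
    """Separable 3D Gaussian smoothing with width given as FWHM in mm.

    ``boundary='renormalize'`` divides by the smoothed indicator so that
    truncation at the grid edge does not darken border voxels (a constant
    volume stays exactly constant); ``'wrap'`` uses periodic boundaries,
    which preserve the volume mean exactly.
    """
    if fwhm_mm < 0:
        raise ValidationError("smoothing width must be non-negative")
    if fwhm_mm == 0:
        return Volume(data=v.data.copy(), voxel_size_mm=v.voxel_size_mm,
                      offset_mm=v.offset_mm)
    sigma_mm = fwhm_mm if width_is_sigma else fwhm_mm * FWHM_TO_SIGMA
    sigma_vox = [sigma_mm / vs for vs in v.voxel_size_mm]
    if boundary == "wrap":
        sm = ndimage.gaussian_filter(v.data.astype(float), sigma_vox, mode="wrap",
                                     truncate=6.0)
    elif boundary == "renormalize":
        sm = ndimage.gaussian_filter(v.data.astype(float), sigma_vox,
                                     mode="constant", truncate=6.0)
        norm = ndimage.gaussian_filter(np.ones(v.shape), sigma_vox,
                                       mode="constant", truncate=6.0)
        sm = sm / norm
    else:
        raise ValidationError(f"unknown boundary mode {boundary!r}")
    return Volume(data=sm, voxel_size_mm=v.voxel_size_mm, offset_mm=v.offset_mm)
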