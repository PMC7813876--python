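"""Core data containers shared across the pipeline stages.

Volumes carry an explicit voxel size and grid offset but no rotation: the
package combines only grid-compatible images (checked, never resampled),
so the affine is always ``diag(voxel_size) + offset``.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class ValidationError(ValueError):
    """An input violates a stage's precondition."""


class FormatError(ValueError):
    """A file does not match the expected on-disk format."""


class ConfigError(ValueError):
    """A pipeline configuration parameter is out of range or missing."""


@dataclass
class Volume:
    """A 3D scalar grid: parametric map, mask, or single PET/fMRI frame.

    Parameters
    ----------
    data : ndarray, shape (nx, ny, nz)
        Voxel values; boolean arrays represent masks.
    voxel_size_mm : tuple of 3 floats
        Edge lengths of a voxel in millimetres.
    offset_mm : tuple of 3 floats
        World-space position of voxel (0, 0, 0).
    """

    data: np.ndarray
    voxel_size_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    offset_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise FormatError(
                f"Volume requires 3 dimensions, got {self.data.ndim} "
                f"(shape {self.data.shape})"
            )
        self.voxel_size_mm = tuple(float(v) for v in self.voxel_size_mm)
        self.offset_mm = tuple(float(v) for v in self.offset_mm)
        if any(v <= 0 for v in self.voxel_size_mm):
            raise ValidationError("voxel sizes must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def affine(self) -> np.ndarray:
        aff = np.eye(4)
        aff[:3, :3] = np.diag(self.voxel_size_mm)
        aff[:3, 3] = self.offset_mm
        return aff

    def same_grid(self, other: "Volume") -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.voxel_size_mm, other.voxel_size_mm)
            and np.allclose(self.offset_mm, other.offset_mm)
        )

    def require_same_grid(self, other: "Volume", what: str = "volumes") -> None:
        if not self.same_grid(other):
            raise ValidationError(
                f"{what} are not on the same grid: "
                f"{self.shape}/{self.voxel_size_mm} vs "
                f"{other.shape}/{other.voxel_size_mm}"
            )


@dataclass
class EEGRecording:
    """Multichannel EEG: a channels x samples matrix with geometry.

    ``positions`` are unit-disc (2D) or unit-sphere (3D) electrode
    coordinates with +x toward the right ear and +y toward the nasion.
    """

    data: np.ndarray
    fs: float
    ch_names: list[str] = field(default_factory=list)
    positions: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.fs <= 0:
            raise ValidationError("sampling rate must be positive")
        if not self.ch_names:
            self.ch_names = [f"ch{i:02d}" for i in range(self.data.shape[0])]
        if len(self.ch_names) != self.data.shape[0]:
            raise FormatError(
                f"{len(self.ch_names)} channel labels for "
                f"{self.data.shape[0]} data rows"
            )
        if self.positions is not None:
            self.positions = np.asarray(self.positions, dtype=float)
            if self.positions.shape[0] != self.data.shape[0]:
                raise FormatError("positions do not match channel count")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


@dataclass
class MicrostateSet:
    """K scalp topographies (rows), zero-mean and unit-norm per map.

    ``labels`` are the canonical class names (A-D) once sorted; unsorted
    sets carry placeholder labels. ``gev`` is the global explained
    variance of the segmentation that produced the maps, when known.
    """

    maps: np.ndarray
    labels: list[str] = field(default_factory=list)
    gev: float | None = None

    def __post_init__(self) -> None:
        self.maps = np.atleast_2d(np.asarray(self.maps, dtype=float))
        if not self.labels:
            self.labels = [f"map{i}" for i in range(self.maps.shape[0])]
        if len(self.labels) != self.maps.shape[0]:
            raise FormatError("label count does not match map count")
        if self.gev is not None and not (0.0 <= self.gev <= 1.0 + 1e-12):
            raise ValidationError(f"gev must lie in [0, 1], got {self.gev}")

    @property
    def n_maps(self) -> int:
        return self.maps.shape[0]

    @property
    def n_channels(self) -> int:
        return self.maps.shape[1]


@dataclass
class Leadfield:
    """Gain matrix mapping unit source activity to scalp potentials."""

    gain: np.ndarray
    source_coords: np.ndarray

    def __post_init__(self) -> None:
        self.gain = np.atleast_2d(np.asarray(self.gain, dtype=float))
        self.source_coords = np.atleast_2d(
            np.asarray(self.source_coords, dtype=float)
        )
        if self.source_coords.shape[0] != self.gain.shape[1]:
            raise FormatError(
                f"{self.source_coords.shape[0]} source coordinates for "
                f"{self.gain.shape[1]} gain columns"
            )

    @property
    def n_channels(self) -> int:
        return self.gain.shape[0]

    @property
    def n_sources(self) -> int:
        return self.gain.shape[1]


@dataclass
class StatResult:
    """One hypothesis test: effect estimate, raw and adjusted p."""

    effect: float
    p: float
    p_adjusted: float
    method: str
    significant: bool
    label: str = ""


@dataclass
class BoldSeries:
    """A 4D BOLD series (x, y, z, t) with repetition time and analysis mask."""

    data: np.ndarray
    tr_s: float
    mask: Volume | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise FormatError(
                f"BOLD series requires 4 dimensions, got {self.data.ndim}"
            )
        if self.data.shape[3] < 32:
            raise ValidationError(
                f"BOLD series needs at least 32 volumes, got {self.data.shape[3]}"
            )
        if self.tr_s <= 0:
            raise ValidationError("tr_s must be positive")
        if self.mask is not None and self.mask.shape != self.data.shape[:3]:
            raise ValidationError("mask grid does not match BOLD grid")

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    def mask_array(self) -> np.ndarray:
        if self.mask is None:
            return np.ones(self.grid_shape, dtype=bool)
        return self.mask.data.astype(bool)
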