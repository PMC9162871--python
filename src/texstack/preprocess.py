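"""Geometric and intensity preprocessing of 3D volumes.

The fixed coordinate convention: a voxel with 0-based index ``(k, i, j)``
(slice, row, column) has its *center* at ``origin_mm + index * spacing_mm``.
All resampling and registration below is nearest-neighbour in these physical
coordinates, so no new intensity values are ever introduced — a deliberate
choice that keeps discretized gray levels meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .errors import DegenerateRoiError, ParameterError, RegistrationError

__all__ = [
    "Volume",
    "RoiMask",
    "DiscretizedRoi",
    "resample_nearest",
    "register_to_reference",
    "normalize_intensities",
    "log_filter",
    "discretize",
    "gray_histogram",
]


@dataclass(frozen=True)
class Volume:
    """A 3D scalar image on a regular anisotropic grid.

    Parameters
    ----------
    data
        ``(n_slices, n_rows, n_cols)`` float array of intensities.
    spacing_mm
        Per-axis voxel spacing ``(slice, row, column)`` in millimetres.
    origin_mm
        Physical position of voxel ``(0, 0, 0)``'s center.
    sequence
        Acquisition tag, one of ``DWI``, ``T1FSE``, ``T2FSE`` (or ``None``
        for derived images).
    """

    data: np.ndarray
    spacing_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    sequence: str | None = None

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "spacing_mm", tuple(float(s) for s in self.spacing_mm))
        object.__setattr__(self, "origin_mm", tuple(float(o) for o in self.origin_mm))
        if data.ndim != 3:
            raise ParameterError(f"volume data must be 3D, got shape {data.shape}")
        if any(s <= 0 for s in self.spacing_mm):
            raise ParameterError(f"spacing must be positive, got {self.spacing_mm}")
        if not np.all(np.isfinite(data)):
            raise ParameterError("volume contains non-finite intensities")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def voxel_centers_mm(self, axis: int) -> np.ndarray:
        """Physical coordinates of voxel centers along one axis."""
        n = self.data.shape[axis]
        return self.origin_mm[axis] + np.arange(n) * self.spacing_mm[axis]


@dataclass(frozen=True)
class RoiMask:
    """A binary region-of-interest mask on the same grid as its Volume."""

    data: np.ndarray
    spacing_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        data = np.asarray(self.data) != 0
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "spacing_mm", tuple(float(s) for s in self.spacing_mm))
        object.__setattr__(self, "origin_mm", tuple(float(o) for o in self.origin_mm))
        if data.ndim != 3:
            raise ParameterError(f"mask data must be 3D, got shape {data.shape}")
        if not data.any():
            raise ParameterError("mask has no foreground voxels")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    def as_volume(self) -> Volume:
        """View the mask as a float Volume (for resampling/registration)."""
        return Volume(self.data.astype(float), self.spacing_mm, self.origin_mm)


@dataclass(frozen=True)
class DiscretizedRoi:
    """Gray levels ``1..levels`` inside the mask, 0 (sentinel) outside."""

    data: np.ndarray
    levels: int
    bin_edges: np.ndarray
    mask: np.ndarray = field(repr=False, default=None)

    def __post_init__(self) -> None:
        mask = self.mask if self.mask is not None else self.data > 0
        object.__setattr__(self, "mask", np.asarray(mask, dtype=bool))


def _nearest_indices(target_centers: np.ndarray, origin: float, spacing: float) -> np.ndarray:
    """Index of the nearest source voxel center for each target coordinate.

    Ties (a target center exactly halfway between two source centers) go to
    the lower index, so an upsampled ramp duplicates each value the same
    number of times.
    """
    frac = (target_centers - origin) / spacing
    return np.ceil(frac - 0.5).astype(int)


def resample_nearest(
    volume: Volume, target_spacing_mm: tuple[float, float, float]
) -> Volume:
    """Resample onto ``target_spacing_mm`` by nearest-neighbour lookup.

    The output grid covers the same physical extent (``shape * spacing``,
    counting whole voxel cells) starting at the same origin. Each output
    voxel takes the value of the nearest input voxel center, so the output
    value set is a subset of the input's.
    """
    target = tuple(float(s) for s in target_spacing_mm)
    if any(s <= 0 for s in target):
        raise ParameterError(f"target spacing must be positive, got {target}")
    out_shape = tuple(
        max(1, int(round(n * s / t)))
        for n, s, t in zip(volume.shape, volume.spacing_mm, target)
    )
    index_axes = []
    for axis in range(3):
        centers = volume.origin_mm[axis] + np.arange(out_shape[axis]) * target[axis]
        idx = _nearest_indices(centers, volume.origin_mm[axis], volume.spacing_mm[axis])
        index_axes.append(np.clip(idx, 0, volume.shape[axis] - 1))
    data = volume.data[np.ix_(*index_axes)]
    return Volume(data, target, volume.origin_mm, volume.sequence)


def register_to_reference(
    volume: Volume, reference: Volume, fill_value: float = 0.0
) -> Volume:
    """Pull ``volume`` onto the reference grid by physical-coordinate lookup.

    Spatial-location registration only: each reference voxel center is mapped
    to the nearest moving voxel center; reference voxels outside the moving
    volume's extent get ``fill_value``.
    """
    index_axes = []
    valid_axes = []
    for axis in range(3):
        centers = reference.voxel_centers_mm(axis)
        idx = _nearest_indices(centers, volume.origin_mm[axis], volume.spacing_mm[axis])
        valid_axes.append((idx >= 0) & (idx < volume.shape[axis]))
        index_axes.append(np.clip(idx, 0, volume.shape[axis] - 1))
    if not all(v.any() for v in valid_axes):
        raise RegistrationError(
            "moving volume and reference grid have disjoint physical extents"
        )
    data = volume.data[np.ix_(*index_axes)]
    inside = np.ones(reference.shape, dtype=bool)
    for axis, valid in enumerate(valid_axes):
        shape = [1, 1, 1]
        shape[axis] = -1
        inside &= valid.reshape(shape)
    data = np.where(inside, data, fill_value)
    return Volume(data, reference.spacing_mm, reference.origin_mm, volume.sequence)


def register_mask_to_reference(mask: RoiMask, reference: Volume) -> RoiMask:
    """Nearest-neighbour mask registration; fill is background."""
    moved = register_to_reference(mask.as_volume(), reference, fill_value=0.0)
    return RoiMask(moved.data > 0.5, reference.spacing_mm, reference.origin_mm)


def normalize_intensities(volume: Volume, mask: RoiMask) -> Volume:
    """Affinely map intensities so the in-mask voxels have mean 0, SD 1.

    The statistics are computed over the ROI only (population SD) and the
    resulting affine map is applied to the whole volume, so the transform is
    bijective and the ROI's texture is standardized regardless of the
    acquisition's intensity scale.
    """
    values = volume.data[mask.data]
    mean = float(values.mean())
    sd = float(values.std())
    if sd == 0.0:
        raise DegenerateRoiError("constant ROI: in-mask variance is zero")
    return replace(volume, data=(volume.data - mean) / sd)


def log_filter(volume: Volume, sigma_mm: float) -> Volume:
    """Laplacian-of-Gaussian filter with physical kernel width ``sigma_mm``.

    The scale is specified in millimetres and converted to voxels per axis,
    so anisotropic grids are filtered isotropically in physical space.
    Reflect padding at the boundary avoids ringing at the volume edge. The
    input is mean-centred first: the LoG of a constant is identically zero,
    and centring makes that hold exactly despite kernel truncation.
    """
    if sigma_mm <= 0:
        raise ParameterError(f"sigma must be positive, got {sigma_mm}")
    sigma_vox = [sigma_mm / s for s in volume.spacing_mm]
    centered = volume.data - volume.data.mean()
    data = ndimage.gaussian_laplace(centered, sigma=sigma_vox, mode="reflect")
    return replace(volume, data=data)


def discretize(volume: Volume, mask: RoiMask, levels: int) -> DiscretizedRoi:
    """Quantize in-mask intensities into ``levels`` equal-width bins.

    Fixed-bin-count scheme over the in-mask range ``[min, max]``; the
    maximum lands in the top bin. A constant ROI maps every voxel to
    level 1 (documented degenerate behaviour, not an error).
    """
    if levels < 2:
        raise ParameterError(f"need at least 2 gray levels, got {levels}")
    values = volume.data[mask.data]
    lo, hi = float(values.min()), float(values.max())
    out = np.zeros(volume.shape, dtype=np.int32)
    if hi == lo:
        out[mask.data] = 1
        edges = np.linspace(lo, lo + 1.0, levels + 1)
    else:
        edges = np.linspace(lo, hi, levels + 1)
        binned = np.floor((volume.data[mask.data] - lo) / (hi - lo) * levels).astype(
            np.int32
        )
        out[mask.data] = np.minimum(binned, levels - 1) + 1
    return DiscretizedRoi(out, levels, edges, mask.data.copy())


def gray_histogram(
    volume: Volume, mask: RoiMask, bins: int = 64
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of in-mask intensities: ``(bin_edges, counts)``.

    Counts sum to the number of in-mask voxels.
    """
    counts, edges = np.histogram(volume.data[mask.data], bins=bins)
    return edges, counts
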