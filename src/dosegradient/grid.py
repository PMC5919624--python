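"""Voxel-grid containers: 3D dose fields and aligned binary structures.

Conventions
-----------
Arrays are indexed ``[i, j, k]`` along the physical x/y/z axes.  ``spacing``
and ``origin`` are in millimetres and refer to voxel *centres*: voxel
``(i, j, k)`` sits at ``origin + (i, j, k) * spacing``.  All derived
quantities are reported in mm / mm^2 / mm^3.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage


def _as_triple(x) -> tuple[float, float, float]:
    arr = np.broadcast_to(np.asarray(x, dtype=float), (3,))
    return (float(arr[0]), float(arr[1]), float(arr[2]))


@dataclass(eq=False)
class _Grid3D:
    values: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError(f"expected a 3D array, got ndim={self.values.ndim}")
        self.spacing = _as_triple(self.spacing)
        self.origin = _as_triple(self.origin)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(np.prod(self.spacing))

    def axes(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Physical coordinates of voxel centres along each axis (mm)."""
        return tuple(
            self.origin[a] + self.spacing[a] * np.arange(self.shape[a])
            for a in range(3)
        )

    def same_geometry(self, other: "_Grid3D", atol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=atol)
            and np.allclose(self.origin, other.origin, atol=atol)
        )

    def require_same_geometry(self, other: "_Grid3D") -> None:
        if not self.same_geometry(other):
            raise ValueError(
                "grids are not aligned: "
                f"shape {self.shape} vs {other.shape}, "
                f"spacing {self.spacing} vs {other.spacing}, "
                f"origin {self.origin} vs {other.origin}"
            )


@dataclass(eq=False)
class DoseGrid(_Grid3D):
    """A 3D scalar dose field in Gy on a regular grid."""

    def __post_init__(self):
        super().__post_init__()
        self.values = np.asarray(self.values, dtype=np.float64)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("dose values must be finite")
        if np.any(self.values < 0):
            raise ValueError("dose values must be non-negative")

    @property
    def max_dose(self) -> float:
        return float(self.values.max())

    @property
    def min_dose(self) -> float:
        return float(self.values.min())

    def resampled(self, spacing=1.0, order: int = 1) -> "DoseGrid":
        """Resample to a new voxel spacing (trilinear by default).

        The new grid covers the same voxel-centre extent, anchored at the
        original origin.
        """
        new_vals, new_sp = _resample(self.values, self.spacing, spacing, order)
        return DoseGrid(new_vals, new_sp, self.origin)


@dataclass(eq=False)
class BinaryMask(_Grid3D):
    """A boolean structure mask aligned to a :class:`DoseGrid`."""

    def __post_init__(self):
        super().__post_init__()
        self.values = np.asarray(self.values).astype(bool)

    @property
    def voxel_count(self) -> int:
        return int(self.values.sum())

    @property
    def volume_mm3(self) -> float:
        """Voxel-counting volume of the structure."""
        return self.voxel_count * self.voxel_volume

    def resampled(self, spacing=1.0) -> "BinaryMask":
        """Nearest-neighbour resampling to a new spacing."""
        new_vals, new_sp = _resample(
            self.values.astype(np.float32), self.spacing, spacing, order=0
        )
        return BinaryMask(new_vals > 0.5, new_sp, self.origin)


def _resample(values, spacing, new_spacing, order):
    new_sp = _as_triple(new_spacing)
    shape = values.shape
    idx = []
    for a in range(3):
        extent = spacing[a] * (shape[a] - 1)
        n = int(np.floor(extent / new_sp[a] + 1e-9)) + 1
        idx.append(np.arange(n) * new_sp[a] / spacing[a])
    coords = np.meshgrid(*idx, indexing="ij")
    out = ndimage.map_coordinates(
        np.asarray(values, dtype=np.float64), coords, order=order, mode="nearest"
    )
    return out, new_sp
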