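"""Dose-volume histogram and the legacy volume-based gradient indices.

GI (gradient index) is the half-prescription isodose volume over the
prescription isodose volume; R50% is the half-prescription isodose volume
over the PTV volume.  Both condense the fall-off into a single ratio and
are provided for benchmarking the distance-based DGC against them.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .dgc import IsodoseLevelRecord
from .exceptions import EmptyStructureError
from .grid import BinaryMask, DoseGrid

__all__ = [
    "DVHCurve",
    "compute_dvh",
    "d_at_volume",
    "gradient_index",
    "r50",
    "PlanIndices",
]


@dataclass(eq=False)
class DVHCurve:
    """Cumulative dose-volume curve of one structure.

    ``volume_fraction[k]`` is the fraction of the structure receiving at
    least ``dose[k]`` Gy: non-increasing, 1 at zero dose, 0 above the
    structure maximum.
    """

    dose: np.ndarray
    volume_fraction: np.ndarray

    def __post_init__(self):
        self.dose = np.asarray(self.dose, dtype=float)
        self.volume_fraction = np.asarray(self.volume_fraction, dtype=float)
        if self.dose.shape != self.volume_fraction.shape:
            raise ValueError("dose and volume_fraction must have equal length")

    def v_at_dose(self, dose: float) -> float:
        """Volume fraction receiving at least ``dose`` (linear interpolation)."""
        return float(np.interp(dose, self.dose, self.volume_fraction))

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {"dose_gy": self.dose, "relative_volume": self.volume_fraction}
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "DVHCurve":
        df = pd.read_csv(path)
        return cls(df["dose_gy"].to_numpy(), df["relative_volume"].to_numpy())


def compute_dvh(
    grid: DoseGrid, structure: BinaryMask, bin_width: float | None = None
) -> DVHCurve:
    """Cumulative DVH of a structure by voxel counting.

    ``bin_width`` defaults to 0.1% of the structure's maximum dose.  No
    sub-voxel dose averaging is applied (consistent with ~1 mm grids).
    """
    grid.require_same_geometry(structure)
    if not structure.values.any():
        raise EmptyStructureError("structure mask is empty")
    doses = np.sort(grid.values[structure.values].ravel())
    dmax = float(doses[-1])
    if bin_width is None:
        bin_width = max(dmax, 1e-12) / 1000.0
    edges = np.arange(0.0, dmax + 2 * bin_width, bin_width)
    frac = 1.0 - np.searchsorted(doses, edges, side="left") / doses.size
    return DVHCurve(edges, frac)


def d_at_volume(dvh: DVHCurve, volume_fraction: float) -> float:
    """Dose covering at least ``volume_fraction`` of the structure (Dx).

    The largest dose D with V(D) >= fraction, linearly interpolated between
    bins; ``d_at_volume(dvh, 1.0)`` is the structure minimum dose (D100%).
    """
    if not 0 < volume_fraction <= 1:
        raise ValueError(f"volume fraction must be in (0, 1], got {volume_fraction}")
    v = dvh.volume_fraction
    d = dvh.dose
    above = np.flatnonzero(v >= volume_fraction)
    if above.size == 0:
        raise ValueError("requested coverage exceeds the DVH maximum")
    i = int(above[-1])
    if i == len(d) - 1 or v[i] == volume_fraction:
        return float(d[i])
    # interpolate on the falling segment [i, i+1]
    return float(d[i] + (v[i] - volume_fraction) / (v[i] - v[i + 1]) * (d[i + 1] - d[i]))


def _volume_at_pct(levels: Sequence[IsodoseLevelRecord], pct: float) -> float:
    for rec in levels:
        if abs(rec.dose_pct - pct) < 1e-6:
            return rec.volume
    raise ValueError(f"no {pct:g}% isodose level in the table")


def gradient_index(levels: Sequence[IsodoseLevelRecord]) -> float:
    """GI: volume of the half-prescription isodose over the prescription isodose."""
    v100 = _volume_at_pct(levels, 100.0)
    if v100 <= 0:
        raise ValueError("prescription isodose volume must be positive")
    return _volume_at_pct(levels, 50.0) / v100


def r50(levels: Sequence[IsodoseLevelRecord], ptv_volume: float) -> float:
    """R50%: half-prescription isodose volume over the PTV volume."""
    if ptv_volume <= 0:
        raise ValueError("PTV volume must be strictly positive")
    return _volume_at_pct(levels, 50.0) / ptv_volume


@dataclass(frozen=True)
class PlanIndices:
    """Flat report of the volume-based plan quality scores."""

    gradient_index: float | None
    r50: float | None
    ptv_volume: float

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)
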