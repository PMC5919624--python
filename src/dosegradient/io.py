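"""File IO and the end-to-end analysis pipeline.

Dose grids (not planning-system isodose exports) are the input boundary:
NRRD (or any SimpleITK-readable volume) and DICOM RT Dose are supported.
Masks arrive as volumetric files on the same grid; RTSTRUCT contours are
deliberately not parsed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .dgc import (
    DGCConfig,
    DGCTable,
    build_level_table,
    cumulative_dgc,
    differential_dgc,
    normalize_ddgc,
)
from .exceptions import DoseReadError, EmptyIsodoseError, OpenSurfaceError
from .grid import BinaryMask, DoseGrid, _Grid3D
from .mesh import crop_body, extract_isosurface, mesh_volume
from .metrics import DVHCurve, PlanIndices, compute_dvh, d_at_volume

logger = logging.getLogger(__name__)

__all__ = [
    "read_dose_volume",
    "read_mask_volume",
    "write_volume",
    "RunConfig",
    "AnalysisResult",
    "run_dgc_analysis",
]


def _read_sitk(path: Path) -> tuple[np.ndarray, tuple, tuple]:
    import SimpleITK as sitk

    try:
        img = sitk.ReadImage(str(path))
    except RuntimeError as exc:  # ITK wraps parse failures in RuntimeError
        raise DoseReadError(f"cannot parse {path}: {exc}") from exc
    # SimpleITK arrays come back [z, y, x]; transpose to our [x, y, z]
    values = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
    return values, tuple(img.GetSpacing()), tuple(img.GetOrigin())


def _read_rtdose(path: Path) -> tuple[np.ndarray, tuple, tuple]:
    import pydicom

    try:
        ds = pydicom.dcmread(str(path))
    except Exception as exc:
        raise DoseReadError(f"cannot parse {path}: {exc}") from exc
    modality = getattr(ds, "Modality", None)
    if modality != "RTDOSE":
        raise DoseReadError(f"{path}: unsupported modality {modality!r} (need RTDOSE)")
    scaling = getattr(ds, "DoseGridScaling", None)
    if scaling is None:
        raise DoseReadError(f"{path}: DoseGridScaling attribute is missing")
    offsets = np.asarray(ds.GridFrameOffsetVector, dtype=float)
    dz = np.diff(offsets)
    if dz.size == 0 or not np.allclose(dz, dz[0], atol=1e-6):
        raise DoseReadError(f"{path}: non-uniform slice spacing {offsets}")
    arr = ds.pixel_array  # (frames=z, rows=y, cols=x)
    values = arr.transpose(2, 1, 0).astype(np.float64) * float(scaling)
    spacing = (float(ds.PixelSpacing[1]), float(ds.PixelSpacing[0]), float(abs(dz[0])))
    origin = tuple(float(v) for v in ds.ImagePositionPatient)
    return values, spacing, origin


def _is_dicom(path: Path) -> bool:
    if path.suffix.lower() in (".dcm", ".dicom"):
        return True
    try:
        with open(path, "rb") as fh:
            fh.seek(128)
            return fh.read(4) == b"DICM"
    except OSError:
        return False


def read_dose_volume(path) -> DoseGrid:
    """Read a dose grid from NRRD/MetaImage or DICOM RT Dose (values in Gy)."""
    path = Path(path)
    if not path.exists():
        raise DoseReadError(f"no such file: {path}")
    if _is_dicom(path):
        values, spacing, origin = _read_rtdose(path)
    else:
        values, spacing, origin = _read_sitk(path)
    return DoseGrid(values, spacing, origin)


def read_mask_volume(path) -> BinaryMask:
    """Read a binary structure mask (any voxel value != 0 is inside)."""
    path = Path(path)
    if not path.exists():
        raise DoseReadError(f"no such file: {path}")
    values, spacing, origin = _read_sitk(path)
    return BinaryMask(values != 0, spacing, origin)


def write_volume(grid: _Grid3D, path) -> None:
    """Write a DoseGrid (float) or BinaryMask (uint8) as NRRD/MetaImage."""
    import SimpleITK as sitk

    values = grid.values
    if values.dtype == bool:
        values = values.astype(np.uint8)
    img = sitk.GetImageFromArray(np.ascontiguousarray(values.transpose(2, 1, 0)))
    img.SetSpacing(tuple(float(s) for s in grid.spacing))
    img.SetOrigin(tuple(float(o) for o in grid.origin))
    sitk.WriteImage(img, str(path))


@dataclass
class RunConfig:
    """Configuration of a full DGC analysis run."""

    dose_path: str
    body_mask_path: str
    ptv_mask_path: str
    prescription_gy: float
    step: float = 1.0
    reference: str = "prescription"  # or "d100"
    crop_margin_mm: float = 3.0
    dose_scale: str = "percent"
    output_dir: str = "dgc_output"
    resample_mm: float | None = 1.0
    make_plots: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.prescription_gy <= 0:
            raise ValueError("prescription_gy must be positive")
        if self.reference not in ("prescription", "d100"):
            raise ValueError("reference must be 'prescription' or 'd100'")


@dataclass
class AnalysisResult:
    """Everything a DGC run produces, plus where it was written."""

    table: DGCTable
    dvh: DVHCurve
    indices: PlanIndices
    reference_dose_gy: float
    outputs: dict = field(default_factory=dict)


def _plan_indices(dose, domain, prescription, ptv) -> PlanIndices:
    from .dgc import IsodoseLevelRecord
    from .metrics import gradient_index, r50

    records = []
    for pct in (50.0, 100.0):
        try:
            mesh = extract_isosurface(dose, pct / 100.0 * prescription, domain)
        except (EmptyIsodoseError, OpenSurfaceError) as exc:
            logger.warning("cannot evaluate %g%% isodose for GI/R50: %s", pct, exc)
            return PlanIndices(None, None, ptv.volume_mm3)
        records.append(
            IsodoseLevelRecord(pct, pct / 100.0 * prescription, 1.0, mesh_volume(mesh))
        )
    return PlanIndices(
        gradient_index=gradient_index(records),
        r50=r50(records, ptv.volume_mm3),
        ptv_volume=ptv.volume_mm3,
    )


def run_dgc_analysis(config: RunConfig) -> AnalysisResult:
    """Run the whole pipeline: read, crop, extract, tabulate, plot, write.

    Stages are logged, including the truncation dose and the effective voxel
    spacing — the two quantities that most often explain surprising DGC
    values.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    try:
        dose = read_dose_volume(config.dose_path)
        body = read_mask_volume(config.body_mask_path)
        ptv = read_mask_volume(config.ptv_mask_path)
    except DoseReadError as exc:
        raise DoseReadError(f"[input stage] {exc}") from exc
    if config.resample_mm is not None and any(
        s > config.resample_mm + 1e-9 for s in dose.spacing
    ):
        logger.info(
            "resampling from %s mm to %g mm isotropic", dose.spacing, config.resample_mm
        )
        dose = dose.resampled(config.resample_mm)
        body = body.resampled(config.resample_mm)
        ptv = ptv.resampled(config.resample_mm)
    logger.info("voxel spacing: %s mm", dose.spacing)
    domain = crop_body(body, config.crop_margin_mm)

    dvh = compute_dvh(dose, ptv, bin_width=config.prescription_gy / 1000.0)
    if config.reference == "d100":
        reference = d_at_volume(dvh, 1.0)
        logger.info("reference dose D100%% = %.3f Gy", reference)
    else:
        reference = config.prescription_gy
    dgc_config = DGCConfig(
        step=config.step, reference_dose=reference, dose_scale=config.dose_scale
    )
    levels = build_level_table(dose, domain, dgc_config)
    logger.info(
        "level table: %d levels, truncation (lowest valid) level %.4g %s",
        len(levels),
        levels[0].dose_pct if config.dose_scale == "percent" else levels[0].dose_gy,
        "%" if config.dose_scale == "percent" else "Gy",
    )
    table = cumulative_dgc(normalize_ddgc(differential_dgc(levels, dgc_config)))
    indices = _plan_indices(dose, domain, config.prescription_gy, ptv)

    outputs = {}
    table_path = outdir / "dgc.csv"
    table.to_csv(table_path)
    outputs["dgc_csv"] = table_path
    dvh_path = outdir / "dvh.csv"
    dvh.to_csv(dvh_path)
    outputs["dvh_csv"] = dvh_path
    idx_path = outdir / "indices.json"
    report = indices.to_dict()
    report["reference_dose_gy"] = reference
    report["v100_pct"] = 100.0 * dvh.v_at_dose(config.prescription_gy)
    report["truncation_level"] = float(
        levels[0].dose_pct if config.dose_scale == "percent" else levels[0].dose_gy
    )
    with open(idx_path, "w") as fh:
        json.dump(report, fh, indent=2)
    outputs["indices_json"] = idx_path
    if config.make_plots:
        from .plotting import plot_dgc

        for kind in ("differential", "normalized", "cumulative"):
            fig = plot_dgc(table, kind=kind)
            p = outdir / f"dgc_{kind}.png"
            fig.savefig(p, dpi=120)
            outputs[f"plot_{kind}"] = p
        fig = plot_dgc(table, dvh=dvh, kind="combined")
        p = outdir / "dgc_combined.png"
        fig.savefig(p, dpi=120)
        outputs["plot_combined"] = p
    return AnalysisResult(table, dvh, indices, reference, outputs)
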