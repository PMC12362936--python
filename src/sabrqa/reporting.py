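"""Summary tables, tallies, fixtures and radiotherapy DICOM I/O.

Turns agreement results and compliance reports into the summary shapes a
dummy-run report prints (per-case and per-center mean (SD) DSC,
prescription means, deviation tallies with center percentages), loads
the packaged fixture tables transcribed from a published 10-center
exercise, and reads/writes DICOM RTSTRUCT and RTDOSE for interoperation
with treatment-planning systems.

Rounding follows the printed convention: half-up at 3 decimals for DSC
and Gy summaries, 1 decimal for percentages.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .compliance import ComplianceReport
from .core import (
    AgreementTable,
    ConstraintSpec,
    DeviationGrade,
    DoseDistribution,
    StructureMask,
    StructureRole,
    VoxelGrid,
)

__all__ = [
    "round_half_up",
    "summarize",
    "SummaryTable",
    "per_case_dsc_summary",
    "per_center_dsc_summary",
    "prescription_summary",
    "records_frame",
    "deviation_tally",
    "load_fixture",
    "load_constraints",
    "read_rtstruct",
    "read_rtdose",
    "write_rtstruct",
    "write_rtdose",
    "FIXTURE_FILES",
]

FIXTURE_FILES = {
    "table1": "table1_dsc.csv",
    "table2": "table2_rx.csv",
    "table3": "table3_ptv_dev.csv",
    "table4": "table4_oar_dev.csv",
    "centers": "centers.csv",
}


def round_half_up(x: float, dp: int) -> float:
    """Round half away from zero at ``dp`` decimals (printed-table rule,
    unlike numpy's banker's rounding)."""
    q = Decimal(10) ** -dp
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def summarize(values, round_dp: int = 3) -> tuple[float, float | None]:
    """Arithmetic mean and sample SD (n-1 denominator), half-up rounded.

    SD is undefined for a single value and reported as None.
    """
    v = np.asarray(list(values), dtype=float)
    if v.size == 0:
        raise ValueError("summarize requires at least one value")
    mean = round_half_up(float(v.mean()), round_dp)
    sd = None if v.size == 1 else round_half_up(float(v.std(ddof=1)), round_dp)
    return mean, sd


@dataclass
class SummaryTable:
    """Grouped mean (SD) statistics; one row per group."""

    df: pd.DataFrame  # grouping keys + columns mean, sd, n (sd empty for n=1)

    def __len__(self) -> int:
        return len(self.df)


def _grouped_summary(df: pd.DataFrame, keys: list[str], value: str,
                     round_dp: int = 3) -> SummaryTable:
    rows = []
    for group_keys, sub in df.groupby(keys, sort=True):
        if not isinstance(group_keys, tuple):
            group_keys = (group_keys,)
        mean, sd = summarize(sub[value], round_dp)
        rows.append(dict(zip(keys, group_keys)) | {"mean": mean, "sd": sd, "n": len(sub)})
    return SummaryTable(pd.DataFrame(rows))


def per_case_dsc_summary(table: AgreementTable, round_dp: int = 3) -> SummaryTable:
    """Mean (SD) DSC over centers, per (case, volume kind)."""
    return _grouped_summary(table.df, ["case_id", "volume_kind"], "dsc", round_dp)


def per_center_dsc_summary(table: AgreementTable, round_dp: int = 3) -> SummaryTable:
    """Mean (SD) DSC over cases, per (center, volume kind)."""
    return _grouped_summary(table.df, ["center_id", "volume_kind"], "dsc", round_dp)


def prescription_summary(rx_table: pd.DataFrame, round_dp: int = 3) -> SummaryTable:
    """Mean (SD) of total dose and fraction count across centers per target.

    Expects columns case_id, target_label, center_id, total_dose_gy,
    fractions (the shape of the packaged prescription fixture).
    """
    if rx_table.empty:
        raise ValueError("prescription table is empty")
    rows = []
    for (case, tgt), sub in rx_table.groupby(["case_id", "target_label"], sort=True):
        td_mean, td_sd = summarize(sub["total_dose_gy"], round_dp)
        fx_mean, fx_sd = summarize(sub["fractions"], round_dp)
        rows.append(
            {
                "case_id": case,
                "target_label": tgt,
                "td_mean": td_mean,
                "td_sd": td_sd,
                "fx_mean": fx_mean,
                "fx_sd": fx_sd,
                "n": len(sub),
            }
        )
    return SummaryTable(pd.DataFrame(rows))


def records_frame(reports: list[ComplianceReport]) -> pd.DataFrame:
    """Flatten compliance reports into one row per evaluated constraint."""
    rows = []
    for rep in reports:
        for rec in rep.records:
            rows.append(
                {
                    "center_id": rec.center_id,
                    "case_id": rec.case_id,
                    "target_label": rec.target_or_oar_label,
                    "metric": rec.metric,
                    "observed_value": rec.observed_value,
                    "limit": rec.limit,
                    "grade": rec.grade.value.lower(),
                    "exempted": rec.exempted,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "center_id", "case_id", "target_label", "metric",
            "observed_value", "limit", "grade", "exempted",
        ],
    )


def deviation_tally(
    records: pd.DataFrame | list[ComplianceReport],
    by: tuple[str, ...] = ("case_id", "metric"),
    centers: list[str] | None = None,
    include_exempted: bool = False,
) -> pd.DataFrame:
    """Count centers with >= 1 non-exempted deviation per stratum.

    ``records`` is either a list of compliance reports or a flat frame
    with columns center_id, case_id, metric, grade (and optionally
    exempted).  ``centers`` fixes the denominator (defaults to all
    centers present); the percentage is 100*count/denominator, half-up
    at 1 decimal.
    """
    if not isinstance(records, pd.DataFrame):
        records = records_frame(records)
    df = records.copy()
    if df.empty:
        raise ValueError("no records to tally")
    if centers is None:
        centers = sorted(df["center_id"].unique())
    if len(centers) == 0:
        raise ValueError("empty center denominator")
    df = df[df["center_id"].isin(centers)]
    dev = df[df["grade"].astype(str).str.lower() != "none"]
    if "exempted" in dev.columns and not include_exempted:
        dev = dev[~dev["exempted"].astype(bool)]
    rows = []
    for group_keys, sub in dev.groupby(list(by), sort=True):
        if not isinstance(group_keys, tuple):
            group_keys = (group_keys,)
        n_hit = sub["center_id"].nunique()
        rows.append(
            dict(zip(by, group_keys))
            | {
                "n_centers_deviating": n_hit,
                "n_centers": len(centers),
                "pct": round_half_up(100.0 * n_hit / len(centers), 1),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[*by, "n_centers_deviating", "n_centers", "pct"],
    )


# ---------------------------------------------------------------------------
# packaged fixtures and configuration


def _fixture_path(name: str):
    fname = FIXTURE_FILES.get(name, name)
    return resources.files("sabrqa.fixtures").joinpath(fname)


def load_fixture(name: str) -> pd.DataFrame:
    """Load a packaged fixture table ('table1' ... 'table4', 'centers')."""
    path = _fixture_path(name)
    with path.open("r") as fh:
        return pd.read_csv(fh, comment="#")


def load_constraints(path: str | Path | None = None) -> list[ConstraintSpec]:
    """Load a constraint table from YAML (package defaults when path is None)."""
    if path is None:
        with _fixture_path("default_constraints.yaml").open("r") as fh:
            doc = yaml.safe_load(fh)
    else:
        doc = yaml.safe_load(Path(path).read_text())
    out = []
    for entry in doc["constraints"]:
        out.append(
            ConstraintSpec(
                structure=entry["structure"],
                metric=entry["metric"],
                limit=float(entry["limit"]),
                limit_sense=entry.get("limit_sense", "max"),
                tolerance_type=entry.get("tolerance_type", "dose_gy"),
                parameter=(
                    float(entry["parameter"]) if "parameter" in entry else None
                ),
                margin_override=(
                    float(entry["margin_override"])
                    if "margin_override" in entry
                    else None
                ),
                name=entry.get("name", ""),
            )
        )
    return out


def agreement_to_csv(table: AgreementTable, path: str | Path) -> None:
    table.df.to_csv(path, index=False, float_format="%.3f")


def dvh_to_csv(curve, path: str | Path) -> None:
    pd.DataFrame(
        {
            "dose_gy": curve.dose_axis_gy,
            "volume_cc": curve.cumulative_volume_cc,
            "volume_pct": curve.cumulative_volume_pct,
        }
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# DICOM RTSTRUCT / RTDOSE

_RTSTRUCT_UID = "1.2.840.10008.5.1.4.1.1.481.3"
_RTDOSE_UID = "1.2.840.10008.5.1.4.1.1.481.2"


def _new_dataset(sop_class_uid: str):
    import pydicom
    from pydicom.dataset import FileDataset, FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian, generate_uid

    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = sop_class_uid
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    ds = FileDataset(None, {}, file_meta=meta, preamble=b"\x00" * 128)
    ds.SOPClassUID = sop_class_uid
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = "RTSTRUCT" if sop_class_uid == _RTSTRUCT_UID else "RTDOSE"
    ds.PatientName = "phantom"
    ds.PatientID = "phantom"
    ds.FrameOfReferenceUID = generate_uid()
    return ds


def write_rtdose(dose: DoseDistribution, path: str | Path) -> None:
    """Write a minimal single-series RTDOSE file (axial frames along z)."""
    ds = _new_dataset(_RTDOSE_UID)
    grid = dose.grid
    nx, ny, nz = grid.shape
    ds.Rows = ny
    ds.Columns = nx
    ds.NumberOfFrames = nz
    ds.PixelSpacing = [grid.spacing[1], grid.spacing[0]]  # row (y), col (x)
    ds.ImagePositionPatient = list(grid.origin)
    ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
    ds.GridFrameOffsetVector = [grid.spacing[2] * k for k in range(nz)]
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.BitsAllocated = 32
    ds.BitsStored = 32
    ds.HighBit = 31
    ds.PixelRepresentation = 0
    ds.DoseUnits = "GY"
    ds.DoseType = "PHYSICAL"
    ds.DoseSummationType = "PLAN"
    dmax = float(dose.dose_gy.max())
    scaling = (dmax / (2**31 - 1)) if dmax > 0 else 1.0
    ds.DoseGridScaling = scaling
    pixels = np.round(dose.dose_gy / scaling).astype(np.uint32)
    ds.PixelData = np.ascontiguousarray(pixels.transpose(2, 1, 0)).tobytes()
    ds.save_as(str(path), enforce_file_format=True)


def read_rtdose(path: str | Path, grid: VoxelGrid) -> DoseDistribution:
    """Read an RTDOSE file and resample it trilinearly onto ``grid``."""
    import pydicom
    from scipy import ndimage

    ds = pydicom.dcmread(str(path))
    if ds.SOPClassUID != _RTDOSE_UID:
        raise ValueError(f"not an RTDOSE file: {path}")
    scaling = float(getattr(ds, "DoseGridScaling", 1.0))
    arr = ds.pixel_array.astype(float) * scaling  # (frames=z, rows=y, cols=x)
    arr = arr.transpose(2, 1, 0)  # -> (x, y, z)
    src_origin = np.array([float(v) for v in ds.ImagePositionPatient])
    offsets = np.array([float(v) for v in ds.GridFrameOffsetVector])
    dz = float(offsets[1] - offsets[0]) if len(offsets) > 1 else 1.0
    src_spacing = np.array(
        [float(ds.PixelSpacing[1]), float(ds.PixelSpacing[0]), dz]
    )
    tx, ty, tz = grid.coordinates_mm()
    X, Y, Z = np.meshgrid(tx, ty, tz, indexing="ij")
    coords = [
        (X - src_origin[0]) / src_spacing[0],
        (Y - src_origin[1]) / src_spacing[1],
        (Z - src_origin[2]) / src_spacing[2],
    ]
    out = ndimage.map_coordinates(arr, coords, order=1, mode="nearest")
    return DoseDistribution(grid=grid, dose_gy=np.clip(out, 0.0, None))


def write_rtstruct(masks: list[StructureMask], path: str | Path) -> None:
    """Write a minimal RTSTRUCT: per-slice closed contours of each mask."""
    from pydicom.dataset import Dataset
    from skimage import measure

    if not masks:
        raise ValueError("no masks to write")
    grid = masks[0].grid
    ds = _new_dataset(_RTSTRUCT_UID)
    ds.StructureSetLabel = "sabrqa"
    ds.StructureSetROISequence = []
    ds.ROIContourSequence = []
    ds.RTROIObservationsSequence = []
    for num, mask in enumerate(masks, start=1):
        if mask.grid != grid:
            raise ValueError("all masks must share one grid")
        roi = Dataset()
        roi.ROINumber = num
        roi.ROIName = mask.label or f"ROI{num}"
        roi.ReferencedFrameOfReferenceUID = ds.FrameOfReferenceUID
        roi.ROIGenerationAlgorithm = "AUTOMATIC"
        ds.StructureSetROISequence.append(roi)

        rc = Dataset()
        rc.ReferencedROINumber = num
        rc.ContourSequence = []
        ox, oy, oz = grid.origin
        dx, dy, dz = grid.spacing
        for k in range(grid.shape[2]):
            sl = mask.voxels[:, :, k]  # (x, y)
            if not sl.any():
                continue
            padded = np.pad(sl.astype(float), 1)
            for contour in measure.find_contours(padded, 0.5):
                pts = contour - 1.0  # undo pad; columns are (x_idx, y_idx)
                c = Dataset()
                c.ContourGeometricType = "CLOSED_PLANAR"
                data = []
                for xi, yi in pts:
                    data += [ox + xi * dx, oy + yi * dy, oz + k * dz]
                c.NumberOfContourPoints = len(pts)
                c.ContourData = [f"{v:.4f}" for v in data]
                rc.ContourSequence.append(c)
        ds.ROIContourSequence.append(rc)
    ds.save_as(str(path), enforce_file_format=True)


def read_rtstruct(
    path: str | Path,
    grid: VoxelGrid,
    roi_names: list[str] | None = None,
    role: StructureRole = StructureRole.GTV,
) -> list[StructureMask]:
    """Rasterize RTSTRUCT contours slice-wise onto ``grid``.

    Each planar contour is converted to a polygon mask (even-odd rule:
    contours on one slice are XOR-combined, so holes subtract).  An ROI
    with an empty contour sequence yields an empty mask with a warning.
    """
    import pydicom
    from skimage.draw import polygon2mask

    ds = pydicom.dcmread(str(path))
    if ds.SOPClassUID != _RTSTRUCT_UID:
        raise ValueError(f"not an RTSTRUCT file: {path}")
    names = {
        int(r.ROINumber): str(r.ROIName) for r in ds.StructureSetROISequence
    }
    if roi_names is not None:
        missing = set(roi_names) - set(names.values())
        if missing:
            raise ValueError(f"ROI names not present in file: {sorted(missing)}")
    ox, oy, oz = grid.origin
    dx, dy, dz = grid.spacing
    nx, ny, nz = grid.shape
    out = []
    for rc in ds.ROIContourSequence:
        name = names.get(int(rc.ReferencedROINumber), "")
        if roi_names is not None and name not in roi_names:
            continue
        voxels = np.zeros(grid.shape, dtype=bool)
        contours = list(getattr(rc, "ContourSequence", []))
        if not contours:
            warnings.warn(
                f"ROI '{name}' has no contours; returning empty mask",
                UserWarning, stacklevel=2,
            )
        for c in contours:
            data = np.asarray([float(v) for v in c.ContourData]).reshape(-1, 3)
            k = int(round((data[0, 2] - oz) / dz))
            if not 0 <= k < nz:
                continue
            poly_xy = np.column_stack(
                [(data[:, 0] - ox) / dx, (data[:, 1] - oy) / dy]
            )
            sl = polygon2mask((nx, ny), poly_xy)
            voxels[:, :, k] ^= sl  # even-odd rule
        out.append(StructureMask(grid=grid, voxels=voxels, label=name, role=role))
    return out
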