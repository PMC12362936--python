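"""Dose-volume computations for SABR plan review.

Implements the DVH queries (Dmax, dose-to-hottest-volume, volume-at-dose),
PTV coverage, and the SBRT conformity/fall-off indices:

* R50%  — volume of the half-prescription isodose cloud divided by the
  PTV volume (moderate-dose spillage);
* D2cm  — maximum dose at >= 2 cm from the PTV surface, as % of the
  prescription (dose fall-off);
* high-dose spillage — volume above 105% of prescription outside the
  PTV, as % of PTV volume;

plus PTV-EVAL construction (PTV minus expanded organs at risk), used when
target coverage must be judged without penalizing OAR sparing.

All metrics sample the dose at mask voxel centers on a single common
lattice; distances are Euclidean in 3D with anisotropic spacing
respected (scipy's exact distance transform).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core import (
    DoseDistribution,
    GridMismatchError,
    Prescription,
    StructureMask,
    StructureRole,
    union_mask,
)

__all__ = [
    "DVHCurve",
    "dvh",
    "d_max",
    "d_cc",
    "v_gy",
    "coverage_pct",
    "r50",
    "d2cm_pct",
    "high_dose_spillage_pct",
    "ptv_eval",
    "distance_from_mask_mm",
]


def _require_dose_on_grid(mask: StructureMask, dose: DoseDistribution) -> None:
    if mask.grid != dose.grid:
        raise GridMismatchError(
            f"structure '{mask.label}' and dose are on different grids"
        )


def _nonempty(mask: StructureMask, what: str) -> None:
    if mask.is_empty:
        raise ValueError(f"{what} requires a non-empty structure ('{mask.label}')")


@dataclass(frozen=True)
class DVHCurve:
    """Cumulative dose-volume histogram of one structure.

    ``cumulative_volume_cc[i]`` is the structure volume receiving at
    least ``dose_axis_gy[i]``; the curve starts at the full structure
    volume at 0 Gy and is non-increasing.
    """

    structure_label: str
    dose_axis_gy: np.ndarray
    cumulative_volume_cc: np.ndarray
    structure_volume_cc: float

    @property
    def cumulative_volume_pct(self) -> np.ndarray:
        return 100.0 * self.cumulative_volume_cc / self.structure_volume_cc


def dvh(mask: StructureMask, dose: DoseDistribution, bin_gy: float = 0.1) -> DVHCurve:
    """Cumulative DVH from the voxel doses inside ``mask``."""
    _require_dose_on_grid(mask, dose)
    _nonempty(mask, "DVH")
    if bin_gy <= 0:
        raise ValueError("bin_gy must be > 0")
    doses = dose.dose_gy[mask.voxels]
    top = float(doses.max())
    n_bins = int(np.ceil(top / bin_gy)) + 1
    axis = np.arange(n_bins + 1) * bin_gy
    vv = mask.grid.voxel_volume_cc
    # volume receiving >= each axis level
    counts = np.count_nonzero(doses[None, :] >= axis[:, None], axis=1)
    return DVHCurve(
        structure_label=mask.label,
        dose_axis_gy=axis,
        cumulative_volume_cc=counts * vv,
        structure_volume_cc=doses.size * vv,
    )


def d_max(mask: StructureMask, dose: DoseDistribution) -> float:
    """Maximum voxel dose inside the structure, Gy."""
    _require_dose_on_grid(mask, dose)
    _nonempty(mask, "Dmax")
    return float(dose.dose_gy[mask.voxels].max())


def d_cc(mask: StructureMask, dose: DoseDistribution, v_cc: float) -> float:
    """Minimum dose received by the hottest ``v_cc`` cc of the structure.

    Converges to Dmax as v_cc -> 0; errors if v_cc exceeds the structure
    volume.
    """
    _require_dose_on_grid(mask, dose)
    _nonempty(mask, "D_cc")
    if v_cc < 0:
        raise ValueError("v_cc must be >= 0")
    vol = mask.volume_cc
    if v_cc > vol:
        raise ValueError(
            f"requested hottest volume {v_cc:g} cc exceeds structure volume {vol:g} cc"
        )
    doses = np.sort(dose.dose_gy[mask.voxels])[::-1]
    n = max(1, int(np.ceil(v_cc / mask.grid.voxel_volume_cc)))
    return float(doses[min(n, doses.size) - 1])


def v_gy(mask: StructureMask, dose: DoseDistribution, d_gy: float) -> float:
    """Structure volume (cc) receiving at least ``d_gy`` Gy."""
    _require_dose_on_grid(mask, dose)
    _nonempty(mask, "V_Gy")
    n = int(np.count_nonzero(dose.dose_gy[mask.voxels] >= d_gy))
    return n * mask.grid.voxel_volume_cc


def coverage_pct(ptv: StructureMask, dose: DoseDistribution, rx: Prescription) -> float:
    """Percent of the PTV receiving at least the prescribed total dose."""
    _require_dose_on_grid(ptv, dose)
    _nonempty(ptv, "coverage")
    covered = int(np.count_nonzero(dose.dose_gy[ptv.voxels] >= rx.total_dose_gy))
    return 100.0 * covered / int(ptv.voxels.sum())


def _union_ptv(ptvs: list[StructureMask]) -> StructureMask:
    if not ptvs:
        raise ValueError("at least one PTV required")
    u = union_mask(ptvs)
    if u.is_empty:
        raise ValueError("union PTV has zero volume")
    return u


def r50(ptvs: list[StructureMask], dose: DoseDistribution, rx: Prescription) -> float:
    """R50%: volume of the 50%-prescription isodose cloud over PTV volume.

    When one prescription covers several PTVs, the denominator is the
    union of those PTVs and the numerator the full isodose cloud — this
    is what makes R50 hard to meet for multi-target plans and motivates
    the exemption policy.
    """
    u = _union_ptv(ptvs)
    _require_dose_on_grid(u, dose)
    iso = int(np.count_nonzero(dose.dose_gy >= 0.5 * rx.total_dose_gy))
    return iso / int(u.voxels.sum())


def distance_from_mask_mm(mask: StructureMask) -> np.ndarray:
    """Euclidean distance (mm) from each voxel center to the structure,
    0 inside; anisotropic spacing respected."""
    if mask.is_empty:
        raise ValueError("distance transform of an empty mask is undefined")
    return ndimage.distance_transform_edt(~mask.voxels, sampling=mask.grid.spacing)


def d2cm_pct(
    ptvs: list[StructureMask],
    dose: DoseDistribution,
    rx: Prescription,
    shell_mm: float = 20.0,
) -> float:
    """Maximum dose at >= ``shell_mm`` from the union-PTV surface, % of TD.

    Distance is taken from a 3D Euclidean distance transform of the PTV
    complement.  The grid must be fine enough (spacing <= shell_mm / 5)
    and large enough to contain voxels at the shell distance.
    """
    u = _union_ptv(ptvs)
    _require_dose_on_grid(u, dose)
    if max(u.grid.spacing) > shell_mm / 5.0:
        raise ValueError(
            f"grid spacing {u.grid.spacing} too coarse for a {shell_mm} mm shell "
            f"(need <= {shell_mm / 5:g} mm)"
        )
    dist = distance_from_mask_mm(u)
    far = dist >= shell_mm
    if not far.any():
        raise ValueError(
            f"no voxel lies >= {shell_mm} mm from the PTV; grid too small"
        )
    return 100.0 * float(dose.dose_gy[far].max()) / rx.total_dose_gy


def high_dose_spillage_pct(
    ptvs: list[StructureMask],
    dose: DoseDistribution,
    rx: Prescription,
    threshold_pct: float = 105.0,
) -> float:
    """Volume above ``threshold_pct``% of TD outside the union PTV,
    as a percentage of the union-PTV volume."""
    u = _union_ptv(ptvs)
    _require_dose_on_grid(u, dose)
    hot = (dose.dose_gy >= threshold_pct / 100.0 * rx.total_dose_gy) & ~u.voxels
    return 100.0 * int(np.count_nonzero(hot)) / int(u.voxels.sum())


def ptv_eval(
    ptv: StructureMask,
    oars: list[StructureMask],
    margin_mm: float = 0.0,
) -> StructureMask:
    """PTV-EVAL: the PTV minus the union of OARs expanded by ``margin_mm``.

    Lets coverage be judged on the part of the target that can actually
    be dosed without violating OAR constraints.  An empty result is
    returned with a warning (coverage is then undefined).
    """
    if margin_mm < 0:
        raise ValueError("margin_mm must be >= 0")
    voxels = ptv.voxels.copy()
    if oars:
        oar_union = union_mask(oars)
        if oar_union.grid != ptv.grid:
            raise GridMismatchError("PTV and OARs are on different grids")
        if not oar_union.is_empty:
            if margin_mm > 0:
                expanded = (
                    ndimage.distance_transform_edt(
                        ~oar_union.voxels, sampling=ptv.grid.spacing
                    )
                    <= margin_mm
                )
            else:
                expanded = oar_union.voxels
            voxels &= ~expanded
    out = StructureMask(
        grid=ptv.grid, voxels=voxels,
        label=f"{ptv.label}-EVAL" if ptv.label else "PTV-EVAL",
        role=StructureRole.PTV_EVAL,
    )
    if out.is_empty:
        warnings.warn(
            f"PTV-EVAL of '{ptv.label}' is empty (OARs cover the whole PTV); "
            "coverage is undefined",
            UserWarning, stacklevel=2,
        )
    return out
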