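"""Domain types shared by every stage of the dummy-run QA pipeline.

All geometry lives on axis-aligned voxel lattices: a :class:`VoxelGrid`
carries the shape, physical spacing (mm) and origin (mm) of the lattice,
and structures (GTV, PTV, PTV-EVAL, organs at risk) are binary occupancy
arrays on that lattice.  Dose is a non-negative scalar field on the same
lattice.  Volumes are reported in cc, doses in Gy, percentages on the
0-100 scale throughout.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "StructureRole",
    "DeviationGrade",
    "VoxelGrid",
    "StructureMask",
    "DoseDistribution",
    "Prescription",
    "ContourSubmission",
    "PlanSubmission",
    "ConstraintMetric",
    "ConstraintSpec",
    "DeviationRecord",
    "AgreementTable",
    "GridMismatchError",
    "volume_cc",
    "union_mask",
]


class GridMismatchError(ValueError):
    """Raised when an operation mixes masks or doses on different lattices."""


class StructureRole(str, enum.Enum):
    GTV = "GTV"
    PTV = "PTV"
    PTV_EVAL = "PTV_EVAL"
    OAR = "OAR"
    DOSE_REGION = "DOSE_REGION"


class DeviationGrade(str, enum.Enum):
    NONE = "NONE"
    MINOR = "MINOR"
    MAJOR = "MAJOR"


@dataclass(frozen=True)
class VoxelGrid:
    """Axis-aligned voxel lattice: index (i, j, k) maps to physical
    position ``origin + index * spacing`` (mm), axes ordered (x, y, z).
    """

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))
        if len(self.shape) != 3 or len(self.spacing) != 3 or len(self.origin) != 3:
            raise ValueError("grid shape, spacing and origin must be 3-vectors")
        if any(s < 1 for s in self.shape):
            raise ValueError(f"grid shape components must be >= 1, got {self.shape}")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"grid spacings must be > 0 mm, got {self.spacing}")

    @property
    def voxel_volume_cc(self) -> float:
        """Volume of one voxel in cc (1 cc = 1000 mm^3)."""
        return float(np.prod(self.spacing)) / 1000.0

    def coordinates_mm(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Physical voxel-center coordinate vectors along each axis."""
        return tuple(
            self.origin[a] + self.spacing[a] * np.arange(self.shape[a])
            for a in range(3)
        )


@dataclass
class StructureMask:
    """Binary occupancy of one structure on a :class:`VoxelGrid`."""

    grid: VoxelGrid
    voxels: np.ndarray
    label: str = ""
    role: StructureRole = StructureRole.GTV

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=bool)
        if self.voxels.shape != self.grid.shape:
            raise ValueError(
                f"mask '{self.label}' has array shape {self.voxels.shape} "
                f"but grid shape {self.grid.shape}"
            )
        self.role = StructureRole(self.role)

    @property
    def volume_cc(self) -> float:
        return volume_cc(self)

    @property
    def is_empty(self) -> bool:
        return not bool(self.voxels.any())

    def copy(self, **changes) -> "StructureMask":
        out = replace(self, **changes)
        out.voxels = out.voxels.copy()
        return out


@dataclass
class DoseDistribution:
    """Planned absorbed dose (Gy) on a :class:`VoxelGrid`."""

    grid: VoxelGrid
    dose_gy: np.ndarray

    def __post_init__(self) -> None:
        self.dose_gy = np.asarray(self.dose_gy, dtype=float)
        if self.dose_gy.shape != self.grid.shape:
            raise ValueError(
                f"dose array shape {self.dose_gy.shape} != grid shape {self.grid.shape}"
            )
        if not np.all(np.isfinite(self.dose_gy)):
            raise ValueError("dose values must be finite")
        if self.dose_gy.min() < 0:
            raise ValueError("dose values must be non-negative")


@dataclass(frozen=True)
class Prescription:
    """Total dose (Gy) in a number of fractions for one target volume."""

    target_label: str
    total_dose_gy: float
    fractions: int

    def __post_init__(self) -> None:
        if self.total_dose_gy <= 0:
            raise ValueError("total dose must be > 0 Gy")
        if self.fractions < 1:
            raise ValueError("fraction count must be >= 1")

    @property
    def dose_per_fraction_gy(self) -> float:
        return self.total_dose_gy / self.fractions


def _check_common_grid(masks: Iterable[StructureMask]) -> VoxelGrid:
    grid = None
    for m in masks:
        if grid is None:
            grid = m.grid
        elif m.grid != grid:
            raise GridMismatchError(
                f"mask '{m.label}' is on grid {m.grid.shape}@{m.grid.spacing}, "
                f"expected {grid.shape}@{grid.spacing}"
            )
    if grid is None:
        raise ValueError("at least one mask required")
    return grid


@dataclass
class ContourSubmission:
    """One institution's delineation of one case (phase 1): its GTV and
    PTV masks.  Lists may be empty — a center may have missed a lesion.
    """

    center_id: str
    case_id: str
    gtvs: list[StructureMask] = field(default_factory=list)
    ptvs: list[StructureMask] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.gtvs or self.ptvs:
            _check_common_grid([*self.gtvs, *self.ptvs])


@dataclass
class PlanSubmission:
    """One institution's treatment plan for one case (phase 2)."""

    center_id: str
    case_id: str
    dose: DoseDistribution
    prescriptions: list[Prescription]
    structures: list[StructureMask]
    uses_ptv_eval: bool = False

    def __post_init__(self) -> None:
        for rx in self.prescriptions:
            self.resolve_target(rx.target_label)

    def resolve_target(self, label: str) -> StructureMask:
        """Resolve a prescription target label to exactly one PTV or
        PTV-EVAL mask."""
        hits = [
            s
            for s in self.structures
            if s.label == label and s.role in (StructureRole.PTV, StructureRole.PTV_EVAL)
        ]
        if len(hits) != 1:
            raise ValueError(
                f"prescription target '{label}' resolves to {len(hits)} "
                f"PTV/PTV_EVAL masks (need exactly 1)"
            )
        return hits[0]

    def find_structures(self, *, role: StructureRole | None = None,
                        label: str | None = None) -> list[StructureMask]:
        out = list(self.structures)
        if role is not None:
            out = [s for s in out if s.role == role]
        if label is not None:
            out = [s for s in out if s.label == label]
        return out


class ConstraintMetric(str, enum.Enum):
    DMAX = "DMAX"                                # max dose in structure, Gy
    D_CC = "D_CC"                                # min dose to hottest v cc, Gy
    V_GY = "V_GY"                                # volume receiving >= d Gy, cc
    COVERAGE_PCT = "COVERAGE_PCT"                # % of PTV receiving >= TD
    R50 = "R50"                                  # 50%-isodose volume / PTV volume
    D2CM_PCT = "D2CM_PCT"                        # max dose >= 2 cm from PTV, % TD
    HIGH_DOSE_SPILLAGE_PCT = "HIGH_DOSE_SPILLAGE_PCT"  # hot volume outside PTV, % PTV


class ToleranceType(str, enum.Enum):
    DOSE_GY = "dose_gy"
    VOLUME_PCT = "volume_pct"


_PARAM_REQUIRED = {ConstraintMetric.D_CC, ConstraintMetric.V_GY}


@dataclass(frozen=True)
class ConstraintSpec:
    """One protocol rule: a metric on a structure with a limit.

    ``parameter`` carries the cc value for D_CC or the Gy value for V_GY.
    ``margin_override`` replaces the default minor/major tolerance margin
    (1 Gy for dose-type, 3 percentage points or 3% relative for
    volume-type limits) for rules whose protocol states its own band.
    """

    structure: str                       # role name ("PTV", "OAR") or label
    metric: ConstraintMetric
    limit: float
    limit_sense: str = "max"             # "max" or "min"
    tolerance_type: ToleranceType = ToleranceType.DOSE_GY
    parameter: float | None = None
    margin_override: float | None = None
    name: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "metric", ConstraintMetric(self.metric))
        object.__setattr__(self, "tolerance_type", ToleranceType(self.tolerance_type))
        if not np.isfinite(self.limit):
            raise ValueError("constraint limit must be finite")
        if self.limit_sense not in ("max", "min"):
            raise ValueError("limit_sense must be 'max' or 'min'")
        if (self.metric in _PARAM_REQUIRED) != (self.parameter is not None):
            raise ValueError(
                f"metric {self.metric.value} "
                f"{'requires' if self.metric in _PARAM_REQUIRED else 'does not take'} "
                f"a parameter"
            )


@dataclass
class DeviationRecord:
    """A graded evaluation of one constraint for one plan.

    ``exempted`` records are kept in reports but excluded from tallies
    (multi-target plans are exempt from moderate-dose spillage rules).
    """

    center_id: str
    case_id: str
    target_or_oar_label: str
    metric: str
    observed_value: float
    limit: float
    grade: DeviationGrade
    exempted: bool = False
    exemption_reason: str = ""

    def __post_init__(self) -> None:
        self.grade = DeviationGrade(self.grade)
        if self.grade == DeviationGrade.NONE and self.exempted:
            raise ValueError("a compliant (NONE) record cannot be exempted")


_AGREEMENT_COLUMNS = ["case_id", "volume_kind", "center_id", "dsc", "ci_low", "ci_high"]


@dataclass
class AgreementTable:
    """Per-case x per-center DSC values with bootstrap CIs.

    Thin validated wrapper over a DataFrame with columns
    ``case_id, volume_kind, center_id, dsc, ci_low, ci_high``
    (``volume_kind`` in {"GTV", "PTV"}).  Percentile CIs may exclude the
    point estimate, so only ``ci_low <= ci_high`` and ``0 <= dsc <= 1``
    are enforced.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in _AGREEMENT_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"agreement table missing columns {missing}")
        self.df = self.df[_AGREEMENT_COLUMNS].reset_index(drop=True)
        bad_kind = set(self.df["volume_kind"]) - {"GTV", "PTV"}
        if bad_kind:
            raise ValueError(f"unknown volume_kind values {sorted(bad_kind)}")
        dsc = self.df["dsc"].to_numpy(float)
        if np.any((dsc < 0) | (dsc > 1)):
            raise ValueError("DSC values must lie in [0, 1]")
        ci = self.df[["ci_low", "ci_high"]].to_numpy(float)
        finite = np.all(np.isfinite(ci), axis=1)
        if np.any(ci[finite, 0] > ci[finite, 1]):
            raise ValueError("ci_low must not exceed ci_high")

    def __len__(self) -> int:
        return len(self.df)


def volume_cc(mask: StructureMask) -> float:
    """Structure volume in cc: occupied-voxel count times voxel volume."""
    return int(mask.voxels.sum()) * mask.grid.voxel_volume_cc


def union_mask(masks: Sequence[StructureMask], label: str | None = None) -> StructureMask:
    """Voxelwise OR of masks sharing one grid ("sum" of volumes).

    The role is preserved when homogeneous across inputs, else falls back
    to DOSE_REGION.  Raises :class:`GridMismatchError` naming the first
    offending mask.
    """
    if not masks:
        raise ValueError("union_mask requires a non-empty mask list")
    grid = _check_common_grid(masks)
    voxels = np.zeros(grid.shape, dtype=bool)
    for m in masks:
        voxels |= m.voxels
    roles = {m.role for m in masks}
    role = roles.pop() if len(roles) == 1 else StructureRole.DOSE_REGION
    if label is None:
        label = "+".join(m.label for m in masks) if len(masks) > 1 else masks[0].label
    return StructureMask(grid=grid, voxels=voxels, label=label, role=role)
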