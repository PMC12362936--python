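"""Synthetic dummy-run cohorts with known ground truth.

The clinical contours and doses behind a multicenter dummy run are never
public, so this module generates the same statistical structure on
phantoms: four case archetypes spanning the delineation difficulty range
(one large nodal target, five small lung nodules, a thin curved
sub-diaphragmatic rind, and multiple peritoneal blobs abutting a
bowel-like organ at risk), institutional contour variants whose Dice
against the reference is dialed to a target value, and dose fields with
an analytically known plateau and linear fall-off so that R50%, D2cm and
Dmax have closed-form expectations.

Everything is deterministic per seed (bitwise on masks, elementwise on
doses).
"""

from __future__ import annotations

import enum
import string
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .core import (
    ContourSubmission,
    DoseDistribution,
    PlanSubmission,
    Prescription,
    StructureMask,
    StructureRole,
    VoxelGrid,
    union_mask,
)
from .agreement import dice

__all__ = [
    "ArchetypeKind",
    "CaseArchetype",
    "PerturbationConfig",
    "CalibrationError",
    "default_grid",
    "make_case",
    "perturb_contour",
    "synth_dose",
    "make_cohort",
]

DEFAULT_MARGIN_MM = 5.0  # isotropic GTV -> PTV expansion


class ArchetypeKind(str, enum.Enum):
    NODAL = "NODAL"                      # one ~165 cc retroperitoneal nodal PTV
    LUNG_MULTI = "LUNG_MULTI"            # five 3-10 cc lung nodules
    LIVER_RIND = "LIVER_RIND"            # thin curved sub-diaphragmatic shell
    PERITONEAL_MULTI = "PERITONEAL_MULTI"  # 2 small + 1 large blob near bowel


@dataclass
class CaseArchetype:
    """Reference anatomy and prescription for one dummy-run case."""

    case_id: str
    description: ArchetypeKind
    grid: VoxelGrid
    reference_gtvs: list[StructureMask]
    reference_ptvs: list[StructureMask]
    oars: list[StructureMask] = field(default_factory=list)
    default_prescription: Prescription = Prescription("PTV", 35.0, 10)

    def __post_init__(self) -> None:
        if len(self.reference_gtvs) != len(self.reference_ptvs):
            raise ValueError("each GTV must have a paired PTV")
        for g, p in zip(self.reference_gtvs, self.reference_ptvs):
            if (g.voxels & ~p.voxels).any():
                raise ValueError(
                    f"PTV '{p.label}' is not a superset of its GTV '{g.label}'"
                )


@dataclass(frozen=True)
class PerturbationConfig:
    """Controls :func:`perturb_contour`.

    ``target_dsc`` is the Dice the output should achieve against the
    reference (tolerance +-0.05 guaranteed, +-0.02 targeted internally);
    ``deformation_scale_mm`` the correlation length of the smooth random
    displacement field.
    """

    target_dsc: float
    seed: int
    deformation_scale_mm: float = 8.0
    max_bisection_iters: int = 30

    def __post_init__(self) -> None:
        if not 0.0 <= self.target_dsc <= 1.0:
            raise ValueError("target_dsc must lie in [0, 1]")
        if self.deformation_scale_mm <= 0:
            raise ValueError("deformation_scale_mm must be > 0")


class CalibrationError(RuntimeError):
    """Bisection could not reach the requested Dice; carries the best
    achieved value."""

    def __init__(self, target: float, achieved: float):
        super().__init__(
            f"could not reach target DSC {target:.3f}; best achieved {achieved:.3f}"
        )
        self.target = target
        self.achieved = achieved


def default_grid(n: int = 128, spacing_mm: float = 2.0) -> VoxelGrid:
    """Desk-scale lattice: 128^3 voxels at 2 mm isotropic by default."""
    return VoxelGrid(shape=(n, n, n), spacing=(spacing_mm,) * 3)


# ---------------------------------------------------------------------------
# geometric primitives

def _coords_mm(grid: VoxelGrid) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    x, y, z = grid.coordinates_mm()
    return np.meshgrid(x, y, z, indexing="ij")


def _center_mm(grid: VoxelGrid) -> np.ndarray:
    return np.array(
        [grid.origin[a] + grid.spacing[a] * (grid.shape[a] - 1) / 2 for a in range(3)]
    )


def _ellipsoid(grid: VoxelGrid, center: np.ndarray, radii: np.ndarray) -> np.ndarray:
    X, Y, Z = _coords_mm(grid)
    return (
        ((X - center[0]) / radii[0]) ** 2
        + ((Y - center[1]) / radii[1]) ** 2
        + ((Z - center[2]) / radii[2]) ** 2
    ) <= 1.0


def _dilate_mm(voxels: np.ndarray, grid: VoxelGrid, margin_mm: float) -> np.ndarray:
    if margin_mm <= 0 or not voxels.any():
        return voxels.copy()
    dist = ndimage.distance_transform_edt(~voxels, sampling=grid.spacing)
    return dist <= margin_mm


def _erode_mm(voxels: np.ndarray, grid: VoxelGrid, margin_mm: float) -> np.ndarray:
    if margin_mm <= 0 or not voxels.any():
        return voxels.copy()
    dist = ndimage.distance_transform_edt(voxels, sampling=grid.spacing)
    return dist > margin_mm


def _sphere_radius_for_cc(volume_cc: float) -> float:
    return (3.0 * volume_cc * 1000.0 / (4.0 * np.pi)) ** (1.0 / 3.0)


def _extent_scale(grid: VoxelGrid) -> float:
    """Positional scale factor relative to the default 254 mm extent, so
    peripheral lesions stay inside smaller grids (radii are absolute)."""
    extent = min(grid.spacing[a] * (grid.shape[a] - 1) for a in range(3))
    return min(1.0, extent / 254.0)


def _gtv_radius(ptv_radius: float, margin_mm: float, grid: VoxelGrid) -> float:
    """GTV radius whose voxelized, margin-dilated result hits the PTV
    target volume; adds a half-voxel-scale compensation for the
    rasterization deficit of small structures."""
    h = float(np.mean(grid.spacing))
    return max(ptv_radius - margin_mm, 0.75 * h) + 0.4 * h


def _mask(grid, voxels, label, role) -> StructureMask:
    return StructureMask(grid=grid, voxels=voxels, label=label, role=role)


# ---------------------------------------------------------------------------
# case archetypes

# nominal PTV volumes (cc) per archetype, the scale the generator aims at
NOMINAL_PTV_CC: dict[ArchetypeKind, tuple[float, ...]] = {
    ArchetypeKind.NODAL: (165.0,),
    ArchetypeKind.LUNG_MULTI: (3.0, 10.5, 7.5, 5.0, 6.5),
    ArchetypeKind.LIVER_RIND: (49.0,),
    ArchetypeKind.PERITONEAL_MULTI: (16.0, 16.0, 544.0),
}

_DEFAULT_RX: dict[ArchetypeKind, Prescription] = {
    ArchetypeKind.NODAL: Prescription("PTV", 35.0, 10),
    ArchetypeKind.LUNG_MULTI: Prescription("PTV", 40.0, 5),
    ArchetypeKind.LIVER_RIND: Prescription("PTV", 24.0, 3),
    ArchetypeKind.PERITONEAL_MULTI: Prescription("PTV", 35.0, 10),
}


def _jitter(rng: np.random.Generator, scale: float) -> float:
    return float(rng.uniform(-scale, scale))


def _make_nodal(grid, rng, margin_mm):
    c = _center_mm(grid) + np.array([_jitter(rng, 3.0) for _ in range(3)])
    r_ptv = _sphere_radius_for_cc(165.0) * (1.0 + _jitter(rng, 0.03))
    r_gtv = _gtv_radius(r_ptv, margin_mm, grid)
    radii = r_gtv * (1.0 + np.array([_jitter(rng, 0.05) for _ in range(3)]))
    radii *= (r_gtv**3 / np.prod(radii)) ** (1.0 / 3.0)  # keep volume
    gtv = _ellipsoid(grid, c, radii)
    return [gtv], []


def _make_lung_multi(grid, rng, margin_mm):
    c0 = _center_mm(grid)
    s = _extent_scale(grid)
    offsets = s * np.array(
        [
            [-60.0, -30.0, 40.0],
            [-55.0, 25.0, -35.0],
            [60.0, -25.0, 30.0],
            [55.0, 30.0, -40.0],
            [65.0, 5.0, -5.0],
        ]
    )
    gtvs = []
    for i, vol in enumerate(NOMINAL_PTV_CC[ArchetypeKind.LUNG_MULTI]):
        r_ptv = _sphere_radius_for_cc(vol) * (1.0 + _jitter(rng, 0.03))
        r_gtv = _gtv_radius(r_ptv, margin_mm, grid)
        center = c0 + offsets[i] + np.array([_jitter(rng, 2.0) for _ in range(3)])
        gtvs.append(_ellipsoid(grid, center, np.full(3, r_gtv)))
    return gtvs, []


def _make_liver_rind(grid, rng, margin_mm):
    # thin shell on the upper cap of a liver-scale sphere
    s = _extent_scale(grid)
    c = _center_mm(grid) + np.array([0.0, 0.0, s * -40.0 + _jitter(rng, 3.0)])
    R = 55.0 * (1.0 + _jitter(rng, 0.03))
    thickness = 3.0
    X, Y, Z = _coords_mm(grid)
    d = np.sqrt((X - c[0]) ** 2 + (Y - c[1]) ** 2 + (Z - c[2]) ** 2)
    shell = (d > R) & (d <= R + thickness)
    cos_theta = np.divide(Z - c[2], d, out=np.zeros_like(d), where=d > 0)
    cap = cos_theta >= np.cos(np.deg2rad(33.0))
    gtv = shell & cap
    return [gtv], []


def _make_peritoneal(grid, rng, margin_mm):
    c0 = _center_mm(grid)
    s = _extent_scale(grid)
    gtvs = []
    # two small blobs
    for i, off in enumerate(([70.0, -50.0, 30.0], [68.0, 52.0, -25.0])):
        r_ptv = _sphere_radius_for_cc(16.0) * (1.0 + _jitter(rng, 0.03))
        center = c0 + s * np.array(off) + np.array([_jitter(rng, 2.0) for _ in range(3)])
        gtvs.append(_ellipsoid(grid, center, np.full(3, _gtv_radius(r_ptv, margin_mm, grid))))
    # one large blob
    r_ptv = _sphere_radius_for_cc(544.0) * (1.0 + _jitter(rng, 0.02))
    big_c = c0 + s * np.array([-35.0, 0.0, 0.0])
    gtvs.append(_ellipsoid(grid, big_c, np.full(3, _gtv_radius(r_ptv, margin_mm, grid))))
    # bowel-like OAR: a tube abutting the large blob's right surface
    X, Y, Z = _coords_mm(grid)
    tube_x = big_c[0] + r_ptv + 6.0
    bowel = ((X - tube_x) ** 2 + (Z - big_c[2]) ** 2) <= 12.0**2
    bowel &= np.abs(Y - big_c[1]) <= s * 90.0
    return gtvs, [bowel]


_BUILDERS = {
    ArchetypeKind.NODAL: _make_nodal,
    ArchetypeKind.LUNG_MULTI: _make_lung_multi,
    ArchetypeKind.LIVER_RIND: _make_liver_rind,
    ArchetypeKind.PERITONEAL_MULTI: _make_peritoneal,
}

_CASE_IDS = {
    ArchetypeKind.NODAL: "case1",
    ArchetypeKind.LUNG_MULTI: "case2",
    ArchetypeKind.LIVER_RIND: "case3",
    ArchetypeKind.PERITONEAL_MULTI: "case4",
}


def make_case(
    archetype_id: ArchetypeKind | str,
    grid: VoxelGrid | None = None,
    seed: int = 0,
    margin_mm: float = DEFAULT_MARGIN_MM,
) -> CaseArchetype:
    """Build one reference case: GTVs, margin-expanded PTVs, OARs.

    Deterministic per seed.  PTV volumes land within +-20% of the
    archetype's nominal scale; the GTV -> PTV margin is isotropic
    (default 5 mm).
    """
    try:
        kind = ArchetypeKind(archetype_id)
    except ValueError as exc:
        raise ValueError(f"unknown archetype id: {archetype_id!r}") from exc
    if grid is None:
        grid = default_grid()
    rng = np.random.default_rng(np.random.SeedSequence([seed, _KIND_CODE[kind]]))
    gtv_arrays, oar_arrays = _BUILDERS[kind](grid, rng, margin_mm)

    gtvs, ptvs = [], []
    for i, g in enumerate(gtv_arrays, start=1):
        gtvs.append(_mask(grid, g, f"GTV{i}", StructureRole.GTV))
        ptvs.append(
            _mask(grid, _dilate_mm(g, grid, margin_mm), f"PTV{i}", StructureRole.PTV)
        )
    oars = [
        _mask(grid, o, f"OAR{i}", StructureRole.OAR)
        for i, o in enumerate(oar_arrays, start=1)
    ]
    if kind == ArchetypeKind.PERITONEAL_MULTI and oars:
        oars[0].label = "bowel"
    return CaseArchetype(
        case_id=_CASE_IDS[kind],
        description=kind,
        grid=grid,
        reference_gtvs=gtvs,
        reference_ptvs=ptvs,
        oars=oars,
        default_prescription=_DEFAULT_RX[kind],
    )


_KIND_CODE = {k: i for i, k in enumerate(ArchetypeKind)}


# ---------------------------------------------------------------------------
# contour perturbation with Dice calibration

def _smooth_field(shape, rng, sigma_vox) -> list[np.ndarray]:
    """Unit-RMS smooth random vector field (one component per axis)."""
    comps = [
        ndimage.gaussian_filter(rng.standard_normal(shape), sigma_vox)
        for _ in range(3)
    ]
    rms = np.sqrt(np.mean(sum(c**2 for c in comps)))
    return [c / max(rms, 1e-12) for c in comps]


def _warp(reference: np.ndarray, field, magnitude_vox: float) -> np.ndarray:
    idx = np.indices(reference.shape).astype(float)
    coords = [idx[a] + magnitude_vox * field[a] for a in range(3)]
    warped = ndimage.map_coordinates(
        reference.astype(np.float32), coords, order=1, mode="constant", cval=0.0
    )
    return warped > 0.5


def _translate_out(mask: StructureMask) -> StructureMask:
    """Shift the structure beyond its own bounding box (DSC 0), clipping
    at the grid boundary if the full extent does not fit."""
    vox = mask.voxels
    for axis in range(3):
        other = tuple(a for a in range(3) if a != axis)
        nz = np.where(vox.any(axis=other))[0]
        shift = int(nz[-1] - nz[0] + 1) + 2
        for sgn in (+1, -1):
            moved = np.zeros_like(vox)
            src = [slice(None)] * 3
            dst = [slice(None)] * 3
            if sgn > 0:
                src[axis] = slice(0, vox.shape[axis] - shift)
                dst[axis] = slice(shift, vox.shape[axis])
            else:
                src[axis] = slice(shift, vox.shape[axis])
                dst[axis] = slice(0, vox.shape[axis] - shift)
            moved[tuple(dst)] = vox[tuple(src)]
            if moved.any() and not (moved & vox).any():
                return mask.copy(voxels=moved)
    raise CalibrationError(0.0, 1.0)


def perturb_contour(reference: StructureMask, cfg: PerturbationConfig) -> StructureMask:
    """Institutional contour variant with Dice ~= ``cfg.target_dsc``.

    A Gaussian-smoothed random displacement field warps the reference,
    followed by a signed morphological adjustment (systematic over- or
    under-segmentation); the displacement magnitude is tuned by
    bisection against the measured Dice.  Raises
    :class:`CalibrationError` (reporting the best achieved Dice) if the
    target is not reached within ``max_bisection_iters``.
    """
    if reference.is_empty:
        raise ValueError("cannot perturb an empty reference mask")
    if cfg.target_dsc >= 1.0:
        return reference.copy()
    if cfg.target_dsc <= 0.0:
        return _translate_out(reference)

    grid = reference.grid
    rng = np.random.default_rng(cfg.seed)
    sigma_vox = [cfg.deformation_scale_mm / s for s in grid.spacing]
    fld = _smooth_field(reference.voxels.shape, rng, sigma_vox)
    morph_sign = 1.0 if rng.random() < 0.5 else -1.0  # over- vs under-segmenting

    mean_spacing = float(np.mean(grid.spacing))

    def candidate(mag_mm: float) -> np.ndarray:
        warped = _warp(reference.voxels, fld, mag_mm / mean_spacing)
        r_morph = 0.25 * mag_mm
        if r_morph >= mean_spacing:
            if morph_sign > 0:
                warped = _dilate_mm(warped, grid, r_morph)
            else:
                warped = _erode_mm(warped, grid, r_morph)
        return warped

    def measure(vox: np.ndarray) -> float:
        out = reference.copy(voxels=vox)
        import warnings as _w

        with _w.catch_warnings():
            _w.simplefilter("ignore")
            return dice(reference, out)

    tol = 0.02
    best_vox, best_d = reference.voxels, 1.0

    # expand until the target is bracketed
    lo, hi = 0.0, 2.0 * mean_spacing
    d_hi = measure(candidate(hi))
    expansions = 0
    while d_hi > cfg.target_dsc and expansions < 12:
        lo, hi = hi, hi * 1.8
        d_hi = measure(candidate(hi))
        expansions += 1
    if abs(d_hi - cfg.target_dsc) < abs(best_d - cfg.target_dsc):
        best_vox, best_d = candidate(hi), d_hi

    for _ in range(cfg.max_bisection_iters):
        if abs(best_d - cfg.target_dsc) <= tol:
            break
        mid = 0.5 * (lo + hi)
        vox = candidate(mid)
        d = measure(vox)
        if abs(d - cfg.target_dsc) < abs(best_d - cfg.target_dsc):
            best_vox, best_d = vox, d
        if d > cfg.target_dsc:
            lo = mid
        else:
            hi = mid

    if abs(best_d - cfg.target_dsc) > 0.05:
        raise CalibrationError(cfg.target_dsc, best_d)
    return reference.copy(voxels=best_vox)


# ---------------------------------------------------------------------------
# analytic dose fields

def synth_dose(
    ptvs: list[StructureMask],
    rx: Prescription,
    falloff_mm: float = 16.0,
    hotspot_pct: float = 100.0,
) -> DoseDistribution:
    """Plateau + linear fall-off dose field with closed-form metrics.

    Dose equals ``TD * hotspot_pct/100`` inside every PTV and decreases
    linearly with Euclidean distance d from the nearest PTV surface,
    ``TD * max(0, 1 - d/falloff_mm)`` outside; overlapping fall-offs
    combine by voxelwise max (equivalently, distance to the union).
    """
    if not ptvs:
        raise ValueError("synth_dose requires at least one PTV")
    if falloff_mm <= 0:
        raise ValueError("falloff_mm must be > 0")
    if hotspot_pct < 100:
        raise ValueError("hotspot_pct must be >= 100")
    u = union_mask(ptvs)
    if u.is_empty:
        raise ValueError("union PTV is empty")
    grid = u.grid
    dist = ndimage.distance_transform_edt(~u.voxels, sampling=grid.spacing)
    # center-to-center EDT overshoots the distance to the smooth surface
    # underlying a voxelized structure by ~h/4 on average (the boundary
    # voxel centers straddle the surface); correct so the fall-off tracks
    # the continuum geometry
    dist = np.clip(dist - 0.25 * float(np.mean(grid.spacing)), 0.0, None)
    td = rx.total_dose_gy
    dose = td * np.clip(1.0 - dist / falloff_mm, 0.0, None)
    dose[u.voxels] = td * hotspot_pct / 100.0
    return DoseDistribution(grid=grid, dose_gy=dose)


# ---------------------------------------------------------------------------
# cohort assembly

def center_ids(n_centers: int) -> list[str]:
    """Center labels A, B, C, ... (AA, AB, ... beyond 26)."""
    letters = string.ascii_uppercase
    out = []
    for i in range(n_centers):
        if i < 26:
            out.append(letters[i])
        else:
            out.append(letters[i // 26 - 1] + letters[i % 26])
    return out


def make_cohort(
    archetypes: list[CaseArchetype],
    n_centers: int,
    dsc_schedule: dict[tuple[str, str], float],
    seed: int = 0,
    falloff_range_mm: tuple[float, float] = (12.0, 24.0),
    hotspot_range_pct: tuple[float, float] = (100.0, 112.0),
    margin_mm: float = DEFAULT_MARGIN_MM,
) -> tuple[list[ContourSubmission], list[PlanSubmission]]:
    """One ContourSubmission and one PlanSubmission per center per case.

    ``dsc_schedule`` maps (center_id, case_id) to the target Dice of
    that center's delineation against the reference; a missing entry is
    an error.  Phase-2 plans use the *reference* structures (as in a
    dummy run's second phase, where standardized volumes are
    distributed) with per-center fall-off and hotspot drawn from the
    given ranges.  Reproducible per seed.
    """
    if n_centers < 1:
        raise ValueError("n_centers must be >= 1")
    ids = center_ids(n_centers)
    contours: list[ContourSubmission] = []
    plans: list[PlanSubmission] = []
    for ci, center in enumerate(ids):
        for ki, case in enumerate(archetypes):
            key = (center, case.case_id)
            if key not in dsc_schedule:
                raise KeyError(f"dsc_schedule missing entry for {key}")
            target = dsc_schedule[key]
            gtvs, ptvs = [], []
            for li, ref_gtv in enumerate(case.reference_gtvs):
                child = int(
                    np.random.SeedSequence([seed, ci, ki, li]).generate_state(1)[0]
                    % (2**31)
                )
                cfg = PerturbationConfig(target_dsc=target, seed=child)
                g = perturb_contour(ref_gtv, cfg)
                gtvs.append(g)
                ptvs.append(
                    _mask(
                        case.grid,
                        _dilate_mm(g.voxels, case.grid, margin_mm),
                        case.reference_ptvs[li].label,
                        StructureRole.PTV,
                    )
                )
            contours.append(
                ContourSubmission(center_id=center, case_id=case.case_id,
                                  gtvs=gtvs, ptvs=ptvs)
            )

            prng = np.random.default_rng(np.random.SeedSequence([seed, ci, ki, 999]))
            falloff = float(prng.uniform(*falloff_range_mm))
            hotspot = float(prng.uniform(*hotspot_range_pct))
            merged_ptv = union_mask(case.reference_ptvs, label="PTV")
            rx = Prescription(
                "PTV",
                case.default_prescription.total_dose_gy,
                case.default_prescription.fractions,
            )
            dose = synth_dose([merged_ptv], rx, falloff_mm=falloff, hotspot_pct=hotspot)
            plans.append(
                PlanSubmission(
                    center_id=center,
                    case_id=case.case_id,
                    dose=dose,
                    prescriptions=[rx],
                    structures=[merged_ptv, *case.oars],
                )
            )
    return contours, plans
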