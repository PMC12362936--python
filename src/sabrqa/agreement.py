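"""Phase-1 agreement statistics for multi-center target delineation.

Inter-institutional agreement on summed target volumes is quantified
with the Dice similarity coefficient (DSC), 2|A&B| / (|A|+|B|), computed
between each center's union-of-lesions mask and the reference panel's
union.  Rating reliability across centers uses the intraclass
correlation ICC(2,1) — two-way random effects, absolute agreement,
single measure — and uncertainty on each DSC comes from a
non-parametric percentile bootstrap over axial slices.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core import (
    ContourSubmission,
    GridMismatchError,
    StructureMask,
    union_mask,
)

__all__ = [
    "RatingsMatrix",
    "ICCResult",
    "dice",
    "reference_dsc",
    "pairwise_dsc",
    "icc_2_1",
    "bootstrap_ci",
]


class VacuousAgreementWarning(UserWarning):
    """Both masks empty: DSC defined as 1.0 by convention."""


@dataclass(frozen=True)
class RatingsMatrix:
    """Complete subjects x raters matrix of agreement values."""

    values: np.ndarray
    subject_ids: tuple[str, ...] = ()
    rater_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.ndim != 2:
            raise ValueError("ratings must be a 2-D subjects x raters array")
        if not np.all(np.isfinite(v)):
            raise ValueError("ratings matrix is incomplete (non-finite cells)")
        if self.subject_ids and len(self.subject_ids) != v.shape[0]:
            raise ValueError("subject_ids length != number of rows")
        if self.rater_ids and len(self.rater_ids) != v.shape[1]:
            raise ValueError("rater_ids length != number of columns")


@dataclass(frozen=True)
class ICCResult:
    """ICC(2,1) with the ANOVA mean squares retained for audit."""

    icc: float
    msr: float  # between-subject (rows) mean square
    msc: float  # between-rater (columns) mean square
    mse: float  # residual mean square
    n_subjects: int
    n_raters: int

    def __float__(self) -> float:
        return self.icc


def _require_same_grid(a: StructureMask, b: StructureMask) -> None:
    if a.grid != b.grid:
        raise GridMismatchError(
            f"masks '{a.label}' and '{b.label}' are on different grids: "
            f"{a.grid.shape}@{a.grid.spacing} vs {b.grid.shape}@{b.grid.spacing}"
        )


def dice(a: StructureMask, b: StructureMask) -> float:
    """Dice similarity coefficient of two masks on one grid.

    Two empty masks agree vacuously: returns 1.0 with a
    :class:`VacuousAgreementWarning`.  Empty vs non-empty gives 0.0.
    """
    _require_same_grid(a, b)
    na = int(a.voxels.sum())
    nb = int(b.voxels.sum())
    if na == 0 and nb == 0:
        warnings.warn(
            "DSC of two empty masks defined as 1.0", VacuousAgreementWarning,
            stacklevel=2,
        )
        return 1.0
    inter = int(np.count_nonzero(a.voxels & b.voxels))
    return 2.0 * inter / (na + nb)


def reference_dsc(sub: ContourSubmission, ref) -> tuple[float, float]:
    """DSC of a center's summed GTV and summed PTV against the reference.

    ``ref`` is a case archetype carrying ``reference_gtvs`` and
    ``reference_ptvs``.  A center that drew no GTV (or PTV) against a
    non-empty reference scores 0.0 for that volume kind.
    """
    out = []
    for sub_masks, ref_masks in (
        (sub.gtvs, ref.reference_gtvs),
        (sub.ptvs, ref.reference_ptvs),
    ):
        if not sub_masks and not ref_masks:
            out.append(1.0)
        elif not sub_masks or not ref_masks:
            out.append(0.0)
        else:
            out.append(dice(union_mask(sub_masks), union_mask(ref_masks)))
    return out[0], out[1]


def pairwise_dsc(subs: list[ContourSubmission], volume_kind: str) -> np.ndarray:
    """Symmetric center x center DSC matrix for one case.

    Entry (i, j) is the DSC of the two centers' union masks for the
    requested volume kind ("GTV" or "PTV"); the diagonal is 1.0.
    """
    if len(subs) < 2:
        raise ValueError("pairwise DSC requires at least 2 submissions")
    cases = {s.case_id for s in subs}
    if len(cases) != 1:
        raise ValueError(f"submissions span several cases: {sorted(cases)}")
    if volume_kind not in ("GTV", "PTV"):
        raise ValueError("volume_kind must be 'GTV' or 'PTV'")

    unions: list[StructureMask | None] = []
    for s in subs:
        masks = s.gtvs if volume_kind == "GTV" else s.ptvs
        unions.append(union_mask(masks) if masks else None)

    k = len(subs)
    out = np.ones((k, k), dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", VacuousAgreementWarning)
        for i in range(k):
            for j in range(i + 1, k):
                if unions[i] is None and unions[j] is None:
                    d = 1.0
                elif unions[i] is None or unions[j] is None:
                    d = 0.0
                else:
                    d = dice(unions[i], unions[j])
                out[i, j] = out[j, i] = d
    return out


def icc_2_1(m: RatingsMatrix | np.ndarray) -> ICCResult:
    """ICC(2,1): two-way random effects, absolute agreement, single measure.

    From the two-way ANOVA decomposition with n subjects and k raters,

        ICC = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)

    where MSR, MSC and MSE are the subject, rater and residual mean
    squares.  A matrix with zero total variance is perfect agreement by
    definition: returns 1.0 with a warning.
    """
    if not isinstance(m, RatingsMatrix):
        m = RatingsMatrix(np.asarray(m, dtype=float))
    x = m.values
    n, k = x.shape
    if n < 2 or k < 2:
        raise ValueError(f"ICC needs >=2 subjects and >=2 raters, got {n}x{k}")

    grand = x.mean()
    ssr = k * float(((x.mean(axis=1) - grand) ** 2).sum())
    ssc = n * float(((x.mean(axis=0) - grand) ** 2).sum())
    sst = float(((x - grand) ** 2).sum())
    sse = sst - ssr - ssc

    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))

    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    zero_variance = sst <= np.finfo(float).eps * x.size * max(1.0, grand**2)
    if denom <= 0 or zero_variance:
        warnings.warn(
            "ratings have zero total variance; ICC(2,1) defined as 1.0",
            UserWarning, stacklevel=2,
        )
        icc = 1.0
    else:
        icc = (msr - mse) / denom
    return ICCResult(icc=icc, msr=msr, msc=msc, mse=mse, n_subjects=n, n_raters=k)


def _slice_counts(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per-axial-slice intersection and per-mask voxel counts over the
    union support (z-slices where either mask is occupied)."""
    support = np.where((a | b).any(axis=(0, 1)))[0]
    inter = (a & b)[:, :, support].sum(axis=(0, 1)).astype(np.int64)
    ca = a[:, :, support].sum(axis=(0, 1)).astype(np.int64)
    cb = b[:, :, support].sum(axis=(0, 1)).astype(np.int64)
    return support, inter, ca, cb


def bootstrap_ci(
    a: StructureMask,
    b: StructureMask,
    n_boot: int = 1000,
    seed: int | None = None,
    unit: str = "axial_slice",
    alpha: float = 0.05,
) -> tuple[float, float]:
    """Percentile bootstrap 95% CI for dice(a, b).

    Resamples spatial units with replacement, recomputes DSC on each
    replicate and returns the (alpha/2, 1-alpha/2) percentiles of the
    replicate distribution ("relative frequency distribution" CI, no
    bias correction).  The default unit is the axial slice of the union
    support region, which preserves within-slice spatial correlation;
    ``voxel_block`` resamples occupied-bounding-box voxel columns
    instead.  Deterministic for a fixed seed.
    """
    _require_same_grid(a, b)
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    if unit not in ("axial_slice", "voxel_block"):
        raise ValueError("unit must be 'axial_slice' or 'voxel_block'")

    if unit == "axial_slice":
        support, inter, ca, cb = _slice_counts(a.voxels, b.voxels)
    else:
        # resampling unit: (x, y) voxel column restricted to the union support
        union = a.voxels | b.voxels
        cols = np.where(union.any(axis=2))
        support = np.arange(len(cols[0]))
        inter = (a.voxels & b.voxels)[cols[0], cols[1], :].sum(axis=1).astype(np.int64)
        ca = a.voxels[cols[0], cols[1], :].sum(axis=1).astype(np.int64)
        cb = b.voxels[cols[0], cols[1], :].sum(axis=1).astype(np.int64)

    n_units = len(support)
    if n_units == 0:
        warnings.warn(
            "both masks empty everywhere; bootstrap CI degenerate (0, 0)",
            UserWarning, stacklevel=2,
        )
        return (0.0, 0.0)

    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n_units, size=(n_boot, n_units))
    inter_s = inter[idx].sum(axis=1)
    denom_s = ca[idx].sum(axis=1) + cb[idx].sum(axis=1)
    valid = denom_s > 0
    if not valid.any():
        warnings.warn(
            "masks empty in every resampled unit; CI reported as (0, 0)",
            UserWarning, stacklevel=2,
        )
        return (0.0, 0.0)
    reps = 2.0 * inter_s[valid] / denom_s[valid]
    lo, hi = np.percentile(reps, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return float(lo), float(hi)
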