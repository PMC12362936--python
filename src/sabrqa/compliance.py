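"""Phase-2 rule engine: grade treatment plans against protocol constraints.

Each constraint is evaluated through the dosimetry layer, the observed
value compared with its limit, and any violation graded minor or major
by whether it exceeds the tolerance by more than 1 Gy (dose-type
limits) or 3% (volume-type limits).  Plans prescribing one dose cloud
over multiple PTV components may have their R50%/D2cm deviations
exempted — the fall-off indices are not achievable for multi-target
plans in the way they are for a single target.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from . import dosimetry
from .core import (
    ConstraintMetric,
    ConstraintSpec,
    DeviationGrade,
    DeviationRecord,
    PlanSubmission,
    StructureMask,
    StructureRole,
    ToleranceType,
    union_mask,
)
from .synthetic import CaseArchetype

__all__ = [
    "ExemptionPolicy",
    "ComplianceReport",
    "grade",
    "evaluate_plan",
    "apply_exemptions",
    "SPILLAGE_METRICS",
]

# metrics exemptable for multi-component targets
SPILLAGE_METRICS = {ConstraintMetric.R50, ConstraintMetric.D2CM_PCT}

# PTV-level metrics (evaluated per prescription / dose cloud)
_PTV_METRICS = {
    ConstraintMetric.COVERAGE_PCT,
    ConstraintMetric.R50,
    ConstraintMetric.D2CM_PCT,
    ConstraintMetric.HIGH_DOSE_SPILLAGE_PCT,
}


class ExemptionPolicy(str, enum.Enum):
    NONE = "none"
    MULTI_PTV = "multi-ptv"


@dataclass
class ComplianceReport:
    """Full graded evaluation of one plan: one record per applicable rule."""

    center_id: str
    case_id: str
    ptv_deviations: list[DeviationRecord] = field(default_factory=list)
    oar_deviations: list[DeviationRecord] = field(default_factory=list)
    uses_ptv_eval: bool = False
    exemption_policy: ExemptionPolicy = ExemptionPolicy.NONE

    @property
    def records(self) -> list[DeviationRecord]:
        return [*self.ptv_deviations, *self.oar_deviations]

    def violations(self, include_exempted: bool = False) -> list[DeviationRecord]:
        return [
            r
            for r in self.records
            if r.grade != DeviationGrade.NONE and (include_exempted or not r.exempted)
        ]


def _margin(rule: ConstraintSpec) -> float:
    """Minor/major tolerance band width in the limit's own units."""
    if rule.margin_override is not None:
        return rule.margin_override
    if rule.tolerance_type == ToleranceType.DOSE_GY:
        return 1.0
    # volume tolerance: 3 percentage points for %-scale metrics,
    # 3% relative for absolute (cc or ratio) limits
    if rule.metric in (
        ConstraintMetric.COVERAGE_PCT,
        ConstraintMetric.D2CM_PCT,
        ConstraintMetric.HIGH_DOSE_SPILLAGE_PCT,
    ):
        return 3.0
    return 0.03 * abs(rule.limit)


def grade(
    observed: float,
    limit: float,
    limit_sense: str = "max",
    tolerance_type: ToleranceType | str = ToleranceType.DOSE_GY,
    margin: float | None = None,
    metric: ConstraintMetric | None = None,
) -> DeviationGrade:
    """Classify one observed metric value as NONE / MINOR / MAJOR.

    The boundary is compliant: ``observed == limit`` is NONE.  A
    violation within the tolerance margin (1 Gy for dose limits, 3% for
    volume limits, unless overridden) is MINOR; beyond it, MAJOR.  For
    min-sense limits (e.g. coverage) the logic mirrors.
    """
    if not (np.isfinite(observed) and np.isfinite(limit)):
        raise ValueError("grade requires finite observed value and limit")
    if margin is None:
        tol = ToleranceType(tolerance_type)
        if tol == ToleranceType.DOSE_GY:
            margin = 1.0
        elif metric is None:
            margin = 3.0  # percentage points; cc/ratio limits pass a metric
        else:
            rule = ConstraintSpec(
                structure="", metric=metric, limit=limit,
                limit_sense=limit_sense, tolerance_type=tol,
                parameter=1.0 if metric in (ConstraintMetric.D_CC,
                                            ConstraintMetric.V_GY) else None,
            )
            margin = _margin(rule)
    if limit_sense == "max":
        excess = observed - limit
    elif limit_sense == "min":
        excess = limit - observed
    else:
        raise ValueError("limit_sense must be 'max' or 'min'")
    if excess <= 0:
        return DeviationGrade.NONE
    if excess <= margin:
        return DeviationGrade.MINOR
    return DeviationGrade.MAJOR


def _count_components(mask: StructureMask) -> int:
    labeled, n = ndimage.label(mask.voxels)
    return int(n)


def _applies_to(rule: ConstraintSpec, mask: StructureMask) -> bool:
    return rule.structure in (mask.label, mask.role.value)


def _eval_ptv_rule(
    rule: ConstraintSpec,
    plan: PlanSubmission,
    rx,
    target: StructureMask,
    coverage_target: StructureMask,
) -> float:
    m = rule.metric
    if m == ConstraintMetric.COVERAGE_PCT:
        return dosimetry.coverage_pct(coverage_target, plan.dose, rx)
    if m == ConstraintMetric.R50:
        return dosimetry.r50([target], plan.dose, rx)
    if m == ConstraintMetric.D2CM_PCT:
        return dosimetry.d2cm_pct([target], plan.dose, rx)
    if m == ConstraintMetric.HIGH_DOSE_SPILLAGE_PCT:
        return dosimetry.high_dose_spillage_pct([target], plan.dose, rx)
    raise ValueError(f"{m} is not a PTV-level metric")


def _eval_oar_rule(rule: ConstraintSpec, plan: PlanSubmission, oar: StructureMask) -> float:
    m = rule.metric
    if m == ConstraintMetric.DMAX:
        return dosimetry.d_max(oar, plan.dose)
    if m == ConstraintMetric.D_CC:
        v = min(rule.parameter, oar.volume_cc)
        return dosimetry.d_cc(oar, plan.dose, v)
    if m == ConstraintMetric.V_GY:
        return dosimetry.v_gy(oar, plan.dose, rule.parameter)
    raise ValueError(f"{m} is not an OAR-level metric")


def evaluate_plan(
    plan: PlanSubmission,
    case: CaseArchetype,
    rules: list[ConstraintSpec],
    exemption_policy: ExemptionPolicy | str = ExemptionPolicy.MULTI_PTV,
) -> ComplianceReport:
    """Evaluate every applicable rule for one plan and grade deviations.

    PTV-level rules run once per prescription (per dose cloud); when the
    plan declares ``uses_ptv_eval``, coverage is judged on the PTV-EVAL
    volume (PTV minus OARs) instead of the full PTV.  OAR rules run on
    every matching organ.  The exemption policy is applied before
    returning.
    """
    if not rules:
        raise ValueError("rules list must be non-empty")
    policy = ExemptionPolicy(exemption_policy)
    report = ComplianceReport(
        center_id=plan.center_id,
        case_id=plan.case_id,
        uses_ptv_eval=plan.uses_ptv_eval,
        exemption_policy=policy,
    )

    ptv_components: dict[str, int] = {}
    for rx in plan.prescriptions:
        target = plan.resolve_target(rx.target_label)
        ptv_components[rx.target_label] = _count_components(target)
        coverage_target = target
        if plan.uses_ptv_eval:
            if target.role == StructureRole.PTV_EVAL:
                coverage_target = target
            else:
                oars = plan.find_structures(role=StructureRole.OAR)
                import warnings as _w

                with _w.catch_warnings():
                    _w.simplefilter("ignore")
                    ev = dosimetry.ptv_eval(target, oars)
                if not ev.is_empty:
                    coverage_target = ev
        for rule in rules:
            if rule.metric not in _PTV_METRICS:
                continue
            if not _applies_to(rule, target):
                continue
            observed = _eval_ptv_rule(rule, plan, rx, target, coverage_target)
            report.ptv_deviations.append(
                DeviationRecord(
                    center_id=plan.center_id,
                    case_id=plan.case_id,
                    target_or_oar_label=rx.target_label,
                    metric=rule.name or rule.metric.value,
                    observed_value=observed,
                    limit=rule.limit,
                    grade=grade(
                        observed, rule.limit, rule.limit_sense,
                        rule.tolerance_type, margin=_margin(rule),
                    ),
                )
            )

    for oar in plan.find_structures(role=StructureRole.OAR):
        if oar.is_empty:
            continue
        for rule in rules:
            if rule.metric in _PTV_METRICS or not _applies_to(rule, oar):
                continue
            observed = _eval_oar_rule(rule, plan, oar)
            report.oar_deviations.append(
                DeviationRecord(
                    center_id=plan.center_id,
                    case_id=plan.case_id,
                    target_or_oar_label=oar.label,
                    metric=rule.name or rule.metric.value,
                    observed_value=observed,
                    limit=rule.limit,
                    grade=grade(
                        observed, rule.limit, rule.limit_sense,
                        rule.tolerance_type, margin=_margin(rule),
                    ),
                )
            )

    report.ptv_deviations = apply_exemptions(
        report.ptv_deviations, ptv_components, policy
    )
    return report


def apply_exemptions(
    records: list[DeviationRecord],
    ptv_components: dict[str, int],
    policy: ExemptionPolicy | str,
) -> list[DeviationRecord]:
    """Mark R50/D2cm deviations of multi-component targets as exempted.

    ``ptv_components`` maps each prescription's target label to its
    connected-component count.  Under policy ``multi-ptv``, R50 and
    D2cm deviation records whose target has >= 2 components are marked
    ``exempted`` (kept in the report, excluded from tallies); under
    ``none`` the records are untouched — the two policies reproduce the
    with- and without-exemption views of a plan review.
    """
    policy = ExemptionPolicy(policy)
    if policy == ExemptionPolicy.NONE:
        return records
    spillage_names = {m.value for m in SPILLAGE_METRICS} | {"R50%", "D2cm"}
    for rec in records:
        if rec.grade == DeviationGrade.NONE:
            continue
        if rec.metric not in spillage_names:
            continue
        if ptv_components.get(rec.target_or_oar_label, 1) >= 2:
            rec.exempted = True
            rec.exemption_reason = (
                f"target '{rec.target_or_oar_label}' contains "
                f"{ptv_components[rec.target_or_oar_label]} components; "
                "R50%/D2cm deviations exempted for multi-target plans"
            )
    return records
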