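# Default plan-review constraint table.
#
# The trial protocol's own numeric limits are distributed only in a
# supplement that does not ship with this package; the values below are
# package defaults following common SBRT practice (RTOG-style conformity
# bands, 5-10 fraction abdominal OAR limits) and are fully overridable by
# passing a YAML file of the same shape.
#
# structure matches either a mask label or a role name (PTV, OAR).
# tolerance_type selects the minor/major band: dose_gy -> 1 Gy,
# volume_pct -> 3 percentage points (or 3% relative for cc/ratio limits),
# unless margin_override gives an explicit band.
constraints:
  - name: PTV coverage
    structure: PTV
    metric: COVERAGE_PCT
    limit: 95.0
    limit_sense: min
    tolerance_type: volume_pct
    margin_override: 5.0   # minor down to 90% coverage, major below
  - name: R50%
    structure: PTV
    metric: R50
    limit: 4.0
    limit_sense: max
    tolerance_type: volume_pct
  - name: D2cm
    structure: PTV
    metric: D2CM_PCT
    limit: 50.0
    limit_sense: max
    tolerance_type: volume_pct
  - name: High-dose spillage
    structure: PTV
    metric: HIGH_DOSE_SPILLAGE_PCT
    limit: 15.0
    limit_sense: max
    tolerance_type: volume_pct
  - name: Small bowel Dmax
    structure: bowel
    metric: DMAX
    limit: 30.0
    limit_sense: max
    tolerance_type: dose_gy
  - name: Small bowel 120 cc
    structure: bowel
    metric: D_CC
    parameter: 120.0
    limit: 15.0
    limit_sense: max
    tolerance_type: dose_gy
  - name: Duodenum Dmax
    structure: duodenum
    metric: DMAX
    limit: 24.0
    limit_sense: max
    tolerance_type: dose_gy
  - name: Duodenum 10 cc
    structure: duodenum
    metric: D_CC
    parameter: 10.0
    limit: 18.0
    limit_sense: max
    tolerance_type: dose_gy
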