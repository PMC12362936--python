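# sabrqa

Dummy-run quality assurance for multicenter stereotactic ablative
radiotherapy (SABR/SBRT) trials.

Before a multicenter radiotherapy trial enrolls patients, participating
centers typically contour and plan a set of benchmark cases (a "dummy
run") so the trial office can quantify how much institutions disagree
about target delineation, dose prescription and plan quality. `sabrqa`
implements that analysis end to end for SABR of recurrent
ovarian-cancer-style metastatic targets:

* **Phase 1 — contour agreement.** Each center's summed gross tumor
  volume (GTV) and planning target volume (PTV) is compared with the
  reference panel's volumes by the Dice similarity coefficient,
  DSC = 2|A∩B| / (|A|+|B|); pairwise inter-center DSC matrices;
  rating reliability by the intraclass correlation ICC(2,1) (two-way
  random effects, absolute agreement, single measure); 95% CIs by a
  non-parametric percentile bootstrap (1,000 replicates) over axial
  slices.
* **Phase 2 — plan compliance.** Dose-volume metrics (Dmax, dose to the
  hottest *v* cc, volume at dose, PTV coverage) and the SBRT conformity
  indices R50% (50%-isodose volume / PTV volume), D2cm (maximum dose at
  ≥ 2 cm from the PTV surface, % of prescription) and high-dose
  spillage, graded against a configurable constraint table. Violations
  are *minor* within a tolerance of 1 Gy (dose limits) or 3% (volume
  limits) and *major* beyond it; R50%/D2cm deviations of plans covering
  multiple PTV components can be exempted, and coverage can be judged on
  PTV-EVAL (PTV minus organs at risk).
* **Synthetic cohorts.** Because clinical dummy-run DICOM data are never
  public, a generator produces the four benchmark-case archetypes (a
  ~165 cc nodal target, five 3–10 cc lung nodules, a thin
  sub-diaphragmatic rind, peritoneal blobs abutting a bowel-like organ
  at risk), institutional contour variants calibrated to any target
  DSC, and dose fields with analytically known R50%/D2cm/Dmax.
* **Fixtures.** The per-center DSC, prescription and deviation tables of
  a published 10-center exercise ship as CSV fixtures, so every summary
  statistic the analysis prints can be recomputed and checked exactly.

## Worked example

```python
import sabrqa

# reference anatomy for the nodal benchmark case on a 2 mm lattice
case = sabrqa.make_case("NODAL", seed=1)
print(round(case.reference_ptvs[0].volume_cc, 1))   # 185.5 (cc)

# a synthetic institutional delineation with Dice ~0.5 vs the reference
variant = sabrqa.perturb_contour(
    case.reference_gtvs[0], sabrqa.PerturbationConfig(target_dsc=0.5, seed=7)
)
print(round(sabrqa.dice(case.reference_gtvs[0], variant), 3))  # 0.503

# an analytically known dose field and its conformity indices
rx = case.default_prescription                      # 35 Gy / 10 fx
dose = sabrqa.synth_dose(case.reference_ptvs, rx, falloff_mm=16.0)
print(round(sabrqa.r50(case.reference_ptvs, dose, rx), 2))       # 1.87
print(sabrqa.coverage_pct(case.reference_ptvs[0], dose, rx))     # 100.0
```

The PTV volume lands within ±20% of the archetype's nominal 165 cc; the
perturbed contour's Dice is within ±0.05 of the requested 0.5; R50% of
a plateau-plus-linear-fall-off plan around a single large target sits
well inside the usual ≤ 4 band, and coverage is 100% by construction.

Summaries of the packaged 10-center tables, from the command line:

```bash
sabrqa summarize --fixtures table1   # per-case / per-center mean (SD) DSC
sabrqa summarize --fixtures table2   # prescription means
sabrqa agree --seed 1 --out agreement/   # phase 1 on a synthetic cohort
sabrqa comply --seed 1 --exemption-policy multi-ptv --out compliance/
```

The first command prints, e.g., `case1,GTV,…,0.463,0.187,10`: across ten
centers the nodal case reached a mean GTV Dice of 0.463 (SD 0.187),
while the liver-rind case collapsed to 0.005 — delineation of thin
seeding lesions is where multicenter agreement fails.

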