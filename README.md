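# dentage

Dental age estimation from tooth-development stages, for forensic
odontologists, biostatisticians and anyone validating age-estimation methods
on staged panoramic radiographs.

Children's chronological age can be estimated from the radiographic
calcification stages (Demirjian stages A–H, plus a pre-calcification stage 0)
of the seven lower-left permanent mandibular teeth, FDI 31–37. In the
Willems formulation each (sex, tooth, stage) carries a score in years and the
estimated dental age (DA) is the seven-term sum

    DA = Σ_{t=31..37} score(sex, t, stage_t)

with prediction error defined as CA − DA (chronological minus estimated;
negative = overestimation). `dentage` provides:

- **Cohort model & I/O** — staged-dentition records with delimited-text
  readers/writers and the standard eligibility filter (age < 16 y, no
  missing tooth, not all seven teeth fully developed).
- **Scoring** — score-table lookup and additive age estimation, with a
  packaged coefficient table transcribed from a published per-sex fit on a
  Saudi Arabian reference sample (n = 1146, ages 4–16); any other table
  (e.g. the original Belgian Caucasian one) plugs in via the same CSV format.
- **Fitting** — country-specific tables by weighted ANOVA: chronological age
  regressed on per-tooth stage indicators, intercept folded into tooth 31,
  uniform or inverse-variance-by-age-band weights, and a seeded
  sex-and-age-stratified train/test split.
- **Validation** — ME / MAE / RMSE with subject-level percentile-bootstrap
  95% CIs, exact-or-approximate Wilcoxon signed-rank tests, paired
  method-vs-method comparison, calibration slope, and linear/quadratic
  weighted kappa for observer agreement on the ordinal stage scale.
- **Synthetic cohorts** — a latent maturation simulator (shared child tempo +
  per-tooth timing noise over calibrated stage-attainment ages) whose
  marginal stage frequencies match a packaged reference table, so fitting and
  validation are fully testable without restricted clinical data.

## Worked example

```python
from dentage import DentitionRecord, estimate_age, load_sa_table
from dentage.stages import StageCode

table = load_sa_table()
stages = {31: StageCode.G, 32: StageCode.G, 33: StageCode.F, 34: StageCode.F,
          35: StageCode.E, 36: StageCode.G, 37: StageCode.E}
boy = DentitionRecord("example-boy", "M", chron_age=10.5, stages=stages)
print(estimate_age(table, boy))
```

prints `9.490` — the sum of the seven per-tooth scores (t31 G contributes
+5.874 y, t36 G −0.413 y, …), so this boy's age is *under*estimated by
+1.01 y under the CA − DA convention. Running
`python examples/04_validate_and_compare.py` fits a table on a simulated
training half and validates on the held-out half:

```
  M+F n= 633  ME +0.011 (SD 0.965)  MAE 0.746  RMSE 0.964 (95% CI 0.900-1.033)  p=0.773
calibration: predicted = 0.996 * chronological + +0.022
```

ME near zero says the fitted table is unbiased on held-out children; the
calibration slope near 1 says predictions track chronological age across the
whole 4–16 y range. The other `examples/` scripts cover simulation, table
fitting/recovery, and observer agreement, one capability each.

There is also a thin CLI mirroring the workflow stages
(`dentage simulate | filter | split | fit | predict | validate | compare |
kappa | run`); every subcommand is a wrapper over the library functions
above.

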