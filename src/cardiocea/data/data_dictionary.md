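# Data dictionary: `annual_parameters.csv`

One row per annual model input. Columns:

| column | meaning |
|---|---|
| `name` | stable snake-case identifier dereferenced by the engine |
| `baseline` | base-case value |
| `low`, `high` | one-way sensitivity endpoints (`low == high` ⇒ held fixed in OWSA) |
| `dist_family` | PSA sampling family: `beta`, `lognormal`, `gamma`, or `fixed` |
| `shape_a`, `shape_b` | family parameters: beta(α, β); lognormal(μ, σ) on the log scale; gamma(shape, **rate**), mean = shape/rate |
| `units` | units of the baseline |
| `role` | `probability`, `relative_effect`, `utility`, `disutility`, `cost` |
| `source` | short provenance note |

Gamma pairs are interpreted as (shape, rate) — the convention that reproduces
the printed cost baselines for most rows (e.g. 96.040/0.730 ≈ 132 for the
annual statin cost).

## Recalibrated rows

For a handful of rows the published shape pair does not reproduce the
published baseline within 2% under either the rate or the scale convention.
Those rows ship with the second shape parameter recalibrated so the
distribution mean equals the baseline, keeping the first shape parameter
(hence the published relative dispersion):

| row | published mean | baseline |
|---|---|---|
| `risk_myopathy` | 0.0005 | 0.0001 |
| `risk_statin_diabetes` | 0.0075 | 0.0015 |
| `risk_statin_hemorrhagic_stroke` | 0.00075 | 0.0002 |
| `mort_chronic_cad` | 0.195 | 0.070 |
| `cost_background` | 4,802 | 4,941 |
| `cost_acute_cad_nonfatal` | 68,200 | 65,442 |
| `cost_acute_ischemic_stroke_nonfatal` | 31,600 | 40,225 |
| `cost_followup_cad` | 10,330 | 11,815 |
| `cost_productivity_first_year_cad_stroke` | 96,040 | 73,492 |
| `cost_productivity_followup_cad_stroke` | 8,731 | 9,056 |
| `cost_productivity_diabetes` | 9,704 | 9,242 |
| `cost_productivity_followup_myopathy` | 8,731 | 9,056 |

`risk_ischemic_stroke_after_cad` (0.015) has no published range or
distribution; it is held fixed in one-way analysis and sampled in PSA from a
beta calibrated so its 95% interval is about ±25% of the mean, for
consistency with the neighbouring probability rows.

Lognormal rows keep their published (μ, σ) untouched. For some of them the
implied median differs from the published point estimate (`hr_cad_diabetes`:
e^0.570 ≈ 1.77 vs 2.000; `hr_ischemic_stroke_diabetes`: e^0.370 ≈ 1.45 vs
2.270; `hr_mort_cad_diabetes`: e^0.690 ≈ 1.99 vs 1.810;
`rr_mort_stroke_diabetes`: e^0.800 ≈ 2.23 vs 1.670). The base case always
uses the `baseline` column; the discrepancy only shifts the PSA cloud for
these minor modifiers.

Other transcription notes:

* The stroke utility row is 0.630 (the table value); the running text of the
  source literature also quotes 0.640 for the same weight.
* First-year lost productivity 73,492 = unrounded absenteeism 14,698.4 ×
  (1 + 4×presenteeism); follow-up 9,056 = 1,811.2 × 5. The rounded
  absenteeism figures usually quoted (14,698 / 1,811) reproduce the totals
  only to within $2.
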