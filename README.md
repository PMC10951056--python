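# podometry

Design-based stereological podometrics and glomerulosclerosis analysis for
kidney biopsy measurements, with a ground-truth synthetic generator that makes
every pipeline stage testable without external data.

The pipeline takes per-glomerulus measurement tables (tuft profile area,
sclerosis grade 0–4, podocyte-nucleus caliper diameters, synaptopodin-positive
area) plus per-patient clinical tables, and derives:

- **Stereology** (`podometry.stereology`): glomerular volume from mean profile
  area (shape-coefficient method, β = 1.382, d = 1.01), confocal optical-slab
  thickness from the axial-resolution formula, podocyte numerical density,
  podocytes per tuft, nuclear/cytoplasmic/total podocyte volumes and the
  podocyte volume fraction.
- **Sclerosis indices** (`podometry.sclerosis`): glomerulosclerotic index
  (count-weighted mean grade), % globally sclerotic glomeruli, % glomeruli
  with segmental lesions, and four threshold classifiers (≤216 podocytes per
  tuft, GSI > 1, > 20 % global sclerosis, > 50 % segmental lesions).
- **Image measurement** (`podometry.image_measure`): IsoData (iterative
  class-mean midpoint) thresholding, podocyte-nucleus detection as the
  colocalization of two nuclear channels inside the tuft with
  capsule-touching components excluded, axis-aligned XY caliper diameters.
- **Clinical layer** (`podometry.clinical`): race-free CKD-EPI eGFR (2021
  coefficients, 2009 available), daily proteinuria from measured 24-h values
  or the total protein/creatinine ratio, and responder/non-responder
  classification at six months.
- **Cohort statistics** (`podometry.cohort_stats`): normality-gated two-group
  comparisons (unpaired t vs exact/asymptotic Mann-Whitney), uncorrected
  chi-square on 2×2 proportions, Spearman correlations with Fisher-z CIs, and
  full report assembly.
- **Synthetic cohorts** (`podometry.synthetic`): spherical tufts with packed
  nuclei sectioned by a thin optical slab (analytically or rasterised into
  3-channel frames with masks), and lognormal group-truth distributions
  calibrated to a 13-responder / 6-non-responder cohort.

## Command-line usage

```sh
# generate a deterministic synthetic cohort
podometry simulate --out sim/ --seed 1

# run the full analysis and write the report tables
podometry analyze --measurements sim/measurements.csv \
                  --clinical sim/clinical.csv --out report/

# measure TIFF frames (with JSON sidecars) into a measurement CSV
podometry measure-images --images frames/ --out measurements.csv
```

`analyze` writes `podometrics.csv`, `sclerosis.csv`, the three comparison
tables (`table1.csv` demographics, `table2.csv` six-month outcomes,
`table3.csv` podometrics), `thresholds.csv` (the four 2×2 contingency
analyses), `correlations.csv`, and a `manifest.json` echoing every setting.
Exit codes: 0 success, 2 validation error, 3 degenerate statistics (e.g. a
single-group cohort makes the contingency tests undefined; the rest of the
report still completes).

## Notes on conventions

- Areas in µm², volumes in µm³; display scaling (per 10⁶ µm³) only in reports.
- The biopsy-inclusion boundary is inclusive: six or fewer glomerular
  profiles excludes the patient, seven includes.
- The density denominator uses the apparent caliper diameter by default (per
  the original method description); the corrected-diameter mode
  (`density_uses_corrected_diameter`, the CLI default for `analyze`) removes
  the thin-slab over-counting bias and is what the recovery tests validate.
- Chi-square tests use no continuity correction; quartiles use linear
  interpolation; α = 0.05.
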