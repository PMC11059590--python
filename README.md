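# glomkit

Glomerular morphometry, rule-based RPS lesion classification and
prognostic statistics for diabetic-nephropathy image analysis — together
with a synthetic-data generator that makes the whole pipeline testable
without any external data.

## What it does

- **`glomkit.synthetic`** — generates every input the pipeline needs:
  labeled glomerulus images (disc tuft, Bowman capsule ring, blob-grown
  mesangial region, point cells of three intrinsic types), label
  predictions with a planted confusion structure, mask perturbations with
  a predictable Dice, and clinical cohorts with class-dependent eGFR
  slopes, proteinuria levels and ESRD events.
- **`glomkit.seg_eval`** — confusion matrices, one-vs-rest per-class
  accuracy / specificity / precision / recall / F1, Dice coefficients and
  grouped Dice means. Undefined ratios surface as NaN, never silent 0;
  both-empty Dice is defined as 1.0.
- **`glomkit.morphometrics`** — per-glomerulus areas (μm²), mesangial
  area fraction, cell counts / densities / ratios; the 50-cell
  midsection rule; the mild-mesangial-expansion flag (fraction <
  0.2596); per-patient aggregation (percent lesion types over all
  glomeruli, intraglomerular means over midsection KW/NOA glomeruli);
  Mann-Whitney / Kruskal-Wallis group comparisons.
- **`glomkit.rps`** — ROC curves with trapezoidal AUC, Youden-optimal
  cutoffs, ordinal early-class cutoff fitting, and the decision tree:
  percent GS > 50 → class IV, else any KW lesion → class III, else the
  chosen mesangial feature against two cutoffs → I / IIa / IIb.
- **`glomkit.stats`** — Cohen's kappa, Spearman correlation, the
  dependent-overlapping-correlation Z test (Dunn–Clark with
  backtransformed averaged Fisher z by default), time-averaged
  proteinuria, OLS eGFR slope, the ESRD event definition with a 3-month
  persistence clause, cohort filters and the prognostic correlation
  table.
- **`glomkit.io` / `glomkit.cli`** — PNG/TIFF mask I/O with code
  validation, CSV/JSON interchange, and the orchestrating pipeline.

## CLI

```bash
# synthetic inputs
glomkit simulate cohort --n-patients 100 --seed 1 --out-dir cohort/
glomkit simulate glomeruli --seed 1 --out-dir gloms/
glomkit simulate predictions --truth truth.csv --config confusion.yaml --seed 1 --out pred.csv

# measurement and aggregation
glomkit morphometrics --masks gloms/ --gloms gloms/glomeruli.csv --cells gloms/cells.csv --out glom_features.csv
glomkit aggregate --in glom_features.csv --out patient_features.csv

# classification
glomkit classify fit --features patient_features.csv --classes pathologist.csv \
    --feature mesangial_area_fraction --out cutoffs.json
glomkit classify apply --features patient_features.csv --cutoffs cutoffs.json --out classes.csv

# evaluation and statistics
glomkit evaluate types --truth truth.csv --pred pred.csv --out metrics.csv
glomkit evaluate dice --truth-dir masks_true/ --pred-dir masks_pred/ --out dice.csv
glomkit agreement --a classes.csv --b pathologist.csv --out kappa.json
glomkit prognosis --cohort visits.csv --classes classes.csv --classes2 pathologist.csv --out prognosis.csv

# full pipeline from a YAML config (paths + feature + seed)
glomkit run --config pipeline.yaml --seed 1
```

`glomkit run` writes `glom_features.csv`, `patient_features.csv`,
`cutoffs.json`, `classes.csv`, `agreement.json`, `prognosis.csv` and a
`run_log.json` with the seed, version and per-stage record counts.
Identical config and seed reproduce byte-identical outputs.

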