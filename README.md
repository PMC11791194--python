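# cetclock

Multi-species methylation age clocks, two-step Stouffer meta-EWAS, and
hypergeometric annotation enrichment — with a fully synthetic data generator
so every analysis in the package can be exercised, validated, and reproduced
without any external data.

## What it does

DNA methylation at a few thousand conserved CpG sites drifts predictably with
age, which makes it possible to estimate the age of an animal from a blood or
skin sample. This package implements the core statistical machinery of that
kind of study for panels spanning many species and tissues:

- **Age transforms** — invertible maps from chronological age to the scale the
  clock is trained on: `log1p` (`log(age + offset)`) and a Horvath-style
  `loglinear` transform that is logarithmic below a knot age and linear above
  it, with matched value and slope at the knot.
- **Elastic-net clocks** — penalized regression (`alpha = 0.5`) of transformed
  age on CpG beta values, with the penalty strength chosen by internal 10-fold
  cross-validation. Two external validation schemes: leave-one-sample-out
  (LOOCV; Pearson *r* and median absolute error in years) and
  leave-one-species-out (LOSOCV; repeated-measures correlation, which
  correlates age and predicted age after centering both within species, and
  the median across species of per-species median errors).
- **Meta-EWAS** — per-stratum (species × tissue) association of each CpG with
  age (Pearson/t) or sex (OLS of beta on sex adjusting for age), converted to
  signed z-scores and combined by unweighted Stouffer's method. For analyses
  spanning species, combination is two-step: tissues are combined within each
  species first, then species are combined, so heavily sampled species do not
  dominate. All p-values are handled in log space, so z-scores survive far
  beyond double-precision underflow (p ≈ 1e-300 and smaller).
- **Enrichment** — hypergeometric tests of CpG lists against interval-based
  annotations (chromatin states, transcription-factor binding sets,
  Polycomb-complex co-binding, and GREAT-style gene regulatory domains), with
  fold change, odds ratio, and log-space enrichment/depletion p-values.
- **Synthetic data** — a generator that plants known age- and sex-associated
  CpGs into a multi-species beta-value panel, plus an annotation-fixture
  generator that plants a chosen enrichment factor into one region set. Ground
  truth is returned alongside the data, so statistical recovery is testable.
- **Pipeline + CLI** — a config-driven end-to-end run (simulate or load →
  clocks → meta-EWAS → enrichment) that writes a manifest with derived
  per-stage seeds and file digests; repeat runs are byte-identical.

## Worked example

```python
import numpy as np
import cetclock as cc

scenario = cc.standard_scenario(n_species=4, samples_per_stratum=25,
                                n_cpgs=1500, n_age_cpgs=150, n_sex_cpgs=20,
                                seed=11)
panel, betas, cpg_map, truth = cc.generate_panel(scenario)
print(f"panel: {len(panel.sample_id)} samples, {len(betas.cpg_ids)} CpGs")

model = cc.fit_clock(betas, panel, seed=11)
print(f"clock: {len(model.weights)} CpGs selected, "
      f"lambda = {model.training_meta['lambda']:.4g}")

loo = cc.loocv(betas, panel, seed=11)
print(f"LOOCV: r = {loo.summary['pearson_r']:.3f}, "
      f"median MAE = {loo.summary['median_mae_years']:.2f} years")

strata = cc.run_strata(betas, panel, kind="age")
meta = cc.two_step_meta(strata, "age-all")
thr = cc.bonferroni_threshold(len(betas.cpg_ids))
n_sig = int((meta.table["log_p"] < np.log(thr)).sum())
print(f"meta-EWAS: {n_sig} CpGs past Bonferroni p < {thr:.2e}")

sets = cc.generate_annotation_fixture(truth, cpg_map, 5.0, seed=11)
top = cc.select_top(meta, n=150, direction="positive")
rows = cc.region_set_enrichment(top, betas.cpg_ids,
                                [s for s in sets if s.source_label is None][:4],
                                cpg_map)
for r in sorted(rows, key=lambda r: r.log_p_enrichment):
    print(f"  {r.set_name:12s} FC={r.fold_change:5.2f}  p={r.p_enrichment:.2e}")
```

Output:

```
panel: 200 samples, 1500 CpGs
clock: 90 CpGs selected, lambda = 0.0202
LOOCV: r = 0.997, median MAE = 0.87 years
meta-EWAS: 150 CpGs past Bonferroni p < 3.33e-05
  BivProm_sim  FC= 2.52  p=4.73e-09
  TxEx_sim     FC= 1.39  p=1.01e-01
  Enh_sim      FC= 0.97  p=5.93e-01
  Quies_sim    FC= 0.85  p=7.64e-01
```

The clock recovers age almost perfectly from the planted signal, the
meta-EWAS puts the planted CpGs past the family-wise threshold, and only the
region set built with a planted enrichment factor (`BivProm_sim`) comes back
significant.

The same workflow is available from the command line:

```
$ cetclock --help
Usage: cetclock [OPTIONS] COMMAND [ARGS]...

  Species- and tissue-aware methylation age clocks and meta-EWAS.

Commands:
  clock     Fit, apply, and cross-validate elastic-net age clocks.
  enrich    Hypergeometric enrichment of CpG lists in annotation BED sets.
  ewas      Two-step Stouffer meta-EWAS of age or sex.
  report    Regenerate the summary report from a run manifest.
  run       Run the full pipeline from a config file.
  simulate  Generate a synthetic multi-species methylation panel.
```

e.g. `cetclock simulate --config scenario.yaml --seed 2 --out-dir sim/`
followed by `cetclock clock loocv --panel sim/panel.csv --betas sim/betas.csv
--seed 3 --out loo.tsv`, or the whole thing at once with
`cetclock run --config run.yaml`.

## Layout

```
src/cetclock/
  types.py       sample panels, beta matrices, CpG maps, region sets, models
  io.py          CSV/TSV/BED/JSON readers and writers
  transform.py   invertible age transforms
  simulate.py    synthetic panel and annotation-fixture generators
  clock.py       elastic-net clocks, LOOCV/LOSOCV, repeated-measures r
  ewas.py        stratum EWAS, Stouffer combination, two-step meta-analysis
  enrichment.py  hypergeometric tests, interval overlap, gene domains
  pipeline.py    config-driven end-to-end runs with manifests
  cli.py         the `cetclock` command
docs/methods.md  statistical methods note
scripts/acceptance.py
tests/
```

See `docs/methods.md` for the precise statistical definitions and the
numerical design choices.
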