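# peagain

Genomic selection toolkit for connected RIL (recombinant inbred line)
populations evaluated in multi-environment trials. The package implements the
full analysis chain of a pea genomic-selection study as reusable, tested
components, exercisable end-to-end on a bundled synthetic-data generator:

- **`peagain.simdata`** — synthetic connected RIL populations (three parents,
  paired crosses, single-seed descent with Poisson/Haldane recombination on 7
  linkage groups) and randomized-complete-block phenotypes with controllable
  heritability and genotype × environment interaction (GEI).
- **`peagain.genotypes`** — VCF/CSV marker I/O, missing-rate and MAF filters,
  mode / rounded-mean / iterative random-forest imputation, VanRaden kinship,
  Nei's standard genetic distance.
- **`peagain.quantgen`** — balanced-ANOVA variance components (with or
  without a population factor), broad-sense heritability (single- and
  multi-environment), genetic coefficient of variation, genetic correlation
  across environments, BLUP shrinkage of line means, trait correlations.
- **`peagain.ammi`** — AMMI decomposition of the genotype × environment
  matrix, F_R axis-retention test, nominal yields, top-entry selection.
- **`peagain.gsmodels`** — rrBLUP (closed form, spectral REML for the ridge
  parameter), G-BLUP on a kinship matrix, Bayesian Lasso (Park & Casella
  Gibbs sampler, numba-accelerated), optional population-structure fixed
  effects, prediction for new lines.
- **`peagain.evaluation`** — stratified k-fold cross-validation with
  repetitions, intra/inter-environment and intra/inter-population prediction
  scenarios, population-first predictive-ability averaging, RMSD-based model
  selection.
- **`peagain.gains`** — truncation-selection intensities, accuracy from
  predictive ability, genetic gain per year, cost-constrained GS-vs-PS
  efficiency ratios.
- **`peagain.gwas`** — stratified PC-adjusted score test with exact
  small-sample calibration, genomic-control inflation correction,
  Benjamini–Yekutieli FDR, LD r².
- **`peagain.pipeline`** — YAML-config-driven orchestration of the whole
  study with a manifest and a markdown report.

## Tests

```bash
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (analytic
selection-intensity values, efficiency-ratio reproduction, oracle
equivalences such as rrBLUP ≡ ridge and rrBLUP ≡ G-BLUP, GWAS null
calibration, and parameter recovery on synthetic data).

## CLI

```bash
# full synthetic study from a YAML config
peagain run --config study.yaml --out results/

# marker QC
peagain filter --geno geno.csv --max-missing 0.01 --min-maf 0.05 --out out.csv

# fit one model
peagain gsfit --model rrblup --geno geno.csv --pheno pheno.csv --out fit.json

# efficiency ratio from printed inputs
peagain gains ratio --rac 0.39 --h 0.632 --tp 1

# generate synthetic data
peagain simulate --out-prefix demo --seed 1
```

A minimal `study.yaml`:

```yaml
sim: {n_markers: 500, lines_per_pop: 60, n_qtl: 50}
missing_thresholds: [0.01, 0.05, 0.10]
models: [rrblup, gblup, bayeslasso]
cv_repetitions: 5
scenarios: [inter_env_intra_pop, intra_env_inter_pop]
seed: 1
```

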