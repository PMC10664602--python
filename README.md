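# retroval

Retrospective, project-time validation of molecular generative models.

`retroval` maps a bioactivity dataset (SMILES + pXC50, with or without
synthesis dates) onto a project time axis, stratifies it into early /
middle / late stages and into three regions —

* **alpha** – early-stage compounds with at least middle activity (the
  fine-tuning / focus pool),
* **beta** – middle/late-stage compounds with low or middle activity,
* **gamma** – middle/late-stage compounds with high or ultra-high activity
  (the rediscovery reference),

— and evaluates any generated compound set against that stratification:
validity, uniqueness, novelty, rediscovery, average single-nearest-
neighbour Tanimoto similarity (aSNN, overall and per stage x activity
class), random-forest activity-score filtering (top-k selection),
k-means cluster-predictivity analysis, and per-region negative log
likelihood under a pluggable generator contract, implemented here by a
desk-scale Markov-chain SMILES model.

For datasets without dates, a *pseudo-time* axis is constructed:
structural fingerprints → PCA(3, standardized scores) → append pXC50 →
PCA(3) → Euclidean distance to the least-potent compound.

A synthetic-project simulator generates congeneric series whose potency
rises over time, in two regimes: **public_like** (late actives stay in
the chemistry of the early actives, so aSNN(alpha,gamma) >
aSNN(alpha,beta)) and **inhouse_like** (the chemistry moves on, so the
converse holds). This makes the whole pipeline runnable and testable
offline.

## Quick start

```bash
# simulate a synthetic project and run the full evaluation
retroval simulate --regime public_like --n 200 --seed 7 --out project.csv
retroval run-all --project project.csv --out-dir results_run

# or stage by stage
retroval prepare --project raw_table.xlsx --out project.csv   # standardize
retroval pseudotime --project project.csv --out ptime.csv
retroval characterize --project project.csv --out-dir results_run
retroval train-scorer --project project.csv --out-dir results_run --seed 17
retroval evaluate --project project.csv --generated gen.smi \
    --out-dir results_run --top-k 100,500
retroval cluster --project project.csv --out-dir results_run --k 10
retroval nll --project project.csv --out-dir results_run
```

All knobs (activity thresholds, stage fractions or date cutpoints, focus
rule, fingerprint configurations, seeds, sample size, top-k list, novelty
reference) live in a YAML `RunConfig`; see `retroval.pipeline.RunConfig`.
`run-all` writes a `manifest.json` listing every artifact with its
SHA-256 hash — runs are bit-reproducible for a fixed config.

Input formats: CSV/XLSX compound tables (default columns `SMILES`,
`pXC50`, optional `date`), plain-text SMILES lists (optional second
column with scores). All outputs are CSV/JSON.

## Tests

```bash
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (metric-oracle
equivalence, pseudo-time and stratification properties, cluster-verdict
rules, Markov sampling/NLL consistency, regime separation, scorer sanity,
end-to-end reproducibility). One criterion — record counts of the
publication's supplementary compound tables — is skipped unless those
files are placed under `data/supplementary/` (they are journal
supplementary material and are not redistributable).

## Package layout

| module | role |
| --- | --- |
| `retroval.chem_io` | compound-table / SMILES-set IO, standardization (de-salt, canonical non-isomeric SMILES) |
| `retroval.pseudotime` | fingerprint + two-stage PCA pseudo-time ordering |
| `retroval.stratify` | activity classes, stages, alpha/beta/gamma regions, focus set |
| `retroval.metrics` | validity / uniqueness / novelty / rediscovery, aSNN, stratified aSNN, top-k |
| `retroval.activity_scorer` | ECFP6 + random-forest activity scorer, region score diagnosis |
| `retroval.cluster_predictivity` | k-means clusters, region counts, predictive/unpredictive verdicts, representatives |
| `retroval.baseline_generator` | Markov-chain SMILES generator (fit / focus / sample / NLL) |
| `retroval.synthetic_data` | synthetic project simulator and fixture suite |
| `retroval.pipeline`, `retroval.cli` | orchestration, config, manifest, CLI |
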