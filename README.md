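# toxcp

Mondrian aggregated conformal prediction for binary molecular toxicity
classification.

Toxicity endpoints are often heavily imbalanced — in acute-toxicity
benchmarks the very-toxic class can be outnumbered ~11:1 — and ordinary
classifiers respond by sacrificing the minority class. `toxcp` takes a
different route: instead of a forced single-class call, each compound
receives a *prediction set* (one label, both, or neither) whose per-class
error rate is controlled at a user-chosen significance level ε, assuming
only that calibration and test data are exchangeable. Because calibration
is class-conditional (Mondrian), the guarantee holds for each class
independently, so sensitivity and specificity stay balanced on imbalanced
data with no resampling, class weighting or cost-sensitive tricks.

The pipeline covers the full chain a modeller needs:

* **standardize** — SMILES cleanup: salt stripping, stereo removal,
  organic element filter, neutralization, tautomer canonicalization, with
  per-molecule exclusion reasons.
* **featurize** — a frozen 96-descriptor physico-chemical RDKit panel, or
  any external feature table (e.g. autoencoder embeddings).
* **splits** — per-ensemble-member stratified partitions into proper
  training / validation / conformal calibration.
* **conformal** — the core: class-conditional inductive conformal
  prediction over any probabilistic scorer (default: random forest),
  p-values `p_c = (#{αᵢ ≥ α} + 1)/(n_c + 1)` with `α = 1 − P(c|x)`,
  median-aggregated over K = 10 members; also calibrates score files from
  external models (e.g. fine-tuned SMILES transformers) through the same
  machinery.
* **metrics** — per-class validity and efficiency, the 2.5-point validity
  flag, SE/SP/BA over single-label predictions, benchmark-style report
  tables.
* **synthetic** — exchangeable Gaussian datasets at the study's two
  imbalance regimes (~1.6:1 and ~11:1), Beta score fixtures, and a curated
  toy SMILES set, so everything is testable offline.

## Worked example

```python
from toxcp import MondrianConformalClassifier, generate_tabular, vt_like
from toxcp.featurize import FeatureMatrix

# 11:1 imbalanced exchangeable data, class separation 1.5
fm, labels = generate_tabular(vt_like(n_total=3000, seed=7))
train = FeatureMatrix(fm.ids[:2000], fm.names, fm.values[:2000])
evalm = FeatureMatrix(fm.ids[2000:], fm.names, fm.values[2000:])

model = MondrianConformalClassifier(train, labels[:2000],
                                    n_members=10, master_seed=7)
results = model.fit()
print(results.summary(evalm, labels[2000:], epsilons=(0.1, 0.2, 0.3),
                      dataset="vt_synth"))
```

```
Mondrian aggregated conformal predictor (K=10, smoothing=off, master_seed=7)
 dataset method  significance  validity_1  validity_0  efficiency_1  efficiency_0    SE    SP    BA
vt_synth     rf         0.100       0.933       0.912         0.382         0.364 0.824 0.759 0.791
vt_synth     rf         0.200       0.742       0.825         0.775         0.742 0.667 0.765 0.716
vt_synth     rf         0.300       0.663       0.730         0.944         0.939 0.643 0.717 0.680
```

Read it row by row: at significance 0.2, at most ~20% of each class
should receive a set missing its true label. The majority class obliges
(error 0.175); the minority class sits at error 0.258, past the 0.225
validity-flag threshold — with only 89 minority compounds in this toy
evaluation set, one-seed fluctuations of ±0.04 are expected, and at study
scale (2000 evaluation compounds, `scripts/acceptance.py`) both classes
stay inside the band. Efficiency is the informative fraction: at ε = 0.1 the
predictor hedges (only ~38% single-label sets, the rest both-label), while
at ε = 0.3 nearly every compound gets exactly one label at the price of
more errors. SE and SP stay close (class-conditional calibration at work
on 11:1 data); BA is their mean, computed over single-label predictions
only.

The same flow runs from the shell:

```bash
toxcp simulate --regime vt --n-total 3000 --seed 7 --outdir data/
toxcp run --config config.yaml --outdir out/     # full pipeline from YAML
toxcp standardize --in raw.csv --out std.csv --report excluded.csv
```

For a real benchmark file downloaded locally, `toxcp ingest-catmos --in
<file> --endpoint vt --outdir data/` maps it onto the pipeline's
`id,smiles,label` layout, preserving the published train/evaluation
assignment.

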