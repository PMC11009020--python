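# litrx

Literature-mined gene features for anticancer drug-response prediction.

Predicting how a tumor or cell line responds to a drug from its
transcriptome is a regression problem with far more genes than samples, so
the choice of input genes (feature selection) largely decides how well a
model generalizes — especially *across* datasets, where batch and protocol
shifts break selectors tuned to one domain.  `litrx` implements a
text-mining route to feature selection: genes whose literature is enriched
for a drug's topic become that drug's feature set.  The package provides
the full analysis around that idea — the mining statistics, eight
competitor selectors, a within-/cross-domain machine-learning benchmark,
univariate biomarker analysis, and survival-based validation — together
with seeded synthetic-data generators with planted ground truth, so every
stage is testable end to end without any external database.

## The method

**Mining.**  Abstracts carry token sets and curated gene links.  A
Bernoulli naive-Bayes classifier scores topic relevance linearly in token
presence, with Laplace-smoothed weights

&nbsp;&nbsp;w(t) = log[(n₊(t)+s)/(N₊+2s)] − log[(n₋(t)+s)/(N₋+2s)],

and a document is *relevant* when its posterior ≥ τ (default 0.5).  For
each gene g the 2×2 table (linked × relevant) over all classified
abstracts gets a one-sided Fisher exact p-value (hypergeometric tail
P(X ≥ a)); genes with p < .01 are reported sorted by ascending
Benjamini–Hochberg FDR.

**Benchmark.**  Drug response is the area above the dose-response curve
(AAC ∈ [0,1], higher = more sensitive).  Nine selectors — text-mining,
variance top-100/500, correlation top-500, L1000, L1000 minus text-mining,
MRMR (MID scheme), GA, RFE — feed Elastic Net, Random Forest and a
sigmoid-output neural network (SGD, learning rate 0.01, momentum 0.9,
dropout 0.2, 15 epochs, MSE loss).  Within-domain performance uses 4-fold
CV repeated 20 times with per-fold selector/scaler refits and grid-search
tuning; cross-domain validation applies the tuned model once to an
independent domain.  Metrics: Pearson, Spearman, Kendall τ-b, RMSE, MSE,
MAE; selector pairs are compared by paired t-tests over drugs.

**Validation.**  Per-gene |Pearson r| with AAC compares text-mining genes
against the rest of the genome (paired across drugs).  A Random Forest
trained on text-mining features predicts responses for a small in-vivo
style cohort; predictions are dichotomized at the median and the groups
compared by Kaplan–Meier curves and a log-rank test.

## Worked example

```bash
python examples/mine_drug_genes.py
```

```
corpus: 5000 abstracts, 1000 linked genes
text-mining feature set: 52 genes at p < .01
top 10 (ascending FDR): ['g0008', 'g0036', 'g0031', 'g0024', 'g0030', ...]
precision 0.904  recall 0.940
```

Fifty of the 1000 genes were planted with 8-fold enriched odds of linking
to drug-topic abstracts; the miner recovers 47 of them with 5 false
positives.  Feeding mined gene lists into the cross-domain benchmark
(`examples/benchmark_selectors.py`, 8 drugs whose causal genes lie inside
the planted set):

```
mean cross-domain Pearson r by selector (both model families):
oracle         0.870
text-mining    0.757
var_100        0.259
var_500        0.346

elastic_net: text-mining vs var_100: mean diff +0.418, paired t p = 0.0073
elastic_net: text-mining vs var_500: mean diff +0.407, paired t p = 0.012
random_forest: text-mining vs var_100: mean diff +0.515, paired t p = 0.0013
random_forest: text-mining vs var_500: mean diff +0.414, paired t p = 0.0045
```

Text-mining features transfer far better across the domain shift than
variance-based selection and sit just below the ground-truth oracle, as
they should: the mined list contains each drug's causal genes plus some
literature noise.  `examples/univariate_biomarkers.py` and
`examples/survival_validation.py` show the univariate and survival stages
(the latter prints `log-rank chi-square = 15.90, p = 6.7e-05` for the
24-subject planted-hazard cohort).

## Layout

```
src/litrx/
  synth.py       seeded corpus / domain-pair / survival-cohort generators
  litminer.py    naive-Bayes classifier, Fisher enrichment, FDR ranking
  pharmodata.py  dataset model, TSV I/O, sample filter, train-fitted scaler
  featsel.py     the nine selectors
  bench.py       models, repeated CV, cross-domain validation, comparisons
  validate.py    univariate biomarkers, KM / log-rank validation
  scenarios.py   end-to-end study scenarios on synthetic data
examples/        one narrative script per capability
docs/methods.md  modelling assumptions, defaults and limitations
```
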