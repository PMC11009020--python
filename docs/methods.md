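# Methods

This note records the models behind `litrx`, the defaults that matter, the
choices made where the design was genuinely open, and what the synthetic
substrates do and do not establish about real data.

## Literature mining

The topic classifier is Bernoulli naive Bayes restricted to token
*presence*: a document's posterior log-odds is the prior log-odds plus the
sum of per-token weights w(t) = log[(n₊(t)+s)/(N₊+2s)] −
log[(n₋(t)+s)/(N₋+2s)] over its distinct tokens, with Laplace smoothing
s = 1.  Tokens seen in neither training class contribute zero.  Training
uses 1000 topic abstracts and an equal-sized background sample, so the
prior log-odds is zero; the decision threshold defaults to 0.5.  Both the
threshold and the background sampling are configuration, not claims about
any particular literature-mining service, whose negative-set composition
is generally unpublished.

Gene scoring uses the 2×2 table of (linked to the gene) × (classified
relevant) over *all* classified abstracts, so the table margins are
identical for every gene; the alternative universe of only gene-linked
abstracts makes margins gene-dependent and p-values incomparable.  The
test is the one-sided (enrichment) Fisher exact test — ranking genes by
depletion would be meaningless here.  Genes below the p < .01 cutoff are
ordered by Benjamini–Hochberg q computed over all scored genes, with ties
broken by (q, p, gene id) for bit-reproducibility.

## Synthetic corpus

The generator plants a gene subset whose linked abstracts have their
topic-label odds multiplied by `link_enrichment` (default 8).  Defaults:
5000 abstracts at 20 % topic prevalence, 1000 genes with 50 planted,
vocabulary of 2000 tokens.  Two design points deserve explanation:

* **Vocabulary strata.**  The vocabulary has a topic-characteristic
  stratum, a background-characteristic stratum (150 tokens each; presence
  rate 0.35 in the "own" class, 0.05 otherwise) and a neutral remainder
  (0.05 everywhere).  A presence-linear classifier needs evidence of both
  signs: if only the topic class had characteristic tokens, every weight
  would be positive and all documents would clear a 0.5 posterior
  threshold.  Real background literature of course has its own
  characteristic vocabulary.
* **Link density.**  Gene links per abstract follow Poisson(8) truncated
  to [1, 10] (mean ≈ 7), giving each gene ≈ 36 linked abstracts.  A
  design-time power analysis showed that much sparser link lists leave
  individual genes with ≈ 10 linked abstracts, too few for a discrete
  Fisher tail to reach p < .01 reliably at 8-fold enrichment — planted
  genes then cannot be recovered at the intended precision/recall (≥ 0.8)
  at any classifier accuracy.  Curated gene-link databases are dense in
  exactly this sense.
* **Prevalence.**  A minority topic class (1 : 4) sharpens the contrast
  between planted-linked and background abstracts; classifier training
  still samples balanced classes.

## Pharmacogenomic domains

Log-expression is N(0, 1) per gene in the training domain; the test
domain adds a per-gene mean shift drawn from N(0, domain_shift_sd),
default 0.5 — an additive location shift only, deliberately the minimal
shift that makes cross-domain validation non-trivial (no covariance or
scale changes).  Each drug's response is AAC = logistic(Σ w_g·x_g + ε),
ε ~ N(0, 0.3): the logistic link keeps AAC strictly inside (0, 1) without
clipping artifacts.  Per-drug signal genes (default 10, weights
N(0, 0.8²) with magnitudes floored at 0.2 to avoid near-null drugs) are
recorded as ground truth on the generated datasets, enabling an oracle
selector.  Default sizes: 150 training and 100 test samples, 1000 genes,
20 drugs — chosen as the scale at which every effect of interest is
measurable with comfortable statistical margins on one CPU.

What the generator does **not** emulate: gene–gene correlation structure,
tissue stratification, heteroscedastic assay noise, non-additive
expression→response relationships, or missingness patterns.  Passing
tests therefore demonstrate correctness of the statistics and the
direction of the selector comparison under a known sparse linear signal,
not performance on real pharmacogenomic panels.

## Preprocessing

The sample filter drops samples with missing values and samples whose
modal expression value covers more than 85 % of genes (an all-constant
profile is dropped at any threshold).  This reading — per-sample modal
fraction — is one interpretation of "zero variance across most genes" at
the sample level; the threshold is configurable and the filter is
idempotent.  Scaling is per-gene z-scoring with statistics fitted on
training data only; zero-variance genes map to 0, the scaler carries a
provenance tag, and applying it to a matrix with unknown genes raises, so
test-domain statistics cannot silently enter the pipeline.

## Selectors

* Variance selection ranks genes on *unscaled* training variance
  (scaling would equalize variances and void the method).
* MRMR uses the MID (difference) scheme with |Pearson r| for both
  relevance and redundancy — the natural instantiation for continuous
  features and a continuous target.  Greedy, deterministic, ties by gene
  id.
* RFE uses a ridge base regressor (α = 1) on internally z-scored data,
  dropping 10 % of remaining genes per round; ridge regularization makes
  the elimination well-defined even for singular designs.
* The GA evolves binary masks over the top-2000-variance candidate pool:
  population 50, 30 generations, tournament size 3, uniform crossover,
  bit-flip mutation at rate 1/L, fitness = 3-fold inner-CV Pearson r of a
  ridge model minus 0.001 per selected gene.  Fully seeded.
* MRMR/GA/RFE default to a 500-gene budget for parity with the
  correlation selector; no canonical budget exists for them.

## Models and protocol

Elastic Net and Random Forest come from scikit-learn with small default
grids (mixing and penalty strength; tree depth).  The neural network is a
compact NumPy implementation: stacked dense layers, ReLU hidden
activations, inverted dropout 0.2 after each hidden layer, a sigmoid
output (predictions confined to (0, 1), matching AAC), MSE loss, SGD with
learning rate 0.01 and momentum 0.9, 15 epochs, and 6 restarts keeping
the best validation-split model.  Default architecture (256, 64), tunable
through the grid.

Within-domain evaluation is 4-fold CV repeated 20 times (fewer repeats in
tests; a protocol parameter).  Supervised selectors, the scaler and the
hyperparameter search are all re-fitted inside each fold's training
portion — an intentionally leak-free reading of "apply selection, then
cross-validate"; a `refit_selector_per_fold=False` flag reproduces the
whole-dataset variant.  The 80/20 language and the 4-fold structure are
reconciled by letting the repeated 4-fold splits provide the ~75/25 outer
evaluation and a 3-fold inner grid search provide tuning; this is one
coherent protocol, fixed and documented rather than guessed per-figure.
Cross-domain validation intersects gene universes, tunes entirely within
the training domain, and applies the chosen model once to the test
domain.

Metric aggregation over folds averages MSE and re-derives RMSE as
√(mean MSE), preserving the RMSE² = MSE identity at the row level.
Constant predictions leave correlations flagged undefined rather than
NaN-propagated; paired selector comparisons drop incomplete drug pairs
and require at least three.

## Univariate and survival validation

The gene-group contrast uses Welch's t-test by default: the text-mining
group (tens of genes) and its complement (hundreds to thousands) have
very unequal sizes and no reason for equal variances; the pooled-variance
variant is available by flag.  The across-drug summary pairs per-drug
group means and applies a paired t-test over drugs.

Survival validation trains a Random Forest on the text-mining genes
shared with the cohort's expression, predicts per-subject response,
splits at the median (ties go to the high group — a fixed rule, relevant
at even cohort sizes), and compares groups with Kaplan–Meier estimates
and the two-group log-rank test (lifelines).  The synthetic cohort draws
time-to-progression from an exponential with hazard
0.01·exp(−4·(r − ½)) days⁻¹, r the true sensitivity, censored at 365
days: more sensitive subjects progress later, with ~no claim about any
particular clinical endpoint.  A 200-seed null (hazard coefficient 0)
verifies the test's size: the empirical false-positive rate at α = 0.05
stays near nominal and the p-distribution is approximately uniform.

## Numerical notes and limitations

* All randomness flows through `numpy.random.default_rng` seeds; every
  generator, selector and scenario is bit-deterministic given its seed.
* Fisher p-values use the exact hypergeometric survival function; tests
  cross-check them against integer enumeration on all small tables.
* BH q-values come from statsmodels; KM/log-rank from lifelines — both
  cross-checked against hand-computed and permutation oracles in tests.
* The GA's fitness landscape is noisy at small sample sizes; its tests
  use planted toys where the optimum is unambiguous.
* Known limitations: the corpus generator's bag-of-words abstracts carry
  no syntax or entity ambiguity (gene links are given, not extracted);
  the domain shift is location-only; the neural model is small and CPU
  oriented; multi-arm survival comparisons and tissue covariates are out
  of scope.
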