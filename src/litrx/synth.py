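"""Seeded synthetic-data generators.

Two substrates are emulated:

1. A literature corpus in which a planted gene subset is enriched for
   drug-topic abstracts (:func:`generate_corpus`).  Each abstract carries a
   bag of tokens drawn from class-conditional Bernoulli presence rates
   (vocabulary split into topic-informative, background-informative and
   neutral strata, so that both classes have characteristic vocabulary)
   and a short list of linked genes; abstracts linked to a planted gene
   have their topic-label odds multiplied by ``link_enrichment``.

2. Paired train/test pharmacogenomic domains sharing a sparse
   expression→AAC signal with additive domain shift
   (:func:`generate_pharmaco_pair`).  AAC = logistic(Σ w_g·x_g + noise),
   which keeps responses strictly inside (0,1); the test domain differs by
   a per-gene mean shift drawn from N(0, domain_shift_sd).

A third generator, :func:`generate_pdx_cohort`, produces a small in-vivo
style validation cohort: subject expression from the same signal model and
survival times whose hazard decreases with the true drug sensitivity.

All generators are bit-deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from litrx.litminer import AbstractRecord, Corpus
from litrx.pharmodata import PharmacoDataset


def gene_id(i: int) -> str:
    return f"g{i + 1:04d}"


def _token_id(i: int) -> str:
    return f"t{i + 1:04d}"


@dataclass(frozen=True)
class CorpusSpec:
    """Parameters of the synthetic literature corpus.

    The default prevalence (1000 topic / 4000 background abstracts) makes
    the drug topic a minority class, as it is in real literature; gene
    links per abstract follow Poisson(link_poisson_mean) truncated to
    [1, 10] — curated link lists are short but dense enough that each gene
    accrues a few dozen linked abstracts.
    """

    n_genes: int = 1000
    planted_genes: frozenset[str] = field(default_factory=frozenset)
    n_abstracts_topic: int = 1000
    n_abstracts_background: int = 4000
    vocab_size: int = 2000
    topic_token_rate: float = 0.35
    background_token_rate: float = 0.05
    link_enrichment: float = 8.0
    seed: int = 0
    n_informative_tokens: int = 150
    link_poisson_mean: float = 8.0

    def __post_init__(self) -> None:
        universe = {gene_id(i) for i in range(self.n_genes)}
        if not set(self.planted_genes) <= universe:
            raise ValueError("planted gene outside the gene universe")
        if not (0.0 < self.background_token_rate < 1.0):
            raise ValueError("background_token_rate must be in (0, 1)")
        if not (0.0 < self.topic_token_rate < 1.0):
            raise ValueError("topic_token_rate must be in (0, 1)")
        if self.topic_token_rate <= self.background_token_rate:
            raise ValueError("topic_token_rate must exceed background_token_rate")
        if self.link_enrichment < 1.0:
            raise ValueError("link_enrichment must be >= 1")
        if 2 * self.n_informative_tokens >= self.vocab_size:
            raise ValueError("informative strata must be smaller than the vocabulary")

    @staticmethod
    def with_planted(n_planted: int = 50, **kw) -> "CorpusSpec":
        """Spec whose planted set is the first ``n_planted`` gene ids."""
        return CorpusSpec(
            planted_genes=frozenset(gene_id(i) for i in range(n_planted)), **kw
        )


def _truncated_poisson(rng: np.random.Generator, mean: float, size: int) -> np.ndarray:
    """Poisson(mean) conditioned on [1, 10]."""
    out = rng.poisson(mean, size=size)
    bad = (out < 1) | (out > 10)
    while bad.any():
        out[bad] = rng.poisson(mean, size=int(bad.sum()))
        bad = (out < 1) | (out > 10)
    return out


def generate_corpus(spec: CorpusSpec) -> Corpus:
    """Generate the labeled corpus with planted gene–topic association."""
    rng = np.random.default_rng(spec.seed)
    n_total = spec.n_abstracts_topic + spec.n_abstracts_background
    base_odds = spec.n_abstracts_topic / spec.n_abstracts_background
    planted = spec.planted_genes

    link_counts = _truncated_poisson(rng, spec.link_poisson_mean, n_total)
    genes_per_abstract = [
        [gene_id(i) for i in rng.choice(spec.n_genes, size=int(k), replace=False)]
        for k in link_counts
    ]
    has_planted = np.array(
        [any(g in planted for g in gs) for gs in genes_per_abstract]
    )
    odds = np.where(has_planted, base_odds * spec.link_enrichment, base_odds)
    is_topic = rng.random(n_total) < odds / (1.0 + odds)

    n_inf = spec.n_informative_tokens
    v = spec.vocab_size
    tokens_all = np.array([_token_id(i) for i in range(v)])
    # stratum 1: topic-characteristic; stratum 2: background-characteristic;
    # remainder: neutral (same low rate in both classes)
    rates_topic = np.full(v, spec.background_token_rate)
    rates_topic[:n_inf] = spec.topic_token_rate
    rates_bg = np.full(v, spec.background_token_rate)
    rates_bg[n_inf : 2 * n_inf] = spec.topic_token_rate

    abstracts = []
    for i in range(n_total):
        rates = rates_topic if is_topic[i] else rates_bg
        present = rng.random(v) < rates
        toks = tokens_all[present]
        if toks.size == 0:  # vanishingly rare; keep the nonempty invariant
            toks = tokens_all[-1:]
        abstracts.append(
            AbstractRecord(
                id=f"a{i + 1:05d}",
                tokens=tuple(toks),
                gene_ids=frozenset(genes_per_abstract[i]),
                label="topic" if is_topic[i] else "background",
            )
        )
    return Corpus(abstracts)


@dataclass(frozen=True)
class PharmacoSpec:
    """Parameters of the paired train/test pharmacogenomic domains.

    ``signal_genes`` / ``effect_sizes`` may be a single list (shared by all
    drugs) or a per-drug mapping.  Log-expression is standard normal in
    the training domain; the test domain adds a per-gene mean shift drawn
    from N(0, domain_shift_sd).
    """

    n_samples_train: int = 150
    n_samples_test: int = 100
    n_genes: int = 1000
    signal_genes: object = None  # Sequence[str] | Mapping[str, Sequence[str]]
    effect_sizes: object = None  # Sequence[float] | Mapping[str, Sequence[float]]
    noise_sd: float = 0.3
    domain_shift_sd: float = 0.5
    n_drugs: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.domain_shift_sd < 0:
            raise ValueError("domain_shift_sd must be >= 0")
        universe = {gene_id(i) for i in range(self.n_genes)}
        for genes, weights in self._iter_signals():
            if not set(genes) <= universe:
                raise ValueError("signal gene outside the gene universe")
            if len(genes) != len(weights):
                raise ValueError("effect_sizes must align with signal_genes")

    def drug_ids(self) -> list[str]:
        if isinstance(self.signal_genes, Mapping):
            return sorted(self.signal_genes)
        return [f"D{i + 1:02d}" for i in range(self.n_drugs)]

    def _iter_signals(self):
        if self.signal_genes is None:
            return
        if isinstance(self.signal_genes, Mapping):
            for d in sorted(self.signal_genes):
                yield list(self.signal_genes[d]), list(self.effect_sizes[d])
        else:
            genes = list(self.signal_genes)
            weights = list(self.effect_sizes) if self.effect_sizes is not None else []
            yield genes, weights

    def signal_for(self, drug: str) -> tuple[list[str], np.ndarray]:
        if self.signal_genes is None:
            return [], np.zeros(0)
        if isinstance(self.signal_genes, Mapping):
            return (
                list(self.signal_genes[drug]),
                np.asarray(self.effect_sizes[drug], dtype=float),
            )
        return (
            list(self.signal_genes),
            np.asarray(self.effect_sizes, dtype=float),
        )


def _logistic(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _make_domain(
    spec: PharmacoSpec,
    rng: np.random.Generator,
    sample_prefix: str,
    n_samples: int,
    gene_shift: np.ndarray,
) -> PharmacoDataset:
    genes = [gene_id(i) for i in range(spec.n_genes)]
    samples = [f"{sample_prefix}{i + 1:04d}" for i in range(n_samples)]
    x = rng.standard_normal((n_samples, spec.n_genes)) + gene_shift
    expr = pd.DataFrame(x, index=samples, columns=genes)
    rows = []
    truth = {}
    for drug in spec.drug_ids():
        sg, w = spec.signal_for(drug)
        idx = [genes.index(g) for g in sg]
        eta = x[:, idx] @ w if idx else np.zeros(n_samples)
        noise = rng.normal(0.0, spec.noise_sd, size=n_samples)
        aac = _logistic(eta + noise)
        truth[drug] = {"genes": list(sg), "weights": list(map(float, w))}
        rows.extend(
            {"sample_id": s, "drug_id": drug, "aac": float(v)}
            for s, v in zip(samples, aac)
        )
    return PharmacoDataset(
        expression=expr, responses=pd.DataFrame(rows), truth=truth
    )


def generate_pharmaco_pair(
    spec: PharmacoSpec,
) -> tuple[PharmacoDataset, PharmacoDataset]:
    """Train/test domains sharing the same sparse linear AAC signal.

    Both domains use identical per-drug signal genes and weights; only the
    per-gene expression means differ.  The ground-truth signal is recorded
    on each dataset's ``truth`` attribute.
    """
    rng = np.random.default_rng(spec.seed)
    train = _make_domain(spec, rng, "T", spec.n_samples_train, np.zeros(spec.n_genes))
    shift = rng.normal(0.0, spec.domain_shift_sd, size=spec.n_genes)
    test = _make_domain(spec, rng, "V", spec.n_samples_test, shift)
    return train, test


def sample_drug_signals(
    pool: Sequence[str],
    n_drugs: int,
    genes_per_drug: int = 10,
    effect_sd: float = 0.8,
    seed: int = 0,
) -> tuple[dict[str, list[str]], dict[str, list[float]]]:
    """Draw per-drug signal gene sets from a pool with N(0, effect_sd²) weights.

    Used to couple the pharmacogenomic generator to the corpus generator:
    passing the corpus's planted genes as the pool makes the text-mining
    feature set the (noisy) superset of every drug's causal genes.
    """
    rng = np.random.default_rng(seed)
    pool = list(pool)
    if genes_per_drug > len(pool):
        raise ValueError("genes_per_drug exceeds the pool size")
    genes = {}
    weights = {}
    for i in range(n_drugs):
        d = f"D{i + 1:02d}"
        pick = rng.choice(len(pool), size=genes_per_drug, replace=False)
        genes[d] = [pool[j] for j in pick]
        w = rng.normal(0.0, effect_sd, size=genes_per_drug)
        # avoid near-null drugs: keep every weight away from zero
        w = np.sign(w) * np.maximum(np.abs(w), 0.25 * effect_sd)
        weights[d] = list(map(float, w))
    return genes, weights


def generate_pdx_cohort(
    spec: PharmacoSpec,
    drug: str,
    n_subjects: int = 24,
    hazard_scale: float = 0.01,
    hazard_coef: float = 4.0,
    censor_horizon: float = 365.0,
    seed: int = 1,
) -> tuple[pd.DataFrame, pd.DataFrame, np.ndarray]:
    """Small in-vivo style cohort: expression, survival table, true response.

    Subject expression follows the training-domain model; the true
    (noise-free) sensitivity r = logistic(Σ w_g·x_g) sets an exponential
    hazard ``hazard_scale · exp(-hazard_coef · (r - 1/2))`` — more
    sensitive subjects progress later.  Times beyond ``censor_horizon``
    are right-censored (event = 0).  Times are in days.
    """
    rng = np.random.default_rng(seed)
    genes = [gene_id(i) for i in range(spec.n_genes)]
    subjects = [f"P{i + 1:03d}" for i in range(n_subjects)]
    x = rng.standard_normal((n_subjects, spec.n_genes))
    expr = pd.DataFrame(x, index=subjects, columns=genes)
    sg, w = spec.signal_for(drug)
    idx = [genes.index(g) for g in sg]
    eta = x[:, idx] @ w if idx else np.zeros(n_subjects)
    response = _logistic(eta)
    hazard = hazard_scale * np.exp(-hazard_coef * (response - 0.5))
    t = rng.exponential(1.0 / hazard)
    event = (t <= censor_horizon).astype(int)
    time = np.minimum(t, censor_horizon)
    surv = pd.DataFrame(
        {"subject_id": subjects, "time_days": time, "event": event}
    )
    return expr, surv, response
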