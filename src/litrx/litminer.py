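"""Text-mining gene–drug association scoring.

Given a corpus of literature abstracts, each carrying a list of linked
genes, the miner (i) trains a Bernoulli naive-Bayes topic classifier on
labeled abstracts, (ii) classifies every abstract in the corpus as
relevant/irrelevant to the drug topic, (iii) scores each gene by the
enrichment of relevant abstracts among those linked to it (one-sided
Fisher's exact test on the 2×2 linked × relevant table), and (iv) emits the
genes passing a p-value cutoff ranked by ascending Benjamini–Hochberg false
discovery rate.  The resulting ordered gene list is the "text-mining"
feature set for the drug.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

LABELS = ("topic", "background", "unlabeled")


@dataclass(frozen=True)
class AbstractRecord:
    """One literature abstract: token presence set, linked genes, label."""

    id: str
    tokens: tuple[str, ...]
    gene_ids: frozenset[str]
    label: str = "unlabeled"

    def __post_init__(self) -> None:
        if not self.tokens:
            raise ValueError(f"abstract {self.id!r} has no tokens")
        if self.label not in LABELS:
            raise ValueError(f"unknown label {self.label!r}")


class Corpus:
    """Abstract collection with a gene → abstract-id inverted index."""

    def __init__(self, abstracts: Sequence[AbstractRecord]):
        self.abstracts: list[AbstractRecord] = list(abstracts)
        ids = [a.id for a in self.abstracts]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate abstract ids")
        self.gene_index: dict[str, set[str]] = {}
        for a in self.abstracts:
            for g in a.gene_ids:
                self.gene_index.setdefault(g, set()).add(a.id)

    def __len__(self) -> int:
        return len(self.abstracts)

    def __getitem__(self, i: int) -> AbstractRecord:
        return self.abstracts[i]

    def labeled(self, label: str) -> list[AbstractRecord]:
        return [a for a in self.abstracts if a.label == label]

    def to_jsonl(self, path: str | Path) -> None:
        """Write one abstract per line: id, tokens, gene_ids, label."""
        with open(path, "w") as fh:
            for a in self.abstracts:
                fh.write(
                    json.dumps(
                        {
                            "id": a.id,
                            "tokens": list(a.tokens),
                            "gene_ids": sorted(a.gene_ids),
                            "label": a.label,
                        }
                    )
                    + "\n"
                )

    @classmethod
    def from_jsonl(cls, path: str | Path) -> "Corpus":
        abstracts = []
        with open(path) as fh:
            for line in fh:
                if not line.strip():
                    continue
                d = json.loads(line)
                abstracts.append(
                    AbstractRecord(
                        id=d["id"],
                        tokens=tuple(d["tokens"]),
                        gene_ids=frozenset(d["gene_ids"]),
                        label=d.get("label", "unlabeled"),
                    )
                )
        return cls(abstracts)


@dataclass
class TopicClassifier:
    """Bernoulli naive Bayes as a linear function of token presence.

    The posterior log-odds of a document being topic-relevant is
    ``prior_log_odds + sum(token_log_odds[t] for t in document)``; a token
    absent from the table contributes 0 (it was seen in neither class, so
    the smoothed class-conditional rates coincide).
    """

    token_log_odds: dict[str, float]
    prior_log_odds: float = 0.0
    decision_threshold: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 <= self.decision_threshold <= 1.0:
            raise ValueError("decision_threshold must be in [0, 1]")

    def log_odds(self, tokens: Iterable[str]) -> float:
        lo = self.prior_log_odds
        for t in set(tokens):
            lo += self.token_log_odds.get(t, 0.0)
        return lo

    def posterior(self, tokens: Iterable[str]) -> float:
        return 1.0 / (1.0 + math.exp(-self.log_odds(tokens)))


def train_topic_classifier(
    positives: Sequence[AbstractRecord],
    background: Sequence[AbstractRecord],
    smoothing: float = 1.0,
) -> TopicClassifier:
    """Fit the presence-based naive-Bayes topic classifier.

    Token weights are smoothed log odds-ratios of document frequency:
    ``log[(n_pos(t)+s)/(N_pos+2s)] - log[(n_bg(t)+s)/(N_bg+2s)]`` with
    Laplace smoothing ``s``.  The prior log-odds reflect the class sizes
    (zero for balanced training sets).
    """
    if not positives or not background:
        raise ValueError("both training classes must be nonempty")
    if smoothing <= 0:
        raise ValueError("smoothing must be > 0")
    n_pos, n_bg = len(positives), len(background)
    df_pos: dict[str, int] = {}
    df_bg: dict[str, int] = {}
    for a in positives:
        for t in set(a.tokens):
            df_pos[t] = df_pos.get(t, 0) + 1
    for a in background:
        for t in set(a.tokens):
            df_bg[t] = df_bg.get(t, 0) + 1
    s = smoothing
    weights = {}
    for t in set(df_pos) | set(df_bg):
        w = math.log((df_pos.get(t, 0) + s) / (n_pos + 2 * s)) - math.log(
            (df_bg.get(t, 0) + s) / (n_bg + 2 * s)
        )
        weights[t] = w
    prior = math.log(n_pos / n_bg)
    return TopicClassifier(token_log_odds=weights, prior_log_odds=prior)


def classify_abstracts(
    clf: TopicClassifier, corpus: Corpus
) -> dict[str, str]:
    """Label every abstract 'relevant' or 'irrelevant' by posterior threshold."""
    out = {}
    for a in corpus.abstracts:
        post = clf.posterior(a.tokens)
        out[a.id] = "relevant" if post >= clf.decision_threshold else "irrelevant"
    return out


def classifier_accuracy(
    clf: TopicClassifier, abstracts: Sequence[AbstractRecord]
) -> float:
    """Held-out accuracy against topic/background labels."""
    labeled = [a for a in abstracts if a.label in ("topic", "background")]
    if not labeled:
        raise ValueError("no labeled abstracts")
    correct = 0
    for a in labeled:
        pred = clf.posterior(a.tokens) >= clf.decision_threshold
        correct += pred == (a.label == "topic")
    return correct / len(labeled)


@dataclass
class GeneScore:
    """Per-gene 2×2 enrichment result.

    a: gene-linked ∧ relevant, b: gene-linked ∧ irrelevant,
    c: not-linked ∧ relevant, d: not-linked ∧ irrelevant.
    """

    gene_id: str
    a: int
    b: int
    c: int
    d: int
    p_value: float
    q_value: float = float("nan")


def fisher_enrichment_p(a: int, b: int, c: int, d: int) -> float:
    """One-sided (enrichment, 'greater') Fisher exact p for a 2×2 table.

    Under the null the count in cell *a* is hypergeometric with population
    N = a+b+c+d, K = a+c successes (relevant), n = a+b draws (gene-linked);
    p = P(X >= a).
    """
    if min(a, b, c, d) < 0:
        raise ValueError("negative cell count")
    n_total = a + b + c + d
    return float(hypergeom.sf(a - 1, n_total, a + c, a + b))


def score_gene(
    gene_id: str, classifications: Mapping[str, str], corpus: Corpus
) -> GeneScore:
    """Fisher enrichment of relevant abstracts among those linked to a gene.

    The scoring universe is every classified abstract, linked or not, so
    the table margins are identical across genes.
    """
    linked = corpus.gene_index.get(gene_id)
    if not linked:
        raise ValueError(f"gene {gene_id!r} has no linked abstracts")
    a = b = c = d = 0
    for aid, cls in classifications.items():
        rel = cls == "relevant"
        if aid in linked:
            a += rel
            b += not rel
        else:
            c += rel
            d += not rel
    p = fisher_enrichment_p(a, b, c, d)
    return GeneScore(gene_id=gene_id, a=a, b=b, c=c, d=d, p_value=p)


def score_all_genes(
    classifications: Mapping[str, str], corpus: Corpus
) -> list[GeneScore]:
    return [
        score_gene(g, classifications, corpus)
        for g in sorted(corpus.gene_index)
        if corpus.gene_index[g]
    ]


@dataclass
class FeatureSet:
    """Ordered gene list emitted by any selector (best first)."""

    drug_id: str
    method: str
    genes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("FeatureSet genes must be unique")

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {"drug": self.drug_id, "method": self.method, "genes": self.genes},
                fh,
                indent=1,
            )

    @classmethod
    def from_json(cls, path: str | Path) -> "FeatureSet":
        with open(path) as fh:
            d = json.load(fh)
        return cls(drug_id=d["drug"], method=d["method"], genes=list(d["genes"]))


def bh_qvalues(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values."""
    return multipletests(np.asarray(pvals, dtype=float), method="fdr_bh")[1]


def rank_and_select(
    scores: Sequence[GeneScore],
    p_cutoff: float = 0.01,
    drug_id: str = "drug",
    method: str = "text-mining",
) -> FeatureSet:
    """Keep genes with p < cutoff, ranked by ascending BH q-value.

    q-values are computed over *all* scored genes; ties broken by ascending
    p then lexical gene id, for reproducibility.
    """
    if not scores:
        return FeatureSet(drug_id=drug_id, method=method, genes=[])
    qs = bh_qvalues([s.p_value for s in scores])
    for s, q in zip(scores, qs):
        s.q_value = float(q)
    kept = [s for s in scores if s.p_value < p_cutoff]
    kept.sort(key=lambda s: (s.q_value, s.p_value, s.gene_id))
    return FeatureSet(drug_id=drug_id, method=method, genes=[s.gene_id for s in kept])


def write_score_table(scores: Sequence[GeneScore], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "gene": s.gene_id,
                "a": s.a,
                "b": s.b,
                "c": s.c,
                "d": s.d,
                "p": s.p_value,
                "q": s.q_value,
            }
            for s in scores
        ]
    ).to_csv(path, sep="\t", index=False)


def mine_genes(
    corpus: Corpus,
    drug_id: str = "drug",
    n_train: int = 1000,
    p_cutoff: float = 0.01,
    smoothing: float = 1.0,
    decision_threshold: float = 0.5,
    seed: int = 0,
) -> tuple[FeatureSet, list[GeneScore], TopicClassifier]:
    """End-to-end mining: train classifier, classify corpus, rank genes.

    Training uses ``n_train`` topic abstracts and an equal-sized background
    sample (balanced priors), both drawn without replacement from the
    labeled part of the corpus; the whole corpus is then classified and
    scored.
    """
    rng = np.random.default_rng(seed)
    topic = corpus.labeled("topic")
    bg = corpus.labeled("background")
    if len(topic) < 2 or len(bg) < 2:
        raise ValueError("corpus must contain labeled topic and background abstracts")
    n = min(n_train, len(topic), len(bg))
    pos = [topic[i] for i in rng.choice(len(topic), size=n, replace=False)]
    neg = [bg[i] for i in rng.choice(len(bg), size=n, replace=False)]
    clf = train_topic_classifier(pos, neg, smoothing=smoothing)
    clf.decision_threshold = decision_threshold
    classifications = classify_abstracts(clf, corpus)
    scores = score_all_genes(classifications, corpus)
    fs = rank_and_select(scores, p_cutoff=p_cutoff, drug_id=drug_id)
    return fs, scores, clf
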