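import numpy as np
import pandas as pd
import pytest

from litrx.litminer import AbstractRecord, Corpus
from litrx.pharmodata import PharmacoDataset
from litrx.synth import (
    CorpusSpec,
    PharmacoSpec,
    generate_corpus,
    generate_pharmaco_pair,
    gene_id,
    sample_drug_signals,
)


@pytest.fixture(scope="session")
def default_corpus_spec() -> CorpusSpec:
    """The default synthetic corpus: 5000 abstracts, 1000 genes, 50 planted,
    link enrichment 8."""
    return CorpusSpec.with_planted(50, seed=20240101)


@pytest.fixture(scope="session")
def default_corpus(default_corpus_spec) -> Corpus:
    return generate_corpus(default_corpus_spec)


@pytest.fixture(scope="session")
def small_pharmaco_pair():
    """A small train/test domain pair with 3 drugs and a known sparse signal."""
    pool = [gene_id(i) for i in range(30)]
    genes, weights = sample_drug_signals(pool, n_drugs=3, genes_per_drug=6, seed=5)
    spec = PharmacoSpec(
        n_samples_train=120,
        n_samples_test=80,
        n_genes=200,
        signal_genes=genes,
        effect_sizes=weights,
        noise_sd=0.3,
        domain_shift_sd=0.4,
        seed=7,
    )
    return spec, generate_pharmaco_pair(spec)


def toy_dataset(x: np.ndarray, y: np.ndarray, drug: str = "D") -> PharmacoDataset:
    """Wrap arrays into a PharmacoDataset (samples s1.., genes f1..)."""
    n, p = x.shape
    samples = [f"s{i+1}" for i in range(n)]
    genes = [f"f{j+1:02d}" for j in range(p)]
    expr = pd.DataFrame(x, index=samples, columns=genes)
    resp = pd.DataFrame(
        {"sample_id": samples, "drug_id": drug, "aac": np.clip(y, 0.0, 1.0)}
    )
    return PharmacoDataset(expression=expr, responses=resp)


def make_abstract(aid: str, tokens, genes=(), label="unlabeled") -> AbstractRecord:
    return AbstractRecord(
        id=aid, tokens=tuple(tokens), gene_ids=frozenset(genes), label=label
    )
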