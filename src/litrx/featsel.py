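"""Nine feature-selection strategies for drug-response modelling.

Each selector consumes only the training domain and emits an ordered
:class:`~litrx.litminer.FeatureSet` (best gene first):

* ``text-mining`` — the literature-mined gene list (see litminer),
  intersected with the dataset universe via :func:`list_select`.
* ``var_100`` / ``var_500`` — top-k genes by unscaled training variance.
* ``cor_500`` — top-k genes by |Pearson r| with the drug's AAC.
* ``L1000`` — a supplied landmark gene list; ``L1000-tm`` — the same list
  with the drug's text-mining genes removed.
* ``MRMR`` — greedy minimum-redundancy maximum-relevance (MID scheme).
* ``RFE`` — recursive feature elimination with a ridge base model.
* ``GA`` — a seeded genetic algorithm over binary feature masks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from sklearn.linear_model import Ridge
from sklearn.model_selection import KFold

from litrx.litminer import FeatureSet
from litrx.pharmodata import PharmacoDataset

METHODS = (
    "text-mining",
    "var_100",
    "var_500",
    "cor_500",
    "L1000",
    "L1000-tm",
    "MRMR",
    "GA",
    "RFE",
)


@dataclass
class SelectorConfig:
    method: str
    k: int = 500
    seed: int = 0
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.method not in METHODS and self.method != "oracle":
            raise ValueError(f"unknown selector method {self.method!r}")
        if self.k < 1:
            raise ValueError("k must be >= 1")


def _aligned_xy(
    train: PharmacoDataset, drug: str
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    y = train.response_vector(drug)
    x = train.expression.loc[y.index]
    return x.to_numpy(dtype=float), y.to_numpy(dtype=float), list(x.columns)


def _abs_pearson(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """|Pearson r| of every column of x with y; zero-variance columns → 0."""
    xc = x - x.mean(axis=0)
    yc = y - y.mean()
    sx = np.sqrt((xc**2).sum(axis=0))
    sy = np.sqrt((yc**2).sum())
    denom = sx * sy
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.abs(xc.T @ yc) / denom
    r[denom == 0] = 0.0
    return np.nan_to_num(r, nan=0.0)


def _ordered_top(names: Sequence[str], score: np.ndarray, k: int) -> list[str]:
    """Top-k names by descending score, ties by lexical name."""
    order = sorted(range(len(names)), key=lambda i: (-score[i], names[i]))
    return [names[i] for i in order[:k]]


def variance_select(train: PharmacoDataset, k: int, drug: str = "") -> FeatureSet:
    """Top-k genes by unscaled training variance (unsupervised)."""
    genes = train.genes
    if k > len(genes):
        raise ValueError(f"k={k} exceeds {len(genes)} genes")
    var = train.expression.to_numpy(dtype=float).var(axis=0, ddof=1)
    return FeatureSet(
        drug_id=drug, method=f"var_{k}", genes=_ordered_top(genes, var, k)
    )


def correlation_select(train: PharmacoDataset, drug: str, k: int = 500) -> FeatureSet:
    """Top-k genes by |Pearson r| with the drug's AAC on training data."""
    x, y, genes = _aligned_xy(train, drug)
    if len(y) < 3:
        raise ValueError("need at least 3 responding samples")
    if k > len(genes):
        raise ValueError(f"k={k} exceeds {len(genes)} genes")
    r = _abs_pearson(x, y)
    return FeatureSet(drug_id=drug, method="cor_500", genes=_ordered_top(genes, r, k))


def list_select(
    gene_list: Sequence[str],
    universe: Sequence[str],
    drug: str = "",
    method: str = "L1000",
) -> FeatureSet:
    """Intersect an external gene list with the dataset universe.

    Input order is preserved; duplicates keep their first occurrence.
    Covers the L1000 and text-mining-as-features selectors.
    """
    if not gene_list:
        raise ValueError("empty gene list")
    uni = set(universe)
    seen: set[str] = set()
    kept = []
    for g in gene_list:
        if g in uni and g not in seen:
            kept.append(g)
            seen.add(g)
    if not kept:
        raise ValueError("gene list does not intersect the dataset universe")
    return FeatureSet(drug_id=drug, method=method, genes=kept)


def l1000_minus_tm(
    l1000: Sequence[str], tm: FeatureSet, drug: str = ""
) -> FeatureSet:
    """L1000 landmark list with the drug's text-mining genes removed."""
    if not l1000:
        raise ValueError("empty L1000 list")
    drop = set(tm.genes)
    seen: set[str] = set()
    kept = []
    for g in l1000:
        if g not in drop and g not in seen:
            kept.append(g)
            seen.add(g)
    return FeatureSet(drug_id=drug or tm.drug_id, method="L1000-tm", genes=kept)


def mrmr_select(train: PharmacoDataset, drug: str, k: int) -> FeatureSet:
    """Greedy MRMR with the MID (difference) scheme on continuous data.

    Relevance of gene g is |Pearson r(x_g, y)|; redundancy is the mean
    |Pearson r| of g with the already-selected set.  The first pick is the
    most relevant gene; afterwards the gene maximizing
    relevance − redundancy is added, ties broken by lexical gene id.
    """
    x, y, genes = _aligned_xy(train, drug)
    n_genes = len(genes)
    if k > n_genes:
        raise ValueError(f"k={k} exceeds {n_genes} genes")
    if len(y) < 3:
        raise ValueError("need at least 3 responding samples")
    relevance = _abs_pearson(x, y)
    # standardized columns for incremental gene-gene correlations
    xc = x - x.mean(axis=0)
    norms = np.sqrt((xc**2).sum(axis=0))
    norms[norms == 0] = 1.0
    xs = xc / norms
    selected: list[int] = []
    red_sum = np.zeros(n_genes)
    available = np.ones(n_genes, dtype=bool)
    # lexical rank for deterministic tie-breaks
    lex = np.argsort(np.argsort(genes))
    for _ in range(k):
        if selected:
            score = relevance - red_sum / len(selected)
        else:
            score = relevance.copy()
        score[~available] = -np.inf
        best = np.lexsort((lex, -score))[0]
        selected.append(best)
        available[best] = False
        red_sum += np.abs(xs.T @ xs[:, best])
    return FeatureSet(
        drug_id=drug, method="MRMR", genes=[genes[i] for i in selected]
    )


def rfe_select(
    train: PharmacoDataset,
    drug: str,
    k: int,
    step: float = 0.1,
    alpha: float = 1.0,
) -> FeatureSet:
    """Recursive feature elimination with a ridge base regressor.

    Data are z-scaled internally; each round drops the ``step`` fraction
    (at least one) of the remaining genes with the smallest |coefficient|
    until ``k`` remain.  Survivors are ranked by final |coefficient|.
    """
    x, y, genes = _aligned_xy(train, drug)
    if k > len(genes):
        raise ValueError(f"k={k} exceeds {len(genes)} genes")
    mu, sd = x.mean(axis=0), x.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    xz = (x - mu) / sd
    remaining = list(range(len(genes)))
    while len(remaining) > k:
        model = Ridge(alpha=alpha).fit(xz[:, remaining], y)
        coefs = np.abs(model.coef_)
        n_drop = max(1, int(step * len(remaining)) if step < 1 else int(step))
        n_drop = min(n_drop, len(remaining) - k)
        # drop smallest |coef|; ties resolved by lexical gene id (drop later ids)
        order = sorted(
            range(len(remaining)),
            key=lambda i: (coefs[i], tuple(reversed(genes[remaining[i]]))),
        )
        drop = {remaining[i] for i in order[:n_drop]}
        remaining = [i for i in remaining if i not in drop]
    final = Ridge(alpha=alpha).fit(xz[:, remaining], y)
    score = np.abs(final.coef_)
    names = [genes[i] for i in remaining]
    return FeatureSet(drug_id=drug, method="RFE", genes=_ordered_top(names, score, k))


@dataclass
class GAParams:
    population: int = 50
    generations: int = 30
    tournament: int = 3
    crossover_rate: float = 0.5
    mutation_rate: Optional[float] = None  # default 1/L
    pool_size: int = 2000
    sparsity_penalty: float = 0.001
    init_density: float = 0.1
    cv_folds: int = 3
    ridge_alpha: float = 1.0

    def __post_init__(self) -> None:
        if self.population < 2 or self.generations < 1 or self.tournament < 1:
            raise ValueError("invalid GA parameters")
        if not 0 < self.init_density <= 1:
            raise ValueError("init_density must be in (0, 1]")


def _ga_fitness(
    mask: np.ndarray,
    x: np.ndarray,
    y: np.ndarray,
    params: GAParams,
    seed: int,
) -> float:
    """Mean inner-CV Pearson r of a ridge model on the masked features,
    penalized by mask size."""
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return -np.inf
    xm = x[:, idx]
    rs = []
    kf = KFold(n_splits=params.cv_folds, shuffle=True, random_state=seed)
    for tr, te in kf.split(xm):
        model = Ridge(alpha=params.ridge_alpha).fit(xm[tr], y[tr])
        pred = model.predict(xm[te])
        if np.std(pred) == 0 or np.std(y[te]) == 0:
            rs.append(0.0)
        else:
            rs.append(float(np.corrcoef(pred, y[te])[0, 1]))
    return float(np.mean(rs)) - params.sparsity_penalty * idx.size


def ga_select(
    train: PharmacoDataset,
    drug: str,
    k_max: int = 500,
    ga_params: Optional[GAParams] = None,
    seed: int = 0,
) -> FeatureSet:
    """Genetic-algorithm feature-subset search over binary masks.

    The candidate pool is the top ``pool_size`` genes by variance.
    Tournament selection, uniform crossover and bit-flip mutation evolve
    masks whose fitness is the inner-CV Pearson r of a ridge model minus a
    sparsity penalty.  Fully deterministic given the seed; the best mask's
    genes are returned ordered by relevance.
    """
    params = ga_params or GAParams()
    x, y, genes = _aligned_xy(train, drug)
    pool_n = min(params.pool_size, len(genes))
    var = x.var(axis=0, ddof=1) if x.shape[0] > 1 else np.zeros(x.shape[1])
    pool_idx = sorted(
        range(len(genes)), key=lambda i: (-var[i], genes[i])
    )[:pool_n]
    xp = x[:, pool_idx]
    names = [genes[i] for i in pool_idx]
    L = pool_n
    mut = params.mutation_rate if params.mutation_rate is not None else 1.0 / L
    rng = np.random.default_rng(seed)

    density = min(params.init_density, k_max / L)
    pop = rng.random((params.population, L)) < density
    for ind in pop:  # every mask starts nonempty
        if not ind.any():
            ind[rng.integers(L)] = True
    fits = np.array(
        [_ga_fitness(ind, xp, y, params, seed) for ind in pop]
    )
    best_mask, best_fit = pop[np.argmax(fits)].copy(), float(fits.max())

    for _ in range(params.generations):
        children = np.empty_like(pop)
        for c in range(params.population):
            cand = rng.integers(params.population, size=params.tournament)
            p1 = pop[cand[np.argmax(fits[cand])]]
            cand = rng.integers(params.population, size=params.tournament)
            p2 = pop[cand[np.argmax(fits[cand])]]
            take = rng.random(L) < params.crossover_rate
            child = np.where(take, p1, p2)
            flip = rng.random(L) < mut
            child = child ^ flip
            if not child.any():
                child[rng.integers(L)] = True
            children[c] = child
        pop = children
        fits = np.array(
            [_ga_fitness(ind, xp, y, params, seed) for ind in pop]
        )
        gen_best = int(np.argmax(fits))
        if fits[gen_best] > best_fit:
            best_fit = float(fits[gen_best])
            best_mask = pop[gen_best].copy()

    idx = np.flatnonzero(best_mask)
    if idx.size > k_max:  # enforce the budget by relevance
        rel = _abs_pearson(xp[:, idx], y)
        idx = idx[np.argsort(-rel)[:k_max]]
    rel = _abs_pearson(xp[:, idx], y)
    chosen = [names[i] for i in idx]
    return FeatureSet(
        drug_id=drug, method="GA", genes=_ordered_top(chosen, rel, len(chosen))
    )


def apply_selector(
    cfg: SelectorConfig, train: PharmacoDataset, drug: str
) -> FeatureSet:
    """Dispatch a SelectorConfig to the matching selector.

    ``text-mining`` and ``L1000`` expect the gene list in
    ``cfg.params['genes']``; ``L1000-tm`` expects ``l1000`` and
    ``tm_genes``; ``oracle`` (synthetic data only) reads the dataset's
    ground-truth signal genes.
    """
    m = cfg.method
    if m in ("var_100", "var_500"):
        return variance_select(train, int(m.split("_")[1]), drug)
    if m == "cor_500":
        return correlation_select(train, drug, min(cfg.k, len(train.genes)))
    if m == "text-mining":
        return list_select(cfg.params["genes"], train.genes, drug, method=m)
    if m == "L1000":
        return list_select(cfg.params["genes"], train.genes, drug, method=m)
    if m == "L1000-tm":
        fs = l1000_minus_tm(
            cfg.params["l1000"],
            FeatureSet(drug_id=drug, method="text-mining", genes=list(cfg.params["tm_genes"])),
            drug,
        )
        return list_select(fs.genes, train.genes, drug, method=m)
    if m == "MRMR":
        return mrmr_select(train, drug, min(cfg.k, len(train.genes)))
    if m == "RFE":
        return rfe_select(train, drug, min(cfg.k, len(train.genes)), **cfg.params)
    if m == "GA":
        return ga_select(
            train, drug, k_max=cfg.k, ga_params=cfg.params.get("ga"), seed=cfg.seed
        )
    if m == "oracle":
        if not train.truth or drug not in train.truth:
            raise ValueError("oracle selector requires ground-truth signal genes")
        return list_select(train.truth[drug]["genes"], train.genes, drug, method=m)
    raise ValueError(f"unknown selector {m!r}")
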