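"""Model training, repeated CV, cross-domain validation and comparison.

Three regression families predict AAC from selected gene features:
Elastic Net, Random Forest, and a sigmoid-output neural network.  The
evaluation protocol is repeated k-fold cross-validation within the
training domain (selector, scaler and hyperparameter tuning all re-fitted
inside each fold) and a single application of the tuned model to an
independent test domain for cross-domain validation.  Selector pairs are
compared with a paired Student's t-test over per-drug metrics.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestRegressor
from sklearn.linear_model import ElasticNet
from sklearn.model_selection import GridSearchCV, RepeatedKFold

from litrx._mlp import MLPRegressorSGD
from litrx.featsel import SelectorConfig, apply_selector
from litrx.pharmodata import PharmacoDataset, apply_scaler, fit_scaler

log = logging.getLogger(__name__)

FAMILIES = ("elastic_net", "random_forest", "mlp")

METRIC_NAMES = ("pearson", "spearman", "kendall", "rmse", "mse", "mae")

DEFAULT_GRIDS = {
    "elastic_net": {
        "alpha": [0.001, 0.01, 0.1],
        "l1_ratio": [0.1, 0.5, 0.9],
    },
    "random_forest": {"max_depth": [None, 10]},
    "mlp": {"hidden_layer_sizes": [(256, 64)]},
}


@dataclass
class ModelSpec:
    """Model family, hyperparameter grid and fixed settings.

    The neural network's training schedule is fixed (SGD, learning rate
    0.01, momentum 0.9, dropout 0.2, 15 epochs, sigmoid output bounding
    predictions to (0,1), MSE loss, 6 restarts); its architecture is the
    only gridded element.
    """

    family: str
    hyper_grid: Optional[dict] = None
    seed: int = 0
    rf_n_estimators: int = 250
    mlp_params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown model family {self.family!r}")
        if self.hyper_grid is None:
            self.hyper_grid = {k: list(v) for k, v in DEFAULT_GRIDS[self.family].items()}
        if not self.hyper_grid:
            raise ValueError("hyperparameter grid must be nonempty")

    def make_estimator(self):
        if self.family == "elastic_net":
            return ElasticNet(max_iter=5000, random_state=self.seed)
        if self.family == "random_forest":
            return RandomForestRegressor(
                n_estimators=self.rf_n_estimators, random_state=self.seed, n_jobs=1
            )
        params = dict(
            learning_rate=0.01,
            momentum=0.9,
            dropout=0.2,
            epochs=15,
            restarts=6,
            random_state=self.seed,
        )
        params.update(self.mlp_params)
        return MLPRegressorSGD(**params)


@dataclass
class CVProtocol:
    """Repeated k-fold protocol with inner grid-search tuning.

    ``n_folds=4`` held-out folds repeated ``n_repeats`` times with fresh
    resample indices; hyperparameters are grid-searched on
    ``tune_folds``-fold CV inside each training portion.
    """

    n_folds: int = 4
    n_repeats: int = 20
    tune_folds: int = 3
    seed: int = 0
    refit_selector_per_fold: bool = True

    def __post_init__(self) -> None:
        if self.n_folds < 2 or self.n_repeats < 1 or self.tune_folds < 2:
            raise ValueError("invalid CV protocol")


def compute_metrics(y_true, y_pred) -> dict:
    """Six-metric bundle: Pearson, Spearman (Pearson on mid-ranks),
    Kendall tau-b, RMSE, MSE, MAE.

    Zero variance in either vector leaves the correlations NaN with the
    ``undefined_correlations`` flag set, never silently propagated.
    """
    yt = np.asarray(y_true, dtype=float)
    yp = np.asarray(y_pred, dtype=float)
    if yt.shape != yp.shape:
        raise ValueError("length mismatch")
    if len(yt) < 3:
        raise ValueError("need at least 3 observations")
    err = yp - yt
    mse = float(np.mean(err**2))
    out = {
        "rmse": float(np.sqrt(mse)),
        "mse": mse,
        "mae": float(np.mean(np.abs(err))),
        "undefined_correlations": False,
    }
    if np.std(yt) == 0 or np.std(yp) == 0:
        out.update(pearson=np.nan, spearman=np.nan, kendall=np.nan)
        out["undefined_correlations"] = True
        return out
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        out["pearson"] = float(stats.pearsonr(yt, yp)[0])
        out["spearman"] = float(stats.spearmanr(yt, yp)[0])
        out["kendall"] = float(stats.kendalltau(yt, yp)[0])  # tau-b
    return out


def train_model(
    spec: ModelSpec,
    X: np.ndarray,
    y: np.ndarray,
    tune_folds: int = 3,
):
    """Grid-search-tuned fit of one model family on scaled features."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(y) < tune_folds:
        raise ValueError("fewer samples than tuning folds")
    grid_size = int(np.prod([len(v) for v in spec.hyper_grid.values()]))
    est = spec.make_estimator()
    if grid_size == 1:
        est.set_params(**{k: v[0] for k, v in spec.hyper_grid.items()})
        return est.fit(X, y)
    gs = GridSearchCV(
        est,
        spec.hyper_grid,
        cv=tune_folds,
        scoring="neg_mean_squared_error",
        n_jobs=1,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        gs.fit(X, y)
    return gs.best_estimator_


def _fit_predict_fold(
    train_ds: PharmacoDataset,
    eval_ds: PharmacoDataset,
    drug: str,
    features: Sequence[str],
    model_spec: ModelSpec,
    tune_folds: int,
) -> tuple[np.ndarray, np.ndarray]:
    scaler = fit_scaler(train_ds)
    tr = apply_scaler(scaler, train_ds)
    ev = apply_scaler(scaler, eval_ds)
    y_tr = tr.response_vector(drug)
    x_tr = tr.expression.loc[y_tr.index, list(features)].to_numpy()
    model = train_model(model_spec, x_tr, y_tr.to_numpy(), tune_folds=tune_folds)
    y_ev = ev.response_vector(drug)
    x_ev = ev.expression.loc[y_ev.index, list(features)].to_numpy()
    return y_ev.to_numpy(), np.asarray(model.predict(x_ev), dtype=float)


def run_cv(
    ds: PharmacoDataset,
    selector_cfg: SelectorConfig,
    model_spec: ModelSpec,
    protocol: CVProtocol,
    drugs: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Within-domain repeated CV; one row per drug (metrics averaged over
    folds × repeats).

    Supervised selectors are re-fitted on each fold's training portion so
    no held-out information reaches selection, scaling or tuning.
    """
    drugs = list(drugs) if drugs is not None else ds.drugs
    rows = []
    for drug in drugs:
        y_all = ds.response_vector(drug)
        samples = list(y_all.index)
        if len(samples) < protocol.n_folds:
            log.warning("drug %s: too few samples, skipped", drug)
            continue
        fold_fs = None
        if not protocol.refit_selector_per_fold:
            fold_fs = apply_selector(selector_cfg, ds, drug)
        rkf = RepeatedKFold(
            n_splits=protocol.n_folds,
            n_repeats=protocol.n_repeats,
            random_state=protocol.seed,
        )
        per_fold = []
        for tr_idx, te_idx in rkf.split(samples):
            tr_ds = ds.subset_samples([samples[i] for i in tr_idx])
            te_ds = ds.subset_samples([samples[i] for i in te_idx])
            fs = fold_fs or apply_selector(selector_cfg, tr_ds, drug)
            if not fs.genes:
                log.warning("drug %s: empty feature set, skipped", drug)
                per_fold = []
                break
            yt, yp = _fit_predict_fold(
                tr_ds, te_ds, drug, fs.genes, model_spec, protocol.tune_folds
            )
            per_fold.append(compute_metrics(yt, yp))
        if not per_fold:
            continue
        row = {
            "drug": drug,
            "selector": selector_cfg.method,
            "model_family": model_spec.family,
            "split_kind": "within",
        }
        for m in METRIC_NAMES:
            row[m] = float(np.nanmean([f[m] for f in per_fold]))
        # keep rmse^2 == mse after fold averaging
        row["rmse"] = float(np.sqrt(row["mse"]))
        rows.append(row)
    return pd.DataFrame(rows)


def run_cross_domain(
    train_ds: PharmacoDataset,
    test_ds: PharmacoDataset,
    selector_cfg: SelectorConfig,
    model_spec: ModelSpec,
    protocol: CVProtocol,
    drugs: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Tune within the training domain, apply once to the test domain.

    Gene universes are intersected first; the test domain is never used in
    selection, scaling or tuning.
    """
    shared = [g for g in train_ds.genes if g in set(test_ds.genes)]
    if not shared:
        raise ValueError("no shared genes between domains")
    tr = PharmacoDataset(
        expression=train_ds.expression[shared],
        responses=train_ds.responses.copy(),
        truth=train_ds.truth,
    )
    te = PharmacoDataset(
        expression=test_ds.expression[shared],
        responses=test_ds.responses.copy(),
        truth=test_ds.truth,
    )
    drugs = list(drugs) if drugs is not None else tr.drugs
    rows = []
    for drug in drugs:
        y_te = te.response_vector(drug)
        if len(y_te) < 10:
            raise ValueError(
                f"drug {drug}: only {len(y_te)} overlapping test samples (<10)"
            )
        fs = apply_selector(selector_cfg, tr, drug)
        if not fs.genes:
            log.warning("drug %s: empty feature set, skipped", drug)
            continue
        yt, yp = _fit_predict_fold(
            tr, te, drug, fs.genes, model_spec, protocol.tune_folds
        )
        row = {
            "drug": drug,
            "selector": selector_cfg.method,
            "model_family": model_spec.family,
            "split_kind": "cross",
        }
        row.update({m: compute_metrics(yt, yp)[m] for m in METRIC_NAMES})
        rows.append(row)
    return pd.DataFrame(rows)


def validate_benchmark_invariants(result: pd.DataFrame) -> None:
    """Sanity of a BenchmarkResult table: correlation range, rmse²=mse,
    mae ≤ rmse."""
    corr = result[["pearson", "spearman", "kendall"]].to_numpy(dtype=float)
    finite = corr[~np.isnan(corr)]
    if ((finite < -1) | (finite > 1)).any():
        raise ValueError("correlation outside [-1, 1]")
    if not np.allclose(result["rmse"] ** 2, result["mse"], atol=1e-10):
        raise ValueError("rmse^2 != mse")
    if ((result["mae"] - result["rmse"]) > 1e-12).any():
        raise ValueError("mae > rmse")


@dataclass
class PairedComparison:
    method_a: str
    method_b: str
    metric: str
    n: int
    mean_difference: float
    t_statistic: float
    df: int
    p_value: float
    zero_variance: bool = False


def compare_selectors(
    result: pd.DataFrame,
    metric: str,
    method_a: str,
    method_b: str,
    split_kind: Optional[str] = None,
    model_family: Optional[str] = None,
) -> PairedComparison:
    """Paired two-sided Student's t-test of a metric between two selectors
    over the common drug set.

    Drugs where either method's metric is undefined (e.g. a correlation
    flagged for a constant prediction) are dropped pairwise; at least
    three complete pairs are required."""
    sub = result
    if split_kind is not None:
        sub = sub[sub["split_kind"] == split_kind]
    if model_family is not None:
        sub = sub[sub["model_family"] == model_family]
    a = sub[sub["selector"] == method_a].set_index("drug")[metric]
    b = sub[sub["selector"] == method_b].set_index("drug")[metric]
    common = sorted(set(a.index) & set(b.index))
    da, db = a[common].to_numpy(), b[common].to_numpy()
    ok = np.isfinite(da) & np.isfinite(db)
    da, db, common = da[ok], db[ok], [c for c, k in zip(common, ok) if k]
    if len(common) < 3:
        raise ValueError("need at least 3 complete paired drugs")
    diff = da - db
    if np.allclose(diff, 0.0):
        return PairedComparison(
            method_a, method_b, metric, len(common), 0.0, 0.0,
            len(common) - 1, 1.0, zero_variance=True,
        )
    t, p = stats.ttest_rel(da, db)
    return PairedComparison(
        method_a,
        method_b,
        metric,
        len(common),
        float(diff.mean()),
        float(t),
        len(common) - 1,
        float(p),
    )
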