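"""Univariate biomarker analysis and survival-based validation.

Two independent checks of the text-mining gene sets:

* :func:`univariate_analysis` — per-gene |Pearson r| between expression
  and AAC, with a two-sample t-test comparing text-mining genes against
  the rest of the genome (Welch by default; group sizes are wildly
  unequal).
* :func:`pdx_style_validation` — train a Random Forest on the text-mining
  features of an in-vitro domain, predict response for an in-vivo style
  cohort, dichotomize predictions at the median, and compare the high and
  low groups by Kaplan–Meier curves and a two-group log-rank test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _lifelines_logrank
from scipy import stats
from sklearn.ensemble import RandomForestRegressor

from litrx.featsel import _abs_pearson, _aligned_xy
from litrx.pharmodata import PharmacoDataset, apply_scaler, fit_scaler


@dataclass
class UnivariateReport:
    drug_id: str
    r_abs: pd.Series  # |Pearson r| per gene
    group: pd.Series  # 'text-mining' / 'other' per gene
    t_statistic: float
    p_value: float
    mean_r_tm: float
    mean_r_other: float


def univariate_analysis(
    ds: PharmacoDataset,
    drug: str,
    tm_genes: Sequence[str],
    equal_var: bool = False,
) -> UnivariateReport:
    """Compare |r(expression, AAC)| of text-mining genes vs the rest.

    ``equal_var=False`` (default) runs Welch's unequal-variance t-test;
    set True for the pooled-variance variant.  Zero-variance genes get
    |r| = 0.
    """
    if not tm_genes:
        raise ValueError("tm_genes must be nonempty")
    x, y, genes = _aligned_xy(ds, drug)
    if len(y) < 3:
        raise ValueError("need at least 3 responding samples")
    r = pd.Series(_abs_pearson(x, y), index=genes)
    tm = set(tm_genes)
    group = pd.Series(
        ["text-mining" if g in tm else "other" for g in genes], index=genes
    )
    r_tm = r[group == "text-mining"]
    r_other = r[group == "other"]
    if r_tm.empty or r_other.empty:
        raise ValueError("both gene groups must be nonempty")
    t, p = stats.ttest_ind(r_tm, r_other, equal_var=equal_var)
    return UnivariateReport(
        drug_id=drug,
        r_abs=r,
        group=group,
        t_statistic=float(t),
        p_value=float(p),
        mean_r_tm=float(r_tm.mean()),
        mean_r_other=float(r_other.mean()),
    )


def univariate_across_drugs(
    ds: PharmacoDataset,
    tm_genes: Sequence[str],
    drugs: Optional[Sequence[str]] = None,
) -> tuple[pd.DataFrame, float, float]:
    """Paired comparison of per-drug mean |r| between gene groups.

    For every drug the mean |Pearson r| with AAC is computed separately
    for the text-mining genes and the remaining genes; a paired t-test
    across drugs summarizes whether text-mining genes correlate more
    strongly with response overall.  Returns (per-drug frame, t, p).
    """
    drugs = list(drugs) if drugs is not None else ds.drugs
    rows = []
    for d in drugs:
        rep = univariate_analysis(ds, d, tm_genes)
        rows.append(
            {"drug": d, "mean_r_tm": rep.mean_r_tm, "mean_r_other": rep.mean_r_other}
        )
    df = pd.DataFrame(rows)
    if len(df) < 3:
        raise ValueError("need at least 3 drugs for the paired comparison")
    t, p = stats.ttest_rel(df["mean_r_tm"], df["mean_r_other"])
    return df, float(t), float(p)


def dichotomize(predictions: Mapping[str, float]) -> dict[str, str]:
    """Median split of predicted responses: ≥ median → 'high', else 'low'.

    Ties at the median go high (fixed rule for reproducibility).
    """
    if len(predictions) < 2:
        raise ValueError("need at least 2 subjects")
    vals = np.array(list(predictions.values()), dtype=float)
    if np.allclose(vals, vals[0]):
        raise ValueError("all predictions identical: degenerate split")
    med = float(np.median(vals))
    return {k: ("high" if v >= med else "low") for k, v in predictions.items()}


@dataclass(frozen=True)
class SurvivalRecord:
    subject_id: str
    time: float  # days
    event: int  # 1 = event observed, 0 = right-censored
    group: str  # 'high' / 'low'

    def __post_init__(self) -> None:
        if self.time <= 0:
            raise ValueError("survival time must be positive")
        if self.event not in (0, 1):
            raise ValueError("event must be 0 or 1")


def km_estimate(
    records: Sequence[SurvivalRecord],
) -> dict[str, pd.DataFrame]:
    """Product-limit survival curve per group.

    Returns per group a frame with columns ``time`` and ``survival``
    (Ŝ right-continuous, Ŝ(0)=1, nonincreasing).
    """
    if not records:
        raise ValueError("no survival records")
    out = {}
    for grp in sorted({r.group for r in records}):
        sub = [r for r in records if r.group == grp]
        kmf = KaplanMeierFitter()
        kmf.fit(
            durations=[r.time for r in sub],
            event_observed=[r.event for r in sub],
        )
        sf = kmf.survival_function_
        out[grp] = pd.DataFrame(
            {"time": sf.index.to_numpy(dtype=float),
             "survival": sf.iloc[:, 0].to_numpy(dtype=float)}
        )
    return out


def logrank_test(records: Sequence[SurvivalRecord]) -> tuple[float, float]:
    """Two-group log-rank test: χ² = U²/V with U the summed
    observed-minus-expected events and V the hypergeometric variances."""
    groups = sorted({r.group for r in records})
    if len(groups) != 2:
        raise ValueError("exactly two groups required")
    if not any(r.event for r in records):
        raise ValueError("no events observed")
    a = [r for r in records if r.group == groups[0]]
    b = [r for r in records if r.group == groups[1]]
    res = _lifelines_logrank(
        [r.time for r in a],
        [r.time for r in b],
        event_observed_A=[r.event for r in a],
        event_observed_B=[r.event for r in b],
    )
    chi2 = float(res.test_statistic)
    if not np.isfinite(chi2):
        raise ValueError("log-rank variance is zero: no comparable risk sets")
    return chi2, float(res.p_value)


@dataclass
class SurvivalValidationReport:
    drug_id: str
    records: list[SurvivalRecord]
    n_high: int
    n_low: int
    chi_square: float
    p_value: float
    predictions: dict[str, float]


def pdx_style_validation(
    train_ds: PharmacoDataset,
    drug: str,
    tm_genes: Sequence[str],
    survival_expression: pd.DataFrame,
    survival_table: pd.DataFrame,
    n_estimators: int = 250,
    seed: int = 0,
) -> SurvivalValidationReport:
    """In-vivo style validation of a literature-mined feature set.

    A Random Forest is trained on the training domain restricted to the
    text-mining genes shared with the survival cohort's expression matrix,
    predicts each subject's drug response, and the median-dichotomized
    groups are compared by log-rank.  ``survival_table`` needs columns
    subject_id, time_days, event.
    """
    shared = [g for g in tm_genes if g in train_ds.expression.columns
              and g in survival_expression.columns]
    if not shared:
        raise ValueError("no text-mining genes shared with the survival cohort")
    scaler = fit_scaler(train_ds)
    tr = apply_scaler(scaler, train_ds)
    y = tr.response_vector(drug)
    x = tr.expression.loc[y.index, shared].to_numpy()
    rf = RandomForestRegressor(
        n_estimators=n_estimators, random_state=seed, n_jobs=1
    ).fit(x, y.to_numpy())

    cohort = PharmacoDataset(
        expression=survival_expression[train_ds.genes],
        responses=pd.DataFrame(
            {"sample_id": [], "drug_id": [], "aac": []}
        ),
    )
    cohort_scaled = apply_scaler(scaler, cohort)
    xs = cohort_scaled.expression[shared].to_numpy()
    preds = dict(
        zip(survival_expression.index, map(float, rf.predict(xs)))
    )
    groups = dichotomize(preds)
    surv = survival_table.set_index("subject_id")
    records = [
        SurvivalRecord(
            subject_id=s,
            time=float(surv.loc[s, "time_days"]),
            event=int(surv.loc[s, "event"]),
            group=groups[s],
        )
        for s in preds
        if s in surv.index
    ]
    n_high = sum(r.group == "high" for r in records)
    n_low = sum(r.group == "low" for r in records)
    if min(n_high, n_low) < 5:
        warnings.warn(
            f"fewer than 5 subjects in a group (high={n_high}, low={n_low})",
            stacklevel=2,
        )
    chi2, p = logrank_test(records)
    return SurvivalValidationReport(
        drug_id=drug,
        records=records,
        n_high=n_high,
        n_low=n_low,
        chi_square=chi2,
        p_value=p,
        predictions=preds,
    )


def plot_km(curves: dict[str, pd.DataFrame], path: str) -> None:
    """Optional step-plot export of KM curves (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for grp, df in curves.items():
        ax.step(df["time"], df["survival"], where="post", label=grp)
    ax.set_xlabel("time (days)")
    ax.set_ylabel("survival probability")
    ax.set_ylim(0, 1.05)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
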