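"""Pharmacogenomic data model, I/O and preprocessing.

A :class:`PharmacoDataset` bundles a samples × genes log-expression matrix
with long-format drug responses (AAC, the area above the dose-response
curve, in [0,1]; higher = more sensitive) and optional sample metadata.
Preprocessing covers degenerate-sample filtering and train-fitted
z-scaling; the scaler carries a provenance tag so that test-domain
statistics can never silently leak into scaling.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

RESPONSE_COLUMNS = ["sample_id", "drug_id", "aac"]


@dataclass
class PharmacoDataset:
    expression: pd.DataFrame  # rows = samples, columns = genes
    responses: pd.DataFrame  # columns: sample_id, drug_id, aac
    sample_meta: Optional[pd.DataFrame] = None
    truth: Optional[dict] = None  # per-drug ground-truth signal (synthetic data)
    scaled: bool = False

    def __post_init__(self) -> None:
        if self.expression.index.duplicated().any():
            raise ValueError("duplicate sample ids in expression matrix")
        if self.expression.columns.duplicated().any():
            raise ValueError("duplicate gene ids in expression matrix")
        vals = self.expression.to_numpy()
        if vals.size and not np.isfinite(vals[~np.isnan(vals)]).all():
            raise ValueError("expression contains non-finite values")
        missing = [c for c in RESPONSE_COLUMNS if c not in self.responses.columns]
        if missing:
            raise ValueError(f"response table missing columns {missing}")
        aac = self.responses["aac"].to_numpy(dtype=float)
        ok = np.isnan(aac) | ((aac >= 0.0) & (aac <= 1.0))
        if not ok.all():
            bad = self.responses.loc[~ok]
            raise ValueError(
                f"AAC outside [0,1] for {len(bad)} rows, e.g. "
                f"{bad.iloc[0].to_dict()}"
            )

    @property
    def samples(self) -> list[str]:
        return list(self.expression.index)

    @property
    def genes(self) -> list[str]:
        return list(self.expression.columns)

    @property
    def drugs(self) -> list[str]:
        return sorted(self.responses["drug_id"].unique())

    def response_vector(self, drug_id: str) -> pd.Series:
        """AAC per sample for one drug, restricted to samples in the
        expression matrix and with a non-missing response."""
        sub = self.responses[self.responses["drug_id"] == drug_id]
        if sub.empty:
            raise KeyError(f"no responses for drug {drug_id!r}")
        y = sub.set_index("sample_id")["aac"].astype(float)
        y = y[~y.isna()]
        y = y[y.index.isin(self.expression.index)]
        return y

    def subset_samples(self, sample_ids) -> "PharmacoDataset":
        ids = [s for s in self.expression.index if s in set(sample_ids)]
        return PharmacoDataset(
            expression=self.expression.loc[ids].copy(),
            responses=self.responses[self.responses["sample_id"].isin(ids)].copy(),
            sample_meta=None
            if self.sample_meta is None
            else self.sample_meta.loc[self.sample_meta.index.isin(ids)].copy(),
            truth=self.truth,
            scaled=self.scaled,
        )


def write_dataset(
    ds: PharmacoDataset, expression_path: str | Path, response_path: str | Path
) -> None:
    """TSV export: matrix with sample-id index and gene-id header; long
    response table (sample_id, drug_id, aac)."""
    ds.expression.to_csv(expression_path, sep="\t", index_label="sample_id")
    ds.responses[RESPONSE_COLUMNS].to_csv(response_path, sep="\t", index=False)


def read_dataset(
    expression_path: str | Path, response_path: str | Path
) -> PharmacoDataset:
    """Load and inner-join a dataset from TSV files.

    Samples must appear in both files; responses for unknown samples are
    dropped, and expression rows without any response are dropped.
    """
    try:
        expr = pd.read_csv(expression_path, sep="\t", index_col=0)
    except pd.errors.ParserError as e:
        raise ValueError(f"malformed expression TSV {expression_path}: {e}") from e
    try:
        resp = pd.read_csv(response_path, sep="\t")
    except pd.errors.ParserError as e:
        raise ValueError(f"malformed response TSV {response_path}: {e}") from e
    missing = [c for c in RESPONSE_COLUMNS if c not in resp.columns]
    if missing:
        raise ValueError(f"response TSV {response_path} missing columns {missing}")
    expr.index = expr.index.astype(str)
    resp["sample_id"] = resp["sample_id"].astype(str)
    shared = [s for s in expr.index if s in set(resp["sample_id"])]
    if not shared:
        raise ValueError("no samples shared between expression and responses")
    expr = expr.loc[shared]
    resp = resp[resp["sample_id"].isin(shared)].reset_index(drop=True)
    return PharmacoDataset(expression=expr, responses=resp)


def filter_samples(
    ds: PharmacoDataset, frac_threshold: float = 0.85
) -> PharmacoDataset:
    """Drop samples with missing values or degenerate expression profiles.

    A profile is degenerate when more than ``frac_threshold`` of its gene
    values equal the sample's modal value — i.e. the sample carries (near)
    zero variance across most genes.  An all-constant profile is always
    degenerate, whatever the threshold.  Idempotent.
    """
    if not 0.0 < frac_threshold <= 1.0:
        raise ValueError("frac_threshold must be in (0, 1]")
    keep = []
    n_genes = ds.expression.shape[1]
    for sid, row in ds.expression.iterrows():
        vals = row.to_numpy(dtype=float)
        if np.isnan(vals).any():
            continue
        _, counts = np.unique(vals, return_counts=True)
        modal_frac = counts.max() / n_genes
        if modal_frac > frac_threshold or modal_frac == 1.0:
            continue
        keep.append(sid)
    if not keep:
        raise ValueError("sample filter removed every sample")
    return ds.subset_samples(keep)


@dataclass
class Scaler:
    """Per-gene z-scaling statistics, fitted on training data only."""

    mean_: pd.Series
    sd_: pd.Series
    fit_tag: str = "train"

    def __post_init__(self) -> None:
        if (self.sd_ < 0).any():
            raise ValueError("negative standard deviation")


def fit_scaler(train: PharmacoDataset, fit_tag: str = "train") -> Scaler:
    mean = train.expression.mean(axis=0)
    sd = train.expression.std(axis=0, ddof=0)
    return Scaler(mean_=mean, sd_=sd, fit_tag=fit_tag)


def apply_scaler(scaler: Scaler, ds: PharmacoDataset) -> PharmacoDataset:
    """Center/scale with the scaler's (training) statistics.

    Genes with zero training sd map to 0; genes absent from the scaler
    raise, so a test matrix can never be scaled by its own statistics by
    accident.
    """
    missing = [g for g in ds.genes if g not in scaler.mean_.index]
    if missing:
        raise KeyError(f"genes absent from scaler: {missing[:5]}...")
    mean = scaler.mean_[ds.genes]
    sd = scaler.sd_[ds.genes]
    safe_sd = sd.replace(0.0, 1.0)
    z = (ds.expression - mean) / safe_sd
    z.loc[:, sd == 0.0] = 0.0
    return PharmacoDataset(
        expression=z,
        responses=ds.responses.copy(),
        sample_meta=ds.sample_meta,
        truth=ds.truth,
        scaled=True,
    )
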