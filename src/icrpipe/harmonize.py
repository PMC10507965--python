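"""Per-cohort normalization and pooling of per-patient results.

Expression values are never pooled across cohorts: each cohort is
quantile-normalized and classified separately, and only labels, scores and
standardized values are merged into the pooled analysis table.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from icrpipe.datatypes import ClinicalTable, ExpressionDataset


def quantile_normalize(ds: ExpressionDataset) -> ExpressionDataset:
    """Force every sample column onto the mean empirical distribution.

    The target distribution is the per-rank mean of the column-sorted
    values. Ties within a column receive the mean of the target values of
    their tied ranks, so the map is well defined and idempotent.
    """
    if ds.n_samples < 2:
        raise ValueError("quantile normalization needs at least 2 samples")
    arr = ds.values.to_numpy(dtype=float)
    target = np.sort(arr, axis=0).mean(axis=1)
    out = np.empty_like(arr)
    for j in range(arr.shape[1]):
        col = arr[:, j]
        # average rank (1-based) -> interpolate into the target distribution
        ranks = stats.rankdata(col, method="average")
        out[:, j] = np.interp(ranks, np.arange(1, len(col) + 1), target)
    return ExpressionDataset(
        pd.DataFrame(out, index=ds.values.index, columns=ds.values.columns),
        cohort_id=ds.cohort_id,
    )


def standardize_gene(ds: ExpressionDataset, gene: str) -> pd.Series:
    """z-scores of one gene within the cohort (mean 0, sample SD 1)."""
    if gene not in ds.values.index:
        raise KeyError(f"gene {gene!r} absent from dataset {ds.cohort_id}")
    x = ds.values.loc[gene].astype(float)
    sd = x.std(ddof=1)
    if not np.isfinite(sd) or sd == 0:
        raise ValueError(f"gene {gene!r} has zero variance in cohort {ds.cohort_id}")
    z = (x - x.mean()) / sd
    z.name = f"{gene}_z"
    return z


def pool_datasets(cohort_tables: list[pd.DataFrame]) -> pd.DataFrame:
    """Concatenate per-cohort patient tables into one pooled analysis table.

    Each table must carry identical columns (per-patient covariates, ICR
    labels, binarized signature classes, outcomes). Raises on schema
    mismatch (naming the missing columns) and on duplicate patient IDs.
    """
    if not cohort_tables:
        raise ValueError("no cohort tables to pool")
    ref_cols = list(cohort_tables[0].columns)
    for i, tab in enumerate(cohort_tables[1:], start=1):
        missing = [c for c in ref_cols if c not in tab.columns]
        extra = [c for c in tab.columns if c not in ref_cols]
        if missing or extra:
            raise ValueError(
                f"cohort table {i} schema mismatch: missing columns {missing}, unexpected {extra}"
            )
    pooled = pd.concat([t[ref_cols] for t in cohort_tables], ignore_index=True)
    if "sample_id" in pooled.columns and pooled["sample_id"].duplicated().any():
        dups = pooled.loc[pooled["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"duplicate patient IDs across cohorts: {dups}")
    return pooled


def build_patient_table(
    clinical: ClinicalTable,
    labels: pd.DataFrame | None = None,
    scores: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Join clinical covariates with per-sample labels/scores on sample_id."""
    out = clinical.data.copy()
    for extra in (labels, scores):
        if extra is None:
            continue
        tab = extra.reset_index() if extra.index.name == "sample_id" else extra
        if "sample_id" not in tab.columns:
            raise ValueError("labels/scores must be indexed by or contain sample_id")
        dup = [c for c in tab.columns if c != "sample_id" and c in out.columns]
        out = out.merge(tab.drop(columns=dup), on="sample_id", how="left", validate="one_to_one")
    return out
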