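"""Core data containers shared across the pipeline.

``ExpressionDataset`` wraps a genes x samples matrix of log2 expression
values together with a cohort identifier; ``ClinicalTable`` wraps the
per-patient covariate/outcome table. Both validate their invariants on
construction and round-trip to plain-text TSV/CSV.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Canonical clinical column names (documented external schema).
CLINICAL_COLUMNS = (
    "sample_id",
    "cohort_id",
    "age",
    "sex",
    "smoker_status",
    "pathological_type",
    "mutational_status",
    "dcb",
    "dfs_months",
    "dfs_event",
)

SEX_LEVELS = ("female", "male")
SMOKER_LEVELS = ("current", "former", "non-smoker")
PATH_LEVELS = ("squamous", "non-squamous")
MUTATION_LEVELS = ("mutated", "wild-type")


@dataclass
class ExpressionDataset:
    """Log2 expression matrix (genes as rows, samples as columns).

    Parameters
    ----------
    values:
        DataFrame indexed by gene symbol with one column per sample ID.
    cohort_id:
        Identifier of the cohort the samples belong to.
    """

    values: pd.DataFrame
    cohort_id: str = "cohort0"

    def __post_init__(self) -> None:
        if not isinstance(self.values, pd.DataFrame):
            self.values = pd.DataFrame(self.values)
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene symbols: {dups}")
        if self.values.columns.has_duplicates:
            dups = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample IDs: {dups}")
        arr = self.values.to_numpy(dtype=float)
        if arr.size and not np.all(np.isfinite(arr)):
            raise ValueError("expression values must be finite")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_genes(self, genes: list[str]) -> "ExpressionDataset":
        missing = [g for g in genes if g not in self.values.index]
        if missing:
            raise KeyError(f"genes absent from dataset: {missing}")
        return ExpressionDataset(self.values.loc[list(genes)].copy(), self.cohort_id)

    def to_tsv(self, path) -> None:
        out = self.values.copy()
        out.index.name = "gene"
        out.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path, cohort_id: str = "cohort0") -> "ExpressionDataset":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(df, cohort_id=cohort_id)


@dataclass
class ClinicalTable:
    """Per-patient clinical covariates, DCB outcome and DFS follow-up."""

    data: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        missing = [c for c in CLINICAL_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"clinical table missing columns: {missing}")
        if self.data["sample_id"].duplicated().any():
            dups = self.data.loc[self.data["sample_id"].duplicated(), "sample_id"].tolist()
            raise ValueError(f"duplicate patient IDs: {dups}")
        for col, levels in (
            ("sex", SEX_LEVELS),
            ("smoker_status", SMOKER_LEVELS),
            ("pathological_type", PATH_LEVELS),
            ("mutational_status", MUTATION_LEVELS),
        ):
            bad = set(self.data[col].dropna()) - set(levels)
            if bad:
                raise ValueError(f"{col} has values outside {levels}: {sorted(bad)}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data["sample_id"])

    def __len__(self) -> int:
        return len(self.data)

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "ClinicalTable":
        return cls(pd.read_csv(path))
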