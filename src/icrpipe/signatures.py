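"""Companion immune-signature scoring and first-quintile binarization.

Gene sets are plain GMT files (name, description, member symbols); the
shipped database under ``icrpipe/data/signatures.gmt`` contains the
immune-cell metagenes, pathway activation scores, antigen-presentation
score, the 18-gene T cell-inflamed signature (TIS) and the 12-chemokine
tertiary-lymphoid-structure signature (TLS). Member lists are editable
surrogates for the published references.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from icrpipe.datatypes import ExpressionDataset
from icrpipe.harmonize import standardize_gene
from icrpipe.icr_classifier import icr_score

#: Predictors binarized at the first quintile by default (low vs high).
DEFAULT_BINARIZED = ("TIS", "TLS", "CD274_z")


@dataclass(frozen=True)
class GeneSet:
    """A named gene set with optional per-gene direction weights (+1/-1)."""

    name: str
    genes: tuple[str, ...]
    weights: tuple[float, ...] | None = None
    description: str = ""

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"gene set {self.name!r} is empty")
        if any(g != g.upper() for g in self.genes):
            raise ValueError(f"gene set {self.name!r} has non-uppercase symbols")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"gene set {self.name!r} has duplicate symbols")
        if self.weights is not None and len(self.weights) != len(self.genes):
            raise ValueError(f"gene set {self.name!r}: weights length mismatch")


def read_gmt(path) -> dict[str, GeneSet]:
    """Parse a GMT file into an ordered name -> GeneSet mapping."""
    sets: dict[str, GeneSet] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"malformed GMT line: {line[:60]!r}")
            name, description, genes = fields[0], fields[1], tuple(fields[2:])
            sets[name] = GeneSet(name=name, genes=genes, description=description)
    return sets


def default_signature_db() -> dict[str, GeneSet]:
    """The gene-set database shipped with the package."""
    with resources.as_file(resources.files("icrpipe.data") / "signatures.gmt") as p:
        return read_gmt(p)


def metagene_score(ds: ExpressionDataset, gs: GeneSet) -> tuple[pd.Series, float]:
    """Mean log2 expression of the present member genes, per sample.

    Direction weights, when provided, weight the mean. Returns the score
    and the fraction of member genes missing from the dataset; a fully
    absent set yields an all-NaN score (recorded, not fatal).
    """
    present = [g for g in gs.genes if g in ds.values.index]
    missing_frac = 1.0 - len(present) / len(gs.genes)
    if not present:
        return pd.Series(np.nan, index=ds.sample_ids, name=gs.name), 1.0
    block = ds.values.loc[present]
    if gs.weights is None:
        score = block.mean(axis=0)
    else:
        w = np.array([gs.weights[gs.genes.index(g)] for g in present], dtype=float)
        score = pd.Series(block.to_numpy().T @ w / np.abs(w).sum(), index=block.columns)
    score.name = gs.name
    return score, missing_frac


def cytolytic_score(ds: ExpressionDataset) -> pd.Series:
    """Cytolytic activity: mean of log2 GZMA and log2 PRF1 per sample.

    On the linear scale this is the log2 of the geometric mean of the two
    granule transcripts.
    """
    missing = [g for g in ("GZMA", "PRF1") if g not in ds.values.index]
    if missing:
        raise KeyError(f"cytolytic score needs GZMA and PRF1; missing: {missing}")
    score = ds.values.loc[["GZMA", "PRF1"]].mean(axis=0)
    score.name = "CYTOLYTIC"
    return score


def quintile_binarize(scores: pd.Series, name: str | None = None) -> pd.Series:
    """Label samples 'low' (first quintile) vs 'high' (upper four quintiles).

    The cut is the 20th percentile (linear interpolation); values <= cut go
    'low', so ties straddling the cut all fall in the low class. Refuses
    degenerate all-equal inputs.
    """
    x = scores.dropna().astype(float)
    if len(x) < 5:
        raise ValueError("quintile binarization needs at least 5 samples")
    if x.nunique() == 1:
        raise ValueError(f"cannot binarize {name or scores.name!r}: all values equal")
    cut = float(np.quantile(x.to_numpy(), 0.2))
    out = pd.Series(
        np.where(scores <= cut, "low", "high"), index=scores.index,
        name=f"{name or scores.name}_class",
    )
    out[scores.isna()] = np.nan
    return out


@dataclass
class SignatureScores:
    """Per-sample signature score table plus binarized predictor classes."""

    scores: pd.DataFrame  # one row per sample, one column per score
    binarized: pd.DataFrame  # low/high classes for the binarized predictors
    missing_fractions: dict[str, float]

    def to_frame(self) -> pd.DataFrame:
        out = pd.concat([self.scores, self.binarized], axis=1)
        out.index.name = "sample_id"
        return out


def score_panel(
    ds: ExpressionDataset,
    signature_db: dict[str, GeneSet] | None = None,
    binarize: tuple[str, ...] = DEFAULT_BINARIZED,
) -> SignatureScores:
    """Score the full companion-signature panel for one cohort.

    Produces the ICR score, one metagene score per gene set, the cytolytic
    score, cohort-standardized CD274 (PDL1) z-scores, the Th1/Th2 ratio
    (Th1 metagene minus Th2 metagene in the log2 domain), and low/high
    classes for the requested predictors (first-quintile cut within the
    cohort).
    """
    if signature_db is None:
        signature_db = default_signature_db()
    cols: dict[str, pd.Series] = {"icr_score": icr_score(ds)}
    missing: dict[str, float] = {}
    for name, gs in signature_db.items():
        score, mf = metagene_score(ds, gs)
        cols[name] = score
        if mf > 0:
            missing[name] = mf
            if mf == 1.0:
                warnings.warn(f"signature {name!r}: no member genes present", stacklevel=2)
    if {"GZMA", "PRF1"} <= set(ds.values.index):
        cols["CYTOLYTIC"] = cytolytic_score(ds)
    if "CD274" in ds.values.index:
        cols["CD274_z"] = standardize_gene(ds, "CD274")
    th1, th2 = cols.get("BINDEA_TH1_CELLS"), cols.get("BINDEA_TH2_CELLS")
    if th1 is not None and th2 is not None:
        ratio = th1 - th2
        ratio.name = "TH1_TH2_RATIO"
        cols["TH1_TH2_RATIO"] = ratio

    scores = pd.DataFrame(cols)
    scores.index.name = "sample_id"

    binar: dict[str, pd.Series] = {}
    for name in binarize:
        if name not in scores.columns:
            warnings.warn(f"cannot binarize unknown predictor {name!r}; skipped", stacklevel=2)
            continue
        b = quintile_binarize(scores[name], name=name)
        binar[b.name] = b
    return SignatureScores(
        scores=scores,
        binarized=pd.DataFrame(binar, index=scores.index),
        missing_fractions=missing,
    )
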