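"""nSolver-style processing of raw nCounter probe counts.

The processing chain is: background subtraction (geometric mean of the
negative-control probes, per sample), geometric-mean scaling to the
positive-control + housekeeping reference probes, then a log2 transform
that maps probes to gene symbols.

Conventions (all configurable):

* background-subtracted endogenous counts are floored at 1 so the log2
  transform stays defined;
* geometric means over counts that may contain zeros are computed on
  ``counts + 1`` and 1 is subtracted afterwards, avoiding zero-collapse;
* the scale-factor reference is the arithmetic mean over samples of the
  per-sample reference geometric means.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from icrpipe.datatypes import ExpressionDataset

PROBE_CLASSES = ("endogenous", "negative", "positive", "housekeeping")
#: Probe classes used as the normalization reference.
REFERENCE_CLASSES = ("positive", "housekeeping")


@dataclass
class RawCounts:
    """Probe-level count matrix with probe-class and gene annotations.

    ``counts`` is probes x samples (index = probe IDs); ``probe_class``
    and ``gene_symbol`` are per-probe series aligned on the same index.
    """

    counts: pd.DataFrame
    probe_class: pd.Series
    gene_symbol: pd.Series

    def __post_init__(self) -> None:
        if not self.counts.index.equals(self.probe_class.index) or not self.counts.index.equals(
            self.gene_symbol.index
        ):
            raise ValueError("counts, probe_class and gene_symbol must share a probe index")
        bad = set(self.probe_class) - set(PROBE_CLASSES)
        if bad:
            raise ValueError(f"unknown probe classes: {sorted(bad)}")
        if (self.probe_class == "negative").sum() < 1:
            raise ValueError("at least one negative-control probe required")
        if self.probe_class.isin(REFERENCE_CLASSES).sum() < 1:
            raise ValueError("at least one positive/housekeeping reference probe required")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")

    def probes_of(self, probe_class: str) -> pd.Index:
        return self.counts.index[self.probe_class == probe_class]

    @classmethod
    def from_csv(cls, path) -> "RawCounts":
        """Read a CSV with columns probe_id, probe_class, gene_symbol, <samples...>."""
        df = pd.read_csv(path)
        meta = ["probe_id", "probe_class", "gene_symbol"]
        missing = [c for c in meta if c not in df.columns]
        if missing:
            raise ValueError(f"count CSV missing columns: {missing}")
        df = df.set_index("probe_id")
        samples = [c for c in df.columns if c not in meta]
        return cls(
            counts=df[samples].astype(float),
            probe_class=df["probe_class"],
            gene_symbol=df["gene_symbol"],
        )

    def to_csv(self, path) -> None:
        out = pd.concat(
            [self.probe_class.rename("probe_class"), self.gene_symbol.rename("gene_symbol"),
             self.counts],
            axis=1,
        )
        out.index.name = "probe_id"
        out.to_csv(path)


def _geomean_shifted(values: np.ndarray, axis: int = 0) -> np.ndarray:
    """Column-wise geometric mean; zero-containing columns fall back to the
    shifted form (geomean of values + 1, minus 1) to avoid zero-collapse."""
    v = np.asarray(values, dtype=float)
    plain = np.exp(np.mean(np.log(np.maximum(v, 1e-300)), axis=axis))
    shifted = np.exp(np.mean(np.log(v + 1.0), axis=axis)) - 1.0
    has_zero = (v == 0).any(axis=axis)
    return np.where(has_zero, shifted, plain)


def subtract_background(raw: RawCounts, floor: float = 1.0) -> RawCounts:
    """Subtract the per-sample negative-control geometric mean from endogenous counts.

    Control probes (negative / positive / housekeeping) are kept unchanged
    so the reference-based scaling step can still see them. Endogenous
    counts falling below the background are floored at ``floor``.
    """
    neg = raw.probes_of("negative")
    background = _geomean_shifted(raw.counts.loc[neg].to_numpy(), axis=0)
    counts = raw.counts.copy().astype(float)
    endo = raw.probe_class == "endogenous"
    counts.loc[endo] = np.maximum(counts.loc[endo].to_numpy() - background, floor)
    return RawCounts(counts, raw.probe_class.copy(), raw.gene_symbol.copy())


def estimate_background(raw: RawCounts) -> pd.Series:
    """Per-sample background estimate (geometric mean of negative controls)."""
    neg = raw.probes_of("negative")
    bg = _geomean_shifted(raw.counts.loc[neg].to_numpy(), axis=0)
    return pd.Series(bg, index=raw.counts.columns, name="background")


def normalize_geomean(raw: RawCounts, reference_value: float | None = None) -> RawCounts:
    """Scale each sample so reference-probe geometric means agree.

    Per sample i, ``g_i`` is the geometric mean of the positive-control and
    housekeeping probes; every count in sample i is multiplied by
    ``f_i = reference / g_i`` where ``reference`` defaults to the arithmetic
    mean of the ``g_i`` over samples.
    """
    ref_probes = raw.counts.index[raw.probe_class.isin(REFERENCE_CLASSES)]
    g = _geomean_shifted(raw.counts.loc[ref_probes].to_numpy(), axis=0)
    zero = np.flatnonzero(g <= 0)
    if zero.size:
        names = [raw.counts.columns[i] for i in zero]
        raise ValueError(f"degenerate reference probes (geometric mean 0) in samples: {names}")
    reference = float(np.mean(g)) if reference_value is None else float(reference_value)
    factors = reference / g
    counts = raw.counts * factors
    return RawCounts(counts, raw.probe_class.copy(), raw.gene_symbol.copy())


def scale_factors(raw: RawCounts, reference_value: float | None = None) -> pd.Series:
    """The per-sample multiplicative factors normalize_geomean would apply."""
    ref_probes = raw.counts.index[raw.probe_class.isin(REFERENCE_CLASSES)]
    g = _geomean_shifted(raw.counts.loc[ref_probes].to_numpy(), axis=0)
    reference = float(np.mean(g)) if reference_value is None else float(reference_value)
    return pd.Series(reference / g, index=raw.counts.columns, name="scale_factor")


def to_log2(raw: RawCounts, offset: float = 1.0, cohort_id: str = "cohort0") -> ExpressionDataset:
    """log2(count + offset) for endogenous probes, collapsed to gene symbols.

    Duplicate probes for the same symbol are collapsed by the mean of their
    log2 values.
    """
    endo = raw.probe_class == "endogenous"
    values = np.log2(raw.counts.loc[endo].to_numpy(dtype=float) + offset)
    df = pd.DataFrame(values, index=raw.gene_symbol[endo].to_numpy(), columns=raw.counts.columns)
    df = df.groupby(level=0, sort=False).mean()
    return ExpressionDataset(df, cohort_id=cohort_id)


def process(
    raw: RawCounts,
    floor: float = 1.0,
    offset: float = 1.0,
    reference_value: float | None = None,
    cohort_id: str = "cohort0",
) -> ExpressionDataset:
    """Full chain: background subtraction, reference scaling, log2."""
    return to_log2(
        normalize_geomean(subtract_background(raw, floor=floor), reference_value=reference_value),
        offset=offset,
        cohort_id=cohort_id,
    )
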