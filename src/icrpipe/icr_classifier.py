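"""Consensus-clustering classifier on the 20-gene ICR panel.

The classifier resamples items (samples) without replacement, clusters each
resample with Ward.D2 agglomeration, accumulates a pairwise co-clustering
consensus matrix, extracts the final k groups by complete linkage on
``1 - consensus``, and renames them ICR1..ICR4 by ascending within-cluster
mean ICR score (mean log2 expression of the 20 panel genes).

Ward.D2 semantics: the Lance-Williams update is applied to unsquared input
distances (scipy's ``linkage(..., method="ward")`` convention). The inner
distance defaults to Euclidean on the per-sample panel vectors; 1 - Pearson
correlation is available by configuration. Resampled indices are drawn on
the sorted-sample-ID order so results do not depend on input column order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import cut_tree, linkage
from scipy.spatial.distance import pdist, squareform

from icrpipe.datatypes import ExpressionDataset

#: The 20-gene ICR panel (Th1 signalling, chemoattraction, cytotoxicity,
#: and immune-checkpoint genes), alphabetical.
ICR_PANEL = (
    "CCL5", "CD274", "CD8A", "CD8B", "CTLA4",
    "CXCL9", "CXCL10", "FOXP3", "GNLY", "GZMA",
    "GZMB", "GZMH", "IDO1", "IFNG", "IL12B",
    "IRF1", "PDCD1", "PRF1", "STAT1", "TBX21",
)

INNER_DISTANCES = ("euclidean", "pearson")


@dataclass
class ConsensusConfig:
    """Parameters of the consensus-clustering run."""

    repetitions: int = 5000
    p_item: float = 0.80
    k: int = 4
    inner_linkage: str = "ward"
    outer_linkage: str = "complete"
    inner_distance: str = "euclidean"
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.p_item <= 1):
            raise ValueError("p_item must be in (0, 1]")
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if self.repetitions < 1:
            raise ValueError("repetitions must be >= 1")
        if self.inner_distance not in INNER_DISTANCES:
            raise ValueError(f"inner_distance must be one of {INNER_DISTANCES}")


@dataclass
class ConsensusResult:
    """Output of a consensus-clustering run (sample order = sorted IDs)."""

    consensus_matrix: pd.DataFrame
    co_sample_counts: pd.DataFrame
    labels: pd.Series  # final cluster index, 1..k
    metadata: dict = field(default_factory=dict)
    icr_class: pd.Series | None = None  # 1..4 after score-based relabeling
    icr_binary: pd.Series | None = None  # "ICR1" vs "ICR2-4"


def _pairwise_distance(x: np.ndarray, metric: str) -> np.ndarray:
    """Condensed distance between rows of x."""
    if metric == "euclidean":
        return pdist(x, metric="euclidean")
    # 1 - Pearson correlation between sample vectors
    return pdist(x, metric="correlation")


def ward_cut(x: np.ndarray, k: int, metric: str = "euclidean") -> np.ndarray:
    """Ward.D2 agglomerative clustering of rows of x, cut at k clusters."""
    d = _pairwise_distance(x, metric)
    z = linkage(d, method="ward")
    # cut_tree (not fcluster maxclust) guarantees exactly k clusters even
    # when merge heights tie
    return cut_tree(z, n_clusters=k).ravel() + 1


def consensus_cluster(panel: ExpressionDataset, config: ConsensusConfig) -> ConsensusResult:
    """Run item-resampled consensus clustering on a genes x samples panel.

    ``panel`` must contain exactly the rows to cluster on (for the ICR
    classifier, the 20 panel genes). Deterministic given ``config.seed``
    and invariant to the input column order.
    """
    n = panel.n_samples
    if n < config.k:
        raise ValueError(f"need at least k={config.k} samples, got {n}")

    order = sorted(panel.sample_ids)
    x = panel.values[order].to_numpy(dtype=float).T  # samples x genes, sorted IDs

    m = int(np.ceil(config.p_item * n))
    rng = np.random.default_rng(config.seed)
    co_cluster = np.zeros((n, n))
    co_sample = np.zeros((n, n))

    for _ in range(config.repetitions):
        idx = np.sort(rng.choice(n, size=m, replace=False))
        labels = ward_cut(x[idx], config.k, config.inner_distance)
        co_sample[np.ix_(idx, idx)] += 1.0
        for c in np.unique(labels):
            members = idx[labels == c]
            co_cluster[np.ix_(members, members)] += 1.0

    with np.errstate(invalid="ignore"):
        consensus = np.where(co_sample > 0, co_cluster / np.maximum(co_sample, 1), 0.5)
    never = int((co_sample == 0).sum() - np.trace(co_sample == 0))
    np.fill_diagonal(consensus, 1.0)

    z = linkage(squareform(1.0 - consensus, checks=False), method=config.outer_linkage)
    final = cut_tree(z, n_clusters=config.k).ravel() + 1

    return ConsensusResult(
        consensus_matrix=pd.DataFrame(consensus, index=order, columns=order),
        co_sample_counts=pd.DataFrame(co_sample, index=order, columns=order),
        labels=pd.Series(final, index=order, name="cluster"),
        metadata={
            "repetitions": config.repetitions,
            "p_item": config.p_item,
            "k": config.k,
            "inner_distance": config.inner_distance,
            "inner_linkage": config.inner_linkage,
            "outer_linkage": config.outer_linkage,
            "seed": config.seed,
            "never_cosampled_pairs": never // 2,
        },
    )


def icr_score(ds: ExpressionDataset) -> pd.Series:
    """Per-sample ICR score: arithmetic mean of the 20 panel genes (log2)."""
    missing = [g for g in ICR_PANEL if g not in ds.values.index]
    if missing:
        raise KeyError(f"ICR panel genes absent: {missing}")
    score = ds.values.loc[list(ICR_PANEL)].mean(axis=0)
    score.name = "icr_score"
    return score


def assign_icr_labels(result: ConsensusResult, scores: pd.Series) -> pd.Series:
    """Rename clusters ICR1..ICRk by ascending within-cluster mean score.

    Ties in cluster mean score are broken by cluster size, then by lowest
    original cluster index; the tie-break is recorded in metadata.
    """
    labels = result.labels
    aligned = scores.reindex(labels.index)
    if aligned.isna().any():
        raise ValueError("scores missing for some clustered samples")
    stats = []
    for c in sorted(labels.unique()):
        members = labels.index[labels == c]
        stats.append((float(aligned[members].mean()), -len(members), int(c)))
    ranked = sorted(stats)
    mapping = {orig: rank + 1 for rank, (_, _, orig) in enumerate(ranked)}
    means = [s[0] for s in stats]
    if len(set(np.round(means, 12))) < len(means):
        result.metadata["relabel_tiebreak"] = "mean-score tie broken by size then index"
    icr = labels.map(mapping).astype(int)
    icr.name = "icr_class"
    result.icr_class = icr
    result.icr_binary = collapse_classes(icr)
    return icr


def collapse_classes(icr_class: pd.Series) -> pd.Series:
    """Collapse 4-level ICR classes to 'ICR1' vs 'ICR2-4'."""
    vals = set(pd.Series(icr_class).unique())
    if not vals <= {1, 2, 3, 4}:
        raise ValueError(f"ICR classes must be in 1..4, got {sorted(vals)}")
    out = pd.Series(
        np.where(np.asarray(icr_class) == 1, "ICR1", "ICR2-4"),
        index=icr_class.index,
        name="icr_binary",
    )
    return out


def classify(ds: ExpressionDataset, config: ConsensusConfig) -> tuple[ConsensusResult, pd.DataFrame]:
    """Classify one cohort: consensus clustering on the panel + relabeling.

    Returns the ConsensusResult and a per-sample table with the ICR score,
    class and collapsed class, in the dataset's sample order.
    """
    panel = ds.subset_genes(list(ICR_PANEL))
    result = consensus_cluster(panel, config)
    scores = icr_score(ds)
    assign_icr_labels(result, scores)
    table = pd.DataFrame(
        {
            "sample_id": ds.sample_ids,
            "cohort_id": ds.cohort_id,
            "icr_score": scores.reindex(ds.sample_ids).to_numpy(),
            "icr_class": result.icr_class.reindex(ds.sample_ids).to_numpy(),
            "icr_binary": result.icr_binary.reindex(ds.sample_ids).to_numpy(),
        }
    )
    return result, table
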