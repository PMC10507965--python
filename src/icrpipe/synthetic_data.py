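"""Multi-cohort synthetic data with a planted four-class immune continuum.

Each sample draws a latent class 1-4; the 20 ICR panel genes get
class-specific mean log2 levels (monotone in class), companion-signature
genes load on the latent immune activity with a stated loading (negative
for the TP53-activation set), and filler genes carry no signal. Cohorts
receive per-gene location shifts and a noise-scale factor as batch
effects. DCB is Bernoulli with per-class probabilities; survival is
exponential with uniform censoring and independent of class by
construction.

Seeding: one root seed; each cohort uses the stream
``default_rng([seed, 1000 + cohort_index])`` and the gene panel a fixed
stream, so cohorts are independently reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from icrpipe.datatypes import (
    MUTATION_LEVELS,
    PATH_LEVELS,
    SEX_LEVELS,
    SMOKER_LEVELS,
    ClinicalTable,
    ExpressionDataset,
)
from icrpipe.icr_classifier import ICR_PANEL
from icrpipe.signatures import default_signature_db

#: Loadings of companion genes on the centered latent immune activity.
IMMUNE_LOADING = 0.9
TH2_LOADING = 0.3  # weaker so the Th1/Th2 ratio rises with class
TP53_LOADING = -0.9


def _class_offsets(step: float) -> np.ndarray:
    return np.arange(4, dtype=float) * step


def default_gene_means(step: float = 1.8, base_low: float = 5.0) -> np.ndarray:
    """4 x 20 matrix of class-wise mean log2 levels for the panel genes."""
    base = base_low + 0.15 * np.arange(len(ICR_PANEL))
    return base[None, :] + _class_offsets(step)[:, None]


@dataclass
class SimConfig:
    """Configuration of the synthetic multi-cohort generator."""

    n_cohorts: int = 5
    n_per_cohort: tuple[int, ...] = (44, 30, 30, 28, 30)
    class_probs: tuple[float, ...] = (0.22, 0.30, 0.22, 0.26)
    dcb_probs: tuple[float, ...] = (0.09, 0.35, 0.35, 0.35)
    icr_gene_means: np.ndarray = field(default_factory=default_gene_means)
    noise_sd: float = 0.7
    batch_shift_sd: float = 0.5
    batch_scale_sd: float = 0.10
    n_extra_genes: int = 480
    survival_event_rate: float = 1.0 / 60.0  # events per month
    censor_window: float = 120.0  # months; censoring ~ Uniform(0, window)
    seed: int = 0

    def __post_init__(self) -> None:
        self.icr_gene_means = np.asarray(self.icr_gene_means, dtype=float)
        if self.n_cohorts < 1:
            raise ValueError("n_cohorts must be >= 1")
        if len(self.n_per_cohort) != self.n_cohorts:
            raise ValueError("n_per_cohort length must equal n_cohorts")
        p = np.asarray(self.class_probs, dtype=float)
        if len(p) != 4 or (p < 0).any() or abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("class_probs must be 4 non-negative values summing to 1")
        d = np.asarray(self.dcb_probs, dtype=float)
        if len(d) != 4 or (d < 0).any() or (d > 1).any():
            raise ValueError("dcb_probs must be 4 probabilities")
        if self.icr_gene_means.shape != (4, len(ICR_PANEL)):
            raise ValueError(f"icr_gene_means must be 4 x {len(ICR_PANEL)}")
        if (np.diff(self.icr_gene_means, axis=0) < 0).any():
            raise ValueError("icr_gene_means must be non-decreasing in class per gene")
        if (np.diff(self.icr_gene_means.mean(axis=1)) <= 0).any():
            raise ValueError("mean panel level must strictly increase ICR1 -> ICR4")
        if self.noise_sd < 0 or self.batch_shift_sd < 0 or self.batch_scale_sd < 0:
            raise ValueError("noise and batch magnitudes must be non-negative")


def strong_separation_config(**overrides) -> SimConfig:
    """Preset with planted classes recoverable by the classifier (ARI >= 0.9)."""
    return SimConfig(**overrides)


def weak_separation_config(**overrides) -> SimConfig:
    """Stress-test preset with heavily overlapping classes."""
    defaults = dict(icr_gene_means=default_gene_means(step=0.6), noise_sd=1.4)
    defaults.update(overrides)
    return SimConfig(**defaults)


@dataclass
class SimCohort:
    """One generated cohort: expression + clinical + latent class labels."""

    expression: ExpressionDataset
    clinical: ClinicalTable
    true_class: pd.Series

    def __post_init__(self) -> None:
        ids = self.expression.sample_ids
        if list(self.clinical.data["sample_id"]) != ids or list(self.true_class.index) != ids:
            raise ValueError("sample IDs must be identical and ordered identically")


def _companion_panel(config: SimConfig) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Companion + filler gene names, baseline levels and loadings.

    Companion genes come from the shipped signature database (everything
    not already on the ICR panel); fillers pad up to n_extra_genes. The
    baseline levels are drawn from a fixed stream of the root seed so all
    cohorts share them.
    """
    db = default_signature_db()
    tp53 = set(db["TP53_ACTIVATION"].genes) if "TP53_ACTIVATION" in db else set()
    th2 = set(db["BINDEA_TH2_CELLS"].genes) if "BINDEA_TH2_CELLS" in db else set()
    companions: list[str] = []
    seen = set(ICR_PANEL)
    for gs in db.values():
        for g in gs.genes:
            if g not in seen:
                companions.append(g)
                seen.add(g)
    companions = companions[: config.n_extra_genes]
    n_filler = max(config.n_extra_genes - len(companions), 0)
    fillers = [f"FILLER{i:04d}" for i in range(n_filler)]
    genes = companions + fillers

    rng = np.random.default_rng([config.seed, 7])
    baselines = rng.uniform(4.0, 10.0, size=len(genes))
    loadings = np.zeros(len(genes))
    for i, g in enumerate(companions):
        if g in tp53:
            loadings[i] = TP53_LOADING
        elif g in th2:
            loadings[i] = TH2_LOADING
        else:
            loadings[i] = IMMUNE_LOADING
    return genes, baselines, loadings


def generate_cohort(config: SimConfig, cohort_index: int) -> SimCohort:
    """Generate one cohort; reproducible from (seed, cohort_index) alone."""
    if not (0 <= cohort_index < config.n_cohorts):
        raise ValueError(f"cohort_index must be < n_cohorts={config.n_cohorts}")
    n = config.n_per_cohort[cohort_index]
    if n < 4:
        raise ValueError(f"cohort size {n} too small to cluster (need >= 4)")

    rng = np.random.default_rng([config.seed, 1000 + cohort_index])
    cohort_id = f"cohort{cohort_index}"
    sample_ids = [f"C{cohort_index}S{j:03d}" for j in range(n)]

    classes = rng.choice(4, size=n, p=np.asarray(config.class_probs)) + 1

    # batch effects: per-gene location shift, scalar noise-scale factor
    extra_genes, baselines, loadings = _companion_panel(config)
    n_genes = len(ICR_PANEL) + len(extra_genes)
    shifts = rng.normal(0.0, config.batch_shift_sd, size=n_genes)
    scale = float(np.exp(rng.normal(0.0, config.batch_scale_sd))) if config.batch_scale_sd else 1.0
    sd = config.noise_sd * scale

    class_means = config.icr_gene_means  # 4 x 20
    panel_mu = class_means[classes - 1]  # n x 20
    panel = panel_mu + shifts[: len(ICR_PANEL)][None, :]
    if sd > 0:
        panel = panel + rng.normal(0.0, sd, size=panel.shape)

    # latent immune activity: centered class index on a fixed unit scale,
    # so companion-gene swing does not grow with the panel class step
    activity = classes - 2.5
    extra = baselines[None, :] + np.outer(activity, loadings)
    extra = extra + shifts[len(ICR_PANEL):][None, :]
    if sd > 0:
        extra = extra + rng.normal(0.0, sd, size=extra.shape)

    values = pd.DataFrame(
        np.hstack([panel, extra]).T,
        index=list(ICR_PANEL) + extra_genes,
        columns=sample_ids,
    )
    expression = ExpressionDataset(values, cohort_id=cohort_id)

    dcb = rng.random(n) < np.asarray(config.dcb_probs)[classes - 1]
    event_time = rng.exponential(1.0 / config.survival_event_rate, size=n)
    censor_time = rng.uniform(0.0, config.censor_window, size=n)
    dfs_months = np.minimum(event_time, censor_time)
    dfs_event = (event_time <= censor_time).astype(int)

    clinical = ClinicalTable(
        pd.DataFrame(
            {
                "sample_id": sample_ids,
                "cohort_id": cohort_id,
                "age": np.clip(np.round(rng.normal(60.0, 10.0, size=n)), 26, 90).astype(int),
                "sex": rng.choice(SEX_LEVELS, size=n, p=(0.33, 0.67)),
                "smoker_status": rng.choice(SMOKER_LEVELS, size=n, p=(0.46, 0.43, 0.11)),
                "pathological_type": rng.choice(PATH_LEVELS, size=n, p=(0.35, 0.65)),
                "mutational_status": rng.choice(MUTATION_LEVELS, size=n, p=(0.38, 0.62)),
                "dcb": dcb.astype(int),
                "dfs_months": dfs_months,
                "dfs_event": dfs_event,
            }
        )
    )
    true_class = pd.Series(classes, index=sample_ids, name="true_class")
    return SimCohort(expression=expression, clinical=clinical, true_class=true_class)


def generate_multi_cohort(config: SimConfig) -> list[SimCohort]:
    """Generate all cohorts of the configuration."""
    return [generate_cohort(config, i) for i in range(config.n_cohorts)]


# ---------------------------------------------------------------------------
# raw NanoString-style fixture
# ---------------------------------------------------------------------------

N_PROBES_TOTAL = 770
N_NEGATIVE = 8
N_POSITIVE = 6
N_HOUSEKEEPING = 40


@dataclass
class RawNanoStringTruth:
    """Raw probe counts plus the ground truth the generator planted."""

    raw: "object"  # RawCounts; typed loosely to avoid an import cycle
    scale_factors: pd.Series  # per-sample multiplicative factor s_i
    background: float  # additive background (counts)
    abundances: pd.Series  # true per-probe abundance (shared by samples)


def generate_raw_nanostring(
    config: SimConfig,
    n_samples: int | None = None,
    background: float = 6.0,
    scale_sd: float = 0.3,
    scale_factors: np.ndarray | None = None,
    noise: bool = True,
) -> RawNanoStringTruth:
    """Raw 770-probe count table with known scale factors and background.

    Probe layout: the 20 ICR genes plus filler endogenous probes, 8
    negative controls, 6 positive controls and 40 housekeeping probes.
    Counts are Poisson around ``s_i * abundance + background`` when
    ``noise`` is true, else deterministic rounded values.
    """
    from icrpipe.nanostring_norm import RawCounts

    if n_samples is None:
        n_samples = config.n_per_cohort[0]
    rng = np.random.default_rng([config.seed, 42])

    n_endo = N_PROBES_TOTAL - N_NEGATIVE - N_POSITIVE - N_HOUSEKEEPING
    endo_genes = list(ICR_PANEL) + [f"ENDO{i:04d}" for i in range(n_endo - len(ICR_PANEL))]
    probe_ids = (
        [f"P_{g}" for g in endo_genes]
        + [f"NEG{i}" for i in range(N_NEGATIVE)]
        + [f"POS{i}" for i in range(N_POSITIVE)]
        + [f"HK{i:02d}" for i in range(N_HOUSEKEEPING)]
    )
    probe_class = (
        ["endogenous"] * n_endo
        + ["negative"] * N_NEGATIVE
        + ["positive"] * N_POSITIVE
        + ["housekeeping"] * N_HOUSEKEEPING
    )
    gene_symbol = (
        endo_genes
        + [f"NEG{i}" for i in range(N_NEGATIVE)]
        + [f"POS{i}" for i in range(N_POSITIVE)]
        + [f"HK{i:02d}" for i in range(N_HOUSEKEEPING)]
    )

    endo_abund = np.round(np.exp(rng.uniform(np.log(20), np.log(2000), size=n_endo)))
    ref_abund = np.round(np.exp(rng.uniform(np.log(500), np.log(5000), size=N_POSITIVE + N_HOUSEKEEPING)))
    abund = np.concatenate([endo_abund, np.zeros(N_NEGATIVE), ref_abund])

    if scale_factors is None:
        s = np.exp(rng.normal(0.0, scale_sd, size=n_samples)) if scale_sd else np.ones(n_samples)
    else:
        s = np.asarray(scale_factors, dtype=float)
        if len(s) != n_samples:
            raise ValueError("scale_factors length must equal n_samples")

    expected = np.outer(abund, s) + background
    counts = rng.poisson(expected).astype(float) if noise else np.round(expected)

    sample_ids = [f"N{j:03d}" for j in range(n_samples)]
    raw = RawCounts(
        counts=pd.DataFrame(counts, index=probe_ids, columns=sample_ids),
        probe_class=pd.Series(probe_class, index=probe_ids, name="probe_class"),
        gene_symbol=pd.Series(gene_symbol, index=probe_ids, name="gene_symbol"),
    )
    return RawNanoStringTruth(
        raw=raw,
        scale_factors=pd.Series(s, index=sample_ids, name="scale_factor"),
        background=float(background),
        abundances=pd.Series(abund, index=probe_ids, name="abundance"),
    )


def write_cohort(cohort: SimCohort, out_dir) -> dict[str, Path]:
    """Write one cohort as plain-text files; returns the written paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cid = cohort.expression.cohort_id
    paths = {
        "expression": out / f"{cid}_expression.tsv",
        "clinical": out / f"{cid}_clinical.csv",
        "truth": out / f"{cid}_truth.csv",
    }
    cohort.expression.to_tsv(paths["expression"])
    cohort.clinical.to_csv(paths["clinical"])
    cohort.true_class.rename_axis("sample_id").to_frame().to_csv(paths["truth"])
    return paths


def with_seed(config: SimConfig, seed: int) -> SimConfig:
    """Copy of the configuration with a different root seed."""
    return replace(config, icr_gene_means=config.icr_gene_means.copy(), seed=seed)
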