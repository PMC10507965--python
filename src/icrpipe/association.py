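"""Outcome-association statistics.

Contingency tables, Wald odds ratios, an exact conditional test for 2 x k
tables (probability-mass ordering), logistic regression by IRLS with Wald
intervals, one-way ANOVA, and Cochran's Q homogeneity across cohorts.

All p-values are nominal; no multiplicity correction is applied.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats

Z975 = 1.959963984540054  # standard normal 97.5% quantile


@dataclass
class AssociationResult:
    """An effect estimate with its Wald interval and test p-value."""

    table: np.ndarray | None
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    test: str
    n: int
    notes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if np.isfinite(self.odds_ratio) and self.odds_ratio <= 0:
            raise ValueError("odds ratio must be positive")
        if np.isfinite(self.odds_ratio) and not (
            self.ci_low <= self.odds_ratio <= self.ci_high
        ):
            raise ValueError("CI must contain the odds ratio")


def contingency_table(group_labels, outcome) -> pd.DataFrame:
    """k x 2 counts of a boolean outcome by group, with per-group rates.

    Groups are row-ordered by first appearance unless the labels are
    categorical with declared order. Empty groups are retained with zeros.
    """
    g = pd.Series(group_labels).reset_index(drop=True)
    y = pd.Series(outcome).reset_index(drop=True).astype(bool)
    if len(g) != len(y):
        raise ValueError("labels and outcomes must be aligned")
    mask = g.notna() & y.notna()
    g, y = g[mask], y[mask]
    if isinstance(g.dtype, pd.CategoricalDtype):
        levels = list(g.cat.categories)
    else:
        levels = list(pd.unique(g))
    rows = []
    for lev in levels:
        sel = g == lev
        rows.append([int((y[sel]).sum()), int((~y[sel]).sum())])
    out = pd.DataFrame(rows, index=levels, columns=["yes", "no"])
    out["rate"] = out["yes"] / out[["yes", "no"]].sum(axis=1).replace(0, np.nan)
    return out


def odds_ratio_wald(table: np.ndarray) -> AssociationResult:
    """Wald odds ratio with 95% CI from a 2 x 2 table [[a, b], [c, d]].

    OR = (a*d)/(b*c) comparing row 1 against row 2 for the column-1
    outcome. Any zero cell triggers the Haldane-Anscombe +0.5 correction
    (flagged in notes); a fully zero row or column is an error.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("need a non-negative 2x2 table")
    if (t.sum(axis=1) == 0).any() or (t.sum(axis=0) == 0).any():
        raise ValueError("odds ratio undefined: a row or column is entirely zero")
    notes = []
    work = t.copy()
    if (work == 0).any():
        work += 0.5
        notes.append("haldane-anscombe +0.5 correction applied")
    a, b, c, d = work.ravel()
    log_or = np.log(a * d / (b * c))
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = log_or / se
    p = 2 * stats.norm.sf(abs(z))
    return AssociationResult(
        table=t.astype(int),
        odds_ratio=float(np.exp(log_or)),
        ci_low=float(np.exp(log_or - Z975 * se)),
        ci_high=float(np.exp(log_or + Z975 * se)),
        p_value=float(p),
        test="wald",
        n=int(t.sum()),
        notes=notes,
    )


def fisher_exact(table: np.ndarray) -> float:
    """Two-sided exact conditional p-value for a 2 x k table.

    Conditions on both margins and sums the multivariate hypergeometric
    probabilities of every table at least as extreme (probability-mass
    ordering) as the observed one. For k = 2 this is Fisher's exact test;
    for larger k it is the Freeman-Halton extension by enumeration.
    """
    t = np.asarray(table, dtype=int)
    if t.ndim != 2 or t.shape[0] != 2 or (t < 0).any():
        raise ValueError("need a non-negative 2 x k integer table")
    col_tot = t.sum(axis=0)
    r1 = int(t[0].sum())
    n = int(t.sum())
    if t.shape[1] < 2 or r1 == 0 or r1 == n or (col_tot == 0).all():
        return 1.0  # degenerate margins: only one table is possible

    def logc(m, x):
        return special.gammaln(m + 1) - special.gammaln(x + 1) - special.gammaln(m - x + 1)

    denom = logc(n, r1)
    tol = 1e-7  # relative slack so equal-probability tables count as tied

    if t.shape[1] == 2:  # vectorized hypergeometric enumeration
        c1 = int(col_tot[0])
        a = np.arange(max(0, r1 - int(col_tot[1])), min(r1, c1) + 1)
        logp = logc(c1, a) + logc(col_tot[1], r1 - a) - denom
        obs = logp[a == t[0, 0]][0]
        return float(min(np.exp(logp[logp <= obs + tol]).sum(), 1.0))

    obs_logp = float(sum(logc(c, x) for c, x in zip(col_tot, t[0])) - denom)
    ranges = [range(0, int(c) + 1) for c in col_tot[:-1]]
    total = 0.0
    last_cap = int(col_tot[-1])
    for head in itertools.product(*ranges):
        a_last = r1 - sum(head)
        if a_last < 0 or a_last > last_cap:
            continue
        lp = float(sum(logc(c, x) for c, x in zip(col_tot, head + (a_last,))) - denom)
        if lp <= obs_logp + tol:
            total += np.exp(lp)
    return float(min(total, 1.0))


@dataclass
class LogisticFit:
    """IRLS logistic-regression fit with per-term Wald statistics."""

    summary: pd.DataFrame  # term, coef, se, odds_ratio, ci_low, ci_high, p
    converged: bool
    n: int
    n_iter: int
    separation: list[str] = field(default_factory=list)

    @property
    def coefficients(self) -> pd.Series:
        return self.summary.set_index("term")["coef"]


def logistic_fit(
    design: pd.DataFrame,
    outcome,
    max_iter: int = 25,
    tol: float = 1e-8,
) -> LogisticFit:
    """Maximum-likelihood logistic regression of a boolean outcome.

    ``design`` holds numeric predictor columns (no intercept; one is added).
    Rows with any missing value are dropped listwise. Fitting is IRLS
    started at zero coefficients with the intercept at the logit of the
    outcome mean; convergence when the maximum absolute score falls below
    ``tol``. Diverging coefficients are reported as non-estimable
    (separation) rather than silently returned.
    """
    x = design.astype(float)
    y = pd.Series(outcome).reset_index(drop=True).astype(float)
    x = x.reset_index(drop=True)
    keep = x.notna().all(axis=1) & y.notna()
    x, y = x[keep], y[keep]
    n, p = len(x), x.shape[1] + 1
    if n <= p:
        raise ValueError(f"n={n} too small for {p} parameters")
    if y.nunique() < 2:
        raise ValueError("outcome must have both levels")

    xmat = np.column_stack([np.ones(n), x.to_numpy()])
    yv = y.to_numpy()
    beta = np.zeros(p)
    ybar = yv.mean()
    beta[0] = np.log(ybar / (1 - ybar))

    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = xmat @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        score = xmat.T @ (yv - mu)
        if np.max(np.abs(score)) < tol:
            converged = True
            break
        info = xmat.T @ (xmat * w[:, None])
        try:
            beta = beta + np.linalg.solve(info, score)
        except np.linalg.LinAlgError:
            break

    eta = xmat @ beta
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = mu * (1.0 - mu)
    info = xmat.T @ (xmat * w[:, None])
    try:
        cov = np.linalg.inv(info)
        se = np.sqrt(np.diag(cov))
    except np.linalg.LinAlgError:
        se = np.full(p, np.inf)

    terms = ["(intercept)"] + list(x.columns)
    separation = [
        t for t, b, s in zip(terms, beta, se) if abs(b) > 12 or not np.isfinite(s) or s > 1e3
    ]
    zstat = beta / se
    pvals = 2 * stats.norm.sf(np.abs(zstat))
    with np.errstate(over="ignore"):  # separated fits can overflow exp()
        summary = pd.DataFrame(
            {
                "term": terms,
                "coef": beta,
                "se": se,
                "odds_ratio": np.exp(beta),
                "ci_low": np.exp(beta - Z975 * se),
                "ci_high": np.exp(beta + Z975 * se),
                "p": pvals,
                "n": n,
            }
        )
    return LogisticFit(
        summary=summary,
        converged=converged,
        n=n,
        n_iter=it,
        separation=separation,
    )


def build_design(df: pd.DataFrame, terms: dict[str, str | None]) -> pd.DataFrame:
    """Dummy-code predictors for logistic_fit.

    ``terms`` maps column name to its reference level (``None`` keeps the
    column as numeric). Each categorical column becomes indicator columns
    ``col[level]`` for the non-reference levels.
    """
    cols = {}
    for col, ref in terms.items():
        if col not in df.columns:
            raise KeyError(f"predictor {col!r} absent")
        if ref is None:
            cols[col] = pd.to_numeric(df[col], errors="coerce")
        else:
            series = df[col]
            levels = [lv for lv in pd.unique(series.dropna()) if lv != ref]
            for lv in sorted(map(str, levels)):
                ind = series.map(lambda v: np.nan if pd.isna(v) else float(str(v) == lv))
                cols[f"{col}[{lv}]"] = ind
    return pd.DataFrame(cols, index=df.index)


def anova_oneway(values, groups) -> tuple[float, float]:
    """Classical one-way ANOVA F statistic and p-value."""
    v = pd.Series(values).reset_index(drop=True).astype(float)
    g = pd.Series(groups).reset_index(drop=True)
    mask = v.notna() & g.notna()
    v, g = v[mask], g[mask]
    levels = pd.unique(g)
    if len(levels) < 2:
        raise ValueError("ANOVA needs at least 2 groups")
    n = len(v)
    grand = v.mean()
    ss_between = sum(len(v[g == lev]) * (v[g == lev].mean() - grand) ** 2 for lev in levels)
    ss_within = sum(((v[g == lev] - v[g == lev].mean()) ** 2).sum() for lev in levels)
    df_b, df_w = len(levels) - 1, n - len(levels)
    if df_w <= 0:
        raise ValueError("not enough observations for within-group variance")
    if ss_within == 0:
        return float("inf"), 0.0
    f = (ss_between / df_b) / (ss_within / df_w)
    return float(f), float(stats.f.sf(f, df_b, df_w))


def homogeneity_test(tables: list[np.ndarray]) -> tuple[float, float]:
    """Cochran's Q for homogeneity of 2 x 2 log odds ratios across cohorts.

    Inverse-variance weights on the per-table log OR; tables with a zero
    cell get the +0.5 correction. Returns (Q, p) with p from chi-square on
    ``len(tables) - 1`` degrees of freedom.
    """
    log_ors, weights = [], []
    for t in tables:
        t = np.asarray(t, dtype=float)
        if t.shape != (2, 2):
            raise ValueError("each stratum must be a 2x2 table")
        if (t.sum(axis=1) == 0).any() or (t.sum(axis=0) == 0).any():
            continue  # log OR not estimable in this stratum
        if (t == 0).any():
            t = t + 0.5
        a, b, c, d = t.ravel()
        log_ors.append(np.log(a * d / (b * c)))
        weights.append(1.0 / (1 / a + 1 / b + 1 / c + 1 / d))
    if len(log_ors) < 2:
        raise ValueError("homogeneity test needs >= 2 estimable cohorts")
    y = np.asarray(log_ors)
    w = np.asarray(weights)
    pooled = np.sum(w * y) / np.sum(w)
    q = float(np.sum(w * (y - pooled) ** 2))
    p = float(stats.chi2.sf(q, len(y) - 1))
    return q, p
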