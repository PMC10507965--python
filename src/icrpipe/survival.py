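"""Kaplan-Meier estimation and log-rank comparison.

The product-limit estimator carries a Greenwood variance; the 95% CI is
computed on log S with symmetric normal quantiles and truncated to [0, 1].
At tied times, deaths precede censorings (standard convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

Z975 = 1.959963984540054


@dataclass
class SurvivalData:
    """Follow-up times (months), event indicators and optional group label."""

    time: np.ndarray
    event: np.ndarray
    group: str = ""

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=int)
        if self.time.shape != self.event.shape:
            raise ValueError("time and event must be aligned")
        if len(self.time) == 0:
            raise ValueError("at least one subject required")
        if not np.all(np.isfinite(self.time)) or (self.time < 0).any():
            raise ValueError("times must be finite and non-negative")
        if not np.isin(self.event, (0, 1)).all():
            raise ValueError("event must be 0/1")

    @classmethod
    def from_frame(cls, df: pd.DataFrame, group: str = "") -> "SurvivalData":
        return cls(df["dfs_months"].to_numpy(), df["dfs_event"].to_numpy(), group=group)


@dataclass
class SurvivalCurve:
    """Kaplan-Meier step function with Greenwood CIs."""

    times: np.ndarray  # distinct event times, ascending
    survival: np.ndarray  # S(t) at each event time
    variance: np.ndarray  # Greenwood variance of S(t)
    ci_low: np.ndarray
    ci_high: np.ndarray
    n_at_risk: np.ndarray
    n_events: np.ndarray
    group: str = ""
    flags: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.times,
                "n_at_risk": self.n_at_risk,
                "n_events": self.n_events,
                "survival": self.survival,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
            }
        )


def km_estimate(data: SurvivalData) -> SurvivalCurve:
    """Product-limit survival estimate with Greenwood log-scale CIs."""
    order = np.lexsort((1 - data.event, data.time))  # deaths before censorings at ties
    t, e = data.time[order], data.event[order]
    n = len(t)

    event_times = np.unique(t[e == 1])
    surv, var, lo, hi, at_risk, n_ev = [], [], [], [], [], []
    s = 1.0
    greenwood_sum = 0.0  # sum of d / (n * (n - d)) on the log scale
    for et in event_times:
        r = int(np.sum(t >= et))
        d = int(np.sum((t == et) & (e == 1)))
        s *= 1.0 - d / r
        if r > d:
            greenwood_sum += d / (r * (r - d))
        var_s = s * s * greenwood_sum
        if s > 0:
            se_log = np.sqrt(greenwood_sum)
            lo.append(max(s * np.exp(-Z975 * se_log), 0.0))
            hi.append(min(s * np.exp(Z975 * se_log), 1.0))
        else:
            lo.append(0.0)
            hi.append(0.0)
        surv.append(s)
        var.append(var_s)
        at_risk.append(r)
        n_ev.append(d)

    flags = []
    if len(event_times) == 0:
        flags.append("no events: curve is identically 1")
    if n == int(np.sum((t == 0) & (e == 0))):
        flags.append("degenerate: all subjects censored at time 0")
    return SurvivalCurve(
        times=np.asarray(event_times, dtype=float),
        survival=np.asarray(surv),
        variance=np.asarray(var),
        ci_low=np.asarray(lo),
        ci_high=np.asarray(hi),
        n_at_risk=np.asarray(at_risk, dtype=int),
        n_events=np.asarray(n_ev, dtype=int),
        group=data.group,
        flags=flags,
    )


def survival_at(curve: SurvivalCurve, t: float) -> tuple[float, float, float, bool]:
    """Right-continuous evaluation of S(t) with its CI.

    Returns (survival, ci_low, ci_high, extrapolated); ``extrapolated`` is
    true when t lies beyond the last observed event time.
    """
    if t < 0:
        raise ValueError("t must be >= 0")
    if len(curve.times) == 0 or t < curve.times[0]:
        return 1.0, 1.0, 1.0, False
    i = int(np.searchsorted(curve.times, t, side="right")) - 1
    extrapolated = t > curve.times[-1]
    return (
        float(curve.survival[i]),
        float(curve.ci_low[i]),
        float(curve.ci_high[i]),
        bool(extrapolated),
    )


def logrank_test(groups: list[SurvivalData]) -> tuple[float, float]:
    """k-sample log-rank test; returns (chi-square, p) with k-1 df.

    With no events anywhere the statistic is undefined and (0, 1) is
    returned.
    """
    if len(groups) < 2:
        raise ValueError("log-rank needs >= 2 groups")
    k = len(groups)
    times = np.concatenate([g.time for g in groups])
    events = np.concatenate([g.event for g in groups])
    membership = np.concatenate([np.full(len(g.time), i) for i, g in enumerate(groups)])
    if events.sum() == 0:
        return 0.0, 1.0

    event_times = np.unique(times[events == 1])
    observed = np.zeros(k)
    expected = np.zeros(k)
    cov = np.zeros((k, k))
    for et in event_times:
        at_risk = times >= et
        n_j = np.array([np.sum(at_risk & (membership == i)) for i in range(k)], dtype=float)
        n_tot = n_j.sum()
        d_tot = float(np.sum((times == et) & (events == 1)))
        d_j = np.array(
            [np.sum((times == et) & (events == 1) & (membership == i)) for i in range(k)],
            dtype=float,
        )
        observed += d_j
        expected += d_tot * n_j / n_tot
        if n_tot > 1:
            frac = n_j / n_tot
            mult = d_tot * (n_tot - d_tot) / (n_tot - 1)
            cov += mult * (np.diag(frac) - np.outer(frac, frac))

    # drop one group: the statistic uses the (k-1)-dim reduced system
    diff = (observed - expected)[:-1]
    vmat = cov[:-1, :-1]
    try:
        chi2 = float(diff @ np.linalg.solve(vmat, diff))
    except np.linalg.LinAlgError:
        chi2 = float(diff @ np.linalg.pinv(vmat) @ diff)
    p = float(stats.chi2.sf(chi2, k - 1))
    return chi2, p


def read_survival_csv(path) -> list[SurvivalData]:
    """Read (id, time_months, event, group) CSV into per-group SurvivalData."""
    df = pd.read_csv(path)
    needed = {"time_months", "event", "group"}
    missing = needed - set(df.columns)
    if missing:
        raise ValueError(f"survival CSV missing columns: {sorted(missing)}")
    return [
        SurvivalData(sub["time_months"].to_numpy(), sub["event"].to_numpy(), group=str(name))
        for name, sub in df.groupby("group")
    ]
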