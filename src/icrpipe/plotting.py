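"""Optional diagnostics plots (requires matplotlib, ``pip install icrpipe[plot]``)."""

from __future__ import annotations

import numpy as np

from icrpipe.icr_classifier import ConsensusResult
from icrpipe.survival import SurvivalCurve


def _axes(ax):
    if ax is not None:
        return ax
    import matplotlib.pyplot as plt

    _, ax = plt.subplots()
    return ax


def plot_km(curve: SurvivalCurve, ax=None, ci: bool = True):
    """Step plot of a Kaplan-Meier curve with its Greenwood CI band."""
    ax = _axes(ax)
    t = np.concatenate([[0.0], curve.times])
    s = np.concatenate([[1.0], curve.survival])
    ax.step(t, s, where="post", label=curve.group or None)
    if ci and len(curve.times):
        lo = np.concatenate([[1.0], curve.ci_low])
        hi = np.concatenate([[1.0], curve.ci_high])
        ax.fill_between(t, lo, hi, step="post", alpha=0.2)
    ax.set_xlabel("months")
    ax.set_ylabel("survival probability")
    ax.set_ylim(0, 1.05)
    return ax


def plot_consensus_heatmap(result: ConsensusResult, ax=None):
    """Consensus matrix heatmap with samples ordered by final cluster."""
    ax = _axes(ax)
    order = result.labels.sort_values(kind="stable").index
    m = result.consensus_matrix.loc[order, order].to_numpy()
    im = ax.imshow(m, vmin=0, vmax=1, cmap="viridis", interpolation="nearest")
    ax.figure.colorbar(im, ax=ax, label="consensus")
    ax.set_xticks([])
    ax.set_yticks([])
    return ax
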