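"""Figures: group mean curves per segment with the SnPM{t} panel."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

_UNITS = {"raw": "kgf", "norm": "-", "draw": "kgf/s", "dnorm": "1/s"}


def plot_contrast(results, segment: str, family: str):
    """Two-panel figure: group means vs normalized time, and the SnPM{t} curve
    with the critical threshold and significant clusters shaded."""
    X, labels = results.segment_matrix(segment, family)
    res = results.snpm(segment, family)
    tau = np.linspace(0, 100, X.shape[1])
    gx, gy = results.groups

    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(9, 3.2), constrained_layout=True)
    for g, color in ((gx, "tab:blue"), (gy, "tab:orange")):
        mean = X[labels == g].mean(axis=0)
        sd = X[labels == g].std(axis=0, ddof=1)
        ax1.plot(tau, mean, color=color, label=g)
        ax1.fill_between(tau, mean - sd, mean + sd, color=color, alpha=0.2)
    ax1.set_xlabel("normalized time (%)")
    ax1.set_ylabel(f"{family} ({_UNITS[family]})")
    ax1.set_title(segment)
    ax1.legend()

    ax2.plot(tau, res.t_curve, "k")
    ax2.axhline(res.t_crit, ls="--", color="r", lw=0.8)
    ax2.axhline(-res.t_crit, ls="--", color="r", lw=0.8)
    for c in res.significant_clusters:
        ax2.axvspan(c.start_pct, c.end_pct, color="0.8")
    ax2.set_xlabel("normalized time (%)")
    ax2.set_ylabel("SnPM{t}")
    ax2.set_title(f"t_crit = {res.t_crit:.2f}")
    return fig
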