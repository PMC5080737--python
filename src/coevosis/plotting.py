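"""Small plotting helpers for run output (matplotlib)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg", force=False)
import matplotlib.pyplot as plt  # noqa: E402
import pandas as pd  # noqa: E402

__all__ = ["plot_epidemic_trajectory", "plot_targeting"]


def plot_epidemic_trajectory(ledger: pd.DataFrame, ax=None):
    """Susceptible / infected counts and per-step transmissibility."""
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 3.5))
    ax.plot(ledger["t"], ledger["S_end"], label="susceptible", color="tab:blue")
    ax.plot(ledger["t"], ledger["I_end"], label="infected", color="tab:red")
    ax.set_xlabel("time step")
    ax.set_ylabel("hosts")
    ax2 = ax.twinx()
    ax2.plot(ledger["t"], ledger["xi"], color="tab:gray", alpha=0.4, lw=0.8,
             label=r"$\xi$")
    ax2.set_ylabel(r"transmissibility $\xi$")
    ax2.set_ylim(0, 1.05)
    ax.legend(loc="upper right", frameon=False)
    return ax


def plot_targeting(ledger: pd.DataFrame, ax=None):
    """Cumulative per-receptor infection counts over time."""
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 3))
    cols = [c for c in ledger.columns if c.startswith("matches_receptor_")]
    for c in cols:
        ax.plot(ledger["t"], ledger[c].cumsum(), label=c.split("_")[-1])
    ax.set_xlabel("time step")
    ax.set_ylabel("cumulative infections")
    ax.legend(title="receptor", frameon=False, fontsize=8)
    return ax
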