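"""Trace and summary figures (matplotlib, Agg-safe)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg", force=False)

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

__all__ = ["plot_spv_trace", "plot_dp_trace", "plot_class_boxplots"]


def _stage_boundaries(stages: np.ndarray) -> list[int]:
    changes = np.flatnonzero(stages[1:] != stages[:-1]) + 1
    return list(changes)


def plot_spv_trace(trace: pd.DataFrame, ax=None):
    """Predicted probability (top) and regulated variance with valence
    markers (bottom) over trials."""
    from .static_model import sigmoid

    if ax is None:
        fig, (ax_top, ax_bot) = plt.subplots(2, 1, figsize=(9, 6), sharex=True)
    else:
        ax_top, ax_bot = ax
        fig = ax_top.figure
    trials = trace["trial"].to_numpy()
    ax_top.plot(trials, sigmoid(trace["mu2"].to_numpy()), "r-", lw=1,
                label="predicted P(u=1)")
    ax_top.plot(trials, trace["u"], "g.", ms=3, alpha=0.5, label="input u")
    ax_top.set_ylabel("probability")
    ax_top.legend(loc="upper right", fontsize=8)

    ax_bot.plot(trials, trace["sigma2_post"], "k-", lw=1)
    V = trace["V"].to_numpy()
    pos, neg = V > 0, V < 0
    ax_bot.plot(trials[pos], trace["sigma2_post"].to_numpy()[pos], "bo", ms=2)
    ax_bot.plot(trials[neg], trace["sigma2_post"].to_numpy()[neg], "ro", ms=2)
    ax_bot.set_xlabel("trial")
    ax_bot.set_ylabel("regulated variance")
    for b in _stage_boundaries(trace["stage"].to_numpy()):
        for a in (ax_top, ax_bot):
            a.axvline(b + 0.5, ls="--", c="gray", lw=0.8)
    fig.tight_layout()
    return fig


def plot_dp_trace(trace: pd.DataFrame):
    """Predicted probability, tendency variance and log-volatility."""
    from .static_model import sigmoid

    fig, axes = plt.subplots(3, 1, figsize=(9, 7), sharex=True)
    trials = trace["trial"].to_numpy()
    axes[0].plot(trials, sigmoid(trace["mu2"].to_numpy()), "r-", lw=1)
    axes[0].plot(trials, trace["u"], "g.", ms=3, alpha=0.5)
    axes[0].set_ylabel("P(u=1)")
    axes[1].plot(trials, trace["sigma2"], "k-", lw=1)
    axes[1].set_ylabel("sigma2")
    axes[2].plot(trials, trace["mu3"], "b-", lw=1)
    axes[2].set_ylabel("mu3 (log-volatility)")
    axes[2].set_xlabel("trial")
    for b in _stage_boundaries(trace["stage"].to_numpy()):
        for a in axes:
            a.axvline(b + 0.5, ls="--", c="gray", lw=0.8)
    fig.tight_layout()
    return fig


def plot_class_boxplots(per_realization: pd.DataFrame):
    """Boxplots of per-realization mean regulated variance by emotion
    class, one panel per volatility stage group."""
    fig, axes = plt.subplots(1, 2, figsize=(8, 4), sharey=True)
    for ax, group in zip(axes, ("low", "high")):
        sub = per_realization[per_realization["stage_group"] == group]
        data = [
            sub.loc[sub["emotion_class"] == c, "mean"].dropna()
            for c in ("factive", "epistemic")
        ]
        ax.boxplot(data, tick_labels=["factive", "epistemic"])
        ax.set_title(f"{group} volatility")
    axes[0].set_ylabel("mean regulated variance")
    fig.tight_layout()
    return fig
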