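"""Batch simulation and the uncertainty-by-emotion-class analysis.

The headline experiment runs many seeded realizations of the reference
scenario through the valence-regulated static agent and summarizes the
regulated posterior variance (the carried estimation uncertainty,
``sigma2_post``) on trials where factive (happiness/unhappiness) versus
epistemic (hope/fear) emotions were elicited, grouped into the low
(stages 1 and 3) and high (stage 2) volatility stages.  Means are taken
per realization first and then across realizations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .emotions import EPISTEMIC, FACTIVE
from .scenario import (
    STAGE_HIGH,
    Schedule,
    build_reference_schedule,
    sample_outcomes,
)
from .static_model import SPVParams, run_spv_agent
from .volatility import HGFParams, run_dp_agent

__all__ = [
    "ExperimentConfig",
    "ExperimentSummary",
    "run_realizations",
    "class_uncertainty_statistics",
    "emotion_class_statistics",
    "stage_trace_summary",
    "stage_group",
]

#: reference parameterization of the uncertainty-by-class experiment
DEFAULT_ALPHA = 0.4
DEFAULT_TAU = -0.13
DEFAULT_N_REALIZATIONS = 100


def stage_group(stages) -> np.ndarray:
    """Map stage labels to volatility groups: 'high' stays, rest 'low'."""
    stages = np.asarray(stages, dtype=object)
    return np.where(stages == STAGE_HIGH, "high", "low").astype(object)


def _emotion_class(labels) -> np.ndarray:
    labels = np.asarray(labels, dtype=object)
    out = np.full(labels.size, "other", dtype=object)
    out[np.isin(labels, list(FACTIVE))] = "factive"
    out[np.isin(labels, list(EPISTEMIC))] = "epistemic"
    return out


@dataclass(frozen=True)
class ExperimentConfig:
    """A batch of seeded agent runs on one schedule.

    Realization r (0-based) samples outcomes with seed ``base_seed + r``.
    """

    agent: str = "spv"
    params: SPVParams | HGFParams = field(
        default_factory=lambda: SPVParams(alpha=DEFAULT_ALPHA, tau=DEFAULT_TAU)
    )
    n_realizations: int = DEFAULT_N_REALIZATIONS
    base_seed: int = 0
    schedule: Schedule = field(default_factory=build_reference_schedule)

    def __post_init__(self) -> None:
        if self.agent not in ("spv", "dp"):
            raise ValueError("agent must be 'spv' or 'dp'")
        if self.n_realizations < 1:
            raise ValueError("n_realizations must be >= 1")


@dataclass
class ExperimentSummary:
    """Per-realization and across-realization cell means.

    ``per_realization`` has one row per (realization, emotion_class,
    stage_group) cell with that realization's mean regulated variance
    and contributing-trial count; empty cells appear with n_trials = 0
    and NaN mean and are excluded from ``across`` (their count is kept
    in ``missing_cells``).  ``marginals`` are the low/high volatility
    margins taken over the stacked per-realization class means (each
    realization contributes one factive and one epistemic value per
    stage group), so each emotion class carries equal weight.
    """

    per_realization: pd.DataFrame
    across: pd.DataFrame
    missing_cells: pd.DataFrame
    marginals: pd.DataFrame | None = None
    base_seed: int | None = None

    def cell_mean(self, emotion_class: str, group: str) -> float:
        sel = self.across[
            (self.across["emotion_class"] == emotion_class)
            & (self.across["stage_group"] == group)
        ]
        if sel.empty:
            raise KeyError((emotion_class, group))
        return float(sel["mean"].iloc[0])


def run_realizations(config: ExperimentConfig) -> list[pd.DataFrame]:
    """Independent seeded outcome samples, each run through the agent."""
    traces = []
    for r in range(config.n_realizations):
        outcomes = sample_outcomes(config.schedule, config.base_seed + r)
        if config.agent == "spv":
            traces.append(run_spv_agent(outcomes, config.params))
        else:
            traces.append(run_dp_agent(outcomes, config.params))
    return traces


def _per_realization_cells(traces, pooled: bool) -> pd.DataFrame:
    rows = []
    classes = ("pooled",) if pooled else ("factive", "epistemic")
    for r, trace in enumerate(traces):
        cls = _emotion_class(trace["emotion"].to_numpy())
        grp = stage_group(trace["stage"].to_numpy())
        s2 = trace["sigma2_post"].to_numpy()
        for c in classes:
            in_class = (cls != "other") if pooled else (cls == c)
            for g in ("low", "high"):
                mask = in_class & (grp == g)
                n = int(mask.sum())
                rows.append(
                    {
                        "realization": r,
                        "emotion_class": c,
                        "stage_group": g,
                        "mean": float(s2[mask].mean()) if n else np.nan,
                        "n_trials": n,
                    }
                )
    return pd.DataFrame(rows)


def _across(per: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    filled = per[per["n_trials"] > 0]
    across = (
        filled.groupby(["emotion_class", "stage_group"], sort=False)
        .agg(
            mean=("mean", "mean"),
            sd=("mean", lambda x: float(np.std(x, ddof=1)) if len(x) > 1 else np.nan),
            n_realizations=("realization", "size"),
            n_trials=("n_trials", "sum"),
        )
        .reset_index()
    )
    missing = (
        per[per["n_trials"] == 0]
        .groupby(["emotion_class", "stage_group"], sort=False)
        .size()
        .rename("n_missing")
        .reset_index()
    )
    return across, missing


def _marginals(per: pd.DataFrame) -> pd.DataFrame:
    filled = per[per["n_trials"] > 0]
    return (
        filled.groupby("stage_group", sort=False)
        .agg(
            mean=("mean", "mean"),
            sd=("mean", lambda x: float(np.std(x, ddof=1)) if len(x) > 1 else np.nan),
            n_cells=("mean", "size"),
        )
        .reset_index()
    )


def emotion_class_statistics(
    traces, base_seed: int | None = None, pooled: bool = False
) -> ExperimentSummary:
    """Mean regulated variance by emotion class and volatility stage group.

    Factive pools happiness and unhappiness trials; epistemic pools hope
    and fear; relief/disappointment crossing trials and neutral or
    undefined trials contribute to neither class.  Across-realization
    statistics are means of per-realization means, never pooled-trial
    means.  With ``pooled=False`` (the default) the ``marginals`` table
    additionally gives the low/high margins over the stacked class
    means; ``pooled=True`` instead pools all four emotions at the trial
    level into a single class.
    """
    per = _per_realization_cells(traces, pooled)
    across, missing = _across(per)
    marginals = None if pooled else _marginals(per)
    return ExperimentSummary(per, across, missing, marginals, base_seed=base_seed)


def class_uncertainty_statistics(traces, base_seed: int | None = None) -> ExperimentSummary:
    """Factive/epistemic x low/high summary of regulated variance."""
    return emotion_class_statistics(traces, base_seed=base_seed, pooled=False)


def stage_trace_summary(trace: pd.DataFrame) -> pd.DataFrame:
    """Per-stage aggregates of one trace.

    One row per stage label, in order of first appearance, with the mean
    regulated variance, the mean |V| over defined-valence trials, and a
    count column per emotion label observed.
    """
    if len(trace) == 0:
        raise ValueError("empty trace")
    var_col = "sigma2_post" if "sigma2_post" in trace.columns else "sigma2"
    rows = []
    for stage in pd.unique(trace["stage"]):
        sub = trace[trace["stage"] == stage]
        row = {
            "stage": stage,
            "n_trials": len(sub),
            "mean_sigma2_post": float(sub[var_col].mean()),
        }
        if "V" in sub.columns:
            row["mean_abs_V"] = float(np.nanmean(np.abs(sub["V"].to_numpy())))
        if "emotion" in sub.columns:
            for name, count in sub["emotion"].value_counts().items():
                row[f"n_{name}"] = int(count)
        rows.append(row)
    return pd.DataFrame(rows).fillna(0)
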