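"""Dynamic perceptual model: three-level hierarchical volatility learner.

Comparison agent for the valence-regulated static model.  The reward
tendency x2 performs a Gaussian random walk whose log step size is
kappa*x3 + omega, and the log-volatility x3 performs a random walk with
step variance theta.  The trial-wise variational inversion is the
standard one for this binary hierarchical filter:

    mu1_hat = s(mu2);  sigma1_hat = mu1_hat*(1-mu1_hat);  delta1 = u - mu1_hat
    v       = exp(kappa*mu3 + omega)                (predicted walk step)
    sigma2' = 1/(1/(sigma2 + v) + sigma1_hat)
    mu2'    = mu2 + sigma2' * delta1
    w2      = v / (v + sigma2)                      (volatility weight)
    delta2  = (sigma2' + (mu2' - mu2)^2) / (sigma2 + v) - 1
    pi3'    = 1/(sigma3 + theta) + (kappa^2/2) * w2 * (w2 + (2*w2 - 1)*delta2)
    mu3'    = mu3 + (kappa/2) * w2 * delta2 / pi3'

The level-3 precision update can turn non-positive for extreme
surprises; that pathology is reported as an error with the trial index.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .scenario import OutcomeSequence
from .static_model import predict, sigmoid

__all__ = [
    "HGFParams",
    "HGFState",
    "HGFUpdateError",
    "VolatilityModel",
    "VolatilityResults",
    "hgf_trial_update",
    "run_dp_agent",
]

_LOG_EPS = np.finfo(float).eps


class HGFUpdateError(RuntimeError):
    """Raised when an update drives a posterior variance non-positive."""

    def __init__(self, trial: int, message: str) -> None:
        super().__init__(f"trial {trial}: {message}")
        self.trial = trial


@dataclass(frozen=True)
class HGFParams:
    """kappa/omega couple the volatility level to the tendency walk;
    theta is the volatility walk's own step variance.  Defaults are the
    reference-scenario values."""

    kappa: float = 1.4
    omega: float = -4.0
    theta: float = 0.5
    mu2_0: float = 0.0
    sigma2_0: float = 1.0
    mu3_0: float = 1.0
    sigma3_0: float = 1.0

    def __post_init__(self) -> None:
        if self.sigma2_0 <= 0 or self.sigma3_0 <= 0:
            raise ValueError("initial variances must be positive")
        if self.theta <= 0:
            raise ValueError("theta must be positive")


@dataclass(frozen=True)
class HGFState:
    k: int
    mu2: float
    sigma2: float
    mu3: float
    sigma3: float

    def __post_init__(self) -> None:
        if self.sigma2 <= 0 or self.sigma3 <= 0:
            raise ValueError("variances must be positive")


def hgf_trial_update(state: HGFState, u: int, params: HGFParams) -> HGFState:
    """One trial of the hierarchical filter given binary input u."""
    if u not in (0, 1):
        raise ValueError("u must be 0 or 1")
    mu1_hat, sigma1_hat = predict(state.mu2)
    delta1 = u - mu1_hat

    v = np.exp(params.kappa * state.mu3 + params.omega)
    sigma2_hat = state.sigma2 + v
    sigma2_new = 1.0 / (1.0 / sigma2_hat + sigma1_hat)
    mu2_new = state.mu2 + sigma2_new * delta1

    w2 = v / sigma2_hat
    delta2 = (sigma2_new + (mu2_new - state.mu2) ** 2) / sigma2_hat - 1.0
    pi3_hat = 1.0 / (state.sigma3 + params.theta)
    pi3 = pi3_hat + 0.5 * params.kappa**2 * w2 * (w2 + (2.0 * w2 - 1.0) * delta2)
    if pi3 <= 0.0:
        raise HGFUpdateError(state.k + 1, "level-3 precision became non-positive")
    sigma3_new = 1.0 / pi3
    mu3_new = state.mu3 + 0.5 * params.kappa * sigma3_new * w2 * delta2
    return HGFState(state.k + 1, mu2_new, sigma2_new, mu3_new, sigma3_new)


def run_dp_agent(outcomes: OutcomeSequence, params: HGFParams) -> pd.DataFrame:
    """Run the volatility learner over an outcome sequence."""
    n = outcomes.n_trials
    cols = {
        name: np.full(n, np.nan)
        for name in ("mu1_hat", "delta1", "mu2", "sigma2", "mu3", "sigma3", "surprise")
    }
    state = HGFState(0, params.mu2_0, params.sigma2_0, params.mu3_0, params.sigma3_0)
    for k in range(n):
        uk = int(outcomes.u[k])
        mu1_hat = sigmoid(state.mu2)
        state = hgf_trial_update(state, uk, params)
        p_obs = mu1_hat if uk == 1 else 1.0 - mu1_hat
        cols["mu1_hat"][k] = mu1_hat
        cols["delta1"][k] = uk - mu1_hat
        cols["mu2"][k] = state.mu2
        cols["sigma2"][k] = state.sigma2
        cols["mu3"][k] = state.mu3
        cols["sigma3"][k] = state.sigma3
        cols["surprise"][k] = -np.log(max(p_obs, _LOG_EPS))
    return pd.DataFrame(
        {
            "trial": np.arange(1, n + 1),
            "stage": outcomes.stages,
            "u": outcomes.u,
            **cols,
        }
    )


class VolatilityModel:
    """Hierarchical volatility learner, statsmodels-style wrapper."""

    def __init__(self, outcomes, **params) -> None:
        if not isinstance(outcomes, OutcomeSequence):
            u = np.asarray(outcomes, dtype=int)
            outcomes = OutcomeSequence(u=u, stages=np.full(u.size, "all", dtype=object))
        self.outcomes = outcomes
        self.params = HGFParams(**params)

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, u_col: str = "u",
                       stage_col: str = "stage", **params) -> "VolatilityModel":
        u = frame[u_col].to_numpy(dtype=int)
        if stage_col in frame.columns:
            stages = frame[stage_col].to_numpy(dtype=object)
        else:
            stages = np.full(u.size, "all", dtype=object)
        return cls(OutcomeSequence(u=u, stages=stages), **params)

    def fit(self) -> "VolatilityResults":
        return VolatilityResults(self, run_dp_agent(self.outcomes, self.params))


class VolatilityResults:
    def __init__(self, model: VolatilityModel, trace: pd.DataFrame) -> None:
        self.model = model
        self.trace = trace
        self.params = model.params

    @property
    def final_prediction(self) -> float:
        return float(sigmoid(self.trace["mu2"].iloc[-1]))

    def summary(self) -> str:
        p = self.params
        t = self.trace
        return "\n".join(
            [
                "Dynamic perceptual model (hierarchical volatility)",
                "=" * 50,
                f"trials                 {len(t):>10d}",
                f"kappa, omega, theta    {p.kappa:.2f}, {p.omega:.2f}, {p.theta:.2f}",
                f"final sigmoid(mu2)     {self.final_prediction:>10.4f}",
                f"final sigma2           {t['sigma2'].iloc[-1]:>10.4f}",
                f"final mu3              {t['mu3'].iloc[-1]:>10.4f}",
            ]
        )

    def to_csv(self, path) -> None:
        self.trace.to_csv(path, index=False)
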