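"""Static perceptual model of a binary environment, with emotional valence.

The agent observes binary inputs u(k) from a one-armed bandit and holds a
Gaussian posterior N(mu2, sigma2) over the logit-scale reward tendency
x2, with sigmoid(x2) the probability of u = 1.  The generative model is
static: the prior over x2 at trial k is the carried posterior from trial
k-1.  Variational inversion (with the Bernoulli log-likelihood expanded
to second order around the prior mean) gives the closed-form trial
update

    mu1_hat(k)  = sigmoid(mu2(k-1))
    sigma1_hat(k) = mu1_hat(k) * (1 - mu1_hat(k))
    delta1(k)   = u(k) - mu1_hat(k)
    1/sigma2(k) = 1/sigma2(k-1) + sigma1_hat(k)
    mu2(k)      = mu2(k-1) + sigma2(k) * delta1(k)

After each update the level-2 free energy F(k) is evaluated exactly
(Gauss-Hermite quadrature of the expected log-likelihood plus the
Gaussian KL complexity term), valence V(k) = -(F(k) - F(k-1)) is formed,
an emotion is classified, and the posterior variance is regulated by
exp(-(alpha*V + tau)) before being carried to the next trial.  With
alpha = tau = 0 the scheme is the standard static perceptual model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .emotions import (
    RegulationParams,
    classify_emotion,
    regulate_uncertainty,
)
from .scenario import OutcomeSequence

__all__ = [
    "SPVParams",
    "StaticValenceModel",
    "StaticValenceResults",
    "sigmoid",
    "predict",
    "update_posterior",
    "level2_free_energy",
    "quadratic_trial_objective",
    "run_spv_agent",
    "TRACE_COLUMNS",
]

TRACE_COLUMNS = [
    "trial",
    "stage",
    "u",
    "mu1_hat",
    "sigma1_hat",
    "delta1",
    "mu2",
    "sigma2_pre",
    "sigma2_post",
    "F",
    "V",
    "emotion",
    "surprise",
]

# 64-node Gauss-Hermite rule; exact enough that halving the node count
# changes F by < 1e-12 on the states visited here.
_GH_NODES, _GH_WEIGHTS = np.polynomial.hermite.hermgauss(64)
_GH_WEIGHTS = _GH_WEIGHTS / np.sqrt(np.pi)

_LOG_EPS = np.finfo(float).eps


@dataclass(frozen=True)
class SPVParams:
    """Agent parameters: sensitiveness alpha, mood tau, initial posterior.

    ``eps`` is the neutral dead-band of the emotion classifier and
    ``crossing_band`` the |V| ceiling under which a valence sign change
    is labelled relief/disappointment; at trial resolution the default
    band of 0 places every macroscopic crossing in the hope/fear
    quadrants (see :mod:`fevalence.emotions`).
    """

    alpha: float = 0.0
    tau: float = 0.0
    mu2_0: float = 0.0
    sigma2_0: float = 1.0
    eps: float = 0.0
    crossing_band: float = 0.0

    def __post_init__(self) -> None:
        if self.sigma2_0 <= 0.0:
            raise ValueError("sigma2_0 must be positive")
        RegulationParams(self.alpha, self.tau)  # validates alpha, tau

    @property
    def regulation(self) -> RegulationParams:
        return RegulationParams(self.alpha, self.tau)


def sigmoid(x):
    """Logistic function 1 / (1 + exp(-x))."""
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out if out.ndim else float(out)


def _softplus(x):
    # log(1 + exp(x)), overflow-safe
    x = np.asarray(x, dtype=float)
    return np.logaddexp(0.0, x)


def predict(mu2: float, sigma2: float | None = None) -> tuple[float, float]:
    """Pre-input prediction: expected probability and its variance.

    mu1_hat = sigmoid(mu2) and sigma1_hat = mu1_hat*(1 - mu1_hat), the
    Bernoulli variance of the predicted input before it is seen.  The
    probability is clipped a machine-epsilon margin away from exact 0/1
    so downstream logs and precisions stay finite.
    """
    mu1_hat = np.clip(sigmoid(mu2), _LOG_EPS, 1.0 - _LOG_EPS)
    return mu1_hat, mu1_hat * (1.0 - mu1_hat)


def update_posterior(
    mu2: float, sigma2: float, u: int
) -> tuple[float, float, float]:
    """One variational Bayesian update of the tendency posterior.

    Returns (mu2_new, sigma2_new, delta1).  Precision accumulates
    (1/sigma2_new = 1/sigma2 + sigma1_hat), so with no regulation the
    posterior variance is strictly decreasing.
    """
    if u not in (0, 1):
        raise ValueError("u must be 0 or 1")
    if sigma2 <= 0.0:
        raise ValueError("sigma2 must be positive")
    mu1_hat, sigma1_hat = predict(mu2)
    delta1 = u - mu1_hat
    sigma2_new = 1.0 / (1.0 / sigma2 + sigma1_hat)
    mu2_new = mu2 + sigma2_new * delta1
    return mu2_new, sigma2_new, delta1


def _expected_loglik(mu2: float, sigma2: float, u: int) -> float:
    # E_{N(mu2, sigma2)}[log p(u | x2)]; log s(x) = -softplus(-x)
    x = mu2 + np.sqrt(2.0 * sigma2) * _GH_NODES
    sign = -1.0 if u == 1 else 1.0
    return -float(np.dot(_GH_WEIGHTS, _softplus(sign * x)))


def _gauss_kl(mu_q: float, var_q: float, mu_p: float, var_p: float) -> float:
    return 0.5 * (
        np.log(var_p / var_q) + (var_q + (mu_q - mu_p) ** 2) / var_p - 1.0
    )


def level2_free_energy(
    mu2: float,
    sigma2: float,
    u: int,
    prior_mu2: float,
    prior_sigma2: float,
) -> float:
    """Variational free energy of the tendency level given input u.

    F = KL(N(mu2, sigma2) || N(prior_mu2, prior_sigma2))
        - E_{N(mu2, sigma2)}[log p(u | x2)],

    with the expectation under the Gaussian recognition density taken by
    Gauss-Hermite quadrature (the first-level recognition density is a
    point mass at the unambiguous input, so it contributes no entropy).
    """
    if sigma2 <= 0.0 or prior_sigma2 <= 0.0:
        raise ValueError("variances must be positive")
    if u not in (0, 1):
        raise ValueError("u must be 0 or 1")
    return _gauss_kl(mu2, sigma2, prior_mu2, prior_sigma2) - _expected_loglik(
        mu2, sigma2, u
    )


def quadratic_trial_objective(
    mu2: float,
    sigma2: float,
    u: int,
    prior_mu2: float,
    prior_sigma2: float,
) -> float:
    """Trial objective with the log-likelihood expanded around the prior mean.

    This is the variational energy whose exact minimizer over
    (mu2, sigma2) is the closed-form update of :func:`update_posterior`;
    it differs from :func:`level2_free_energy` by the second-order
    (Laplace-style) treatment of E[log p(u | x2)].
    """
    if sigma2 <= 0.0 or prior_sigma2 <= 0.0:
        raise ValueError("variances must be positive")
    mu1_hat, sigma1_hat = predict(prior_mu2)
    loglik0 = np.log(max(mu1_hat if u == 1 else 1.0 - mu1_hat, _LOG_EPS))
    d = mu2 - prior_mu2
    exp_loglik = loglik0 + (u - mu1_hat) * d - 0.5 * sigma1_hat * (d * d + sigma2)
    return _gauss_kl(mu2, sigma2, prior_mu2, prior_sigma2) - exp_loglik


def _run_core(u: np.ndarray, params: SPVParams, eps: float) -> dict[str, np.ndarray]:
    n = u.size
    out = {
        name: np.full(n, np.nan)
        for name in (
            "mu1_hat",
            "sigma1_hat",
            "delta1",
            "mu2",
            "sigma2_pre",
            "sigma2_post",
            "F",
            "V",
            "surprise",
        )
    }
    emotion = np.full(n, "undefined", dtype=object)
    reg = params.regulation

    mu2, lam = params.mu2_0, params.sigma2_0
    F_prev = np.nan
    V_prev = np.nan
    for k in range(n):
        mu1_hat, sigma1_hat = predict(mu2)
        uk = int(u[k])
        mu2_new, sigma2_pre, delta1 = update_posterior(mu2, lam, uk)
        F = level2_free_energy(mu2_new, sigma2_pre, uk, mu2, lam)
        V = -(F - F_prev) if k > 0 else np.nan
        if k >= 2:
            emotion[k] = classify_emotion(V, V_prev, eps, params.crossing_band).label
        sigma2_post = float(regulate_uncertainty(sigma2_pre, V, reg))
        p_obs = mu1_hat if uk == 1 else 1.0 - mu1_hat
        out["mu1_hat"][k] = mu1_hat
        out["sigma1_hat"][k] = sigma1_hat
        out["delta1"][k] = delta1
        out["mu2"][k] = mu2_new
        out["sigma2_pre"][k] = sigma2_pre
        out["sigma2_post"][k] = sigma2_post
        out["F"][k] = F
        out["V"][k] = V
        out["surprise"][k] = -np.log(max(p_obs, _LOG_EPS))
        mu2, lam = mu2_new, sigma2_post
        F_prev, V_prev = F, V
    out["emotion"] = emotion
    return out


def run_spv_agent(outcomes: OutcomeSequence, params: SPVParams) -> pd.DataFrame:
    """Run the agent over an outcome sequence; one trace row per trial."""
    core = _run_core(outcomes.u, params, params.eps)
    trace = pd.DataFrame(
        {
            "trial": np.arange(1, outcomes.n_trials + 1),
            "stage": outcomes.stages,
            "u": outcomes.u,
            **{c: core[c] for c in TRACE_COLUMNS[3:]},
        }
    )
    return trace[TRACE_COLUMNS]


class StaticValenceModel:
    """Static perceptual model with valence, statsmodels-style.

    Parameters
    ----------
    outcomes
        An :class:`~fevalence.scenario.OutcomeSequence` or a 1-d binary
        array (stages then default to a single unnamed stage).
    alpha, tau
        Sensitiveness to valence (in [0, 1]) and mood.
    mu2_0, sigma2_0
        Initial posterior mean and variance of the reward tendency.
    eps
        Dead-band around zero valence for emotion classification.
    """

    def __init__(
        self,
        outcomes,
        alpha: float = 0.0,
        tau: float = 0.0,
        mu2_0: float = 0.0,
        sigma2_0: float = 1.0,
        eps: float = 0.0,
        crossing_band: float = 0.0,
    ) -> None:
        if not isinstance(outcomes, OutcomeSequence):
            u = np.asarray(outcomes, dtype=int)
            outcomes = OutcomeSequence(
                u=u, stages=np.full(u.size, "all", dtype=object)
            )
        self.outcomes = outcomes
        self.params = SPVParams(alpha, tau, mu2_0, sigma2_0, eps, crossing_band)

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, u_col: str = "u",
                       stage_col: str = "stage", **params) -> "StaticValenceModel":
        """Build from a table with an outcome column and optional stages."""
        u = frame[u_col].to_numpy(dtype=int)
        if stage_col in frame.columns:
            stages = frame[stage_col].to_numpy(dtype=object)
        else:
            stages = np.full(u.size, "all", dtype=object)
        return cls(OutcomeSequence(u=u, stages=stages), **params)

    def fit(self) -> "StaticValenceResults":
        """Run the trial-by-trial variational inversion."""
        trace = run_spv_agent(self.outcomes, self.params)
        return StaticValenceResults(self, trace)


class StaticValenceResults:
    """Trace and summaries of a fitted :class:`StaticValenceModel`."""

    def __init__(self, model: StaticValenceModel, trace: pd.DataFrame) -> None:
        self.model = model
        self.trace = trace
        self.params = model.params

    @property
    def final_prediction(self) -> float:
        """sigmoid(mu2) after the last trial."""
        return float(sigmoid(self.trace["mu2"].iloc[-1]))

    @property
    def total_valence(self) -> float:
        """Sum of defined valence = net free-energy decrease F(1)-F(n)."""
        return float(np.nansum(self.trace["V"].to_numpy()))

    def stage_summary(self) -> pd.DataFrame:
        from .experiments import stage_trace_summary

        return stage_trace_summary(self.trace)

    def emotion_counts(self) -> pd.Series:
        return self.trace["emotion"].value_counts()

    def summary(self) -> str:
        p = self.params
        n = len(self.trace)
        lines = [
            "Static perceptual model with valence",
            "=" * 44,
            f"trials                 {n:>10d}",
            f"sensitiveness alpha    {p.alpha:>10.3f}",
            f"mood tau               {p.tau:>10.3f}",
            f"initial mu2, sigma2    {p.mu2_0:>6.2f}, {p.sigma2_0:.2f}",
            f"final sigmoid(mu2)     {self.final_prediction:>10.4f}",
            f"final sigma2 (reg.)    {self.trace['sigma2_post'].iloc[-1]:>10.4f}",
            f"total valence          {self.total_valence:>10.4f}",
            "-" * 44,
            "emotion counts:",
        ]
        for name, count in self.emotion_counts().items():
            lines.append(f"  {name:<16s} {count:>6d}")
        return "\n".join(lines)

    def plot_trace(self, ax=None):
        from .plotting import plot_spv_trace

        return plot_spv_trace(self.trace, ax=ax)

    def to_csv(self, path) -> None:
        self.trace.to_csv(path, index=False)
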