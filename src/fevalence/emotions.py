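"""Valence, basic emotions and the emotional regulation of uncertainty.

Valence is defined as the negative first backward difference of the
variational free energy of a hierarchy level: V(k) = -(F(k) - F(k-1)).
Basic emotions are read off the signs of the first and second discrete
time-derivatives of F:

==============  =======  ================  =====  =====
emotion         valence  factive/epistemic  F'     F''
==============  =======  ================  =====  =====
happiness       +        factive            < 0    > 0
unhappiness     -        factive            > 0    < 0
hope            +        epistemic          < 0    < 0
fear            -        epistemic          > 0    > 0
neutral         0        neutral            = 0    = 0
relief          +        factive            sign change + -> -
disappointment  -        factive            sign change - -> +
==============  =======  ================  =====  =====

Relief and disappointment are the transition states of the scheme: F'
changes sign and is still very close to zero just after the crossing.
On a densely sampled smooth free-energy series the step that crosses
zero always satisfies this, so there a sign change of V takes
precedence over the quadrants: transitions from negative to positive
emotions pass through relief and the reverse through disappointment.
On a trial-resolution series driven by binary inputs, however, valence
flips sign with macroscopic magnitude at every surprise, and such a
crossing lies well inside the fear/hope quadrants rather than near
F' = 0.  The ``crossing_band`` argument draws the line: a sign change
is labelled relief/disappointment only if |V(k)| <= crossing_band.
The standalone classifier defaults to an infinite band (every crossing
is a transition state); the trial-by-trial agent uses a band of zero.

Positive valence shrinks, and negative valence inflates, the posterior
variance of the level's state: the regulated variance is the Bayesian
posterior variance times exp(-(alpha*V + tau)), equivalently a shift of
the Gaussian posterior entropy by (alpha*V + tau)/2.  alpha is the
agent's sensitiveness to its valence signal; tau is its mood, a
persistent referent-free valence offset.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "EMOTIONS",
    "FACTIVE",
    "EPISTEMIC",
    "REGULATION_EXPONENT",
    "EmotionLabel",
    "RegulationParams",
    "ValenceSignal",
    "annotate_free_energy_frame",
    "classify_emotion",
    "classify_emotion_series",
    "gaussian_entropy",
    "regulation_factor",
    "regulate_uncertainty",
    "valence_from_free_energy",
]

# Entropy-shift constant of the regulation rule: the regulated posterior's
# Gaussian entropy is the unregulated entropy minus REGULATION_EXPONENT/2
# times (alpha*V + tau), i.e. variance factor exp(-REGULATION_EXPONENT*(aV+t)).
REGULATION_EXPONENT = 1.0

HAPPINESS = "happiness"
UNHAPPINESS = "unhappiness"
HOPE = "hope"
FEAR = "fear"
RELIEF = "relief"
DISAPPOINTMENT = "disappointment"
NEUTRAL = "neutral_surprise"
UNDEFINED = "undefined"

EMOTIONS = (HAPPINESS, UNHAPPINESS, HOPE, FEAR, RELIEF, DISAPPOINTMENT, NEUTRAL)

#: emotion classes used by the uncertainty analysis; relief and
#: disappointment are crossing states and belong to neither group there.
FACTIVE = frozenset({HAPPINESS, UNHAPPINESS})
EPISTEMIC = frozenset({HOPE, FEAR})

_SIGNS = {
    HAPPINESS: "positive",
    HOPE: "positive",
    RELIEF: "positive",
    UNHAPPINESS: "negative",
    FEAR: "negative",
    DISAPPOINTMENT: "negative",
    NEUTRAL: "neutral",
    UNDEFINED: "neutral",
}
_CLASSES = {
    HAPPINESS: "factive",
    UNHAPPINESS: "factive",
    RELIEF: "factive",
    DISAPPOINTMENT: "factive",
    HOPE: "epistemic",
    FEAR: "epistemic",
    NEUTRAL: "neutral",
    UNDEFINED: "neutral",
}


@dataclass(frozen=True)
class EmotionLabel:
    label: str
    valence_sign: str
    emotion_class: str


@dataclass(frozen=True)
class RegulationParams:
    """Sensitiveness alpha (in [0, 1]) and mood tau (real)."""

    alpha: float = 0.0
    tau: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")
        if not np.isfinite(self.tau):
            raise ValueError("tau must be finite")


@dataclass(frozen=True)
class ValenceSignal:
    """Valence V(k) = -(F(k)-F(k-1)) and its backward difference dV."""

    V: np.ndarray
    dV: np.ndarray
    level: int = 2


def _label(name: str) -> EmotionLabel:
    return EmotionLabel(name, _SIGNS[name], _CLASSES[name])


def valence_from_free_energy(F_series, level: int = 2) -> ValenceSignal:
    """Negative first backward difference of a free-energy series.

    V and dV are NaN where undefined (V at the first element, dV at the
    first two).  The series must have length >= 2 and be finite.
    """
    F = np.asarray(F_series, dtype=float)
    if F.ndim != 1 or F.size < 2:
        raise ValueError("free-energy series must be 1-d with length >= 2")
    if not np.all(np.isfinite(F)):
        raise ValueError("free-energy series must be finite")
    V = np.full(F.size, np.nan)
    V[1:] = -np.diff(F)
    dV = np.full(F.size, np.nan)
    dV[2:] = np.diff(V[1:])
    return ValenceSignal(V=V, dV=dV, level=level)


def classify_emotion(
    V_k: float,
    V_km1: float,
    eps: float = 0.0,
    crossing_band: float = np.inf,
) -> EmotionLabel:
    """Label one time point from consecutive valence values.

    The discrete derivatives are F' = -V(k) and F'' = V(k-1) - V(k).
    A sign change of valence with |V(k)| <= crossing_band is a
    transition state (relief for - -> +, disappointment for + -> -);
    values within +/-eps of zero on both derivatives are neutral; a
    nonzero F' with F'' in [-eps, eps] (steady change) maps to the
    factive label of the same valence sign.
    """
    if eps < 0.0:
        raise ValueError("eps must be nonnegative")
    if crossing_band < 0.0:
        raise ValueError("crossing_band must be nonnegative")
    if V_k is None or V_km1 is None or not (np.isfinite(V_k) and np.isfinite(V_km1)):
        return _label(UNDEFINED)
    if V_km1 < -eps and V_k > eps and V_k <= crossing_band:
        return _label(RELIEF)
    if V_km1 > eps and V_k < -eps and -V_k <= crossing_band:
        return _label(DISAPPOINTMENT)
    d2 = V_km1 - V_k  # F''
    if abs(V_k) <= eps:
        return _label(NEUTRAL)
    if V_k > eps:  # F' < 0
        return _label(HOPE) if d2 < -eps else _label(HAPPINESS)
    return _label(FEAR) if d2 > eps else _label(UNHAPPINESS)


def classify_emotion_series(
    V: np.ndarray, eps: float = 0.0, crossing_band: float = np.inf
) -> np.ndarray:
    """Per-element labels for a valence series (NaN where undefined)."""
    V = np.asarray(V, dtype=float)
    out = np.full(V.size, UNDEFINED, dtype=object)
    for k in range(1, V.size):
        if np.isfinite(V[k]) and np.isfinite(V[k - 1]):
            out[k] = classify_emotion(V[k], V[k - 1], eps, crossing_band).label
    return out


def gaussian_entropy(sigma2: float) -> float:
    """Differential entropy of N(mu, sigma2): 0.5*log(2*pi*e*sigma2)."""
    sigma2 = np.asarray(sigma2, dtype=float)
    if np.any(sigma2 <= 0.0):
        raise ValueError("variance must be positive")
    return 0.5 * np.log(2.0 * np.pi * np.e * sigma2)


def regulation_factor(V: float, params: RegulationParams) -> float:
    """Multiplicative variance factor exp(-(alpha*V + tau))."""
    return np.exp(-REGULATION_EXPONENT * (params.alpha * V + params.tau))


def regulate_uncertainty(sigma2, V, params: RegulationParams):
    """Scale a posterior variance by the valence/mood factor.

    Strictly positive output; strictly decreasing in V for alpha > 0 and
    in tau.  V undefined (NaN) is treated as 0 so the mood acts alone.
    """
    sigma2 = np.asarray(sigma2, dtype=float)
    if np.any(sigma2 <= 0.0):
        raise ValueError("variance must be positive")
    V = np.nan_to_num(np.asarray(V, dtype=float), nan=0.0)
    return sigma2 * regulation_factor(V, params)


def annotate_free_energy_frame(
    frame: pd.DataFrame, eps: float = 0.0, crossing_band: float = np.inf
) -> pd.DataFrame:
    """Append V, dV and emotion columns to a table of free-energy series.

    Expects a ``time`` column plus one or more free-energy columns named
    ``F`` or ``F_<level>``; each gets ``V[_<level>]``, ``dV[_<level>]``
    and ``emotion[_<level>]`` columns.
    """
    fcols = [c for c in frame.columns if c == "F" or c.startswith("F_")]
    if "time" not in frame.columns or not fcols:
        raise ValueError("expected a 'time' column and at least one F column")
    out = frame.copy()
    for col in fcols:
        suffix = col[1:]  # '' or '_<level>'
        sig = valence_from_free_energy(out[col].to_numpy())
        out["V" + suffix] = sig.V
        out["dV" + suffix] = sig.dV
        out["emotion" + suffix] = classify_emotion_series(sig.V, eps, crossing_band)
    return out
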