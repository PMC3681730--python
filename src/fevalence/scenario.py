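"""Ground-truth outcome schedules and sampled binary input sequences.

The environment is a one-armed bandit that pays $1 with a per-trial
probability that is piecewise constant in time.  The reference scenario
used throughout the package has three stages: 100 trials at p = 0.5 (low
volatility), 120 trials alternating between p = 0.9 and p = 0.1 every 20
trials (high volatility), and a final low-volatility stage in which the
*outcomes* of the first stage are replayed in the same order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "Schedule",
    "OutcomeSequence",
    "build_reference_schedule",
    "build_custom_schedule",
    "sample_outcomes",
    "REFERENCE_N_TRIALS",
    "STAGE_LOW1",
    "STAGE_HIGH",
    "STAGE_LOW2",
]

STAGE_LOW1 = "low1"
STAGE_HIGH = "high"
STAGE_LOW2 = "low2"

REFERENCE_N_TRIALS = 320
_REF_LOW_LEN = 100
_REF_HIGH_BLOCK = 20
_REF_HIGH_BLOCKS = 6


@dataclass(frozen=True)
class Schedule:
    """Per-trial Bernoulli probabilities with stage labels.

    Trials are indexed 1..n_trials in documentation and output files;
    arrays are stored 0-based.
    """

    probs: np.ndarray
    stages: np.ndarray
    schedule_id: str = "custom"

    def __post_init__(self) -> None:
        probs = np.asarray(self.probs, dtype=float)
        stages = np.asarray(self.stages, dtype=object)
        if probs.ndim != 1 or probs.size == 0:
            raise ValueError("schedule must contain at least one trial")
        if probs.size != stages.size:
            raise ValueError("probs and stages must have equal length")
        if np.any(probs < 0.0) or np.any(probs > 1.0):
            raise ValueError("probabilities must lie in [0, 1]")
        object.__setattr__(self, "probs", probs)
        object.__setattr__(self, "stages", stages)

    @property
    def n_trials(self) -> int:
        return int(self.probs.size)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "trial": np.arange(1, self.n_trials + 1),
                "prob": self.probs,
                "stage": self.stages,
            }
        )


@dataclass(frozen=True)
class OutcomeSequence:
    """Sampled binary inputs u(k) in {0, 1}, one per scheduled trial."""

    u: np.ndarray
    stages: np.ndarray
    seed: int | None = None
    schedule_id: str = "custom"

    def __post_init__(self) -> None:
        u = np.asarray(self.u, dtype=int)
        stages = np.asarray(self.stages, dtype=object)
        if u.size != stages.size:
            raise ValueError("u and stages must have equal length")
        if not np.isin(u, (0, 1)).all():
            raise ValueError("outcomes must be binary")
        object.__setattr__(self, "u", u)
        object.__setattr__(self, "stages", stages)

    @property
    def n_trials(self) -> int:
        return int(self.u.size)

    def to_frame(self, schedule: Schedule | None = None) -> pd.DataFrame:
        frame = pd.DataFrame(
            {
                "trial": np.arange(1, self.n_trials + 1),
                "stage": self.stages,
                "u": self.u,
            }
        )
        if schedule is not None:
            frame.insert(1, "prob", schedule.probs)
        return frame


def build_reference_schedule(high_starts_high: bool = True) -> Schedule:
    """The 320-trial three-stage reference scenario.

    Trials 1-100: p = 0.5 (stage ``low1``).  Trials 101-220: p alternates
    between 0.9 and 0.1 in six blocks of 20 (stage ``high``).  Trials
    221-320: p = 0.5 (stage ``low2``; outcomes are replayed from low1 by
    :func:`sample_outcomes`).

    Parameters
    ----------
    high_starts_high
        If True (default) the volatile stage opens with p = 0.9; set
        False to open with p = 0.1.
    """
    lo = np.full(_REF_LOW_LEN, 0.5)
    pair = (0.9, 0.1) if high_starts_high else (0.1, 0.9)
    hi = np.repeat([pair[i % 2] for i in range(_REF_HIGH_BLOCKS)], _REF_HIGH_BLOCK)
    probs = np.concatenate([lo, hi, lo])
    stages = np.concatenate(
        [
            np.full(_REF_LOW_LEN, STAGE_LOW1, dtype=object),
            np.full(hi.size, STAGE_HIGH, dtype=object),
            np.full(_REF_LOW_LEN, STAGE_LOW2, dtype=object),
        ]
    )
    return Schedule(probs=probs, stages=stages, schedule_id="reference")


def build_custom_schedule(block_probs, block_lengths, stage_labels) -> Schedule:
    """Concatenate constant-probability blocks into a schedule."""
    if not (len(block_probs) == len(block_lengths) == len(stage_labels)):
        raise ValueError("block_probs, block_lengths and stage_labels must match")
    if len(block_probs) == 0:
        raise ValueError("schedule must contain at least one block")
    lengths = [int(n) for n in block_lengths]
    if any(n <= 0 for n in lengths):
        raise ValueError("block lengths must be positive")
    probs = np.repeat(np.asarray(block_probs, dtype=float), lengths)
    stages = np.repeat(np.asarray(stage_labels, dtype=object), lengths)
    return Schedule(probs=probs, stages=stages)


def sample_outcomes(schedule: Schedule, seed: int) -> OutcomeSequence:
    """Draw u(k) ~ Bernoulli(p(k)); replay low1 outcomes in low2.

    For the reference schedule the final low-volatility stage repeats the
    first stage's sampled outcomes bit for bit, implemented by copying the
    drawn values (not by re-seeding) so the identity holds for any
    generator.  Deterministic given (schedule, seed).
    """
    rng = np.random.default_rng(seed)
    u = (rng.random(schedule.n_trials) < schedule.probs).astype(int)
    is_low2 = schedule.stages == STAGE_LOW2
    if schedule.schedule_id == "reference" and is_low2.any():
        u[is_low2] = u[schedule.stages == STAGE_LOW1]
    return OutcomeSequence(
        u=u, stages=schedule.stages.copy(), seed=seed, schedule_id=schedule.schedule_id
    )
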