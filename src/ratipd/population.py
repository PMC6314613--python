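"""Simulated-population reward/timeout baseline.

A large population of simulated individuals, each playing one fixed random
sequence with a prescribed cooperation level against Tit-for-Tat, traces
out the attainable (total timeout, total reward) region at that level.  An
ordinary least-squares line fit through the population's cloud separates
subjects that out-perform the prescribed level (above the line: more reward
for the same timeout) from those that under-perform it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .game import PayoffMatrix

__all__ = [
    "PopulationConfig",
    "SeparationLine",
    "simulate_population",
    "fit_separation_line",
    "classify_relative_to_line",
]


@dataclass(frozen=True)
class PopulationConfig:
    """Population of fixed-composition random strategies.

    Each individual is a uniformly random permutation of exactly
    ``round(cooperation_level * n_trials)`` C's among ``n_trials`` choices
    (Bernoulli per-trial draws available via ``bernoulli_mode``), played
    once against Tit-for-Tat under ``matrix``.
    """

    matrix: PayoffMatrix
    n_individuals: int = 100_000
    cooperation_level: float = 0.60
    n_trials: int = 30
    seed: int = 0
    bernoulli_mode: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.cooperation_level <= 1.0):
            raise ValueError("cooperation_level outside [0, 1]")
        if self.n_individuals < 2:
            raise ValueError("n_individuals must be >= 2")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")

    @property
    def n_cooperate(self) -> int:
        return int(round(self.cooperation_level * self.n_trials))


@dataclass(frozen=True)
class SeparationLine:
    """OLS line total_reward = slope * total_timeout + intercept."""

    slope: float
    intercept: float
    fit_n: int


def simulate_population(config: PopulationConfig) -> pd.DataFrame:
    """Per-individual (total_reward, total_timeout) against Tit-for-Tat.

    Vectorized over individuals: the opponent's move on trial t is the
    subject's move on trial t-1 (C on trial 0), so each trial is classified
    directly from the shifted action matrix.  Returns a DataFrame with
    columns ``individual_id``, ``total_reward``, ``total_timeout``;
    reproducible for a fixed seed.
    """
    rng = np.random.default_rng(config.seed)
    n, m = config.n_individuals, config.n_trials
    k = config.n_cooperate
    if config.bernoulli_mode:
        coop = rng.random((n, m)) < config.cooperation_level
    else:
        # exactly k C's per row, uniformly permuted
        base = np.zeros((n, m), dtype=bool)
        base[:, :k] = True
        coop = np.take_along_axis(base, np.argsort(rng.random((n, m)), axis=1),
                                  axis=1)

    opp_coop = np.ones_like(coop)
    opp_coop[:, 1:] = coop[:, :-1]

    mat = config.matrix
    r_mask = coop & opp_coop
    t_mask = ~coop & opp_coop
    s_mask = coop & ~opp_coop
    p_mask = ~coop & ~opp_coop

    reward = mat.p_r * r_mask.sum(axis=1) + mat.p_t * t_mask.sum(axis=1)
    if mat.all_pellet_mode:
        reward = reward + mat.p_s * s_mask.sum(axis=1) + mat.p_p * p_mask.sum(axis=1)
        timeout = np.zeros(n)
    else:
        timeout = mat.p_s * s_mask.sum(axis=1) + mat.p_p * p_mask.sum(axis=1)

    return pd.DataFrame({
        "individual_id": np.arange(n),
        "total_reward": reward.astype(int),
        "total_timeout": timeout.astype(float),
    })


def fit_separation_line(points: pd.DataFrame) -> SeparationLine:
    """OLS fit of total_reward on total_timeout.

    Raises when the timeout values are degenerate (all equal), where the
    slope is unidentifiable.
    """
    x = np.asarray(points["total_timeout"], dtype=float)
    y = np.asarray(points["total_reward"], dtype=float)
    if len(x) < 2:
        raise ValueError("need at least two points")
    if np.ptp(x) == 0:
        raise ValueError("degenerate fit: all timeout values are equal")
    slope, intercept = np.polyfit(x, y, deg=1)
    return SeparationLine(slope=float(slope), intercept=float(intercept),
                          fit_n=len(x))


def classify_relative_to_line(
    subject_point: tuple[float, float],
    line: SeparationLine,
    tol: float = 1e-9,
) -> str:
    """Classify a (total_reward, total_timeout) point against the line.

    Returns ``"above"``, ``"on"`` or ``"below"`` from the sign of
    reward - (slope * timeout + intercept), with ``tol`` for "on".
    """
    reward, timeout = subject_point
    resid = reward - (line.slope * timeout + line.intercept)
    if abs(resid) <= tol:
        return "on"
    return "above" if resid > 0 else "below"
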