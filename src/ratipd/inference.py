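"""Strategy inference from session logs and Markov-chain analysis.

A memory-one subject facing a Tit-for-Tat opponent induces a Markov chain
on the four outcome states.  Because the opponent copies the subject's
previous move, the current state fully determines the opponent's next move,
and the subject's cooperation probability given the state determines the
rest:

* from R or S (subject just cooperated, so the opponent will cooperate):
  the chain moves to R with the state's cooperation probability, else to T;
* from T or P (subject just defected, so the opponent will defect):
  the chain moves to S with the state's cooperation probability, else to P.

The stationary distribution of this chain is the model-implied long-run
occupancy of the four states, and its R + S mass is the model-implied
cooperation rate — the consistency contract that links a group's estimated
transition vector to its observed cooperation level.

Estimation is by conditional counting: within each session, every
(previous state, current action) pair contributes one Bernoulli observation
to the component matching the previous state.  Trial 0 of each session has
no previous state and is skipped; pairs never straddle session boundaries.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .agents import TransitionVector
from .game import Action, OutcomeState, SessionLog, STATE_ORDER

__all__ = [
    "OccupancyDistribution",
    "StrategySummary",
    "ChainModel",
    "CriterionConfig",
    "summarize",
    "build_chain",
    "transition_matrix",
    "stationary_by_power_iteration",
    "simulate_occupancy",
    "predicted_cooperation",
    "classify_cooperator",
    "write_group_table",
]

_IDX = {s: i for i, s in enumerate(STATE_ORDER)}  # R=0, T=1, S=2, P=3


@dataclass(frozen=True)
class OccupancyDistribution:
    """Long-run (or empirical) fraction of trials in each outcome state."""

    p_R: float
    p_T: float
    p_S: float
    p_P: float
    n_trials: int = 0

    def __post_init__(self) -> None:
        total = self.p_R + self.p_T + self.p_S + self.p_P
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"occupancy components sum to {total}, not 1")
        for v in (self.p_R, self.p_T, self.p_S, self.p_P):
            if not (-1e-12 <= v <= 1 + 1e-12):
                raise ValueError("occupancy component outside [0, 1]")

    def as_array(self) -> np.ndarray:
        """Components in canonical (R, T, S, P) order."""
        return np.array([self.p_R, self.p_T, self.p_S, self.p_P])


@dataclass
class StrategySummary:
    """Pooled behavioral summary of one subject (or one group's pooled logs).

    ``transition_estimate`` maps each previous state to the empirical
    p(cooperate | state); components never observed are NaN, never 0/0.
    """

    cooperation_rate: float
    occupancy: OccupancyDistribution
    transition_estimate: dict[OutcomeState, float]
    transition_counts: dict[OutcomeState, tuple[int, int]]
    sessions_used: int

    def transition_vector(self, first_move_p_c: float = 0.5) -> TransitionVector:
        """Estimate as a TransitionVector; raises if any component is undefined."""
        est = self.transition_estimate
        if any(math.isnan(est[s]) for s in STATE_ORDER):
            undefined = [s.value for s in STATE_ORDER if math.isnan(est[s])]
            raise ValueError(f"transition components undefined for states {undefined}")
        return TransitionVector(
            est[OutcomeState.T], est[OutcomeState.R],
            est[OutcomeState.S], est[OutcomeState.P], first_move_p_c,
        )


@dataclass(frozen=True)
class CriterionConfig:
    """Learning criterion: cooperation above threshold for a run of sessions."""

    threshold: float = 0.60
    consecutive_sessions: int = 5

    def __post_init__(self) -> None:
        if not (0.0 < self.threshold < 1.0):
            raise ValueError("threshold must be in (0, 1)")
        if self.consecutive_sessions < 1:
            raise ValueError("consecutive_sessions must be >= 1")


@dataclass
class ChainModel:
    """The TFT-coupled 4-state chain of a transition vector.

    ``transition_matrix`` is row-stochastic over states in canonical
    (R, T, S, P) order; ``stationary`` solves pi @ M = pi.  ``reducible``
    flags chains that are not irreducible over all four states; the
    stationary then describes the closed set reachable from R (the state
    the experiment starts nearest to, since the opponent opens with C).
    """

    transition_matrix: np.ndarray
    stationary: OccupancyDistribution
    reducible: bool = False


def summarize(sessions: Sequence[SessionLog]) -> StrategySummary:
    """Pool session logs into cooperation rate, occupancy and transition counts."""
    sessions = list(sessions)
    if not sessions or any(len(s) == 0 for s in sessions):
        raise ValueError("summarize requires at least one non-empty session")

    n_trials = 0
    n_coop = 0
    occ = {s: 0 for s in STATE_ORDER}
    n_given = {s: 0 for s in STATE_ORDER}
    n_coop_after = {s: 0 for s in STATE_ORDER}

    for log in sessions:
        prev_state: OutcomeState | None = None
        for t in log.trials:
            n_trials += 1
            if t.subject_action is Action.C:
                n_coop += 1
            occ[t.state] += 1
            if prev_state is not None:
                n_given[prev_state] += 1
                if t.subject_action is Action.C:
                    n_coop_after[prev_state] += 1
            prev_state = t.state

    estimate = {
        s: (n_coop_after[s] / n_given[s]) if n_given[s] > 0 else float("nan")
        for s in STATE_ORDER
    }
    occupancy = OccupancyDistribution(
        p_R=occ[OutcomeState.R] / n_trials,
        p_T=occ[OutcomeState.T] / n_trials,
        p_S=occ[OutcomeState.S] / n_trials,
        p_P=occ[OutcomeState.P] / n_trials,
        n_trials=n_trials,
    )
    return StrategySummary(
        cooperation_rate=n_coop / n_trials,
        occupancy=occupancy,
        transition_estimate=estimate,
        transition_counts={s: (n_given[s], n_coop_after[s]) for s in STATE_ORDER},
        sessions_used=len(sessions),
    )


def transition_matrix(tv: TransitionVector) -> np.ndarray:
    """Row-stochastic 4x4 matrix over (R, T, S, P) induced by the vector vs TFT.

    Structural zeros: from R and S only {R, T} are reachable; from T and P
    only {S, P} (the opponent's next move is pinned by the subject's last).
    """
    pcT, pcR, pcS, pcP = tv.as_tuple()
    M = np.zeros((4, 4))
    M[_IDX[OutcomeState.R], _IDX[OutcomeState.R]] = pcR
    M[_IDX[OutcomeState.R], _IDX[OutcomeState.T]] = 1 - pcR
    M[_IDX[OutcomeState.S], _IDX[OutcomeState.R]] = pcS
    M[_IDX[OutcomeState.S], _IDX[OutcomeState.T]] = 1 - pcS
    M[_IDX[OutcomeState.T], _IDX[OutcomeState.S]] = pcT
    M[_IDX[OutcomeState.T], _IDX[OutcomeState.P]] = 1 - pcT
    M[_IDX[OutcomeState.P], _IDX[OutcomeState.S]] = pcP
    M[_IDX[OutcomeState.P], _IDX[OutcomeState.P]] = 1 - pcP
    return M


def _reachable(M: np.ndarray, start: int) -> set[int]:
    seen = {start}
    frontier = [start]
    while frontier:
        i = frontier.pop()
        for j in np.nonzero(M[i] > 0)[0]:
            if j not in seen:
                seen.add(int(j))
                frontier.append(int(j))
    return seen


def build_chain(tv: TransitionVector) -> ChainModel:
    """Construct the TFT-coupled chain and solve its stationary distribution.

    The stationary vector solves the linear system (M^T - I) pi = 0 with one
    row replaced by the normalization sum(pi) = 1.  When the chain is
    reducible, the stationary of the closed recurrent set reachable from R
    is returned (zeros on transient states) with ``reducible=True``.
    """
    for name, v in zip(("p_c_given_T", "p_c_given_R", "p_c_given_S", "p_c_given_P"),
                       tv.as_tuple()):
        if v is None or math.isnan(v):
            raise ValueError(f"transition component {name} undefined")

    M = transition_matrix(tv)
    r = _IDX[OutcomeState.R]
    reach_r = _reachable(M, r)
    # recurrent states among those reachable from R: states whose whole
    # reachable set reaches back to them
    recurrent = {i for i in reach_r if all(i in _reachable(M, j)
                                           for j in _reachable(M, i))}
    closed = sorted({i for i in recurrent})
    irreducible = all(len(_reachable(M, i)) == 4 for i in range(4))

    if not closed:  # cannot happen on a finite chain, defensive
        raise RuntimeError("no recurrent class reachable from R")

    sub = M[np.ix_(closed, closed)]
    k = len(closed)
    A = np.vstack([(sub.T - np.eye(k))[:-1], np.ones(k)])
    b = np.zeros(k)
    b[-1] = 1.0
    pi_sub, *_ = np.linalg.lstsq(A, b, rcond=None)
    pi = np.zeros(4)
    pi[closed] = np.clip(pi_sub, 0.0, 1.0)
    pi /= pi.sum()

    stationary = OccupancyDistribution(p_R=pi[0], p_T=pi[1], p_S=pi[2], p_P=pi[3])
    return ChainModel(transition_matrix=M, stationary=stationary,
                      reducible=not irreducible)


def stationary_by_power_iteration(
    tv: TransitionVector, tol: float = 1e-12, max_iter: int = 1_000_000
) -> np.ndarray:
    """Stationary distribution by power iteration on the lazy chain.

    Iterates pi <- pi (M + I)/2, which has the same stationary vector but is
    aperiodic, so the iteration converges even for periodic chains (e.g. the
    deterministic alternator's T-S cycle).  Serves as an independent check
    on the linear solve.
    """
    M = transition_matrix(tv)
    L = 0.5 * (M + np.eye(4))
    pi = np.full(4, 0.25)
    for _ in range(max_iter):
        nxt = pi @ L
        if np.abs(nxt - pi).max() < tol:
            return nxt / nxt.sum()
        pi = nxt
    return pi / pi.sum()


def simulate_occupancy(
    tv: TransitionVector, n_steps: int = 1_000_000, seed: int | None = None
) -> np.ndarray:
    """Empirical occupancy of the chain over ``n_steps`` transitions from R.

    Monte-Carlo oracle for the analytic stationary distribution; returns
    state frequencies in canonical (R, T, S, P) order.
    """
    pcT, pcR, pcS, pcP = tv.as_tuple()
    # next-state tables: (state under cooperation, state under defection,
    # cooperation probability) indexed by current state R,T,S,P
    coop_next = (0, 2, 0, 2)
    defect_next = (1, 3, 1, 3)
    p_coop = (pcR, pcT, pcS, pcP)
    rng = np.random.default_rng(seed)
    u = rng.random(n_steps)
    counts = [0, 0, 0, 0]
    state = 0
    for i in range(n_steps):
        state = coop_next[state] if u[i] < p_coop[state] else defect_next[state]
        counts[state] += 1
    return np.asarray(counts, dtype=float) / n_steps


def predicted_cooperation(tv: TransitionVector) -> float:
    """Model-implied long-run cooperation rate: stationary mass of R + S.

    In both R and S the subject's own action was C, so the stationary
    probability of landing in either state is the probability the subject
    cooperates on a trial, once the chain has mixed.
    """
    chain = build_chain(tv)
    return chain.stationary.p_R + chain.stationary.p_S


def classify_cooperator(
    per_session_rates: Sequence[float],
    criterion: CriterionConfig = CriterionConfig(),
) -> tuple[bool, int | None]:
    """Apply the learning criterion to a per-session cooperation-rate series.

    Returns ``(reached, first_index)`` where ``reached`` is True iff some
    run of at least ``consecutive_sessions`` sessions all have rate strictly
    above ``threshold``, and ``first_index`` is the first session of the
    first qualifying run (None when the criterion is never met).
    """
    rates = list(per_session_rates)
    if not rates:
        raise ValueError("empty rate sequence")
    run_start = None
    run_len = 0
    for i, r in enumerate(rates):
        if r > criterion.threshold:
            if run_len == 0:
                run_start = i
            run_len += 1
            if run_len >= criterion.consecutive_sessions:
                return True, run_start
        else:
            run_len = 0
            run_start = None
    return False, None


def write_group_table(
    group_summaries: dict[str, Sequence[StrategySummary]],
    path: str | Path,
) -> None:
    """Write a group-level summary table (CSV).

    One row per group: cooperation mean and s.e.m. over subjects, mean
    occupancy of each state, and mean of each transition-vector component
    (NaN components excluded per subject).
    """
    header = ["group", "n_subjects", "cooperation_mean", "cooperation_sem",
              "p_T", "p_R", "p_S", "p_P",
              "p_c_given_T", "p_c_given_R", "p_c_given_S", "p_c_given_P"]
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(header)
        for group, summaries in group_summaries.items():
            summaries = list(summaries)
            rates = np.array([s.cooperation_rate for s in summaries])
            occ = np.array([s.occupancy.as_array() for s in summaries]).mean(axis=0)
            comps = []
            for state in (OutcomeState.T, OutcomeState.R,
                          OutcomeState.S, OutcomeState.P):
                vals = [s.transition_estimate[state] for s in summaries
                        if not math.isnan(s.transition_estimate[state])]
                comps.append(float(np.mean(vals)) if vals else float("nan"))
            sem = rates.std(ddof=1) / np.sqrt(len(rates)) if len(rates) > 1 else 0.0
            writer.writerow([
                group, len(summaries),
                round(float(rates.mean()), 6), round(float(sem), 6),
                round(float(occ[1]), 6), round(float(occ[0]), 6),
                round(float(occ[2]), 6), round(float(occ[3]), 6),
                *(round(c, 6) for c in comps),
            ])
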