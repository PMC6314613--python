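"""How the payoff matrix shapes optimal play against Tit-for-Tat.

Two quantities organize the analysis.  The *contrast index*

    CI = (P_T - P_R) / (P_T + P_R)

measures the relative advantage of unilateral defection over mutual
cooperation in pellet terms, and the inequality 2 P_R > P_T + P_S (with the
sucker outcome S valued as a non-positive pellet equivalent) decides whether
the matrix favors sustained cooperation over T/S alternation.

The *best strategy* against a Tit-for-Tat opponent is found by exhaustive
search over the deterministic memory-one rules (a cooperate/defect choice
for each of the four previous states, crossed with the first move: 32
strategies, which include ALLC, ALLD and the alternator).  Against TFT a
deterministic rule's outcome-state orbit enters a cycle within at most four
steps, so per-trial and per-second payoff rates are computed exactly by
cycle detection rather than by simulation; simulation remains available as
an oracle.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Sequence

from .agents import alternation_cycle_states  # noqa: F401  (re-export convenience)
from .game import (
    Action,
    OutcomeState,
    PayoffMatrix,
    SessionLog,
    TimingModel,
    payoff,
    total_reward,
)

__all__ = [
    "ContrastIndex",
    "StrategyEvaluation",
    "NormalizedReward",
    "contrast_index",
    "favors_cooperation",
    "deterministic_memory_one_ids",
    "evaluate_strategy",
    "evaluate_strategies",
    "normalized_reward",
]


@dataclass(frozen=True)
class ContrastIndex:
    """Relative pellet contrast between temptation and mutual cooperation."""

    value: Fraction

    def __float__(self) -> float:
        return float(self.value)


@dataclass(frozen=True)
class StrategyEvaluation:
    """Exact long-run payoff rates of one deterministic strategy vs TFT."""

    strategy_id: str
    pellets_per_trial: float
    timeout_s_per_trial: float
    pellets_per_second: float
    total_pellets: int
    total_timeout_s: float
    is_pareto_optimal: bool = False


@dataclass(frozen=True)
class NormalizedReward:
    """Session reward as a fraction of the best strategy's reward."""

    value: float
    best_strategy_id: str
    best_session_reward: int


def contrast_index_from_rewards(p_r: int, p_t: int) -> ContrastIndex:
    """CI = (p_t - p_r) / (p_t + p_r), evaluated exactly as a rational.

    Lies in (0, 1) whenever p_t > p_r >= 0; scale-invariant in the pellet
    unit; zero for symmetric rewards.  CI = 1/3 for the (1, 2) pellet pair,
    1/5 for (2, 3).
    """
    if p_t + p_r <= 0:
        raise ZeroDivisionError("contrast index undefined when p_t + p_r = 0")
    return ContrastIndex(Fraction(p_t - p_r, p_t + p_r))


def contrast_index(matrix: PayoffMatrix) -> ContrastIndex:
    """Contrast index of a payoff matrix's pellet rewards."""
    return contrast_index_from_rewards(matrix.p_r, matrix.p_t)


def favors_cooperation(matrix: PayoffMatrix,
                       sucker_pellet_equivalent: float = 0.0) -> bool:
    """Whether the matrix favors cooperation: 2 p_r > p_t + s_equiv.

    ``sucker_pellet_equivalent`` is the (non-positive) pellet value assigned
    to the S timeout.  At the default 0, a matrix with p_t = 2 p_r sits
    exactly on the boundary and the strict inequality fails; any negative
    valuation of the timeout tips it toward cooperation.
    """
    if sucker_pellet_equivalent > 0:
        raise ValueError("sucker_pellet_equivalent must be <= 0")
    return 2 * matrix.p_r > matrix.p_t + sucker_pellet_equivalent


# ---------------------------------------------------------------------------
# Deterministic memory-one strategy search

_STATES = (OutcomeState.R, OutcomeState.T, OutcomeState.S, OutcomeState.P)


def deterministic_memory_one_ids() -> list[str]:
    """Ids of the 32 deterministic memory-one rules.

    ``m1:<f><aR><aT><aS><aP>`` lists the first move and the action after
    each previous state in (R, T, S, P) order, e.g. ``m1:CCCCC`` is ALLC
    and ``m1:CDCDC`` (defect after own cooperation, cooperate after own
    defection) is the alternator.
    """
    ids = []
    for first in "CD":
        for bits in range(16):
            rule = "".join("CD"[(bits >> i) & 1] for i in range(4))
            ids.append(f"m1:{first}{rule}")
    return ids


def _rule_from_id(strategy_id: str):
    body = strategy_id.split(":", 1)[1]
    first = Action(body[0])
    rule = {s: Action(a) for s, a in zip(_STATES, body[1:])}
    return first, rule


def _orbit_states(strategy_id: str) -> tuple[list[OutcomeState], list[OutcomeState]]:
    """Transient prefix and cycle of the deterministic orbit against TFT.

    The opponent's move is pinned by the subject's previous move, so the
    outcome state evolves deterministically: state[t+1] depends only on
    state[t].  With four states the orbit cycles within four steps.
    """
    first, rule = _rule_from_id(strategy_id)
    # trial 0: opponent plays C
    state = OutcomeState.R if first is Action.C else OutcomeState.T
    seen: dict[OutcomeState, int] = {}
    orbit: list[OutcomeState] = []
    while state not in seen:
        seen[state] = len(orbit)
        orbit.append(state)
        my_next = rule[state]
        # opponent mirrors the subject's action embedded in the current state
        opp_next = Action.C if state in (OutcomeState.R, OutcomeState.S) else Action.D
        state = {
            (Action.C, Action.C): OutcomeState.R,
            (Action.D, Action.C): OutcomeState.T,
            (Action.C, Action.D): OutcomeState.S,
            (Action.D, Action.D): OutcomeState.P,
        }[(my_next, opp_next)]
    start = seen[state]
    return orbit[:start], orbit[start:]


_NAMED = {"allc": "m1:CCCCC", "alld": "m1:DDDDD", "alternator": "m1:CDCDC"}


def evaluate_strategy(
    strategy_id: str,
    matrix: PayoffMatrix,
    timing: TimingModel,
    n_trials: int,
) -> StrategyEvaluation:
    """Payoff accounting of one deterministic strategy against TFT.

    Accepts a deterministic memory-one id (``m1:...``) or one of the named
    aliases ``allc``, ``alld``, ``alternator``.  The ``*_per_trial`` and
    ``per_second`` fields are long-run rates averaged over the orbit's
    recurrent cycle (so the alternator earns exactly p_t / 2 pellets per
    trial regardless of session parity); ``total_pellets`` and
    ``total_timeout_s`` are the exact finite totals over ``n_trials``,
    equal to brute-force simulation.
    """
    mid = _NAMED.get(strategy_id, strategy_id)
    transient, cycle = _orbit_states(mid)

    # long-run rates: averages over the recurrent cycle, independent of the
    # transient and of where the session happens to cut the cycle
    cyc_pellets = cyc_timeout = cyc_duration = 0.0
    for s in cycle:
        p, to = payoff(s, matrix)
        cyc_pellets += p
        cyc_timeout += to
        cyc_duration += timing.trial_duration(p, to)

    # exact finite-session totals: transient prefix plus whole and partial
    # repetitions of the cycle
    states: list[OutcomeState] = []
    states.extend(transient[:n_trials])
    remaining = n_trials - len(states)
    if remaining > 0:
        reps, extra = divmod(remaining, len(cycle))
        states.extend(cycle * reps + cycle[:extra])

    pellets = 0
    timeout = 0.0
    for s in states:
        p, to = payoff(s, matrix)
        pellets += p
        timeout += to

    return StrategyEvaluation(
        strategy_id=strategy_id,
        pellets_per_trial=cyc_pellets / len(cycle),
        timeout_s_per_trial=cyc_timeout / len(cycle),
        pellets_per_second=(cyc_pellets / cyc_duration) if cyc_duration > 0 else 0.0,
        total_pellets=pellets,
        total_timeout_s=timeout,
    )


def evaluate_strategies(
    matrix: PayoffMatrix,
    timing: TimingModel | None = None,
    n_trials: int = 30,
) -> list[StrategyEvaluation]:
    """Evaluate the named strategies and all 32 deterministic memory-one rules.

    Flags the Pareto set under (maximize pellets/trial, minimize
    timeout/trial): an evaluation is Pareto-optimal iff no other evaluated
    strategy is at least as good on both axes and strictly better on one.
    """
    if n_trials < 2:
        raise ValueError("n_trials must be >= 2")
    timing = timing or TimingModel()
    ids = ["allc", "alld", "alternator"] + deterministic_memory_one_ids()
    evals = [evaluate_strategy(sid, matrix, timing, n_trials) for sid in ids]

    flagged = []
    for e in evals:
        dominated = any(
            o.pellets_per_trial >= e.pellets_per_trial
            and o.timeout_s_per_trial <= e.timeout_s_per_trial
            and (o.pellets_per_trial > e.pellets_per_trial
                 or o.timeout_s_per_trial < e.timeout_s_per_trial)
            for o in evals
        )
        flagged.append(StrategyEvaluation(
            strategy_id=e.strategy_id,
            pellets_per_trial=e.pellets_per_trial,
            timeout_s_per_trial=e.timeout_s_per_trial,
            pellets_per_second=e.pellets_per_second,
            total_pellets=e.total_pellets,
            total_timeout_s=e.total_timeout_s,
            is_pareto_optimal=not dominated,
        ))
    return flagged


def normalized_reward(
    session: SessionLog,
    matrix: PayoffMatrix,
    timing: TimingModel | None = None,
) -> NormalizedReward:
    """Session pellets divided by the best strategy's pellets at equal length.

    The best strategy is selected from the evaluated deterministic set by
    the long-run per-trial pellet rate, ties broken by lower timeout (so at
    a boundary matrix where ALLC and the alternator tie on pellets, the
    timeout-free ALLC is the benchmark); the denominator is that strategy's
    exact pellet total over the session's length.  The per-second
    objective — which is what makes ALLC uniquely optimal when pellets
    tie — is reported by :func:`evaluate_strategies`, not used here.
    """
    n_trials = len(session)
    evals = evaluate_strategies(matrix, timing, n_trials)
    best = max(evals, key=lambda e: (e.pellets_per_trial, -e.timeout_s_per_trial))
    if best.total_pellets == 0:
        raise ZeroDivisionError("best strategy earns zero pellets under this matrix")
    return NormalizedReward(
        value=total_reward(session) / best.total_pellets,
        best_strategy_id=best.strategy_id,
        best_session_reward=best.total_pellets,
    )
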