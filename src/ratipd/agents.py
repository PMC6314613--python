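"""Subject-side decision policies.

The central model is the *memory-one* stochastic strategy: the probability
of cooperating on trial ``t`` depends only on the outcome state of trial
``t - 1``, collected in a four-component *transition vector*
(p(c|T), p(c|R), p(c|S), p(c|P)).  A vector of all 0.5 is indistinguishable
from random responding; components near 1 describe an almost-always-
cooperate reciprocal strategy.

Deterministic reference policies used in best-strategy arguments (ALLC,
ALLD, the cooperate/defect alternator) and utility policies (Bernoulli,
fixed action sequence) share the same interface so any of them can drive
:func:`ratipd.game.play_session`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .game import Action, OutcomeState, PayoffMatrix

__all__ = [
    "TransitionVector",
    "AgentPolicy",
    "MemoryOne",
    "AllC",
    "AllD",
    "Alternator",
    "Bernoulli",
    "FixedSequence",
    "policy_from_dict",
    "policy_to_dict",
    "policy_from_json",
    "alternation_cycle_states",
]


@dataclass(frozen=True)
class TransitionVector:
    """Conditional cooperation probabilities given the previous outcome state."""

    p_c_given_T: float
    p_c_given_R: float
    p_c_given_S: float
    p_c_given_P: float
    first_move_p_c: float = 0.5

    def __post_init__(self) -> None:
        for name in ("p_c_given_T", "p_c_given_R", "p_c_given_S",
                     "p_c_given_P", "first_move_p_c"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")

    def p_c(self, previous_state: OutcomeState | None) -> float:
        """Cooperation probability given the previous state (None on trial 0)."""
        if previous_state is None:
            return self.first_move_p_c
        return {
            OutcomeState.T: self.p_c_given_T,
            OutcomeState.R: self.p_c_given_R,
            OutcomeState.S: self.p_c_given_S,
            OutcomeState.P: self.p_c_given_P,
        }[OutcomeState(previous_state)]

    def as_tuple(self) -> tuple[float, float, float, float]:
        """Components in (T, R, S, P) order."""
        return (self.p_c_given_T, self.p_c_given_R,
                self.p_c_given_S, self.p_c_given_P)


class AgentPolicy:
    """Base class: a policy maps the previous outcome state to an action."""

    kind: str = "abstract"

    def reset(self) -> None:
        """Clear per-session state before a new session."""

    def act(self, previous_state: OutcomeState | None,
            rng: np.random.Generator) -> Action:
        raise NotImplementedError


class MemoryOne(AgentPolicy):
    """Stochastic memory-one strategy parameterized by a transition vector."""

    kind = "memory_one"

    def __init__(self, tv: TransitionVector):
        self.tv = tv

    def act(self, previous_state, rng):
        return Action.C if rng.random() < self.tv.p_c(previous_state) else Action.D


class AllC(AgentPolicy):
    """Unconditional cooperation."""

    kind = "allc"

    def act(self, previous_state, rng):
        return Action.C


class AllD(AgentPolicy):
    """Unconditional defection."""

    kind = "alld"

    def act(self, previous_state, rng):
        return Action.D


class Alternator(AgentPolicy):
    """Alternate own action every trial, starting with cooperation."""

    kind = "alternator"

    def __init__(self):
        self._last: Action | None = None

    def reset(self):
        self._last = None

    def act(self, previous_state, rng):
        nxt = Action.C if self._last in (None, Action.D) else Action.D
        self._last = nxt
        return nxt


class Bernoulli(AgentPolicy):
    """Cooperate independently with fixed probability ``p`` each trial."""

    kind = "bernoulli"

    def __init__(self, p: float):
        if not (0.0 <= p <= 1.0):
            raise ValueError("p outside [0, 1]")
        self.p = p

    def act(self, previous_state, rng):
        return Action.C if rng.random() < self.p else Action.D


class FixedSequence(AgentPolicy):
    """Play a pre-specified action sequence; errors when exhausted."""

    kind = "fixed_sequence"

    def __init__(self, actions):
        self.actions = [Action(a) for a in actions]
        self._i = 0

    def reset(self):
        self._i = 0

    def act(self, previous_state, rng):
        if self._i >= len(self.actions):
            raise IndexError("fixed action sequence exhausted")
        a = self.actions[self._i]
        self._i += 1
        return a


def policy_to_dict(policy: AgentPolicy) -> dict:
    """Serialize a policy to the JSON-schema dict form."""
    if isinstance(policy, MemoryOne):
        return {"kind": "memory_one",
                "transition_vector": list(policy.tv.as_tuple()),
                "first_move_p_c": policy.tv.first_move_p_c}
    if isinstance(policy, Bernoulli):
        return {"kind": "bernoulli", "p": policy.p}
    if isinstance(policy, FixedSequence):
        return {"kind": "fixed_sequence",
                "sequence": "".join(a.value for a in policy.actions)}
    return {"kind": policy.kind}


def policy_from_dict(d: dict) -> AgentPolicy:
    """Build a policy from its JSON-schema dict form.

    ``kind`` selects the class; memory-one takes ``transition_vector``
    ``[p(c|T), p(c|R), p(c|S), p(c|P)]`` plus optional ``first_move_p_c``;
    fixed sequences are strings over {C, D}.
    """
    kind = d["kind"]
    if kind == "memory_one":
        t, r, s, p = d["transition_vector"]
        return MemoryOne(TransitionVector(t, r, s, p,
                                          d.get("first_move_p_c", 0.5)))
    if kind == "allc":
        return AllC()
    if kind == "alld":
        return AllD()
    if kind == "alternator":
        return Alternator()
    if kind == "bernoulli":
        return Bernoulli(d["p"])
    if kind == "fixed_sequence":
        return FixedSequence(d["sequence"])
    raise ValueError(f"unknown policy kind {kind!r}")


def policy_from_json(path: str | Path) -> AgentPolicy:
    return policy_from_dict(json.loads(Path(path).read_text(encoding="utf-8")))


def alternation_cycle_states(
    matrix: PayoffMatrix,
) -> tuple[list[OutcomeState], list[OutcomeState]]:
    """Outcome-state orbit of the alternator against Tit-for-Tat.

    The subject plays C, D, C, D, ...; the opponent mirrors with one trial
    of lag, so the orbit is a one-trial transient in R followed by the
    period-2 cycle (T, S): the alternator harvests the temptation pellets
    every other trial at the cost of the sucker timeout in between.

    Returns ``(transient, cycle)``.  Per two-trial cycle the payoff is
    ``p_t`` pellets and ``p_s`` timeout seconds (``p_s`` pellets in
    all-pellet mode).
    """
    return [OutcomeState.R], [OutcomeState.T, OutcomeState.S]
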