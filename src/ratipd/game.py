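"""Iterated Prisoner's Dilemma game engine for operant-conditioning sessions.

Encodes the two-action game a rat plays against a Tit-for-Tat opponent:
outcome states, payoff matrices that mix food pellets (positive
reinforcement) with timeouts (negative reinforcement), trial timing, and
seeded session simulation.  A session is an ordered sequence of trials; by
default 30 trials, two sessions per day in the experimental protocol this
package models.

State naming follows the standard Prisoner's Dilemma convention:

====== ============== ==============
state  subject action opponent action
====== ============== ==============
R      cooperate      cooperate
T      defect         cooperate
S      cooperate      defect
P      defect         defect
====== ============== ==============

R and T deliver pellets; S and P impose a timeout (in the all-pellet mode
used for classic addable matrices, all four cells deliver pellets).
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, asdict
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Action",
    "OutcomeState",
    "PayoffMatrix",
    "TimingModel",
    "TrialRecord",
    "SessionLog",
    "classify_state",
    "payoff",
    "tft_next",
    "play_session",
    "total_reward",
    "total_timeout",
    "sessions_to_csv",
    "sessions_from_csv",
    "config_to_json",
    "config_from_json",
]


class Action(str, Enum):
    """A player's choice in a single trial: cooperate or defect."""

    C = "C"
    D = "D"


class OutcomeState(str, Enum):
    """The four outcome states of one Prisoner's Dilemma trial."""

    R = "R"  # mutual cooperation (reward)
    T = "T"  # subject defected, opponent cooperated (temptation)
    S = "S"  # subject cooperated, opponent defected (sucker)
    P = "P"  # mutual defection (punishment)


#: Canonical internal state order used by every module (chain rows, occupancy
#: vectors, report columns translate at the I/O boundary if needed).
STATE_ORDER: tuple[OutcomeState, ...] = (
    OutcomeState.R,
    OutcomeState.T,
    OutcomeState.S,
    OutcomeState.P,
)


@dataclass(frozen=True)
class PayoffMatrix:
    """Reinforcement magnitudes for the four outcome states.

    Parameters
    ----------
    p_r, p_t
        Pellets delivered for mutual cooperation (R) and unilateral
        defection (T).  Temptation must exceed the cooperation reward
        (``p_t > p_r``), the defining inequality of the dilemma.
    p_p, p_s
        Timeout seconds imposed for mutual defection (P) and unilateral
        cooperation (S); the sucker timeout is at least the punishment
        timeout.  In ``all_pellet_mode`` these two values are instead
        pellet counts and no timeout is ever imposed, which is how classic
        "addable" matrices such as (T=6, R=4, P=1, S=0) are expressed.
    label
        Free-text identifier used in session logs and reports.
    """

    p_r: int
    p_t: int
    p_p: float
    p_s: float
    label: str = ""
    all_pellet_mode: bool = False

    def __post_init__(self) -> None:
        if self.p_r < 0 or self.p_t < 0 or self.p_p < 0 or self.p_s < 0:
            raise ValueError("payoff magnitudes must be non-negative")
        if self.p_t <= self.p_r:
            raise ValueError("temptation p_t must exceed reward p_r")
        if int(self.p_r) != self.p_r or int(self.p_t) != self.p_t:
            raise ValueError("pellet counts p_r, p_t must be integers")
        if self.all_pellet_mode:
            if int(self.p_p) != self.p_p or int(self.p_s) != self.p_s:
                raise ValueError("all-pellet mode requires integer p_p, p_s")
        elif self.p_s < self.p_p:
            raise ValueError("sucker timeout p_s must be >= punishment timeout p_p")


@dataclass(frozen=True)
class TimingModel:
    """Component durations of a single trial, in seconds.

    ``iti_s`` is the inter-trial interval; ``cs_max_s`` the maximum time the
    conditioned stimulus (lever light) stays on awaiting a response;
    ``eating_s`` the pellet-consumption window; ``feeder_light_s`` the cue
    preceding pellet delivery; ``response_latency_s`` the modeled latency
    from light onset to lever press (agents always respond, so ``cs_max_s``
    never elapses).  ``opponent_fixed_ratio`` is the opponent's FR lever
    schedule, recorded for bookkeeping only.
    """

    iti_s: float = 5.0
    cs_max_s: float = 45.0
    eating_s: float = 5.0
    feeder_light_s: float = 1.0
    response_latency_s: float = 0.0
    opponent_fixed_ratio: int = 3

    def __post_init__(self) -> None:
        for name in ("iti_s", "cs_max_s", "eating_s", "feeder_light_s",
                     "response_latency_s"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.cs_max_s <= 0:
            raise ValueError("cs_max_s must be positive")

    def trial_duration(self, pellets: int, timeout_s: float) -> float:
        """Duration of one trial: ITI + latency + eating/light or timeout."""
        if pellets > 0:
            return self.iti_s + self.response_latency_s + self.eating_s + self.feeder_light_s
        return self.iti_s + self.response_latency_s + timeout_s


@dataclass(frozen=True)
class TrialRecord:
    trial_index: int
    subject_action: Action
    opponent_action: Action
    state: OutcomeState
    pellets: int
    timeout_s: float
    trial_duration_s: float


@dataclass
class SessionLog:
    """One operant session: ordered trials plus subject/phase metadata."""

    subject_id: str
    group: str
    phase: str
    session_index: int
    matrix_label: str
    trials: list[TrialRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.trials)

    @property
    def cooperation_rate(self) -> float:
        """Fraction of trials on which the subject chose C."""
        if not self.trials:
            raise ValueError("empty session has no cooperation rate")
        n_c = sum(1 for t in self.trials if t.subject_action is Action.C)
        return n_c / len(self.trials)


_STATE_BY_PAIR = {
    (Action.C, Action.C): OutcomeState.R,
    (Action.D, Action.C): OutcomeState.T,
    (Action.C, Action.D): OutcomeState.S,
    (Action.D, Action.D): OutcomeState.P,
}


def classify_state(subject: Action, opponent: Action) -> OutcomeState:
    """Map a (subject, opponent) action pair to its outcome state."""
    return _STATE_BY_PAIR[(Action(subject), Action(opponent))]


def payoff(state: OutcomeState, matrix: PayoffMatrix) -> tuple[int, float]:
    """Reinforcement for a state: ``(pellets, timeout_s)``.

    R and T always pay pellets.  S and P impose timeouts, except in
    all-pellet mode where they pay ``p_s`` / ``p_p`` pellets instead.
    """
    state = OutcomeState(state)
    if state is OutcomeState.R:
        return int(matrix.p_r), 0.0
    if state is OutcomeState.T:
        return int(matrix.p_t), 0.0
    if matrix.all_pellet_mode:
        if state is OutcomeState.P:
            return int(matrix.p_p), 0.0
        return int(matrix.p_s), 0.0
    if state is OutcomeState.P:
        return 0, float(matrix.p_p)
    return 0, float(matrix.p_s)


def tft_next(previous_subject_action: Action | None) -> Action:
    """Tit-for-Tat opponent: cooperate first, then copy the subject's last move."""
    if previous_subject_action is None:
        return Action.C
    return Action(previous_subject_action)


def play_session(
    agent,
    matrix: PayoffMatrix,
    timing: TimingModel | None = None,
    n_trials: int = 30,
    seed: int | None = None,
    *,
    subject_id: str = "sim",
    group: str = "sim",
    phase: str = "sim",
    session_index: int = 0,
    rng: np.random.Generator | None = None,
) -> SessionLog:
    """Simulate one session of the subject policy against Tit-for-Tat.

    The opponent's move on trial ``t`` is the subject's move on trial
    ``t - 1`` (cooperate on trial 0).  Reinforcement follows ``payoff``;
    trial duration follows :meth:`TimingModel.trial_duration`.  The run is
    deterministic given ``(agent, matrix, timing, seed)``.

    ``rng`` may be passed instead of ``seed`` to continue an existing
    random stream (used by the cohort generator).
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    timing = timing or TimingModel()
    if rng is None:
        rng = np.random.default_rng(seed)
    agent.reset()

    trials: list[TrialRecord] = []
    prev_subject: Action | None = None
    prev_state: OutcomeState | None = None
    for i in range(n_trials):
        opponent = tft_next(prev_subject)
        subject = agent.act(prev_state, rng)
        state = classify_state(subject, opponent)
        pellets, timeout_s = payoff(state, matrix)
        trials.append(
            TrialRecord(
                trial_index=i,
                subject_action=subject,
                opponent_action=opponent,
                state=state,
                pellets=pellets,
                timeout_s=timeout_s,
                trial_duration_s=timing.trial_duration(pellets, timeout_s),
            )
        )
        prev_subject, prev_state = subject, state

    return SessionLog(
        subject_id=subject_id,
        group=group,
        phase=phase,
        session_index=session_index,
        matrix_label=matrix.label,
        trials=trials,
    )


def total_reward(session: SessionLog) -> int:
    """Total pellets earned by the subject over the session."""
    if not session.trials:
        raise ValueError("empty session")
    return sum(t.pellets for t in session.trials)


def total_timeout(session: SessionLog) -> float:
    """Total timeout seconds imposed on the subject over the session."""
    if not session.trials:
        raise ValueError("empty session")
    return float(sum(t.timeout_s for t in session.trials))


# ---------------------------------------------------------------------------
# I/O: session-log CSV dialect and matrix/timing JSON configs

_CSV_COLUMNS = [
    "subject_id", "group", "phase", "session_index", "matrix_label",
    "trial_index", "subject_action", "opponent_action", "state",
    "pellets", "timeout_s", "trial_duration_s",
]


def sessions_to_csv(sessions: Iterable[SessionLog], path: str | Path) -> None:
    """Write session logs as one-trial-per-row CSV (UTF-8, header required)."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(_CSV_COLUMNS)
        for s in sessions:
            for t in s.trials:
                writer.writerow([
                    s.subject_id, s.group, s.phase, s.session_index,
                    s.matrix_label, t.trial_index, t.subject_action.value,
                    t.opponent_action.value, t.state.value, t.pellets,
                    repr(t.timeout_s), repr(t.trial_duration_s),
                ])


def sessions_from_csv(path: str | Path) -> list[SessionLog]:
    """Read session logs written by :func:`sessions_to_csv`."""
    sessions: dict[tuple, SessionLog] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        missing = set(_CSV_COLUMNS) - set(reader.fieldnames or [])
        if missing:
            raise ValueError(f"session CSV missing columns: {sorted(missing)}")
        for row in reader:
            key = (row["subject_id"], row["group"], row["phase"],
                   int(row["session_index"]), row["matrix_label"])
            log = sessions.get(key)
            if log is None:
                log = SessionLog(*key)
                sessions[key] = log
            log.trials.append(TrialRecord(
                trial_index=int(row["trial_index"]),
                subject_action=Action(row["subject_action"]),
                opponent_action=Action(row["opponent_action"]),
                state=OutcomeState(row["state"]),
                pellets=int(row["pellets"]),
                timeout_s=float(row["timeout_s"]),
                trial_duration_s=float(row["trial_duration_s"]),
            ))
    out = list(sessions.values())
    for log in out:
        log.trials.sort(key=lambda t: t.trial_index)
        if [t.trial_index for t in log.trials] != list(range(len(log.trials))):
            raise ValueError(
                f"non-contiguous trial indices in session {log.subject_id}/{log.session_index}"
            )
    return out


def config_to_json(matrix: PayoffMatrix, timing: TimingModel,
                   path: str | Path) -> None:
    """Write the payoff-matrix + timing configuration as JSON."""
    d = {**asdict(matrix), **asdict(timing)}
    d.pop("label")
    d["label"] = matrix.label
    Path(path).write_text(json.dumps(d, indent=2), encoding="utf-8")


def config_from_json(path: str | Path) -> tuple[PayoffMatrix, TimingModel]:
    """Read a configuration written by :func:`config_to_json`."""
    d = json.loads(Path(path).read_text(encoding="utf-8"))
    matrix = PayoffMatrix(
        p_r=d["p_r"], p_t=d["p_t"], p_p=d["p_p"], p_s=d["p_s"],
        label=d.get("label", ""), all_pellet_mode=d.get("all_pellet_mode", False),
    )
    timing = TimingModel(
        iti_s=d.get("iti_s", 5.0), cs_max_s=d.get("cs_max_s", 45.0),
        eating_s=d.get("eating_s", 5.0), feeder_light_s=d.get("feeder_light_s", 1.0),
        response_latency_s=d.get("response_latency_s", 0.0),
        opponent_fixed_ratio=d.get("opponent_fixed_ratio", 3),
    )
    return matrix, timing
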