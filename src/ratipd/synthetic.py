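"""Synthetic-cohort generator: the full experiment without any animals.

Subjects are memory-one stochastic agents whose transition vectors drift
from chance (0.5, 0.5, 0.5, 0.5) toward a group-specific target vector —
a phenomenological stand-in for acquisition (no learning rule is modeled;
the drift is linear per component and the module isolates it so alternative
acquisition curves can be plugged in).  Each subject draws a
sessions-to-criterion horizon from a truncated normal, reaches its target
at the end of that horizon, and is then held at the target for a block of
stable sessions.  Reversal phases swap the meaning of the levers and re-run
a (shorter) drift from chance back to target; matrix-switch phases drift
from the previous target to the new phase's target under the new matrix.

Session logs use :mod:`ratipd.game` structures throughout, so every
generated cohort flows through the same inference and reporting code paths
as a real dataset would.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .agents import MemoryOne, TransitionVector
from .game import PayoffMatrix, SessionLog, TimingModel, play_session, sessions_to_csv
from .reference import GROUP_TVS, MATRICES

__all__ = [
    "CohortConfig",
    "ExperimentBundle",
    "CHANCE_TV",
    "generate_subject",
    "generate_cohort",
    "generate_experiment",
    "default_study_plan",
]

#: Random-mode vector: cooperation probability 0.5 after every outcome.
CHANCE_TV = TransitionVector(0.5, 0.5, 0.5, 0.5)


@dataclass(frozen=True)
class CohortConfig:
    """One group of subjects sharing a target strategy and phase schedule.

    ``matrix_schedule`` is an ordered list of (phase name, matrix label)
    pairs; ``phase_targets`` optionally overrides the drift target per
    phase (defaulting to ``target_tv``).  The criterion horizon is drawn
    per subject as round(N(mean, sd)) truncated at 5; drift sessions are
    labeled with the phase name and held sessions with ``<phase>-stable``.
    """

    group_name: str
    n_subjects: int
    target_tv: TransitionVector
    start_tv: TransitionVector = CHANCE_TV
    sessions_to_criterion_mean: float = 30.0
    sessions_to_criterion_sd: float = 4.0
    n_trials_per_session: int = 30
    sessions_per_day: int = 2
    n_stable_sessions: int = 5
    matrix_schedule: tuple[tuple[str, str], ...] = (("acquisition", "1-2-4-8"),)
    phase_targets: tuple[tuple[str, tuple[float, float, float, float]], ...] = ()
    reversal: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or self.n_trials_per_session < 1:
            raise ValueError("counts must be positive")
        if self.n_stable_sessions < 1 or self.sessions_per_day < 1:
            raise ValueError("counts must be positive")
        if not self.matrix_schedule:
            raise ValueError("matrix_schedule must be non-empty")

    def target_for(self, phase: str) -> TransitionVector:
        for name, comps in self.phase_targets:
            if name == phase:
                return TransitionVector(*comps)
        return self.target_tv


@dataclass
class ExperimentBundle:
    """Generated sessions plus the manifest that replays them."""

    sessions: list[SessionLog]
    manifest: dict

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        sessions_to_csv(self.sessions, out / "sessions.csv")
        (out / "manifest.json").write_text(
            json.dumps(self.manifest, indent=2, sort_keys=True), encoding="utf-8"
        )


def _interpolate(start: TransitionVector, target: TransitionVector,
                 frac: float) -> TransitionVector:
    comps = [a + frac * (b - a) for a, b in zip(start.as_tuple(), target.as_tuple())]
    return TransitionVector(*comps, first_move_p_c=start.first_move_p_c)


def _draw_horizon(rng: np.random.Generator, mean: float, sd: float,
                  minimum: int = 5, max_retries: int = 100) -> int:
    for _ in range(max_retries):
        h = int(round(rng.normal(mean, sd)))
        if h >= minimum:
            return h
    return minimum


def generate_subject(
    config: CohortConfig,
    subject_index: int,
    matrices: dict[str, PayoffMatrix] | None = None,
    timing: TimingModel | None = None,
) -> list[SessionLog]:
    """All sessions of one subject, deterministic per (seed, subject_index).

    The first phase drifts from ``start_tv`` to the phase target over the
    subject's drawn horizon.  Later phases drift over half that horizon
    (at least 5 sessions): reversal phases restart from ``start_tv``
    (lever meanings swapped, prior mapping uninformative), matrix-switch
    phases start from the previous phase's target.  Every phase ends with
    ``n_stable_sessions`` sessions held at its target.
    """
    matrices = matrices or MATRICES
    timing = timing or TimingModel()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, subject_index]))
    subject_id = f"{config.group_name}-{subject_index:02d}"

    logs: list[SessionLog] = []
    session_index = 0
    first_horizon = _draw_horizon(rng, config.sessions_to_criterion_mean,
                                  config.sessions_to_criterion_sd)
    prev_target = config.start_tv

    for phase_pos, (phase, matrix_label) in enumerate(config.matrix_schedule):
        if matrix_label not in matrices:
            raise KeyError(f"unknown matrix label {matrix_label!r}")
        matrix = matrices[matrix_label]
        target = config.target_for(phase)
        if phase_pos == 0:
            horizon, origin = first_horizon, config.start_tv
        else:
            horizon = max(5, first_horizon // 2)
            is_reversal = config.reversal and "revers" in phase.lower()
            origin = config.start_tv if is_reversal else prev_target

        for s in range(1, horizon + 1):
            tv = _interpolate(origin, target, s / horizon)
            logs.append(play_session(
                MemoryOne(tv), matrix, timing, config.n_trials_per_session,
                rng=rng, subject_id=subject_id, group=config.group_name,
                phase=phase, session_index=session_index,
            ))
            session_index += 1
        for _ in range(config.n_stable_sessions):
            logs.append(play_session(
                MemoryOne(target), matrix, timing, config.n_trials_per_session,
                rng=rng, subject_id=subject_id, group=config.group_name,
                phase=f"{phase}-stable", session_index=session_index,
            ))
            session_index += 1
        prev_target = target

    return logs


def generate_cohort(config: CohortConfig, **kwargs) -> list[SessionLog]:
    """Sessions of every subject in the cohort, in subject order."""
    logs: list[SessionLog] = []
    for i in range(config.n_subjects):
        logs.extend(generate_subject(config, i, **kwargs))
    return logs


def default_study_plan() -> dict:
    """The two-experiment study design as cohort configurations.

    Experiment 1 (matrix 1-2-4-8): twelve subjects — eight drifting to the
    cooperative group vector, four held near the non-cooperative vector —
    plus a four-subject arm that continues into a lever reversal.
    Experiment 2: six naive subjects on matrix 1-3-4-8, three cooperative
    (switched mid-course to the greater-temptation matrix 1-5-4-8) and
    three non-cooperative (switched to the low-contrast matrix 2-3-4-8).
    """
    tv = {k: v.as_tuple() for k, v in GROUP_TVS.items()}
    return {
        "cohorts": [
            {"group_name": "coop", "n_subjects": 8, "target": tv["coop"],
             "schedule": [["acquisition", "1-2-4-8"]]},
            {"group_name": "noncoop", "n_subjects": 4, "target": tv["noncoop"],
             "start": tv["noncoop"],  # stationary from the outset
             "schedule": [["acquisition", "1-2-4-8"]]},
            {"group_name": "reversal", "n_subjects": 4, "target": tv["coop"],
             "schedule": [["acquisition", "1-2-4-8"], ["reversal", "1-2-4-8"]],
             "phase_targets": {"reversal": tv["reversal"]},
             "reversal": True},
            {"group_name": "treat-A", "n_subjects": 3, "target": tv["treat2A"],
             "schedule": [["treat2", "1-3-4-8"], ["treat3", "1-5-4-8"]],
             "phase_targets": {"treat3": tv["treat3A"]}},
            {"group_name": "treat-B", "n_subjects": 3, "target": tv["treat2B"],
             "schedule": [["treat2", "1-3-4-8"], ["treat3", "2-3-4-8"]],
             "phase_targets": {"treat3": tv["treat3B"]}},
        ],
    }


def _cohort_from_plan(entry: dict, seed: int) -> CohortConfig:
    return CohortConfig(
        group_name=entry["group_name"],
        n_subjects=entry["n_subjects"],
        target_tv=TransitionVector(*entry["target"]),
        start_tv=TransitionVector(*entry.get("start", CHANCE_TV.as_tuple())),
        sessions_to_criterion_mean=entry.get("sessions_to_criterion_mean", 30.0),
        sessions_to_criterion_sd=entry.get("sessions_to_criterion_sd", 4.0),
        n_trials_per_session=entry.get("n_trials_per_session", 30),
        sessions_per_day=entry.get("sessions_per_day", 2),
        n_stable_sessions=entry.get("n_stable_sessions", 5),
        matrix_schedule=tuple((p, m) for p, m in entry["schedule"]),
        phase_targets=tuple((k, tuple(v)) for k, v in
                            entry.get("phase_targets", {}).items()),
        reversal=entry.get("reversal", False),
        seed=seed,
    )


def generate_experiment(study_plan: dict | None = None,
                        seed: int = 0) -> ExperimentBundle:
    """Generate every cohort of the study plan into one replayable bundle.

    Each cohort gets a sub-seed derived from ``seed`` and its position, so
    the bundle is byte-identical across runs with the same plan and seed.
    """
    plan = study_plan or default_study_plan()
    sessions: list[SessionLog] = []
    manifest: dict = {"seed": seed, "cohorts": []}
    for pos, entry in enumerate(plan["cohorts"]):
        cohort_seed = int(np.random.SeedSequence([seed, pos]).generate_state(1)[0]
                          % (2**31))
        config = _cohort_from_plan(entry, cohort_seed)
        logs = generate_cohort(config)
        sessions.extend(logs)
        boundaries: dict[str, list] = {}
        for log in logs:
            boundaries.setdefault(log.subject_id, []).append(
                [log.session_index, log.phase, log.matrix_label])
        manifest["cohorts"].append({
            **entry,
            "cohort_seed": cohort_seed,
            "n_sessions": len(logs),
            "phase_boundaries": {
                sid: [b for i, b in enumerate(rows)
                      if i == 0 or rows[i - 1][1] != b[1]]
                for sid, rows in boundaries.items()
            },
        })
    return ExperimentBundle(sessions=sessions, manifest=manifest)
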