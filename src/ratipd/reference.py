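"""Reference configurations: payoff matrices and group-level strategies.

These are the payoff matrices of the two-experiment rat protocol this
package models, and the group-average memory-one transition vectors and
occupancy distributions estimated for its cohorts.  The synthetic-data
generator drifts subjects toward these vectors, and the chain analysis
checks that each vector's stationary distribution is consistent with the
group's reported cooperation level and state occupancy.
"""

from __future__ import annotations

from .agents import TransitionVector
from .game import PayoffMatrix

__all__ = [
    "MATRICES",
    "STANDARD_ALL_PELLET_MATRIX",
    "GROUP_TVS",
    "GROUP_COOPERATION",
    "GROUP_OCCUPANCY",
]

#: Experimental matrices keyed by label: (p_r, p_t) pellets, (p_p, p_s)
#: timeout seconds.  "1-2-4-8" is the first experiment's matrix; the others
#: are the greater-temptation and low-contrast variants of the second.
MATRICES: dict[str, PayoffMatrix] = {
    "1-2-4-8": PayoffMatrix(p_r=1, p_t=2, p_p=4, p_s=8, label="1-2-4-8"),
    "1-3-4-8": PayoffMatrix(p_r=1, p_t=3, p_p=4, p_s=8, label="1-3-4-8"),
    "1-5-4-8": PayoffMatrix(p_r=1, p_t=5, p_p=4, p_s=8, label="1-5-4-8"),
    "2-3-4-8": PayoffMatrix(p_r=2, p_t=3, p_p=4, p_s=8, label="2-3-4-8"),
}

#: Classic "addable" matrix in which every cell pays pellets
#: (T=6, R=4, P=1, S=0): the benchmark for the 16-vs-12-pellet contrast
#: argument about why purely positive matrices discriminate poorly.
STANDARD_ALL_PELLET_MATRIX = PayoffMatrix(
    p_r=4, p_t=6, p_p=1, p_s=0, label="standard-6-4-1-0", all_pellet_mode=True,
)

#: Group-average transition vectors (p(c|T), p(c|R), p(c|S), p(c|P)).
GROUP_TVS: dict[str, TransitionVector] = {
    "coop": TransitionVector(0.76, 0.85, 0.93, 0.87),
    "noncoop": TransitionVector(0.44, 0.38, 0.32, 0.32),
    "reversal": TransitionVector(0.86, 0.89, 1.00, 0.82),
    "treat2A": TransitionVector(0.65, 0.90, 0.87, 0.94),
    "treat2B": TransitionVector(0.47, 0.55, 0.56, 0.65),
    "treat3A": TransitionVector(0.45, 0.64, 0.62, 0.78),
    "treat3B": TransitionVector(0.62, 0.66, 0.67, 0.66),
}

#: Reported group-mean cooperation rates (fraction of C choices).
GROUP_COOPERATION: dict[str, float] = {
    "coop": 0.86,
    "noncoop": 0.36,
    "reversal": 0.87,
    "treat2A": 0.87,
    "treat2B": 0.64,
    "treat3A": 0.61,
    "treat3B": 0.71,
}

#: Reported empirical occupancy (p_T, p_R, p_S, p_P) for the first
#: experiment's groups.
GROUP_OCCUPANCY: dict[str, tuple[float, float, float, float]] = {
    "coop": (0.10, 0.76, 0.10, 0.04),
    "noncoop": (0.25, 0.19, 0.23, 0.33),
}
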