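# ratipd

Tools for modeling and analyzing iterated Prisoner's Dilemma (iPD)
experiments in which a rodent plays against a Tit-for-Tat (TFT) opponent for
food pellets (positive reinforcement) and timeouts (negative reinforcement).
The package is aimed at behavioral researchers who want to simulate such
operant protocols, infer the strategies animals adopt from trial-level
session logs, and reason about how the payoff matrix itself shapes the
economics of cooperation.

## The model

Each trial, the subject chooses to cooperate (C) or defect (D); the TFT
opponent cooperates on trial 0 and thereafter copies the subject's previous
choice. The joint choice yields one of four outcome states — R (mutual
cooperation, `P_R` pellets), T (unilateral defection, `P_T` pellets), S
(unilateral cooperation, `P_S` seconds timeout), P (mutual defection, `P_P`
seconds timeout).

Subjects are modeled as **memory-one stochastic strategies**: a transition
vector `(p(c|T), p(c|R), p(c|S), p(c|P))` gives the probability of
cooperating after each previous outcome. Against TFT this induces a Markov
chain on the four states — from R or S the chain moves to R with the
state's cooperation probability (else T); from T or P it moves to S (else
P) — whose stationary distribution π is the model-implied state occupancy,
and `π_R + π_S` the implied long-run cooperation rate. The package solves
π exactly from the linear system `π M = π`.

Matrix economics are summarized by the contrast index
`CI = (P_T − P_R)/(P_T + P_R)`, the cooperation-favoring condition
`2 P_R > P_T + P_S` (with S valued as a non-positive pellet equivalent),
and an exhaustive best-strategy search over the 32 deterministic memory-one
rules (which include ALLC, ALLD and the C/D alternator), evaluated exactly
by cycle detection on their deterministic orbits against TFT.

Modules:

| module | contents |
| --- | --- |
| `ratipd.game` | actions, states, payoff matrices, timing, session simulation, CSV/JSON I/O |
| `ratipd.agents` | memory-one and named deterministic policies |
| `ratipd.inference` | strategy summaries, chain construction, stationary solve, cooperation criterion |
| `ratipd.matrix_analysis` | contrast index, best-strategy search, normalized reward |
| `ratipd.population` | fixed-cooperation population baseline and separation line |
| `ratipd.stats_report` | rank-sum, chi-square vs chance, one-way ANOVA contracts |
| `ratipd.synthetic` | synthetic cohorts with acquisition drift, reversal and matrix switches |

## Worked example

A four-trial session against TFT under a classic all-pellet matrix
(T=6, R=4, P=1, S=0) versus the pellet/timeout matrix (1, 2, 4 s, 8 s):

```python
from ratipd import FixedSequence, play_session, total_reward, total_timeout
from ratipd.reference import MATRICES, STANDARD_ALL_PELLET_MATRIX

for matrix in (STANDARD_ALL_PELLET_MATRIX, MATRICES["1-2-4-8"]):
    for seq in ("CCCC", "CDDD"):
        log = play_session(FixedSequence(seq), matrix, n_trials=4)
        print(matrix.label, seq, total_reward(log), total_timeout(log))
```

```
standard-6-4-1-0 CCCC 16 0.0
standard-6-4-1-0 CDDD 12 0.0
1-2-4-8 CCCC 4 0.0
1-2-4-8 CDDD 3 8.0
```

Under the all-pellet matrix a single opening cooperation followed by
defection still earns 12 of the 16 pellets that full cooperation pays — a
25% difference; under the pellet/timeout matrix the same comparison is 3
pellets plus 8 s of timeout versus 4 pellets and none, a far sharper
contrast. Chain analysis of a highly cooperative group-average strategy:

```python
from ratipd import TransitionVector, build_chain, predicted_cooperation

tv = TransitionVector(0.76, 0.85, 0.93, 0.87)   # p(c|T), p(c|R), p(c|S), p(c|P)
pi = build_chain(tv).stationary
print(f"R={pi.p_R:.3f} T={pi.p_T:.3f} S={pi.p_S:.3f} P={pi.p_P:.3f}")
print(f"implied cooperation: {predicted_cooperation(tv):.3f}")
```

```
R=0.731 T=0.118 S=0.118 P=0.033
implied cooperation: 0.849
```

The subject spends 73% of trials in mutual cooperation and cooperates on
85% of trials in the long run — consistent with the observed occupancy and
cooperation rate of the group this vector summarizes.

A CLI mirrors the library: `ratipd analyze-matrix`, `ratipd popsim`,
`ratipd simulate` (synthetic cohorts) and `ratipd report` (group tables and
chance tests from session CSVs).

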