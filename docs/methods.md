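# Methods

## Game engine

A trial is a simultaneous choice by the subject (C or D) and the
Tit-for-Tat opponent (C on trial 0, then a copy of the subject's previous
choice). The payoff matrix mixes units: R and T pay integer pellet counts,
S and P impose timeout seconds. Because pellets and seconds are not
commensurable, per-trial reinforcement is reported as the pair
(pellets, timeout) and never collapsed into one scalar. An
`all_pellet_mode` expresses classic matrices in which all four cells pay
pellets (e.g. T=6, R=4, P=1, S=0); in that mode no timeout exists and the
`p_s >= p_p` timeout ordering does not apply.

Trial duration is modeled as
`iti + response_latency + (eating + feeder_light if rewarded else timeout)`.
The component times (ITI 5 s, eating 5 s, feeder light 1 s, CS limit 45 s)
are protocol constants; the composition into a single duration is this
package's construction, used only for pellets-per-second comparisons.
Agents always respond (the 45 s stimulus window never elapses), so omitted
trials are not modeled. The opponent's own earnings (one pellet per FR-3
completion) are not tracked in any analysis: only the subject's payoff
stream matters for strategy economics.

## Memory-one strategies and the TFT-coupled chain

The behavioral model is a memory-one stochastic policy: a transition
vector `(p(c|T), p(c|R), p(c|S), p(c|P))`, plus a first-move cooperation
probability (default 0.5 — the first trial has no previous outcome and
subjects' opening bias is treated as unknown). All components 0.5 is
random responding.

Against TFT the previous outcome state pins the opponent's next move, so
the outcome process is a 4-state Markov chain with structural zeros: from
R and S only {R, T} are reachable, from T and P only {S, P}. The canonical
state order is (R, T, S, P) everywhere in memory; report columns that
follow the (T, R, S, P) convention are translated at the I/O boundary
only. The stationary distribution is solved from the linear system
`(M^T − I) π = 0` with a normalization row; an independent power-iteration
oracle runs on the lazy chain `(M + I)/2` so that periodic chains (the
deterministic alternator's T–S cycle) still converge. A structural
consequence used as an internal consistency check: every defection (into
T or P) is mirrored by the opponent one trial later, forcing `π_T = π_S`
exactly.

Reducible chains (vectors with 0/1 components that create absorbing sets)
return the stationary of the recurrent class reachable from R — the state
adjacent to the experiment's start, since the opponent opens with C — with
a `reducible` flag rather than an error.

Transition vectors are estimated by conditional counting of
(previous state, current action) pairs within sessions; trial 0 of each
session is skipped (no previous state is imputed) and pairs never straddle
session boundaries. Components never observed are NaN, never 0/0.

## Matrix economics

The contrast index `(P_T − P_R)/(P_T + P_R)` is evaluated as an exact
rational. The cooperation-favoring condition `2 P_R > P_T + s_equiv`
takes the pellet-equivalent value of the S timeout as an explicit
non-positive parameter defaulting to 0; at that default the (1, 2) matrix
sits exactly on the boundary, and any negative valuation of the 8 s
sucker timeout tips it toward cooperation. The parameter is never
hard-coded away.

The best-strategy search enumerates the 32 deterministic memory-one rules
(4-state action table × first move), a closed set containing ALLC, ALLD
and the alternator. Against TFT each rule's state orbit enters a cycle
within four steps, so payoffs are computed exactly: the `*_per_trial` and
`*_per_second` fields are cycle averages (transient-independent — the
alternator earns exactly `P_T / 2` pellets per trial, tying ALLC precisely
when `P_T = 2 P_R`), while `total_pellets` / `total_timeout_s` are exact
finite-session sums equal to brute-force replay. Pareto optimality is
judged on (maximize pellets/trial, minimize timeout/trial) within the
evaluated set.

Normalized reward divides a session's pellet total by the pellet total of
the best strategy, where "best" is chosen by per-trial pellet rate with
ties broken by lower timeout (making timeout-free ALLC the benchmark at
the boundary matrix) and its total is evaluated at the session's exact
length. A session that exploits a favorable cycle cut can exceed 1 by at
most one temptation payoff; values are deliberately not clamped.

## Population baseline

The baseline population draws individuals as uniformly random permutations
of a fixed C/D composition — `round(level × n_trials)` cooperative choices,
default 60% of 30 trials, 100,000 individuals — rather than Bernoulli
per-trial draws (a `bernoulli_mode` flag provides the alternative).
Sequences are sampled with replacement; with ~8.6e7 possible 18-of-30
compositions, occasional duplicates are accepted. The separation line is
an ordinary least-squares fit of total reward on total timeout. Subjects
are classified above/on/below by the sign of the residual with a 1e-9
tolerance for "on".

## Statistics

The reporting tests are thin contracts over scipy.stats: two-sided
Wilcoxon rank-sum (exact null when both n ≤ 10 and no ties, else normal
approximation with continuity correction), 1-df chi-square goodness of fit
of cooperation counts against chance 0.5 with a Bonferroni threshold of
alpha/4 over the four transition-vector components (0.0125 at alpha 0.05),
and one-way ANOVA across the four state occupancies with Bonferroni-
corrected pairwise rank-sum post-hocs run only when the omnibus test is
significant. The statistical unit is always an explicit argument
(per-subject summaries by default); the module never touches raw logs.
Golden fixtures computed with an independent R implementation pin all three
tests to 1e-8.

## Synthetic cohorts

The generator emulates the study's structure: sessions of 30 trials, two
per day, cohorts whose transition vectors drift componentwise linearly
from chance (0.5, 0.5, 0.5, 0.5) to a group target over a per-subject
horizon drawn as `round(N(30, 4))` truncated at ≥ 5 sessions, then held at
target for a stable block (default 5 sessions, the criterion's length).
The linear drift is a phenomenological stand-in for acquisition — no
learning rule is claimed or fitted — and is isolated so other acquisition
curves can be substituted. The 30 ± 4 horizon spread is exposed as a free
parameter (the source statistic is a mean ± s.e.m.; the generator treats
it as a per-subject spread).

Reversal phases model the lever swap as a restart of the drift from chance
to the (post-reversal) target over half the acquisition horizon; matrix
switches drift from the previous target to the new phase's target under
the new matrix, also over half the horizon. Non-cooperative cohorts are
held at their vector throughout (no drift) by setting start = target. The
default study plan emits the two-experiment design: 8 cooperative + 4
non-cooperative subjects on the (1, 2, 4, 8) matrix, a 4-subject reversal
arm, and two 3-subject arms that switch from (1, 3, 4, 8) to (1, 5, 4, 8)
and (2, 3, 4, 8) respectively. Everything is reproducible: cohorts derive
sub-seeds from the experiment seed via `numpy.random.SeedSequence`, and
re-running a plan with the same seed yields byte-identical CSVs.

What the generator does *not* emulate: within-session nonstationarity,
satiety or motivation drift, response omissions and latency variation,
individual differences beyond the criterion-horizon draw, and any
closed-loop learning. Passing recovery tests therefore show that the
inference pipeline is correct for memory-one behavior, not that real
subjects are memory-one.

## Problem sizes and numerical choices

Stationary solves are exact linear algebra on 4×4 systems; the
power-iteration oracle uses tolerance 1e-12. Simulation-based checks use:
10,000-trial logs for single-agent parameter recovery (binomial error
< 0.05 per component with high margin), cohorts of 8 × 30 stable sessions
for end-to-end recovery, 10^6 chain steps × 100 random vectors for the
analytic-vs-simulated occupancy equivalence (tolerance 0.01), 100,000
individuals for the population baseline, and 1,000 replicates for the
separation-line classification check (≥ 95% expected on each side). Chain
agreement with reported group statistics is asserted at 0.05 absolute —
the reported empirical occupancies are not exactly the stationary
distributions of the reported rounded vectors (e.g. 0.76 observed vs 0.731
implied for the cooperative group's R state), and 0.05 covers that
estimation gap without hiding transposition or construction errors.

## Known limitations

Only TFT opponents are modeled; strategy search covers memory-one
deterministic rules, not history-dependent strategies; no evolutionary or
learning dynamics; the criterion classifier assumes per-session rates are
supplied in chronological order.
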