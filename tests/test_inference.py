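"""Strategy inference and Markov-chain analysis of the TFT-coupled game."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ratipd import (
    AllC,
    CriterionConfig,
    FixedSequence,
    MemoryOne,
    OutcomeState,
    TransitionVector,
    build_chain,
    classify_cooperator,
    play_session,
    predicted_cooperation,
    simulate_occupancy,
    stationary_by_power_iteration,
    summarize,
)
from ratipd.inference import write_group_table
from ratipd.reference import GROUP_TVS


class TestSummarize:
    def test_cooperation_rate_is_count_ratio(self, matrix1):
        seq = "C" * 18 + "D" * 12
        log = play_session(FixedSequence(seq), matrix1, n_trials=30)
        assert summarize([log]).cooperation_rate == pytest.approx(0.6)

    def test_allc_log_single_state(self, matrix1):
        """ALLC vs TFT only ever visits R: occupancy 1, other components NaN."""
        log = play_session(AllC(), matrix1, n_trials=30)
        summ = summarize([log])
        assert summ.occupancy.p_R == 1.0
        assert summ.transition_estimate[OutcomeState.R] == 1.0
        for state in (OutcomeState.T, OutcomeState.S, OutcomeState.P):
            assert math.isnan(summ.transition_estimate[state])
            assert summ.transition_counts[state] == (0, 0)
        with pytest.raises(ValueError):
            summ.transition_vector()

    def test_no_pairing_across_session_boundaries(self, matrix1):
        """Counts from two sessions equal the sum of per-session counts."""
        a = play_session(FixedSequence("CCDD"), matrix1, n_trials=4)
        b = play_session(FixedSequence("DDCC"), matrix1, n_trials=4)
        pooled = summarize([a, b]).transition_counts
        separate = [summarize([s]).transition_counts for s in (a, b)]
        for state in OutcomeState:
            assert pooled[state][0] == sum(c[state][0] for c in separate)
            assert pooled[state][1] == sum(c[state][1] for c in separate)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            summarize([])


class TestBuildChain:
    def test_allc_vector_absorbs_in_r(self):
        chain = build_chain(TransitionVector(1, 1, 1, 1))
        assert chain.stationary.as_array() == pytest.approx([1, 0, 0, 0])
        assert chain.reducible

    def test_cooperative_group_stationary(self):
        """Frozen linear-solve values for the cooperative group's vector."""
        chain = build_chain(GROUP_TVS["coop"])
        assert chain.stationary.as_array() == pytest.approx(
            [0.731489, 0.117982, 0.117982, 0.032547], abs=1e-6)
        assert not chain.reducible

    def test_structural_zeros_of_tft_coupling(self):
        M = build_chain(GROUP_TVS["coop"]).transition_matrix
        # rows ordered R,T,S,P; from R and S only {R,T}; from T and P only {S,P}
        assert M[0, 2] == M[0, 3] == 0
        assert M[2, 2] == M[2, 3] == 0
        assert M[1, 0] == M[1, 1] == 0
        assert M[3, 0] == M[3, 1] == 0
        assert M.sum(axis=1) == pytest.approx([1, 1, 1, 1])

    def test_undefined_component_rejected(self):
        tv = TransitionVector(0.5, 0.5, 0.5, 0.5)
        object.__setattr__(tv, "p_c_given_P", float("nan"))
        with pytest.raises(ValueError):
            build_chain(tv)

    @pytest.mark.parametrize("name", sorted(GROUP_TVS))
    def test_linear_solve_matches_power_iteration(self, name):
        chain = build_chain(GROUP_TVS[name])
        power = stationary_by_power_iteration(GROUP_TVS[name])
        assert chain.stationary.as_array() == pytest.approx(power, abs=1e-9)

    @pytest.mark.parametrize("name", sorted(GROUP_TVS))
    def test_flow_balance_pi_t_equals_pi_s(self, name):
        """Every subject defection (into T or P) is mirrored one trial later,
        forcing equal stationary mass in T and S."""
        pi = build_chain(GROUP_TVS[name]).stationary
        assert pi.p_T == pytest.approx(pi.p_S, abs=1e-12)

    def test_simulated_occupancy_approximates_stationary(self):
        tv = GROUP_TVS["coop"]
        occ = simulate_occupancy(tv, n_steps=100_000, seed=4)
        assert occ == pytest.approx(build_chain(tv).stationary.as_array(),
                                    abs=0.02)


class TestPredictedCooperation:
    def test_alld_vector_never_cooperates(self):
        assert predicted_cooperation(TransitionVector(0, 0, 0, 0)) == 0.0

    @pytest.mark.parametrize("name, expected", [
        ("coop", 0.849471),
        ("noncoop", 0.355388),
        ("reversal", 0.896043),
        ("treat2A", 0.876057),
        ("treat3A", 0.614865),
    ])
    def test_group_vectors_frozen_values(self, name, expected):
        assert predicted_cooperation(GROUP_TVS[name]) == pytest.approx(
            expected, abs=1e-6)

    def test_monotone_in_each_component(self):
        """Raising any conditional cooperation probability cannot lower the
        long-run cooperation rate (checked on a coarse grid)."""
        grid = [0.1, 0.4, 0.7]
        for base in [(a, b, c, d) for a in grid for b in grid
                     for c in grid for d in grid]:
            p0 = predicted_cooperation(TransitionVector(*base))
            for i in range(4):
                bumped = list(base)
                bumped[i] += 0.25
                assert predicted_cooperation(TransitionVector(*bumped)) >= p0 - 1e-12


@settings(max_examples=15, deadline=None, derandomize=True)
@given(st.tuples(*[st.floats(0.15, 0.85) for _ in range(4)]))
def test_round_trip_recovery_of_memory_one_vector(tv_components):
    """summarize(simulate(memory_one(tv))) recovers tv within sampling error."""
    from ratipd.reference import MATRICES
    tv = TransitionVector(*tv_components)
    log = play_session(MemoryOne(tv), MATRICES["1-2-4-8"], n_trials=10_000,
                       seed=123)
    est = summarize([log]).transition_estimate
    truth = dict(zip((OutcomeState.T, OutcomeState.R, OutcomeState.S,
                      OutcomeState.P), tv.as_tuple()))
    for state, true_p in truth.items():
        assert est[state] == pytest.approx(true_p, abs=0.05)


@pytest.mark.parametrize("rates, expected", [
    ([0.5, 0.7, 0.7, 0.7, 0.7, 0.7], (True, 1)),
    ([0.6] * 10, (False, None)),           # strict inequality at the threshold
    ([0.9, 0.9, 0.9, 0.9], (False, None)),  # run too short
    ([0.7] * 5, (True, 0)),
    ([0.7, 0.7, 0.5, 0.7, 0.7, 0.7, 0.7, 0.7], (True, 3)),
])
def test_cooperator_criterion(rates, expected):
    assert classify_cooperator(rates) == expected


def test_cooperator_criterion_is_configurable():
    rates = [0.55, 0.55, 0.55]
    assert classify_cooperator(
        rates, CriterionConfig(threshold=0.5, consecutive_sessions=3)) == (True, 0)
    with pytest.raises(ValueError):
        classify_cooperator([])


def test_group_table_layout(tmp_path, matrix1):
    logs_a = [play_session(MemoryOne(GROUP_TVS["coop"]), matrix1,
                           n_trials=30, seed=s) for s in range(3)]
    summaries = {"coop": [summarize([log]) for log in logs_a]}
    path = tmp_path / "table.csv"
    write_group_table(summaries, path)
    header, row = path.read_text().strip().split("\n")
    assert header.split(",")[:4] == ["group", "n_subjects",
                                    "cooperation_mean", "cooperation_sem"]
    fields = row.split(",")
    assert fields[0] == "coop"
    assert fields[1] == "3"
    mean = float(fields[2])
    assert mean == pytest.approx(
        np.mean([s.cooperation_rate for s in summaries["coop"]]), abs=1e-6)
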