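"""Payoff-matrix economics: contrast index, best strategies, normalized reward."""

from fractions import Fraction

import pytest

from ratipd import (
    AllD,
    FixedSequence,
    PayoffMatrix,
    TimingModel,
    contrast_index,
    evaluate_strategies,
    favors_cooperation,
    normalized_reward,
    play_session,
)
from ratipd.agents import MemoryOne, TransitionVector
from ratipd.matrix_analysis import (
    contrast_index_from_rewards,
    deterministic_memory_one_ids,
    evaluate_strategy,
)
from ratipd.reference import MATRICES


@pytest.mark.parametrize("p_r, p_t, expected", [
    (1, 2, Fraction(1, 3)),
    (2, 3, Fraction(1, 5)),
    (1, 3, Fraction(1, 2)),
    (1, 5, Fraction(2, 3)),
    (1, 1, Fraction(0)),  # symmetric rewards: zero contrast
])
def test_contrast_index_values(p_r, p_t, expected):
    assert contrast_index_from_rewards(p_r, p_t).value == expected


def test_contrast_index_of_matrix(matrix1):
    assert contrast_index(matrix1).value == Fraction(1, 3)


def test_contrast_index_scale_invariance():
    for k in (2, 3, 7):
        assert (contrast_index_from_rewards(2 * k, 3 * k).value
                == contrast_index_from_rewards(2, 3).value)


def test_contrast_index_zero_denominator():
    with pytest.raises(ZeroDivisionError):
        contrast_index_from_rewards(0, 0)


class TestFavorsCooperation:
    def test_boundary_matrix_needs_negative_sucker_value(self, matrix1):
        # 2*1 > 2 + 0 fails at equality; any timeout aversion tips it
        assert not favors_cooperation(matrix1, sucker_pellet_equivalent=0)
        assert favors_cooperation(matrix1, sucker_pellet_equivalent=-0.5)

    def test_clear_cases(self):
        assert favors_cooperation(MATRICES["2-3-4-8"])       # 4 > 3
        assert not favors_cooperation(MATRICES["1-5-4-8"])   # 2 > 5 fails

    def test_positive_sucker_equivalent_rejected(self, matrix1):
        with pytest.raises(ValueError):
            favors_cooperation(matrix1, sucker_pellet_equivalent=0.1)


class TestEvaluateStrategies:
    def _by_id(self, matrix, n_trials=30):
        return {e.strategy_id: e
                for e in evaluate_strategies(matrix, TimingModel(), n_trials)}

    def test_boundary_matrix_allc_pareto_dominates(self, matrix1):
        evals = self._by_id(matrix1)
        allc, alt = evals["allc"], evals["alternator"]
        assert allc.pellets_per_trial == 1.0
        assert allc.timeout_s_per_trial == 0.0
        assert alt.pellets_per_trial == 1.0       # p_t / 2, ties ALLC exactly
        assert alt.timeout_s_per_trial == 4.0     # p_s / 2
        assert allc.is_pareto_optimal
        assert not alt.is_pareto_optimal          # same pellets, more timeout
        assert allc.pellets_per_second > alt.pellets_per_second

    @pytest.mark.parametrize("label, alt_rate", [
        ("1-3-4-8", 1.5),
        ("1-5-4-8", 2.5),
    ])
    def test_greater_temptation_favors_alternation(self, label, alt_rate):
        evals = self._by_id(MATRICES[label])
        assert evals["alternator"].pellets_per_trial == alt_rate
        assert evals["alternator"].pellets_per_trial > evals["allc"].pellets_per_trial

    @pytest.mark.parametrize("p_r, p_t", [(1, 2), (1, 3), (2, 3), (1, 5),
                                          (2, 5), (3, 4), (2, 4)])
    def test_alternator_vs_allc_boundary_property(self, p_r, p_t):
        """Alternation out-earns ALLC per trial iff p_t > 2 p_r, exactly."""
        matrix = PayoffMatrix(p_r=p_r, p_t=p_t, p_p=4, p_s=8)
        evals = self._by_id(matrix)
        diff = evals["alternator"].pellets_per_trial - evals["allc"].pellets_per_trial
        if p_t > 2 * p_r:
            assert diff > 0
        elif p_t < 2 * p_r:
            assert diff < 0
        else:
            assert diff == 0

    def test_strategy_set_covers_all_memory_one_rules(self, matrix1):
        ids = deterministic_memory_one_ids()
        assert len(ids) == 32 and len(set(ids)) == 32
        evals = self._by_id(matrix1)
        assert set(ids) <= set(evals)

    @pytest.mark.parametrize("strategy_id", ["allc", "alld", "alternator",
                                             "m1:CDDCD", "m1:DCDCC", "m1:DDCCD"])
    @pytest.mark.parametrize("n_trials", [7, 30, 1000])
    def test_cycle_detection_matches_brute_force(self, matrix1, strategy_id,
                                                 n_trials):
        """Exact orbit accounting equals trial-by-trial simulation."""
        ev = evaluate_strategy(strategy_id, matrix1, TimingModel(), n_trials)
        named = {"allc": "m1:CCCCC", "alld": "m1:DDDDD", "alternator": "m1:CDCDC"}
        body = named.get(strategy_id, strategy_id).split(":")[1]
        first = 1.0 if body[0] == "C" else 0.0
        c = {s: (1.0 if a == "C" else 0.0) for s, a in zip("RTSP", body[1:])}
        policy = MemoryOne(TransitionVector(
            c["T"], c["R"], c["S"], c["P"], first_move_p_c=first))
        log = play_session(policy, matrix1, n_trials=n_trials, seed=0)
        assert ev.total_pellets == sum(t.pellets for t in log.trials)
        assert ev.total_timeout_s == sum(t.timeout_s for t in log.trials)

    def test_timeouts_never_help_pellets_per_second(self):
        """For a fixed pellet sequence, adding timeout lowers the reward rate."""
        fast = evaluate_strategy("alternator", MATRICES["1-3-4-8"],
                                 TimingModel(), 30)
        slow = evaluate_strategy(
            "alternator", PayoffMatrix(p_r=1, p_t=3, p_p=4, p_s=20), TimingModel(), 30)
        assert fast.pellets_per_trial == slow.pellets_per_trial
        assert slow.pellets_per_second < fast.pellets_per_second

    def test_n_trials_validation(self, matrix1):
        with pytest.raises(ValueError):
            evaluate_strategies(matrix1, TimingModel(), n_trials=1)


class TestNormalizedReward:
    def test_all_r_session_under_cooperation_matrix_is_one(self):
        matrix = MATRICES["2-3-4-8"]
        log = play_session(FixedSequence("C" * 30), matrix, n_trials=30)
        nr = normalized_reward(log, matrix)
        assert nr.value == 1.0
        assert nr.best_strategy_id == "allc"
        assert nr.best_session_reward == 60

    def test_alld_session_under_boundary_matrix(self, matrix1):
        """ALLD earns only the single opening temptation: 2 of 30 pellets."""
        log = play_session(AllD(), matrix1, n_trials=30)
        nr = normalized_reward(log, matrix1)
        assert nr.best_session_reward == 30
        assert nr.value == pytest.approx(2 / 30)

    def test_value_is_a_fraction_of_the_best(self, matrix1):
        log = play_session(FixedSequence("CD" * 15), matrix1, n_trials=30)
        nr = normalized_reward(log, matrix1)
        assert 0.0 <= nr.value <= 31 / 30  # alternation can beat ALLC's total by one T
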