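"""Hypothesis-set elimination, Bayes updating and experiment selection."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from helo import (
    ExperimentSpec,
    HypothesisSet,
    ValidationError,
    bayes_update,
    eliminate,
    entropy_bits,
    expected_information_gain,
    select_experiment,
    uniform_set,
)

SUM_TOL = 1e-9


def make_experiment(exp_id, members, table, cost=1.0):
    """table: rows (per member) of outcome probabilities."""
    outcomes = tuple(f"o{i}" for i in range(len(table[0])))
    likelihood = {
        m: dict(zip(outcomes, row)) for m, row in zip(members, table)
    }
    return ExperimentSpec(exp_id, cost, outcomes, likelihood)


def random_experiment(rng, members, n_outcomes, exp_id="e", cost=1.0):
    raw = rng.random((len(members), n_outcomes)) + 1e-3
    table = raw / raw.sum(axis=1, keepdims=True)
    return make_experiment(exp_id, members, table.tolist(), cost)


def mutual_information_oracle(hset, experiment):
    """Independent route: I(H; O) from the joint distribution."""
    joint = np.array(
        [
            [p * experiment.likelihood[m][o] for o in experiment.outcomes]
            for m, p in zip(hset.members, hset.probs)
        ]
    )
    ph = joint.sum(axis=1, keepdims=True)
    po = joint.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = joint * np.log2(joint / (ph * po))
    return float(np.nansum(terms))


class TestUniformSet:
    def test_eight_members_each_one_eighth(self):
        hset = uniform_set([f"h{i}" for i in range(8)])
        assert all(p == pytest.approx(0.125) for p in hset.probs)
        assert sum(hset.probs) == pytest.approx(1.0, abs=SUM_TOL)

    def test_single_member_gets_probability_one(self):
        assert uniform_set(["h"]).probs == (1.0,)

    def test_three_members_renormalized_exactly(self):
        hset = uniform_set(["a", "b", "c"])
        assert abs(sum(hset.probs) - 1.0) <= SUM_TOL

    @pytest.mark.parametrize("bad", [[], ["a", "a"]])
    def test_empty_or_duplicate_members_rejected(self, bad):
        with pytest.raises(ValidationError):
            uniform_set(bad)


class TestEliminate:
    def test_hand_renormalization(self):
        hset = HypothesisSet(("a", "b", "c"), (0.5, 0.3, 0.2))
        out = eliminate(hset, ["a"])
        assert out.members == ("b", "c")
        assert out.probs == pytest.approx((0.6, 0.4))

    def test_reject_none_is_identity(self):
        hset = uniform_set(["a", "b", "c"])
        assert eliminate(hset, []) == hset

    def test_rejecting_all_members_rejected(self):
        hset = uniform_set(["a", "b"])
        with pytest.raises(ValidationError, match="empty hypothesis set"):
            eliminate(hset, ["a", "b"])

    def test_survivors_strictly_increase(self):
        hset = uniform_set([f"h{i}" for i in range(8)])
        out = eliminate(hset, ["h0", "h1"])
        assert all(p > 0.125 for p in out.probs)

    def test_sequential_rejection_of_seven_leaves_survivor_at_one(self):
        hset = uniform_set([f"h{i}" for i in range(8)])
        for rejected in ["h1", "h2", "h3", "h4", "h5", "h6", "h7"]:
            hset = eliminate(hset, [rejected])
        assert hset.members == ("h0",)
        assert hset.probs[0] == pytest.approx(1.0, abs=SUM_TOL)

    def test_matches_bayes_update_with_indicator_likelihoods(self):
        """Elimination is Bayes with a 0/1 outcome-consistency likelihood."""
        rng = np.random.default_rng(9)
        for _ in range(25):
            n = int(rng.integers(3, 7))
            raw = rng.random(n) + 1e-3
            members = tuple(f"h{i}" for i in range(n))
            hset = HypothesisSet(members, tuple(raw / raw.sum()))
            n_rej = int(rng.integers(1, n))
            rejected = list(rng.choice(members, size=n_rej, replace=False))
            table = [
                [0.0, 1.0] if m in rejected else [1.0, 0.0] for m in members
            ]
            exp = make_experiment("ind", members, table)
            via_bayes = bayes_update(hset, exp, "o0")
            via_elim = eliminate(hset, rejected)
            for m in via_elim.members:
                assert via_bayes.probability_of(m) == pytest.approx(
                    via_elim.probability_of(m), abs=1e-12
                )
            for m in rejected:
                assert via_bayes.probability_of(m) == 0.0


class TestBayesUpdate:
    def test_equal_likelihoods_leave_set_unchanged(self):
        hset = HypothesisSet(("a", "b"), (0.7, 0.3))
        exp = make_experiment("e", ("a", "b"), [[0.5, 0.5], [0.5, 0.5]])
        out = bayes_update(hset, exp, "o0")
        assert out.probs == pytest.approx(hset.probs)

    def test_hand_arithmetic(self):
        hset = HypothesisSet(("a", "b"), (0.5, 0.5))
        exp = make_experiment("e", ("a", "b"), [[0.8, 0.2], [0.2, 0.8]])
        out = bayes_update(hset, exp, "o0")
        assert out.probs == pytest.approx((0.8, 0.2))

    def test_zero_likelihood_eliminates_hypothesis(self):
        hset = HypothesisSet(("a", "b"), (0.5, 0.5))
        exp = make_experiment("e", ("a", "b"), [[0.0, 1.0], [0.5, 0.5]])
        out = bayes_update(hset, exp, "o0")
        assert out.probability_of("a") == 0.0

    def test_impossible_outcome_rejected(self):
        hset = HypothesisSet(("a", "b"), (0.5, 0.5))
        exp = make_experiment("e", ("a", "b"), [[0.0, 1.0], [0.0, 1.0]])
        with pytest.raises(ValidationError, match="impossible"):
            bayes_update(hset, exp, "o0")

    def test_unknown_outcome_rejected(self):
        hset = HypothesisSet(("a", "b"), (0.5, 0.5))
        exp = make_experiment("e", ("a", "b"), [[0.5, 0.5], [0.5, 0.5]])
        with pytest.raises(ValidationError):
            bayes_update(hset, exp, "nope")


class TestEntropyAndGain:
    def test_entropy_known_values(self):
        assert entropy_bits(uniform_set([f"h{i}" for i in range(8)])) == pytest.approx(3.0)
        assert entropy_bits(HypothesisSet(("a", "b"), (1.0, 0.0))) == 0.0
        assert entropy_bits(
            HypothesisSet(("a", "b", "c"), (0.5, 0.25, 0.25))
        ) == pytest.approx(1.5)

    def test_uninformative_experiment_has_zero_gain(self):
        hset = uniform_set(["a", "b", "c"])
        exp = make_experiment("e", hset.members, [[0.3, 0.7]] * 3)
        assert expected_information_gain(hset, exp) == pytest.approx(0.0, abs=1e-12)

    def test_perfect_binary_experiment_gains_one_bit(self):
        hset = uniform_set(["a", "b"])
        exp = make_experiment("e", hset.members, [[1.0, 0.0], [0.0, 1.0]])
        assert expected_information_gain(hset, exp) == pytest.approx(1.0)

    def test_matches_mutual_information_oracle(self):
        rng = np.random.default_rng(13)
        for _ in range(40):
            raw = rng.random(3) + 1e-3
            hset = HypothesisSet(("a", "b", "c"), tuple(raw / raw.sum()))
            exp = random_experiment(rng, hset.members, 2)
            assert expected_information_gain(hset, exp) == pytest.approx(
                mutual_information_oracle(hset, exp), abs=1e-12
            )

    def test_malformed_likelihood_table_rejected(self):
        with pytest.raises(ValidationError):
            make_experiment("e", ("a", "b"), [[0.5, 0.6], [0.5, 0.5]])
        hset = uniform_set(["a", "b", "c"])
        exp = make_experiment("e", ("a", "b"), [[0.5, 0.5], [0.5, 0.5]])
        with pytest.raises(ValidationError, match="missing"):
            expected_information_gain(hset, exp)

    @given(st.integers(0, 10_000))
    @settings(derandomize=True, max_examples=120)
    def test_gain_bounded_by_entropy(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 6))
        raw = rng.random(n) + 1e-3
        hset = HypothesisSet(
            tuple(f"h{i}" for i in range(n)), tuple(raw / raw.sum())
        )
        exp = random_experiment(rng, hset.members, int(rng.integers(2, 5)))
        gain = expected_information_gain(hset, exp)
        assert -1e-12 <= gain <= entropy_bits(hset) + 1e-9


class TestSelectExperiment:
    def test_cheaper_of_equal_gains_wins(self):
        hset = uniform_set(["a", "b"])
        table = [[1.0, 0.0], [0.0, 1.0]]
        cheap = make_experiment("cheap", hset.members, table, cost=1.0)
        dear = make_experiment("dear", hset.members, table, cost=2.0)
        assert select_experiment(hset, [dear, cheap]) == "cheap"

    def test_all_zero_gain_falls_back_to_first_candidate(self, caplog):
        hset = uniform_set(["a", "b"])
        flat = [[0.5, 0.5], [0.5, 0.5]]
        e1 = make_experiment("e1", hset.members, flat)
        e2 = make_experiment("e2", hset.members, flat)
        with caplog.at_level("WARNING", logger="helo"):
            assert select_experiment(hset, [e1, e2]) == "e1"
        assert any("uninformative" in r.message for r in caplog.records)

    def test_empty_candidate_list_rejected(self):
        with pytest.raises(ValidationError):
            select_experiment(uniform_set(["a", "b"]), [])

    def test_matches_exhaustive_scoring_oracle(self):
        rng = np.random.default_rng(17)
        for _ in range(20):
            n = int(rng.integers(2, 6))
            raw = rng.random(n) + 1e-3
            hset = HypothesisSet(
                tuple(f"h{i}" for i in range(n)), tuple(raw / raw.sum())
            )
            pool = [
                random_experiment(
                    rng, hset.members, int(rng.integers(2, 4)),
                    exp_id=f"e{j}", cost=float(rng.uniform(0.5, 3.0)),
                )
                for j in range(int(rng.integers(1, 6)))
            ]
            scores = [
                expected_information_gain(hset, e) / (e.cost + 1e-9) for e in pool
            ]
            assert select_experiment(hset, pool) == pool[int(np.argmax(scores))].id


class TestConservation:
    @given(st.integers(0, 10_000))
    @settings(derandomize=True, max_examples=200)
    def test_sum_to_one_after_random_operation_sequences(self, seed):
        """Total probability mass is conserved by eliminate/bayes_update."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 9))
        hset = uniform_set([f"h{i}" for i in range(n)])
        for _ in range(int(rng.integers(1, 8))):
            if len(hset.members) > 1 and rng.random() < 0.5:
                n_rej = int(rng.integers(1, len(hset.members)))
                hset = eliminate(
                    hset,
                    list(rng.choice(hset.members, size=n_rej, replace=False)),
                )
            else:
                exp = random_experiment(rng, hset.members, int(rng.integers(2, 4)))
                outcome = exp.outcomes[int(rng.integers(len(exp.outcomes)))]
                hset = bayes_update(hset, exp, outcome)
            assert abs(sum(hset.probs) - 1.0) <= SUM_TOL
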