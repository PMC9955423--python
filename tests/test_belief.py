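"""Pretest prior inference, Bayesian updating, trajectories, convergence."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pupilsurprise.belief import (
    BeliefState,
    BeliefTrajectory,
    DegenerateBeliefError,
    convergence_trial,
    expected_response,
    pretest_prior,
    trajectory,
    update,
)
from pupilsurprise.stimuli import (
    Direction,
    Phase,
    Rule,
    Trial,
    outcome_likelihood,
    predict_direction,
    response_likelihood,
)
from .conftest import learning, make_trial


def oracle_update(weights, likelihoods):
    """Four-term arithmetic oracle for one Bayes step."""
    unnorm = [w * l for w, l in zip(weights, likelihoods)]
    total = sum(unnorm)
    return [u / total for u in unnorm]


class TestBeliefState:
    def test_must_sum_to_one(self):
        with pytest.raises(DegenerateBeliefError):
            BeliefState(np.zeros(4))
        with pytest.raises(ValueError):
            BeliefState(np.array([0.5, 0.5, -0.1, 0.1]))

    def test_drift_renormalized(self):
        b = BeliefState(np.array([0.3, 0.3, 0.3, 0.1 + 1e-9]))
        assert b.weights.sum() == pytest.approx(1.0, abs=1e-15)

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(st.lists(st.floats(0.001, 10), min_size=4, max_size=4))
    def test_states_sum_to_one_within_tolerance(self, raw):
        w = np.array(raw) / sum(raw)
        assert abs(BeliefState(w).weights.sum() - 1.0) <= 1e-12


class TestPretestPrior:
    def test_empty_input_is_uniform(self):
        assert pretest_prior([], []).allclose(BeliefState.uniform())

    def test_single_trial_hand_example(self, size_right_trial):
        # S predicts RIGHT, M and W predict LEFT; response 5, eta 0.1:
        # renormalize (0.25*0.45, 0.25/30, 0.25/30, 0.25*0.2)
        prior = pretest_prior([size_right_trial], [5], eta=0.1)
        expected = np.array([0.45, 0.1 / 3, 0.1 / 3, 0.2])
        expected /= expected.sum()
        np.testing.assert_allclose(prior.weights, expected, atol=1e-12)
        np.testing.assert_allclose(
            prior.weights, [0.6279, 0.0465, 0.0465, 0.2791], atol=5e-4
        )

    def test_noiseless_size_responder_recovered(self, size_right_trial, rng):
        # responses always assert the Size rule's predicted direction
        trials = [
            make_trial((1.0, 8.0), (2.0 + i * 0.1, 0.25), trial_index=i + 1)
            for i in range(10)
        ]
        responses = [
            {Direction.LEFT: 1, Direction.EQUAL: 3, Direction.RIGHT: 5}[
                predict_direction(Rule.SIZE, t)
            ]
            for t in trials
        ]
        prior = pretest_prior(trials, responses, eta=0.1)
        # oracle: exhaustive likelihood product per rule
        oracle = np.full(4, 0.25)
        for t, r in zip(trials, responses):
            oracle *= [response_likelihood(rule, t, r, 0.1) for rule in Rule]
        oracle /= oracle.sum()
        np.testing.assert_allclose(prior.weights, oracle, atol=1e-12)
        assert int(np.argmax(prior.weights)) == Rule.SIZE

    def test_outcome_bearing_trial_rejected(self, size_right_trial):
        bad = learning(size_right_trial, Direction.RIGHT)
        with pytest.raises(ValueError):
            pretest_prior([bad], [5])

    def test_length_mismatch_rejected(self, size_right_trial):
        with pytest.raises(ValueError):
            pretest_prior([size_right_trial], [5, 4])


class TestUpdate:
    def test_hard_likelihood_example(self, size_right_trial):
        # epsilon 0: S matches the outcome, M and W are contradicted
        trial = learning(size_right_trial, Direction.RIGHT)
        prior = BeliefState(np.array([0.4, 0.3, 0.2, 0.1]))
        post = update(prior, trial, epsilon=0.0)
        np.testing.assert_allclose(
            post.weights, oracle_update(prior.weights, [1, 0, 0, 1 / 3]), atol=1e-12
        )
        np.testing.assert_allclose(post.weights, [0.9231, 0, 0, 0.0769], atol=5e-5)

    def test_congruent_trial_no_change_without_random_mass(self, congruent_trial):
        trial = learning(congruent_trial, Direction.LEFT)
        prior = BeliefState(np.array([0.5, 0.25, 0.25, 0.0]))
        assert update(prior, trial, epsilon=0.0) == prior

    def test_uniform_prior_all_rules_match(self, congruent_trial):
        trial = learning(congruent_trial, Direction.LEFT)
        post = update(BeliefState.uniform(), trial, epsilon=0.0)
        np.testing.assert_allclose(post.weights, [0.3, 0.3, 0.3, 0.1], atol=1e-12)

    def test_zero_marginal_names_trial(self, size_right_trial):
        trial = learning(size_right_trial, Direction.RIGHT, index=7)
        prior = BeliefState(np.array([0.0, 0.6, 0.4, 0.0]))  # all contradicted
        with pytest.raises(DegenerateBeliefError, match="7"):
            update(prior, trial, epsilon=0.0)

    def test_posterior_prior_ratio_monotone_in_likelihood(self, size_right_trial):
        trial = learning(size_right_trial, Direction.RIGHT)
        prior = BeliefState(np.array([0.3, 0.3, 0.2, 0.2]))
        post = update(prior, trial, epsilon=0.1)
        ratios = post.weights / prior.weights
        liks = np.array(
            [outcome_likelihood(rule, trial, Direction.RIGHT, 0.1) for rule in Rule]
        )
        # pairwise: a larger likelihood never yields a smaller posterior/prior ratio
        for i in range(4):
            for j in range(4):
                assert (liks[i] - liks[j]) * (ratios[i] - ratios[j]) >= -1e-15

    def test_zero_weight_stays_zero(self, size_right_trial):
        trial = learning(size_right_trial, Direction.RIGHT)
        prior = BeliefState(np.array([0.5, 0.0, 0.25, 0.25]))
        post = update(prior, trial, epsilon=0.1)
        assert post[Rule.MATERIAL] == 0.0


class TestTrajectory:
    def test_empty_trials_returns_prior_only(self):
        traj = trajectory(BeliefState.uniform(), [], epsilon=0.1)
        assert len(traj) == 1 and traj[0] == BeliefState.uniform()

    def test_congruent_trials_inert(self, congruent_trial):
        trials = [learning(congruent_trial, Direction.LEFT, i + 1) for i in range(9)]
        prior = BeliefState(np.array([0.2, 0.4, 0.4, 0.0]))
        traj = trajectory(prior, trials, epsilon=0.0)
        assert len(traj) == 10
        for state in traj.states:
            assert state.allclose(prior)

    def test_mass_dominant_prior_converts_to_size(self, size_right_trial):
        trials = [learning(size_right_trial, Direction.RIGHT, i + 1) for i in range(10)]
        prior = BeliefState(np.array([0.05, 0.05, 0.85, 0.05]))
        traj = trajectory(prior, trials, epsilon=0.1)
        # oracle: repeated four-term update
        w = list(prior.weights)
        for t in trials:
            w = oracle_update(w, [outcome_likelihood(r, t, t.outcome, 0.1) for r in Rule])
        np.testing.assert_allclose(traj[-1].weights, w, atol=1e-12)
        assert int(np.argmax(traj[-1].weights)) == Rule.SIZE

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(
        raw=st.lists(st.floats(0.01, 5), min_size=4, max_size=4),
        n=st.integers(1, 5),
    )
    def test_batch_equals_product_posterior_at_epsilon_zero(
        self, raw, n
    ):
        # order invariance: sequential hard updating equals a single-step
        # posterior from the product of all likelihoods
        trial = learning(make_trial((1.0, 8.0), (3.0, 0.25)), Direction.RIGHT)
        trials = [learning(trial, Direction.RIGHT, i + 1) for i in range(n)]
        prior_w = np.array(raw) / sum(raw)
        traj = trajectory(BeliefState(prior_w), trials, epsilon=0.0)
        lik = np.array(
            [outcome_likelihood(r, trial, Direction.RIGHT, 0.0) for r in Rule]
        )
        oneshot = prior_w * lik**n
        np.testing.assert_allclose(
            traj[-1].weights, oneshot / oneshot.sum(), atol=1e-10
        )

    def test_repeating_confirming_trial_never_decreases_size_weight(
        self, size_right_trial
    ):
        trials = [learning(size_right_trial, Direction.RIGHT, i + 1) for i in range(15)]
        traj = trajectory(BeliefState.uniform(), trials, epsilon=0.1)
        sizes = traj.as_array()[:, Rule.SIZE]
        assert np.all(np.diff(sizes) >= -1e-15)

    def test_sum_to_one_along_trajectory(self, size_right_trial):
        trials = [learning(size_right_trial, Direction.RIGHT, i + 1) for i in range(20)]
        traj = trajectory(BeliefState.uniform(), trials, epsilon=0.1)
        np.testing.assert_allclose(traj.as_array().sum(axis=1), 1.0, atol=1e-12)


class TestConvergence:
    def test_first_threshold_crossing(self):
        traj = BeliefTrajectory(
            tuple(
                BeliefState(np.array(w))
                for w in [
                    (0.25, 0.25, 0.25, 0.25),
                    (0.6, 0.2, 0.15, 0.05),
                    (0.92, 0.04, 0.03, 0.01),
                ]
            )
        )
        assert convergence_trial(traj, Rule.SIZE, 10.0) == 2

    def test_flat_trajectory_never_converges(self):
        traj = BeliefTrajectory(tuple(BeliefState.uniform() for _ in range(5)))
        assert convergence_trial(traj, Rule.SIZE, 10.0) is None

    def test_consistent_evidence_converges_quickly(self, size_right_trial):
        trials = [learning(size_right_trial, Direction.RIGHT, i + 1) for i in range(10)]
        traj = trajectory(BeliefState.uniform(), trials, epsilon=0.1)
        t = convergence_trial(traj, Rule.SIZE, 10.0)
        # oracle: scan the exact trajectory for the first odds crossing
        states = traj.as_array()
        others = [r for r in Rule if r is not Rule.SIZE]
        expected = next(
            (
                k
                for k in range(1, len(states))
                if states[k, Rule.SIZE] / states[k, others].max() >= 10.0
            ),
            None,
        )
        assert t == expected and t is not None and t <= 10

    def test_threshold_must_exceed_one(self):
        traj = BeliefTrajectory((BeliefState.uniform(),))
        with pytest.raises(ValueError):
            convergence_trial(traj, Rule.SIZE, 1.0)


class TestExpectedResponse:
    def test_pure_size_believer_noiseless(self, size_right_trial):
        belief = BeliefState(np.array([1.0, 0.0, 0.0, 0.0]))
        assert expected_response(belief, size_right_trial, eta=0.0) == pytest.approx(4.5)

    def test_pure_size_believer_noisy(self, size_right_trial):
        belief = BeliefState(np.array([1.0, 0.0, 0.0, 0.0]))
        # (eta/3)(1+2+3) + ((1-eta)/2)(4+5) with eta = 0.1
        assert expected_response(belief, size_right_trial, eta=0.1) == pytest.approx(4.25)

    def test_pure_random_believer_is_midpoint(self, size_right_trial):
        belief = BeliefState(np.array([0.0, 0.0, 0.0, 1.0]))
        assert expected_response(belief, size_right_trial, eta=0.37) == pytest.approx(3.0)
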