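"""Belief states over the four candidate rules and Bayesian belief revision.

A child's belief is a probability 4-vector over (Size, Material, Mass,
Random). The pretest (no feedback) pins down an individualized prior from the
child's 5-point responses; the learning phase (feedback shown) then drives
sequential Bayesian updating against observed outcomes. Convergence onto the
correct Size rule is measured by posterior odds against the strongest
competitor.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .stimuli import (
    Direction,
    Phase,
    Rule,
    Trial,
    outcome_likelihood_vector,
    response_likelihood_matrix,
)

__all__ = [
    "BeliefState",
    "BeliefTrajectory",
    "DegenerateBeliefError",
    "pretest_prior",
    "update",
    "trajectory",
    "trajectory_array",
    "convergence_trial",
    "expected_response",
]

#: Drift tolerance on the sum-to-one invariant.
SUM_TOL = 1e-12


class DegenerateBeliefError(ValueError):
    """All hypotheses assigned zero probability to the observed data."""


@dataclass(frozen=True)
class BeliefState:
    """Normalized probability vector over (Size, Material, Mass, Random).

    Entries that reach exactly 0 stay 0 under Bayesian updating (zero prior
    mass cannot be revived by likelihood multiplication).
    """

    weights: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.shape != (4,):
            raise ValueError(f"belief vector must have 4 entries, got shape {w.shape}")
        if np.any(w < 0):
            raise ValueError(f"belief weights must be nonnegative, got {w}")
        total = w.sum()
        if total <= 0:
            raise DegenerateBeliefError("belief vector has zero total mass")
        if abs(total - 1.0) > SUM_TOL:
            # defensive renormalization when drift exceeds tolerance
            w = w / total
        object.__setattr__(self, "weights", w)
        self.weights.setflags(write=False)

    @classmethod
    def uniform(cls) -> "BeliefState":
        return cls(np.full(4, 0.25))

    def __getitem__(self, rule: Rule) -> float:
        return float(self.weights[rule])

    def as_array(self) -> np.ndarray:
        return np.array(self.weights)

    def __eq__(self, other: object) -> bool:  # value semantics
        if not isinstance(other, BeliefState):
            return NotImplemented
        return bool(np.array_equal(self.weights, other.weights))

    def allclose(self, other: "BeliefState", atol: float = 1e-12) -> bool:
        return bool(np.allclose(self.weights, other.weights, atol=atol, rtol=0))


@dataclass(frozen=True)
class BeliefTrajectory:
    """Belief states at t = 0..T; state 0 is the pretest-derived prior."""

    states: tuple[BeliefState, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "states", tuple(self.states))
        if not self.states:
            raise ValueError("a trajectory needs at least the prior state")

    def __len__(self) -> int:
        return len(self.states)

    def __getitem__(self, t: int) -> BeliefState:
        return self.states[t]

    def as_array(self) -> np.ndarray:
        return np.stack([s.weights for s in self.states])


def pretest_prior(
    pretest_trials: Sequence[Trial],
    responses: Sequence[int],
    eta: float = 0.1,
) -> BeliefState:
    """Infer a child's prior belief from pretest responses (Stage 1).

    Starting from the uniform vector, multiplies in the response likelihood
    of each (trial, response) pair per rule and renormalizes at the end. No
    feedback is shown at pretest, so responses — not outcomes — carry the
    evidence about which rule the child holds.
    """
    if len(pretest_trials) != len(responses):
        raise ValueError(
            f"got {len(pretest_trials)} trials but {len(responses)} responses"
        )
    weights = np.full(4, 0.25)
    for trial, response in zip(pretest_trials, responses):
        if trial.outcome is not None:
            raise ValueError(f"pretest trial {trial.trial_index} carries an outcome")
        weights = weights * response_likelihood_matrix(trial, eta)[:, response - 1]
    if weights.sum() <= 0:
        raise DegenerateBeliefError(
            "pretest responses have zero likelihood under every rule"
        )
    return BeliefState(weights / weights.sum())


def update(
    belief: BeliefState,
    trial: Trial,
    outcome: Direction | None = None,
    epsilon: float = 0.1,
) -> BeliefState:
    """One step of Bayesian updating against an observed outcome.

    posterior_i ∝ prior_i * p(outcome | rule_i); the posterior/prior ratio is
    monotone in the likelihood, so the best-supported rules gain weight.
    """
    if outcome is None:
        outcome = trial.outcome
    if outcome is None:
        raise ValueError(f"trial {trial.trial_index} has no outcome to update on")
    likelihood = outcome_likelihood_vector(trial, outcome, epsilon)
    unnorm = belief.weights * likelihood
    total = unnorm.sum()
    if total <= 0:
        raise DegenerateBeliefError(
            f"trial {trial.trial_index}: zero marginal probability for outcome "
            f"{outcome.letter} (epsilon={epsilon} with all prior mass on "
            "contradicted rules)"
        )
    return BeliefState(unnorm / total)


def trajectory_array(prior: np.ndarray, likelihoods: np.ndarray) -> np.ndarray:
    """Fast path: states (T+1, 4) from a prior and per-trial likelihood rows.

    Row t of ``likelihoods`` holds p(outcome_t | rule) for the four rules.
    Sequential renormalized updating equals normalizing the running product
    (normalization is projective), so the whole trajectory is one cumprod.
    """
    prior = np.asarray(prior, dtype=float)
    likelihoods = np.asarray(likelihoods, dtype=float)
    if likelihoods.size == 0:
        return prior[None, :].copy()
    unnorm = prior[None, :] * np.cumprod(likelihoods, axis=0)
    totals = unnorm.sum(axis=1, keepdims=True)
    if np.any(totals <= 0):
        t = int(np.argmax(totals.ravel() <= 0))
        raise DegenerateBeliefError(
            f"zero marginal probability at learning trial {t + 1}"
        )
    return np.vstack([prior, unnorm / totals])


def trajectory(
    prior: BeliefState,
    learning_trials: Sequence[Trial],
    epsilon: float = 0.1,
) -> BeliefTrajectory:
    """Sequential posterior updating over an ordered learning phase (Stage 2)."""
    for trial in learning_trials:
        if trial.outcome is None:
            raise ValueError(f"learning trial {trial.trial_index} has no outcome")
    likelihoods = np.array(
        [
            outcome_likelihood_vector(trial, trial.outcome, epsilon)
            for trial in learning_trials
        ]
    ).reshape(len(learning_trials), 4)
    states = trajectory_array(prior.weights, likelihoods)
    return BeliefTrajectory(tuple(BeliefState(row) for row in states))


def convergence_trial(
    traj: BeliefTrajectory | np.ndarray,
    target: Rule = Rule.SIZE,
    odds_threshold: float = 10.0,
) -> int | None:
    """First t >= 1 with posterior odds target/strongest-competitor >= threshold.

    Posterior odds against the best competitor is the convergence criterion;
    the default threshold of 10 is the conventional strong-evidence cut.
    Returns None when the trajectory never reaches the threshold.
    """
    if not odds_threshold > 1:
        raise ValueError(f"odds_threshold must exceed 1, got {odds_threshold}")
    states = traj.as_array() if isinstance(traj, BeliefTrajectory) else np.asarray(traj)
    others = [r for r in Rule if r is not target]
    for t in range(1, states.shape[0]):
        rival = states[t, others].max()
        if rival == 0 or states[t, target] / rival >= odds_threshold:
            if states[t, target] > 0:
                return t
    return None


def expected_response(belief: BeliefState, trial: Trial, eta: float = 0.1) -> float:
    """Model-predicted mean 5-point response under a belief state.

    Mixture over rules of each rule's expected response; lies in [1, 5].
    """
    rl = response_likelihood_matrix(trial, eta)  # (4 rules, 5 responses)
    per_rule = rl @ np.arange(1, 6)
    return float(belief.weights @ per_rule)
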