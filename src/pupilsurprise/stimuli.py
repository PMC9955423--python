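"""Stimuli for the two-sphere water-displacement task.

Each trial shows two spheres side by side; a child judges which sphere will
displace more water on a 5-point scale (1 = certainly left ... 3 = equal ...
5 = certainly right). Children's intuitions fall into four candidate causal
rules: displacement is governed by the spheres' *size*, their *material*
(density), their *mass* (size x density), or responding is *random*. The
ground truth of the task is the Size rule.

This module defines the sphere/trial containers, the four rules, their
deterministic directional predictions, and the noisy likelihoods that tie
rules to observed outcomes (feedback shown during the learning phase) and to
5-point behavioural responses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum, IntEnum

import numpy as np

__all__ = [
    "Direction",
    "Rule",
    "Phase",
    "Congruence",
    "Sphere",
    "Trial",
    "DETERMINISTIC_RULES",
    "RESPONSES",
    "predict_direction",
    "outcome_likelihood",
    "outcome_likelihood_vector",
    "response_likelihood",
    "response_likelihood_matrix",
    "classify_trial_congruence",
]


class Direction(IntEnum):
    """Directional outcome / judged winner of a trial."""

    LEFT = 0
    EQUAL = 1
    RIGHT = 2

    @property
    def letter(self) -> str:
        return {Direction.LEFT: "L", Direction.EQUAL: "E", Direction.RIGHT: "R"}[self]

    @classmethod
    def from_letter(cls, letter: str) -> "Direction":
        try:
            return {"L": cls.LEFT, "E": cls.EQUAL, "R": cls.RIGHT}[letter]
        except KeyError:
            raise ValueError(f"unknown direction letter {letter!r}; expected L, E or R")


class Rule(IntEnum):
    """Candidate causal rules (hypotheses) for water displacement.

    Index order (S, M, W, R) is the canonical order of the belief vector.
    """

    SIZE = 0
    MATERIAL = 1
    MASS = 2
    RANDOM = 3

    @property
    def symbol(self) -> str:
        return {Rule.SIZE: "S", Rule.MATERIAL: "M", Rule.MASS: "W", Rule.RANDOM: "R"}[self]


DETERMINISTIC_RULES = (Rule.SIZE, Rule.MATERIAL, Rule.MASS)

#: 5-point responses grouped by the direction they assert.
RESPONSES = {
    Direction.LEFT: (1, 2),
    Direction.EQUAL: (3,),
    Direction.RIGHT: (4, 5),
}


class Phase(str, Enum):
    PRETEST = "pretest"
    LEARNING = "learning"
    POSTTEST = "posttest"


class Congruence(str, Enum):
    CONGRUENT = "congruent"
    DISAMBIGUATING = "disambiguating"


@dataclass(frozen=True)
class Sphere:
    """A stimulus sphere with abstract positive feature levels.

    ``weight`` defaults to ``size_level * density_level`` (mass as a mixture
    of size and material) but may be supplied explicitly.
    """

    size_level: float
    density_level: float
    weight: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.weight is None:
            object.__setattr__(self, "weight", self.size_level * self.density_level)
        for name in ("size_level", "density_level", "weight"):
            value = getattr(self, name)
            if not (value > 0):
                raise ValueError(f"Sphere.{name} must be strictly positive, got {value}")


@dataclass(frozen=True)
class Trial:
    """One two-sphere comparison.

    ``outcome`` is the feedback direction shown to the child; it is present
    exactly for learning-phase trials (no feedback at pre/posttest).
    """

    trial_index: int
    left: Sphere
    right: Sphere
    phase: Phase = Phase.LEARNING
    outcome: Direction | None = None

    def __post_init__(self) -> None:
        if self.trial_index < 1:
            raise ValueError(f"trial_index must be >= 1, got {self.trial_index}")
        has_outcome = self.outcome is not None
        if (self.phase is Phase.LEARNING) != has_outcome:
            raise ValueError(
                f"trial {self.trial_index}: outcome must be present iff phase is "
                f"learning (phase={self.phase.value}, outcome={self.outcome})"
            )


_RULE_ATTR = {
    Rule.SIZE: "size_level",
    Rule.MATERIAL: "density_level",
    Rule.MASS: "weight",
}


def predict_direction(rule: Rule, trial: Trial) -> Direction:
    """Deterministic directional prediction of a rule for a trial.

    The side with the larger relevant feature wins; exact equality predicts
    EQUAL. The Random rule makes no deterministic prediction and is rejected.
    """
    if rule is Rule.RANDOM:
        raise ValueError("the Random rule has no deterministic prediction")
    attr = _RULE_ATTR[rule]
    lv, rv = getattr(trial.left, attr), getattr(trial.right, attr)
    if lv > rv:
        return Direction.LEFT
    if rv > lv:
        return Direction.RIGHT
    return Direction.EQUAL


def outcome_likelihood(
    rule: Rule, trial: Trial, outcome: Direction, epsilon: float = 0.1
) -> float:
    """p(outcome | rule, trial) with evidence noise ``epsilon``.

    A deterministic rule puts 1 - epsilon on its predicted direction and
    epsilon/2 on each of the other two; Random is uniform over the three
    directions. For fixed rule and trial the three probabilities sum to 1.
    """
    if not (0.0 <= epsilon < 1.0):
        raise ValueError(f"epsilon must lie in [0, 1), got {epsilon}")
    if rule is Rule.RANDOM:
        return 1.0 / 3.0
    return 1.0 - epsilon if predict_direction(rule, trial) is outcome else epsilon / 2.0


def outcome_likelihood_vector(
    trial: Trial, outcome: Direction, epsilon: float = 0.1
) -> np.ndarray:
    """Length-4 array of p(outcome | rule) in canonical (S, M, W, R) order."""
    return np.array(
        [outcome_likelihood(rule, trial, outcome, epsilon) for rule in Rule]
    )


def response_likelihood(
    rule: Rule, trial: Trial, response: int, eta: float = 0.1
) -> float:
    """p(5-point response | rule, trial) with response noise ``eta``.

    A deterministic rule spreads 1 - eta uniformly over the responses that
    assert its predicted direction ({1,2} for LEFT, {3} for EQUAL, {4,5} for
    RIGHT) and eta uniformly over the remaining responses; Random is uniform
    over all five. Probabilities over responses 1..5 sum to 1.
    """
    if response not in (1, 2, 3, 4, 5):
        raise ValueError(f"response must be an integer in 1..5, got {response}")
    if not (0.0 <= eta < 1.0):
        raise ValueError(f"eta must lie in [0, 1), got {eta}")
    if rule is Rule.RANDOM:
        return 0.2
    matching = RESPONSES[predict_direction(rule, trial)]
    if response in matching:
        return (1.0 - eta) / len(matching)
    return eta / (5 - len(matching))


def response_likelihood_matrix(trial: Trial, eta: float = 0.1) -> np.ndarray:
    """(4, 5) array of p(response | rule), rows in (S, M, W, R) order."""
    return np.array(
        [[response_likelihood(rule, trial, r, eta) for r in (1, 2, 3, 4, 5)] for rule in Rule]
    )


def classify_trial_congruence(trial: Trial) -> Congruence:
    """Congruent iff the three deterministic rules all predict the same direction.

    Congruent trials carry no disambiguating evidence: every hypothesis
    expects the same outcome, so an ideal learner has nothing to revise.
    """
    predictions = {predict_direction(rule, trial) for rule in DETERMINISTIC_RULES}
    return Congruence.CONGRUENT if len(predictions) == 1 else Congruence.DISAMBIGUATING
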