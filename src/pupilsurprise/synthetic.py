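"""Synthetic cohort generator for the water-displacement pupillometry study.

Emulates the statistical structure the analysis assumes, so every downstream
stage runs without the original dataset:

* a cohort of children (default 94) split ~evenly between a Prediction and a
  Postdiction condition;
* heterogeneous prior beliefs drawn from archetype profiles (size-, material-
  or mass-dominant, or mixed between Size and Mass), with a configured
  fraction of "already-knowers" holding size-dominant priors;
* a shared trial sequence: a disambiguating pretest with no feedback, then a
  learning phase of congruent trials (all rules agree) followed by
  disambiguating trials whose ground-truth outcomes follow the Size rule;
* noisy 5-point responses sampled from belief-conditioned likelihoods, with
  beliefs advancing on learning-phase feedback only;
* per-trial baseline-corrected pupil change scores coupled to a chosen
  surprise metric (default: KL divergence in Prediction, pure noise in
  Postdiction).

Reproducibility: one root seed; per-child generators derive from
(seed, child index) so changing the cohort size does not reshuffle existing
children.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .belief import BeliefState, trajectory_array
from .stimuli import (
    Congruence,
    Direction,
    Phase,
    Rule,
    Sphere,
    Trial,
    classify_trial_congruence,
    outcome_likelihood_vector,
    predict_direction,
    response_likelihood_matrix,
)
from .surprise import surprise_series_arrays

__all__ = [
    "Archetype",
    "SimulatedChild",
    "PupilModel",
    "CohortConfig",
    "Cohort",
    "sample_prior_profile",
    "generate_trial_sequence",
    "simulate_responses",
    "simulate_pupil",
    "generate_cohort",
]


class Archetype(str, Enum):
    """Prior-belief profiles observed across children."""

    SIZE_DOMINANT = "size_dominant"
    MATERIAL_DOMINANT = "material_dominant"
    MASS_DOMINANT = "mass_dominant"
    MIXED = "mixed"


_ARCHETYPE_RULE = {
    Archetype.SIZE_DOMINANT: Rule.SIZE,
    Archetype.MATERIAL_DOMINANT: Rule.MATERIAL,
    Archetype.MASS_DOMINANT: Rule.MASS,
}


@dataclass(frozen=True)
class SimulatedChild:
    """One simulated participant with individual prior and noise levels."""

    child_id: str
    condition: Literal["prediction", "postdiction"]
    prior: BeliefState
    eta: float = 0.1
    epsilon: float = 0.1
    archetype: Archetype | None = None


class PupilModel(BaseModel):
    """Generative model for per-trial baseline-corrected pupil change.

    The pupil score is ``gain * standardized(metric) + N(0, noise_sd)`` for
    the metric coupled in the child's condition (``none`` means pure noise).
    Standardizing the metric first makes the gain map directly onto the
    population correlation r = gain / sqrt(gain**2 + noise_sd**2).
    """

    model_config = ConfigDict(extra="forbid")

    coupling_by_condition: dict[str, Literal["kld", "si", "none"]] = Field(
        default_factory=lambda: {"prediction": "kld", "postdiction": "none"}
    )
    gain: float = Field(default=0.15 / math.sqrt(1 - 0.15**2), ge=0.0)
    noise_sd: float = Field(default=1.0, gt=0.0)

    @classmethod
    def from_target_r(
        cls, r: float, noise_sd: float = 1.0, **kwargs
    ) -> "PupilModel":
        """Pupil model whose coupled-condition population correlation is r."""
        if not (0.0 <= r < 1.0):
            raise ValueError(f"target correlation must lie in [0, 1), got {r}")
        return cls(gain=noise_sd * r / math.sqrt(1.0 - r * r), noise_sd=noise_sd, **kwargs)

    @property
    def target_r(self) -> float:
        return self.gain / math.sqrt(self.gain**2 + self.noise_sd**2)


class CohortConfig(BaseModel):
    """Study-design parameters of the simulated cohort.

    Defaults mirror the modelled study: 94 children, ~half per condition,
    19/94 already holding the correct Size belief, a learning phase of 9
    congruent then 21 disambiguating trials, and a 10-trial disambiguating
    pretest used to infer individual priors.
    """

    model_config = ConfigDict(extra="forbid")

    n_children: int = Field(default=94, gt=0)
    n_pretest: int = Field(default=10, ge=0)
    n_congruent: int = Field(default=9, ge=0)
    n_disambiguating: int = Field(default=21, ge=0)
    prior_profile_mix: dict[Archetype, float] = Field(
        default_factory=lambda: {
            Archetype.SIZE_DOMINANT: 0.0,
            Archetype.MATERIAL_DOMINANT: 0.25,
            Archetype.MASS_DOMINANT: 0.45,
            Archetype.MIXED: 0.30,
        }
    )
    fraction_already_knowers: float = Field(default=19 / 94, ge=0.0, le=1.0)
    concentration: float = Field(default=20.0, gt=0.0)
    eta: float = Field(default=0.1, ge=0.0, lt=1.0)
    epsilon: float = Field(default=0.1, ge=0.0, lt=1.0)
    seed: int = 0

    @model_validator(mode="after")
    def _check_mix(self) -> "CohortConfig":
        if self.n_congruent + self.n_disambiguating <= 0:
            raise ValueError("learning phase must contain at least one trial")
        if any(w < 0 for w in self.prior_profile_mix.values()):
            raise ValueError("prior_profile_mix weights must be nonnegative")
        if sum(self.prior_profile_mix.values()) <= 0:
            raise ValueError("prior_profile_mix weights must not all be zero")
        return self

    @property
    def n_learning(self) -> int:
        return self.n_congruent + self.n_disambiguating


def sample_prior_profile(
    archetype: Archetype, concentration: float, rng: np.random.Generator
) -> BeliefState:
    """Draw a prior belief concentrated on an archetype's dominant rule(s).

    Dirichlet draw with pseudo-count ``concentration`` on the dominant rule
    and 1 elsewhere; the mixed archetype splits the concentration equally
    between Size and Mass (the empirically common size/weight ambivalence).
    """
    alpha = np.ones(4)
    if archetype is Archetype.MIXED:
        alpha[Rule.SIZE] = concentration / 2.0
        alpha[Rule.MASS] = concentration / 2.0
    else:
        alpha[_ARCHETYPE_RULE[archetype]] = concentration
    return BeliefState(rng.dirichlet(alpha))


# Categorical sphere feature levels. Congruent pairs make one side dominate
# size, density and hence weight; disambiguating pairs oppose a large, light
# sphere (Size rule's pick) to a small, dense one (Material and Mass's pick).
_CONG_BIG_SIZE = (2.0, 2.5, 3.0)
_CONG_SMALL_SIZE = (1.0, 1.2, 1.5)
_CONG_HIGH_DENS = (4.0, 5.0, 6.0)
_CONG_LOW_DENS = (1.0, 1.5, 2.0)
_DIS_BIG_SIZE = (2.5, 3.0, 3.5)
_DIS_SMALL_SIZE = (1.0, 1.2, 1.5)
_DIS_LOW_DENS = (0.2, 0.25, 0.3)
_DIS_HIGH_DENS = (5.0, 6.5, 8.0)


def _congruent_pair(rng: np.random.Generator) -> tuple[Sphere, Sphere]:
    winner = Sphere(rng.choice(_CONG_BIG_SIZE), rng.choice(_CONG_HIGH_DENS))
    loser = Sphere(rng.choice(_CONG_SMALL_SIZE), rng.choice(_CONG_LOW_DENS))
    return (winner, loser) if rng.random() < 0.5 else (loser, winner)


def _disambiguating_pair(rng: np.random.Generator) -> tuple[Sphere, Sphere]:
    big_light = Sphere(rng.choice(_DIS_BIG_SIZE), rng.choice(_DIS_LOW_DENS))
    small_dense = Sphere(rng.choice(_DIS_SMALL_SIZE), rng.choice(_DIS_HIGH_DENS))
    return (big_light, small_dense) if rng.random() < 0.5 else (small_dense, big_light)


def generate_trial_sequence(
    config: CohortConfig, rng: np.random.Generator
) -> list[Trial]:
    """Shared trial sequence: pretest, then congruent-then-disambiguating learning.

    Pretest trials are disambiguating (they separate the hypotheses) and carry
    no outcome. Every learning-phase outcome equals the Size rule's
    prediction — the task's ground truth.
    """
    trials: list[Trial] = []
    for i in range(config.n_pretest):
        left, right = _disambiguating_pair(rng)
        trials.append(Trial(i + 1, left, right, Phase.PRETEST))
    for i in range(config.n_learning):
        maker = _congruent_pair if i < config.n_congruent else _disambiguating_pair
        left, right = maker(rng)
        stub = Trial(i + 1, left, right, Phase.PRETEST)  # for prediction only
        outcome = predict_direction(Rule.SIZE, stub)
        trials.append(Trial(i + 1, left, right, Phase.LEARNING, outcome))
    return trials


def _sample_categorical_rows(
    probs: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """One categorical draw per row of a (n, k) probability matrix."""
    u = rng.random(probs.shape[0])[:, None]
    return (probs.cumsum(axis=1) > u).argmax(axis=1)


def simulate_responses(
    child: SimulatedChild,
    trials: Sequence[Trial],
    rng: np.random.Generator,
) -> list[int]:
    """Sample the child's 5-point responses across pretest and learning trials.

    On each trial a rule is sampled from the child's current belief state and
    a response from that rule's response likelihood. Beliefs advance (by
    Bayesian updating on the shown outcome) only on learning trials; pretest
    responses leave the prior untouched.
    """
    belief = child.prior.as_array()
    responses: list[int] = []
    for trial in trials:
        rule = int(_sample_categorical_rows(belief[None, :], rng)[0])
        probs = response_likelihood_matrix(trial, child.eta)[rule]
        responses.append(int(_sample_categorical_rows(probs[None, :], rng)[0]) + 1)
        if trial.phase is Phase.LEARNING:
            belief = belief * outcome_likelihood_vector(
                trial, trial.outcome, child.epsilon
            )
            belief = belief / belief.sum()
    return responses


def simulate_pupil(
    child: SimulatedChild,
    surprise: Sequence,
    model: PupilModel,
    rng: np.random.Generator,
    loc: float | None = None,
    scale: float | None = None,
) -> np.ndarray:
    """Per-trial baseline-corrected pupil change for one child.

    ``surprise`` holds the child's own per-trial surprise records (or a bare
    metric array). ``loc``/``scale`` are the cohort-level mean/sd used to
    standardize the coupled metric; when omitted they are taken from the
    child's own series (single-child use).
    """
    metric_name = model.coupling_by_condition.get(child.condition, "none")
    n = len(surprise)
    noise = rng.normal(0.0, model.noise_sd, size=n)
    if metric_name == "none" or model.gain == 0.0:
        return noise
    values = np.asarray(
        [getattr(rec, metric_name) if hasattr(rec, metric_name) else rec for rec in surprise],
        dtype=float,
    )
    loc = float(values.mean()) if loc is None else loc
    scale = float(values.std()) if scale is None else scale
    if scale <= 0:
        raise ValueError("coupled surprise metric is constant; cannot standardize")
    return model.gain * (values - loc) / scale + noise


@dataclass
class Cohort:
    """Generated dataset tables plus the in-memory trial sequence."""

    children: pd.DataFrame
    trials: pd.DataFrame
    responses: pd.DataFrame
    pupil: pd.DataFrame
    trial_list: list[Trial]
    config: CohortConfig
    pupil_model: PupilModel

    @property
    def learning_trials(self) -> list[Trial]:
        return [t for t in self.trial_list if t.phase is Phase.LEARNING]

    @property
    def pretest_trials(self) -> list[Trial]:
        return [t for t in self.trial_list if t.phase is Phase.PRETEST]


def _trials_frame(trials: Sequence[Trial]) -> pd.DataFrame:
    rows = []
    for t in trials:
        rows.append(
            {
                "phase": t.phase.value,
                "trial_index": t.trial_index,
                "left_size": t.left.size_level,
                "left_density": t.left.density_level,
                "left_weight": t.left.weight,
                "right_size": t.right.size_level,
                "right_density": t.right.density_level,
                "right_weight": t.right.weight,
                "outcome": t.outcome.letter if t.outcome is not None else "",
            }
        )
    return pd.DataFrame(rows)


def generate_cohort(
    config: CohortConfig | None = None,
    model: PupilModel | None = None,
    seed: int | None = None,
) -> Cohort:
    """Simulate a full cohort and assemble its dataset tables.

    Deterministic given ``config.seed`` (or the ``seed`` override): the trial
    sequence and cohort-level assignments use dedicated substreams, and each
    child's responses/pupil use a generator derived from (seed, child index).
    """
    config = config or CohortConfig()
    model = model or PupilModel()
    if seed is not None:
        config = config.model_copy(update={"seed": seed})

    trial_rng = np.random.default_rng(np.random.SeedSequence((config.seed, 1_000_003)))
    assign_rng = np.random.default_rng(np.random.SeedSequence((config.seed, 2_000_003)))

    trials = generate_trial_sequence(config, trial_rng)
    learning = [t for t in trials if t.phase is Phase.LEARNING]
    pretest = [t for t in trials if t.phase is Phase.PRETEST]

    # balanced-within-1 random condition assignment
    n = config.n_children
    conditions = np.array(
        ["prediction", "postdiction"] * (n // 2) + ["prediction"] * (n % 2)
    )
    assign_rng.shuffle(conditions)

    # already-knowers get size-dominant priors; the rest draw from the mix
    n_knowers = int(round(config.fraction_already_knowers * n))
    knower_flags = np.zeros(n, dtype=bool)
    knower_flags[assign_rng.choice(n, size=n_knowers, replace=False)] = True
    mix_items = [
        (a, w) for a, w in config.prior_profile_mix.items() if w > 0
    ]
    mix_archetypes = [a for a, _ in mix_items]
    mix_weights = np.array([w for _, w in mix_items], dtype=float)
    mix_weights = mix_weights / mix_weights.sum()

    # per-trial likelihood tables shared by every child
    learn_lik = np.array(
        [outcome_likelihood_vector(t, t.outcome, config.epsilon) for t in learning]
    ).reshape(len(learning), 4)
    pre_resp = np.array([response_likelihood_matrix(t, config.eta) for t in pretest])
    learn_resp = np.array([response_likelihood_matrix(t, config.eta) for t in learning])

    children_rows, response_rows = [], []
    pupil_metric = np.empty((n, len(learning)))
    child_rngs = []
    coupled_names = []
    for i in range(n):
        rng = np.random.default_rng(np.random.SeedSequence((config.seed, i)))
        child_rngs.append(rng)
        archetype = (
            Archetype.SIZE_DOMINANT
            if knower_flags[i]
            else mix_archetypes[int(_sample_categorical_rows(mix_weights[None, :], rng)[0])]
        )
        prior = sample_prior_profile(archetype, config.concentration, rng)
        child = SimulatedChild(
            child_id=f"c{i:03d}",
            condition=str(conditions[i]),
            prior=prior,
            eta=config.eta,
            epsilon=config.epsilon,
            archetype=archetype,
        )
        children_rows.append(
            {
                "child_id": child.child_id,
                "condition": child.condition,
                "archetype": archetype.value,
                "eta": child.eta,
                "epsilon": child.epsilon,
            }
        )

        # responses: pretest from the static prior, learning along the child's
        # own evolving belief (which depends only on the shared outcomes)
        states = trajectory_array(prior.weights, learn_lik)  # (T+1, 4)
        pre_beliefs = np.broadcast_to(prior.weights, (len(pretest), 4))
        rules_pre = _sample_categorical_rows(np.asarray(pre_beliefs), rng)
        rules_learn = _sample_categorical_rows(states[:-1], rng)
        resp_pre = (
            _sample_categorical_rows(pre_resp[np.arange(len(pretest)), rules_pre], rng)
            + 1
        )
        resp_learn = (
            _sample_categorical_rows(
                learn_resp[np.arange(len(learning)), rules_learn], rng
            )
            + 1
        )
        for t, r in zip(pretest, resp_pre):
            response_rows.append(
                {
                    "child_id": child.child_id,
                    "phase": "pretest",
                    "trial_index": t.trial_index,
                    "response": int(r),
                }
            )
        for t, r in zip(learning, resp_learn):
            response_rows.append(
                {
                    "child_id": child.child_id,
                    "phase": "learning",
                    "trial_index": t.trial_index,
                    "response": int(r),
                }
            )

        # the pupil couples to the child's model-side surprise series: the one
        # computed from the pretest-inferred prior, which is also what the
        # analysis stage measures (the inferred prior is far sharper than the
        # generative one, so the generative-prior series would decorrelate)
        pretest_like = pre_resp[np.arange(len(pretest)), :, resp_pre - 1]  # (P, 4)
        inferred = np.full(4, 0.25) * pretest_like.prod(axis=0)
        inferred = inferred / inferred.sum()
        si, kld, _jsd = surprise_series_arrays(inferred, learn_lik)
        metric_name = model.coupling_by_condition.get(child.condition, "none")
        coupled_names.append(metric_name)
        if metric_name == "si":
            pupil_metric[i] = si
        elif metric_name == "kld":
            pupil_metric[i] = kld
        else:
            pupil_metric[i] = 0.0

    # cohort-level standardization of each coupled metric
    pupil_rows = []
    active = [name for name in set(coupled_names) if name != "none"]
    stats = {}
    for name in active:
        vals = np.concatenate(
            [pupil_metric[i] for i in range(n) if coupled_names[i] == name]
        )
        stats[name] = (float(vals.mean()), float(vals.std()))
    for i in range(n):
        rng = child_rngs[i]
        name = coupled_names[i]
        noise = rng.normal(0.0, model.noise_sd, size=len(learning))
        if name == "none" or model.gain == 0.0:
            signal = noise
        else:
            loc, scale = stats[name]
            if scale <= 0:
                raise ValueError("coupled surprise metric is constant across cohort")
            signal = model.gain * (pupil_metric[i] - loc) / scale + noise
        for t, v in zip(learning, signal):
            pupil_rows.append(
                {
                    "child_id": f"c{i:03d}",
                    "trial_index": t.trial_index,
                    "pupil_change": float(v),
                }
            )

    return Cohort(
        children=pd.DataFrame(children_rows),
        trials=_trials_frame(trials),
        responses=pd.DataFrame(response_rows),
        pupil=pd.DataFrame(pupil_rows),
        trial_list=trials,
        config=config,
        pupil_model=model,
    )
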