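"""Shared fixtures: small hand-built trials and a session-scoped default cohort."""

from __future__ import annotations

import numpy as np
import pytest

from pupilsurprise import generate_cohort
from pupilsurprise.pipeline import model_cohort
from pupilsurprise.stimuli import Direction, Phase, Sphere, Trial


def make_trial(
    left=(2.0, 1.0),
    right=(1.0, 1.0),
    phase=Phase.PRETEST,
    outcome=None,
    trial_index=1,
):
    """Build a trial from (size, density) pairs; weight derives as the product."""
    return Trial(
        trial_index=trial_index,
        left=Sphere(*left),
        right=Sphere(*right),
        phase=phase,
        outcome=outcome,
    )


@pytest.fixture
def size_right_trial():
    """Size favours RIGHT while material and mass favour LEFT (disambiguating)."""
    return make_trial(left=(1.0, 8.0), right=(3.0, 0.25))


@pytest.fixture
def congruent_trial():
    """One side dominates size, density and weight (all rules agree on LEFT)."""
    return make_trial(left=(3.0, 5.0), right=(1.0, 1.0))


def learning(trial: Trial, outcome: Direction, index: int = 1) -> Trial:
    return Trial(index, trial.left, trial.right, Phase.LEARNING, outcome)


@pytest.fixture(scope="session")
def default_cohort():
    return generate_cohort(seed=1234)


@pytest.fixture(scope="session")
def default_modeled(default_cohort):
    return model_cohort(default_cohort)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def null_batch():
    """Grid results on 200 uncoupled (gain 0) cohorts, shared across tests.

    Counts, per grid cell, how many null cohorts reject at raw alpha 0.05
    and at the Bonferroni-corrected alpha.
    """
    from pupilsurprise.analysis import condition_analysis
    from pupilsurprise.synthetic import PupilModel

    n_seeds = 200
    cells = [
        (c, e) for c in ("prediction", "postdiction") for e in ("si", "kld")
    ]
    raw = {cell: 0 for cell in cells}
    corrected = {cell: 0 for cell in cells}
    model = PupilModel(gain=0.0)
    for seed in range(n_seeds):
        cohort = generate_cohort(model=model, seed=30_000 + seed)
        grid = condition_analysis(model_cohort(cohort).merged)
        for cell in cells:
            result = grid.cells[cell]
            raw[cell] += result.p < 0.05
            corrected[cell] += result.p < grid.alpha_corrected
    return {
        "n_seeds": n_seeds,
        "raw_rejections": raw,
        "corrected_rejections": corrected,
    }
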