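"""Trial-by-trial surprise metrics over belief states.

Two rival accounts of the pupillary surprise response are quantified per
trial:

* Shannon information, SI = -log p(d): how unexpected the observed outcome
  was under the child's current (pre-update) beliefs, with p(d) the marginal
  outcome probability summed over the four hypotheses.
* Kullback-Leibler divergence, KLD(posterior || prior): how much "work" the
  outcome did on the belief distribution — the relative entropy from the
  pre-update to the post-update state.

The Jensen-Shannon divergence, a symmetric and bounded (<= log 2) variant of
KLD via the midpoint distribution, is carried alongside as a robustness
metric. All metrics default to natural-log units (nats); downstream Pearson
correlations are invariant to the base, which only rescales.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .belief import BeliefState, trajectory_array
from .stimuli import Direction, Rule, Trial, outcome_likelihood_vector

__all__ = [
    "SurpriseRecord",
    "marginal_outcome_prob",
    "shannon_information",
    "kl_divergence",
    "js_divergence",
    "surprise_series",
    "surprise_series_arrays",
    "minmax_normalize",
]


@dataclass(frozen=True)
class SurpriseRecord:
    """Per-trial surprise estimates (log-units set by the chosen base)."""

    trial_index: int
    si: float
    kld: float
    jsd: float
    child_id: str | None = None


def _as_weights(p: BeliefState | np.ndarray) -> np.ndarray:
    return p.weights if isinstance(p, BeliefState) else np.asarray(p, dtype=float)


def marginal_outcome_prob(
    belief: BeliefState,
    trial: Trial,
    outcome: Direction,
    epsilon: float = 0.1,
) -> float:
    """Marginal probability of an outcome: prior-weighted sum of likelihoods."""
    p = float(belief.weights @ outcome_likelihood_vector(trial, outcome, epsilon))
    if p <= 0:
        raise ZeroDivisionError(
            f"trial {trial.trial_index}: marginal outcome probability is zero"
        )
    return p


def shannon_information(
    belief: BeliefState,
    trial: Trial,
    outcome: Direction,
    epsilon: float = 0.1,
    log_base: float = math.e,
) -> float:
    """SI = -log p(d) of the observed outcome under the current beliefs."""
    return -math.log(marginal_outcome_prob(belief, trial, outcome, epsilon)) / math.log(
        log_base
    )


def _kl_nats(p: np.ndarray, q: np.ndarray) -> float:
    """KL(p || q) in nats with the 0*log(0/x) := 0 convention."""
    support = p > 0
    if np.any(q[support] == 0):
        raise ValueError(
            "KL divergence undefined: posterior mass on a zero-prior entry "
            "(absolute continuity violated)"
        )
    return float(np.sum(p[support] * np.log(p[support] / q[support])))


def kl_divergence(
    posterior: BeliefState | np.ndarray,
    prior: BeliefState | np.ndarray,
    log_base: float = math.e,
) -> float:
    """KL(posterior || prior): relative entropy of the belief shift.

    Nonnegative (Gibbs' inequality), zero iff the distributions are equal,
    and asymmetric in its arguments. The argument order follows the
    belief-revision reading: how far the updated state moved from the prior.
    """
    return _kl_nats(_as_weights(posterior), _as_weights(prior)) / math.log(log_base)


def js_divergence(
    p: BeliefState | np.ndarray,
    q: BeliefState | np.ndarray,
    log_base: float = math.e,
) -> float:
    """Jensen-Shannon divergence: symmetric, bounded by log 2, always finite."""
    pw, qw = _as_weights(p), _as_weights(q)
    m = 0.5 * (pw + qw)
    return (0.5 * _kl_nats(pw, m) + 0.5 * _kl_nats(qw, m)) / math.log(log_base)


def surprise_series_arrays(
    prior: np.ndarray,
    likelihoods: np.ndarray,
    log_base: float = math.e,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized (si, kld, jsd) arrays for a whole learning phase.

    ``likelihoods`` row t holds p(outcome_t | rule); SI for trial t uses the
    pre-update state t-1, while KLD/JSD compare state t against state t-1.
    """
    likelihoods = np.asarray(likelihoods, dtype=float)
    states = trajectory_array(prior, likelihoods)  # (T+1, 4)
    scale = math.log(log_base)
    marginals = np.einsum("tj,tj->t", states[:-1], likelihoods)
    if np.any(marginals <= 0):
        t = int(np.argmax(marginals <= 0))
        raise ZeroDivisionError(f"zero marginal outcome probability at trial {t + 1}")
    si = -np.log(marginals) / scale
    pre, post = states[:-1], states[1:]
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(post > 0, post / np.where(pre > 0, pre, 1.0), 1.0)
        kld = np.sum(np.where(post > 0, post * np.log(ratio), 0.0), axis=1) / scale
        m = 0.5 * (pre + post)
        jsd = (
            0.5 * np.sum(np.where(pre > 0, pre * np.log(np.where(pre > 0, pre, 1.0) / np.where(m > 0, m, 1.0)), 0.0), axis=1)
            + 0.5 * np.sum(np.where(post > 0, post * np.log(np.where(post > 0, post, 1.0) / np.where(m > 0, m, 1.0)), 0.0), axis=1)
        ) / scale
    # clip tiny negative rounding residue
    return np.maximum(si, 0.0), np.maximum(kld, 0.0), np.maximum(jsd, 0.0)


def surprise_series(
    prior: BeliefState,
    learning_trials: Sequence[Trial],
    epsilon: float = 0.1,
    log_base: float = math.e,
    child_id: str | None = None,
) -> list[SurpriseRecord]:
    """Per-trial surprise records across an ordered learning phase (Stage 3)."""
    likelihoods = np.array(
        [
            outcome_likelihood_vector(t, t.outcome, epsilon)
            for t in learning_trials
        ]
    ).reshape(len(learning_trials), 4)
    si, kld, jsd = surprise_series_arrays(prior.weights, likelihoods, log_base)
    return [
        SurpriseRecord(
            trial_index=trial.trial_index,
            si=float(si[i]),
            kld=float(kld[i]),
            jsd=float(jsd[i]),
            child_id=child_id,
        )
        for i, trial in enumerate(learning_trials)
    ]


def minmax_normalize(values: Sequence[float]) -> np.ndarray:
    """Rescale a series to [0, 1] as (x - min) / (max - min).

    Used when comparing metrics that live on different ranges. A constant
    series has an undefined normalization and is rejected.
    """
    x = np.asarray(values, dtype=float)
    lo, hi = x.min(), x.max()
    if hi == lo:
        raise ValueError("cannot min-max normalize a constant series")
    return (x - lo) / (hi - lo)
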