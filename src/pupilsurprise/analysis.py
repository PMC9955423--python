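"""Statistical surface: correlation grids, comparisons, and subset analyses.

The central object is the Condition (Prediction, Postdiction) x Estimate
(SI, KLD) grid of trial-level Pearson correlations between a surprise metric
and the pupil response, tested against a Bonferroni-corrected alpha
(0.05 / 4 = 0.0125). Two correlation comparisons accompany the grid:

* between conditions (independent samples): Fisher's r-to-z transformation;
* within a condition, KLD vs SI against the same pupil series (dependent,
  overlapping correlations): Steiger's z, which accounts for the SI-KLD
  correlation.

Subset analyses rerun the grid for learners vs already-knowers (split by the
argmax of the pretest-inferred belief) and for the critical learning trials
(the first disambiguating block), each with its own Bonferroni family.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .belief import BeliefState
from .stimuli import Rule

__all__ = [
    "CorrelationResult",
    "ComparisonResult",
    "AnalysisGrid",
    "ConstantInputError",
    "pearson",
    "bonferroni_alpha",
    "compare_independent",
    "compare_dependent_overlapping",
    "subset_learners",
    "condition_analysis",
    "individual_differences",
    "SCOPES",
]

SCOPES = ("all", "learners", "already_knowers", "critical_trials")

CONDITIONS = ("prediction", "postdiction")
ESTIMATES = ("si", "kld")


class ConstantInputError(ValueError):
    """Correlation is undefined for a constant series."""


@dataclass(frozen=True)
class CorrelationResult:
    label: str
    r: float
    n: int
    df: int
    p: float

    def __post_init__(self) -> None:
        if self.df != self.n - 2:
            raise ValueError(f"df must equal n - 2, got n={self.n}, df={self.df}")
        if not (-1.0 <= self.r <= 1.0) or not (0.0 <= self.p <= 1.0):
            raise ValueError(f"invalid correlation result r={self.r}, p={self.p}")


@dataclass(frozen=True)
class ComparisonResult:
    method: Literal["fisher_independent", "steiger_dependent"]
    z: float
    p: float
    contrast: str = ""
    sided: Literal["one", "two"] = "one"


@dataclass
class AnalysisGrid:
    """4-cell correlation grid for one scope, plus its comparisons.

    ``cells`` maps (condition, estimate) to a CorrelationResult, or to None
    when the scope leaves that cell empty (reported as missing, never
    silently dropped).
    """

    scope: str
    cells: dict[tuple[str, str], CorrelationResult | None]
    alpha: float
    alpha_corrected: float
    comparisons: list[ComparisonResult] = field(default_factory=list)
    combined: dict[str, CorrelationResult | None] = field(default_factory=dict)

    def significant(self, condition: str, estimate: str) -> bool:
        cell = self.cells[(condition, estimate)]
        return cell is not None and cell.p < self.alpha_corrected


def pearson(x: Sequence[float], y: Sequence[float], label: str = "") -> CorrelationResult:
    """Sample Pearson correlation with a two-sided t-test p (df = n - 2)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D sequences")
    if len(x) < 3:
        raise ValueError(f"need at least 3 observations, got {len(x)}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ConstantInputError(f"correlation undefined for constant input ({label!r})")
    res = stats.pearsonr(x, y)
    return CorrelationResult(
        label=label, r=float(res.statistic), n=len(x), df=len(x) - 2, p=float(res.pvalue)
    )


def bonferroni_alpha(alpha: float, m: int) -> float:
    """Bonferroni-corrected per-test alpha: alpha / m."""
    if m < 1:
        raise ValueError(f"family size must be >= 1, got {m}")
    return alpha / m


def _tail_p(z: float, sided: str) -> float:
    if sided == "one":
        return float(stats.norm.sf(abs(z)))
    if sided == "two":
        return float(2.0 * stats.norm.sf(abs(z)))
    raise ValueError(f"sided must be 'one' or 'two', got {sided!r}")


def compare_independent(
    r1: float,
    n1: int,
    r2: float,
    n2: int,
    sided: Literal["one", "two"] = "one",
    contrast: str = "",
) -> ComparisonResult:
    """Fisher r-to-z comparison of two correlations from independent samples.

    z = (atanh r1 - atanh r2) / sqrt(1/(n1-3) + 1/(n2-3)); the p-value is a
    standard-normal tail (one-sided by default).
    """
    if not (abs(r1) < 1 and abs(r2) < 1):
        raise ValueError("correlations must lie strictly inside (-1, 1)")
    if n1 <= 3 or n2 <= 3:
        raise ValueError("both samples must exceed 3 observations")
    z = (math.atanh(r1) - math.atanh(r2)) / math.sqrt(
        1.0 / (n1 - 3) + 1.0 / (n2 - 3)
    )
    return ComparisonResult(
        method="fisher_independent", z=z, p=_tail_p(z, sided), contrast=contrast, sided=sided
    )


def compare_dependent_overlapping(
    r12: float,
    r13: float,
    r23: float,
    n: int,
    sided: Literal["one", "two"] = "one",
    contrast: str = "",
) -> ComparisonResult:
    """Steiger's z for two dependent correlations sharing one variable.

    Compares corr(1,2) with corr(1,3) measured on the same n cases (variable
    1 is shared — here the pupil series), accounting for corr(2,3) between
    the two competing predictors via the Fisher-transformed difference with
    Steiger's (1980) covariance term.
    """
    if not (abs(r12) < 1 and abs(r13) < 1 and abs(r23) <= 1):
        raise ValueError("correlations must lie inside the unit interval")
    if n <= 3:
        raise ValueError("need more than 3 observations")
    corr = np.array([[1.0, r12, r13], [r12, 1.0, r23], [r13, r23, 1.0]])
    if np.linalg.eigvalsh(corr).min() < -1e-10:
        raise ValueError(
            "correlation triple (r12, r13, r23) is not positive semidefinite"
        )
    rbar2 = ((r12 + r13) / 2.0) ** 2
    cov = (r23 * (1.0 - 2.0 * rbar2) - 0.5 * rbar2 * (1.0 - 2.0 * rbar2 - r23**2)) / (
        (1.0 - rbar2) ** 2
    )
    z = (math.atanh(r12) - math.atanh(r13)) * math.sqrt(
        (n - 3) / (2.0 - 2.0 * cov)
    )
    return ComparisonResult(
        method="steiger_dependent", z=z, p=_tail_p(z, sided), contrast=contrast, sided=sided
    )


def subset_learners(
    pretest_beliefs: Mapping[str, BeliefState],
) -> dict[str, list[str]]:
    """Split children into learners vs already-knowers by pretest belief.

    Already-knower iff the pretest-inferred belief's unique argmax is the
    Size rule; a tie involving Size counts as learner (conservative).
    """
    learners, knowers = [], []
    for child_id, belief in pretest_beliefs.items():
        w = belief.weights
        top = w.max()
        if w[Rule.SIZE] == top and int(np.sum(w == top)) == 1:
            knowers.append(child_id)
        else:
            learners.append(child_id)
    return {"learners": sorted(learners), "already_knowers": sorted(knowers)}


def _scope_frame(
    df: pd.DataFrame,
    scope: str,
    critical_window: tuple[int, int] = (10, 19),
) -> pd.DataFrame:
    if scope == "all":
        return df
    if scope == "learners":
        return df[~df["already_knower"]]
    if scope == "already_knowers":
        return df[df["already_knower"]]
    if scope == "critical_trials":
        lo, hi = critical_window
        return df[(df["trial_index"] >= lo) & (df["trial_index"] <= hi)]
    raise ValueError(f"unknown scope {scope!r}; expected one of {SCOPES}")


def condition_analysis(
    df: pd.DataFrame,
    scope: str = "all",
    alpha: float = 0.05,
    critical_window: tuple[int, int] = (10, 19),
    cell_sided: Literal["one", "two"] = "two",
    comparison_sided: Literal["one", "two"] = "one",
) -> AnalysisGrid:
    """Condition x Estimate correlation grid for one scope of the dataset.

    ``df`` is the merged trial table with columns child_id, condition,
    trial_index, si, kld, pupil_change, already_knower. Trials are pooled
    across children within scope and condition (trials treated as
    exchangeable). The grid's Bonferroni family is its own 4 cells; the
    comparisons are the between-condition KLD contrast (Fisher) and the
    within-Prediction KLD-vs-SI contrast (Steiger).
    """
    required = {"child_id", "condition", "trial_index", "si", "kld", "pupil_change"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"merged trial table lacks columns {sorted(missing)}")
    sub = _scope_frame(df, scope, critical_window)

    cells: dict[tuple[str, str], CorrelationResult | None] = {}
    for condition in CONDITIONS:
        pool = sub[sub["condition"] == condition]
        for estimate in ESTIMATES:
            key = (condition, estimate)
            if len(pool) < 3:
                cells[key] = None
                continue
            result = pearson(
                pool[estimate].to_numpy(),
                pool["pupil_change"].to_numpy(),
                label=f"{scope}:{condition}:{estimate}",
            )
            if cell_sided == "one":
                result = CorrelationResult(
                    label=result.label, r=result.r, n=result.n, df=result.df,
                    p=result.p / 2.0 if result.r > 0 else 1.0 - result.p / 2.0,
                )
            cells[key] = result

    combined: dict[str, CorrelationResult | None] = {}
    for estimate in ESTIMATES:
        combined[estimate] = (
            pearson(
                sub[estimate].to_numpy(),
                sub["pupil_change"].to_numpy(),
                label=f"{scope}:combined:{estimate}",
            )
            if len(sub) >= 3
            else None
        )

    grid = AnalysisGrid(
        scope=scope,
        cells=cells,
        alpha=alpha,
        alpha_corrected=bonferroni_alpha(alpha, len(CONDITIONS) * len(ESTIMATES)),
        combined=combined,
    )

    pred_kld = cells[("prediction", "kld")]
    post_kld = cells[("postdiction", "kld")]
    pred_si = cells[("prediction", "si")]
    if pred_kld is not None and post_kld is not None:
        grid.comparisons.append(
            compare_independent(
                pred_kld.r, pred_kld.n, post_kld.r, post_kld.n,
                sided=comparison_sided,
                contrast="kld:prediction_vs_postdiction",
            )
        )
    if pred_kld is not None and pred_si is not None:
        pred_pool = sub[sub["condition"] == "prediction"]
        r23 = pearson(
            pred_pool["kld"].to_numpy(), pred_pool["si"].to_numpy(), label="kld_vs_si"
        ).r
        grid.comparisons.append(
            compare_dependent_overlapping(
                pred_kld.r, pred_si.r, r23, pred_kld.n,
                sided=comparison_sided,
                contrast="prediction:kld_vs_si",
            )
        )
    return grid


def individual_differences(
    per_child: Mapping[str, Mapping[str, Sequence[float]]],
    min_trials: int = 3,
) -> dict[str, object]:
    """Correlation-of-correlations linking pupil-model fit to learning fit.

    For each child, compute (a) r_behavior: Pearson between the child's
    5-point responses and the model's expected responses across learning
    trials, and (b) r_pupil,metric: Pearson between the pupil series and the
    child's KLD (and SI) series. Across children, correlate each
    r_pupil,metric vector with the r_behavior vector. Children with a
    constant series (undefined per-child correlation) are excluded and
    counted.

    ``per_child`` maps child_id to a mapping with keys 'responses',
    'expected', 'pupil', 'kld', 'si'.
    """
    r_behavior, r_kld, r_si, excluded = [], [], [], []
    for child_id, series in per_child.items():
        arrays = {k: np.asarray(series[k], dtype=float) for k in
                  ("responses", "expected", "pupil", "kld", "si")}
        if len(arrays["responses"]) < min_trials:
            excluded.append(child_id)
            continue
        try:
            rb = pearson(arrays["responses"], arrays["expected"]).r
            rk = pearson(arrays["pupil"], arrays["kld"]).r
            rs = pearson(arrays["pupil"], arrays["si"]).r
        except ConstantInputError:
            excluded.append(child_id)
            continue
        r_behavior.append(rb)
        r_kld.append(rk)
        r_si.append(rs)
    if len(r_behavior) < 3:
        raise ValueError(
            f"fewer than 3 usable children ({len(r_behavior)}); "
            f"{len(excluded)} excluded"
        )
    return {
        "kld": pearson(r_kld, r_behavior, label="cross_child:kld_fit_vs_behavior_fit"),
        "si": pearson(r_si, r_behavior, label="cross_child:si_fit_vs_behavior_fit"),
        "n_children": len(r_behavior),
        "n_excluded": len(excluded),
        "excluded": excluded,
        "per_child": pd.DataFrame(
            {"r_behavior": r_behavior, "r_pupil_kld": r_kld, "r_pupil_si": r_si}
        ),
    }
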