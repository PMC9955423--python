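"""Correlation grid, Fisher/Steiger comparisons, subsets, individual differences."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pupilsurprise.analysis import (
    ConstantInputError,
    bonferroni_alpha,
    compare_dependent_overlapping,
    compare_independent,
    condition_analysis,
    individual_differences,
    pearson,
    subset_learners,
)
from pupilsurprise.belief import BeliefState
from pupilsurprise.pipeline import model_cohort
from pupilsurprise.synthetic import PupilModel, generate_cohort


class TestPearson:
    def test_perfect_linearity(self):
        assert pearson([1, 2, 3], [2, 4, 6]).r == pytest.approx(1.0)
        assert pearson([1, 2, 3], [6, 4, 2]).r == pytest.approx(-1.0)

    def test_hand_computed_half(self):
        res = pearson([1, 2, 3], [1, 3, 2])
        assert res.r == pytest.approx(0.5)
        assert res.df == 1

    def test_constant_input_rejected(self):
        with pytest.raises(ConstantInputError):
            pearson([1, 1, 1], [1, 2, 3])

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            pearson([1, 2], [3, 4])


class TestBonferroni:
    @pytest.mark.parametrize(
        "alpha,m,expected", [(0.05, 4, 0.0125), (0.05, 1, 0.05), (0.01, 5, 0.002)]
    )
    def test_division(self, alpha, m, expected):
        assert bonferroni_alpha(alpha, m) == pytest.approx(expected)

    def test_family_size_must_be_positive(self):
        with pytest.raises(ValueError):
            bonferroni_alpha(0.05, 0)


class TestCompareIndependent:
    def test_equal_correlations_give_zero(self):
        assert compare_independent(0.3, 50, 0.3, 80).z == pytest.approx(0.0)

    def test_textbook_value(self):
        res = compare_independent(0.3, 103, 0.0, 103)
        assert res.z == pytest.approx(np.arctanh(0.3) / np.sqrt(2 / 100), abs=1e-12)
        assert res.z == pytest.approx(2.189, abs=1e-3)
        assert res.p == pytest.approx(stats.norm.sf(res.z), abs=1e-12)

    def test_antisymmetry(self):
        a = compare_independent(0.4, 60, 0.1, 90)
        b = compare_independent(0.1, 90, 0.4, 60)
        assert a.z == pytest.approx(-b.z)

    def test_two_sided_doubles_tail(self):
        one = compare_independent(0.3, 103, 0.0, 103, sided="one")
        two = compare_independent(0.3, 103, 0.0, 103, sided="two")
        assert two.p == pytest.approx(2 * one.p)


class TestCompareDependentOverlapping:
    def test_equal_correlations_give_zero(self):
        assert compare_dependent_overlapping(0.3, 0.3, 0.5, 100).z == pytest.approx(0.0)

    def test_monotone_in_gap(self):
        zs = [
            compare_dependent_overlapping(0.2 + gap, 0.2, 0.5, 100).z
            for gap in (0.05, 0.15, 0.3)
        ]
        assert zs[0] < zs[1] < zs[2]

    def test_non_psd_triple_rejected(self):
        with pytest.raises(ValueError):
            compare_dependent_overlapping(0.9, -0.9, 0.9, 100)

    def test_matches_permutation_reference(self):
        """Steiger's z agrees with a permutation null of the correlation gap.

        On simulated trivariate data, permuting which of the two predictors'
        labels is 'first' (sign-flipping the gap) yields a null for
        r(pupil, a) - r(pupil, b); the permutation p should match Steiger's
        one-sided p within Monte-Carlo error.
        """
        rng = np.random.default_rng(42)
        n = 200
        latent = rng.normal(size=n)
        # a and b are exchangeable by construction, so H0 holds exactly
        a = latent + rng.normal(scale=1.0, size=n)
        b = latent + rng.normal(scale=1.0, size=n)
        pupil = latent + rng.normal(scale=1.3, size=n)
        r12 = stats.pearsonr(pupil, a).statistic
        r13 = stats.pearsonr(pupil, b).statistic
        r23 = stats.pearsonr(a, b).statistic
        observed = compare_dependent_overlapping(r12, r13, r23, n, sided="two")

        # permutation oracle: swapping a_i and b_i per case is an
        # exchangeability-preserving transformation under H0
        gaps = np.empty(10_000)
        observed_gap = abs(r12 - r13)
        for k in range(10_000):
            swap = rng.random(n) < 0.5
            aa = np.where(swap, b, a)
            bb = np.where(swap, a, b)
            gaps[k] = (
                stats.pearsonr(pupil, aa).statistic
                - stats.pearsonr(pupil, bb).statistic
            )
        p_perm = (np.sum(np.abs(gaps) >= observed_gap) + 1) / (len(gaps) + 1)
        assert observed.p == pytest.approx(p_perm, abs=0.03)


class TestSubsetLearners:
    def test_size_argmax_is_knower(self):
        beliefs = {
            "a": BeliefState(np.array([0.7, 0.1, 0.1, 0.1])),
            "b": BeliefState(np.array([0.1, 0.2, 0.6, 0.1])),
            "c": BeliefState.uniform(),  # tie involving Size -> learner
        }
        part = subset_learners(beliefs)
        assert part["already_knowers"] == ["a"]
        assert part["learners"] == ["b", "c"]


def _merged_frame(n_children=10, n_trials=20, seed=0, coupled=True):
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_children):
        condition = "prediction" if i % 2 == 0 else "postdiction"
        kld = np.abs(rng.normal(size=n_trials))
        si = 0.5 * kld + np.abs(rng.normal(size=n_trials))
        pupil = rng.normal(size=n_trials)
        if coupled and condition == "prediction":
            pupil = pupil + 1.5 * kld
        for t in range(n_trials):
            rows.append(
                {
                    "child_id": f"c{i}",
                    "condition": condition,
                    "trial_index": t + 1,
                    "si": si[t],
                    "kld": kld[t],
                    "pupil_change": pupil[t],
                    "already_knower": i < 2,
                }
            )
    return pd.DataFrame(rows)


class TestConditionAnalysis:
    def test_grid_has_four_cells_and_corrected_alpha(self):
        grid = condition_analysis(_merged_frame())
        assert set(grid.cells) == {
            ("prediction", "si"), ("prediction", "kld"),
            ("postdiction", "si"), ("postdiction", "kld"),
        }
        assert grid.alpha_corrected == pytest.approx(0.0125)

    def test_critical_scope_restricts_trial_window(self):
        df = _merged_frame(n_trials=30)
        grid = condition_analysis(df, scope="critical_trials")
        expected_n = len(
            df[(df.trial_index >= 10) & (df.trial_index <= 19)
               & (df.condition == "prediction")]
        )
        assert grid.cells[("prediction", "kld")].n == expected_n

    def test_pooling_equals_concatenation(self):
        df = _merged_frame()
        grid = condition_analysis(df)
        pred = df[df.condition == "prediction"]
        post = df[df.condition == "postdiction"]
        pooled = pd.concat([pred, post])
        direct = stats.pearsonr(pooled["kld"], pooled["pupil_change"]).statistic
        assert grid.combined["kld"].r == pytest.approx(direct, abs=1e-14)

    def test_empty_cell_reported_as_missing(self):
        df = _merged_frame()
        grid = condition_analysis(
            df[df.condition == "prediction"], scope="all"
        )
        assert grid.cells[("postdiction", "kld")] is None
        assert grid.cells[("prediction", "kld")] is not None

    def test_learner_scope_excludes_knowers(self):
        df = _merged_frame()
        grid = condition_analysis(df, scope="learners")
        assert grid.cells[("prediction", "kld")].n == len(
            df[(df.condition == "prediction") & (~df.already_knower)]
        )


class TestIndividualDifferences:
    @staticmethod
    def _per_child(n_children=30, n_trials=25, noise=0.2, seed=3, couple=True):
        rng = np.random.default_rng(seed)
        out = {}
        for i in range(n_children):
            strength = rng.uniform(0.2, 2.0)  # how much "learning" the child shows
            kld = strength * np.abs(rng.normal(size=n_trials))
            si = kld + np.abs(rng.normal(size=n_trials))
            pupil = (kld if couple else 0.0) + rng.normal(scale=noise, size=n_trials)
            expected = 3 + kld
            responses = expected + rng.normal(scale=1.0 / strength, size=n_trials)
            out[f"c{i}"] = {
                "responses": responses, "expected": expected,
                "pupil": pupil, "kld": kld, "si": si,
            }
        return out

    def test_constructed_coupling_yields_positive_cross_child_r(self):
        result = individual_differences(self._per_child())
        assert result["kld"].r > 0

    def test_constant_pupil_child_excluded(self):
        data = self._per_child(n_children=5)
        data["c0"]["pupil"] = np.zeros_like(data["c0"]["pupil"])
        result = individual_differences(data)
        assert result["n_excluded"] == 1 and "c0" in result["excluded"]
        assert result["kld"].n == 4

    def test_too_few_usable_children_rejected(self):
        data = self._per_child(n_children=3)
        for cid in ("c0", "c1"):
            data[cid]["pupil"] = np.zeros_like(data[cid]["pupil"])
        with pytest.raises(ValueError):
            individual_differences(data)


class TestErrorCalibration:
    """Type-I error of the grid on null cohorts (no pupil coupling)."""

    def test_raw_rejection_rate_near_nominal(self, null_batch):
        lo, hi = stats.binom.interval(0.99, null_batch["n_seeds"], 0.05)
        for cell, count in null_batch["raw_rejections"].items():
            assert lo <= count <= hi, (
                f"cell {cell}: {count} raw rejections outside 99% binomial "
                f"band [{lo}, {hi}] over {null_batch['n_seeds']} null cohorts"
            )
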