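import numpy as np
import pandas as pd
import pytest

from prososcan import (
    Cohort,
    Encoder,
    Group,
    dispersion_index,
    dprime_criterion,
    eye_mouth_index,
    left_right_index,
    load_recognition_scores,
    one_tailed_t,
    one_way_anova,
    pearson_r,
    percentile_overlays,
    permutation_test,
    preset_profiles,
    roi_contrast_profile,
    subject_prediction_summary,
)
from prososcan.stats import contrast_anova
from prososcan.synthetic import generate_cohort


class TestPermutationTest:
    def _cohort(self):
        presets = preset_profiles(trials_per_subject=2)
        from prososcan.synthetic import two_group_cohort

        return two_group_cohort(presets["control"], presets["acquired"], 4, 4, seed=0)

    def test_no_null_exceeding_truth_gives_one_over_101(self):
        out = permutation_test(lambda c, s: 0.5, self._cohort(), true_auc=0.9, n_perm=100, seed=0)
        assert out["p"] == pytest.approx(1 / 101)
        assert out["p"] < 0.01

    def test_all_nulls_exceeding_truth_gives_one(self):
        out = permutation_test(lambda c, s: 0.9, self._cohort(), true_auc=0.5, n_perm=100, seed=0)
        assert out["p"] == 1.0

    def test_zero_permutations_rejected(self):
        with pytest.raises(ValueError):
            permutation_test(lambda c, s: 0.5, self._cohort(), true_auc=0.5, n_perm=0)

    def test_labels_shuffled_at_subject_level(self):
        """Each permuted cohort keeps group sizes and every subject's
        trials move together."""
        seen = []

        def recorder(cohort, seed):
            roster = dict(zip(cohort.subjects["subject"], cohort.subjects["group"]))
            seen.append(roster)
            for t in cohort.trials:
                assert t.group.value == roster[t.subject_id]
            assert sorted(roster.values()).count("control") == 4
            return 0.5

        permutation_test(recorder, self._cohort(), true_auc=1.0, n_perm=5, seed=1)
        assert len(seen) == 5


class TestPercentileOverlays:
    def _preds(self, probs, fold=0):
        return pd.DataFrame(
            {
                "fold": fold,
                "subject": "S1",
                "trial": [f"T{i}" for i in range(len(probs))],
                "probability": probs,
            }
        )

    def _trials(self, n, trial_factory):
        return {("S1", f"T{i}"): trial_factory([8, 9], trial_id=f"T{i}") for i in range(n)}

    def test_hundred_distinct_predictions_give_ten_per_tail(self, trial_factory):
        probs = np.linspace(0.001, 0.999, 100)
        lo, hi = percentile_overlays(
            self._preds(probs), self._trials(100, trial_factory), Encoder.ROI_SEQUENCE, 2
        )
        assert lo.n_trials == 10 and hi.n_trials == 10

    def test_identical_predictions_raise(self, trial_factory):
        with pytest.raises(ValueError, match="tail"):
            percentile_overlays(
                self._preds(np.full(20, 0.5)), self._trials(20, trial_factory),
                Encoder.ROI_SEQUENCE, 2,
            )


class TestSubjectSummary:
    def _df(self, mapping):
        rows = [
            {"subject": s, "group": "control", "probability": p}
            for s, probs in mapping.items()
            for p in probs
        ]
        return pd.DataFrame(rows)

    def test_singleton_subject(self):
        out = subject_prediction_summary(self._df({"A": [0.7]}))
        row = out.iloc[0]
        assert row["median"] == row["q1"] == row["q3"] == 0.7

    def test_median_order_statistic_and_sorting(self):
        out = subject_prediction_summary(self._df({"A": [0.1, 0.5, 0.9], "B": [0.2, 0.3, 0.4]}))
        assert list(out["subject"]) == ["B", "A"]  # sorted by median
        assert out.set_index("subject").loc["A", "median"] == 0.5

    def test_duplicate_of_median_keeps_median(self):
        a = subject_prediction_summary(self._df({"A": [0.1, 0.5, 0.9]}))
        b = subject_prediction_summary(self._df({"A": [0.1, 0.5, 0.5, 0.9]}))
        assert a.loc[0, "median"] == b.loc[0, "median"] == 0.5


class TestScanIndices:
    def _cohort(self, rois_by_trial, trial_factory, group=Group.CONTROL):
        trials = [
            trial_factory(rois, subject="S1", group=group, trial_id=f"T{i}")
            for i, rois in enumerate(rois_by_trial)
        ]
        return Cohort(trials)

    def test_left_right_balanced_is_zero(self, trial_factory):
        cohort = self._cohort([[1, 2, 1, 2]], trial_factory)
        assert left_right_index(cohort, 4)["value"].iloc[0] == 0.0

    def test_left_right_three_to_one(self, trial_factory):
        cohort = self._cohort([[1, 1, 1, 2]], trial_factory)
        assert left_right_index(cohort, 4)["value"].iloc[0] == 0.5

    def test_left_right_boundary(self, trial_factory):
        cohort = self._cohort([[2, 2, 2, 2]], trial_factory)
        assert left_right_index(cohort, 4)["value"].iloc[0] == -1.0

    def test_no_eye_fixations_excluded_and_flagged(self, trial_factory):
        cohort = self._cohort([[8, 9, 8, 9]], trial_factory)
        row = left_right_index(cohort, 4).iloc[0]
        assert row["excluded"] and np.isnan(row["value"])

    def test_eye_mouth_forms(self, trial_factory):
        cohort = self._cohort([[1, 2, 9, 9]], trial_factory)
        assert eye_mouth_index(cohort, 4)["value"].iloc[0] == 0.0
        cohort = self._cohort([[1, 2, 1, 2, 1, 2, 9, 9]], trial_factory)
        assert eye_mouth_index(cohort, 8)["value"].iloc[0] == 0.5
        cohort = self._cohort([[1, 2, 1, 1]], trial_factory)
        assert eye_mouth_index(cohort, 4)["value"].iloc[0] == 1.0

    def test_index_invariant_to_trial_duplication(self, trial_factory):
        once = self._cohort([[1, 1, 2, 9]], trial_factory)
        twice = self._cohort([[1, 1, 2, 9]] * 2, trial_factory)
        assert (
            left_right_index(once, 4)["value"].iloc[0]
            == left_right_index(twice, 4)["value"].iloc[0]
        )

    def test_dispersion_two_distances(self, trial_factory, template):
        cx, cy = template.center
        xy = [(cx + 10, cy), (cx + 20, cy)]
        cohort = Cohort([trial_factory([8, 8], xy=xy)])
        val = dispersion_index(cohort, template, m=2)["value"].iloc[0]
        assert val == pytest.approx(7.0711, abs=1e-3)

    def test_dispersion_zero_on_circle(self, trial_factory, template):
        cx, cy = template.center
        xy = [(cx + 30, cy), (cx, cy + 30), (cx - 30, cy)]
        cohort = Cohort([trial_factory([8, 8, 8], xy=xy)])
        assert dispersion_index(cohort, template, m=3)["value"].iloc[0] == pytest.approx(0.0)

    def test_dispersion_scales_with_coordinates(self, trial_factory, template):
        cx, cy = template.center
        xy1 = [(cx + 10, cy), (cx + 25, cy), (cx, cy + 40)]
        xy3 = [(cx + 30, cy), (cx + 75, cy), (cx, cy + 120)]
        c1 = Cohort([trial_factory([8, 8, 8], xy=xy1)])
        c3 = Cohort([trial_factory([8, 8, 8], xy=xy3)])
        v1 = dispersion_index(c1, template, m=3)["value"].iloc[0]
        v3 = dispersion_index(c3, template, m=3)["value"].iloc[0]
        assert v3 == pytest.approx(3 * v1)


class TestRoiContrast:
    def test_uniform_row_zero(self):
        out = roi_contrast_profile(np.full((1, 10), 7.0))
        assert out["contrast"].iloc[0] == 0.0

    def test_one_hot_row_is_three(self):
        row = np.zeros((1, 10))
        row[0, 4] = 50
        assert roi_contrast_profile(row)["contrast"].iloc[0] == pytest.approx(3.0)

    def test_scale_invariance(self):
        rng = np.random.default_rng(0)
        counts = rng.integers(1, 20, size=(4, 10)).astype(float)
        a = roi_contrast_profile(counts)["contrast"]
        b = roi_contrast_profile(2 * counts)["contrast"]
        assert np.allclose(a, b)

    def test_zero_row_flagged(self):
        out = roi_contrast_profile(np.zeros((1, 10)))
        assert out["flagged"].iloc[0]

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            roi_contrast_profile(-np.ones((1, 10)))


class TestDprime:
    def test_chance_symmetric(self):
        s = dprime_criterion(5, 5, 5, 5)
        assert s.d_prime == pytest.approx(0.0) and s.criterion == pytest.approx(0.0)

    def test_hand_computed_rates(self):
        s = dprime_criterion(9, 1, 2, 8)  # H=0.9, F=0.2
        assert s.d_prime == pytest.approx(2.1232, abs=1e-3)
        assert s.criterion == pytest.approx(-0.2200, abs=1e-3)

    def test_swapping_h_and_f_negates_dprime(self):
        a = dprime_criterion(9, 1, 2, 8)
        b = dprime_criterion(2, 8, 9, 1)
        assert b.d_prime == pytest.approx(-a.d_prime)

    def test_matches_quantile_table_oracle(self):
        """Independent z-table values: z(0.75)=0.6745, z(0.25)=-0.6745."""
        s = dprime_criterion(3, 1, 1, 3)  # H=0.75, F=0.25
        assert s.d_prime == pytest.approx(0.6745 + 0.6745, abs=1e-3)
        assert s.criterion == pytest.approx(0.0, abs=1e-9)

    def test_extreme_rates_corrected(self):
        s = dprime_criterion(10, 0, 0, 10)  # would be infinite uncorrected
        from scipy.stats import norm

        expected = norm.ppf(1 - 1 / 20) - norm.ppf(1 / 20)
        assert s.d_prime == pytest.approx(expected)

    def test_zero_targets_rejected(self):
        with pytest.raises(ValueError):
            dprime_criterion(0, 0, 2, 8)


class TestGroupStatistics:
    def test_identical_groups_t_zero_p_half(self):
        g = [1.0, 2.0, 3.0]
        out = one_tailed_t(g, g)
        assert out["t"] == pytest.approx(0.0) and out["p"] == pytest.approx(0.5)

    def test_equal_mean_groups_small_f(self):
        rng = np.random.default_rng(0)
        groups = [rng.normal(0, 1, 2000) for _ in range(3)]
        out = one_way_anova(*groups)
        assert out["p"] > 0.01

    def test_published_dprime_table_anova(self):
        scores = load_recognition_scores()
        by_group = [g["dprime"].to_numpy() for _, g in scores.groupby("group")]
        out = one_way_anova(*by_group)
        assert out["F"] == pytest.approx(6.58, abs=0.1)
        assert out["df1"] == 2 and out["df2"] == 35

    def test_pearson(self):
        out = pearson_r([1, 2, 3, 4], [2, 4, 6, 8])
        assert out["r"] == pytest.approx(1.0)

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            one_tailed_t([1.0], [1.0, 2.0])

    def test_contrast_anova_detects_group_difference(self):
        rng = np.random.default_rng(1)
        rows = []
        for group, shift in [("control", 1.0), ("patient", 0.0)]:
            for rep in range(6):
                for fixation in range(1, 5):
                    rows.append(
                        {"group": group, "repetition": rep, "fixation": fixation,
                         "contrast": shift + 0.1 * fixation + rng.normal(0, 0.05)}
                    )
        out = contrast_anova(pd.DataFrame(rows))
        assert out["group"]["p"] < 0.01
        assert out["fixation"]["p"] < 0.01
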