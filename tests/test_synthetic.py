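import numpy as np
import pytest
from dataclasses import replace
from math import factorial
from scipy import stats as sps

from prososcan import Group, GroupProfile, generate_cohort, generate_trial, preset_profiles
from prososcan.core import FaceTemplate, distance_from_center
from prososcan.synthetic import two_group_cohort


def _uniform_profile(**overrides) -> GroupProfile:
    kw = dict(
        name=Group.CONTROL,
        roi_transition=np.full((10, 10), 0.1),
        initial_roi_distribution=np.full(10, 0.1),
        spatial_jitter_sd=0.0,
        duration_lognormal=(np.log(250.0), 0.3),
        n_fixations_nb=(10.0, 10.0 / 29.0),
        trials_per_subject=5,
    )
    kw.update(overrides)
    return GroupProfile(**kw)


class TestGenerateTrial:
    def test_zero_jitter_lands_on_anchors_with_chain_roi(self, template):
        rng = np.random.default_rng(0)
        trial = generate_trial(_uniform_profile(), rng, template)
        for f in trial.fixations:
            assert (f.x, f.y) == template.anchor(f.roi)

    def test_degenerate_length_distribution(self):
        profile = _uniform_profile(n_fixations_nb=(5.0, 1.0), n_fixations_shift=5)
        rng = np.random.default_rng(1)
        lengths = {len(generate_trial(profile, rng)) for _ in range(20)}
        assert lengths == {5}

    def test_absorbing_nose_chain(self):
        init = np.zeros(10)
        init[7] = 1.0  # all mass on the nose
        profile = _uniform_profile(roi_transition=np.eye(10), initial_roi_distribution=init)
        rng = np.random.default_rng(2)
        trial = generate_trial(profile, rng)
        assert all(f.roi == 8 for f in trial.fixations)

    def test_invalid_transition_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            _uniform_profile(roi_transition=np.full((10, 10), 0.2))


class TestGenerateCohort:
    def test_same_seed_reproduces_cohort_exactly(self):
        profile = preset_profiles(trials_per_subject=3)["control"]
        a = generate_cohort(3, profile, seed=9)
        b = generate_cohort(3, profile, seed=9)
        assert a.to_frame().equals(b.to_frame())

    def test_trial_counting(self):
        profile = _uniform_profile(trials_per_subject=45)
        cohort = generate_cohort(20, profile, seed=0)
        assert len(cohort) == 900

    def test_learning_then_recognition_phases(self):
        profile = preset_profiles(trials_per_subject=12)["control"]
        cohort = generate_cohort(1, profile, seed=0)
        phases = [t.phase.value for t in cohort.trials]
        assert phases[:10] == ["learning"] * 10 and phases[10:] == ["recognition"] * 2

    def test_n_subjects_validated(self):
        with pytest.raises(ValueError):
            generate_cohort(0, _uniform_profile(), seed=0)


def _exact_prefix_left_right_expectation(profile: GroupProfile, m: int = 4) -> float:
    """Enumeration oracle: E[(L-R)/(L+R) | L+R>0] over the first m fixations
    of a rank-one chain (first fixation from the initial distribution,
    subsequent fixations i.i.d. from the shared transition row)."""
    init = profile.initial_roi_distribution
    row = profile.roi_transition[0]
    assert np.allclose(profile.roi_transition, row)  # rank-one presets only

    def cat_probs(p):
        return p[0], p[1], 1.0 - p[0] - p[1]  # (left eye, right eye, other)

    iL, iR, iO = cat_probs(init)
    rL, rR, rO = cat_probs(row)
    total, mass = 0.0, 0.0
    k = m - 1  # i.i.d. fixations after the first
    for first, pfirst in (((1, 0), iL), ((0, 1), iR), ((0, 0), iO)):
        for l in range(k + 1):
            for r in range(k - l + 1):
                p = (
                    pfirst
                    * factorial(k)
                    / (factorial(l) * factorial(r) * factorial(k - l - r))
                    * rL**l * rR**r * rO ** (k - l - r)
                )
                L, R = first[0] + l, first[1] + r
                if L + R > 0:
                    total += p * (L - R) / (L + R)
                    mass += p
    return total / mass


@pytest.fixture(scope="module")
def big_cohorts():
    presets = preset_profiles(trials_per_subject=500, subject_heterogeneity_sd=0.0)
    return {
        name: generate_cohort(4, presets[name], seed=11 + i)
        for i, name in enumerate(["control", "acquired", "developmental"])
    }  # 2,000 trials per group


class TestPresetProfiles:
    @staticmethod
    def _trial_lr_indices(cohort, m=4):
        vals = []
        for t in cohort.trials:
            codes = t.roi_sequence(m)
            L, R = int((codes == 1).sum()), int((codes == 2).sum())
            if L + R > 0:
                vals.append((L - R) / (L + R))
        return np.array(vals)

    def test_control_mean_left_right_positive(self, big_cohorts):
        assert self._trial_lr_indices(big_cohorts["control"]).mean() > 0

    def test_acquired_mean_left_right_negative(self, big_cohorts):
        assert self._trial_lr_indices(big_cohorts["acquired"]).mean() < 0

    def test_control_left_right_matches_chain_enumeration(self):
        """Monte-Carlo mean of the per-trial prefix left:right index agrees
        with the exact enumeration over the unperturbed chain (3 SE)."""
        profile = preset_profiles(trials_per_subject=2500, subject_heterogeneity_sd=0.0)[
            "control"
        ]
        profile = replace(profile, spatial_jitter_sd=0.0)  # keep codes = chain states
        cohort = generate_cohort(4, profile, seed=3)  # 10,000 trials
        vals = self._trial_lr_indices(cohort)
        expected = _exact_prefix_left_right_expectation(profile)
        se = vals.std(ddof=1) / np.sqrt(len(vals))
        assert abs(vals.mean() - expected) < 3 * se

    def test_developmental_more_dispersed_than_control(self, big_cohorts, template):
        def mean_trial_sd(cohort):
            sds = []
            for t in cohort.trials:
                if len(t) < 8:
                    continue
                d = [distance_from_center(f, template) for f in t.fixations[:8]]
                sds.append(np.std(d, ddof=1))
            return np.mean(sds)

        assert mean_trial_sd(big_cohorts["developmental"]) > mean_trial_sd(big_cohorts["control"])

    def test_most_developmental_trials_survive_m16(self, big_cohorts):
        lengths = np.array([len(t) for t in big_cohorts["developmental"].trials])
        assert (lengths >= 16).mean() >= 0.6
        assert (lengths < 16).any()  # attrition is actually exercised

    def test_visit_frequencies_match_chain_marginal(self):
        """Chi-square goodness of fit of post-first ROI visit frequencies
        against the chain's transition row (jitter 0, 10,000 fixations)."""
        profile = preset_profiles(trials_per_subject=600, subject_heterogeneity_sd=0.0)["control"]
        profile = replace(profile, spatial_jitter_sd=0.0)
        cohort = generate_cohort(1, profile, seed=4)
        codes = np.concatenate([t.roi_sequence()[1:] for t in cohort.trials])[:10000]
        counts = np.bincount(codes - 1, minlength=10)
        expected = profile.roi_transition[0] * counts.sum()
        chi2 = ((counts - expected) ** 2 / expected).sum()
        assert sps.chi2.sf(chi2, df=9) > 0.01

    def test_profile_yaml_round_trip(self, tmp_path):
        profile = preset_profiles()["acquired"]
        path = tmp_path / "p.yaml"
        profile.to_yaml(path)
        again = GroupProfile.from_yaml(path)
        assert np.allclose(again.roi_transition, profile.roi_transition)
        assert again.name is Group.ACQUIRED


def test_two_group_cohort_holds_both_groups():
    presets = preset_profiles(trials_per_subject=2)
    cohort = two_group_cohort(presets["control"], presets["acquired"], 3, 2, seed=0)
    counts = cohort.group_counts()
    assert counts["control"] == 3 and counts["acquired"] == 2
    assert len(cohort) == 10
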