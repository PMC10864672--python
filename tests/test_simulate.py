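"""Synthetic cohort generator: structure, calibration, recovery."""

import numpy as np
import pandas as pd
import pytest

from runiei.clustering import FuzzyKMeans, match_clusters
from runiei.iei import compute_iei
from runiei.simulate import (
    BLOCK_STRUCTURE,
    CohortConfig,
    LatentProfile,
    RTParams,
    calibrate_shift,
    default_profiles,
    generate_cohort,
    generate_stiat_session,
)
from runiei.stiat import score_cohort, score_participant


def uniform_profile(**overrides):
    base = dict(
        label="flat",
        implicit_mean=0.0, implicit_sd=0.0,
        explicit_mean=5.0, explicit_sd=0.0,
        running_behavior_probs=(1 / 3, 1 / 3, 1 / 3),
        ssk_subscale_means=(3.0, 3.0, 3.0, 3.0),
        ssk_subscale_sds=(0.5, 0.5, 0.5, 0.5),
        intention_mean=5.0, intention_sd=1.0,
        effort_mean=5.0, effort_sd=1.0,
        past_experience_probs=(0.2, 0.2, 0.2, 0.2, 0.2),
    )
    base.update(overrides)
    return LatentProfile(**base)


class TestSessionStructure:
    def test_block_sizes_and_stimulus_ratios(self):
        session = generate_stiat_session("P1", 0.0, seed=1, shift_ms=0.0)
        sizes = session.groupby("block").size().to_dict()
        assert sizes == {"B1": 24, "B2": 44, "B3": 84, "B4": 44, "B5": 84}
        counts = (
            session.groupby(["block", "stimulus_type"]).size().unstack(fill_value=0)
        )
        for block, (n_s, n_f, n_r) in BLOCK_STRUCTURE.items():
            assert counts.loc[block, "smiley"] == n_s
            assert counts.loc[block, "frowny"] == n_f
            assert counts.loc[block].get("runner", 0) == n_r

    def test_conditions_follow_blocks(self):
        session = generate_stiat_session("P1", 0.0, seed=1, shift_ms=0.0)
        cond = session.groupby("block")["condition"].unique()
        assert list(cond["B1"]) == ["affective_only"]
        assert list(cond["B2"]) == list(cond["B3"]) == ["negative_assoc"]
        assert list(cond["B4"]) == list(cond["B5"]) == ["positive_assoc"]

    def test_rts_positive_and_trial_index_unique(self):
        session = generate_stiat_session("P1", 0.3, seed=2, shift_ms=80.0)
        assert (session["rt_ms"] > 0).all()
        assert not session.duplicated(["block", "trial_index"]).any()

    def test_deterministic_under_seed(self):
        a = generate_stiat_session("P1", 0.2, seed=7, shift_ms=40.0)
        b = generate_stiat_session("P1", 0.2, seed=7, shift_ms=40.0)
        pd.testing.assert_frame_equal(a, b)


class TestCalibration:
    def test_g_stats_matches_public_scoring(self, calibration):
        """The vectorized calibration scorer must equal the stiat pipeline."""
        from runiei.simulate import _apply_condition_shift, _CONDITIONS_ARR

        for shift in (0.0, 120.0, -90.0):
            p = calibration.rt_params
            rts = p.mu_ms + p.sigma_ms * calibration._normals + calibration._expos
            _apply_condition_shift(rts, shift)
            np.maximum(rts, p.min_rt_ms, out=rts)
            per_session = [
                _score_like_gstats(row, _CONDITIONS_ARR) for row in rts
            ]
            assert calibration.expected_g(shift) == pytest.approx(
                np.mean(per_session), abs=1e-10
            )

    def test_zero_target_needs_near_zero_shift(self, calibration):
        assert abs(calibration.shift_for_interp(0.0)) < 8.0

    def test_monotone_in_target(self, calibration):
        shifts = [calibration.shift_for_interp(g) for g in (-0.6, -0.2, 0.0, 0.2, 0.6)]
        assert np.all(np.diff(shifts) > 0)

    def test_calibrate_shift_roundtrip(self, calibration):
        shift = calibrate_shift(0.4, n_rep=200, seed=0, tol=0.02)
        assert abs(calibration.expected_g(shift) - 0.4) < 0.03

    def test_unreachable_target_raises(self, calibration):
        with pytest.raises(ValueError, match="range"):
            calibration.shift_for(3.0)
        with pytest.raises(ValueError, match="range"):
            calibration.shift_for_interp(np.array([0.1, -2.5]))

    def test_planted_value_recovered_in_expectation(self, calibration):
        """Fresh sessions (seeds disjoint from calibration) score near target."""
        target = 0.5
        shift = float(calibration.shift_for_interp(target))
        gs = [
            score_participant(
                generate_stiat_session("P1", target, seed=1000 + i, shift_ms=shift)
            ).g
            for i in range(120)
        ]
        assert abs(np.mean(gs) - target) < 3.5 * calibration.measurement_sd / np.sqrt(120)
        assert np.mean(np.array(gs) > 0) > 0.95

    def test_flat_rt_model_rejected(self):
        """All RTs clamp to the floor near zero shift: no usable curve."""
        from runiei.simulate import ShiftCalibration

        with pytest.raises(RuntimeError, match="flat"):
            ShiftCalibration(
                RTParams(mu_ms=1.0, sigma_ms=0.0, tau_ms=0.0), n_rep=10, seed=0
            )


def _score_like_gstats(row, conditions):
    """Reference scoring of one calibration session via the public path."""
    from runiei.stiat import _gscore_from_arrays

    scored = conditions != "affective_only"
    return _gscore_from_arrays(
        row[scored], (conditions[scored] == "negative_assoc"), 0.10, "inverse_normal"
    )


class TestCohort:
    def test_shape_and_profile_sizes(self, cohort):
        assert len(cohort.participants) == 89
        assert len(cohort.trials) == 89 * 280
        assert len(cohort.ground_truth) == 89
        sizes = cohort.ground_truth["profile_label"].value_counts()
        assert sizes["positive_non_discrepant"] == 36
        assert sizes["positive_discrepant"] == 16
        assert sizes["negative_discrepant"] == 20
        assert sizes["negative_non_discrepant"] == 17

    def test_deterministic_under_seed(self):
        small = CohortConfig(n_participants=6, profile_sizes=(2, 2, 1, 1), seed=5)
        a = generate_cohort(small)
        b = generate_cohort(small)
        pd.testing.assert_frame_equal(a.trials, b.trials)
        pd.testing.assert_frame_equal(a.participants, b.participants)
        pd.testing.assert_frame_equal(a.ground_truth, b.ground_truth)

    def test_variable_ranges(self, cohort):
        p = cohort.participants
        assert p["explicit_ft"].between(0, 10).all()
        assert p["intention"].between(1, 10).all()
        assert p["effort"].between(1, 10).all()
        assert p["past_experience"].between(1, 5).all()
        for i in range(1, 13):
            assert p[f"ssk_{i:02d}"].between(1, 6).all()
        assert p["running_behavior"].isin(["regular", "irregular", "non"]).all()
        # runs_per_week consistent with the category
        regular = p["running_behavior"] == "regular"
        assert (p.loc[regular, "runs_per_week"] >= 1).all()
        assert (p.loc[p["running_behavior"] == "non", "runs_per_week"] == 0).all()

    def test_no_exclusions_without_contamination(self, cohort_scores):
        assert not cohort_scores["excluded"].any()

    def test_fast_guess_contamination_triggers_exclusions(self):
        cfg = CohortConfig(
            n_participants=4,
            profile_sizes=(1, 1, 1, 1),
            rt_params=RTParams(fast_guess_rate=0.25),
            seed=3,
        )
        scores = score_cohort(generate_cohort(cfg).trials)
        assert scores["excluded"].all()

    def test_zero_variance_profile_is_degenerate(self):
        cfg = CohortConfig(
            n_participants=3,
            profile_sizes=(3,),
            profiles=(uniform_profile(explicit_mean=8.0),),
            seed=2,
        )
        data = generate_cohort(cfg)
        assert (data.participants["explicit_ft"] == 8).all()
        assert np.allclose(data.ground_truth["planted_implicit"], 0.0)

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError, match="sum"):
            CohortConfig(n_participants=10, profile_sizes=(3, 3, 3, 3)).validate()
        with pytest.raises(ValueError, match="one size per profile"):
            CohortConfig(n_participants=9, profile_sizes=(3, 3, 3)).validate()
        with pytest.raises(ValueError, match="SDs"):
            uniform_profile(implicit_sd=-0.1).validate()
        with pytest.raises(ValueError, match="probabilities"):
            uniform_profile(running_behavior_probs=(0.5, 0.5, 0.5)).validate()
        with pytest.raises(ValueError, match="separation_scale"):
            CohortConfig(separation_scale=0.0).validate()
        with pytest.raises(ValueError, match="custom profiles"):
            CohortConfig(
                n_participants=3,
                profile_sizes=(3,),
                profiles=(uniform_profile(),),
                separation_scale=2.0,
            ).effective_profiles()

    def test_separation_scaling_widens_profiles_about_grand_mean(self):
        base = default_profiles(1.0)
        wide = default_profiles(3.0)
        w = np.array([36, 16, 20, 17]) / 89.0
        # implicit means scale exactly about the size-weighted grand mean
        g_base = sum(p.implicit_mean * wi for p, wi in zip(base, w))
        g_wide = sum(p.implicit_mean * wi for p, wi in zip(wide, w))
        assert g_wide == pytest.approx(g_base, abs=1e-9)
        spread = lambda ps: max(p.implicit_mean for p in ps) - min(
            p.implicit_mean for p in ps
        )
        assert spread(wide) == pytest.approx(3.0 * spread(base), rel=1e-9)
        # explicit means widen too but stay clipped to the 0-10 scale
        g_exp = sum(p.explicit_mean * wi for p, wi in zip(base, w))
        for b, s in zip(base, wide):
            assert 0.0 <= s.explicit_mean <= 10.0
            assert abs(s.explicit_mean - g_exp) >= abs(b.explicit_mean - g_exp) - 1e-9


class TestRecovery:
    def test_scored_g_tracks_planted_value(self, cohort_merged):
        r = np.corrcoef(cohort_merged["g"], cohort_merged["planted_implicit"])[0, 1]
        assert r >= 0.8

    def test_mean_ari_at_default_separation(self):
        """Fuzzy profiles recover the planted partition at realistic overlap:
        mean adjusted Rand over six cohorts at the calibrated separations."""
        from sklearn.metrics import adjusted_rand_score

        aris = []
        for seed in range(1, 7):
            data = generate_cohort(CohortConfig(seed=seed))
            scores = score_cohort(data.trials)
            merged = scores.merge(data.participants, on="participant_id").merge(
                data.ground_truth, on="participant_id"
            )
            iei = compute_iei(merged["g"], merged["explicit_ft"])
            fkm = FuzzyKMeans(n_clusters=4, random_state=0).fit(
                iei[["iec", "ied"]].to_numpy()
            )
            aris.append(
                adjusted_rand_score(merged["profile_label"], fkm.labels_)
            )
        assert np.mean(aris) >= 0.6
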