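"""G-Score scoring and split-half reliability."""

from statistics import NormalDist

import numpy as np
import pandas as pd
import pytest

from runiei.simulate import RTParams, generate_stiat_session
from runiei.stiat import (
    _gscore_fast,
    compute_gscore,
    exclude_fast_responders,
    gaussian_rank_transform,
    score_cohort,
    score_participant,
    select_scoring_trials,
    split_half_reliability,
    winsorize_rts,
)

from conftest import make_session_frame, noiseless_cohort_trials


def ref_gscore(rts, is_negative, tail_fraction=0.10):
    """Step-by-step stdlib reference implementation (test oracle)."""
    rts = list(map(float, rts))
    n = len(rts)
    if tail_fraction > 0:
        s = sorted(rts)

        def quantile(q):
            pos = (n - 1) * q
            lo = int(pos)
            frac = pos - lo
            return s[lo] if frac == 0 else s[lo] * (1 - frac) + s[lo + 1] * frac

        lo_v, hi_v = quantile(tail_fraction), quantile(1 - tail_fraction)
        rts = [min(max(r, lo_v), hi_v) for r in rts]
    ranks = [
        1 + sum(o < r for o in rts) + (sum(o == r for o in rts) - 1) / 2.0
        for r in rts
    ]
    dev = [NormalDist().inv_cdf((rk - 0.5) / n) for rk in ranks]
    neg = [d for d, m in zip(dev, is_negative) if m]
    pos = [d for d, m in zip(dev, is_negative) if not m]
    return sum(neg) / len(neg) - sum(pos) / len(pos)


class TestSelectScoringTrials:
    def test_drops_b1_keeps_errors(self):
        session = generate_stiat_session("P1", 0.0, seed=3, shift_ms=0.0)
        scored = select_scoring_trials(session)
        assert len(scored) == 256
        assert set(scored["block"]) == {"B2", "B3", "B4", "B5"}
        # error trials are retained untreated
        assert (~scored["correct"]).sum() > 0

    def test_only_b1_gives_empty(self):
        session = generate_stiat_session("P1", 0.0, seed=3, shift_ms=0.0)
        b1 = session.loc[session["block"] == "B1"]
        assert len(select_scoring_trials(b1)) == 0

    def test_unknown_block_rejected(self):
        bad = pd.DataFrame({"block": ["B9"], "rt_ms": [500.0]})
        with pytest.raises(ValueError, match="unknown block"):
            select_scoring_trials(bad)

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            select_scoring_trials(pd.DataFrame({"block": [], "rt_ms": []}))


class TestFastResponderRule:
    @pytest.mark.parametrize(
        "n_fast, expect_excluded",
        [(0, False), (25, False), (26, True), (256, True)],
    )
    def test_strict_boundary_at_10_percent_of_256(self, n_fast, expect_excluded):
        rts = np.full(256, 600.0)
        rts[:n_fast] = 250.0
        excluded, fraction = exclude_fast_responders(pd.DataFrame({"rt_ms": rts}))
        assert excluded is expect_excluded
        assert fraction == pytest.approx(n_fast / 256)

    def test_exactly_300ms_is_not_fast(self):
        excluded, fraction = exclude_fast_responders(
            pd.DataFrame({"rt_ms": np.full(100, 300.0)})
        )
        assert not excluded and fraction == 0.0

    def test_score_participant_returns_nan_record(self):
        frame = make_session_frame(
            {"negative_assoc": 250.0, "positive_assoc": 600.0}
        )
        res = score_participant(frame)
        assert res.excluded and np.isnan(res.g)
        with pytest.raises(ValueError, match="excluded"):
            compute_gscore(frame)


class TestWinsorize:
    def test_constant_unchanged(self):
        x = np.full(20, 500.0)
        assert np.array_equal(winsorize_rts(x), x)

    def test_tail_zero_is_identity(self):
        x = np.array([100.0, 900.0, 500.0])
        assert np.array_equal(winsorize_rts(x, 0.0), x)

    def test_against_quantile_oracle(self):
        rng = np.random.default_rng(5)
        x = rng.uniform(200, 1500, 37)
        lo, hi = np.quantile(x, [0.1, 0.9])
        expected = np.minimum(np.maximum(x, lo), hi)
        assert np.allclose(winsorize_rts(x), expected)

    def test_order_and_bounds_preserved(self):
        rng = np.random.default_rng(6)
        x = np.sort(rng.exponential(200, 50)) + 200
        w = winsorize_rts(x)
        assert np.all(np.diff(w) >= 0)
        assert w.min() >= np.quantile(x, 0.1) - 1e-12
        assert w.max() <= np.quantile(x, 0.9) + 1e-12

    def test_invalid_tail_fraction(self):
        with pytest.raises(ValueError):
            winsorize_rts([1.0, 2.0], tail_fraction=0.5)


class TestGaussianRankTransform:
    def test_single_value_maps_to_zero(self):
        assert gaussian_rank_transform([432.0]) == pytest.approx([0.0])

    def test_four_distinct_values_closed_form(self):
        dev = gaussian_rank_transform([400.0, 500.0, 600.0, 700.0])
        expected = [NormalDist().inv_cdf(p) for p in (0.125, 0.375, 0.625, 0.875)]
        assert np.allclose(dev, expected)

    def test_symmetric_and_finite(self):
        dev = gaussian_rank_transform(np.arange(1, 101, dtype=float))
        assert np.isfinite(dev).all()
        assert dev.sum() == pytest.approx(0.0, abs=1e-10)

    def test_ties_get_average_rank(self):
        dev = gaussian_rank_transform([500.0, 500.0, 700.0])
        # tied pair shares rank 1.5 -> p = 1/3
        assert dev[0] == pytest.approx(dev[1])
        assert dev[0] == pytest.approx(NormalDist().inv_cdf(1.0 / 3.0))

    def test_zscore_convention(self):
        dev = gaussian_rank_transform(np.arange(10.0), convention="zscore")
        assert dev.mean() == pytest.approx(0.0, abs=1e-12)
        assert dev.std(ddof=1) == pytest.approx(1.0)

    def test_unknown_convention(self):
        with pytest.raises(ValueError, match="convention"):
            gaussian_rank_transform([1.0, 2.0], convention="rankit")


class TestComputeGScore:
    def test_identical_condition_multisets_score_zero(self):
        frame = make_session_frame(
            {"negative_assoc": lambda i: 400.0 + 10 * (i % 12),
             "positive_assoc": lambda i: 400.0 + 10 * (i % 12)}
        )
        assert compute_gscore(frame).g == pytest.approx(0.0, abs=1e-12)

    def test_small_example_against_stdlib_oracle(self):
        neg = [412.0, 530.0, 488.0, 600.0]
        pos = [390.0, 455.0, 470.0, 520.0]
        frame = make_session_frame(
            {"negative_assoc": lambda i: neg[i % 4],
             "positive_assoc": lambda i: pos[i % 4]},
            n_per_stratum=4,
        )
        rts = frame["rt_ms"].to_numpy()
        is_neg = (frame["condition"] == "negative_assoc").to_numpy()
        for tail in (0.0, 0.10):
            got = compute_gscore(frame, tail_fraction=tail).g
            assert got == pytest.approx(ref_gscore(rts, is_neg, tail), abs=1e-12)

    def test_antisymmetry_under_condition_swap(self):
        rng = np.random.default_rng(7)
        frame = make_session_frame(
            {"negative_assoc": lambda i: 400 + 200 * rng.random(),
             "positive_assoc": lambda i: 420 + 150 * rng.random()}
        )
        g = compute_gscore(frame).g
        swapped = frame.copy()
        swapped["condition"] = swapped["condition"].map(
            {"negative_assoc": "positive_assoc", "positive_assoc": "negative_assoc"}
        )
        assert compute_gscore(swapped).g == pytest.approx(-g, abs=1e-12)

    def test_invariance_under_monotone_transform(self):
        """Rank-based: any strictly increasing RT transform leaves G fixed
        (winsorizing disabled so caps do not re-enter raw units)."""
        rng = np.random.default_rng(8)
        frame = make_session_frame(
            {"negative_assoc": lambda i: 350 + 500 * rng.random(),
             "positive_assoc": lambda i: 350 + 400 * rng.random()}
        )
        g = compute_gscore(frame, tail_fraction=0.0).g
        transforms = (lambda x: 3.0 * x + 17.0, np.log, lambda x: x**2)
        for transform in transforms:
            warped = frame.copy()
            warped["rt_ms"] = transform(warped["rt_ms"] / 100.0) + 1000.0
            assert compute_gscore(warped, tail_fraction=0.0).g == pytest.approx(
                g, abs=1e-12
            )

    def test_rejects_affective_only_and_single_condition(self):
        frame = make_session_frame(
            {"negative_assoc": 500.0, "positive_assoc": 600.0}
        )
        b1ish = frame.copy()
        b1ish.loc[0, "condition"] = "affective_only"
        with pytest.raises(ValueError, match="affective_only"):
            compute_gscore(b1ish)
        one_cond = frame.loc[frame["condition"] == "negative_assoc"]
        with pytest.raises(ValueError, match="both association conditions"):
            compute_gscore(one_cond)


class TestFastPathEquivalence:
    def test_matches_public_pipeline_including_ties(self):
        rng = np.random.default_rng(9)
        for _ in range(60):
            n = int(rng.integers(8, 120))
            rts = np.round(rng.uniform(300, 1200, n), int(rng.integers(0, 2)))
            is_neg = rng.random(n) < 0.5
            if is_neg.all() or not is_neg.any():
                continue
            for tail in (0.0, 0.10, 0.2):
                fast = _gscore_fast(rts, is_neg, tail)
                slow = ref_gscore(rts, is_neg, tail)
                assert fast == pytest.approx(slow, abs=1e-10)


class TestScoreCohort:
    def test_one_row_per_participant_in_order(self, cohort, cohort_scores):
        assert list(cohort_scores["participant_id"]) == list(
            cohort.participants["participant_id"]
        )
        assert set(cohort_scores.columns) == {
            "participant_id", "g", "n_trials_scored", "fraction_fast", "excluded",
        }
        assert (cohort_scores["n_trials_scored"] == 256).all()

    def test_no_exclusions_without_fast_guessing(self, cohort_scores):
        assert not cohort_scores["excluded"].any()
        assert np.isfinite(cohort_scores["g"]).all()


class TestSplitHalfReliability:
    def test_deterministic_under_seed(self):
        trials = pd.concat(
            [
                generate_stiat_session(f"P{i}", 0.0, seed=i, shift_ms=30.0 * i)
                for i in range(6)
            ],
            ignore_index=True,
        )
        a = split_half_reliability(trials, n_replications=20, seed=42)
        b = split_half_reliability(trials, n_replications=20, seed=42)
        assert a == b

    def test_noiseless_simulation_is_perfectly_reliable(self):
        params = RTParams(sigma_ms=1.0, tau_ms=0.0, error_rate=0.0)
        trials = pd.concat(
            [
                generate_stiat_session(
                    f"P{i}", 0.0, rt_params=params, seed=i, shift_ms=25.0 * i
                )
                for i in range(10)
            ],
            ignore_index=True,
        )
        rel = split_half_reliability(trials, n_replications=50, seed=0)
        assert rel.r_mean >= 0.99

    def test_degenerate_zero_noise_returns_one(self):
        rel = split_half_reliability(
            noiseless_cohort_trials(8), n_replications=10, seed=0
        )
        # rank scores are identical across participants and halves
        assert rel.r_mean == pytest.approx(1.0)

    def test_bootstrap_scheme_and_spearman_run(self, cohort):
        two = cohort.trials[
            cohort.trials["participant_id"].isin(["P01", "P02", "P03", "P04"])
        ]
        rel = split_half_reliability(
            two, n_replications=5, seed=1, scheme="bootstrap", correlation="spearman"
        )
        assert -1.0 <= rel.r_mean <= 1.0

    def test_realistic_cohort_reliability_plausible(self, cohort):
        rel = split_half_reliability(cohort.trials, n_replications=100, seed=3)
        assert 0.6 <= rel.r_mean <= 0.95
        assert rel.n_replications == 100

    def test_rejects_bad_arguments(self, cohort):
        with pytest.raises(ValueError):
            split_half_reliability(cohort.trials, n_replications=0)
        with pytest.raises(ValueError, match="scheme"):
            split_half_reliability(cohort.trials, n_replications=1, scheme="odd_even")
        one = cohort.trials[cohort.trials["participant_id"] == "P01"]
        with pytest.raises(ValueError, match="2 participants"):
            split_half_reliability(one, n_replications=1)
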