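"""Synthetic ST-IAT cohort generator with planted four-profile structure.

No public data accompany the original cohort, so every downstream stage is
exercised on simulated data. The generator emulates

* the exact task structure: five blocks of 24/44/84/44/84 trials with
  smiley:frowny:runner stimulus ratios of 12:12:20 in practice blocks and
  24:24:36 in critical blocks; blocks B2/B3 form the negative association
  condition and B4/B5 the positive one;
* trial-level reaction times from an ex-Gaussian model (normal plus
  exponential component — the standard skewed RT family), with a pure
  location shift between association conditions calibrated by Monte-Carlo
  so that the *expected scored G* of a session equals the participant's
  planted implicit value;
* a four-profile population (positive non-discrepant, positive discrepant,
  negative discrepant, negative non-discrepant) whose per-profile means and
  SDs of implicit/explicit associations, motivation subscales, intention
  and effort, and whose running-behavior/past-experience category
  frequencies, are calibrated to the printed cluster summaries of the
  reference cohort (n = 89, profile sizes 36/16/20/17).

Because the printed per-profile SD of the implicit score describes
*observed* (scored) G values, which include rank-scoring measurement noise,
latent planted values are drawn with variance reduced by the calibrated
measurement variance of the scoring procedure.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import norm as _norm
from scipy.stats import rankdata as _rankdata

from .questionnaires import classify_running_behavior, score_ehi
from .stiat import BLOCK_CONDITION

_norm_ppf = _norm.ppf

__all__ = [
    "RTParams",
    "LatentProfile",
    "CohortConfig",
    "CohortData",
    "ShiftCalibration",
    "calibrate_shift",
    "default_profiles",
    "generate_stiat_session",
    "generate_cohort",
    "BLOCK_STRUCTURE",
    "FIXATION_MS",
    "INTERTRIAL_INTERVAL_MS",
]

#: task timing metadata, recorded as constants only (no rendering).
FIXATION_MS = 700
INTERTRIAL_INTERVAL_MS = 1200

#: per-block stimulus counts (smiley, frowny, runner). B1 has affective
#: categories only; practice blocks B2/B4 use the 12:12:20 ratio and
#: critical blocks B3/B5 the 24:24:36 ratio.
BLOCK_STRUCTURE: dict[str, tuple[int, int, int]] = {
    "B1": (12, 12, 0),
    "B2": (12, 12, 20),
    "B3": (24, 24, 36),
    "B4": (12, 12, 20),
    "B5": (24, 24, 36),
}

PAST_EXPERIENCE_CATEGORIES = (1, 2, 3, 4, 5)  # see docs/methods.md
RUNNING_CATEGORIES = ("regular", "irregular", "non")


@dataclass(frozen=True)
class RTParams:
    """Ex-Gaussian RT model: ``rt = mu + sigma * N(0,1) + Exp(tau)``.

    ``tau_ms = 0`` gives a symmetric (pure normal) model. ``error_rate`` is
    the per-trial probability of an incorrect response (errors are retained
    in scoring); ``fast_guess_rate`` is the fraction of trials replaced by
    uniform fast guesses on (150, 299) ms, used to exercise the
    fast-responder exclusion rule.
    """

    mu_ms: float = 450.0
    sigma_ms: float = 80.0
    tau_ms: float = 150.0
    error_rate: float = 0.05
    fast_guess_rate: float = 0.0
    min_rt_ms: float = 180.0

    def validate(self) -> None:
        if self.sigma_ms < 0 or self.tau_ms < 0 or self.min_rt_ms <= 0:
            raise ValueError("RT scale parameters must be nonnegative")
        for rate in (self.error_rate, self.fast_guess_rate):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must be in [0, 1]")


@dataclass(frozen=True)
class LatentProfile:
    """Ground-truth affective profile a participant is drawn from."""

    label: str
    implicit_mean: float
    implicit_sd: float
    explicit_mean: float
    explicit_sd: float
    running_behavior_probs: tuple[float, float, float]  # regular, irregular, non
    ssk_subscale_means: tuple[float, float, float, float]  # intr, ident, intro, extr
    ssk_subscale_sds: tuple[float, float, float, float]
    intention_mean: float
    intention_sd: float
    effort_mean: float
    effort_sd: float
    past_experience_probs: tuple[float, float, float, float, float]

    def validate(self) -> None:
        for probs in (self.running_behavior_probs, self.past_experience_probs):
            if abs(sum(probs) - 1.0) > 1e-9 or min(probs) < 0:
                raise ValueError(f"{self.label}: probabilities must sum to 1")
        sds = (
            self.implicit_sd,
            self.explicit_sd,
            self.intention_sd,
            self.effort_sd,
            *self.ssk_subscale_sds,
        )
        if min(sds) < 0:
            raise ValueError(f"{self.label}: SDs must be >= 0")
        if not 0 <= self.explicit_mean <= 10:
            raise ValueError(f"{self.label}: explicit mean outside 0-10")
        if not all(1 <= m <= 6 for m in self.ssk_subscale_means):
            raise ValueError(f"{self.label}: SSK means outside 1-6")
        for m in (self.intention_mean, self.effort_mean):
            if not 1 <= m <= 10:
                raise ValueError(f"{self.label}: intention/effort mean outside 1-10")


def default_profiles(separation_scale: float = 1.0) -> tuple[LatentProfile, ...]:
    """The four affective profiles calibrated to the reference cohort.

    ``separation_scale`` multiplies the deviation of each profile's implicit
    and explicit mean from the cross-profile grand mean (sample-size
    weighted); values > 1 make profiles easier to separate, used by the
    parameter-recovery analyses.
    """
    base = (
        LatentProfile(
            label="positive_non_discrepant",
            implicit_mean=0.14, implicit_sd=0.18,
            explicit_mean=7.97, explicit_sd=1.18,
            running_behavior_probs=(17 / 36, 14 / 36, 5 / 36),
            ssk_subscale_means=(4.20, 5.14, 3.41, 1.52),
            ssk_subscale_sds=(1.25, 0.78, 0.89, 0.81),
            intention_mean=7.56, intention_sd=2.51,
            effort_mean=7.42, effort_sd=1.84,
            past_experience_probs=(1 / 36, 3 / 36, 1 / 36, 14 / 36, 17 / 36),
        ),
        LatentProfile(
            label="positive_discrepant",
            implicit_mean=-0.37, implicit_sd=0.19,
            explicit_mean=8.44, explicit_sd=0.96,
            running_behavior_probs=(7 / 16, 8 / 16, 1 / 16),
            ssk_subscale_means=(4.52, 5.48, 4.04, 1.19),
            ssk_subscale_sds=(1.18, 0.53, 1.18, 0.52),
            intention_mean=8.00, intention_sd=2.16,
            effort_mean=7.81, effort_sd=1.68,
            past_experience_probs=(1 / 16, 2 / 16, 1 / 16, 5 / 16, 7 / 16),
        ),
        LatentProfile(
            label="negative_discrepant",
            implicit_mean=0.07, implicit_sd=0.17,
            explicit_mean=2.65, explicit_sd=1.35,
            running_behavior_probs=(1 / 20, 4 / 20, 15 / 20),
            ssk_subscale_means=(1.68, 2.93, 2.35, 1.57),
            ssk_subscale_sds=(0.88, 1.45, 1.32, 1.01),
            intention_mean=3.10, intention_sd=2.73,
            effort_mean=4.25, effort_sd=2.67,
            past_experience_probs=(9 / 20, 4 / 20, 3 / 20, 3 / 20, 1 / 20),
        ),
        LatentProfile(
            label="negative_non_discrepant",
            implicit_mean=-0.43, implicit_sd=0.28,
            explicit_mean=4.29, explicit_sd=1.65,
            running_behavior_probs=(0.0, 8 / 17, 9 / 17),
            ssk_subscale_means=(2.18, 3.59, 2.59, 1.33),
            ssk_subscale_sds=(0.92, 1.04, 0.98, 0.68),
            intention_mean=3.41, intention_sd=1.87,
            effort_mean=4.35, effort_sd=1.93,
            past_experience_probs=(6 / 17, 2 / 17, 6 / 17, 3 / 17, 0.0),
        ),
    )
    if separation_scale == 1.0:
        return base
    sizes = np.array([36, 16, 20, 17], dtype=float)
    w = sizes / sizes.sum()
    grand_imp = float(sum(p.implicit_mean * wi for p, wi in zip(base, w)))
    grand_exp = float(sum(p.explicit_mean * wi for p, wi in zip(base, w)))
    scaled = []
    for p in base:
        imp = grand_imp + separation_scale * (p.implicit_mean - grand_imp)
        exp = grand_exp + separation_scale * (p.explicit_mean - grand_exp)
        scaled.append(
            replace(p, implicit_mean=imp, explicit_mean=float(np.clip(exp, 0, 10)))
        )
    return tuple(scaled)


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions for a simulated cohort."""

    n_participants: int = 89
    profile_sizes: tuple[int, ...] = (36, 16, 20, 17)
    profiles: tuple[LatentProfile, ...] = field(default_factory=default_profiles)
    rt_params: RTParams = field(default_factory=RTParams)
    seed: int | None = None
    separation_scale: float = 1.0

    def validate(self) -> None:
        if len(self.profile_sizes) != len(self.profiles):
            raise ValueError("one size per profile required")
        if sum(self.profile_sizes) != self.n_participants:
            raise ValueError(
                f"profile sizes {self.profile_sizes} do not sum to "
                f"n_participants = {self.n_participants}"
            )
        if self.separation_scale <= 0:
            raise ValueError("separation_scale must be > 0")
        self.rt_params.validate()
        for p in self.profiles:
            p.validate()

    def effective_profiles(self) -> tuple[LatentProfile, ...]:
        if self.separation_scale == 1.0:
            return self.profiles
        if self.profiles == default_profiles():
            return default_profiles(self.separation_scale)
        raise ValueError(
            "separation_scale is only supported with the default profiles; "
            "scale custom profiles explicitly"
        )


@dataclass
class CohortData:
    """Generator output: trial table, participant table, ground truth."""

    trials: pd.DataFrame
    participants: pd.DataFrame
    ground_truth: pd.DataFrame  # participant_id, profile_label, planted_implicit


def _session_structure() -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Static per-trial block, condition and stimulus-type arrays."""
    blocks, stim = [], []
    for block, (n_s, n_f, n_r) in BLOCK_STRUCTURE.items():
        stimuli = ["smiley"] * n_s + ["frowny"] * n_f + ["runner"] * n_r
        blocks.extend([block] * len(stimuli))
        stim.extend(stimuli)
    blocks = np.array(blocks)
    conditions = np.array([BLOCK_CONDITION[b] for b in blocks])
    return blocks, conditions, np.array(stim)


_BLOCKS_ARR, _CONDITIONS_ARR, _STIM_ARR = _session_structure()
_N_TRIALS = len(_BLOCKS_ARR)
_SCORED = _CONDITIONS_ARR != "affective_only"
_NEGATIVE = _CONDITIONS_ARR == "negative_assoc"
_POSITIVE = _CONDITIONS_ARR == "positive_assoc"


def _apply_condition_shift(rts, shift_ms: float) -> None:
    """Slow the association-incongruent condition by ``|shift_ms|`` in place.

    A positive implicit association (positive shift) slows the negative
    association condition, and vice versa; responding is never made faster
    than baseline, so the condition effect cannot inflate the fast-trial
    fraction. ``rts`` may be 1-D (one session) or 2-D (sessions x trials).
    """
    if shift_ms >= 0:
        rts[..., _NEGATIVE] += shift_ms
    else:
        rts[..., _POSITIVE] -= shift_ms


def _session_rts(
    rt_params: RTParams, shift_ms: float, rng: np.random.Generator
) -> np.ndarray:
    """One session's RT vector with stimulus order shuffled within blocks."""
    rts = (
        rt_params.mu_ms
        + rt_params.sigma_ms * rng.standard_normal(_N_TRIALS)
        + (rng.exponential(rt_params.tau_ms, _N_TRIALS) if rt_params.tau_ms > 0 else 0.0)
    )
    _apply_condition_shift(rts, shift_ms)
    np.maximum(rts, rt_params.min_rt_ms, out=rts)
    if rt_params.fast_guess_rate > 0:
        guess = rng.random(_N_TRIALS) < rt_params.fast_guess_rate
        rts[guess] = rng.uniform(150.0, 299.0, int(guess.sum()))
    return rts


class ShiftCalibration:
    """Monte-Carlo map between the condition RT shift and the expected G.

    The Gaussian-rank transform has no closed form for the expected scored
    G under a location shift, so the map is estimated empirically: a fixed
    set of ``n_rep`` base sessions is simulated once (common random
    numbers), and ``expected_g(shift)`` rescores those sessions under the
    given shift. Under common random numbers the map is smooth and strictly
    increasing, so a planted G is inverted by bisection (or, for whole
    cohorts, by interpolation on a precomputed grid).
    """

    def __init__(
        self,
        rt_params: RTParams,
        n_rep: int = 200,
        seed: int | None = 0,
        max_shift_ms: float = 800.0,
        grid_size: int = 33,
    ):
        rt_params.validate()
        # calibration characterizes the noise model itself: fast guesses /
        # errors do not enter the scored RT path, so they are disabled here
        self.rt_params = replace(rt_params, fast_guess_rate=0.0)
        self.n_rep = n_rep
        self.max_shift_ms = float(max_shift_ms)
        rng = np.random.default_rng(seed)
        self._normals = rng.standard_normal((n_rep, _N_TRIALS))
        if self.rt_params.tau_ms > 0:
            self._expos = rng.exponential(self.rt_params.tau_ms, (n_rep, _N_TRIALS))
        else:
            self._expos = np.zeros((n_rep, _N_TRIALS))
        shift_grid = np.linspace(-max_shift_ms, max_shift_ms, grid_size)
        stats = [self._g_stats(s) for s in shift_grid]
        g_grid = np.array([m for m, _ in stats])
        #: measurement SD of a scored session at zero planted effect
        self.measurement_sd = float(stats[grid_size // 2][1])
        # the curve saturates (and, with the minimum-RT clamp, can wobble
        # slightly) once the conditions are nearly perfectly separated; keep
        # the contiguous strictly increasing run around zero shift
        diffs = np.diff(g_grid)
        mid = grid_size // 2
        lo = mid
        while lo > 0 and diffs[lo - 1] > 1e-4:
            lo -= 1
        hi = mid
        while hi < grid_size - 1 and diffs[hi] > 1e-4:
            hi += 1
        if hi - lo < 2:
            raise RuntimeError("calibration curve is flat for this RT model")
        self._shift_grid = shift_grid[lo : hi + 1]
        self._g_grid = g_grid[lo : hi + 1]

    def _g_stats(self, shift_ms: float) -> tuple[float, float]:
        # vectorized replica of the scoring pipeline (winsorize 10% per
        # tail, mid-rank Gaussian transform, condition mean difference);
        # equivalence with stiat.compute_gscore is asserted in the tests
        p = self.rt_params
        rts = p.mu_ms + p.sigma_ms * self._normals + self._expos
        _apply_condition_shift(rts, shift_ms)
        np.maximum(rts, p.min_rt_ms, out=rts)
        x = rts[:, _SCORED]
        lo = np.quantile(x, 0.10, axis=1, keepdims=True)
        hi = np.quantile(x, 0.90, axis=1, keepdims=True)
        x = np.clip(x, lo, hi)
        ranks = _rankdata(x, axis=1)
        deviates = _norm_ppf((ranks - 0.5) / x.shape[1])
        neg = _NEGATIVE[_SCORED]
        gs = deviates[:, neg].mean(axis=1) - deviates[:, ~neg].mean(axis=1)
        return float(gs.mean()), float(gs.std(ddof=1))

    @property
    def g_range(self) -> tuple[float, float]:
        return float(self._g_grid[0]), float(self._g_grid[-1])

    def expected_g(self, shift_ms: float) -> float:
        """Mean scored G over the calibration sessions at a given shift."""
        return self._g_stats(shift_ms)[0]

    def shift_for(self, g_target: float, tol: float = 0.02) -> float:
        """Invert the map by bisection to within ``tol`` G units."""
        lo, hi = float(self._shift_grid[0]), float(self._shift_grid[-1])
        g_lo, g_hi = self.g_range
        if not g_lo - tol <= g_target <= g_hi + tol:
            raise ValueError(
                f"planted G {g_target:.3f} outside achievable range "
                f"({g_lo:.3f}, {g_hi:.3f}) for this RT model"
            )
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            g_mid = self.expected_g(mid)
            if abs(g_mid - g_target) < tol:
                return mid
            if g_mid < g_target:
                lo = mid
            else:
                hi = mid
            if hi - lo < 1e-3:
                break
        raise RuntimeError("shift bisection did not converge within tolerance")

    def shift_for_interp(self, g_target) -> np.ndarray:
        """Fast grid-interpolated inverse, used for whole cohorts."""
        g_target = np.asarray(g_target, dtype=float)
        g_lo, g_hi = self.g_range
        if np.any(g_target < g_lo) or np.any(g_target > g_hi):
            raise ValueError("planted G outside achievable calibration range")
        return np.interp(g_target, self._g_grid, self._shift_grid)


def calibrate_shift(
    g_target: float,
    rt_params: RTParams | None = None,
    n_rep: int = 200,
    seed: int | None = 0,
    tol: float = 0.02,
) -> float:
    """Condition shift (ms) whose simulated expected G matches ``g_target``.

    Monotone in ``g_target``; raises when the target lies outside the
    achievable range of the RT model or the bisection fails to converge.
    """
    cal = ShiftCalibration(rt_params or RTParams(), n_rep=n_rep, seed=seed)
    return cal.shift_for(g_target, tol=tol)


def generate_stiat_session(
    participant_id: str,
    planted_implicit: float,
    rt_params: RTParams | None = None,
    seed: int | None = None,
    calibration: ShiftCalibration | None = None,
    shift_ms: float | None = None,
) -> pd.DataFrame:
    """Simulate one full five-block ST-IAT session.

    The condition shift is taken from ``shift_ms`` when given, otherwise
    calibrated so the expected scored G equals ``planted_implicit``.
    Returns a trial table with columns ``participant_id, block,
    trial_index, condition, stimulus_type, rt_ms, correct``.
    """
    rt_params = rt_params or RTParams()
    rt_params.validate()
    rng = np.random.default_rng(seed)
    if shift_ms is None:
        if calibration is None:
            calibration = ShiftCalibration(rt_params)
        shift_ms = float(calibration.shift_for_interp(planted_implicit))
    rts = _session_rts(rt_params, shift_ms, rng)
    # shuffle stimulus order within blocks (RTs are i.i.d. given condition,
    # so only the stimulus sequence needs shuffling)
    stim = _STIM_ARR.copy()
    trial_index = np.empty(_N_TRIALS, dtype=int)
    for block in BLOCK_STRUCTURE:
        idx = np.flatnonzero(_BLOCKS_ARR == block)
        stim[idx] = stim[rng.permutation(idx)]
        trial_index[idx] = np.arange(idx.size)
    correct = rng.random(_N_TRIALS) >= rt_params.error_rate
    return pd.DataFrame(
        {
            "participant_id": participant_id,
            "block": _BLOCKS_ARR,
            "trial_index": trial_index,
            "condition": _CONDITIONS_ARR,
            "stimulus_type": stim,
            "rt_ms": rts,
            "correct": correct,
        }
    )


def _draw_discrete_normal(
    rng, mean: float, sd: float, lo: int, hi: int, size: int
) -> np.ndarray:
    """Normal draws rounded to integers and clamped to a scale range."""
    return np.clip(np.round(rng.normal(mean, sd, size)), lo, hi).astype(int)


_EHI_ITEM_CHOICES = {
    "right": (("usually_right", "always_right"), (0.35, 0.65)),
    "left": (("usually_left", "always_left"), (0.35, 0.65)),
    "ambidextrous": (
        ("usually_left", "no_preference", "usually_right"),
        (0.2, 0.6, 0.2),
    ),
}


def _draw_ehi_items(rng, cls: str) -> list[str]:
    choices, probs = _EHI_ITEM_CHOICES[cls]
    while True:
        items = list(rng.choice(choices, size=8, p=probs))
        if score_ehi(items)[1] == cls:
            return items


def generate_cohort(config: CohortConfig | None = None) -> CohortData:
    """Simulate a full cohort: ST-IAT sessions plus the participant table.

    One session and one participant row per person; each participant's
    variables are drawn from their latent profile (truncated/discretized to
    scale ranges) and the profile label plus planted implicit value are
    recorded as ground truth. Deterministic under a fixed ``config.seed``.
    """
    config = config or CohortConfig()
    config.validate()
    profiles = config.effective_profiles()
    ss = np.random.SeedSequence(
        config.seed if config.seed is not None else np.random.SeedSequence().entropy
    )
    seed_cal, seed_people, seed_sessions = ss.spawn(3)
    calibration = ShiftCalibration(
        config.rt_params, seed=seed_cal.generate_state(1)[0] % 2**31
    )
    rng = np.random.default_rng(seed_people)
    g_lo, g_hi = calibration.g_range
    meas_var = calibration.measurement_sd**2

    trial_frames = []
    part_rows = []
    truth_rows = []
    session_seeds = seed_sessions.spawn(config.n_participants)
    pid_width = len(str(config.n_participants))
    i_person = 0
    # cohort-level attributes not tied to a profile
    occupations = rng.choice(
        ["high_school", "university", "working", "not_reported"],
        size=config.n_participants,
        p=(2 / 89, 56 / 89, 29 / 89, 2 / 89),
    )
    main_exercises = rng.choice(
        ["running", "other", "none"],
        size=config.n_participants,
        p=(6 / 89, 80 / 89, 3 / 89),
    )
    handed_classes = rng.choice(
        ["right", "left", "ambidextrous"],
        size=config.n_participants,
        p=(77 / 89, 6 / 89, 6 / 89),
    )
    for profile, size in zip(profiles, config.profile_sizes):
        # latent implicit variance: printed SDs describe scored G values,
        # so subtract the scoring measurement variance (floored at 25%)
        latent_sd = np.sqrt(
            max(profile.implicit_sd**2 - meas_var, (0.25 * profile.implicit_sd) ** 2)
        )
        for _ in range(size):
            pid = f"P{i_person + 1:0{pid_width}d}"
            planted = float(
                np.clip(
                    rng.normal(profile.implicit_mean, latent_sd),
                    g_lo + 1e-6,
                    g_hi - 1e-6,
                )
            )
            explicit = int(
                _draw_discrete_normal(
                    rng, profile.explicit_mean, profile.explicit_sd, 0, 10, 1
                )[0]
            )
            ssk_items = np.empty(12, dtype=int)
            for s in range(4):
                latent = rng.normal(
                    profile.ssk_subscale_means[s], profile.ssk_subscale_sds[s]
                )
                ssk_items[3 * s : 3 * s + 3] = np.clip(
                    np.round(latent + rng.normal(0.0, 0.5, 3)), 1, 6
                ).astype(int)
            intention = int(
                _draw_discrete_normal(
                    rng, profile.intention_mean, profile.intention_sd, 1, 10, 1
                )[0]
            )
            effort = int(
                _draw_discrete_normal(
                    rng, profile.effort_mean, profile.effort_sd, 1, 10, 1
                )[0]
            )
            behavior = rng.choice(
                RUNNING_CATEGORIES, p=profile.running_behavior_probs
            )
            if behavior == "regular":
                runs_per_week = float(np.round(rng.uniform(1.0, 4.0), 1))
            elif behavior == "irregular":
                runs_per_week = float(np.round(rng.uniform(0.1, 0.9), 1))
            else:
                runs_per_week = 0.0
            assert classify_running_behavior(runs_per_week) == behavior
            past = int(rng.choice(PAST_EXPERIENCE_CATEGORIES, p=profile.past_experience_probs))
            ehi_items = _draw_ehi_items(rng, handed_classes[i_person])
            ehi_score, ehi_class = score_ehi(ehi_items)
            row = {
                "participant_id": pid,
                "age": int(rng.integers(18, 31)),
                "occupation": occupations[i_person],
                "explicit_ft": explicit,
                "intention": intention,
                "effort": effort,
                "past_experience": past,
                "running_behavior": behavior,
                "runs_per_week": runs_per_week,
                "main_exercise": main_exercises[i_person],
                "ehi_score": ehi_score,
                "handedness": ehi_class,
            }
            row.update({f"ssk_{j + 1:02d}": int(v) for j, v in enumerate(ssk_items)})
            row.update({f"ehi_{j + 1}": r for j, r in enumerate(ehi_items)})
            part_rows.append(row)
            truth_rows.append(
                {
                    "participant_id": pid,
                    "profile_label": profile.label,
                    "planted_implicit": planted,
                }
            )
            trial_frames.append(
                generate_stiat_session(
                    pid,
                    planted,
                    rt_params=config.rt_params,
                    seed=session_seeds[i_person],
                    calibration=calibration,
                )
            )
            i_person += 1
    return CohortData(
        trials=pd.concat(trial_frames, ignore_index=True),
        participants=pd.DataFrame(part_rows),
        ground_truth=pd.DataFrame(truth_rows),
    )
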