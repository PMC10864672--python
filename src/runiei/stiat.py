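"""ST-IAT G-Score computation and split-half reliability.

The Single-Target Implicit Association Test (ST-IAT) measures the implicit
affective association towards one target concept (running) by comparing
response speeds between two association conditions: blocks in which the
target shares a response key with negative stimuli versus blocks in which it
shares a key with positive stimuli.

Scoring follows the rank-based G-Score algorithm:

1.  participants with more than 10% of scored trials faster than 300 ms are
    excluded,
2.  practice and critical trials of blocks B2-B5 are scored; block B1
    (affective categories only) is dropped; error trials are retained,
3.  extreme reaction times are treated by 10% winsorizing per tail,
4.  all retained reaction times are pooled regardless of condition, given
    fractional (average-tie) ranks, converted to mid-rank percentiles
    ``p = (rank - 0.5) / N`` and mapped through the inverse standard-normal
    CDF,
5.  the G-Score is the mean Gaussian deviate under the negative association
    condition minus the mean under the positive association condition, so a
    positive score indicates a positive implicit association (faster
    responding when the target is paired with positive stimuli).

Internal consistency is estimated by stratified Monte-Carlo split-half
reliability: trials are repeatedly split within strata defined by
association condition x stimulus type, both halves are scored, the
half-scores are correlated across participants, and the replication
correlations are averaged (no Spearman-Brown step).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import ndtri
from scipy.stats import norm, rankdata, spearmanr

__all__ = [
    "BLOCKS",
    "BLOCK_CONDITION",
    "STIMULUS_TYPES",
    "FAST_RT_MS",
    "FAST_FRACTION_LIMIT",
    "GScoreResult",
    "ReliabilityEstimate",
    "select_scoring_trials",
    "exclude_fast_responders",
    "winsorize_rts",
    "gaussian_rank_transform",
    "compute_gscore",
    "score_participant",
    "score_cohort",
    "split_half_reliability",
]

BLOCKS = ("B1", "B2", "B3", "B4", "B5")

#: condition is fully determined by block: B1 features affective categories
#: only; B2/B3 pair the target with negative stimuli, B4/B5 with positive.
BLOCK_CONDITION = {
    "B1": "affective_only",
    "B2": "negative_assoc",
    "B3": "negative_assoc",
    "B4": "positive_assoc",
    "B5": "positive_assoc",
}

STIMULUS_TYPES = ("smiley", "frowny", "runner")

FAST_RT_MS = 300.0
FAST_FRACTION_LIMIT = 0.10


@dataclass(frozen=True)
class GScoreResult:
    """Per-participant scoring outcome.

    ``g`` is NaN when the participant is excluded (more than 10% of the
    scored trials are faster than 300 ms).
    """

    participant_id: str
    g: float
    n_trials_scored: int
    fraction_fast: float
    excluded: bool


@dataclass(frozen=True)
class ReliabilityEstimate:
    """Mean split-half correlation over Monte-Carlo replications."""

    r_mean: float
    r_sd: float
    n_replications: int
    seed: int | None
    strata: str = "association condition x stimulus type"


def _require_columns(trials: pd.DataFrame, cols: tuple[str, ...]) -> None:
    missing = [c for c in cols if c not in trials.columns]
    if missing:
        raise ValueError(f"trials table is missing columns: {missing}")


def select_scoring_trials(trials: pd.DataFrame) -> pd.DataFrame:
    """Return the trials entering the G-Score: blocks B2-B5, errors kept.

    Both practice (B2, B4) and critical (B3, B5) blocks are scored; no
    distinction is made between them within an association condition.
    Error trials are retained untreated.
    """
    _require_columns(trials, ("block", "rt_ms"))
    if len(trials) == 0:
        raise ValueError("empty trials table")
    unknown = set(trials["block"].unique()) - set(BLOCKS)
    if unknown:
        raise ValueError(f"unknown block labels: {sorted(unknown)}")
    return trials.loc[trials["block"] != "B1"].copy()


def exclude_fast_responders(trials: pd.DataFrame) -> tuple[bool, float]:
    """Participant-level exclusion rule for fast responding.

    Returns ``(excluded, fraction_fast)``; excluded is True iff strictly
    more than 10% of the scored trials have RT < 300 ms. Fast trials are
    *not* dropped for retained participants — winsorizing handles extremes.
    """
    _require_columns(trials, ("rt_ms",))
    if len(trials) == 0:
        raise ValueError("empty trials table")
    fraction = float(np.mean(trials["rt_ms"].to_numpy() < FAST_RT_MS))
    return fraction > FAST_FRACTION_LIMIT, fraction


def winsorize_rts(rts, tail_fraction: float = 0.10) -> np.ndarray:
    """Cap RTs below the ``tail_fraction`` quantile and above the
    ``1 - tail_fraction`` quantile at those quantiles.

    Quantiles use linear interpolation between order statistics. Order and
    length are preserved; with ``tail_fraction = 0`` the input is returned
    unchanged.
    """
    rts = np.asarray(rts, dtype=float)
    if rts.size == 0:
        raise ValueError("empty RT sequence")
    if not 0.0 <= tail_fraction < 0.5:
        raise ValueError("tail_fraction must be in [0, 0.5)")
    if tail_fraction == 0.0:
        return rts.copy()
    lo, hi = np.quantile(rts, [tail_fraction, 1.0 - tail_fraction])
    return np.clip(rts, lo, hi)


def gaussian_rank_transform(rts, convention: str = "inverse_normal") -> np.ndarray:
    """Map pooled RTs to standard-normal deviates via fractional ranks.

    Each RT receives a fractional (average-tie) rank ``r`` over the pooled
    ``N`` values; its mid-rank percentile is ``p = (r - 0.5) / N``. Under the
    default convention the output is the inverse standard-normal CDF of
    ``p``, which keeps deviates finite for the extreme ranks. The
    alternative convention ``"zscore"`` z-standardizes the raw percentiles
    instead.
    """
    rts = np.asarray(rts, dtype=float)
    if rts.size == 0:
        raise ValueError("empty RT sequence")
    ranks = rankdata(rts, method="average")
    p = (ranks - 0.5) / rts.size
    if convention == "inverse_normal":
        return norm.ppf(p)
    if convention == "zscore":
        if rts.size < 2 or np.ptp(p) == 0:
            raise ValueError("zscore convention needs >= 2 distinct values")
        return (p - p.mean()) / p.std(ddof=1)
    raise ValueError(f"unknown convention: {convention!r}")


def _gscore_fast(rts: np.ndarray, is_negative: np.ndarray, tail_fraction: float) -> float:
    """Low-overhead replica of the winsorize/rank/G pipeline.

    Used in the Monte-Carlo reliability loop where the scipy call overhead
    dominates; agrees with :func:`compute_gscore` to numerical precision
    (asserted by the test suite). Inverse-normal convention only.
    """
    n = rts.size
    order = np.argsort(rts, kind="stable")
    x = rts[order]
    if tail_fraction > 0.0:
        # linear-interpolation quantiles on the sorted values
        for q, bound in ((tail_fraction, 0), (1.0 - tail_fraction, 1)):
            pos = (n - 1) * q
            lo = int(pos)
            frac = pos - lo
            val = x[lo] if frac == 0 else x[lo] * (1 - frac) + x[lo + 1] * frac
            if bound == 0:
                x = np.maximum(x, val)
            else:
                x = np.minimum(x, val)
    # average ranks of the (still sorted) winsorized values
    starts = np.flatnonzero(np.r_[True, x[1:] != x[:-1]])
    counts = np.diff(np.r_[starts, n])
    avg_rank = starts + (counts + 1) / 2.0  # 1-based mid rank per tie group
    ranks = np.repeat(avg_rank, counts)
    deviates = ndtri((ranks - 0.5) / n)
    neg = is_negative[order]
    return float(deviates[neg].mean() - deviates[~neg].mean())


def _gscore_from_arrays(
    rts: np.ndarray,
    is_negative: np.ndarray,
    tail_fraction: float,
    convention: str,
) -> float:
    if not is_negative.any() or is_negative.all():
        raise ValueError("both association conditions must contain trials")
    deviates = gaussian_rank_transform(
        winsorize_rts(rts, tail_fraction), convention=convention
    )
    return float(deviates[is_negative].mean() - deviates[~is_negative].mean())


def compute_gscore(
    trials: pd.DataFrame,
    tail_fraction: float = 0.10,
    convention: str = "inverse_normal",
    participant_id: str | None = None,
) -> GScoreResult:
    """Score one participant's selected (B2-B5) trials.

    RTs of both conditions are pooled for winsorizing and the rank
    transform; the G-Score is the mean deviate of the negative association
    condition minus that of the positive condition. Raises for excluded
    participants (use :func:`score_participant` to obtain an exclusion
    record instead).
    """
    _require_columns(trials, ("condition", "rt_ms"))
    if len(trials) == 0:
        raise ValueError("empty trials table")
    if (trials["condition"] == "affective_only").any():
        raise ValueError("B1/affective_only trials must be removed before scoring")
    excluded, fraction_fast = exclude_fast_responders(trials)
    if excluded:
        raise ValueError(
            f"participant excluded: {fraction_fast:.1%} of trials < {FAST_RT_MS:g} ms"
        )
    if participant_id is None:
        ids = trials["participant_id"].unique() if "participant_id" in trials else ["?"]
        if len(ids) != 1:
            raise ValueError("trials must belong to a single participant")
        participant_id = str(ids[0])
    rts = trials["rt_ms"].to_numpy(dtype=float)
    is_negative = trials["condition"].to_numpy() == "negative_assoc"
    g = _gscore_from_arrays(rts, is_negative, tail_fraction, convention)
    return GScoreResult(
        participant_id=participant_id,
        g=g,
        n_trials_scored=int(len(trials)),
        fraction_fast=fraction_fast,
        excluded=False,
    )


def score_participant(
    trials: pd.DataFrame,
    tail_fraction: float = 0.10,
    convention: str = "inverse_normal",
) -> GScoreResult:
    """Full scoring pipeline for one participant's session (B1-B5 trials).

    Applies trial selection and the fast-responder rule; excluded
    participants yield a result with ``g = NaN`` rather than an error.
    """
    scored = select_scoring_trials(trials)
    ids = scored["participant_id"].unique() if "participant_id" in scored else ["?"]
    if len(ids) != 1:
        raise ValueError("trials must belong to a single participant")
    pid = str(ids[0])
    if len(scored) == 0:
        raise ValueError(f"participant {pid}: no scorable (B2-B5) trials")
    excluded, fraction_fast = exclude_fast_responders(scored)
    if excluded:
        return GScoreResult(pid, float("nan"), int(len(scored)), fraction_fast, True)
    return compute_gscore(
        scored, tail_fraction=tail_fraction, convention=convention, participant_id=pid
    )


def score_cohort(
    trials: pd.DataFrame,
    tail_fraction: float = 0.10,
    convention: str = "inverse_normal",
) -> pd.DataFrame:
    """Score every participant in a trials table.

    Returns one row per participant with columns ``participant_id, g,
    n_trials_scored, fraction_fast, excluded``, in participant order of
    first appearance.
    """
    _require_columns(trials, ("participant_id",))
    rows = []
    for pid, grp in trials.groupby("participant_id", sort=False):
        res = score_participant(grp, tail_fraction=tail_fraction, convention=convention)
        rows.append(
            {
                "participant_id": pid,
                "g": res.g,
                "n_trials_scored": res.n_trials_scored,
                "fraction_fast": res.fraction_fast,
                "excluded": res.excluded,
            }
        )
    return pd.DataFrame(rows)


def _participant_arrays(trials: pd.DataFrame, tail_fraction: float):
    """Precompute per-participant numpy arrays for the reliability loop."""
    out = []
    for pid, grp in trials.groupby("participant_id", sort=False):
        scored = select_scoring_trials(grp)
        excluded, _ = exclude_fast_responders(scored)
        if excluded:
            continue
        rts = scored["rt_ms"].to_numpy(dtype=float)
        neg = scored["condition"].to_numpy() == "negative_assoc"
        stim = scored["stimulus_type"].to_numpy()
        # stratum id = condition x stimulus type
        strata_keys = np.char.add(np.where(neg, "n|", "p|"), stim.astype(str))
        strata = [np.flatnonzero(strata_keys == k) for k in np.unique(strata_keys)]
        for idx in strata:
            if idx.size < 2:
                raise ValueError(
                    f"participant {pid}: stratum with fewer than 2 trials"
                )
        out.append((rts, neg, strata))
    return out


def split_half_reliability(
    trials: pd.DataFrame,
    n_replications: int = 10_000,
    seed: int | None = None,
    tail_fraction: float = 0.10,
    scheme: str = "disjoint",
    correlation: str = "pearson",
    convention: str = "inverse_normal",
) -> ReliabilityEstimate:
    """Stratified Monte-Carlo split-half reliability of the G-Score.

    Per replication, each retained participant's scored trials are split
    within strata (association condition x stimulus type) into two halves,
    each half is scored through the full winsorize/rank/G pipeline, and the
    half-scores are correlated across participants. The estimate is the
    simple mean of the replication correlations.

    ``scheme="disjoint"`` (default) splits each stratum into two disjoint
    random halves; with an odd stratum size the extra trial joins a half at
    random. ``scheme="bootstrap"`` draws both halves with replacement, the
    literal reading of resampling "with replacement".
    """
    if n_replications < 1:
        raise ValueError("n_replications must be >= 1")
    if scheme not in ("disjoint", "bootstrap"):
        raise ValueError(f"unknown scheme: {scheme!r}")
    if correlation not in ("pearson", "spearman"):
        raise ValueError(f"unknown correlation: {correlation!r}")
    data = _participant_arrays(trials, tail_fraction)
    if len(data) < 2:
        raise ValueError("need at least 2 participants with valid scores")
    rng = np.random.default_rng(seed)
    n_p = len(data)
    rs = np.empty(n_replications)
    g1 = np.empty(n_p)
    g2 = np.empty(n_p)
    for rep in range(n_replications):
        for i, (rts, neg, strata) in enumerate(data):
            half1: list[np.ndarray] = []
            half2: list[np.ndarray] = []
            for idx in strata:
                n = idx.size
                if scheme == "disjoint":
                    perm = rng.permutation(idx)
                    n1 = n // 2
                    if n % 2 and rng.random() < 0.5:
                        n1 += 1
                    half1.append(perm[:n1])
                    half2.append(perm[n1:])
                else:
                    n1 = n // 2 + (n % 2 and rng.random() < 0.5)
                    half1.append(rng.choice(idx, size=max(n1, 1), replace=True))
                    half2.append(rng.choice(idx, size=max(n - n1, 1), replace=True))
            i1 = np.concatenate(half1)
            i2 = np.concatenate(half2)
            if convention == "inverse_normal":
                g1[i] = _gscore_fast(rts[i1], neg[i1], tail_fraction)
                g2[i] = _gscore_fast(rts[i2], neg[i2], tail_fraction)
            else:
                g1[i] = _gscore_from_arrays(rts[i1], neg[i1], tail_fraction, convention)
                g2[i] = _gscore_from_arrays(rts[i2], neg[i2], tail_fraction, convention)
        if correlation == "pearson":
            s1, s2 = g1.std(), g2.std()
            if s1 == 0 or s2 == 0:
                # degenerate (e.g. noiseless simulations): identical halves
                rs[rep] = 1.0 if np.allclose(g1, g2) else 0.0
            else:
                rs[rep] = float(np.corrcoef(g1, g2)[0, 1])
        else:
            rs[rep] = float(spearmanr(g1, g2).statistic)
    return ReliabilityEstimate(
        r_mean=float(rs.mean()),
        r_sd=float(rs.std(ddof=1)) if n_replications > 1 else 0.0,
        n_replications=n_replications,
        seed=seed,
    )
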