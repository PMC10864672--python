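"""Scoring of the self-report instruments and descriptive statistics.

Covers the running-adapted sport- and exercise-related self-concordance
scale (SSK: intrinsic, identified, introjected, extrinsic motivation and
the self-concordance index), single-item intention strength and effort
readiness, the 8-item rating-scale Edinburgh Handedness Inventory, the
current running-behavior categorization, Cronbach's alpha and the
moment-based descriptives (mean, SD, range, skew, kurtosis) used in the
cohort summary tables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "DEFAULT_SSK_ITEM_MAP",
    "EHI_WEIGHTS",
    "SskScores",
    "score_ssk",
    "score_ehi",
    "classify_running_behavior",
    "cronbach_alpha",
    "describe",
]

#: item-index (0-based) to subscale assignment for the 12 SSK items;
#: configurable because the running-adapted instrument does not fix an
#: ordering — three items per motivational subdimension.
DEFAULT_SSK_ITEM_MAP: dict[str, tuple[int, int, int]] = {
    "intrinsic": (0, 1, 2),
    "identified": (3, 4, 5),
    "introjected": (6, 7, 8),
    "extrinsic": (9, 10, 11),
}

#: laterality-quotient weights for the 5-point EHI preference ratings;
#: sum of weights over 8 items divided by the maximum (16) scales to +-100.
EHI_WEIGHTS = {
    "always_left": -2,
    "usually_left": -1,
    "no_preference": 0,
    "usually_right": 1,
    "always_right": 2,
}


@dataclass(frozen=True)
class SskScores:
    """Subscale means (1-6 scale) and the self-concordance index.

    ``ssk_index = (intrinsic + identified) - (introjected + extrinsic)``,
    bounded in [-10, 10].
    """

    intrinsic: float
    identified: float
    introjected: float
    extrinsic: float

    @property
    def ssk_index(self) -> float:
        return (self.intrinsic + self.identified) - (self.introjected + self.extrinsic)


def score_ssk(items, item_map: dict | None = None) -> SskScores:
    """Score the 12 SSK items (responses 1-6) into subscale means.

    Each of the four subscales is the mean of its three items; no
    imputation — out-of-range or missing responses raise.
    """
    items = np.asarray(items, dtype=float)
    if items.shape != (12,):
        raise ValueError("expected exactly 12 SSK item responses")
    if np.isnan(items).any():
        raise ValueError("missing SSK item responses")
    if ((items < 1) | (items > 6)).any() or not np.all(items == np.round(items)):
        raise ValueError("SSK responses must be integers in 1..6")
    item_map = DEFAULT_SSK_ITEM_MAP if item_map is None else item_map
    means = {}
    seen: set[int] = set()
    for sub in ("intrinsic", "identified", "introjected", "extrinsic"):
        idx = item_map[sub]
        if len(idx) != 3 or seen.intersection(idx):
            raise ValueError("item map must assign 3 distinct items per subscale")
        seen.update(idx)
        means[sub] = float(items[list(idx)].mean())
    return SskScores(**means)


def score_ehi(items) -> tuple[float, str]:
    """Laterality quotient and handedness class from 8 EHI preference items.

    Responses are the five preference categories; the quotient is
    ``100 * sum(weights) / 16`` in [-100, 100]. Classes: left-handed
    (-100..-50), ambidextrous (-49..+49), right-handed (+50..+100).
    """
    items = list(items)
    if len(items) != 8:
        raise ValueError("expected exactly 8 EHI item responses")
    try:
        total = sum(EHI_WEIGHTS[r] for r in items)
    except KeyError as exc:
        raise ValueError(f"unknown EHI response: {exc.args[0]!r}") from None
    score = 100.0 * total / (2 * 8)
    if score <= -50:
        cls = "left"
    elif score >= 50:
        cls = "right"
    else:
        cls = "ambidextrous"
    return score, cls


def classify_running_behavior(runs_per_week: float) -> str:
    """Categorize current running behavior from the 6-month weekly average.

    0 -> "non", below one run per week -> "irregular", at least one run per
    week -> "regular".
    """
    if runs_per_week < 0:
        raise ValueError("runs_per_week must be >= 0")
    if runs_per_week == 0:
        return "non"
    if runs_per_week < 1:
        return "irregular"
    return "regular"


def cronbach_alpha(item_matrix) -> float:
    """Cronbach's alpha: ``p/(p-1) * (1 - sum(var_items) / var(sum))``.

    ``item_matrix`` is n observations x p items; variances use the sample
    (n-1) denominator.
    """
    X = np.asarray(item_matrix, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("need an n x p matrix with p >= 2 items")
    p = X.shape[1]
    var_total = X.sum(axis=1).var(ddof=1)
    if var_total == 0:
        raise ValueError("zero variance of item sums: alpha undefined")
    return float(p / (p - 1) * (1 - X.var(axis=0, ddof=1).sum() / var_total))


def describe(values) -> dict[str, float | tuple[float, float]]:
    """Moment descriptives in the layout of the cohort summary table.

    Returns mean, sample SD, range, moment skewness ``m3 / m2^1.5`` and
    non-excess kurtosis ``m4 / m2^2`` (a normal distribution gives about 3).
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 values")
    m2 = ((x - x.mean()) ** 2).mean()
    if m2 == 0:
        raise ValueError("zero variance: skew/kurtosis undefined")
    m3 = ((x - x.mean()) ** 3).mean()
    m4 = ((x - x.mean()) ** 4).mean()
    return {
        "mean": float(x.mean()),
        "sd": float(x.std(ddof=1)),
        "range": (float(x.min()), float(x.max())),
        "skew": float(m3 / m2**1.5),
        "kurtosis": float(m4 / m2**2),
    }
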