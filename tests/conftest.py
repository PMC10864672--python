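"""Shared fixtures: expensive cohort simulations are session-scoped."""

import numpy as np
import pandas as pd
import pytest

from runiei.simulate import CohortConfig, RTParams, ShiftCalibration, generate_cohort
from runiei.stiat import score_cohort


@pytest.fixture(scope="session")
def calibration():
    """One shift calibration shared across tests (default RT model)."""
    return ShiftCalibration(RTParams(), n_rep=200, seed=0)


@pytest.fixture(scope="session")
def cohort():
    """Default-separation cohort, n = 89, seed 1."""
    return generate_cohort(CohortConfig(seed=1))


@pytest.fixture(scope="session")
def cohort_scores(cohort):
    return score_cohort(cohort.trials)


@pytest.fixture(scope="session")
def cohort_merged(cohort, cohort_scores):
    """Scores + participant table + ground truth, exclusions dropped."""
    valid = cohort_scores.loc[~cohort_scores["excluded"]]
    return valid.merge(cohort.participants, on="participant_id").merge(
        cohort.ground_truth, on="participant_id"
    )


@pytest.fixture(scope="session")
def tripled_cohort():
    """Cohort with tripled profile separation (parameter recovery)."""
    return generate_cohort(CohortConfig(seed=11, separation_scale=3.0))


def make_session_frame(rts_by_condition, n_per_stratum=4):
    """Minimal scorable one-participant trial table.

    ``rts_by_condition`` maps condition -> callable(i) or constant giving
    the RT of the i-th trial of each (condition, stimulus) stratum.
    """
    rows = []
    i = 0
    for block, condition in (("B2", "negative_assoc"), ("B4", "positive_assoc")):
        for stim in ("smiley", "frowny", "runner"):
            for t in range(n_per_stratum):
                spec = rts_by_condition[condition]
                rt = spec(i) if callable(spec) else spec
                rows.append(
                    {
                        "participant_id": "P1",
                        "block": block,
                        "trial_index": len(rows),
                        "condition": condition,
                        "stimulus_type": stim,
                        "rt_ms": float(rt),
                        "correct": True,
                    }
                )
                i += 1
    return pd.DataFrame(rows)


def noiseless_cohort_trials(n_participants=12):
    """Deterministic RTs: condition gap varies by participant, no noise."""
    frames = []
    for p in range(n_participants):
        frame = make_session_frame(
            {
                "negative_assoc": 600.0 + 15.0 * p,
                "positive_assoc": 500.0,
            }
        )
        frame["participant_id"] = f"S{p + 1:02d}"
        frames.append(frame)
    return pd.concat(frames, ignore_index=True)


def exact_rank_sum_p(x, y):
    """Two-sided exact Mann-Whitney p by full enumeration (test oracle)."""
    from itertools import combinations

    from scipy.stats import rankdata

    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    n1 = len(x)
    obs = ranks[:n1].sum()
    mean = n1 * (len(pooled) + 1) / 2.0
    stats = [
        sum(ranks[list(c)]) for c in combinations(range(len(pooled)), n1)
    ]
    stats = np.asarray(stats)
    return float(np.mean(np.abs(stats - mean) >= abs(obs - mean) - 1e-9))


def all_partitions(items):
    """Every set partition of ``items`` as a label vector (test oracle)."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in all_partitions(rest):
        k = max(part, default=-1) + 1
        for c in range(k):
            yield [c] + part
        yield [k] + part
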