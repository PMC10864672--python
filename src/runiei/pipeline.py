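"""End-to-end orchestration: simulate -> score -> IEI -> cluster -> compare.

Every stage writes plain-text artifacts (CSV/JSON/TSV) into a run directory
and a manifest records the configuration, the per-stage seeds and a SHA-256
checksum of each artifact, so a rerun with an identical configuration is
byte-identical and auditable.

A single master seed fans out to per-stage seeds through
``numpy.random.SeedSequence([master, stage_index])`` with a fixed stage
order (simulate=0, reliability=1, clustering=2, comparison=3), so stages
are independently rerunnable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .clustering import (
    FuzzyKMeans,
    cut_tree_k,
    kmeans_cluster,
    label_clusters,
    match_clusters,
    mean_membership_table,
    overlap_table,
    rand_index,
    ward_tree,
)
from .compare import fisher_exact_rxc, kruskal_wallis_eta2, pairwise_wilcoxon_bonferroni
from .iei import compute_iei
from .io import (
    read_participants_csv,
    read_trials_csv,
    write_participants_csv,
    write_trials_csv,
)
from .questionnaires import score_ssk
from .simulate import CohortConfig, RTParams, generate_cohort
from .stiat import score_cohort, split_half_reliability

logger = logging.getLogger("runiei")

__all__ = ["PipelineConfig", "run_pipeline", "add_ssk_scores"]

_STAGES = ("simulate", "reliability", "clustering", "comparison")

CONTINUOUS_VARIABLES = (
    "intrinsic",
    "identified",
    "introjected",
    "extrinsic",
    "self_concordance",
    "intention",
    "effort",
)
CATEGORICAL_VARIABLES = ("running_behavior", "past_experience")


@dataclass
class PipelineConfig:
    """Options for a full analysis run; see docs/methods.md for defaults."""

    seed: int = 1
    out_dir: str = "runiei_run"
    # inputs: when trials_csv is unset, a cohort is simulated
    trials_csv: str | None = None
    participants_csv: str | None = None
    # simulator
    n_participants: int = 89
    profile_sizes: tuple[int, ...] = (36, 16, 20, 17)
    separation_scale: float = 1.0
    rt_params: dict = field(default_factory=dict)
    # ST-IAT scoring
    tail_fraction: float = 0.10
    convention: str = "inverse_normal"
    # reliability (0 disables the stage)
    n_replications: int = 500
    reliability_scheme: str = "disjoint"
    reliability_correlation: str = "pearson"
    # clustering
    k: int = 4
    m: float = 2.0
    n_starts: int = 25
    max_iter: int = 1000
    tol: float = 1e-9
    # comparison
    continuous_variables: tuple[str, ...] = CONTINUOUS_VARIABLES
    categorical_variables: tuple[str, ...] = CATEGORICAL_VARIABLES
    mc_draws: int = 100_000

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if not 0.0 <= self.tail_fraction < 0.5:
            raise ValueError("tail_fraction must be in [0, 0.5)")
        if self.k < 1 or self.m <= 1.0 or self.n_starts < 1:
            raise ValueError("invalid clustering options")
        if self.n_replications < 0 or self.mc_draws < 1:
            raise ValueError("invalid resampling options")

    def stage_seed(self, stage: str) -> int:
        """Per-stage seed derived from the master seed (always < 2**31)."""
        idx = _STAGES.index(stage)
        return int(np.random.SeedSequence([self.seed, idx]).generate_state(1)[0] % 2**31)


def add_ssk_scores(participants: pd.DataFrame) -> pd.DataFrame:
    """Append SSK subscale means and the self-concordance index."""
    out = participants.copy()
    item_cols = [f"ssk_{i:02d}" for i in range(1, 13)]
    scores = [score_ssk(row) for row in out[item_cols].to_numpy()]
    out["intrinsic"] = [s.intrinsic for s in scores]
    out["identified"] = [s.identified for s in scores]
    out["introjected"] = [s.introjected for s in scores]
    out["extrinsic"] = [s.extrinsic for s in scores]
    out["self_concordance"] = [s.ssk_index for s in scores]
    return out


def _json_ready(obj):
    if isinstance(obj, dict):
        return {str(k): _json_ready(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_json_ready(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return _json_ready(obj.tolist())
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return None if np.isnan(v) else v
    return obj


def _write_json(data: dict, path: Path) -> None:
    path.write_text(json.dumps(_json_ready(data), indent=2, sort_keys=True) + "\n")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def cluster_stage(
    iei: pd.DataFrame, config: PipelineConfig
) -> tuple[pd.DataFrame, dict]:
    """Ward diagnostic, crisp k-means and fuzzy k-means on (IEC, IED).

    Fuzzy clusters are renumbered to correspond to their crisp k-means
    counterparts (optimal assignment on the confusion matrix); the returned
    assignment table carries matched hard labels, membership degrees,
    pattern labels and the unclear-membership flag (max membership < 0.5).
    """
    points = iei[["iec", "ied"]].to_numpy()
    seed = config.stage_seed("clustering")
    tree = ward_tree(points)
    elbow = {
        str(kk): float(
            sum(
                ((points[cut_tree_k(tree, kk) == c] -
                  points[cut_tree_k(tree, kk) == c].mean(axis=0)) ** 2).sum()
                for c in range(kk)
            )
        )
        for kk in range(1, min(9, len(points)) + 1)
    }
    km_labels, km_centers, km_inertia = kmeans_cluster(
        points, config.k, n_starts=config.n_starts, max_iter=config.max_iter, seed=seed
    )
    fkm = FuzzyKMeans(
        n_clusters=config.k,
        m=config.m,
        n_starts=config.n_starts,
        max_iter=config.max_iter,
        tol=config.tol,
        random_state=seed,
    ).fit(points)
    mapping = match_clusters(fkm.labels_, km_labels)
    order = [0] * config.k  # new column j <- old fuzzy cluster with map[old]=j
    for old, new in mapping.items():
        order[new] = old
    membership = fkm.membership_[:, order]
    centers = fkm.cluster_centers_[order]
    hard = membership.argmax(axis=1)
    max_m = membership.max(axis=1)
    patterns = label_clusters(centers) if config.k == 4 else [
        f"cluster_{j + 1}" for j in range(config.k)
    ]
    assignments = pd.DataFrame(
        {
            "participant_id": iei["participant_id"],
            "hard_label": hard,
            "pattern_label": [patterns[j] for j in hard],
            "max_membership": max_m,
            "unclear": max_m < 0.5,
        }
    )
    for j in range(config.k):
        assignments[f"u{j + 1}"] = membership[:, j]
    diagnostics = {
        "kmeans": {"centers": km_centers, "inertia": km_inertia},
        "fuzzy": {
            "centers": centers,
            "objective": fkm.objective_,
            "n_iter": fkm.n_iter_,
            "m": config.m,
            "pattern_labels": patterns,
        },
        "rand_index": rand_index(hard, km_labels),
        "overlap_table_pct": overlap_table(hard, km_labels, config.k),
        "mean_membership_table_pct": mean_membership_table(hard, membership),
        "ward_within_ss_by_k": elbow,
        "n_unclear": int((max_m < 0.5).sum()),
        "cluster_sizes": np.bincount(hard, minlength=config.k),
    }
    return assignments, diagnostics


def comparison_stage(
    participants: pd.DataFrame, assignments: pd.DataFrame, config: PipelineConfig
) -> dict:
    """Kruskal-Wallis/eta-squared, pairwise rank-sum and Fisher exact tests
    across the fuzzy clusters."""
    merged = assignments.merge(participants, on="participant_id", how="inner")
    merged = add_ssk_scores(merged)
    seed = config.stage_seed("comparison")
    report: dict = {"continuous": {}, "categorical": {}, "group_order": None}
    labels = sorted(merged["hard_label"].unique())
    report["group_order"] = [int(c) for c in labels]
    groups_by = {c: merged.loc[merged["hard_label"] == c] for c in labels}
    for var in config.continuous_variables:
        groups = [g[var].to_numpy(dtype=float) for g in groups_by.values()]
        kw = kruskal_wallis_eta2(groups)
        entry = {
            "H": kw.h,
            "df": kw.df,
            "p": kw.p,
            "eta_squared": kw.eta_squared,
        }
        if kw.p < 0.05:
            entry["pairwise_adjusted_p"] = pairwise_wilcoxon_bonferroni(groups)
        report["continuous"][var] = entry
    for var in config.categorical_variables:
        table = pd.crosstab(merged["hard_label"], merged[var])
        fr = fisher_exact_rxc(
            table.to_numpy(), n_mc=config.mc_draws, seed=seed
        )
        report["categorical"][var] = {
            "levels": [str(v) for v in table.columns],
            "table": table.to_numpy(),
            "chi2": fr.chi2,
            "df": fr.df,
            "fisher_p": fr.fisher_p,
            "method": fr.method,
        }
    return report


def _summary_tsv(
    participants: pd.DataFrame, assignments: pd.DataFrame, config: PipelineConfig
) -> str:
    """Cluster-profile summary (M (SD) per variable per cluster) as TSV."""
    merged = add_ssk_scores(assignments.merge(participants, on="participant_id"))
    clusters = sorted(merged["hard_label"].unique())
    header = ["variable"] + [
        f"cluster_{c + 1}:{merged.loc[merged.hard_label == c, 'pattern_label'].iloc[0]}"
        for c in clusters
    ]
    lines = ["\t".join(header)]
    sizes = ["cluster_size_n"] + [
        f"{(merged.hard_label == c).sum()} ({int(merged.loc[merged.hard_label == c, 'unclear'].sum())})"
        for c in clusters
    ]
    lines.append("\t".join(map(str, sizes)))
    for var in ("explicit_ft",) + tuple(config.continuous_variables):
        row = [var]
        for c in clusters:
            vals = merged.loc[merged["hard_label"] == c, var]
            row.append(f"{vals.mean():.2f} ({vals.std(ddof=1):.2f})")
        lines.append("\t".join(row))
    return "\n".join(lines) + "\n"


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute all stages, writing artifacts and a manifest to ``out_dir``.

    Returns the run directory. Stage failures abort with a stage-named
    error; artifacts written before the failure are retained.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}

    def stage(name: str):
        logger.info("stage: %s", name)

    try:
        stage("simulate/load")
        if config.trials_csv is None:
            cohort_cfg = CohortConfig(
                n_participants=config.n_participants,
                profile_sizes=tuple(config.profile_sizes),
                rt_params=RTParams(**config.rt_params),
                seed=config.stage_seed("simulate"),
                separation_scale=config.separation_scale,
            )
            cohort = generate_cohort(cohort_cfg)
            trials, participants = cohort.trials, cohort.participants
            write_trials_csv(trials, out / "trials.csv")
            write_participants_csv(participants, out / "participants.csv")
            _write_json(
                {
                    "ground_truth": cohort.ground_truth.to_dict(orient="records"),
                    "separation_scale": config.separation_scale,
                },
                out / "ground_truth.json",
            )
            artifacts["trials.csv"] = out / "trials.csv"
            artifacts["participants.csv"] = out / "participants.csv"
            artifacts["ground_truth.json"] = out / "ground_truth.json"
        else:
            trials = read_trials_csv(config.trials_csv)
            if config.participants_csv is None:
                raise ValueError("participants_csv required when trials_csv is given")
            participants = read_participants_csv(config.participants_csv)
    except Exception as exc:
        raise RuntimeError(f"stage 'simulate/load' failed: {exc}") from exc

    try:
        stage("score-stiat")
        scores = score_cohort(
            trials, tail_fraction=config.tail_fraction, convention=config.convention
        )
        scores.to_csv(out / "scores.csv", index=False)
        artifacts["scores.csv"] = out / "scores.csv"
    except Exception as exc:
        raise RuntimeError(f"stage 'score-stiat' failed: {exc}") from exc

    if config.n_replications > 0:
        try:
            stage("reliability")
            rel = split_half_reliability(
                trials,
                n_replications=config.n_replications,
                seed=config.stage_seed("reliability"),
                tail_fraction=config.tail_fraction,
                scheme=config.reliability_scheme,
                correlation=config.reliability_correlation,
                convention=config.convention,
            )
            _write_json(dataclasses.asdict(rel), out / "reliability.json")
            artifacts["reliability.json"] = out / "reliability.json"
        except Exception as exc:
            raise RuntimeError(f"stage 'reliability' failed: {exc}") from exc

    try:
        stage("iei")
        # excluded ST-IAT participants are dropped listwise before scoring
        valid = scores.loc[~scores["excluded"]]
        merged = valid.merge(participants, on="participant_id", how="inner")
        iei = compute_iei(
            merged["g"], merged["explicit_ft"], participant_ids=merged["participant_id"]
        )
        iei.to_csv(out / "iei.csv", index=False)
        artifacts["iei.csv"] = out / "iei.csv"
    except Exception as exc:
        raise RuntimeError(f"stage 'iei' failed: {exc}") from exc

    try:
        stage("cluster")
        assignments, diagnostics = cluster_stage(iei, config)
        assignments.to_csv(out / "clusters.csv", index=False)
        _write_json(diagnostics, out / "cluster_diagnostics.json")
        artifacts["clusters.csv"] = out / "clusters.csv"
        artifacts["cluster_diagnostics.json"] = out / "cluster_diagnostics.json"
    except Exception as exc:
        raise RuntimeError(f"stage 'cluster' failed: {exc}") from exc

    try:
        stage("compare")
        report = comparison_stage(participants, assignments, config)
        _write_json(report, out / "comparison.json")
        (out / "cluster_summary.tsv").write_text(
            _summary_tsv(participants, assignments, config)
        )
        artifacts["comparison.json"] = out / "comparison.json"
        artifacts["cluster_summary.tsv"] = out / "cluster_summary.tsv"
    except Exception as exc:
        raise RuntimeError(f"stage 'compare' failed: {exc}") from exc

    from . import __version__ as pkg_version

    manifest = {
        "package_version": pkg_version,
        "config": dataclasses.asdict(config),
        "stage_seeds": {s: PipelineConfig.stage_seed(config, s) for s in _STAGES},
        "artifacts": {name: _sha256(path) for name, path in sorted(artifacts.items())},
    }
    _write_json(manifest, out / "manifest.json")
    return out
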