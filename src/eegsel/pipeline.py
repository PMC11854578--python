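"""End-to-end orchestration of the three binary classification tasks.

A task separates two of the three cohort groups: control vs the
schizotypy-featured group (C-PSF), control vs the cyclothymia-featured
group (C-CTF), or the two risk groups from each other (CTF-PSF).  A run
preprocesses the recordings, builds the (full or microstate-only) feature
table, performs the AHFS stability analysis whose union-of-final-sets
prefilters the features, runs CFFS over the low-correlation cliques,
trains logistic regression / random forest / neural-net candidates,
explains the top models with exact Shapley values and aggregates them
into normalised importance scores.

Every stage is seeded from the run seed, so a manifest reproduces its
artifacts exactly.  Accuracy always means accuracy pooled over all
cross-validation held-out predictions.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import ahfs as _ahfs
from . import cffs as _cffs
from . import shapley as _shapley
from .features import FeatureConfig, FeatureTable, build_feature_table, normalize_features
from .microstate import microstates_for_recording, microstate_features
from .preprocess import PreprocessConfig, run_preprocess
from .synth import Recording

__all__ = ["TaskSpec", "PipelineConfig", "PipelineError", "RunManifest", "run_task",
           "accuracy_report", "TASKS", "microstate_feature_table",
           "study_cohort", "desk_scale_config"]


log = logging.getLogger(__name__)


class PipelineError(ValueError):
    """Raised for invalid task configurations."""


#: The three binary tasks: (groups, positive class, default clique threshold).
TASKS: dict[str, tuple[tuple[str, str], str, float]] = {
    "C-PSF": (("CONTROL", "PSF"), "PSF", 0.4),
    "C-CTF": (("CONTROL", "CTF"), "CTF", 0.35),
    "CTF-PSF": (("CTF", "PSF"), "PSF", 0.4),
}


@dataclass(frozen=True)
class TaskSpec:
    task_id: str
    positive_class: str | None = None
    threshold: float | None = None
    feature_mode: str = "full"  # or "microstate-only"

    def resolved(self) -> tuple[tuple[str, str], str, float]:
        if self.task_id not in TASKS:
            raise PipelineError(f"unknown task {self.task_id!r}; one of {list(TASKS)}")
        groups, pos, tau = TASKS[self.task_id]
        pos = self.positive_class or pos
        tau = self.threshold if self.threshold is not None else tau
        if not 0 < tau <= 1:
            raise PipelineError(f"threshold {tau} outside (0, 1]")
        if pos not in groups:
            raise PipelineError(f"positive class {pos!r} not in task groups {groups}")
        return groups, pos, tau


@dataclass(frozen=True)
class PipelineConfig:
    """Stage parameters.  The defaults are the full-scale analysis
    settings (20 AHFS runs of up to 20 steps, up to 600 sampled cliques
    of 3-9 features, top 20 models per algorithm); scaled-down runs pass
    smaller values."""

    seed: int = 0
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    features: FeatureConfig = field(default_factory=FeatureConfig)
    microstate_k: int = 4
    ahfs_runs: int = 20
    ahfs_max_steps: int = 20
    ahfs_ann_max_iter: int = 400
    cv_folds: int = 3
    clique_min: int = 3
    clique_max: int = 9
    clique_cap: int = 600
    clique_enum_limit: int = 20000
    top_k: int = 20
    algorithms: tuple[str, ...] = ("LR", "RF", "ANN")
    estimator_overrides: dict = field(default_factory=dict)
    background_max: int | None = None
    prefilter_fallback_n: int = 35


@dataclass
class RunManifest:
    """Everything a run produced, JSON-serialisable."""

    task_id: str
    positive_class: str
    threshold: float
    feature_mode: str
    seed: int
    n_subjects: int
    accuracies: dict[str, list[float]]  # per algorithm entry, top-model list
    best_accuracy: dict[str, float]
    importance: dict[str, float]
    breakdowns: dict[str, dict[str, float]]
    prefilter: list[str]
    n_cliques_enumerated: int
    n_cliques_trained: int
    flags: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(asdict(self), indent=1, default=float))
        return path


def study_cohort(
    seed: int,
    duration_s: float = 12.0,
    fs: float = 256.0,
    effect_scale: float = 1.0,
) -> list[Recording]:
    """A synthetic cohort with the study's group sizes (21/20/17).

    The default duration and rate are the package's desk-scale simulation
    size: long enough for stable epoch summaries after edge trimming,
    with a Nyquist that keeps the planted gamma effects (<= 64 Hz).
    ``effect_scale=0`` yields a null cohort with no group differences.
    """
    from .synth import CohortConfig, default_profiles, generate_cohort

    cfg = CohortConfig(
        group_sizes={"CONTROL": 21, "PSF": 20, "CTF": 17},
        duration_s=duration_s,
        fs=fs,
        seed=seed,
        profiles=default_profiles(effect_scale=effect_scale),
    )
    return generate_cohort(cfg)


def desk_scale_config(seed: int) -> PipelineConfig:
    """A reduced-size pipeline configuration for replicated desk runs.

    Fewer AHFS runs/steps, a smaller clique sample with tighter size
    bounds, fewer top models and a capped Shapley background keep one
    full task run well under a minute while exercising every stage.
    """
    return PipelineConfig(
        seed=seed,
        ahfs_runs=4,
        ahfs_max_steps=5,
        ahfs_ann_max_iter=150,
        clique_cap=80,
        clique_max=6,
        clique_enum_limit=4000,
        top_k=5,
        estimator_overrides={"RF": {"n_estimators": 50}, "ANN": {"max_iter": 150}},
        background_max=16,
    )


def microstate_feature_table(
    recordings: list[Recording], k: int = 4, seed: int = 0, n_restarts: int = 10
) -> FeatureTable:
    """Per-subject microstate statistics as a feature table."""
    rows, flags = [], {}
    for i, rec in enumerate(recordings):
        model, labels, stats, fl = microstates_for_recording(
            rec, k=k, seed=seed + i, n_restarts=n_restarts
        )
        rows.append(microstate_features(stats))
        if fl["low_gev"]:
            flags[rec.subject_id] = fl
    data = pd.DataFrame(rows, index=[r.subject_id for r in recordings])
    labels_s = pd.Series([r.group for r in recordings], index=data.index, name="group")
    table = FeatureTable(data=data, labels=labels_s)
    table.normalization["__low_gev_subjects__"] = flags  # type: ignore[assignment]
    return table


def _prepare_table(
    recordings: list[Recording], spec: TaskSpec, config: PipelineConfig
) -> FeatureTable:
    groups, _, _ = spec.resolved()
    present = {r.group for r in recordings}
    for g in groups:
        if g not in present:
            raise PipelineError(f"group {g!r} missing from the cohort")
    recs = [r for r in recordings if r.group in groups]
    log.info("task %s: preprocessing %d subjects", spec.task_id, len(recs))
    recs = [run_preprocess(r, config.preprocess) for r in recs]
    if spec.feature_mode == "microstate-only":
        table = microstate_feature_table(recs, k=config.microstate_k, seed=config.seed)
    elif spec.feature_mode == "full":
        table = build_feature_table(recs, config.features)
    else:
        raise PipelineError(f"unknown feature mode {spec.feature_mode!r}")
    return normalize_features(table)


def run_task(
    recordings: list[Recording],
    spec: TaskSpec,
    config: PipelineConfig | None = None,
    table: FeatureTable | None = None,
) -> RunManifest:
    """Execute one binary task end to end.

    ``table`` may carry a precomputed normalised feature table (the
    preprocessing and feature stages are then skipped); it must contain
    exactly the task's two groups or is restricted to them.
    """
    config = config or PipelineConfig()
    groups, positive, tau = spec.resolved()
    if table is None:
        table = _prepare_table(recordings, spec, config)
    else:
        table = table.restrict_groups(list(groups))

    # AHFS stability: nominates features and provides the ANN (AHFS) entry
    log.info("task %s: AHFS stability (%d runs)", spec.task_id, config.ahfs_runs)
    stability = _ahfs.ahfs_stability(
        table,
        n_runs=config.ahfs_runs,
        base_seed=config.seed,
        max_steps=config.ahfs_max_steps,
        cv_folds=config.cv_folds,
        model_factory=lambda seed: _ahfs.default_ann(seed, config.ahfs_ann_max_iter),
    )
    prefilter = list(stability.prefilter)
    flags = {}
    if len(prefilter) < config.clique_min:
        prefilter = list(
            _cffs.variance_prefilter(table, config.prefilter_fallback_n, by="relevance")
        )
        flags["prefilter_fallback"] = True

    ahfs_step_accs = sorted(
        (acc for tr in stability.traces for _, _, acc in tr.steps), reverse=True
    )[: config.top_k]

    # CFFS: low-correlation cliques over the prefiltered features
    log.info("task %s: CFFS over %d prefiltered features (tau=%g)",
             spec.task_id, len(prefilter), tau)
    graph = _cffs.correlation_graph(table, prefilter, threshold=tau)
    cliques = _cffs.enumerate_cliques(
        graph, config.clique_min, config.clique_max, limit=config.clique_enum_limit
    )
    if not cliques.cliques:
        # the AHFS picks can be mutually correlated above tau (they chase
        # the same effect, and relevance-ranked features share that
        # property); widen the node set with a seeded label-independent
        # spread so the graph has low-correlation cliques to offer
        rng = np.random.default_rng(config.seed)
        pool = [f for f in table.feature_names if f not in prefilter]
        k = min(config.prefilter_fallback_n, len(pool))
        extra = list(rng.choice(pool, size=k, replace=False))
        prefilter = prefilter + extra
        flags["prefilter_widened"] = True
        graph = _cffs.correlation_graph(table, prefilter, threshold=tau)
        cliques = _cffs.enumerate_cliques(
            graph, config.clique_min, config.clique_max,
            limit=config.clique_enum_limit,
        )
        if not cliques.cliques:
            raise PipelineError(
                "no low-correlation cliques within the size bounds; "
                "raise the threshold or widen the prefilter"
            )
    if cliques.truncated:
        flags["clique_enumeration_truncated"] = True
    sampled = _cffs.sample_cliques(cliques, cap=config.clique_cap, seed=config.seed)
    records = _cffs.train_candidates(
        table, sampled, positive_class=positive,
        algorithms=config.algorithms, cv_folds=config.cv_folds,
        seed=config.seed, estimator_overrides=config.estimator_overrides,
    )
    # clique property holds post hoc for every trained feature set
    for r in records:
        sub = graph.correlation.loc[list(r.feature_set), list(r.feature_set)].to_numpy()
        off = np.abs(sub[~np.eye(len(sub), dtype=bool)])
        assert off.size == 0 or off.max() <= tau + 1e-12, "clique property violated"

    top, shortfall = _cffs.top_models(records, k=config.top_k)
    flags.update({f"top_shortfall_{a}": v for a, v in shortfall.items() if v})

    log.info("task %s: exact Shapley on %d top models",
             spec.task_id, sum(len(v) for v in top.values()))
    explained = []
    for alg, recs_alg in top.items():
        for r in recs_alg:
            explained.append(
                _shapley.shapley_for_record(
                    r, table, background_max=config.background_max, seed=config.seed
                )
            )
    importance = _shapley.aggregate_importance(explained)
    breakdowns = _shapley.importance_breakdowns(importance)

    accuracies = {"ANN (AHFS)": [float(a) for a in ahfs_step_accs]}
    for alg in config.algorithms:
        name = "ANN (CFFS)" if alg == "ANN" else alg
        accuracies[name] = [float(r.pooled_accuracy) for r in top.get(alg, [])]
    best = {k: (max(v) if v else float("nan")) for k, v in accuracies.items()}

    return RunManifest(
        task_id=spec.task_id,
        positive_class=positive,
        threshold=tau,
        feature_mode=spec.feature_mode,
        seed=config.seed,
        n_subjects=len(table.data),
        accuracies=accuracies,
        best_accuracy=best,
        importance={k: float(v) for k, v in importance.scores.items()},
        breakdowns={k: {kk: float(vv) for kk, vv in v.items()} for k, v in breakdowns.items()},
        prefilter=prefilter,
        n_cliques_enumerated=len(cliques.cliques),
        n_cliques_trained=len(sampled.cliques),
        flags=flags,
    )


def accuracy_report(manifest: RunManifest) -> pd.DataFrame:
    """Box-plot data: per algorithm, the top-model pooled accuracies and
    their maximum (the headline statistic)."""
    rows = []
    for alg, vals in manifest.accuracies.items():
        for v in vals:
            rows.append((alg, v))
    df = pd.DataFrame(rows, columns=["algorithm", "pooled_accuracy"])
    df.attrs["maxima"] = manifest.best_accuracy
    return df
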