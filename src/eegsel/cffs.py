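"""Clique Forming Feature Selection (CFFS).

Candidate feature sets are cliques of a graph whose nodes are features and
whose edges connect pairs with low absolute Pearson correlation
(|r| <= threshold).  Every clique is, by construction, a set of mutually
weakly correlated features — which keeps the downstream Shapley
attributions from splitting importance across near-duplicates.  Cliques
within the configured size bounds are enumerated (all of them, not only
the maximal ones, by default), capped by a stratified random sample, and
each sampled set is trained with logistic regression, a random forest and
a small neural net under shared stratified cross-validation folds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.neural_network import MLPClassifier

from .features import FeatureTable

__all__ = [
    "CffsError",
    "FeatureGraph",
    "CliqueSet",
    "ModelRecord",
    "ALGORITHMS",
    "correlation_graph",
    "enumerate_cliques",
    "sample_cliques",
    "train_candidates",
    "top_models",
    "variance_prefilter",
]


class CffsError(ValueError):
    """Raised for invalid CFFS requests."""


@dataclass(frozen=True)
class FeatureGraph:
    """Low-correlation feature graph: edge iff |pearson| <= threshold."""

    graph: nx.Graph
    correlation: pd.DataFrame
    threshold: float
    constant_features: tuple[str, ...] = ()

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)


@dataclass(frozen=True)
class CliqueSet:
    cliques: tuple[tuple[str, ...], ...]
    min_size: int
    max_size: int
    seed: int | None = None
    truncated: bool = False


@dataclass
class ModelRecord:
    """One trained (clique, algorithm) candidate with CV bookkeeping."""

    algorithm: str
    feature_set: tuple[str, ...]
    fold_assignment: np.ndarray  # subject -> fold index
    pooled_accuracy: float
    per_subject_prediction: np.ndarray  # P(positive class), held-out
    fold_models: list = field(repr=False, default_factory=list)
    shapley: np.ndarray | None = None  # (n_subjects, n_features)
    base_values: np.ndarray | None = None  # per subject


def correlation_graph(
    table: FeatureTable, features: list[str] | None = None, threshold: float = 0.4
) -> FeatureGraph:
    """Build the low-correlation graph over the given features."""
    if not 0 < threshold <= 1:
        raise CffsError(f"threshold {threshold} outside (0, 1]")
    features = list(features) if features is not None else table.feature_names
    missing = [f for f in features if f not in table.data.columns]
    if missing:
        raise CffsError(f"unknown features: {missing[:5]}")
    if len(table.data) < 3:
        raise CffsError("need at least 3 subjects")
    X = table.data[features].to_numpy(dtype=float)
    sd = X.std(axis=0)
    constant = tuple(f for f, s in zip(features, sd) if s == 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = np.corrcoef(X, rowvar=False)
    corr = np.atleast_2d(corr)
    corr[~np.isfinite(corr)] = 0.0  # constant features: correlation defined as 0
    np.fill_diagonal(corr, 1.0)
    cdf = pd.DataFrame(corr, index=features, columns=features)

    g = nx.Graph()
    g.add_nodes_from(features)
    for i, j in combinations(range(len(features)), 2):
        r = corr[i, j]
        if abs(r) <= threshold:
            g.add_edge(features[i], features[j], weight=float(r))
    return FeatureGraph(graph=g, correlation=cdf, threshold=threshold, constant_features=constant)


def enumerate_cliques(
    graph: FeatureGraph, min_size: int = 3, max_size: int = 9,
    maximal_only: bool = False, limit: int | None = None,
) -> CliqueSet:
    """All cliques with size within the bounds.

    The default enumerates every fully connected subgraph in the size
    range (via networkx's ascending-size clique enumeration, so the walk
    stops as soon as the size bound is passed).  ``maximal_only`` keeps
    only maximal cliques within the bounds.  On dense graphs the count
    grows combinatorially; ``limit`` stops the walk after that many
    cliques have been collected (ascending size, so small cliques are
    kept preferentially) and records the truncation.
    """
    if min_size < 1 or max_size < min_size:
        raise CffsError(f"bad size bounds ({min_size}, {max_size})")
    truncated = False
    out: list[tuple[str, ...]] = []
    if maximal_only:
        for c in nx.find_cliques(graph.graph):
            if min_size <= len(c) <= max_size:
                out.append(tuple(sorted(c)))
                if limit is not None and len(out) >= limit:
                    truncated = True
                    break
    else:
        for c in nx.enumerate_all_cliques(graph.graph):
            if len(c) > max_size:
                break
            if len(c) >= min_size:
                out.append(tuple(sorted(c)))
                if limit is not None and len(out) >= limit:
                    truncated = True
                    break
    out = sorted(set(out))
    return CliqueSet(
        cliques=tuple(out), min_size=min_size, max_size=max_size,
        truncated=truncated,
    )


def sample_cliques(cliques: CliqueSet, cap: int = 600, seed: int = 0) -> CliqueSet:
    """At most ``cap`` cliques, sampled without replacement, stratified by
    size proportionally to availability."""
    if cap <= 0:
        raise CffsError("cap must be positive")
    all_c = cliques.cliques
    if len(all_c) <= cap:
        return CliqueSet(all_c, cliques.min_size, cliques.max_size, seed,
                         cliques.truncated)
    rng = np.random.default_rng(seed)
    by_size: dict[int, list[tuple[str, ...]]] = {}
    for c in all_c:
        by_size.setdefault(len(c), []).append(c)
    sizes = sorted(by_size)
    total = len(all_c)
    # proportional allocation, largest-remainder rounding
    exact = {s: cap * len(by_size[s]) / total for s in sizes}
    alloc = {s: int(np.floor(exact[s])) for s in sizes}
    short = cap - sum(alloc.values())
    for s in sorted(sizes, key=lambda s: -(exact[s] - alloc[s]))[:short]:
        alloc[s] += 1
    chosen: list[tuple[str, ...]] = []
    for s in sizes:
        pool = by_size[s]
        k = min(alloc[s], len(pool))
        idx = rng.choice(len(pool), size=k, replace=False)
        chosen.extend(pool[i] for i in sorted(idx))
    return CliqueSet(tuple(chosen[:cap]), cliques.min_size, cliques.max_size,
                     seed, cliques.truncated)


# ---------------------------------------------------------------------------
# candidate training


def _make_estimator(algorithm: str, seed: int, overrides: dict | None = None):
    overrides = overrides or {}
    if algorithm == "LR":
        return LogisticRegression(C=1.0, max_iter=1000, **overrides)
    if algorithm == "RF":
        return RandomForestClassifier(
            n_estimators=overrides.pop("n_estimators", 100),
            random_state=seed, **overrides,
        )
    if algorithm == "ANN":
        return MLPClassifier(
            hidden_layer_sizes=overrides.pop("hidden_layer_sizes", (8,)),
            activation="logistic", max_iter=overrides.pop("max_iter", 400),
            random_state=seed, **overrides,
        )
    raise CffsError(f"unknown algorithm {algorithm!r}")


ALGORITHMS = ("LR", "RF", "ANN")


def train_candidates(
    table: FeatureTable,
    cliques: CliqueSet,
    positive_class: str,
    algorithms: tuple[str, ...] = ALGORITHMS,
    cv_folds: int = 3,
    seed: int = 0,
    estimator_overrides: dict[str, dict] | None = None,
) -> list[ModelRecord]:
    """Train one model per (clique, algorithm) under shared CV folds.

    Accuracy is pooled over all held-out predictions; every subject is
    predicted exactly once per model.  ``per_subject_prediction`` holds
    the held-out probability of the positive class.
    """
    labels = table.labels
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) != 2:
        raise CffsError(f"binary task expected, got classes {list(classes)}")
    if positive_class not in classes:
        raise CffsError(f"positive class {positive_class!r} not present")
    if counts.min() < cv_folds:
        raise CffsError("a fold would see a single class: too few subjects per class")
    y = (labels.to_numpy() == positive_class).astype(int)

    skf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    X_all = table.data.to_numpy(dtype=float)
    col = {c: i for i, c in enumerate(table.data.columns)}
    folds = list(skf.split(X_all, y))
    fold_assignment = np.empty(len(y), dtype=int)
    for f, (tr, te) in enumerate(folds):
        assert np.intersect1d(tr, te).size == 0, "subject leakage across folds"
        fold_assignment[te] = f

    overrides = estimator_overrides or {}
    records: list[ModelRecord] = []
    for clique in cliques.cliques:
        missing = [f for f in clique if f not in col]
        if missing:
            raise CffsError(f"clique references unknown features {missing}")
        cols = [col[f] for f in clique]
        X = X_all[:, cols]
        for alg in algorithms:
            proba = np.empty(len(y))
            pred = np.empty(len(y), dtype=int)
            fold_models = []
            for f, (tr, te) in enumerate(folds):
                est = _make_estimator(
                    alg, (seed * 1000 + f) % (2**32), dict(overrides.get(alg, {}))
                )
                est.fit(X[tr], y[tr])
                p = est.predict_proba(X[te])[:, list(est.classes_).index(1)]
                proba[te] = p
                pred[te] = (p >= 0.5).astype(int)
                fold_models.append(est)
            records.append(
                ModelRecord(
                    algorithm=alg,
                    feature_set=clique,
                    fold_assignment=fold_assignment.copy(),
                    pooled_accuracy=float((pred == y).mean()),
                    per_subject_prediction=proba,
                    fold_models=fold_models,
                )
            )
    return records


def top_models(
    records: list[ModelRecord], k: int = 20
) -> tuple[dict[str, list[ModelRecord]], dict[str, bool]]:
    """The k most accurate records per algorithm.

    Ties break toward smaller feature sets, then lexicographic feature
    names.  Returns (per-algorithm lists, per-algorithm shortfall flags).
    """
    if not records:
        raise CffsError("no model records")
    by_alg: dict[str, list[ModelRecord]] = {}
    for r in records:
        by_alg.setdefault(r.algorithm, []).append(r)
    out: dict[str, list[ModelRecord]] = {}
    flags: dict[str, bool] = {}
    for alg, rs in by_alg.items():
        rs = sorted(rs, key=lambda r: (-r.pooled_accuracy, len(r.feature_set), r.feature_set))
        out[alg] = rs[:k]
        flags[alg] = len(rs) < k
    return out, flags


def variance_prefilter(
    table: FeatureTable, n_keep: int = 35, by: str = "variance"
) -> tuple[str, ...]:
    """Fallback prefilter when AHFS is skipped.

    ``by='variance'`` keeps the n highest-variance features (useful on raw
    tables); ``by='relevance'`` keeps the n features with the highest
    absolute point-biserial correlation with the group labels (useful on
    normalised tables, where variances are flat).
    """
    if by == "variance":
        score = table.data.std(axis=0)
    elif by == "relevance":
        y = pd.factorize(table.labels)[0].astype(float)
        score = table.data.apply(
            lambda c: abs(np.corrcoef(c.to_numpy(dtype=float), y)[0, 1])
            if c.std() > 0 else 0.0
        )
    else:
        raise CffsError(f"unknown prefilter mode {by!r}")
    return tuple(score.sort_values(ascending=False).index[:n_keep])
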