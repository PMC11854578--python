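"""Adaptive Hybrid Feature Selection (AHFS).

A sequential forward selection in which several relevance/redundancy
criteria — mutual-information based (mRMR, JMIM, MMIFS) and correlation
based (LCFS, CORR) — each nominate their best candidate at every step.
Every nominated augmented set is scored by the pooled cross-validated
accuracy of a small evaluation model (a single-hidden-layer neural net by
default), and the best nominee is kept.  Because later steps are noisy,
multiple runs with distinct seeds are performed and features are ranked
by how often they appear ("stability"); features appearing at least once
form the prefilter set consumed by the clique-based selector.

Mutual information uses a plug-in estimate on an equal-frequency
discretisation with ceil(sqrt(n)) bins.  Pooled accuracy always means
accuracy over the union of all folds' held-out predictions, never an
average of per-fold accuracies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from sklearn.neural_network import MLPClassifier

from .features import FeatureTable

__all__ = [
    "SelectionError",
    "CRITERIA",
    "AHFSConfig",
    "SelectionTrace",
    "StabilityResult",
    "mutual_information",
    "criterion_score",
    "ahfs_run",
    "ahfs_stability",
    "pooled_cv_accuracy",
    "default_ann",
]

CRITERIA = ("MRMR", "JMIM", "MMIFS", "LCFS", "CORR")


class SelectionError(ValueError):
    """Raised for invalid feature-selection requests."""


# ---------------------------------------------------------------------------
# discretisation and mutual information


def _discretize(x: np.ndarray, bins: int) -> np.ndarray:
    """Equal-frequency binning into integer codes (constant columns -> 0)."""
    x = np.asarray(x, dtype=float)
    if np.all(x == x[0]):
        return np.zeros(len(x), dtype=np.int64)
    edges = np.quantile(x, np.linspace(0, 1, bins + 1)[1:-1])
    return np.searchsorted(edges, x, side="left").astype(np.int64)


def _codes(y) -> np.ndarray:
    """Integer codes for a label-like vector."""
    return pd.factorize(np.asarray(y))[0].astype(np.int64)


def _mi_codes(a: np.ndarray, b: np.ndarray) -> float:
    """Plug-in mutual information (nats) between two integer-code vectors."""
    ka, kb = a.max() + 1, b.max() + 1
    joint = np.bincount(a * kb + b, minlength=ka * kb).reshape(ka, kb)
    n = joint.sum()
    pj = joint / n
    pa = pj.sum(axis=1, keepdims=True)
    pb = pj.sum(axis=0, keepdims=True)
    nz = pj > 0
    return float((pj[nz] * np.log(pj[nz] / (pa @ pb)[nz])).sum())


def _entropy_codes(a: np.ndarray) -> float:
    p = np.bincount(a) / len(a)
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def mutual_information(x, y, bins: int | None = None) -> float:
    """MI between a continuous (or discrete) column and labels/another column.

    Continuous inputs are discretised into equal-frequency bins
    (default ceil(sqrt(n))).  Non-negative and symmetric.
    """
    x = np.asarray(x)
    y = np.asarray(y)
    if len(x) != len(y):
        raise SelectionError("x and y must have equal length")
    if len(x) < 4:
        raise SelectionError("need at least 4 observations")
    bins = bins or int(np.ceil(np.sqrt(len(x))))

    def prep(v):
        if v.dtype.kind in "OUSb" or (v.dtype.kind in "iu" and len(np.unique(v)) <= bins):
            return _codes(v)
        return _discretize(v.astype(float), bins)

    return max(0.0, _mi_codes(prep(x), prep(y)))


# ---------------------------------------------------------------------------
# criterion scores


def _abs_pearson(x: np.ndarray, y: np.ndarray) -> float:
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        return 0.0
    return float(abs(np.corrcoef(x, y)[0, 1]))


class _ScoreContext:
    """Caches MI/correlation terms over a fixed table and label vector."""

    def __init__(self, data: pd.DataFrame, labels, bins: int | None = None):
        self.data = data
        self.X = data.to_numpy(dtype=float)
        self.names = list(data.columns)
        self.col = {c: i for i, c in enumerate(self.names)}
        self.y = _codes(labels)
        n = len(self.y)
        self.bins = bins or int(np.ceil(np.sqrt(n)))
        self.B = np.stack(
            [_discretize(self.X[:, j], self.bins) for j in range(self.X.shape[1])],
            axis=1,
        )
        self._rel_mi: np.ndarray | None = None
        self._red_mi: dict[str, np.ndarray] = {}
        self._joint_mi: dict[str, np.ndarray] = {}
        self._rel_corr: np.ndarray | None = None
        self._red_corr: dict[str, np.ndarray] = {}
        self._h_s: dict[str, float] = {}

    def relevance_mi(self) -> np.ndarray:
        if self._rel_mi is None:
            self._rel_mi = np.array(
                [_mi_codes(self.B[:, j], self.y) for j in range(self.B.shape[1])]
            )
        return self._rel_mi

    def redundancy_mi(self, s: str) -> np.ndarray:
        if s not in self._red_mi:
            bs = self.B[:, self.col[s]]
            self._red_mi[s] = np.array(
                [_mi_codes(self.B[:, j], bs) for j in range(self.B.shape[1])]
            )
        return self._red_mi[s]

    def joint_mi(self, s: str) -> np.ndarray:
        """I((f, s); Y) for every feature f, with s and Y fixed."""
        if s not in self._joint_mi:
            bs = self.B[:, self.col[s]]
            ks = bs.max() + 1
            out = np.empty(self.B.shape[1])
            for j in range(self.B.shape[1]):
                pair = self.B[:, j] * ks + bs
                out[j] = _mi_codes(pair, self.y)
            self._joint_mi[s] = out
        return self._joint_mi[s]

    def _zscored(self) -> np.ndarray:
        if getattr(self, "_Xz", None) is None:
            mu = self.X.mean(axis=0)
            sd = self.X.std(axis=0)
            safe = np.where(sd > 0, sd, 1.0)
            xz = (self.X - mu) / safe
            xz[:, sd == 0] = 0.0
            self._Xz = xz
        return self._Xz

    def _abs_corr_with(self, v: np.ndarray) -> np.ndarray:
        """|pearson| of every column against a vector, vectorised."""
        sd = v.std()
        if sd == 0:
            return np.zeros(self.X.shape[1])
        vz = (v - v.mean()) / sd
        return np.abs(self._zscored().T @ vz) / len(v)

    def relevance_corr(self) -> np.ndarray:
        if self._rel_corr is None:
            self._rel_corr = self._abs_corr_with(self.y.astype(float))
        return self._rel_corr

    def redundancy_corr(self, s: str) -> np.ndarray:
        if s not in self._red_corr:
            self._red_corr[s] = self._abs_corr_with(self.X[:, self.col[s]])
        return self._red_corr[s]

    def entropy_s(self, s: str) -> float:
        if s not in self._h_s:
            self._h_s[s] = _entropy_codes(self.B[:, self.col[s]])
        return self._h_s[s]

    def scores(self, cid: str, selected: list[str]) -> np.ndarray:
        """Score every feature as a candidate given the selected set.

        With an empty selected set every criterion reduces to its
        relevance term.  The MMIFS/LCFS variants implemented here are
        documented in the package methods note; they are isolated behind
        the criterion id so substitutions are one-line.
        """
        if cid in ("MRMR", "JMIM", "MMIFS"):
            rel = self.relevance_mi()
            if not selected:
                return rel.copy()
            if cid == "MRMR":
                red = np.mean([self.redundancy_mi(s) for s in selected], axis=0)
                return rel - red
            if cid == "JMIM":
                return np.min([self.joint_mi(s) for s in selected], axis=0)
            # MMIFS: redundancy weighted by how informative each selected
            # feature is about the labels, relative to its entropy
            terms = []
            for s in selected:
                w = self.relevance_mi()[self.col[s]] / max(self.entropy_s(s), 1e-12)
                terms.append(w * self.redundancy_mi(s))
            return rel - np.mean(terms, axis=0)
        if cid in ("LCFS", "CORR"):
            rel = self.relevance_corr()
            if not selected:
                return rel.copy()
            red = np.mean([self.redundancy_corr(s) for s in selected], axis=0)
            if cid == "LCFS":
                return rel - red
            return rel / (1.0 + red)
        raise SelectionError(f"unknown criterion id {cid!r}")


def criterion_score(
    cid: str,
    candidate: str,
    selected: list[str],
    data: pd.DataFrame,
    labels,
    bins: int | None = None,
) -> float:
    """Score one candidate feature under one criterion (reference path)."""
    if candidate in selected:
        raise SelectionError("candidate already selected")
    ctx = _ScoreContext(data, labels, bins=bins)
    return float(ctx.scores(cid, selected)[ctx.col[candidate]])


# ---------------------------------------------------------------------------
# evaluation model and pooled CV


def default_ann(seed: int = 0, max_iter: int = 400) -> MLPClassifier:
    """The small evaluation network: one hidden layer of 8 logistic units,
    trained for a fixed iteration budget."""
    return MLPClassifier(
        hidden_layer_sizes=(8,),
        activation="logistic",
        max_iter=max_iter,
        random_state=seed,
        solver="adam",
    )


def pooled_cv_accuracy(
    make_model, X: np.ndarray, y: np.ndarray, cv_folds: int, seed: int
) -> float:
    """Pooled accuracy over all folds' held-out predictions."""
    skf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    pred = np.empty(len(y), dtype=y.dtype)
    for f, (tr, te) in enumerate(skf.split(X, y)):
        assert len(np.intersect1d(tr, te)) == 0
        model = make_model(seed + f)
        model.fit(X[tr], y[tr])
        pred[te] = model.predict(X[te])
    return float((pred == y).mean())


# ---------------------------------------------------------------------------
# AHFS proper


@dataclass(frozen=True)
class AHFSConfig:
    seed: int = 0
    max_steps: int = 20
    cv_folds: int = 3
    criteria: tuple[str, ...] = CRITERIA
    model_factory: object = None  # callable seed -> estimator; default ANN
    mi_bins: int | None = None

    def factory(self):
        return self.model_factory or default_ann


@dataclass(frozen=True)
class SelectionTrace:
    """One AHFS run: the chosen feature, winning criterion and pooled CV
    accuracy at every step."""

    run_seed: int
    steps: tuple[tuple[str, str, float], ...]

    @property
    def final_set(self) -> tuple[str, ...]:
        return tuple(s[0] for s in self.steps)

    @property
    def best_accuracy(self) -> float:
        return max(s[2] for s in self.steps)


def ahfs_run(
    table: FeatureTable,
    config: AHFSConfig | None = None,
    _ctx: _ScoreContext | None = None,
) -> SelectionTrace:
    """One seeded sequential-forward-selection run.

    ``_ctx`` optionally reuses a score context built on the same table
    (the stability wrapper shares one across runs; scores are
    deterministic, so sharing cannot change any trace).
    """
    config = config or AHFSConfig()
    data, labels = table.data, table.labels
    if data.shape[1] == 0 or len(data) == 0:
        raise SelectionError("empty feature table")
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise SelectionError("need at least 2 classes")
    if counts.min() < config.cv_folds:
        raise SelectionError("need at least cv_folds subjects per class")

    ctx = _ctx or _ScoreContext(data, labels, bins=config.mi_bins)
    y = _codes(labels)
    X = ctx.X
    factory = config.factory()

    selected: list[str] = []
    selected_idx: list[int] = []
    steps: list[tuple[str, str, float]] = []
    remaining = set(range(X.shape[1]))
    for step in range(config.max_steps):
        if not remaining:
            break
        nominees: dict[int, str] = {}  # feature idx -> first nominating criterion
        for cid in config.criteria:
            sc = ctx.scores(cid, selected)
            # exclude selected features; tie-break lexicographically
            order = sorted(remaining, key=lambda j: (-sc[j], ctx.names[j]))
            top = order[0]
            nominees.setdefault(top, cid)
        evaluated = []
        for j, cid in sorted(nominees.items(), key=lambda kv: ctx.names[kv[0]]):
            cols = selected_idx + [j]
            acc = pooled_cv_accuracy(
                factory, X[:, cols], y, config.cv_folds, config.seed
            )
            evaluated.append((acc, ctx.names[j], j, cid))
        evaluated.sort(key=lambda t: (-t[0], t[1]))
        acc, name, j, cid = evaluated[0]
        selected.append(name)
        selected_idx.append(j)
        remaining.discard(j)
        steps.append((name, cid, acc))
    return SelectionTrace(run_seed=config.seed, steps=tuple(steps))


@dataclass(frozen=True)
class StabilityResult:
    traces: tuple[SelectionTrace, ...]
    counts: dict[str, int]

    @property
    def prefilter(self) -> tuple[str, ...]:
        """Features appearing at least once across all runs."""
        return tuple(sorted(self.counts))


def ahfs_stability(
    table: FeatureTable,
    n_runs: int = 20,
    base_seed: int = 0,
    max_steps: int = 20,
    cv_folds: int = 3,
    criteria: tuple[str, ...] = CRITERIA,
    model_factory=None,
) -> StabilityResult:
    """Run AHFS ``n_runs`` times with derived seeds; count appearances."""
    seeds = [
        int(c.generate_state(1)[0] % (2**31))
        for c in np.random.SeedSequence(base_seed).spawn(n_runs)
    ]
    traces = []
    counts: dict[str, int] = {}
    ctx = _ScoreContext(table.data, table.labels)
    for s in seeds:
        tr = ahfs_run(
            table,
            AHFSConfig(
                seed=s, max_steps=max_steps, cv_folds=cv_folds,
                criteria=criteria, model_factory=model_factory,
            ),
            _ctx=ctx,
        )
        traces.append(tr)
        for f in tr.final_set:
            counts[f] = counts.get(f, 0) + 1
    return StabilityResult(traces=tuple(traces), counts=counts)
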