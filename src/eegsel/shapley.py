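"""Exact Shapley attribution and the aggregation into importance scores.

The value function is interventional: v(S) is the mean model output over
a background set with the subject's values substituted for the features
in coalition S.  Feature sets are small (at most ~9 features), so the
2^n coalitions are enumerated exactly — no sampling estimator is needed —
and the efficiency identity sum(phi) + base = f(x) holds to numerical
precision.

Importance aggregation across the top cross-validated models: a feature's
raw score is the sum over models containing it of the mean absolute
Shapley value across subjects (so features appearing in more models
accrue more mass); scores are normalised to sum to one.  Breakdowns by
metric type, frequency bin and electrode partition that unit total.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import factorial

import numpy as np
import pandas as pd

from .cffs import ModelRecord
from .features import FeatureName, FeatureTable
from .montage import Montage

__all__ = [
    "ShapleyError",
    "exact_shapley",
    "shapley_for_record",
    "aggregate_importance",
    "summary_plot_data",
    "importance_breakdowns",
    "ImportanceTable",
]


class ShapleyError(ValueError):
    """Raised for invalid Shapley computations."""


def _coalition_masks(n: int) -> np.ndarray:
    """(2^n, n) boolean matrix; row index is the coalition bitmask."""
    idx = np.arange(2**n)
    return (idx[:, None] >> np.arange(n)) & 1 == 1


def _shapley_weights(n: int) -> np.ndarray:
    """w[s] = s! (n-1-s)! / n! for coalition size s (s = |S| without i)."""
    return np.array(
        [factorial(s) * factorial(n - 1 - s) / factorial(n) for s in range(n)]
    )


def _shapley_batch(
    predict, Xs: np.ndarray, background: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Exact Shapley values for several subjects sharing one background.

    ``Xs`` is (n_subjects, n_features).  Returns (phi matrix, base values).
    """
    Xs = np.atleast_2d(np.asarray(Xs, dtype=float))
    background = np.atleast_2d(np.asarray(background, dtype=float))
    if background.shape[0] == 0:
        raise ShapleyError("empty background set")
    n_subj, n = Xs.shape
    if background.shape[1] != n:
        raise ShapleyError("background width does not match the feature count")
    masks = _coalition_masks(n)
    n_bg = background.shape[0]
    n_coal = 2**n

    # hybrid rows: (subject, coalition, background row, feature)
    tiled = np.broadcast_to(
        background[None, None, :, :], (n_subj, n_coal, n_bg, n)
    ).copy()
    sub = np.broadcast_to(Xs[:, None, None, :], (n_subj, n_coal, n_bg, n))
    sel = np.broadcast_to(masks[None, :, None, :], (n_subj, n_coal, n_bg, n))
    tiled[sel] = sub[sel]
    out = np.asarray(predict(tiled.reshape(-1, n)), dtype=float)
    v = out.reshape(n_subj, n_coal, n_bg).mean(axis=2)  # v(S) per bitmask

    w = _shapley_weights(n)
    sizes = masks.sum(axis=1)
    phi = np.zeros((n_subj, n))
    for i in range(n):
        s_idx = np.flatnonzero(~masks[:, i])
        gain = v[:, s_idx | (1 << i)] - v[:, s_idx]
        phi[:, i] = gain @ w[sizes[s_idx]]
    return phi, v[:, 0].copy()


def exact_shapley(
    predict, x: np.ndarray, background: np.ndarray
) -> tuple[np.ndarray, float]:
    """Exact interventional Shapley values of ``predict`` at ``x``.

    ``predict`` maps an (m, n_features) array to m scalar outputs.
    Returns (per-feature values, base value v(empty set)); the efficiency
    identity sum(phi) + base = predict(x) holds to numerical precision.
    """
    phi, base = _shapley_batch(predict, np.asarray(x, dtype=float)[None, :], background)
    return phi[0], float(base[0])


def shapley_for_record(
    record: ModelRecord,
    table: FeatureTable,
    background_max: int | None = None,
    seed: int = 0,
) -> ModelRecord:
    """Fill a model record's Shapley matrix.

    Each subject is explained by the fold model for which it was held
    out, with that fold's training rows as background (optionally
    subsampled to ``background_max`` rows).  The explained quantity is
    the predicted probability of the positive class.
    """
    if not record.fold_models:
        raise ShapleyError("record has no trained fold models")
    cols = [table.data.columns.get_loc(f) for f in record.feature_set]
    X = table.data.to_numpy(dtype=float)[:, cols]
    n_subj, n_feat = X.shape
    phi = np.zeros((n_subj, n_feat))
    base = np.zeros(n_subj)
    rng = np.random.default_rng(seed)
    for f, model in enumerate(record.fold_models):
        te = np.flatnonzero(record.fold_assignment == f)
        tr = np.flatnonzero(record.fold_assignment != f)
        bg = X[tr]
        if background_max is not None and len(bg) > background_max:
            bg = bg[rng.choice(len(bg), size=background_max, replace=False)]
        pos = list(model.classes_).index(1)

        def predict(rows, _m=model, _p=pos):
            return _m.predict_proba(rows)[:, _p]

        # chunk subjects so a batch stays below ~500k hybrid rows
        rows_per_subject = (2**n_feat) * len(bg)
        chunk = max(1, 500_000 // rows_per_subject)
        for start in range(0, len(te), chunk):
            sel = te[start : start + chunk]
            phi[sel], base[sel] = _shapley_batch(predict, X[sel], bg)
    record.shapley = phi
    record.base_values = base
    return record


@dataclass(frozen=True)
class ImportanceTable:
    """Normalised per-feature importance scores (they sum to one)."""

    scores: pd.Series  # index: feature name

    def __post_init__(self) -> None:
        if len(self.scores) and not np.isclose(self.scores.sum(), 1.0, atol=1e-9):
            raise ShapleyError("importance scores must sum to 1")
        if (self.scores < 0).any():
            raise ShapleyError("importance scores must be nonnegative")

    def top(self, n: int = 5) -> pd.Series:
        return self.scores.sort_values(ascending=False).head(n)


def aggregate_importance(records: list[ModelRecord]) -> ImportanceTable:
    """Aggregate |Shapley| across models into normalised importance.

    raw(feature) = sum over models containing it of mean-over-subjects
    |shapley| (equivalently the across-model mean weighted by the number
    of models containing the feature); features absent everywhere score 0.
    """
    if not records:
        raise ShapleyError("no records to aggregate")
    raw: dict[str, float] = {}
    for r in records:
        if r.shapley is None:
            raise ShapleyError("record lacks Shapley values; run shapley_for_record")
        mean_abs = np.abs(r.shapley).mean(axis=0)
        for f, v in zip(r.feature_set, mean_abs):
            raw[f] = raw.get(f, 0.0) + float(v)
    s = pd.Series(raw, dtype=float).sort_values(ascending=False)
    total = s.sum()
    if total > 0:
        s = s / total
    return ImportanceTable(scores=s)


def summary_plot_data(records: list[ModelRecord], table: FeatureTable) -> pd.DataFrame:
    """Beeswarm-style data: one point per (feature, subject).

    ``shapley`` is the subject's mean signed value across the models
    containing the feature; ``feature_value`` is the subject's
    (normalised) value for colouring.
    """
    if not records:
        raise ShapleyError("no records")
    sums: dict[str, np.ndarray] = {}
    counts: dict[str, int] = {}
    for r in records:
        if r.shapley is None:
            raise ShapleyError("record lacks Shapley values")
        for j, f in enumerate(r.feature_set):
            sums[f] = sums.get(f, 0.0) + r.shapley[:, j]
            counts[f] = counts.get(f, 0) + 1
    rows = []
    subjects = list(table.data.index)
    for f in sums:
        mean_phi = sums[f] / counts[f]
        vals = table.data[f].to_numpy(dtype=float)
        for s_idx, subj in enumerate(subjects):
            rows.append((f, subj, float(mean_phi[s_idx]), float(vals[s_idx])))
    return pd.DataFrame(rows, columns=["feature", "subject", "shapley", "feature_value"])


_MS_PREFIXES = ("MS_", "MSTRANS_")


def _parse_or_none(name: str):
    if name.startswith(_MS_PREFIXES):
        return None
    return FeatureName.parse(name)


def importance_breakdowns(
    table: ImportanceTable,
) -> dict[str, pd.Series]:
    """Partition the unit importance total three ways.

    ``by_type`` groups by metric token (microstate features pool under
    'microstate'); ``by_frequency`` groups PSD features by their 2-Hz bin
    and pools everything else under 'non-PSD'; ``by_channel`` groups by
    electrode (microstate features pool under 'n/a').  Each breakdown
    sums to the same unit total.
    """
    by_type: dict[str, float] = {}
    by_freq: dict[str, float] = {}
    by_chan: dict[str, float] = {}
    for name, score in table.scores.items():
        parsed = _parse_or_none(name)
        if parsed is None:
            by_type["microstate"] = by_type.get("microstate", 0.0) + score
            by_freq["non-PSD"] = by_freq.get("non-PSD", 0.0) + score
            by_chan["n/a"] = by_chan.get("n/a", 0.0) + score
            continue
        by_type[parsed.metric] = by_type.get(parsed.metric, 0.0) + score
        if parsed.metric == "PSD" and parsed.band is not None:
            lo, hi = parsed.band
            key = f"{lo:g}-{hi:g}"
        else:
            key = "non-PSD"
        by_freq[key] = by_freq.get(key, 0.0) + score
        by_chan[parsed.channel] = by_chan.get(parsed.channel, 0.0) + score
    return {
        "by_type": pd.Series(by_type).sort_values(ascending=False),
        "by_frequency": pd.Series(by_freq).sort_values(ascending=False),
        "by_channel": pd.Series(by_chan).sort_values(ascending=False),
    }


# ---------------------------------------------------------------------------
# plotting (file output; kept minimal)


def plot_summary(points: pd.DataFrame, path, top_n: int = 12) -> None:
    """Beeswarm-style summary plot of the aggregated Shapley values."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    order = (
        points.groupby("feature")["shapley"].apply(lambda s: s.abs().mean())
        .sort_values(ascending=False).head(top_n).index
    )
    fig, ax = plt.subplots(figsize=(7, 0.4 * len(order) + 1.5))
    for i, f in enumerate(order):
        sub = points[points["feature"] == f]
        jitter = (np.arange(len(sub)) % 7 - 3) * 0.04
        sc = ax.scatter(
            sub["shapley"], np.full(len(sub), i) + jitter,
            c=sub["feature_value"], cmap="coolwarm", s=14,
        )
    ax.set_yticks(range(len(order)), order)
    ax.invert_yaxis()
    ax.axvline(0, color="k", lw=0.5)
    ax.set_xlabel("Shapley value (impact on model output)")
    fig.colorbar(sc, ax=ax, label="feature value")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_scalp_importance(by_channel: pd.Series, montage: Montage, path) -> None:
    """Relative importance mass per electrode on the 2-D scalp layout."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    circ = plt.Circle((0, 0), 1.0, fill=False, color="k")
    ax.add_patch(circ)
    for ch in montage.channel_names:
        x, y = montage.position(ch)
        mass = float(by_channel.get(ch, 0.0))
        ax.scatter(x, y, s=100 + 4000 * mass, c="tab:red", alpha=0.6 if mass else 0.15)
        ax.annotate(ch, (x, y), fontsize=7, ha="center", va="center")
    ax.set_xlim(-1.2, 1.2)
    ax.set_ylim(-1.2, 1.2)
    ax.set_aspect("equal")
    ax.axis("off")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_frequency_importance(by_frequency: pd.Series, path) -> None:
    """Importance mass against the centre of each 2-Hz PSD bin."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    xs, ys = [], []
    for key, v in by_frequency.items():
        if key == "non-PSD":
            continue
        lo, hi = (float(t) for t in key.split("-"))
        xs.append((lo + hi) / 2)
        ys.append(v)
    fig, ax = plt.subplots(figsize=(6, 3.5))
    ax.scatter(xs, ys)
    ax.set_xlabel("frequency (Hz)")
    ax.set_ylabel("importance score")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
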