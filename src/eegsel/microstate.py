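"""EEG microstate analysis.

Microstates are brief quasi-stable scalp topographies.  The analysis
extracts maps at the peaks of the Global Field Power, clusters them with a
polarity-invariant "modified K-means" (similarity is squared spatial
correlation; the template update is the dominant eigenvector of the
cluster's outer-product sum), backfits the winning templates onto the full
recording, and summarises the label sequence by duration, occurrence,
coverage and transition probabilities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from .synth import Recording

__all__ = [
    "MicrostateError",
    "MicrostateModel",
    "MicrostateStats",
    "gfp",
    "gfp_peaks",
    "fit_microstates",
    "backfit",
    "microstate_stats",
    "microstate_features",
    "microstates_for_recording",
]


class MicrostateError(ValueError):
    """Raised for invalid microstate-analysis requests."""


@dataclass(frozen=True)
class MicrostateModel:
    """k unit-norm template topographies and their explained variance."""

    templates: np.ndarray  # (k, n_channels), unit rows
    gev: float
    channel_names: tuple[str, ...]

    def __post_init__(self) -> None:
        norms = np.linalg.norm(self.templates, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-8):
            raise MicrostateError("templates must have unit norm")
        if not 0.0 <= self.gev <= 1.0 + 1e-9:
            raise MicrostateError(f"gev {self.gev} outside [0, 1]")

    @property
    def k(self) -> int:
        return self.templates.shape[0]


@dataclass(frozen=True)
class MicrostateStats:
    """Temporal statistics of a microstate label sequence."""

    mean_duration_ms: np.ndarray  # per class; 0 for absent classes
    occurrence_per_s: np.ndarray
    coverage: np.ndarray
    transitions: np.ndarray  # (k, k) conditional probabilities, zero diagonal
    absent_classes: tuple[int, ...] = ()

    @property
    def k(self) -> int:
        return len(self.coverage)


def gfp(rec_or_samples) -> np.ndarray:
    """Global Field Power: per-time-point standard deviation across channels."""
    x = rec_or_samples.samples if isinstance(rec_or_samples, Recording) else rec_or_samples
    return np.asarray(x).std(axis=0)


def gfp_peaks(
    series: np.ndarray, fs: float | None = None, min_separation_ms: float = 0.0
) -> np.ndarray:
    """Strict local maxima of the GFP series, thinned to a minimum distance.

    When two peaks fall within the separation window the larger survives
    (this is scipy's distance-pruning rule, which drops smaller peaks
    first).  Separation requires ``fs``.
    """
    series = np.asarray(series)
    if len(series) < 3:
        raise MicrostateError("series too short for peak detection")
    if min_separation_ms > 0:
        if fs is None:
            raise MicrostateError("fs required when min_separation_ms > 0")
        distance = max(1, int(round(min_separation_ms / 1000.0 * fs)))
        idx, _ = find_peaks(series, distance=distance)
    else:
        idx, _ = find_peaks(series)
    return idx


def _assign(maps: np.ndarray, templates: np.ndarray) -> np.ndarray:
    """Polarity-invariant assignment: argmax squared correlation; ties and
    zero maps resolve to the lowest class index."""
    norms = np.linalg.norm(maps, axis=1, keepdims=True)
    safe = np.where(norms > 0, norms, 1.0)
    corr = (maps / safe) @ templates.T
    return np.argmax(np.round(corr**2, 12), axis=1)


def _gev(maps: np.ndarray, templates: np.ndarray, labels: np.ndarray) -> float:
    """GFP²-weighted fraction of variance explained by the assigned templates."""
    g = maps.std(axis=1)
    norms = np.linalg.norm(maps, axis=1)
    safe = np.where(norms > 0, norms, 1.0)
    corr = np.einsum("ij,ij->i", maps / safe[:, None], templates[labels])
    denom = (g**2).sum()
    if denom == 0:
        return 0.0
    return float(((g**2) * corr**2).sum() / denom)


def fit_microstates(
    maps: np.ndarray,
    k: int = 4,
    n_restarts: int = 10,
    seed: int = 0,
    channel_names: tuple[str, ...] | None = None,
    max_iter: int = 100,
) -> MicrostateModel:
    """Modified K-means on peak maps; best of ``n_restarts`` by GEV.

    ``maps`` has shape (n_maps, n_channels) and should be average
    referenced.  Assignment ignores polarity; the template update is the
    dominant eigenvector of each cluster's outer-product sum, so sign
    flips of the input leave the fit unchanged.
    """
    maps = np.asarray(maps, dtype=float)
    n_maps, n_ch = maps.shape
    if n_maps < k:
        raise MicrostateError(f"need at least k={k} maps, got {n_maps}")
    rng = np.random.default_rng(seed)

    best: tuple[float, np.ndarray] | None = None
    for _ in range(n_restarts):
        idx = rng.choice(n_maps, size=k, replace=False)
        templates = maps[idx].copy()
        norms = np.linalg.norm(templates, axis=1, keepdims=True)
        templates /= np.where(norms > 0, norms, 1.0)
        labels = _assign(maps, templates)
        for _ in range(max_iter):
            for j in range(k):
                members = maps[labels == j]
                if len(members) == 0:
                    # re-seed an empty cluster with a random map
                    m = maps[rng.integers(n_maps)]
                    templates[j] = m / max(np.linalg.norm(m), 1e-12)
                    continue
                s = members.T @ members
                w, v = np.linalg.eigh(s)
                templates[j] = v[:, -1]
            new_labels = _assign(maps, templates)
            if np.array_equal(new_labels, labels):
                break
            labels = new_labels
        gev = _gev(maps, templates, labels)
        if best is None or gev > best[0]:
            best = (gev, templates.copy())

    gev, templates = best
    names = channel_names or tuple(f"ch{i}" for i in range(n_ch))
    return MicrostateModel(templates=templates, gev=min(gev, 1.0), channel_names=tuple(names))


def backfit(model: MicrostateModel, rec: Recording) -> np.ndarray:
    """Label every time point by the template with maximal squared
    spatial correlation (polarity invariant, ties to the lowest index)."""
    if tuple(rec.montage.channel_names) != model.channel_names:
        raise MicrostateError("model channels do not match the recording")
    return _assign(rec.samples.T, model.templates)


def reorder_by_coverage(model: MicrostateModel, labels: np.ndarray) -> tuple[MicrostateModel, np.ndarray]:
    """Sort classes by descending coverage for stable reporting."""
    counts = np.bincount(labels, minlength=model.k)
    order = np.argsort(-counts, kind="stable")
    remap = np.empty(model.k, dtype=int)
    remap[order] = np.arange(model.k)
    new_model = MicrostateModel(
        templates=model.templates[order],
        gev=model.gev,
        channel_names=model.channel_names,
    )
    return new_model, remap[labels]


def microstate_stats(labels: np.ndarray, fs: float, k: int | None = None) -> MicrostateStats:
    """Run-length statistics of a label sequence."""
    labels = np.asarray(labels)
    if labels.size == 0:
        raise MicrostateError("empty label sequence")
    k = k if k is not None else int(labels.max()) + 1
    n = len(labels)

    # run-length encoding
    change = np.flatnonzero(np.diff(labels)) + 1
    starts = np.r_[0, change]
    ends = np.r_[change, n]
    run_labels = labels[starts]
    run_lengths = ends - starts

    duration = np.zeros(k)
    occurrence = np.zeros(k)
    coverage = np.zeros(k)
    total_s = n / fs
    absent = []
    for j in range(k):
        sel = run_labels == j
        if not sel.any():
            absent.append(j)
            continue
        duration[j] = run_lengths[sel].mean() / fs * 1000.0
        occurrence[j] = sel.sum() / total_s
        coverage[j] = run_lengths[sel].sum() / n

    trans = np.zeros((k, k))
    for a, b in zip(run_labels[:-1], run_labels[1:]):
        trans[a, b] += 1
    row = trans.sum(axis=1, keepdims=True)
    trans = np.divide(trans, row, out=np.zeros_like(trans), where=row > 0)
    return MicrostateStats(
        mean_duration_ms=duration,
        occurrence_per_s=occurrence,
        coverage=coverage,
        transitions=trans,
        absent_classes=tuple(absent),
    )


def microstate_features(stats: MicrostateStats) -> dict[str, float]:
    """Flatten the stats into named scalar features.

    Naming: ``MS_<class>_<metric>`` and ``MSTRANS_<i>to<j>`` (off-diagonal
    transition probabilities only); 24 columns for k=4.
    """
    out: dict[str, float] = {}
    for j in range(stats.k):
        out[f"MS_{j}_duration"] = float(stats.mean_duration_ms[j])
        out[f"MS_{j}_occurrence"] = float(stats.occurrence_per_s[j])
        out[f"MS_{j}_coverage"] = float(stats.coverage[j])
    for i in range(stats.k):
        for j in range(stats.k):
            if i != j:
                out[f"MSTRANS_{i}to{j}"] = float(stats.transitions[i, j])
    return out


def microstates_for_recording(
    rec: Recording,
    k: int = 4,
    n_restarts: int = 10,
    seed: int = 0,
    min_separation_ms: float = 10.0,
    gev_floor: float = 0.5,
) -> tuple[MicrostateModel, np.ndarray, MicrostateStats, dict]:
    """Fit, backfit and summarise microstates for a single recording.

    Subjects whose fitted model explains less than ``gev_floor`` of the
    GFP-weighted variance are flagged (``flags['low_gev']``), not dropped.
    Classes are reordered by descending coverage.
    """
    g = gfp(rec)
    peaks = gfp_peaks(g, fs=rec.fs, min_separation_ms=min_separation_ms)
    if len(peaks) < k:
        raise MicrostateError(f"only {len(peaks)} GFP peaks; need at least {k}")
    maps = rec.samples[:, peaks].T
    model = fit_microstates(
        maps, k=k, n_restarts=n_restarts, seed=seed,
        channel_names=tuple(rec.montage.channel_names),
    )
    labels = backfit(model, rec)
    model, labels = reorder_by_coverage(model, labels)
    stats = microstate_stats(labels, rec.fs, k=model.k)
    flags = {"low_gev": bool(model.gev < gev_floor), "gev": model.gev}
    return model, labels, stats, flags
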