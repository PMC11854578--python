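"""Epoch-wise feature engineering for resting-state EEG.

Each preprocessed recording is cut into contiguous one-second epochs.  Per
epoch and channel, six metric families are computed — 2-Hz power-spectral-
density bins, canonical band powers, Lempel-Ziv complexity (LZ76 on a
median-binarised epoch), Hjorth activity and mobility, and sample entropy
— yielding a secondary time series per (channel, metric).  Each series is
summarised by four statistics (mean, population standard deviation, upper
and lower quartile with linear-interpolation quantiles), and the summaries
become the columns of a subjects-by-features table.

Feature names follow the grammar ``<metric>_<channel>[_<lo>-<hi>]_<stat>``,
e.g. ``PSD_CP5_44-46_std`` or ``LZC_T7_upper_qrt``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import periodogram

from .synth import Recording

__all__ = [
    "FeatureError",
    "FeatureName",
    "FeatureTable",
    "STATS",
    "CANONICAL_BANDS",
    "epoch_signal",
    "psd_bins",
    "band_powers",
    "lempel_ziv",
    "lz76_phrase_count",
    "hjorth_activity",
    "hjorth_mobility",
    "sample_entropy",
    "summarize",
    "build_feature_table",
    "normalize_features",
]


class FeatureError(ValueError):
    """Raised for invalid feature-extraction requests."""


class DegenerateSignalError(FeatureError):
    """Raised when a metric is undefined on the given signal."""


STATS = ("mean", "std", "upper_qrt", "lower_qrt")

#: Canonical EEG bands: delta below 4 Hz, theta 4-8, alpha 8-13,
#: beta 14-30, gamma above 30 Hz (upper edge set by Nyquist downstream).
CANONICAL_BANDS: dict[str, tuple[float, float]] = {
    "delta": (0.0, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (14.0, 30.0),
    "gamma": (30.0, np.inf),
}


def _fmt_hz(x: float) -> str:
    return f"{int(x)}" if float(x).is_integer() else f"{x:g}"


@dataclass(frozen=True)
class FeatureName:
    """Structured feature name; ``serialize``/``parse`` round trip."""

    metric: str
    channel: str
    stat: str
    band: tuple[float, float] | None = None

    def serialize(self) -> str:
        if self.stat not in STATS:
            raise FeatureError(f"unknown stat {self.stat!r}")
        parts = [self.metric, self.channel]
        if self.band is not None:
            parts.append(f"{_fmt_hz(self.band[0])}-{_fmt_hz(self.band[1])}")
        parts.append(self.stat)
        return "_".join(parts)

    @classmethod
    def parse(cls, name: str) -> "FeatureName":
        stat = None
        for s in sorted(STATS, key=len, reverse=True):
            if name.endswith("_" + s):
                stat = s
                body = name[: -len(s) - 1]
                break
        if stat is None:
            raise FeatureError(f"no stat suffix in feature name {name!r}")
        parts = body.split("_")
        if len(parts) == 2:
            metric, channel = parts
            band = None
        elif len(parts) == 3:
            metric, channel, freq = parts
            try:
                lo, hi = freq.split("-")
                band = (float(lo), float(hi))
            except ValueError:
                raise FeatureError(f"bad frequency token {freq!r} in {name!r}") from None
        else:
            raise FeatureError(f"cannot parse feature name {name!r}")
        return cls(metric=metric, channel=channel, stat=stat, band=band)


# ---------------------------------------------------------------------------
# epoching


def epoch_signal(rec: Recording, window_s: float = 1.0) -> np.ndarray:
    """Cut into contiguous non-overlapping windows.

    Returns an array of shape (n_channels, n_epochs, window_samples); the
    trailing partial window is dropped.
    """
    if window_s <= 0:
        raise FeatureError("window_s must be > 0")
    w = int(round(window_s * rec.fs))
    n_epochs = rec.n_times // w
    if n_epochs == 0:
        raise FeatureError("recording shorter than one window")
    x = rec.samples[:, : n_epochs * w]
    return x.reshape(rec.n_channels, n_epochs, w)


# ---------------------------------------------------------------------------
# per-epoch metrics


def _epoch_spectrum(epoch: np.ndarray, fs: float) -> tuple[np.ndarray, np.ndarray]:
    """One-sided power spectrum (µV²) of a detrended, boxcar-windowed epoch."""
    freqs, p = periodogram(
        epoch, fs=fs, window="boxcar", detrend="constant", scaling="spectrum"
    )
    return freqs, p


def psd_bins(
    epoch: np.ndarray, fs: float, bin_width: float = 2.0
) -> dict[str, float]:
    """Power summed into contiguous bins [0-2), [2-4), ... up to Nyquist.

    The Nyquist frequency itself is folded into the last bin.
    """
    nyq = fs / 2
    if bin_width > nyq:
        raise FeatureError(f"bin width {bin_width} exceeds Nyquist {nyq}")
    freqs, p = _epoch_spectrum(np.asarray(epoch, dtype=float), fs)
    n_bins = int(math.ceil(nyq / bin_width))
    idx = np.minimum((freqs / bin_width).astype(int), n_bins - 1)
    sums = np.bincount(idx, weights=p, minlength=n_bins)
    return {
        f"{_fmt_hz(k * bin_width)}-{_fmt_hz((k + 1) * bin_width)}": float(sums[k])
        for k in range(n_bins)
    }


def band_powers(epoch: np.ndarray, fs: float) -> dict[str, float]:
    """Power in the canonical delta/theta/alpha/beta/gamma bands."""
    nyq = fs / 2
    if nyq <= 4:
        raise FeatureError(f"Nyquist {nyq} Hz too low for canonical bands")
    freqs, p = _epoch_spectrum(np.asarray(epoch, dtype=float), fs)
    out = {}
    for name, (lo, hi) in CANONICAL_BANDS.items():
        hi = min(hi, nyq)
        sel = (freqs >= lo) & (freqs < hi) if np.isfinite(hi) else freqs >= lo
        if name == "gamma":
            sel = freqs > 30.0
        out[name] = float(p[sel].sum())
    return out


def lz76_phrase_count(bits: np.ndarray) -> int:
    """Number of phrases in the LZ76 exhaustive parsing of a binary string."""
    s = np.asarray(bits).astype(np.uint8).tobytes()
    n = len(s)
    if n == 0:
        return 0
    if n == 1:
        return 1
    # Kaspar & Schuster formulation of the LZ76 exhaustive parsing
    c, l, i, k, k_max = 1, 1, 0, 1, 1
    while True:
        if s[i + k - 1] == s[l + k - 1]:
            k += 1
            if l + k > n:
                c += 1
                break
        else:
            k_max = max(k, k_max)
            i += 1
            if i == l:
                c += 1
                l += k_max
                if l + 1 > n:
                    break
                i, k, k_max = 0, 1, 1
            else:
                k = 1
    return c


def lempel_ziv(epoch: np.ndarray) -> float:
    """Normalised Lempel-Ziv complexity c(n) * log2(n) / n.

    The epoch is binarised by a strict median split (value > median -> 1,
    ties -> 0).  Lower values indicate a more regular signal.
    """
    x = np.asarray(epoch, dtype=float)
    n = len(x)
    if n < 2:
        raise FeatureError("epoch must have at least 2 samples")
    bits = (x > np.median(x)).astype(np.uint8)
    c = lz76_phrase_count(bits)
    return c * math.log2(n) / n


def hjorth_activity(epoch: np.ndarray) -> float:
    """Variance of the epoch (µV²)."""
    return float(np.var(np.asarray(epoch, dtype=float)))


def hjorth_mobility(epoch: np.ndarray, fs: float) -> float:
    """sqrt(var(dx/dt) / var(x)) in rad/s; 0 for a constant epoch.

    For a sinusoid at frequency f this approximates the analytic value
    2*pi*f (the first difference scaled by fs approximates the derivative).
    """
    x = np.asarray(epoch, dtype=float)
    if len(x) < 3:
        raise FeatureError("mobility needs at least 3 samples")
    v = np.var(x)
    if v == 0:
        return 0.0
    dv = np.var(np.diff(x) * fs)
    return float(np.sqrt(dv / v))


def sample_entropy(epoch: np.ndarray, m: int = 2, r: float | None = None) -> float:
    """SampEn(m, r) = -ln(A/B) under the Chebyshev metric, strict < r.

    ``r`` defaults to 0.2 times the epoch's (population) standard
    deviation.  Self-matches are excluded.  A degenerate signal with no
    m-length template matches raises :class:`DegenerateSignalError`.
    """
    x = np.asarray(epoch, dtype=float)
    n = len(x)
    if n <= m + 1:
        raise FeatureError(f"epoch too short for m={m}")
    if r is None:
        r = 0.2 * float(np.std(x))
    if r <= 0:
        raise DegenerateSignalError("tolerance r is not positive (constant epoch?)")

    # Chebyshev window distances from one pairwise |x_i - x_j| matrix,
    # via running maxima over diagonal shifts
    d0 = np.abs(x[:, None] - x[None, :])
    n_t = n - m  # template count, shared by both window lengths

    def count(mm: int) -> int:
        d = d0[:n_t, :n_t].copy()
        for k in range(1, mm):
            np.maximum(d, d0[k : k + n_t, k : k + n_t], out=d)
        return int((d < r).sum() - n_t)  # exclude self-matches

    b = count(m)
    if b == 0:
        raise DegenerateSignalError("no m-length template matches (B = 0)")
    a = count(m + 1)
    if a == 0:
        return float("inf")
    return float(-math.log(a / b))


def summarize(series: np.ndarray) -> dict[str, float]:
    """The four summary statistics of a secondary time series."""
    s = np.asarray(series, dtype=float)
    if s.size == 0:
        raise FeatureError("cannot summarize an empty series")
    srt = np.sort(s)

    def quartile(q: float) -> float:
        # linear-interpolation quantile (numpy's "linear" method)
        h = (len(srt) - 1) * q
        lo = int(h)
        hi = min(lo + 1, len(srt) - 1)
        return float(srt[lo] + (h - lo) * (srt[hi] - srt[lo]))

    return {
        "mean": float(s.mean()),
        "std": float(s.std()),  # population std
        "upper_qrt": quartile(0.75),
        "lower_qrt": quartile(0.25),
    }


# ---------------------------------------------------------------------------
# feature table


@dataclass
class FeatureTable:
    """Subjects-by-features table with group labels.

    ``data`` is indexed by subject id; ``labels`` is a parallel Series of
    group names; ``normalization`` records, per column, how it was scaled.
    """

    data: pd.DataFrame
    labels: pd.Series
    normalization: dict[str, dict] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.data.index.equals(self.labels.index):
            raise FeatureError("data and labels must share the subject index")
        if self.data.columns.duplicated().any():
            raise FeatureError("duplicate feature columns")

    @property
    def feature_names(self) -> list[str]:
        return list(self.data.columns)

    def subset(self, features: list[str]) -> "FeatureTable":
        return FeatureTable(
            data=self.data[features].copy(),
            labels=self.labels.copy(),
            normalization={k: v for k, v in self.normalization.items() if k in features},
        )

    def restrict_groups(self, groups: list[str]) -> "FeatureTable":
        mask = self.labels.isin(groups)
        return FeatureTable(
            data=self.data.loc[mask].copy(),
            labels=self.labels.loc[mask].copy(),
            normalization=dict(self.normalization),
        )

    def to_csv(self, path: str | Path) -> None:
        path = Path(path)
        out = self.data.copy()
        out.insert(0, "group", self.labels)
        out.to_csv(path, index_label="subject_id")
        if self.normalization:
            sidecar = path.with_suffix(path.suffix + ".norm.json")
            sidecar.write_text(json.dumps(self.normalization, indent=1))

    @classmethod
    def from_csv(cls, path: str | Path) -> "FeatureTable":
        path = Path(path)
        df = pd.read_csv(path, index_col="subject_id")
        labels = df.pop("group")
        sidecar = path.with_suffix(path.suffix + ".norm.json")
        norm = json.loads(sidecar.read_text()) if sidecar.exists() else {}
        return cls(data=df, labels=labels, normalization=norm)


@dataclass(frozen=True)
class FeatureConfig:
    window_s: float = 1.0
    psd_bin_width: float = 2.0
    sampen_m: int = 2
    sampen_r_factor: float = 0.2
    metrics: tuple[str, ...] = (
        "PSD", "bandPower", "LZC", "hjorthActivity", "hjorthMobility", "sampEn"
    )


def _channel_metric_series(
    epochs: np.ndarray, fs: float, cfg: FeatureConfig
) -> dict[tuple[str, tuple[float, float] | None], np.ndarray]:
    """Secondary time series for one channel: (metric, band) -> per-epoch values.

    Spectral metrics are computed for all epochs in one batched
    periodogram call; the sequence metrics (LZC, SampEn) loop per epoch.
    """
    n_epochs = epochs.shape[0]
    nyq = fs / 2
    out: dict[tuple[str, tuple[float, float] | None], np.ndarray] = {}

    if "PSD" in cfg.metrics or "bandPower" in cfg.metrics:
        freqs, p = _epoch_spectrum(epochs, fs)  # p: (n_epochs, n_freqs)
        if "PSD" in cfg.metrics:
            bw = cfg.psd_bin_width
            n_bins = int(math.ceil(nyq / bw))
            idx = np.minimum((freqs / bw).astype(int), n_bins - 1)
            for k in range(n_bins):
                key = ("PSD", (k * bw, (k + 1) * bw))
                out[key] = p[:, idx == k].sum(axis=1)
        if "bandPower" in cfg.metrics:
            for name, (lo, hi) in CANONICAL_BANDS.items():
                sel = freqs > 30.0 if name == "gamma" else (freqs >= lo) & (freqs < hi)
                out[("bandPower", (lo, min(hi, nyq)))] = p[:, sel].sum(axis=1)

    if "hjorthActivity" in cfg.metrics:
        out[("hjorthActivity", None)] = epochs.var(axis=1)
    if "hjorthMobility" in cfg.metrics:
        v = epochs.var(axis=1)
        dv = np.var(np.diff(epochs, axis=1) * fs, axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            mob = np.sqrt(np.where(v > 0, dv / np.where(v > 0, v, 1.0), 0.0))
        out[("hjorthMobility", None)] = mob
    if "LZC" in cfg.metrics:
        out[("LZC", None)] = np.array([lempel_ziv(epochs[e]) for e in range(n_epochs)])
    if "sampEn" in cfg.metrics:
        vals = []
        for e in range(n_epochs):
            try:
                vals.append(
                    sample_entropy(
                        epochs[e], cfg.sampen_m,
                        cfg.sampen_r_factor * float(np.std(epochs[e])),
                    )
                )
            except DegenerateSignalError:
                vals.append(float("nan"))
        out[("sampEn", None)] = np.asarray(vals)
    return out


def build_feature_table(
    recordings: list[Recording], cfg: FeatureConfig | None = None
) -> FeatureTable:
    """One row per subject; columns are every (metric, channel, band?) x stat."""
    if not recordings:
        raise FeatureError("no recordings")
    cfg = cfg or FeatureConfig()
    montage0 = recordings[0].montage.channel_names
    fs0 = recordings[0].fs
    for rec in recordings:
        if rec.montage.channel_names != montage0 or rec.fs != fs0:
            raise FeatureError("recordings have heterogeneous montages or rates")

    rows: list[dict[str, float]] = []
    for rec in recordings:
        epochs = epoch_signal(rec, cfg.window_s)
        row: dict[str, float] = {}
        for ci, ch in enumerate(montage0):
            series = _channel_metric_series(epochs[ci], rec.fs, cfg)
            for (metric, band), values in series.items():
                finite = values[np.isfinite(values)]
                stats = summarize(finite if finite.size else np.array([0.0]))
                for stat, v in stats.items():
                    name = FeatureName(metric, ch, stat, band).serialize()
                    row[name] = v
        rows.append(row)

    data = pd.DataFrame(rows, index=[r.subject_id for r in recordings])
    labels = pd.Series([r.group for r in recordings], index=data.index, name="group")
    return FeatureTable(data=data, labels=labels)


def normalize_features(
    table: FeatureTable, log_std_threshold: float = 1e-4
) -> FeatureTable:
    """Z-score every column; near-zero-variance columns take a log path.

    Columns whose (population) standard deviation is below the threshold
    are shifted to strict positivity, log-transformed, then z-scored.
    Constant columns map to all zeros and are flagged in the metadata.
    """
    if len(table.data) < 2:
        raise FeatureError("normalization needs at least 2 subjects")
    out = table.data.copy()
    meta: dict[str, dict] = {}
    for col in out.columns:
        x = out[col].to_numpy(dtype=float)
        sd = x.std()
        info: dict = {"log": False, "constant": False}
        if sd == 0:
            out[col] = 0.0
            info["constant"] = True
            meta[col] = info
            continue
        if sd < log_std_threshold:
            shift = x.min() - max(sd, 1e-12)
            x = np.log(x - shift)
            info["log"] = True
            sd = x.std()
            if sd == 0:
                out[col] = 0.0
                info["constant"] = True
                meta[col] = info
                continue
        mu = x.mean()
        out[col] = (x - mu) / sd
        info.update(mean=float(mu), std=float(sd))
        meta[col] = info
    return FeatureTable(data=out, labels=table.labels.copy(), normalization=meta)
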