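"""Deterministic signal conditioning for resting-state EEG.

The standard chain is: polyphase resampling to 128 Hz, a zero-phase IIR
notch at the 50 Hz line frequency, a zero-phase Butterworth bandpass
(0.5-60 Hz), neighbour-weighted interpolation of bad channels, and common
average re-referencing.  All filters are applied forward-backward so the
chain is phase preserving, and the first and last second are trimmed at
the end of the full chain to drop filter transients.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
from scipy import signal

from .synth import Recording

__all__ = [
    "PreprocessError",
    "PreprocessConfig",
    "resample",
    "notch",
    "bandpass",
    "interpolate_channels",
    "rereference_average",
    "reject_epochs",
    "run_preprocess",
]

log = logging.getLogger(__name__)


class PreprocessError(ValueError):
    """Raised for invalid preprocessing requests."""


@dataclass(frozen=True)
class PreprocessConfig:
    """Parameters of the conditioning chain.

    ``reject_epoch_uV`` optionally drops one-second epochs whose
    peak-to-peak amplitude on any channel exceeds the threshold; it is a
    hook for real, artifact-laden data and is disabled by default.
    """

    target_fs: float = 128.0
    notch_hz: float = 50.0
    band: tuple[float, float] = (0.5, 60.0)
    bad_channels: tuple[str, ...] = ()
    reject_epoch_uV: float | None = None
    notch_quality: float = 30.0
    edge_trim_s: float = 1.0

    def __post_init__(self) -> None:
        low, high = self.band
        if not (0 < low < high):
            raise PreprocessError(f"invalid band {self.band}")
        if high > self.target_fs / 2:
            raise PreprocessError(
                f"band edge {high} Hz at or above Nyquist ({self.target_fs / 2} Hz)"
            )
        if not (low < self.notch_hz < high):
            raise PreprocessError("notch frequency must lie inside the passband")

    @classmethod
    def from_file(cls, path) -> "PreprocessConfig":
        """Load a configuration from a YAML or JSON mapping file."""
        import json
        from pathlib import Path

        import yaml

        text = Path(path).read_text()
        data = (
            json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
        )
        if not isinstance(data, dict):
            raise PreprocessError(f"config file {path} does not hold a mapping")
        if "band" in data:
            data["band"] = tuple(data["band"])
        if "bad_channels" in data:
            data["bad_channels"] = tuple(data["bad_channels"])
        return cls(**data)


def resample(rec: Recording, target_fs: float) -> Recording:
    """Polyphase anti-aliased resampling (downsampling only)."""
    if target_fs > rec.fs:
        raise PreprocessError(
            f"upsampling {rec.fs} -> {target_fs} Hz is not supported"
        )
    if target_fs == rec.fs:
        return rec
    frac = Fraction(target_fs / rec.fs).limit_denominator(10000)
    out = signal.resample_poly(rec.samples, frac.numerator, frac.denominator, axis=1)
    n_expected = int(round(rec.n_times * target_fs / rec.fs))
    out = out[:, :n_expected]
    return rec.copy_with(samples=out, fs=float(target_fs))


def notch(rec: Recording, f0: float, quality: float = 30.0) -> Recording:
    """Zero-phase IIR notch at f0 Hz."""
    if not 0 < f0 < rec.fs / 2:
        raise PreprocessError(f"notch frequency {f0} Hz outside (0, Nyquist)")
    b, a = signal.iirnotch(f0, quality, fs=rec.fs)
    out = signal.filtfilt(b, a, rec.samples, axis=1)
    return rec.copy_with(samples=out)


def bandpass(rec: Recording, low: float, high: float, order: int = 8) -> Recording:
    """Zero-phase Butterworth bandpass with -3 dB points at (low, high).

    The design cutoffs are pre-warped so the -3 dB points of the combined
    forward-backward response land on the requested edges.
    """
    nyq = rec.fs / 2
    if not (0 < low < high < nyq):
        raise PreprocessError(f"invalid band ({low}, {high}) at fs={rec.fs}")
    # |H|^4 = 1/2 at the edge => per-edge warp factor (sqrt(2)-1)^(1/2N)
    q = (np.sqrt(2.0) - 1.0) ** (1.0 / (2 * order))
    lo = low * q
    hi = min(high / q, 0.999 * nyq)
    sos = signal.butter(order, [lo, hi], btype="bandpass", fs=rec.fs, output="sos")
    out = signal.sosfiltfilt(sos, rec.samples, axis=1)
    return rec.copy_with(samples=out)


def interpolate_channels(rec: Recording, bad: list[str]) -> Recording:
    """Replace bad channels by the neighbour-weighted average of good ones."""
    if not bad:
        return rec
    names = rec.montage.channel_names
    unknown = [ch for ch in bad if ch not in names]
    if unknown:
        raise PreprocessError(f"unknown channels: {unknown}")
    bad_set = set(bad)
    if bad_set == set(names):
        raise PreprocessError("cannot interpolate: every channel is bad")
    out = rec.samples.copy()
    for ch in bad:
        nb = {
            name: w
            for name, w in rec.montage.neighbors[ch].items()
            if name not in bad_set
        }
        if not nb:
            raise PreprocessError(f"channel {ch!r} has no good neighbors")
        total = sum(nb.values())
        i = rec.montage.index(ch)
        out[i] = sum(
            (w / total) * rec.samples[rec.montage.index(name)]
            for name, w in nb.items()
        )
    return rec.copy_with(samples=out)


def rereference_average(rec: Recording) -> Recording:
    """Common average reference: subtract the instantaneous channel mean."""
    if rec.n_channels < 2:
        raise PreprocessError("average reference requires at least 2 channels")
    out = rec.samples - rec.samples.mean(axis=0, keepdims=True)
    return rec.copy_with(samples=out)


def reject_epochs(rec: Recording, threshold_uV: float, window_s: float = 1.0) -> Recording:
    """Drop whole windows whose peak-to-peak amplitude exceeds the threshold."""
    w = int(round(window_s * rec.fs))
    n_epochs = rec.n_times // w
    keep = []
    for e in range(n_epochs):
        seg = rec.samples[:, e * w : (e + 1) * w]
        if np.ptp(seg, axis=1).max() <= threshold_uV:
            keep.append(seg)
    if not keep:
        raise PreprocessError("all epochs exceeded the rejection threshold")
    return rec.copy_with(samples=np.hstack(keep))


def run_preprocess(rec: Recording, cfg: PreprocessConfig | None = None) -> Recording:
    """Full conditioning chain, in order: resample, notch, bandpass,
    bad-channel interpolation, average reference, edge trim, optional
    epoch rejection."""
    cfg = cfg or PreprocessConfig()
    log.info("preprocess %s: resample %g -> %g Hz", rec.subject_id, rec.fs, cfg.target_fs)
    rec = resample(rec, cfg.target_fs)
    log.info("preprocess %s: notch %g Hz", rec.subject_id, cfg.notch_hz)
    rec = notch(rec, cfg.notch_hz, cfg.notch_quality)
    log.info("preprocess %s: bandpass %s Hz", rec.subject_id, cfg.band)
    rec = bandpass(rec, *cfg.band)
    if cfg.bad_channels:
        log.info("preprocess %s: interpolate %s", rec.subject_id, cfg.bad_channels)
        rec = interpolate_channels(rec, list(cfg.bad_channels))
    rec = rereference_average(rec)
    if cfg.edge_trim_s > 0:
        t = int(round(cfg.edge_trim_s * rec.fs))
        if rec.n_times <= 2 * t:
            raise PreprocessError("recording too short for edge trimming")
        rec = rec.copy_with(samples=rec.samples[:, t : rec.n_times - t])
    if cfg.reject_epoch_uV is not None:
        rec = reject_epochs(rec, cfg.reject_epoch_uV)
    return rec
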