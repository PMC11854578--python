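"""Recording containers on disk.

Two containers are supported:

* ``.npz`` — a lossless numpy archive (samples, sampling rate, channel
  names, scalp positions, subject id, group); the container used by the
  test suite whenever exact round trips matter.
* ``.edf`` / ``.bdf`` — the 16-bit EDF and 24-bit BioSemi BDF interchange
  formats.  Reading supports both; writing emits EDF.  EDF/BDF quantise
  samples onto a fixed physical range, so round trips are exact only to
  the container's quantisation step.  The writer/reader here are minimal
  single-record-duration implementations of the fixed-layout header; parse
  failures raise :class:`RecordingParseError` carrying the byte offset.

A cohort is stored as a directory of recording files plus a ``manifest.csv``
with columns ``subject_id, group, file``.
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np

from .montage import CHANNELS_32, standard_montage, montage_from_positions
from .synth import Recording

__all__ = [
    "RecordingParseError",
    "write_recording",
    "read_recording",
    "edf_quantization_step",
    "write_manifest",
    "read_manifest",
]


class RecordingParseError(ValueError):
    """Malformed recording file; ``offset`` is the failing byte position."""

    def __init__(self, message: str, offset: int):
        super().__init__(f"{message} (byte offset {offset})")
        self.offset = offset


# ---------------------------------------------------------------------------
# lossless container


def _write_npz(rec: Recording, path: Path) -> None:
    np.savez(
        path,
        samples=rec.samples,
        fs=rec.fs,
        channel_names=np.array(rec.montage.channel_names),
        positions=rec.montage.positions,
        subject_id=rec.subject_id,
        group=rec.group,
    )


def _read_npz(path: Path) -> Recording:
    try:
        with np.load(path, allow_pickle=False) as z:
            names = tuple(str(c) for c in z["channel_names"])
            montage = montage_from_positions(names, z["positions"])
            return Recording(
                subject_id=str(z["subject_id"]),
                group=str(z["group"]),
                fs=float(z["fs"]),
                samples=z["samples"],
                montage=montage,
            )
    except (OSError, KeyError, ValueError) as e:
        if isinstance(e, RecordingParseError):
            raise
        raise RecordingParseError(f"cannot read npz container: {e}", 0) from e


# ---------------------------------------------------------------------------
# EDF / BDF


def edf_quantization_step(phys_min: float, phys_max: float, n_bits: int = 16) -> float:
    """Physical µV per digital unit for the given physical range."""
    return (phys_max - phys_min) / (2**n_bits - 1)


def _ascii(field: str, width: int) -> bytes:
    b = field.encode("ascii")[:width]
    return b.ljust(width)


def _write_edf(rec: Recording, path: Path) -> None:
    fs = rec.fs
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    fs = int(round(fs))
    n_ch = rec.n_channels
    n = rec.n_times
    n_rec = int(np.ceil(n / fs))
    pad = n_rec * fs - n
    data = rec.samples
    if pad:
        data = np.hstack([data, np.zeros((n_ch, pad))])

    pmax = float(max(1.0, np.ceil(np.abs(rec.samples).max())))
    dig_min, dig_max = -32768, 32767
    scale = (2 * pmax) / (dig_max - dig_min)

    header = b"".join(
        [
            _ascii("0", 8),
            _ascii(rec.subject_id, 80),
            _ascii(f"grp={rec.group} n={n}", 80),
            _ascii("01.01.00", 8),
            _ascii("00.00.00", 8),
            _ascii(str(256 * (1 + n_ch)), 8),
            _ascii("", 44),
            _ascii(str(n_rec), 8),
            _ascii("1", 8),
            _ascii(str(n_ch), 4),
        ]
    )
    sig = b"".join(
        [
            b"".join(_ascii(ch, 16) for ch in rec.montage.channel_names),
            b"".join(_ascii("AgAgCl electrode", 80) for _ in range(n_ch)),
            b"".join(_ascii("uV", 8) for _ in range(n_ch)),
            b"".join(_ascii(f"{-pmax:g}", 8) for _ in range(n_ch)),
            b"".join(_ascii(f"{pmax:g}", 8) for _ in range(n_ch)),
            b"".join(_ascii(str(dig_min), 8) for _ in range(n_ch)),
            b"".join(_ascii(str(dig_max), 8) for _ in range(n_ch)),
            b"".join(_ascii("", 80) for _ in range(n_ch)),
            b"".join(_ascii(str(fs), 8) for _ in range(n_ch)),
            b"".join(_ascii("", 32) for _ in range(n_ch)),
        ]
    )
    digital = np.round(data / scale).clip(dig_min, dig_max).astype("<i2")
    with open(path, "wb") as f:
        f.write(header)
        f.write(sig)
        # records: per record, per signal, fs samples
        for r in range(n_rec):
            f.write(digital[:, r * fs : (r + 1) * fs].tobytes())


def _parse_number(raw: bytes, offset: int, what: str) -> float:
    try:
        return float(raw.decode("ascii").strip())
    except (UnicodeDecodeError, ValueError) as e:
        raise RecordingParseError(f"bad {what} field {raw!r}", offset) from e


def _read_edf_bdf(path: Path) -> Recording:
    blob = Path(path).read_bytes()
    if len(blob) < 256:
        raise RecordingParseError("file shorter than the 256-byte header", len(blob))
    is_bdf = blob[0] == 0xFF
    bps = 3 if is_bdf else 2

    def field(off: int, width: int) -> bytes:
        return blob[off : off + width]

    subject_id = field(8, 80).decode("ascii", "replace").strip()
    rec_field = field(88, 80).decode("ascii", "replace").strip()
    n_rec = int(_parse_number(field(236, 8), 236, "record count"))
    rec_dur = _parse_number(field(244, 8), 244, "record duration")
    n_ch = int(_parse_number(field(252, 4), 252, "signal count"))
    if n_ch <= 0:
        raise RecordingParseError(f"non-positive signal count {n_ch}", 252)
    header_len = 256 + 256 * n_ch
    if len(blob) < header_len:
        raise RecordingParseError("truncated signal header", len(blob))

    base = 256
    labels = [
        field(base + 16 * i, 16).decode("ascii", "replace").strip() for i in range(n_ch)
    ]
    o_pmin = base + n_ch * (16 + 80 + 8)
    o_pmax = o_pmin + n_ch * 8
    o_dmin = o_pmax + n_ch * 8
    o_dmax = o_dmin + n_ch * 8
    o_spr = o_dmax + n_ch * 8 + n_ch * 80
    pmin = [_parse_number(field(o_pmin + 8 * i, 8), o_pmin + 8 * i, "phys min") for i in range(n_ch)]
    pmax = [_parse_number(field(o_pmax + 8 * i, 8), o_pmax + 8 * i, "phys max") for i in range(n_ch)]
    dmin = [_parse_number(field(o_dmin + 8 * i, 8), o_dmin + 8 * i, "dig min") for i in range(n_ch)]
    dmax = [_parse_number(field(o_dmax + 8 * i, 8), o_dmax + 8 * i, "dig max") for i in range(n_ch)]
    spr = [int(_parse_number(field(o_spr + 8 * i, 8), o_spr + 8 * i, "samples/record")) for i in range(n_ch)]
    if len(set(spr)) != 1:
        raise RecordingParseError("heterogeneous per-signal sampling rates", o_spr)
    fs = spr[0] / rec_dur

    rec_bytes = sum(spr) * bps
    expected = header_len + n_rec * rec_bytes
    if len(blob) < expected:
        raise RecordingParseError(
            f"data truncated: expected {expected} bytes, got {len(blob)}", len(blob)
        )

    data = np.empty((n_ch, n_rec * spr[0]))
    for r in range(n_rec):
        off = header_len + r * rec_bytes
        for i in range(n_ch):
            raw = blob[off : off + spr[i] * bps]
            if bps == 2:
                dig = np.frombuffer(raw, dtype="<i2").astype(np.int64)
            else:
                b = np.frombuffer(raw, dtype=np.uint8).reshape(-1, 3).astype(np.int64)
                dig = b[:, 0] | (b[:, 1] << 8) | (b[:, 2] << 16)
                dig[dig >= 1 << 23] -= 1 << 24
            scale = (pmax[i] - pmin[i]) / (dmax[i] - dmin[i])
            data[i, r * spr[i] : (r + 1) * spr[i]] = (dig - dmin[i]) * scale + pmin[i]
            off += spr[i] * bps

    group = "UNKNOWN"
    n_true = data.shape[1]
    for tok in rec_field.split():
        if tok.startswith("grp="):
            group = tok[4:]
        elif tok.startswith("n="):
            n_true = min(int(tok[2:]), data.shape[1])
    data = data[:, :n_true]

    if tuple(labels) == CHANNELS_32:
        montage = standard_montage()
    else:
        # no layout metadata in the container: place channels on a circle
        ang = 2 * np.pi * np.arange(n_ch) / n_ch
        montage = montage_from_positions(labels, np.c_[np.cos(ang), np.sin(ang)])
    return Recording(
        subject_id=subject_id or Path(path).stem,
        group=group,
        fs=fs,
        samples=data,
        montage=montage,
    )


# ---------------------------------------------------------------------------
# public API


def write_recording(rec: Recording, path: str | Path) -> Path:
    """Write a recording; the container is chosen by the file suffix."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".npz":
        _write_npz(rec, path)
    elif suffix == ".edf":
        _write_edf(rec, path)
    else:
        raise ValueError(f"unsupported container {suffix!r}; use .npz or .edf")
    return path


def read_recording(path: str | Path) -> Recording:
    """Read a recording from an .npz, .edf or .bdf container."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".npz":
        return _read_npz(path)
    if suffix in (".edf", ".bdf"):
        return _read_edf_bdf(path)
    raise ValueError(f"unsupported container {suffix!r}; use .npz, .edf or .bdf")


def write_manifest(
    recordings: list[Recording], directory: str | Path, container: str = "npz"
) -> Path:
    """Write a cohort as one file per recording plus a manifest.csv."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = directory / "manifest.csv"
    with open(manifest, "w", newline="") as f:
        w = csv.writer(f)
        w.writerow(["subject_id", "group", "file"])
        for rec in recordings:
            fname = f"{rec.subject_id}.{container}"
            write_recording(rec, directory / fname)
            w.writerow([rec.subject_id, rec.group, fname])
    return manifest


def read_manifest(manifest: str | Path) -> list[Recording]:
    """Load a cohort from a manifest.csv written by :func:`write_manifest`."""
    manifest = Path(manifest)
    out = []
    with open(manifest, newline="") as f:
        for row in csv.DictReader(f):
            rec = read_recording(manifest.parent / row["file"])
            out.append(rec.copy_with(subject_id=row["subject_id"], group=row["group"]))
    return out
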