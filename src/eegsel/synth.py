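"""Synthetic eyes-closed resting-state EEG cohorts.

Each channel is generated as Gaussian 1/f^beta background noise plus an
amplitude-modulated 10 Hz alpha rhythm with a posterior-dominant scalp
gradient.  Group effects are planted as multiplicative band-power scalings
on named channels (applied in the frequency domain) and as a regularity
("complexity") shift implemented by mixing an AR(1) component into the
channel, which monotonically lowers Lempel-Ziv complexity.

The generator is a pure function of its seed: identical configurations
yield bitwise-identical cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .montage import Montage, standard_montage

__all__ = [
    "SynthesisError",
    "GroupEffectProfile",
    "CohortConfig",
    "Recording",
    "control_profile",
    "default_profiles",
    "generate_recording",
    "generate_cohort",
]

GROUPS = ("CONTROL", "PSF", "CTF")


class SynthesisError(ValueError):
    """Raised for invalid synthesis configurations."""


@dataclass(frozen=True)
class Recording:
    """One subject's multichannel signal in microvolts."""

    subject_id: str
    group: str
    fs: float
    samples: np.ndarray  # (n_channels, n_times), µV
    montage: Montage

    def __post_init__(self) -> None:
        if self.samples.ndim != 2:
            raise SynthesisError("samples must be 2-D (channels x time)")
        if self.samples.shape[0] != len(self.montage):
            raise SynthesisError(
                f"{self.samples.shape[0]} rows for {len(self.montage)}-channel montage"
            )
        if not np.all(np.isfinite(self.samples)):
            raise SynthesisError("samples contain non-finite values")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_times(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_times / self.fs

    def copy_with(self, **kw) -> "Recording":
        d = dict(
            subject_id=self.subject_id,
            group=self.group,
            fs=self.fs,
            samples=self.samples,
            montage=self.montage,
        )
        d.update(kw)
        return Recording(**d)


@dataclass(frozen=True)
class GroupEffectProfile:
    """Planted spectral and regularity effects for one group.

    band_power_multipliers maps (channel, (low_hz, high_hz)) to a positive
    power scale factor; complexity_shift maps channel to a signed factor in
    [-1, 1] (negative = more regular signal, hence lower LZ complexity).
    """

    group_id: str
    band_power_multipliers: dict[tuple[str, tuple[float, float]], float] = field(
        default_factory=dict
    )
    complexity_shift: dict[str, float] = field(default_factory=dict)
    alpha_amplitude: float = 10.0  # µV
    noise_exponent: float = 1.0  # beta of the 1/f^beta background
    noise_rms: float = 15.0  # µV

    def __post_init__(self) -> None:
        for (ch, band), m in self.band_power_multipliers.items():
            if m <= 0:
                raise SynthesisError(f"multiplier for {ch} {band} must be > 0")
            if band[0] >= band[1] or band[0] < 0:
                raise SynthesisError(f"invalid band {band}")
        for ch, s in self.complexity_shift.items():
            if not -1.0 <= s <= 1.0:
                raise SynthesisError(f"complexity shift for {ch} out of [-1, 1]")


def control_profile(**kw) -> GroupEffectProfile:
    """A neutral profile: no planted effects."""
    return GroupEffectProfile(group_id="CONTROL", **kw)


def default_profiles(effect_scale: float = 1.0) -> dict[str, GroupEffectProfile]:
    """The three study-group profiles.

    The schizotypy-like (PSF) group gets elevated high-gamma power at CP5
    and elevated delta at Fp1; the cyclothymia-like (CTF) group gets
    elevated 30-56 Hz power at CP5, a milder delta elevation at Fp1 and a
    regularity increase (lower Lempel-Ziv complexity) at FC5 and T7,
    mirroring where the group differences localise.  ``effect_scale``
    scales the planted log-multipliers and complexity shifts jointly
    (0 = null cohort, 1 = default strong effects).
    """

    def m(x: float) -> float:
        return float(np.exp(effect_scale * np.log(x)))

    psf = GroupEffectProfile(
        group_id="PSF",
        band_power_multipliers={
            ("CP5", (52.0, 64.0)): m(3.0),
            ("Fp1", (0.5, 4.0)): m(2.5),
        },
    )
    ctf = GroupEffectProfile(
        group_id="CTF",
        band_power_multipliers={
            ("CP5", (30.0, 56.0)): m(3.0),
            ("Fp1", (0.5, 4.0)): m(1.8),
        },
        complexity_shift={"FC5": -0.5 * effect_scale, "T7": -0.5 * effect_scale},
    )
    return {"CONTROL": control_profile(), "PSF": psf, "CTF": ctf}


@dataclass(frozen=True)
class CohortConfig:
    """Cohort layout.  Default group sizes follow the study cohort."""

    group_sizes: dict[str, int] = field(
        default_factory=lambda: {"CONTROL": 21, "PSF": 20, "CTF": 17}
    )
    duration_s: float = 60.0
    fs: float = 8192.0
    seed: int = 0
    profiles: dict[str, GroupEffectProfile] | None = None

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise SynthesisError("duration_s must be > 0")
        if self.fs <= 0:
            raise SynthesisError("fs must be > 0")
        if any(n < 0 for n in self.group_sizes.values()):
            raise SynthesisError("group sizes must be nonnegative")


def _pink_noise(rng: np.random.Generator, n: int, fs: float, beta: float) -> np.ndarray:
    """Gaussian noise with a 1/f^beta amplitude spectrum, unit RMS."""
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    spec = rng.standard_normal(len(freqs)) + 1j * rng.standard_normal(len(freqs))
    amp = np.ones_like(freqs)
    nz = freqs > 0
    amp[nz] = freqs[nz] ** (-beta / 2.0)
    amp[0] = 0.0  # no DC
    x = np.fft.irfft(spec * amp, n=n)
    return x / x.std()


def _alpha_envelope(rng: np.random.Generator, n: int, fs: float) -> np.ndarray:
    """Slow (~1 Hz) positive modulation envelope, mean approximately 1."""
    raw = _pink_noise(rng, n, fs, beta=0.0)
    # low-pass by FFT truncation at 1 Hz
    spec = np.fft.rfft(raw)
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    spec[freqs > 1.0] = 0.0
    slow = np.fft.irfft(spec, n=n)
    sd = slow.std()
    if sd > 0:
        slow = slow / sd
    return 1.0 + 0.5 * np.clip(slow, -1.8, 1.8)


def _ar1(rng: np.random.Generator, n: int, phi: float = 0.95) -> np.ndarray:
    """Unit-variance AR(1) series; strongly autocorrelated, hence regular."""
    from scipy.signal import lfilter

    eps = rng.standard_normal(n) * np.sqrt(1.0 - phi * phi)
    eps[0] = rng.standard_normal() * np.sqrt(1.0 - phi * phi)
    x = lfilter([1.0], [1.0, -phi], eps)
    return np.asarray(x)


def _apply_band_multiplier(
    x: np.ndarray, fs: float, band: tuple[float, float], mult: float
) -> np.ndarray:
    spec = np.fft.rfft(x)
    freqs = np.fft.rfftfreq(len(x), 1.0 / fs)
    sel = (freqs >= band[0]) & (freqs < band[1])
    spec[sel] *= np.sqrt(mult)
    return np.fft.irfft(spec, n=len(x))


def generate_recording(
    profile: GroupEffectProfile,
    duration_s: float,
    fs: float,
    montage: Montage | None = None,
    seed: int = 0,
    subject_id: str = "sub-000",
) -> Recording:
    """Generate one synthetic eyes-closed resting-state recording.

    Requires duration_s >= 2 s and fs >= 256 Hz so that gamma-band effects
    up to 64 Hz survive downstream resampling to 128 Hz.
    """
    if duration_s < 2:
        raise SynthesisError("duration_s must be >= 2 s")
    if fs < 256:
        raise SynthesisError("fs must be >= 256 Hz")
    montage = montage or standard_montage()
    names = montage.channel_names
    for ch, band in profile.band_power_multipliers:
        if ch not in names:
            raise SynthesisError(f"unknown channel in profile: {ch!r}")
        if band[1] > fs / 2:
            raise SynthesisError(
                f"band {band} exceeds Nyquist ({fs / 2} Hz) for fs={fs}"
            )
    for ch in profile.complexity_shift:
        if ch not in names:
            raise SynthesisError(f"unknown channel in profile: {ch!r}")

    n = int(round(duration_s * fs))
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    t = np.arange(n) / fs

    # posterior-dominant alpha gradient: stronger towards the back (-y)
    posterior = (1.0 - montage.positions[:, 1]) / 2.0  # in [0, 1]-ish
    alpha_gain = 0.4 + 0.6 * np.clip(posterior, 0.0, 1.0)
    phase = rng.uniform(0, 2 * np.pi)
    envelope = _alpha_envelope(rng, n, fs)
    alpha_src = envelope * np.sin(2 * np.pi * 10.0 * t + phase)

    data = np.empty((len(names), n))
    for i, ch in enumerate(names):
        bg = _pink_noise(rng, n, fs, profile.noise_exponent) * profile.noise_rms
        x = bg + profile.alpha_amplitude * alpha_gain[i] * alpha_src
        for (pch, band), mult in profile.band_power_multipliers.items():
            if pch == ch:
                x = _apply_band_multiplier(x, fs, band, mult)
        shift = profile.complexity_shift.get(ch, 0.0)
        if shift != 0.0:
            frac = abs(shift)
            if shift < 0:  # more regular: mix in a smooth AR(1) component
                comp = _ar1(rng, n) * x.std()
            else:  # more irregular: mix in white noise
                comp = rng.standard_normal(n) * x.std()
            x = (1.0 - frac) * x + frac * comp
        data[i] = x

    return Recording(
        subject_id=subject_id, group=profile.group_id, fs=fs, samples=data,
        montage=montage,
    )


def subject_seeds(config_seed: int, n: int) -> list[int]:
    """Reproducible per-subject seeds derived from the cohort seed."""
    ss = np.random.SeedSequence(config_seed)
    return [int(child.generate_state(1)[0] % (2**31)) for child in ss.spawn(n)]


def generate_cohort(config: CohortConfig, montage: Montage | None = None) -> list[Recording]:
    """Generate one Recording per subject, per-group effect profiles applied."""
    total = sum(config.group_sizes.values())
    if total == 0:
        raise SynthesisError("empty cohort: all group sizes are zero")
    montage = montage or standard_montage()
    profiles = config.profiles or default_profiles()
    for g in config.group_sizes:
        if g not in profiles:
            raise SynthesisError(f"no effect profile for group {g!r}")

    seeds = subject_seeds(config.seed, total)
    recordings: list[Recording] = []
    idx = 0
    for group, size in config.group_sizes.items():
        for j in range(size):
            rec = generate_recording(
                profiles[group],
                duration_s=config.duration_s,
                fs=config.fs,
                montage=montage,
                seed=seeds[idx],
                subject_id=f"sub-{idx:03d}",
            )
            # the cohort's group key wins over the profile's group_id
            recordings.append(rec.copy_with(group=group))
            idx += 1
    return recordings
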