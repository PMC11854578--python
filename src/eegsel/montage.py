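"""Scalp montage for the 32-channel BioSemi ActiveTwo layout.

The channel set is the standard 10-10 subset used for 32-electrode caps.
Positions are an azimuthal-equidistant projection of the 3-D electrode
coordinates onto the unit disc (vertex at the origin, nose towards +y),
which is the convention used for 2-D scalp maps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["CHANNELS_32", "Montage", "standard_montage", "MontageError"]


class MontageError(ValueError):
    """Raised for invalid montage construction or unknown channels."""


#: The 32 electrode labels, in acquisition order.
CHANNELS_32: tuple[str, ...] = (
    "Fp1", "AF3", "F7", "F3", "FC1", "FC5", "T7", "C3",
    "CP1", "CP5", "P7", "P3", "Pz", "PO3", "O1", "Oz",
    "O2", "PO4", "P4", "P8", "CP6", "CP2", "C4", "T8",
    "FC6", "FC2", "F4", "F8", "AF4", "Fp2", "Fz", "Cz",
)

# 2-D unit-disc projection of the standard 10-10 positions.
_POSITIONS_2D: dict[str, tuple[float, float]] = {
    "Fp1": (-0.2954, +0.8421),
    "AF3": (-0.2876, +0.6556),
    "F7": (-0.7914, +0.4784),
    "F3": (-0.3895, +0.4117),
    "FC1": (-0.2115, +0.1615),
    "FC5": (-0.6691, +0.1616),
    "T7": (-0.8928, -0.1699),
    "C3": (-0.4267, -0.0759),
    "CP1": (-0.1868, -0.2487),
    "CP5": (-0.5825, -0.3407),
    "P7": (-0.6060, -0.6145),
    "P3": (-0.3137, -0.4662),
    "Pz": (+0.0017, -0.4200),
    "PO3": (-0.2279, -0.6295),
    "O1": (-0.2047, -0.7826),
    "Oz": (+0.0007, -0.7813),
    "O2": (+0.2080, -0.7818),
    "PO4": (+0.2306, -0.6324),
    "P4": (+0.3253, -0.4590),
    "P8": (+0.6104, -0.6105),
    "CP6": (+0.5938, -0.3285),
    "CP2": (+0.2018, -0.2475),
    "C4": (+0.4374, -0.0710),
    "T8": (+0.8954, -0.1581),
    "FC6": (+0.6725, +0.1686),
    "FC2": (+0.2181, +0.1658),
    "F4": (+0.4008, +0.4199),
    "F8": (+0.7907, +0.4809),
    "AF4": (+0.2981, +0.6488),
    "Fp2": (+0.2962, +0.8419),
    "Fz": (+0.0021, +0.3906),
    "Cz": (+0.0022, -0.0493),
}


@dataclass(frozen=True)
class Montage:
    """Electrode layout: names, flat scalp positions, neighbour weights.

    Parameters
    ----------
    channel_names
        Ordered, unique electrode labels.
    positions
        (n_channels, 2) array of unit-disc coordinates.
    neighbors
        Per channel, a mapping neighbour-label -> weight.  Weights are
        positive and sum to one per channel; used for bad-channel
        interpolation.
    """

    channel_names: tuple[str, ...]
    positions: np.ndarray
    neighbors: dict[str, dict[str, float]] = field(repr=False)

    def __post_init__(self) -> None:
        names = self.channel_names
        if len(set(names)) != len(names):
            raise MontageError("channel names must be unique")
        if self.positions.shape != (len(names), 2):
            raise MontageError(
                f"positions must be ({len(names)}, 2), got {self.positions.shape}"
            )
        for ch in names:
            nb = self.neighbors.get(ch, {})
            if not nb:
                raise MontageError(f"channel {ch!r} has no neighbors")
            w = sum(nb.values())
            if not np.isclose(w, 1.0):
                raise MontageError(f"neighbor weights of {ch!r} sum to {w}, not 1")
            if any(v <= 0 for v in nb.values()):
                raise MontageError(f"non-positive neighbor weight at {ch!r}")

    def __len__(self) -> int:
        return len(self.channel_names)

    def index(self, channel: str) -> int:
        try:
            return self.channel_names.index(channel)
        except ValueError:
            raise MontageError(f"unknown channel {channel!r}") from None

    def position(self, channel: str) -> np.ndarray:
        return self.positions[self.index(channel)]


def _inverse_distance_neighbors(
    names: tuple[str, ...], positions: np.ndarray, k: int
) -> dict[str, dict[str, float]]:
    """k nearest neighbours per channel, weights proportional to 1/distance."""
    d = np.linalg.norm(positions[:, None, :] - positions[None, :, :], axis=-1)
    np.fill_diagonal(d, np.inf)
    k = min(k, len(names) - 1)
    out: dict[str, dict[str, float]] = {}
    for i, ch in enumerate(names):
        idx = np.argsort(d[i])[:k]
        w = 1.0 / d[i, idx]
        w = w / w.sum()
        out[ch] = {names[j]: float(wj) for j, wj in zip(idx, w)}
    return out


def standard_montage(k_neighbors: int = 4) -> Montage:
    """The 32-channel BioSemi montage with inverse-distance neighbour weights."""
    pos = np.array([_POSITIONS_2D[ch] for ch in CHANNELS_32])
    nb = _inverse_distance_neighbors(CHANNELS_32, pos, k_neighbors)
    return Montage(channel_names=CHANNELS_32, positions=pos, neighbors=nb)


def montage_from_positions(
    names: "tuple[str, ...] | list[str]",
    positions: np.ndarray,
    k_neighbors: int = 4,
) -> Montage:
    """Build a montage for an arbitrary channel set from 2-D positions."""
    names = tuple(names)
    positions = np.asarray(positions, dtype=float)
    nb = _inverse_distance_neighbors(names, positions, k_neighbors)
    return Montage(channel_names=names, positions=positions, neighbors=nb)
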