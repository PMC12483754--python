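"""Electrode montages of the extended 10-20 system.

A :class:`Montage` fixes the channel axis of every matrix in the pipeline:
signals, relevance maps and rankings all use its ordering.  Positions are
unitless 2-D head-plane coordinates used only for topographic export.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

#: 62-channel eyes-closed resting-state cap (extended 10-20, mastoid
#: references excluded), the standard clinical layout this package targets.
CHANNELS_62 = (
    "Fp1 Fpz Fp2 AF7 AF3 AF4 AF8 F7 F5 F3 F1 Fz F2 F4 F6 F8 "
    "FT7 FC5 FC3 FC1 FCz FC2 FC4 FC6 FT8 T7 C5 C3 C1 Cz C2 C4 C6 T8 "
    "TP7 CP5 CP3 CP1 CPz CP2 CP4 CP6 TP8 P7 P5 P3 P1 Pz P2 P4 P6 P8 "
    "PO7 PO5 PO3 POz PO4 PO6 PO8 O1 Oz O2"
).split()


@dataclass(frozen=True)
class Montage:
    """Ordered set of named electrodes with 2-D head-plane positions."""

    channel_names: tuple[str, ...]
    positions: np.ndarray  # (n_channels, 2), unitless head plane

    def __post_init__(self) -> None:
        names = tuple(self.channel_names)
        object.__setattr__(self, "channel_names", names)
        pos = np.asarray(self.positions, dtype=float)
        if len(names) < 1:
            raise ValueError("montage needs at least one channel")
        if len(set(names)) != len(names):
            raise ValueError("montage channel names must be unique")
        if pos.shape != (len(names), 2):
            raise ValueError(
                f"positions shape {pos.shape} != ({len(names)}, 2)"
            )
        if not np.all(np.isfinite(pos)):
            raise ValueError("montage positions must be finite")
        object.__setattr__(self, "positions", pos)

    def __len__(self) -> int:
        return len(self.channel_names)

    def index(self, name: str) -> int:
        try:
            return self.channel_names.index(name)
        except ValueError:
            raise KeyError(f"channel {name!r} not in montage") from None

    def indices(self, names) -> np.ndarray:
        return np.array([self.index(n) for n in names], dtype=int)

    def subset(self, names) -> "Montage":
        """Sub-montage restricted to ``names`` in the given order."""
        idx = self.indices(names)
        return Montage(tuple(names), self.positions[idx])

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {
                "name": self.channel_names,
                "x": self.positions[:, 0],
                "y": self.positions[:, 1],
            }
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "Montage":
        df = pd.read_csv(path)
        missing = {"name", "x", "y"} - set(df.columns)
        if missing:
            raise ValueError(f"montage CSV missing columns {sorted(missing)}")
        return cls(tuple(df["name"].astype(str)), df[["x", "y"]].to_numpy())


def _standard_positions(names) -> np.ndarray:
    """Head-plane (x, y) for 10-20-family labels via MNE's standard layout."""
    import warnings

    import mne

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        std = mne.channels.make_standard_montage("standard_1005")
    pos3d = std.get_positions()["ch_pos"]
    out = np.empty((len(names), 2))
    for i, name in enumerate(names):
        if name not in pos3d:
            raise KeyError(f"no standard 10-20 position for channel {name!r}")
        x, y, _ = pos3d[name]
        out[i] = (x, y)
    return out


_CACHE: dict[tuple[str, ...], Montage] = {}


def standard_montage(names=CHANNELS_62) -> Montage:
    """Montage for extended 10-20 labels (default: the 62-channel cap)."""
    key = tuple(names)
    if key not in _CACHE:
        _CACHE[key] = Montage(key, _standard_positions(key))
    return _CACHE[key]
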