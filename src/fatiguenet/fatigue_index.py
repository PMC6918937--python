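"""Band powers and the (theta + alpha1 + alpha2) / beta mental-fatigue ratio.

Mental fatigue shifts EEG power from fast (beta) towards slow (theta,
alpha) rhythms, so the slow/fast power ratio rises as fatigue builds.
Delta is excluded from the index: it marks sleep, overlaps with artifacts,
and is not expected to show task-related activity.

Power is the time-domain mean of squared samples of the band-filtered
signal; for the brick-wall FFT filtering used upstream this equals the
integral of the PSD over the band (Parseval).  The ratio is computed per
epoch and channel, then averaged over epochs and the nine centrally
distributed channels (F3, C3, P3, F4, C4, P4, Fz, Cz, Pz) -- an ordering
that is robust to single-epoch outliers.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .design import MIDLINE_9
from .preprocess import BandDecomposition

__all__ = ["BandPowerTable", "band_power", "fatigue_ratio", "RATIO_NUMERATOR", "RATIO_DENOMINATOR"]

RATIO_NUMERATOR = ("theta", "alpha1", "alpha2")
RATIO_DENOMINATOR = "beta"


@dataclass(frozen=True)
class BandPowerTable:
    """Per-(epoch, channel, rhythm) signal power in signal-units squared."""

    power: np.ndarray  # shape (n_epochs, n_channels, n_rhythms)
    channels: tuple[str, ...]
    rhythms: tuple[str, ...]

    def __post_init__(self) -> None:
        p = np.asarray(self.power, dtype=float)
        if p.ndim != 3:
            raise ValueError("power must have shape (n_epochs, n_channels, n_rhythms)")
        if p.shape[1] != len(self.channels) or p.shape[2] != len(self.rhythms):
            raise ValueError("power shape inconsistent with labels")
        if not np.all(np.isfinite(p)):
            raise ValueError("powers must be finite")
        if (p < 0).any():
            raise ValueError("powers must be non-negative")
        object.__setattr__(self, "power", p)
        object.__setattr__(self, "channels", tuple(self.channels))
        object.__setattr__(self, "rhythms", tuple(self.rhythms))

    def get(self, rhythm: str) -> np.ndarray:
        """Power array (n_epochs, n_channels) for one rhythm."""
        try:
            k = self.rhythms.index(rhythm)
        except ValueError:
            raise KeyError(f"rhythm {rhythm!r} missing from table") from None
        return self.power[:, :, k]

    def to_frame(self) -> pd.DataFrame:
        """Long-format table (epoch, channel, rhythm, power)."""
        ep, ch, rh = np.meshgrid(
            np.arange(self.power.shape[0]),
            np.arange(len(self.channels)),
            np.arange(len(self.rhythms)),
            indexing="ij",
        )
        return pd.DataFrame(
            {
                "epoch": ep.ravel(),
                "channel": np.asarray(self.channels)[ch.ravel()],
                "rhythm": np.asarray(self.rhythms)[rh.ravel()],
                "power": self.power.ravel(),
            }
        )


def band_power(decomp: BandDecomposition) -> BandPowerTable:
    """Mean of squared samples per (epoch, channel) for every rhythm present."""
    rhythms = decomp.band_names
    power = np.stack(
        [np.mean(decomp[name].data ** 2, axis=1) for name in rhythms], axis=-1
    )
    return BandPowerTable(
        power=power, channels=decomp.source.channels, rhythms=rhythms
    )


def fatigue_ratio(
    table: BandPowerTable, channels: Sequence[str] = MIDLINE_9
) -> float:
    """(P_theta + P_alpha1 + P_alpha2) / P_beta averaged over epochs and channels.

    The ratio is formed per epoch-channel first and then averaged.

    Raises
    ------
    KeyError
        If a required rhythm or a named channel is missing.
    ValueError
        If any selected beta power is zero (the ratio is undefined).
    """
    for rhythm in (*RATIO_NUMERATOR, RATIO_DENOMINATOR):
        if rhythm not in table.rhythms:
            raise KeyError(f"rhythm {rhythm!r} missing from table")
    idx = []
    for ch in channels:
        try:
            idx.append(table.channels.index(ch))
        except ValueError:
            raise KeyError(f"channel {ch!r} missing from table") from None
    num = sum(table.get(r)[:, idx] for r in RATIO_NUMERATOR)
    den = table.get(RATIO_DENOMINATOR)[:, idx]
    if (den <= 0).any():
        raise ValueError("zero beta power: fatigue ratio undefined")
    return float(np.mean(num / den))
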