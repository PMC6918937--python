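"""Resampling, epoching, and FFT band decomposition into the EEG rhythms.

The five canonical rhythms are delta 2-4, theta 4-8, alpha1 8-10,
alpha2 10-13 and beta 13-30 Hz.  Band extraction is a brick-wall filter in
the discrete Fourier domain: every frequency bin with |f| outside the band
is zeroed and the epoch is inverse-transformed.  Band edges are half-open
``[lo, hi)`` so adjacent rhythms never share a bin (4 Hz belongs to theta,
not delta).  Filtering is applied per epoch; the edge ringing this implies
for 5-s windows is accepted and documented.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Sequence

import numpy as np
from scipy.signal import resample_poly

from .design import EpochSet

__all__ = [
    "BandDefinition",
    "DEFAULT_BANDS",
    "BandDecomposition",
    "resample",
    "band_filter",
    "decompose",
]


@dataclass(frozen=True)
class BandDefinition:
    """One EEG rhythm: a named frequency band ``[lo, hi)`` in Hz."""

    name: str
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not (0 < self.lo < self.hi):
            raise ValueError(f"band {self.name}: need 0 < lo < hi, got [{self.lo}, {self.hi})")

    def validate_for(self, fs: float) -> None:
        if self.hi > fs / 2:
            raise ValueError(
                f"band {self.name} [{self.lo}, {self.hi}) exceeds the Nyquist "
                f"frequency {fs / 2} Hz"
            )


DEFAULT_BANDS: tuple[BandDefinition, ...] = (
    BandDefinition("delta", 2.0, 4.0),
    BandDefinition("theta", 4.0, 8.0),
    BandDefinition("alpha1", 8.0, 10.0),
    BandDefinition("alpha2", 10.0, 13.0),
    BandDefinition("beta", 13.0, 30.0),
)


@dataclass
class BandDecomposition:
    """Per-rhythm band-filtered copies of one :class:`EpochSet`."""

    source: EpochSet
    bands: dict[str, EpochSet]

    def __post_init__(self) -> None:
        for name, es in self.bands.items():
            if es.data.shape != self.source.data.shape:
                raise ValueError(f"band {name} shape differs from source")

    def __getitem__(self, name: str) -> EpochSet:
        try:
            return self.bands[name]
        except KeyError:
            raise KeyError(f"rhythm {name!r} not in decomposition") from None

    def __contains__(self, name: str) -> bool:
        return name in self.bands

    @property
    def band_names(self) -> tuple[str, ...]:
        return tuple(self.bands)


def resample(epochs: EpochSet, target_fs: float) -> EpochSet:
    """Polyphase rational resampling with anti-alias filtering.

    The 1000 -> 256 Hz case reduces to an exact 32/125 rational factor.
    Output epochs have ``round(n_samples * target_fs / fs)`` samples.

    Raises
    ------
    ValueError
        If ``target_fs`` exceeds the source rate (upsampling is out of scope).
    """
    if target_fs > epochs.fs:
        raise ValueError(
            f"target_fs {target_fs} Hz exceeds source rate {epochs.fs} Hz"
        )
    if target_fs == epochs.fs:
        return epochs.with_data(epochs.data.copy())
    ratio = Fraction(target_fs / epochs.fs).limit_denominator(10**6)
    up, down = ratio.numerator, ratio.denominator
    out = resample_poly(epochs.data, up, down, axis=1)
    n_target = round(epochs.n_samples * target_fs / epochs.fs)
    out = out[:, :n_target, :]
    res = EpochSet(out, fs=target_fs, channels=epochs.channels, meta=dict(epochs.meta))
    return res


def band_filter(epochs: EpochSet, band: BandDefinition) -> EpochSet:
    """Brick-wall FFT filter: keep DFT bins with ``lo <= f < hi``, zero the rest.

    Linear, zero-phase, applied independently to every epoch and channel.
    """
    band.validate_for(epochs.fs)
    freqs = np.fft.rfftfreq(epochs.n_samples, d=1.0 / epochs.fs)
    keep = (freqs >= band.lo) & (freqs < band.hi)
    spec = np.fft.rfft(epochs.data, axis=1)
    spec[:, ~keep, :] = 0.0
    out = np.fft.irfft(spec, n=epochs.n_samples, axis=1)
    return epochs.with_data(out, band=band.name)


def decompose(
    epochs: EpochSet, bands: Sequence[BandDefinition] = DEFAULT_BANDS
) -> BandDecomposition:
    """Apply :func:`band_filter` per rhythm, preserving the given band order."""
    bands = tuple(bands)
    if not bands:
        raise ValueError("band list must not be empty")
    names = [b.name for b in bands]
    if len(set(names)) != len(names):
        raise ValueError("band names must be unique")
    return BandDecomposition(
        source=epochs, bands={b.name: band_filter(epochs, b) for b in bands}
    )
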