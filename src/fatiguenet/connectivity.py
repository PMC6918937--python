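"""Histogram mutual-information connectivity between EEG channels.

The dependence between two channels is estimated with the classic
equal-width-histogram plug-in estimator of mutual information,

    MI = sum_xy p(x, y) ln[ p(x, y) / (p(x) p(y)) ]   (nats),

optionally with the Miller-Madow bias correction, which subtracts
``(K_xy - K_x - K_y + 1) / (2 N)`` where the K are occupied cell/bin
counts.  Negative corrected estimates clamp to zero (MI is non-negative).

The default number of bins per axis is ``ceil(sqrt(N / 5))`` -- 16 bins at
the pipeline's epoch length N = 1280 -- with bins spanning each vector's
observed min-max range.

All unordered channel pairs of an epoch set yield a symmetric 19 x 19
weighted adjacency matrix (zero diagonal); per-pair estimates are averaged
across the set's epochs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from math import ceil, sqrt
from typing import Optional

import numpy as np
import pandas as pd

from .design import EpochSet

__all__ = [
    "MIEstimatorConfig",
    "WeightedAdjacency",
    "mutual_information",
    "adjacency_from_epochs",
    "mean_mi",
    "write_adjacency_csv",
    "read_adjacency_csv",
]


@dataclass(frozen=True)
class MIEstimatorConfig:
    """Histogram-MI settings: bins per axis (``None`` = ``ceil(sqrt(N/5))``)
    and whether the Miller-Madow bias correction is applied."""

    n_bins: Optional[int] = None
    bias_correction: bool = True

    def __post_init__(self) -> None:
        if self.n_bins is not None and self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")

    def bins_for(self, n_samples: int) -> int:
        if self.n_bins is not None:
            return self.n_bins
        return max(2, ceil(sqrt(n_samples / 5.0)))


@dataclass(frozen=True)
class WeightedAdjacency:
    """Symmetric channel x channel MI matrix in nats, zero diagonal."""

    values: np.ndarray
    channels: tuple[str, ...]
    rhythm: Optional[str] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("adjacency must be square")
        if v.shape[0] != len(self.channels):
            raise ValueError("channel label count must match matrix size")
        if not np.all(np.isfinite(v)):
            raise ValueError("adjacency contains non-finite values")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("adjacency must be symmetric")
        if (v < 0).any():
            raise ValueError("MI weights must be non-negative")
        if np.abs(np.diagonal(v)).max(initial=0.0) > 0:
            raise ValueError("diagonal must be zero")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "channels", tuple(self.channels))


def _bin_indices(x: np.ndarray, n_bins: int) -> Optional[np.ndarray]:
    """Equal-width bin index per sample; ``None`` for constant input."""
    lo, hi = x.min(), x.max()
    if hi == lo:
        return None
    idx = ((x - lo) * (n_bins / (hi - lo))).astype(np.int64)
    return np.minimum(idx, n_bins - 1)


def _mi_from_joint(joint: np.ndarray, n: int, bias_correction: bool) -> float:
    # marginals are summed as integer counts, so they are exact and the
    # result does not depend on the orientation of the joint table
    pxy = joint / n
    px = (joint.sum(axis=1, keepdims=True)) / n
    py = (joint.sum(axis=0, keepdims=True)) / n
    mask = pxy > 0
    terms = pxy[mask] * np.log(pxy[mask] / (px @ py)[mask])
    # summing in sorted order makes the result exactly invariant under
    # transposition of the joint table, i.e. MI(x, y) == MI(y, x) bit-for-bit
    mi = float(np.sort(terms).sum())
    if bias_correction:
        k_xy = int(mask.sum())
        k_x = int((px > 0).sum())
        k_y = int((py > 0).sum())
        mi -= (k_xy - k_x - k_y + 1) / (2.0 * n)
    return max(mi, 0.0)


def mutual_information(
    x: np.ndarray, y: np.ndarray, cfg: MIEstimatorConfig = MIEstimatorConfig()
) -> float:
    """Histogram mutual information between two sample vectors, in nats.

    Symmetric in its arguments.  Constant (zero-range) input has no
    information content; it yields 0 with a warning.

    Raises
    ------
    ValueError
        On length mismatch, non-finite values, or fewer than ``4 * n_bins``
        samples (too few for a meaningful 2-D histogram).
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    n = x.size
    n_bins = cfg.bins_for(n)
    if n < 4 * n_bins:
        raise ValueError(f"need at least {4 * n_bins} samples for {n_bins} bins")
    ix = _bin_indices(x, n_bins)
    iy = _bin_indices(y, n_bins)
    if ix is None or iy is None:
        warnings.warn("constant input: MI defined as 0", stacklevel=2)
        return 0.0
    joint = np.bincount(ix * n_bins + iy, minlength=n_bins * n_bins)
    joint = joint.reshape(n_bins, n_bins)
    return _mi_from_joint(joint, n, cfg.bias_correction)


def adjacency_from_epochs(
    band_epochs: EpochSet, cfg: MIEstimatorConfig = MIEstimatorConfig()
) -> WeightedAdjacency:
    """MI between all unordered channel pairs, averaged across epochs.

    Each epoch contributes one estimate per pair computed over that epoch's
    samples; the matrix entry is the mean over epochs (one adjacency per
    cell of the design, the convention used throughout the pipeline).
    """
    if band_epochs.n_epochs < 1:
        raise ValueError("need at least one epoch")
    n_ch = band_epochs.n_channels
    n = band_epochs.n_samples
    n_bins = cfg.bins_for(n)
    if n < 4 * n_bins:
        raise ValueError(f"need at least {4 * n_bins} samples for {n_bins} bins")
    acc = np.zeros((n_ch, n_ch))
    warned_constant = False
    for ep in range(band_epochs.n_epochs):
        sig = band_epochs.data[ep]
        binned = []
        for ch in range(n_ch):
            b = _bin_indices(sig[:, ch], n_bins)
            if b is None and not warned_constant:
                warnings.warn("constant channel: MI defined as 0", stacklevel=2)
                warned_constant = True
            binned.append(b)
        for i in range(n_ch):
            if binned[i] is None:
                continue
            base = binned[i] * n_bins
            for j in range(i + 1, n_ch):
                if binned[j] is None:
                    continue
                joint = np.bincount(base + binned[j], minlength=n_bins * n_bins)
                mi = _mi_from_joint(joint.reshape(n_bins, n_bins), n, cfg.bias_correction)
                acc[i, j] += mi
    acc /= band_epochs.n_epochs
    values = acc + acc.T
    return WeightedAdjacency(
        values=values,
        channels=band_epochs.channels,
        rhythm=band_epochs.meta.get("band"),
        meta=dict(band_epochs.meta),
    )


def mean_mi(adj: WeightedAdjacency) -> float:
    """Mean of the strictly-upper-triangle entries (the 171 pairs for n=19)."""
    n = len(adj.channels)
    if n < 2:
        raise ValueError("need at least two channels")
    iu, ju = np.triu_indices(n, k=1)
    return float(adj.values[iu, ju].mean())


def write_adjacency_csv(adj: WeightedAdjacency, path) -> None:
    """Square CSV with electrode labels as header row and index column."""
    pd.DataFrame(adj.values, index=adj.channels, columns=adj.channels).to_csv(path)


def read_adjacency_csv(path, rhythm: Optional[str] = None) -> WeightedAdjacency:
    df = pd.read_csv(path, index_col=0)
    if list(df.index) != list(df.columns):
        raise ValueError("adjacency CSV must have identical row and column labels")
    return WeightedAdjacency(
        values=df.to_numpy(dtype=float), channels=tuple(df.columns), rhythm=rhythm
    )
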