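"""Reading and writing recordings and epochs.

Epochs travel as plain CSV matrices (samples x channels, header row of
electrode labels), one file per epoch, named
``sub{SS}_{time}_{cond}_ep{EE}.csv`` so a directory of files reconstructs
the full design.  Continuous recordings can be read from the same CSV
layout or from EDF (through MNE) and cut into fixed-length non-overlapping
epochs.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Iterator, Optional

import numpy as np
import pandas as pd

from .design import EpochSet

__all__ = [
    "write_epoch_set_csv",
    "read_epoch_set_csv",
    "iter_epoch_cells",
    "read_raw_csv",
    "read_raw_edf",
    "epoch_continuous",
    "cell_stem",
]

_EPOCH_RE = re.compile(r"^sub(\d+)_([^_]+)_([^_]+)_ep(\d+)\.csv$")


def cell_stem(subject: int, time_point: str, condition: str) -> str:
    return f"sub{subject:02d}_{time_point}_{condition}"


def write_epoch_set_csv(epochs: EpochSet, out_dir) -> list[Path]:
    """One ``samples x channels`` CSV per epoch; returns the written paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    meta = epochs.meta
    stem = cell_stem(
        int(meta.get("subject", 0)),
        str(meta.get("time_point", "T0")),
        str(meta.get("condition", "C1")),
    )
    paths = []
    for ep in range(epochs.n_epochs):
        path = out_dir / f"{stem}_ep{ep:02d}.csv"
        pd.DataFrame(epochs.data[ep], columns=list(epochs.channels)).to_csv(
            path, index=False, float_format="%.6f"
        )
        paths.append(path)
    return paths


def read_epoch_set_csv(
    paths, fs: float, meta: Optional[dict] = None
) -> EpochSet:
    """Stack epoch CSVs (consistent headers required) into one EpochSet."""
    frames = [pd.read_csv(p) for p in paths]
    channels = tuple(frames[0].columns)
    for p, f in zip(paths, frames):
        if tuple(f.columns) != channels:
            raise ValueError(f"channel header mismatch in {p}")
    data = np.stack([f.to_numpy(dtype=float) for f in frames])
    return EpochSet(data, fs=fs, channels=channels, meta=dict(meta or {}))


def iter_epoch_cells(epoch_dir, fs: float) -> Iterator[tuple[int, str, str, EpochSet]]:
    """Group epoch CSVs of a directory by (subject, time point, condition)."""
    epoch_dir = Path(epoch_dir)
    cells: dict[tuple[int, str, str], list[Path]] = {}
    for path in sorted(epoch_dir.glob("*.csv")):
        m = _EPOCH_RE.match(path.name)
        if not m:
            continue
        key = (int(m.group(1)), m.group(2), m.group(3))
        cells.setdefault(key, []).append(path)
    if not cells:
        raise FileNotFoundError(f"no epoch CSVs found in {epoch_dir}")
    for (subject, tp, cond), paths in sorted(cells.items()):
        meta = {"subject": subject, "time_point": tp, "condition": cond}
        yield subject, tp, cond, read_epoch_set_csv(sorted(paths), fs=fs, meta=meta)


def read_raw_csv(path) -> tuple[np.ndarray, tuple[str, ...]]:
    """Continuous recording from CSV (samples x channels with header)."""
    df = pd.read_csv(path)
    return df.to_numpy(dtype=float), tuple(df.columns)


def read_raw_edf(path) -> tuple[np.ndarray, tuple[str, ...], float]:
    """Continuous recording from an EDF file, via MNE.

    Returns ``(data samples x channels, channel labels, sampling rate)``.
    """
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    return raw.get_data().T, tuple(raw.ch_names), float(raw.info["sfreq"])


def epoch_continuous(
    data: np.ndarray,
    fs: float,
    epoch_seconds: float,
    channels,
    meta: Optional[dict] = None,
) -> EpochSet:
    """Cut a continuous (samples x channels) record into fixed windows.

    Windows do not overlap; a trailing remainder shorter than one epoch is
    dropped.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 2:
        raise ValueError("continuous data must be 2-D (samples x channels)")
    n_per = round(fs * epoch_seconds)
    if n_per < 1 or data.shape[0] < n_per:
        raise ValueError("recording shorter than one epoch")
    n_ep = data.shape[0] // n_per
    trimmed = data[: n_ep * n_per].reshape(n_ep, n_per, data.shape[1])
    return EpochSet(trimmed, fs=fs, channels=tuple(channels), meta=dict(meta or {}))
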