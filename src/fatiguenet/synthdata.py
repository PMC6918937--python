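"""Synthetic multichannel EEG with controlled band power and coupling.

Every channel is a sum over the five rhythms of band-limited Gaussian noise
(white noise band-pass filtered with a zero-phase 4th-order Butterworth).
Two ground-truth controls are layered on top:

* **Spectral state** -- the theta/alpha1/alpha2 amplitudes are multiplied by
  the trajectory's ``slow_fast_gain`` for the cell's time point, so the
  (theta+alpha1+alpha2)/beta power ratio is known by construction.

* **alpha1 coupling** -- each alpha1 channel is a variance-preserving convex
  mixture ``y_ch = sqrt(1 - c_ch) * x_ch + sqrt(c_ch) * s`` with a single
  shared alpha1-band source ``s``.  The mixture weight is channel-wise
  heterogeneous, ``c_ch = c * u_ch`` with fixed per-subject factors
  ``u_ch ~ U(1-h, 1+h)``: fatigue-related alpha1 synchronisation is
  topographically uneven, and it is this unevenness that progressively
  randomises the rank order of pair weights as the global coupling ``c``
  rises, degrading the small-world organisation the way the real data do.

* **Stationary background** -- within every rhythm the per-channel noises
  ``x_ch`` are not independent but carry a fixed distance-decaying
  correlation ``rho0(d) = rho_max * exp(-(d / scale)^2)`` over schematic
  10-20 head coordinates (nearby electrodes see partly shared cortical
  activity).  This baseline organisation is what makes the thresholded
  graphs clustered ("small-world") before any fatigue effect is added.
  Setting ``spatial_rho_max = 0`` recovers fully independent channels.

Seed policy: a master seed spawns one independent child stream per
(subject, time point, condition) cell and one per subject (for the coupling
weights) through :class:`numpy.random.SeedSequence` spawn keys, so cells
are reproducible individually and mutually independent.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from scipy.signal import butter, sosfiltfilt

from .design import ELECTRODE_XY, EpochSet, ExperimentDesign, FatigueTrajectory
from .network import BinaryGraph
from .preprocess import DEFAULT_BANDS

__all__ = [
    "generate_epoch_set",
    "generate_dataset",
    "generate_ws_graph",
    "spatial_correlation",
    "subject_coupling_factors",
]

# Spawn-key stream tags: keep cell streams and subject streams disjoint.
_CELL_STREAM = 0
_SUBJECT_STREAM = 1

_BAND_RANGES = {b.name: (b.lo, b.hi) for b in DEFAULT_BANDS}
#: Rhythms whose amplitude is scaled by the trajectory's slow/fast gain.
_SLOW_RHYTHMS = ("theta", "alpha1", "alpha2")


def _cell_rng(seed: int, subject: int, t_idx: int, c_idx: int) -> np.random.Generator:
    ss = np.random.SeedSequence(seed, spawn_key=(_CELL_STREAM, subject, t_idx, c_idx))
    return np.random.default_rng(ss)


def _subject_rng(seed: int, subject: int) -> np.random.Generator:
    ss = np.random.SeedSequence(seed, spawn_key=(_SUBJECT_STREAM, subject))
    return np.random.default_rng(ss)


@lru_cache(maxsize=32)
def _band_sos(fs: float, lo: float, hi: float):
    nyq = fs / 2.0
    return butter(4, [lo / nyq, hi / nyq], btype="band", output="sos")


def _band_noise(
    rng: np.random.Generator, n_samples: int, n_cols: int, fs: float, lo: float, hi: float
) -> np.ndarray:
    """Unit-RMS band-limited Gaussian noise, one column per signal."""
    white = rng.standard_normal((n_samples, n_cols))
    x = sosfiltfilt(_band_sos(fs, lo, hi), white, axis=0)
    rms = np.sqrt(np.mean(x**2, axis=0))
    return x / rms


def spatial_correlation(
    channels: tuple[str, ...], rho_max: float, scale: float
) -> np.ndarray:
    """Baseline inter-channel correlation matrix from electrode geometry.

    Gaussian (RBF) decay of correlation with scalp distance; unit diagonal.
    Positive definite for ``rho_max < 1`` since the RBF kernel is positive
    definite and the diagonal is lifted by ``1 - rho_max``.
    """
    missing = [ch for ch in channels if ch not in ELECTRODE_XY]
    if missing and rho_max > 0:
        raise KeyError(f"no schematic coordinates for channels {missing}")
    n = len(channels)
    if rho_max == 0:
        return np.eye(n)
    xy = np.array([ELECTRODE_XY[ch] for ch in channels])
    d = np.linalg.norm(xy[:, None, :] - xy[None, :, :], axis=-1)
    corr = rho_max * np.exp(-((d / scale) ** 2))
    np.fill_diagonal(corr, 1.0)
    return corr


def subject_coupling_factors(
    trajectory: FatigueTrajectory, n_channels: int, subject: int, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Per-subject coupling topography: weight factors and disorder loadings.

    Returns ``(u, W)`` where ``u`` (n_channels,) are the per-channel
    coupling weight factors ``u_ch ~ U(1-h, 1+h)`` and ``W``
    (n_channels, disorder_rank) are unit-norm rows of random loadings onto
    the extra shared sources.  Drawn once per subject from the subject's
    own seed stream, hence constant across time points, conditions and
    epochs.
    """
    h = trajectory.coupling_heterogeneity
    rng = _subject_rng(seed, subject)
    u = rng.uniform(1.0 - h, 1.0 + h, size=n_channels)
    w = rng.standard_normal((n_channels, trajectory.disorder_rank))
    w /= np.linalg.norm(w, axis=1, keepdims=True)
    return u, w


def generate_epoch_set(
    design: ExperimentDesign,
    trajectory: FatigueTrajectory,
    subject: int,
    time_point: str,
    condition: str,
    seed: int,
) -> EpochSet:
    """Generate the epochs of one (subject, time point, condition) cell.

    Deterministic given ``(seed, subject, time_point, condition)``; the
    cell's child stream does not depend on the order in which cells are
    generated.

    Raises
    ------
    KeyError
        For a time point or condition label not present in the design.
    ValueError
        For a subject index outside ``0 .. n_subjects-1``.
    """
    if time_point not in design.time_points:
        raise KeyError(f"unknown time point {time_point!r}")
    if condition not in design.conditions:
        raise KeyError(f"unknown condition {condition!r}")
    if not (0 <= subject < design.n_subjects):
        raise ValueError(f"subject index {subject} outside the design")
    for name in trajectory.band_amplitude:
        if name not in _BAND_RANGES:
            raise KeyError(f"unknown rhythm {name!r} in band_amplitude")

    t_idx = design.time_points.index(time_point)
    c_idx = design.conditions.index(condition)
    rng = _cell_rng(seed, subject, t_idx, c_idx)

    n_ep, n_samp, n_ch = design.epochs_per_cell, design.n_samples, len(design.channels)
    gain = trajectory.gain_for(time_point)
    c_global = trajectory.coupling_for(
        time_point, task=(condition == design.task_condition)
    )
    u, w_dis = subject_coupling_factors(trajectory, n_ch, subject, seed)
    c_ch = np.clip(c_global * u, 0.0, 0.95)
    beta_dis = trajectory.coupling_disorder

    corr = spatial_correlation(
        design.channels, trajectory.spatial_rho_max, trajectory.spatial_scale
    )
    chol = np.linalg.cholesky(corr)

    data = np.zeros((n_ep, n_samp, n_ch))
    for ep in range(n_ep):
        for name, amp in trajectory.band_amplitude.items():
            lo, hi = _BAND_RANGES[name]
            noise = _band_noise(rng, n_samp, n_ch, design.fs, lo, hi)
            x = noise @ chol.T  # spatially structured background
            if name == "alpha1" and c_global > 0:
                shared = _band_noise(rng, n_samp, 1, design.fs, lo, hi)
                if beta_dis > 0:
                    extra = _band_noise(
                        rng, n_samp, trajectory.disorder_rank, design.fs, lo, hi
                    )
                    s_ch = (
                        np.sqrt(1.0 - beta_dis) * shared
                        + np.sqrt(beta_dis) * (extra @ w_dis.T)
                    )
                else:
                    s_ch = shared
                x = np.sqrt(1.0 - c_ch) * x + np.sqrt(c_ch) * s_ch
            scale = amp * (gain if name in _SLOW_RHYTHMS else 1.0)
            data[ep] += scale * x

    return EpochSet(
        data,
        fs=design.fs,
        channels=design.channels,
        meta={
            "subject": subject,
            "time_point": time_point,
            "condition": condition,
            "seed": seed,
        },
    )


def generate_dataset(
    design: ExperimentDesign, trajectory: FatigueTrajectory, seed: int
):
    """Yield ``(subject, time_point, condition, EpochSet)`` for every cell."""
    for subject in range(design.n_subjects):
        for tp in design.time_points:
            for cond in design.conditions:
                yield subject, tp, cond, generate_epoch_set(
                    design, trajectory, subject, tp, cond, seed
                )


def generate_ws_graph(
    n: int, k: int, p: float, seed: int, max_retries: int = 100
) -> BinaryGraph:
    """Watts-Strogatz ring-lattice rewiring graph, guaranteed connected.

    A test fixture for the small-world criterion: at ``p = 0`` the ring
    lattice has clustering 0.5 (for k = 4) and long paths; small ``p``
    introduces shortcuts that shrink path length while keeping clustering.
    Connectivity is enforced by retrying with an incremented seed.
    """
    import networkx as nx

    if k % 2 != 0:
        raise ValueError("k must be even")
    if not (n > k >= 2):
        raise ValueError("need n > k >= 2")
    if not (0.0 <= p <= 1.0):
        raise ValueError("rewiring probability must lie in [0, 1]")
    for attempt in range(max_retries):
        g = nx.watts_strogatz_graph(n, k, p, seed=seed + attempt)
        if nx.is_connected(g):
            labels = tuple(f"v{i}" for i in range(n))
            adj = nx.to_numpy_array(g, nodelist=range(n)) > 0
            return BinaryGraph(adj, labels)
    raise RuntimeError(
        f"no connected Watts-Strogatz graph found in {max_retries} attempts"
    )
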