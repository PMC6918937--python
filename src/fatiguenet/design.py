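"""Experiment layout, ground-truth fatigue trajectory, and the epoch container.

The study design mirrors a sustained mental-arithmetic fatigue experiment:
EEG is acquired at five time points (T0..T4) spread over the task, in two
conditions per time point (C1 = eyes-closed rest, C2 = mental-arithmetic
task), from a 19-electrode 10-20 montage referenced to the earlobes.  From
each acquisition, ten artifact-free 5-second epochs are retained at 256 Hz.

:class:`FatigueTrajectory` is the ground truth driving the synthetic
generator: per-time-point spectral gains (slow rhythms relative to beta)
and per-time-point alpha1 inter-channel coupling.  Default values live in
``data/default_trajectory.yaml`` so they can be edited without touching
code.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import yaml

__all__ = [
    "CHANNELS_1020",
    "MIDLINE_9",
    "ELECTRODE_XY",
    "ExperimentDesign",
    "FatigueTrajectory",
    "EpochSet",
]

#: The 19 scalp electrodes of the international 10-20 system, in montage order.
CHANNELS_1020 = (
    "Fp1", "Fp2", "F3", "F4", "C3", "C4", "P3", "P4", "O1", "O2",
    "F7", "F8", "T3", "T4", "T5", "T6", "Fz", "Cz", "Pz",
)

#: Nine centrally distributed channels used for the fatigue power ratio.
MIDLINE_9 = ("F3", "C3", "P3", "F4", "C4", "P4", "Fz", "Cz", "Pz")

#: Schematic 2-D head coordinates (x: left->right, y: back->front), head
#: radius 1.  Used only to give the synthetic background a realistic
#: distance-decaying correlation structure; not a forward model.
ELECTRODE_XY: Mapping[str, tuple[float, float]] = {
    "Fp1": (-0.31, 0.95), "Fp2": (0.31, 0.95),
    "F7": (-0.81, 0.59), "F3": (-0.40, 0.50), "Fz": (0.0, 0.50),
    "F4": (0.40, 0.50), "F8": (0.81, 0.59),
    "T3": (-1.0, 0.0), "C3": (-0.50, 0.0), "Cz": (0.0, 0.0),
    "C4": (0.50, 0.0), "T4": (1.0, 0.0),
    "T5": (-0.81, -0.59), "P3": (-0.40, -0.50), "Pz": (0.0, -0.50),
    "P4": (0.40, -0.50), "T6": (0.81, -0.59),
    "O1": (-0.31, -0.95), "O2": (0.31, -0.95),
}


def _load_packaged_yaml(name: str) -> dict:
    ref = importlib.resources.files("fatiguenet.data").joinpath(name)
    with ref.open("r") as fh:
        return yaml.safe_load(fh)


@dataclass(frozen=True)
class ExperimentDesign:
    """Fixed layout of one synthetic recording campaign.

    Parameters
    ----------
    n_subjects : int
        Number of subjects (default 18, the analysed cohort size).
    time_points : sequence of str
        Ordered acquisition labels, default ``T0..T4``.
    conditions : sequence of str
        Condition labels; by convention the first is the resting state and
        the second the task state.
    epochs_per_cell : int
        Artifact-free epochs retained per (subject, time point, condition).
    epoch_seconds : float
        Epoch duration in seconds.
    fs : float
        Sampling rate in Hz (post-resampling rate of the analysis).
    channels : sequence of str
        Electrode labels; default the 19-channel 10-20 montage.
    """

    n_subjects: int = 18
    time_points: tuple[str, ...] = ("T0", "T1", "T2", "T3", "T4")
    conditions: tuple[str, ...] = ("C1", "C2")
    epochs_per_cell: int = 10
    epoch_seconds: float = 5.0
    fs: float = 256.0
    channels: tuple[str, ...] = CHANNELS_1020

    def __post_init__(self) -> None:
        object.__setattr__(self, "time_points", tuple(self.time_points))
        object.__setattr__(self, "conditions", tuple(self.conditions))
        object.__setattr__(self, "channels", tuple(self.channels))
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.epochs_per_cell < 1:
            raise ValueError("epochs_per_cell must be >= 1")
        if self.fs <= 0 or self.epoch_seconds <= 0:
            raise ValueError("fs and epoch_seconds must be positive")
        n = self.fs * self.epoch_seconds
        if abs(n - round(n)) > 1e-9:
            raise ValueError(
                f"epoch length fs*epoch_seconds = {n} is not an integer number "
                "of samples"
            )
        if len(set(self.channels)) != len(self.channels):
            raise ValueError("channel labels must be unique")
        if len(set(self.time_points)) != len(self.time_points):
            raise ValueError("time point labels must be unique")
        if len(self.conditions) < 1:
            raise ValueError("at least one condition required")

    @property
    def n_samples(self) -> int:
        """Epoch length in samples."""
        return round(self.fs * self.epoch_seconds)

    @property
    def rest_condition(self) -> str:
        return self.conditions[0]

    @property
    def task_condition(self) -> str:
        return self.conditions[-1]

    @classmethod
    def default(cls) -> "ExperimentDesign":
        return cls.from_dict(_load_packaged_yaml("default_design.yaml"))

    @classmethod
    def from_dict(cls, d: Mapping) -> "ExperimentDesign":
        return cls(**{k: v for k, v in d.items()})

    @classmethod
    def from_yaml(cls, path) -> "ExperimentDesign":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_dict(self) -> dict:
        return {
            "n_subjects": self.n_subjects,
            "time_points": list(self.time_points),
            "conditions": list(self.conditions),
            "epochs_per_cell": self.epochs_per_cell,
            "epoch_seconds": self.epoch_seconds,
            "fs": self.fs,
            "channels": list(self.channels),
        }


@dataclass(frozen=True)
class FatigueTrajectory:
    """Ground-truth evolution of spectral and coupling state over time points.

    ``slow_fast_gain`` multiplies the theta/alpha1/alpha2 amplitudes relative
    to beta at each time point, driving the (theta+alpha1+alpha2)/beta power
    ratio.  ``alpha1_coupling`` is the variance share of a globally shared
    alpha1-band source in the task condition; the resting condition uses the
    constant ``rest_alpha1_coupling``.  Defaults rise monotonically T0->T3
    and dip at T4, the qualitative shape of fatigue build-up with a
    late-session release.

    The remaining fields parameterise the stationary background: a
    distance-decaying inter-channel correlation field (``spatial_rho_max``,
    ``spatial_scale``) common to all rhythms, per-rhythm RMS amplitudes, and
    ``coupling_heterogeneity`` h, which scatters each subject's per-channel
    coupling weight as ``c_ch = c * u_ch`` with ``u_ch ~ U(1-h, 1+h)``.
    ``coupling_disorder`` (off by default) routes that share of the fatigue
    synchronisation through ``disorder_rank`` extra shared sources with
    random per-subject loadings instead of the single global source.
    """

    time_points: tuple[str, ...] = ("T0", "T1", "T2", "T3", "T4")
    slow_fast_gain: tuple[float, ...] = (1.0, 1.12, 1.24, 1.36, 1.30)
    alpha1_coupling: tuple[float, ...] = (0.10, 0.22, 0.34, 0.46, 0.38)
    rest_alpha1_coupling: float = 0.10
    coupling_heterogeneity: float = 0.5
    coupling_disorder: float = 0.0
    disorder_rank: int = 8
    spatial_rho_max: float = 0.85
    spatial_scale: float = 1.1
    band_amplitude: Mapping[str, float] = field(
        default_factory=lambda: {
            "delta": 8.0, "theta": 6.0, "alpha1": 9.0, "alpha2": 6.0, "beta": 5.0
        }
    )

    def __post_init__(self) -> None:
        object.__setattr__(self, "time_points", tuple(self.time_points))
        object.__setattr__(self, "slow_fast_gain", tuple(float(g) for g in self.slow_fast_gain))
        object.__setattr__(self, "alpha1_coupling", tuple(float(c) for c in self.alpha1_coupling))
        object.__setattr__(self, "band_amplitude", dict(self.band_amplitude))
        if len(self.slow_fast_gain) != len(self.time_points):
            raise ValueError("one slow_fast_gain per time point required")
        if len(self.alpha1_coupling) != len(self.time_points):
            raise ValueError("one alpha1_coupling per time point required")
        if any(g <= 0 for g in self.slow_fast_gain):
            raise ValueError("slow_fast_gain values must be > 0")
        couplings = (*self.alpha1_coupling, self.rest_alpha1_coupling)
        if any(not (0.0 <= c < 1.0) for c in couplings):
            raise ValueError("alpha1 couplings must lie in [0, 1)")
        if not (0.0 <= self.coupling_heterogeneity < 1.0):
            raise ValueError("coupling_heterogeneity must lie in [0, 1)")
        if not (0.0 <= self.coupling_disorder <= 1.0):
            raise ValueError("coupling_disorder must lie in [0, 1]")
        if self.disorder_rank < 1:
            raise ValueError("disorder_rank must be >= 1")
        if not (0.0 <= self.spatial_rho_max < 1.0):
            raise ValueError("spatial_rho_max must lie in [0, 1)")
        if self.spatial_scale <= 0:
            raise ValueError("spatial_scale must be positive")
        if any(a < 0 for a in self.band_amplitude.values()):
            raise ValueError("band amplitudes must be non-negative")

    def gain_for(self, time_point: str) -> float:
        return self.slow_fast_gain[self._index(time_point)]

    def coupling_for(self, time_point: str, *, task: bool) -> float:
        """Shared alpha1-source variance share for one cell of the design."""
        if task:
            return self.alpha1_coupling[self._index(time_point)]
        return self.rest_alpha1_coupling

    def _index(self, time_point: str) -> int:
        try:
            return self.time_points.index(time_point)
        except ValueError:
            raise KeyError(f"unknown time point {time_point!r}") from None

    def flattened(self) -> "FatigueTrajectory":
        """A null trajectory: constant gains and couplings at the T0 values.

        Useful for type-I-error calibration where no time effect must exist.
        """
        k = len(self.time_points)
        return replace(
            self,
            slow_fast_gain=(self.slow_fast_gain[0],) * k,
            alpha1_coupling=(self.alpha1_coupling[0],) * k,
        )

    @classmethod
    def default(cls) -> "FatigueTrajectory":
        return cls.from_dict(_load_packaged_yaml("default_trajectory.yaml"))

    @classmethod
    def from_dict(cls, d: Mapping) -> "FatigueTrajectory":
        return cls(**{k: v for k, v in d.items()})

    @classmethod
    def from_yaml(cls, path) -> "FatigueTrajectory":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_dict(self) -> dict:
        return {
            "time_points": list(self.time_points),
            "slow_fast_gain": list(self.slow_fast_gain),
            "alpha1_coupling": list(self.alpha1_coupling),
            "rest_alpha1_coupling": self.rest_alpha1_coupling,
            "coupling_heterogeneity": self.coupling_heterogeneity,
            "coupling_disorder": self.coupling_disorder,
            "disorder_rank": self.disorder_rank,
            "spatial_rho_max": self.spatial_rho_max,
            "spatial_scale": self.spatial_scale,
            "band_amplitude": dict(self.band_amplitude),
        }


@dataclass
class EpochSet:
    """A block of fixed-length multichannel epochs from one cell of the design.

    Attributes
    ----------
    data : ndarray, shape (n_epochs, n_samples, n_channels)
        Signal in microvolt-scaled arbitrary units.
    fs : float
        Sampling rate in Hz.
    channels : tuple of str
        Electrode labels, one per data column.
    meta : dict
        Provenance tags (subject, time_point, condition, seed, band, ...).
    """

    data: np.ndarray
    fs: float
    channels: tuple[str, ...]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.channels = tuple(self.channels)
        if self.data.ndim != 3:
            raise ValueError("data must have shape (n_epochs, n_samples, n_channels)")
        if self.data.shape[2] != len(self.channels):
            raise ValueError(
                f"{self.data.shape[2]} data channels but "
                f"{len(self.channels)} channel labels"
            )
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("epoch data contains non-finite values")

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def n_channels(self) -> int:
        return self.data.shape[2]

    def channel_index(self, label: str) -> int:
        try:
            return self.channels.index(label)
        except ValueError:
            raise KeyError(f"unknown channel {label!r}") from None

    def with_data(self, data: np.ndarray, **meta_updates) -> "EpochSet":
        """A copy carrying new data and (optionally) extra provenance tags."""
        meta = {**self.meta, **meta_updates}
        return EpochSet(data=data, fs=self.fs, channels=self.channels, meta=meta)
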