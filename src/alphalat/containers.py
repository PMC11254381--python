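"""In-memory containers shared across the pipeline stages.

Conventions used throughout:

* ``hemisphere`` is ``"left"`` or ``"right"``.
* A *pair* links a left-hemisphere sensor location to its mirror-symmetric
  right-hemisphere partner (same ``pair_id``).
* A *location* carries two orthogonal planar gradiometer channels
  (``planar_channel_index`` 1 and 2) whose power values are summed by
  :func:`alphalat.spectral.combine_planar`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

STRUCTURES = ("Th", "CN", "Put", "GP", "Hipp", "Amyg", "Acc")
"""Subcortical structures, in canonical order: thalamus, caudate nucleus,
putamen, globus pallidus, hippocampus, amygdala, nucleus accumbens."""

HEMISPHERES = ("left", "right")
CONDITIONS = (1, 2, 3, 4)
CUE_SIDES = ("left", "right")


@dataclass
class EpochSet:
    """Sensor-level epoched data for one subject.

    data
        ``(n_trials, n_sensors, n_samples)`` array, arbitrary units.
    trial_meta
        One row per trial with columns ``trial``, ``cue_side`` and
        ``condition`` (1-4, the load/salience cells).
    sensor_meta
        One row per channel with columns ``label``, ``hemisphere``,
        ``pair_id`` and ``planar_channel_index``.
    """

    data: np.ndarray
    trial_meta: pd.DataFrame
    sensor_meta: pd.DataFrame
    sampling_rate: float
    times: np.ndarray
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be (trials, sensors, samples)")
        n_trials, n_sensors, n_samples = self.data.shape
        if len(self.trial_meta) != n_trials:
            raise ValueError("trial_meta length mismatch")
        if len(self.sensor_meta) != n_sensors:
            raise ValueError("sensor_meta length mismatch")
        if len(self.times) != n_samples:
            raise ValueError("time axis length mismatch")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]


@dataclass
class TFRPower:
    """Time-frequency representation of power.

    ``power`` is ``(n_trials, n_sensors, n_freqs, n_times)``; entries where
    the analysis window did not fully fit inside the epoch are NaN.
    """

    power: np.ndarray
    freqs: np.ndarray
    times: np.ndarray
    sensor_meta: pd.DataFrame
    combined: bool = False

    def __post_init__(self) -> None:
        self.power = np.asarray(self.power, dtype=float)
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.power.ndim != 4:
            raise ValueError("power must be (trials, sensors, freqs, times)")
        if self.power.size and np.any(self.power[np.isfinite(self.power)] < 0):
            raise ValueError("power must be non-negative")


@dataclass
class MIMap:
    """Per-sensor alpha modulation index MI = (P_right - P_left)/(P_right + P_left),

    where the subscripts denote the attended hemifield.  ``sensor_meta`` is
    the pair-combined metadata (columns ``label``, ``hemisphere``,
    ``pair_id``).
    """

    values: np.ndarray
    sensor_meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape[0] != len(self.sensor_meta):
            raise ValueError("values/sensor_meta length mismatch")

    def value_for(self, label: str) -> float:
        mask = (self.sensor_meta["label"] == label).to_numpy()
        if mask.sum() != 1:
            raise KeyError(f"sensor {label!r} not present exactly once")
        return float(self.values[int(np.argmax(mask))])


@dataclass
class ROISelection:
    """Mirror-paired region of interest: the ``n_pairs`` sensor pairs with the
    largest right-minus-left MI difference."""

    n_pairs: int
    pair_ids: list = field(default_factory=list)
    left_sensors: list = field(default_factory=list)
    right_sensors: list = field(default_factory=list)
    differences: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.left_sensors) != self.n_pairs or len(self.right_sensors) != self.n_pairs:
            raise ValueError("ROI must contain n_pairs sensors per hemisphere")
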