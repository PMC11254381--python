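"""Readers and writers for the on-disk cohort layout.

Formats: volume table and behavior as CSV, ground truth as JSON, epochs as
an HDF5 file per subject (datasets ``data`` and ``times``, groups
``trial_meta`` and ``sensor_meta``, attribute ``sampling_rate``).  A
long-format CSV export of epochs is available for interoperability with
tools that do not read HDF5.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .containers import STRUCTURES, EpochSet
from .synthetic import GeneratorConfig, GroundTruth

VOLUME_COLUMNS = ["subject_id", "structure", "hemisphere", "voxels"]


def write_volume_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


def read_volume_table(path) -> pd.DataFrame:
    """Read and validate a volume table CSV.

    Requires header ``subject_id,structure,hemisphere,voxels``; rejects
    unknown structure labels, hemispheres other than left/right, duplicate
    (subject, structure, hemisphere) rows and nonpositive voxel counts.
    """
    table = pd.read_csv(path)
    missing = [c for c in VOLUME_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"volume table missing columns: {missing}")
    table = table[VOLUME_COLUMNS].copy()
    unknown = set(table["structure"]) - set(STRUCTURES)
    if unknown:
        raise ValueError(f"unknown structure labels: {sorted(unknown)}")
    bad_hemi = set(table["hemisphere"]) - {"left", "right"}
    if bad_hemi:
        raise ValueError(f"unknown hemisphere labels: {sorted(bad_hemi)}")
    dup = table.duplicated(["subject_id", "structure", "hemisphere"])
    if dup.any():
        rows = table.index[dup].tolist()
        raise ValueError(f"duplicate (subject, structure, hemisphere) rows: {rows}")
    nonpos = table["voxels"] <= 0
    if nonpos.any():
        rows = table.index[nonpos].tolist()
        raise ValueError(f"nonpositive voxel count in rows: {rows}")
    return table


def write_epochs_h5(epochs: EpochSet, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=epochs.data)
        f.create_dataset("times", data=epochs.times)
        f.attrs["sampling_rate"] = float(epochs.sampling_rate)
        f.attrs["subject_id"] = epochs.subject_id
        tm = f.create_group("trial_meta")
        tm.create_dataset("trial", data=epochs.trial_meta["trial"].to_numpy())
        tm.create_dataset(
            "cue_side",
            data=np.array(epochs.trial_meta["cue_side"], dtype="S8"))
        tm.create_dataset(
            "condition", data=epochs.trial_meta["condition"].to_numpy())
        sm = f.create_group("sensor_meta")
        sm.create_dataset(
            "label", data=np.array(epochs.sensor_meta["label"], dtype="S16"))
        sm.create_dataset(
            "hemisphere",
            data=np.array(epochs.sensor_meta["hemisphere"], dtype="S8"))
        sm.create_dataset(
            "pair_id", data=epochs.sensor_meta["pair_id"].to_numpy())
        sm.create_dataset(
            "planar_channel_index",
            data=epochs.sensor_meta["planar_channel_index"].to_numpy())


def read_epochs_h5(path) -> EpochSet:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"epoch file not found: {path}")
    with h5py.File(path, "r") as f:
        data = f["data"][()]
        times = f["times"][()]
        fs = float(f.attrs["sampling_rate"])
        subject_id = str(f.attrs.get("subject_id", ""))
        trial_meta = pd.DataFrame({
            "trial": f["trial_meta/trial"][()],
            "cue_side": [b.decode() for b in f["trial_meta/cue_side"][()]],
            "condition": f["trial_meta/condition"][()],
        })
        sensor_meta = pd.DataFrame({
            "label": [b.decode() for b in f["sensor_meta/label"][()]],
            "hemisphere": [b.decode() for b in f["sensor_meta/hemisphere"][()]],
            "pair_id": f["sensor_meta/pair_id"][()],
            "planar_channel_index": f["sensor_meta/planar_channel_index"][()],
        })
    return EpochSet(data=data, trial_meta=trial_meta, sensor_meta=sensor_meta,
                    sampling_rate=fs, times=times, subject_id=subject_id)


def epochs_to_long_frame(epochs: EpochSet) -> pd.DataFrame:
    """Delimited long-format export: one row per (trial, sensor, sample)."""
    n_trials, n_sensors, n_samples = epochs.data.shape
    trial = np.repeat(epochs.trial_meta["trial"].to_numpy(),
                      n_sensors * n_samples)
    label = np.tile(np.repeat(epochs.sensor_meta["label"].to_numpy(), n_samples),
                    n_trials)
    time = np.tile(epochs.times, n_trials * n_sensors)
    return pd.DataFrame({
        "trial": trial, "sensor": label, "time": time,
        "value": epochs.data.ravel(),
    })


def read_ground_truth(path) -> tuple:
    payload = json.loads(Path(path).read_text())
    config = GeneratorConfig.from_dict(payload["config"])
    truth = GroundTruth.from_dict(payload["truth"])
    return config, truth


def read_behavior(path) -> pd.DataFrame:
    beh = pd.read_csv(path)
    required = {"subject_id", "cue_side", "correct", "rt"}
    missing = required - set(beh.columns)
    if missing:
        raise ValueError(f"behavior table missing columns: {sorted(missing)}")
    return beh
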