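"""Laterality indices: MI(alpha), ROI selection, HLM(alpha), LV and BA.

Sign conventions:

* MI > 0 at a sensor means more alpha power when attending right than left.
* HLM < 0 means stronger modulation of alpha power over the left hemisphere
  than the right; HLM is bounded by (-2, 2).
* LV > 0 means rightward volumetric asymmetry of a structure.
* BA > 0 means better (or slower, for RT) performance when attending right.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import CONDITIONS, STRUCTURES, MIMap, ROISelection, TFRPower
from .spectral import band_window_average


def modulation_index(power_att_right: np.ndarray, power_att_left: np.ndarray,
                     sensor_meta: pd.DataFrame | None = None) -> MIMap:
    """Per-sensor modulation index (P_right - P_left)/(P_right + P_left).

    Both power vectors must be strictly positive; a nonpositive entry raises
    with the offending sensor named.
    """
    pr = np.asarray(power_att_right, dtype=float)
    pl = np.asarray(power_att_left, dtype=float)
    if pr.shape != pl.shape:
        raise ValueError("power vectors must have equal shape")
    if sensor_meta is None:
        sensor_meta = pd.DataFrame({
            "label": [f"S{i}" for i in range(pr.size)],
            "hemisphere": [""] * pr.size,
            "pair_id": np.arange(pr.size),
        })
    bad = np.flatnonzero(~((pr > 0) & (pl > 0)))
    if bad.size:
        label = sensor_meta["label"].iloc[bad[0]]
        raise ValueError(f"nonpositive power at sensor {label!r}")
    return MIMap(values=(pr - pl) / (pr + pl), sensor_meta=sensor_meta)


def select_roi(group_mean_mi: MIMap, n_pairs: int = 5) -> ROISelection:
    """Select the ``n_pairs`` mirror-symmetric sensor pairs with the largest
    right-minus-left MI difference at the group level.

    Ties at the cutoff are broken deterministically by ascending pair id.
    Returns both hemispheres' members (2 x n_pairs sensors in total).
    """
    meta = group_mean_mi.sensor_meta
    if not {"pair_id", "hemisphere", "label"} <= set(meta.columns):
        raise ValueError("MI map lacks pairing metadata")
    frame = meta.assign(mi=group_mean_mi.values)
    diffs = {}
    labels = {}
    for pid, g in frame.groupby("pair_id"):
        hemis = set(g["hemisphere"])
        if len(g) != 2 or hemis != {"left", "right"}:
            raise ValueError(f"pair {pid} is not a left/right sensor pair")
        right = g[g["hemisphere"] == "right"].iloc[0]
        left = g[g["hemisphere"] == "left"].iloc[0]
        diffs[pid] = float(right["mi"] - left["mi"])
        labels[pid] = (left["label"], right["label"])
    if n_pairs > len(diffs):
        raise ValueError(
            f"n_pairs={n_pairs} exceeds available pairs ({len(diffs)})")
    order = sorted(diffs, key=lambda pid: (-diffs[pid], pid))
    chosen = order[:n_pairs]
    return ROISelection(
        n_pairs=n_pairs,
        pair_ids=list(chosen),
        left_sensors=[labels[p][0] for p in chosen],
        right_sensors=[labels[p][1] for p in chosen],
        differences={p: diffs[p] for p in chosen},
    )


def hlm(mi_map: MIMap, roi: ROISelection) -> float:
    """Hemispheric lateralized modulation: mean MI over the right-ROI sensors
    plus mean MI over the left-ROI sensors."""
    right = [mi_map.value_for(lbl) for lbl in roi.right_sensors]
    left = [mi_map.value_for(lbl) for lbl in roi.left_sensors]
    return float(np.mean(right) + np.mean(left))


def lateralization_volume(volumes: pd.DataFrame) -> pd.DataFrame:
    """Per-subject, per-structure LV = (V_right - V_left)/(V_right + V_left).

    ``volumes`` is the long-format table (subject_id, structure, hemisphere,
    voxels).  Raises on missing hemisphere rows or nonpositive counts.
    Returns a subjects x structures frame with columns in canonical order.
    """
    required = {"subject_id", "structure", "hemisphere", "voxels"}
    if not required <= set(volumes.columns):
        raise ValueError("volume table lacks required columns")
    if (volumes["voxels"] <= 0).any():
        raise ValueError("nonpositive voxel count in volume table")
    wide = volumes.pivot_table(index="subject_id", columns=["structure", "hemisphere"],
                               values="voxels", aggfunc="first", sort=False)
    subjects = list(dict.fromkeys(volumes["subject_id"]))
    out = {}
    for s in STRUCTURES:
        if s not in {c[0] for c in wide.columns}:
            continue
        for hemi in ("left", "right"):
            if (s, hemi) not in wide.columns or wide[(s, hemi)].isna().any():
                raise ValueError(f"missing {hemi} hemisphere row for {s}")
        vr = wide[(s, "right")]
        vl = wide[(s, "left")]
        out[s] = (vr - vl) / (vr + vl)
    lv = pd.DataFrame(out).loc[subjects]
    lv.index.name = "subject_id"
    return lv


def condition_hlm(tfr: TFRPower, roi: ROISelection, trial_meta: pd.DataFrame,
                  band=(8.0, 13.0), window=(-0.850, 0.0)) -> pd.Series:
    """HLM(alpha) per load/salience condition on a fixed ROI.

    For each condition the band/window-averaged power is recomputed per cue
    side over that condition's trials only, MI follows, then HLM on the
    given ROI.  Raises if any condition lacks a cue side.
    """
    values = {}
    cond = trial_meta["condition"].to_numpy()
    side = trial_meta["cue_side"].to_numpy()
    for c in CONDITIONS:
        sel_r = (cond == c) & (side == "right")
        sel_l = (cond == c) & (side == "left")
        if not sel_r.any() or not sel_l.any():
            raise ValueError(f"condition {c} lacks trials on one cue side")
        p_r = band_window_average(tfr, band, window, sel_r)
        p_l = band_window_average(tfr, band, window, sel_l)
        mi = modulation_index(p_r, p_l, tfr.sensor_meta)
        values[f"cond{c}"] = hlm(mi, roi)
    return pd.Series(values)


def behavioral_asymmetry(metric_att_right: float, metric_att_left: float) -> float:
    """Behavioral asymmetry (right - left)/(right + left) for a positive
    performance metric (accuracy or response time)."""
    r = float(metric_att_right)
    l = float(metric_att_left)
    if r <= 0 or l <= 0:
        raise ValueError("behavioral metrics must be positive")
    return (r - l) / (r + l)
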