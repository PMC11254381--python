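"""Synthetic cohorts with known structure-function coupling.

The generator emulates the study design this pipeline analyses: a cohort of
subjects performing a cued change-detection task (four load/salience
conditions, cue left/right balanced within condition), each contributing

* a subcortical volume table (7 structures x 2 hemispheres) whose
  lateralization volumes LV_s = (V_right - V_left)/(V_right + V_left) are
  drawn from configurable normal distributions,
* sensor-level epochs in which 8-13 Hz alpha power is modulated by the cue
  side such that the subject-level hemispheric lateralized modulation
  HLM(alpha) equals ``beta0 + sum_s beta_s LV_s + eps`` with configurable
  coupling coefficients and noise, and
* a trial-level behavior table (accuracy, response time) with optional
  side-bias and LV coupling.

Everything is a pure function of ``(config, seed)``.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import CONDITIONS, CUE_SIDES, STRUCTURES, EpochSet

# Printed cohort distributions where available; structures without a robust
# lateralization get zero-mean LV with a spread of the same order.  The total
# (bilateral) volume scales are typical adult values in 1 mm^3 voxels.
DEFAULT_VOLUME_ASYM_PARAMS: dict = {
    "Th": (-0.0123, 0.0121, 15600.0),
    "CN": (0.0115, 0.0285, 7200.0),
    "Put": (-0.0149, 0.0285, 8200.0),
    "GP": (0.0, 0.030, 3200.0),
    "Hipp": (0.0, 0.020, 7600.0),
    "Amyg": (0.0, 0.030, 2900.0),
    "Acc": (-0.1141, 0.0746, 1000.0),
}

# Winning-model coupling: thalamus negative, caudate and pallidus positive.
DEFAULT_COUPLING_BETAS: dict = {
    "Th": -2.19, "CN": 0.92, "Put": 0.0, "GP": 0.51,
    "Hipp": 0.0, "Amyg": 0.0, "Acc": 0.0,
}


@dataclass
class GeneratorConfig:
    """All knobs of the synthetic cohort, with study-scale defaults.

    ``n_trials_per_condition`` defaults to 128 so the cohort totals
    2 x 256 = 512 trials per subject across the four conditions.
    ``hlm_noise_sd`` (sd of eps in the coupling model) defaults to 0.049,
    which puts the mean adjusted R^2 of the three-structure model near 0.38
    at n = 33 given the default LV spreads and coupling coefficients.
    """

    n_subjects: int = 33
    n_trials_per_condition: int = 128
    sampling_rate: float = 200.0
    epoch_window: tuple = (-1.5, 0.5)
    n_sensor_pairs: int = 8
    n_hotspot_pairs: int = 5
    offroi_mi_fraction: float = 0.25
    alpha_freq: float = 10.0
    base_alpha_amplitude: float = 1.0
    modulation_depth: float = 0.2
    noise_amplitude: float = 0.5
    coupling_beta0: float = 0.0
    coupling_betas: dict = field(default_factory=lambda: dict(DEFAULT_COUPLING_BETAS))
    hlm_noise_sd: float = 0.049
    condition_sd: float = 0.02
    condition_betas: dict | None = None
    volume_asym_params: dict = field(
        default_factory=lambda: dict(DEFAULT_VOLUME_ASYM_PARAMS))
    base_accuracy: float = 0.8
    acc_side_bias: float = 0.0
    rt_log_mu: float = math.log(0.55)
    rt_log_sigma: float = 0.2
    rt_side_shift: float = 0.0
    acc_coupling: dict | None = None
    rt_coupling: dict | None = None
    lv_max_tries: int = 100
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.n_trials_per_condition < 1:
            raise ValueError("n_trials_per_condition must be >= 1")
        if self.n_trials_per_condition % 2:
            raise ValueError(
                "n_trials_per_condition must be even so cue sides balance")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if not self.epoch_window[0] < self.epoch_window[1]:
            raise ValueError("epoch_window start must precede end")
        if not 0 < self.n_hotspot_pairs <= self.n_sensor_pairs:
            raise ValueError("n_hotspot_pairs must be in 1..n_sensor_pairs")
        if not abs(self.modulation_depth) < 1:
            raise ValueError("|modulation_depth| must be < 1")
        if not 0 < self.base_accuracy < 1:
            raise ValueError("base_accuracy must be in (0, 1)")
        for s in STRUCTURES:
            if s not in self.volume_asym_params:
                raise ValueError(f"volume_asym_params missing structure {s}")
            _, sd, total = self.volume_asym_params[s]
            if total <= 0:
                raise ValueError(f"nonpositive total volume for {s}")
            if sd < 0:
                raise ValueError(f"negative LV sd for {s}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["epoch_window"] = list(self.epoch_window)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        d = dict(d)
        if "epoch_window" in d:
            d["epoch_window"] = tuple(d["epoch_window"])
        return cls(**d)


@dataclass
class GroundTruth:
    """What the generator actually drew, for parameter-recovery checks."""

    subjects: list
    lv: pd.DataFrame                 # n_subjects x 7, columns = STRUCTURES
    hlm: pd.Series                   # target overall HLM(alpha)
    hlm_condition: pd.DataFrame      # n_subjects x 4, columns cond1..cond4
    coupling_beta0: float
    coupling_betas: dict
    hlm_noise_sd: float
    seed: int

    def to_dict(self) -> dict:
        return {
            "subjects": list(self.subjects),
            "lv": {s: [float(v) for v in self.lv[s]] for s in self.lv.columns},
            "hlm": [float(v) for v in self.hlm],
            "hlm_condition": {
                c: [float(v) for v in self.hlm_condition[c]]
                for c in self.hlm_condition.columns
            },
            "coupling_beta0": float(self.coupling_beta0),
            "coupling_betas": {k: float(v) for k, v in self.coupling_betas.items()},
            "hlm_noise_sd": float(self.hlm_noise_sd),
            "seed": int(self.seed),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        subjects = list(d["subjects"])
        lv = pd.DataFrame(d["lv"], index=subjects)[list(STRUCTURES)]
        hlm = pd.Series(d["hlm"], index=subjects, name="hlm")
        cond_cols = sorted(d["hlm_condition"])
        hc = pd.DataFrame(d["hlm_condition"], index=subjects)[cond_cols]
        return cls(subjects, lv, hlm, hc, d["coupling_beta0"],
                   dict(d["coupling_betas"]), d["hlm_noise_sd"], int(d["seed"]))


def _subject_ids(n: int) -> list:
    return [f"sub-{i + 1:02d}" for i in range(n)]


def generate_volumes(config: GeneratorConfig, rng: np.random.Generator):
    """Draw per-subject lateralization volumes and the voxel table they imply.

    For each subject and structure, LV ~ Normal(mean, sd) (resampled while
    |LV| >= 1, up to ``config.lv_max_tries``); hemispheric volumes are set to
    ``V_right = V_total (1 + LV)/2`` and ``V_left = V_total (1 - LV)/2`` so
    that the LV index applied to the table returns the draw exactly.

    Returns ``(volume_table, lv_frame)``.
    """
    config.validate()
    subjects = _subject_ids(config.n_subjects)
    rows = []
    lv_data = {}
    for s in STRUCTURES:
        mean, sd, total = config.volume_asym_params[s]
        draws = rng.normal(mean, sd, size=config.n_subjects)
        for _ in range(config.lv_max_tries):
            bad = np.abs(draws) >= 1
            if not bad.any():
                break
            draws[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        else:
            raise ValueError(f"could not draw |LV| < 1 for structure {s}")
        lv_data[s] = draws
    for i, subj in enumerate(subjects):
        for s in STRUCTURES:
            _, _, total = config.volume_asym_params[s]
            lv = lv_data[s][i]
            v_right = total * (1 + lv) / 2.0
            v_left = total * (1 - lv) / 2.0
            rows.append((subj, s, "right", v_right))
            rows.append((subj, s, "left", v_left))
    table = pd.DataFrame(rows, columns=["subject_id", "structure",
                                        "hemisphere", "voxels"])
    lv_frame = pd.DataFrame(lv_data, index=subjects)[list(STRUCTURES)]
    return table, lv_frame


def draw_truth(config: GeneratorConfig, rng: np.random.Generator):
    """Draw the cohort-level ground truth: LVs, volumes, and target HLMs.

    The overall target is ``HLM = beta0 + sum_s beta_s LV_s + eps`` with
    ``eps ~ Normal(0, hlm_noise_sd)``.  Condition targets are either the
    overall HLM plus mean-centered Gaussian perturbations (sd
    ``condition_sd``), or -- when ``config.condition_betas`` maps condition
    number to its own ``(beta0, {structure: beta})`` -- each condition's own
    linear predictor plus noise, in which case the overall target is their
    mean (equal trial counts make the all-trials HLM the condition average).

    Returns ``(volume_table, GroundTruth)``.
    """
    table, lv = generate_volumes(config, rng)
    subjects = list(lv.index)
    betas = np.array([config.coupling_betas.get(s, 0.0) for s in STRUCTURES])
    eps = rng.normal(0.0, config.hlm_noise_sd, size=len(subjects))
    if config.condition_betas is None:
        hlm = config.coupling_beta0 + lv.values @ betas + eps
        pert = rng.normal(0.0, config.condition_sd, size=(len(subjects), 4))
        pert -= pert.mean(axis=1, keepdims=True)
        hc = hlm[:, None] + pert
    else:
        hc = np.empty((len(subjects), 4))
        for ci, c in enumerate(CONDITIONS):
            b0_c, betas_c = config.condition_betas[c]
            bvec = np.array([betas_c.get(s, 0.0) for s in STRUCTURES])
            eps_c = rng.normal(0.0, config.hlm_noise_sd, size=len(subjects))
            hc[:, ci] = b0_c + lv.values @ bvec + eps_c
        hlm = hc.mean(axis=1)
    truth = GroundTruth(
        subjects=subjects,
        lv=lv,
        hlm=pd.Series(hlm, index=subjects, name="hlm"),
        hlm_condition=pd.DataFrame(
            hc, index=subjects, columns=[f"cond{c}" for c in CONDITIONS]),
        coupling_beta0=config.coupling_beta0,
        coupling_betas=dict(config.coupling_betas),
        hlm_noise_sd=config.hlm_noise_sd,
        seed=config.seed,
    )
    return table, truth


def _sensor_meta(config: GeneratorConfig) -> pd.DataFrame:
    rows = []
    for pid in range(config.n_sensor_pairs):
        for hemi in ("left", "right"):
            for ch in (1, 2):
                rows.append((f"P{pid:02d}{hemi[0].upper()}_{ch}", hemi, pid, ch))
    return pd.DataFrame(rows, columns=["label", "hemisphere", "pair_id",
                                       "planar_channel_index"])


def _trial_meta(config: GeneratorConfig, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    for c in CONDITIONS:
        for side in CUE_SIDES:
            rows.extend((side, c) for _ in range(config.n_trials_per_condition // 2))
    order = rng.permutation(len(rows))
    meta = pd.DataFrame([rows[i] for i in order], columns=["cue_side", "condition"])
    meta.insert(0, "trial", np.arange(len(meta)))
    return meta


def _pink_noise(rng: np.random.Generator, shape: tuple, n_samples: int,
                fs: float) -> np.ndarray:
    """Broadband noise with a 1/f power spectrum (unit variance per trace)."""
    freqs = np.fft.rfftfreq(n_samples, 1.0 / fs)
    scale = np.zeros_like(freqs)
    scale[1:] = 1.0 / np.sqrt(freqs[1:])
    spec = (rng.standard_normal(shape + (len(freqs),))
            + 1j * rng.standard_normal(shape + (len(freqs),))) * scale
    x = np.fft.irfft(spec, n=n_samples, axis=-1)
    sd = x.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def generate_epochs(subject_truth: dict, config: GeneratorConfig,
                    rng: np.random.Generator) -> EpochSet:
    """Simulate one subject's sensor-level epochs.

    ``subject_truth`` needs keys ``subject_id``, ``hlm_condition`` (length-4
    array of per-condition targets).  At hotspot pair locations, the target
    trial-averaged modulation index in condition c is ``+m + h_c/2`` on the
    right hemisphere and ``-m + h_c/2`` on the left (``m`` =
    ``modulation_depth``), so that mean right-ROI MI plus mean left-ROI MI
    recovers ``h_c``; off-hotspot pairs carry ``offroi_mi_fraction`` of the
    target, giving the spatial contrast that ROI selection needs.  A target
    MI maps to attend-right/attend-left alpha power ``1 + MI`` / ``1 - MI``
    (power ratio ``(1+MI)/(1-MI)``), realised as an amplitude-scaled alpha
    sinusoid; phases within each (condition, cue side) cell are evenly
    spaced so trial-averaged power matches the target without bias.
    1/f-shaped broadband noise is added per channel.
    """
    config.validate()
    hc = np.asarray(subject_truth["hlm_condition"], dtype=float)
    if hc.shape != (4,):
        raise ValueError("hlm_condition must have 4 entries")
    m = config.modulation_depth
    fs = config.sampling_rate
    t0, t1 = config.epoch_window
    n_samples = int(round((t1 - t0) * fs))
    times = t0 + np.arange(n_samples) / fs
    sensor_meta = _sensor_meta(config)
    trial_meta = _trial_meta(config, rng)
    n_trials = len(trial_meta)
    n_sensors = len(sensor_meta)

    # target MI per (condition, hemisphere sign, pair fraction)
    fracs = np.where(np.arange(config.n_sensor_pairs) < config.n_hotspot_pairs,
                     1.0, config.offroi_mi_fraction)
    for c_idx in range(4):
        for sign in (+1.0, -1.0):
            mi = fracs * (sign * m + hc[c_idx] / 2.0)
            if np.any(np.abs(mi) >= 1):
                raise ValueError(
                    "implied power ratio non-positive: |target MI| >= 1 "
                    f"(condition {c_idx + 1})")

    # fixed per-location planar orientation; same for both hemispheres' channels
    theta = rng.uniform(0.0, np.pi / 2.0, size=config.n_sensor_pairs)

    data = config.noise_amplitude * _pink_noise(
        rng, (n_trials, n_sensors), n_samples, fs)

    # evenly spaced phases within each (condition, side) cell cancel the
    # phase-dependent interference term of windowed-sinusoid power exactly
    phase = np.empty(n_trials)
    cond_arr = trial_meta["condition"].to_numpy()
    side_arr = trial_meta["cue_side"].to_numpy()
    for c in CONDITIONS:
        for side in CUE_SIDES:
            cell = np.flatnonzero((cond_arr == c) & (side_arr == side))
            if len(cell) == 0:
                raise ValueError(f"empty condition cell ({c}, {side})")
            offs = rng.uniform(0.0, 2.0 * np.pi)
            phase[cell] = offs + 2.0 * np.pi * np.arange(len(cell)) / len(cell)

    omega = 2.0 * np.pi * config.alpha_freq
    carrier = np.cos(omega * times[None, :] + phase[:, None])  # trials x samples

    hemi_sign = np.where(sensor_meta["hemisphere"].to_numpy() == "right", 1.0, -1.0)
    pair_idx = sensor_meta["pair_id"].to_numpy()
    ch_idx = sensor_meta["planar_channel_index"].to_numpy() - 1
    orient = np.where(ch_idx == 0,
                      np.cos(theta[pair_idx]), np.sin(theta[pair_idx]))

    cond_i = cond_arr - 1
    target_mi = fracs[pair_idx][None, :] * (
        hemi_sign[None, :] * m + hc[cond_i][:, None] / 2.0)  # trials x sensors
    attend_right = (side_arr == "right")[:, None]
    rel_power = np.where(attend_right, 1.0 + target_mi, 1.0 - target_mi)
    amp = config.base_alpha_amplitude * np.sqrt(rel_power) * orient[None, :]

    data += amp[:, :, None] * carrier[:, None, :]
    return EpochSet(data=data, trial_meta=trial_meta, sensor_meta=sensor_meta,
                    sampling_rate=fs, times=times,
                    subject_id=str(subject_truth.get("subject_id", "")))


def generate_behavior(subject_truth: dict, config: GeneratorConfig,
                      rng: np.random.Generator,
                      trial_meta: pd.DataFrame | None = None) -> pd.DataFrame:
    """Simulate one subject's trial-level behavior.

    Accuracy is Bernoulli with side-dependent probability ``base +- d/2``
    where ``d = acc_side_bias + sum_s acc_coupling_s LV_s``; response times
    are log-normal with location ``rt_log_mu +- e/2`` where
    ``e = rt_side_shift + sum_s rt_coupling_s LV_s`` (right minus left).
    """
    config.validate()
    if trial_meta is None:
        trial_meta = _trial_meta(config, rng)
    lv = subject_truth.get("lv", None)
    d = config.acc_side_bias
    e = config.rt_side_shift
    if lv is not None:
        lv = pd.Series(lv)
        if config.acc_coupling:
            d += sum(coef * float(lv[s]) for s, coef in config.acc_coupling.items())
        if config.rt_coupling:
            e += sum(coef * float(lv[s]) for s, coef in config.rt_coupling.items())
    p_right = config.base_accuracy + d / 2.0
    p_left = config.base_accuracy - d / 2.0
    if not (0 < p_right < 1 and 0 < p_left < 1):
        raise ValueError("side-dependent accuracy probability outside (0, 1)")
    is_right = (trial_meta["cue_side"] == "right").to_numpy()
    p = np.where(is_right, p_right, p_left)
    correct = (rng.uniform(size=len(trial_meta)) < p).astype(int)
    mu = np.where(is_right, config.rt_log_mu + e / 2.0, config.rt_log_mu - e / 2.0)
    rt = np.exp(rng.normal(mu, config.rt_log_sigma))
    out = trial_meta.copy()
    out["correct"] = correct
    out["rt"] = rt
    out.insert(0, "subject_id", str(subject_truth.get("subject_id", "")))
    return out


def generate_cohort(config: GeneratorConfig, out_dir) -> dict:
    """Write a full synthetic cohort to ``out_dir`` and return its paths.

    Layout: ``volumes.csv``, ``behavior.csv``, ``ground_truth.json`` and one
    HDF5 epoch file per subject under ``epochs/``.  Re-running with the same
    config and seed reproduces every file byte-for-byte.
    """
    from . import io as _io

    config.validate()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    epochs_dir = out_dir / "epochs"
    epochs_dir.mkdir(exist_ok=True)

    root_ss = np.random.SeedSequence(config.seed)
    truth_ss, *subj_ss = root_ss.spawn(1 + 2 * config.n_subjects)
    table, truth = draw_truth(config, np.random.default_rng(truth_ss))

    _io.write_volume_table(table, out_dir / "volumes.csv")

    behavior_frames = []
    epoch_paths = {}
    for i, subj in enumerate(truth.subjects):
        st = {
            "subject_id": subj,
            "hlm": float(truth.hlm.iloc[i]),
            "hlm_condition": truth.hlm_condition.iloc[i].to_numpy(),
            "lv": truth.lv.iloc[i],
        }
        ep_rng = np.random.default_rng(subj_ss[2 * i])
        beh_rng = np.random.default_rng(subj_ss[2 * i + 1])
        epochs = generate_epochs(st, config, ep_rng)
        path = epochs_dir / f"{subj}.h5"
        _io.write_epochs_h5(epochs, path)
        epoch_paths[subj] = path
        behavior_frames.append(
            generate_behavior(st, config, beh_rng, trial_meta=epochs.trial_meta))
    behavior = pd.concat(behavior_frames, ignore_index=True)
    behavior.to_csv(out_dir / "behavior.csv", index=False)

    gt_path = out_dir / "ground_truth.json"
    payload = {"config": config.to_dict(), "truth": truth.to_dict()}
    gt_path.write_text(json.dumps(payload, sort_keys=True, indent=1) + "\n")

    return {
        "volumes": out_dir / "volumes.csv",
        "behavior": out_dir / "behavior.csv",
        "ground_truth": gt_path,
        "epochs_dir": epochs_dir,
        "epochs": epoch_paths,
        "truth": truth,
    }
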