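"""End-to-end pipeline: epochs + volumes + behavior -> report bundle.

Stage order: spectral (TFR, planar combination, band/window power) ->
laterality (MI maps, group ROI, HLM overall and per condition, LV, BA) ->
model selection (exhaustive AIC/BIC search, winning fit, VIF) ->
multivariate regression (nested comparisons, per-regressor tests) ->
behavioral GLMs.  The run is a pure function of (inputs, config); the
report carries a provenance block (config hash, seed, version) and every
number it contains is regenerable from the inputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as _io
from .behavior import fit_behavior_glm, summarize_behavior
from .containers import STRUCTURES, MIMap
from .glm import model_search, normality_check, one_sample_test, vif
from .laterality import (condition_hlm, hlm, lateralization_volume,
                         modulation_index, select_roi)
from .mmr import compare_nested_mmr, fit_mmr, test_regressor_across_outcomes
from .spectral import band_window_average, combine_planar, compute_tfr

logger = logging.getLogger("alphalat")

read_volume_table = _io.read_volume_table


class PipelineError(RuntimeError):
    """Stage-tagged pipeline failure."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Paths and analysis parameters of one pipeline run.

    Defaults mirror the standard recipe: 8-13 Hz band, -850-0 ms pre-target
    window, 5 ROI pairs, AIC-ranked exhaustive search over all seven
    structures, key structures Th/CN/GP for the focused models.
    """

    volumes: str = ""
    epochs_dir: str = ""
    behavior: str = ""
    out_dir: str = ""
    band: tuple = (8.0, 13.0)
    window: tuple = (-0.850, 0.0)
    n_roi_pairs: int = 5
    structures: tuple = STRUCTURES
    key_structures: tuple = ("Th", "CN", "GP")
    criterion: str = "aic"
    n_cycles: int = 3
    time_step: float = 0.010
    rt_correct_only: bool = True
    seed: int = 0
    verbose: bool = False

    def validate(self) -> None:
        if not self.band[0] < self.band[1]:
            raise ValueError("band must be (low, high) with low < high")
        if not self.window[0] < self.window[1]:
            raise ValueError("window must be (start, end) with start < end")
        if self.n_roi_pairs < 1:
            raise ValueError("n_roi_pairs must be >= 1")
        if self.criterion not in ("aic", "bic"):
            raise ValueError("criterion must be 'aic' or 'bic'")
        unknown = set(self.structures) - set(STRUCTURES)
        if unknown:
            raise ValueError(f"unknown structures: {sorted(unknown)}")
        if not set(self.key_structures) <= set(self.structures):
            raise ValueError("key_structures must be among structures")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for key in ("band", "window", "structures", "key_structures"):
            d[key] = list(d[key])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        for key in ("band", "window", "structures", "key_structures"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    @classmethod
    def for_cohort(cls, cohort_dir, out_dir=None, **kwargs) -> "PipelineConfig":
        """Convenience constructor for the on-disk cohort layout that
        :func:`alphalat.synthetic.generate_cohort` writes."""
        cohort_dir = Path(cohort_dir)
        return cls(volumes=str(cohort_dir / "volumes.csv"),
                   epochs_dir=str(cohort_dir / "epochs"),
                   behavior=str(cohort_dir / "behavior.csv"),
                   out_dir=str(out_dir if out_dir is not None
                               else cohort_dir / "report"),
                   **kwargs)


@dataclass
class ReportBundle:
    """All pipeline outputs plus provenance."""

    laterality: pd.DataFrame
    search_table: pd.DataFrame
    winning_subset: tuple
    winning_fit: dict
    vif: dict
    lv_tests: dict
    hlm_normality: dict
    mmr_report: dict
    behavior_fits: dict
    provenance: dict
    roi: dict = field(default_factory=dict)

    def to_json(self) -> str:
        payload = {
            "provenance": self.provenance,
            "roi": self.roi,
            "laterality": self.laterality.reset_index().to_dict("list"),
            "search_table": self.search_table.to_dict("list"),
            "winning_subset": list(self.winning_subset),
            "winning_fit": self.winning_fit,
            "vif": self.vif,
            "lv_tests": self.lv_tests,
            "hlm_normality": self.hlm_normality,
            "mmr": self.mmr_report,
            "behavior_fits": self.behavior_fits,
        }
        return json.dumps(payload, sort_keys=True, indent=1)


def _config_hash(config: PipelineConfig) -> str:
    canon = json.dumps(config.to_dict(), sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _band_freqs(band) -> np.ndarray:
    lo = int(np.ceil(band[0] - 1e-9))
    hi = int(np.floor(band[1] + 1e-9))
    return np.arange(float(lo), float(hi) + 0.5)


def subject_indices(epochs, config: PipelineConfig):
    """Spectral + laterality indices for one subject's epochs.

    Returns ``(mi_map, tfr_combined, trial_meta)``; the MI map covers all
    trials, the combined TFR is retained for condition-wise reuse.
    """
    freqs = _band_freqs(config.band)
    tfr = compute_tfr(epochs, freqs=freqs, n_cycles=config.n_cycles,
                      time_step=config.time_step,
                      tmin=config.window[0], tmax=config.window[1])
    tfr = combine_planar(tfr)
    side = epochs.trial_meta["cue_side"].to_numpy()
    p_r = band_window_average(tfr, config.band, config.window, side == "right")
    p_l = band_window_average(tfr, config.band, config.window, side == "left")
    mi = modulation_index(p_r, p_l, tfr.sensor_meta)
    return mi, tfr, epochs.trial_meta


def run_pipeline(config: PipelineConfig) -> ReportBundle:
    """Execute the full analysis and write the report bundle to
    ``config.out_dir``."""
    config.validate()
    logging.basicConfig(level=logging.INFO if config.verbose else logging.WARNING)

    def stage(name):
        logger.info("stage %s", name)
        return time.perf_counter()

    timings = {}

    # ---- load ----
    t0 = stage("load")
    try:
        volumes = _io.read_volume_table(config.volumes)
        behavior = _io.read_behavior(config.behavior)
    except (OSError, ValueError) as exc:
        raise PipelineError("load", str(exc)) from exc
    subjects = list(dict.fromkeys(volumes["subject_id"]))
    epochs_dir = Path(config.epochs_dir)
    epoch_paths = {}
    for subj in subjects:
        p = epochs_dir / f"{subj}.h5"
        if not p.exists():
            raise PipelineError("load", f"missing epoch file for subject {subj}: {p}")
        epoch_paths[subj] = p
    timings["load"] = time.perf_counter() - t0

    # ---- spectral + per-subject MI ----
    t0 = stage("spectral")
    mi_maps = {}
    tfrs = {}
    trial_metas = {}
    try:
        for subj in subjects:
            epochs = _io.read_epochs_h5(epoch_paths[subj])
            mi, tfr, tm = subject_indices(epochs, config)
            mi_maps[subj], tfrs[subj], trial_metas[subj] = mi, tfr, tm
    except ValueError as exc:
        raise PipelineError("spectral", f"subject {subj}: {exc}") from exc
    timings["spectral"] = time.perf_counter() - t0

    # ---- laterality ----
    t0 = stage("laterality")
    try:
        sensor_meta = mi_maps[subjects[0]].sensor_meta
        group_vals = np.mean([mi_maps[s].values for s in subjects], axis=0)
        group_mi = MIMap(values=group_vals, sensor_meta=sensor_meta)
        roi = select_roi(group_mi, config.n_roi_pairs)
        lv = lateralization_volume(volumes)
        beh_summary = summarize_behavior(behavior, config.rt_correct_only)
        records = []
        for subj in subjects:
            rec = {"subject_id": subj, "hlm": hlm(mi_maps[subj], roi)}
            rec.update(condition_hlm(tfrs[subj], roi, trial_metas[subj],
                                     config.band, config.window).to_dict())
            for s in config.structures:
                rec[f"LV_{s}"] = float(lv.loc[subj, s])
            rec["ba_acc"] = float(beh_summary.loc[subj, "ba_acc"])
            rec["ba_rt"] = float(beh_summary.loc[subj, "ba_rt"])
            records.append(rec)
        laterality = pd.DataFrame(records).set_index("subject_id")
    except (KeyError, ValueError) as exc:
        raise PipelineError("laterality", str(exc)) from exc
    timings["laterality"] = time.perf_counter() - t0

    # ---- model selection ----
    t0 = stage("glm_selection")
    try:
        lv_mat = lv[list(config.structures)]
        search = model_search(lv_mat, laterality["hlm"], config.criterion)
        winning = search.winning
        win_entry = next(e for e in search.entries if e["subset"] == winning)
        win_fit = win_entry["fit"]
        vifs = (vif(lv_mat[list(winning)]).to_dict()
                if len(winning) >= 2 else {})
        lv_tests = {}
        for s in config.structures:
            tstat, pval = one_sample_test(lv[s])
            lv_tests[s] = {"mean": float(lv[s].mean()),
                           "sd": float(lv[s].std(ddof=1)),
                           "t": tstat, "p": pval}
        w, p_norm = normality_check(laterality["hlm"])
        hlm_norm = {"W": w, "p": p_norm}
    except ValueError as exc:
        raise PipelineError("glm_selection", str(exc)) from exc
    timings["glm_selection"] = time.perf_counter() - t0

    # ---- multivariate regression ----
    t0 = stage("mmr")
    try:
        cond_cols = [c for c in laterality.columns if c.startswith("cond")]
        Y = laterality[cond_cols]
        key = list(config.key_structures)
        fit_key = fit_mmr(Y, lv_mat[key])
        fit_full = fit_mmr(Y, lv_mat)
        non_key = [s for s in config.structures if s not in key]
        fit_reduced = fit_mmr(Y, lv_mat[non_key]) if non_key else None
        fit_null = fit_mmr(Y, lv_mat[[]])  # intercept-only design
    except ValueError as exc:
        raise PipelineError("mmr", str(exc)) from exc
    try:
        full_vs_reduced = (compare_nested_mmr(fit_full, fit_reduced)
                           if fit_reduced is not None else None)
        key_vs_null = compare_nested_mmr(fit_key, fit_null)
        regressor_tests = {
            s: dataclasses.asdict(test_regressor_across_outcomes(fit_key, s))
            for s in key
        }
        mmr_report = {
            "coefficients": fit_key.to_dict(),
            "full_vs_reduced": (dataclasses.asdict(full_vs_reduced)
                                if full_vs_reduced else None),
            "key_vs_null": dataclasses.asdict(key_vs_null),
            "per_regressor": regressor_tests,
        }
    except ValueError as exc:
        raise PipelineError("mmr", str(exc)) from exc
    timings["mmr"] = time.perf_counter() - t0

    # ---- behavioral ----
    t0 = stage("behavioral")
    try:
        beh_fits = {}
        for metric in ("ba_acc", "ba_rt"):
            fit = fit_behavior_glm(laterality[metric], lv_mat,
                                   structures=config.key_structures)
            beh_fits[metric] = fit.to_dict()
    except ValueError as exc:
        raise PipelineError("behavioral", str(exc)) from exc
    timings["behavioral"] = time.perf_counter() - t0

    from . import __version__

    provenance = {
        "config": config.to_dict(),
        "config_hash": _config_hash(config),
        "seed": int(config.seed),
        "version": __version__,
        "n_subjects": len(subjects),
    }
    logger.info("stage timings: %s",
                {k: round(v, 3) for k, v in timings.items()})

    bundle = ReportBundle(
        laterality=laterality,
        search_table=search.table().drop(columns=[], errors="ignore"),
        winning_subset=winning,
        winning_fit=win_fit.to_dict(),
        vif=vifs,
        lv_tests=lv_tests,
        hlm_normality=hlm_norm,
        mmr_report=mmr_report,
        behavior_fits=beh_fits,
        provenance=provenance,
        roi={"pair_ids": [int(p) for p in roi.pair_ids],
             "left_sensors": list(roi.left_sensors),
             "right_sensors": list(roi.right_sensors),
             "differences": {str(k): float(v)
                             for k, v in roi.differences.items()}},
    )

    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        laterality.reset_index().to_csv(out / "laterality.csv", index=False)
        bundle.search_table.to_csv(out / "model_search.csv", index=False)
        (out / "report.json").write_text(bundle.to_json() + "\n")
    return bundle
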