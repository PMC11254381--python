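import json

import numpy as np
import pytest

from alphalat import (GeneratorConfig, draw_truth, generate_behavior,
                      generate_cohort, generate_epochs, generate_volumes,
                      lateralization_volume)
from alphalat.containers import STRUCTURES
from alphalat.pipeline import PipelineConfig, subject_indices


class TestGenerateVolumes:
    def test_zero_spread_gives_symmetric_volumes(self):
        cfg = GeneratorConfig(n_subjects=4)
        cfg.volume_asym_params = {s: (0.0, 0.0, 1000.0) for s in STRUCTURES}
        table, lv = generate_volumes(cfg, np.random.default_rng(0))
        assert np.all(lv.values == 0)
        wide = table.pivot_table(index=["subject_id", "structure"],
                                 columns="hemisphere", values="voxels")
        np.testing.assert_allclose(wide["left"], wide["right"])

    def test_inverse_algebra(self):
        # LV fixed at 0.01 with V_total 8000 -> volumes 4040 / 3960
        cfg = GeneratorConfig(n_subjects=1)
        cfg.volume_asym_params = {s: (0.01, 0.0, 8000.0) for s in STRUCTURES}
        table, _ = generate_volumes(cfg, np.random.default_rng(0))
        th = table[table.structure == "Th"].set_index("hemisphere")["voxels"]
        assert th["right"] == pytest.approx(4040.0)
        assert th["left"] == pytest.approx(3960.0)

    def test_lv_roundtrip_machine_precision(self):
        cfg = GeneratorConfig(n_subjects=6)
        table, lv = generate_volumes(cfg, np.random.default_rng(1))
        recovered = lateralization_volume(table)
        np.testing.assert_allclose(recovered.values, lv.values, rtol=0,
                                   atol=1e-15)

    def test_thalamus_population_mean(self):
        cfg = GeneratorConfig(n_subjects=10_000)
        _, lv = generate_volumes(cfg, np.random.default_rng(2))
        # population mean -0.0123, sd 0.0121 -> MC error ~1.2e-4
        assert lv["Th"].mean() == pytest.approx(-0.0123, abs=4e-4)
        assert lv["Th"].std() == pytest.approx(0.0121, abs=4e-4)


class TestDrawTruth:
    def test_hlm_is_linear_in_lv_plus_noise(self):
        cfg = GeneratorConfig(n_subjects=200, hlm_noise_sd=0.0)
        _, truth = draw_truth(cfg, np.random.default_rng(3))
        betas = np.array([cfg.coupling_betas[s] for s in STRUCTURES])
        expected = cfg.coupling_beta0 + truth.lv.values @ betas
        np.testing.assert_allclose(truth.hlm.values, expected, atol=1e-12)

    def test_condition_targets_average_to_overall(self):
        cfg = GeneratorConfig(n_subjects=20, condition_sd=0.05)
        _, truth = draw_truth(cfg, np.random.default_rng(4))
        np.testing.assert_allclose(truth.hlm_condition.mean(axis=1),
                                   truth.hlm, atol=1e-12)

    def test_condition_specific_coupling_mode(self):
        cfg = GeneratorConfig(n_subjects=150, hlm_noise_sd=0.0)
        cfg.condition_betas = {
            1: (0.0, {"Th": -3.63}), 2: (0.0, {"GP": 0.93}),
            3: (0.0, {"GP": 0.89}), 4: (0.0, {"CN": 1.64}),
        }
        _, truth = draw_truth(cfg, np.random.default_rng(5))
        np.testing.assert_allclose(truth.hlm_condition["cond1"],
                                   -3.63 * truth.lv["Th"], atol=1e-12)
        np.testing.assert_allclose(truth.hlm_condition["cond4"],
                                   1.64 * truth.lv["CN"], atol=1e-12)


class TestGenerateEpochs:
    def test_trial_counts_balanced(self):
        cfg = GeneratorConfig(n_trials_per_condition=16, n_sensor_pairs=4,
                              n_hotspot_pairs=2)
        st = {"subject_id": "s", "hlm_condition": np.zeros(4)}
        ep = generate_epochs(st, cfg, np.random.default_rng(0))
        counts = ep.trial_meta.groupby(["condition", "cue_side"]).size()
        assert set(counts) == {8}
        assert len(ep.trial_meta) == 64

    def test_sensor_pairing_structure(self):
        cfg = GeneratorConfig(n_sensor_pairs=5, n_trials_per_condition=4)
        st = {"subject_id": "s", "hlm_condition": np.zeros(4)}
        ep = generate_epochs(st, cfg, np.random.default_rng(0))
        by_pair = ep.sensor_meta.groupby("pair_id")
        for _, g in by_pair:
            assert sorted(g["hemisphere"]) == ["left", "left", "right", "right"]
            assert sorted(g["planar_channel_index"]) == [1, 1, 2, 2]

    def test_time_axis_spacing(self):
        cfg = GeneratorConfig(n_trials_per_condition=2, n_sensor_pairs=2,
                              n_hotspot_pairs=1)
        st = {"subject_id": "s", "hlm_condition": np.zeros(4)}
        ep = generate_epochs(st, cfg, np.random.default_rng(0))
        assert ep.times[0] == pytest.approx(cfg.epoch_window[0])
        np.testing.assert_allclose(np.diff(ep.times), 1.0 / cfg.sampling_rate)

    def test_noise_free_mi_targeting(self):
        # >= 100 trials per cue side, zero broadband noise: realized
        # per-sensor MI must hit the configured target within 1e-3
        cfg = GeneratorConfig(n_trials_per_condition=64, n_sensor_pairs=6,
                              n_hotspot_pairs=3, noise_amplitude=0.0)
        target_hlm = 0.04
        st = {"subject_id": "s", "hlm_condition": np.full(4, target_hlm)}
        ep = generate_epochs(st, cfg, np.random.default_rng(1))
        mi, _, _ = subject_indices(ep, PipelineConfig(n_roi_pairs=3))
        frac = np.where(mi.sensor_meta["pair_id"] < 3, 1.0, 0.25)
        sign = np.where(mi.sensor_meta["hemisphere"] == "right", 1.0, -1.0)
        expected = frac * (sign * cfg.modulation_depth + target_hlm / 2)
        np.testing.assert_allclose(mi.values, expected, atol=1e-3)

    def test_zero_modulation_gives_zero_mi(self):
        cfg = GeneratorConfig(n_trials_per_condition=32, n_sensor_pairs=4,
                              n_hotspot_pairs=2, modulation_depth=0.0,
                              noise_amplitude=0.2)
        st = {"subject_id": "s", "hlm_condition": np.zeros(4)}
        ep = generate_epochs(st, cfg, np.random.default_rng(2))
        mi, _, _ = subject_indices(ep, PipelineConfig(n_roi_pairs=2))
        assert np.abs(mi.values).max() < 0.05

    def test_invalid_power_ratio_rejected(self):
        cfg = GeneratorConfig(modulation_depth=0.9, n_trials_per_condition=4,
                              n_sensor_pairs=2, n_hotspot_pairs=1)
        st = {"subject_id": "s", "hlm_condition": np.full(4, 0.5)}
        with pytest.raises(ValueError, match="power ratio"):
            generate_epochs(st, cfg, np.random.default_rng(0))


class TestGenerateBehavior:
    def test_base_accuracy_recovered(self):
        cfg = GeneratorConfig(n_trials_per_condition=1000, base_accuracy=0.8)
        st = {"subject_id": "s"}
        beh = generate_behavior(st, cfg, np.random.default_rng(0))
        assert beh["correct"].mean() == pytest.approx(0.8, abs=0.02)

    def test_no_bias_gives_symmetric_accuracy(self):
        cfg = GeneratorConfig(n_trials_per_condition=2000)
        st = {"subject_id": "s"}
        beh = generate_behavior(st, cfg, np.random.default_rng(1))
        by_side = beh.groupby("cue_side")["correct"].mean()
        ba = (by_side["right"] - by_side["left"]) / (by_side["right"] + by_side["left"])
        assert abs(ba) < 0.02

    def test_lognormal_median(self):
        cfg = GeneratorConfig(n_trials_per_condition=2000, rt_log_sigma=0.2)
        st = {"subject_id": "s"}
        beh = generate_behavior(st, cfg, np.random.default_rng(2))
        assert np.median(beh["rt"]) == pytest.approx(np.exp(cfg.rt_log_mu),
                                                     rel=0.03)

    def test_invalid_probability_rejected(self):
        cfg = GeneratorConfig(acc_side_bias=0.6, base_accuracy=0.8,
                              n_trials_per_condition=4)
        with pytest.raises(ValueError, match="probability"):
            generate_behavior({"subject_id": "s"}, cfg,
                              np.random.default_rng(0))


class TestGenerateCohort:
    def test_file_counts_and_truth_shape(self, tiny_cohort, tiny_config):
        files = sorted(tiny_cohort["epochs_dir"].glob("*.h5"))
        assert len(files) == tiny_config.n_subjects
        assert tiny_cohort["truth"].lv.shape == (tiny_config.n_subjects, 7)

    def test_ground_truth_roundtrips_coupling(self, tiny_cohort, tiny_config):
        payload = json.loads(tiny_cohort["ground_truth"].read_text())
        assert payload["truth"]["coupling_betas"] == {
            k: float(v) for k, v in tiny_config.coupling_betas.items()}

    def test_seed_determinism(self, tmp_path):
        cfg = GeneratorConfig(n_subjects=2, n_trials_per_condition=8,
                              n_sensor_pairs=3, n_hotspot_pairs=2, seed=99)
        a = generate_cohort(cfg, tmp_path / "a")
        b = generate_cohort(cfg, tmp_path / "b")
        assert (a["ground_truth"].read_bytes() == b["ground_truth"].read_bytes())
        assert (a["volumes"].read_bytes() == b["volumes"].read_bytes())
        assert (a["behavior"].read_bytes() == b["behavior"].read_bytes())
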