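import numpy as np
import pandas as pd
import pytest

from alphalat import GeneratorConfig, generate_cohort
from alphalat.containers import MIMap
from alphalat.synthetic import _sensor_meta


def paired_sensor_meta(n_pairs: int, combined: bool = True) -> pd.DataFrame:
    """Pair-combined sensor metadata with n_pairs mirror-symmetric locations."""
    cfg = GeneratorConfig(n_sensor_pairs=n_pairs, n_hotspot_pairs=1)
    meta = _sensor_meta(cfg)
    if not combined:
        return meta
    meta = meta[meta["planar_channel_index"] == 1].copy()
    meta["label"] = [l.rsplit("_", 1)[0] for l in meta["label"]]
    return meta.drop(columns="planar_channel_index").reset_index(drop=True)


def random_mi_map(n_pairs: int, rng: np.random.Generator) -> MIMap:
    meta = paired_sensor_meta(n_pairs)
    return MIMap(values=rng.uniform(-0.5, 0.5, size=len(meta)), sensor_meta=meta)


@pytest.fixture(scope="session")
def tiny_config() -> GeneratorConfig:
    """Desk-scale cohort: 14 subjects, 16 trials/condition, 6 sensor pairs."""
    return GeneratorConfig(n_subjects=14, n_trials_per_condition=16,
                           n_sensor_pairs=6, n_hotspot_pairs=3, seed=7)


@pytest.fixture(scope="session")
def tiny_cohort(tiny_config, tmp_path_factory):
    out = tmp_path_factory.mktemp("cohort")
    paths = generate_cohort(tiny_config, out)
    paths["dir"] = out
    paths["config"] = tiny_config
    return paths


@pytest.fixture(scope="session")
def tiny_bundle(tiny_cohort):
    from alphalat import PipelineConfig, run_pipeline

    cfg = PipelineConfig.for_cohort(tiny_cohort["dir"], n_roi_pairs=3)
    return run_pipeline(cfg), cfg
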