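"""Shared fixtures: tiny deterministic cohorts and trained models.

Everything is generated programmatically at test time; no stored data.
"""

from __future__ import annotations

import numpy as np
import pytest

from octmark.globalfeat import GlobalTrainConfig
from octmark.local import LocalTrainConfig, fit_local_encoder
from octmark.pipeline import PipelineConfig
from octmark.simulate import CohortGenConfig, generate_cohort
from octmark.volume import OCTVolume, ScanGeometry


def make_volume(rng: np.random.Generator, dims=(8, 4, 16), scan_id="s") -> OCTVolume:
    arr = rng.random(dims, dtype=np.float32)
    # pin the range so min-max normalisation is the identity
    arr.flat[0] = 0.0
    arr.flat[-1] = 1.0
    return OCTVolume(intensities=arr, geometry=ScanGeometry(dims=dims), scan_id=scan_id)


@pytest.fixture(scope="session")
def tiny_cohort_cfg() -> CohortGenConfig:
    return CohortGenConfig(
        n_patients=12, split=(9, 3), geometry=ScanGeometry(dims=(32, 16, 96)), seed=11
    )


@pytest.fixture(scope="session")
def tiny_cohort(tiny_cohort_cfg):
    scans, table = generate_cohort(tiny_cohort_cfg)
    return scans, table


def tiny_pipeline_config(seed: int = 11) -> PipelineConfig:
    return PipelineConfig(
        cohort=CohortGenConfig(
            n_patients=12, split=(9, 3), geometry=ScanGeometry(dims=(32, 16, 96)), seed=seed
        ),
        local=LocalTrainConfig(code_dim=8, hidden=(48, 16), epochs=4, columns_per_volume=48,
                               batch_size=64),
        global_cfg=GlobalTrainConfig(code_dim=8, pool_shape=(8, 4), hidden=(64, 16), epochs=30),
        folds=3,
        seed=seed,
    )


@pytest.fixture(scope="session")
def trained_local(tiny_cohort):
    """A briefly trained per-A-scan encoder on the tiny cohort."""
    scans, _ = tiny_cohort
    vols = [v for v, _ in scans]
    cfg = LocalTrainConfig(code_dim=8, hidden=(48, 16), epochs=8, columns_per_volume=64,
                           batch_size=64)
    return fit_local_encoder(vols, cfg, seed=7)
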