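"""Per-A-scan auto-encoder: training, encoding, locality and summaries."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from octmark.errors import ValidationError
from octmark.local import (
    LocalFeatureVolume,
    LocalTrainConfig,
    encode_volume,
    fit_local_encoder,
    init_local_encoder,
    load_local_model,
    mean_activation,
    reconstruct_volume,
    save_local_model,
)
from octmark.volume import OCTVolume, ScanGeometry

from conftest import make_volume

SMALL_CFG = LocalTrainConfig(code_dim=6, hidden=(32, 12), epochs=10, columns_per_volume=64,
                             batch_size=64)


def _constant_volume(value: float, dims=(6, 4, 32)) -> OCTVolume:
    return OCTVolume(intensities=np.full(dims, value, np.float32),
                     geometry=ScanGeometry(dims=dims))


# ---------------------------------------------------------------------------
# training

def test_training_beats_random_init_on_held_out():
    rng = np.random.default_rng(0)
    train = [make_volume(rng, dims=(8, 6, 32), scan_id=f"t{i}") for i in range(6)]
    held_out = make_volume(rng, dims=(8, 6, 32), scan_id="h")
    x = held_out.intensities.reshape(-1, 32)
    baseline = init_local_encoder(32, SMALL_CFG, seed=5).ae.reconstruction_mse(x)
    model = fit_local_encoder(train, SMALL_CFG, seed=5)
    assert model.ae.reconstruction_mse(x) < baseline
    assert model.loss_trace[-1] <= model.loss_trace[0]


def test_constant_ascans_reach_near_zero_mse():
    vols = [_constant_volume(0.5) for _ in range(3)]
    cfg = LocalTrainConfig(code_dim=4, hidden=(16,), epochs=60, columns_per_volume=24,
                           batch_size=24, lr=5e-3)
    model = fit_local_encoder(vols, cfg, seed=2)
    x = vols[0].intensities.reshape(-1, 32)
    assert model.ae.reconstruction_mse(x) < 1e-3


def test_same_seed_identical_loss_trace():
    rng = np.random.default_rng(1)
    vols = [make_volume(rng, dims=(6, 4, 32)) for _ in range(3)]
    m1 = fit_local_encoder(vols, SMALL_CFG, seed=9)
    m2 = fit_local_encoder(vols, SMALL_CFG, seed=9)
    assert m1.loss_trace == m2.loss_trace
    assert m1.model_hash == m2.model_hash


def test_inconsistent_depths_rejected():
    rng = np.random.default_rng(2)
    vols = [make_volume(rng, dims=(4, 4, 32)), make_volume(rng, dims=(4, 4, 16))]
    with pytest.raises(ValidationError):
        fit_local_encoder(vols, SMALL_CFG, seed=0)


def test_non_compressive_code_warns():
    with pytest.warns(UserWarning, match="not compressive"):
        init_local_encoder(4, LocalTrainConfig(code_dim=8, hidden=(16,)), seed=0)


# ---------------------------------------------------------------------------
# encoding

def test_encode_shape_contract(trained_local, tiny_cohort):
    scans, _ = tiny_cohort
    vol = scans[0][0]
    fv = encode_volume(trained_local, vol)
    w, h, _ = vol.dims
    assert fv.activations.shape == (w, h, trained_local.code_dim)
    assert np.all(np.isfinite(fv.activations))


def test_encoding_is_local_to_columns():
    """Changing one A-scan changes exactly one (x, y) position of the maps."""
    rng = np.random.default_rng(3)
    model = init_local_encoder(32, SMALL_CFG, seed=1)
    v1 = make_volume(rng, dims=(6, 4, 32))
    arr = v1.intensities.copy()
    arr[2, 3, :] = np.linspace(0, 1, 32, dtype=np.float32)
    v2 = OCTVolume(intensities=arr, geometry=v1.geometry)
    f1 = encode_volume(model, v1).activations
    f2 = encode_volume(model, v2).activations
    diff = np.abs(f1 - f2).sum(axis=2)
    assert diff[2, 3] > 0
    diff[2, 3] = 0
    assert np.all(diff == 0)


def test_constant_volume_gives_uniform_code():
    model = init_local_encoder(32, SMALL_CFG, seed=1)
    fv = encode_volume(model, _constant_volume(0.25))
    first = fv.activations[0, 0]
    np.testing.assert_allclose(fv.activations, np.broadcast_to(first, fv.activations.shape),
                               atol=1e-6)


def test_position_permutation_equivariance():
    """Permuting A-scan positions permutes the maps identically and leaves
    the mean activation unchanged."""
    rng = np.random.default_rng(4)
    model = init_local_encoder(32, SMALL_CFG, seed=2)
    vol = make_volume(rng, dims=(6, 4, 32))
    perm_x = rng.permutation(6)
    perm_y = rng.permutation(4)
    permuted = OCTVolume(intensities=vol.intensities[perm_x][:, perm_y],
                         geometry=vol.geometry)
    f = encode_volume(model, vol)
    fp = encode_volume(model, permuted)
    np.testing.assert_allclose(fp.activations, f.activations[perm_x][:, perm_y], atol=1e-7)
    np.testing.assert_allclose(mean_activation(fp), mean_activation(f), atol=1e-7)


def test_depth_mismatch_rejected(trained_local):
    bad = _constant_volume(0.3, dims=(4, 4, 48))
    with pytest.raises(ValidationError):
        encode_volume(trained_local, bad)


# ---------------------------------------------------------------------------
# reconstruction

def test_reconstruct_trained_constant_volume():
    vols = [_constant_volume(0.5) for _ in range(3)]
    cfg = LocalTrainConfig(code_dim=4, hidden=(16,), epochs=60, columns_per_volume=24,
                           batch_size=24, lr=5e-3)
    model = fit_local_encoder(vols, cfg, seed=3)
    recon = reconstruct_volume(model, encode_volume(model, vols[0]))
    assert np.abs(recon.intensities - 0.5).max() < 0.05


def test_reconstruct_shape_mismatch_rejected(trained_local):
    bad = LocalFeatureVolume(activations=np.zeros((4, 4, trained_local.code_dim + 1), np.float32))
    with pytest.raises(ValidationError):
        reconstruct_volume(trained_local, bad)


def test_zero_code_reconstruction_is_defined(trained_local):
    zeros = LocalFeatureVolume(
        activations=np.zeros((2, 2, trained_local.code_dim), np.float32))
    out = reconstruct_volume(trained_local, zeros)
    assert out.dims == (2, 2, trained_local.input_dim)
    assert np.all(np.isfinite(out.intensities))


# ---------------------------------------------------------------------------
# mean activation

def test_mean_activation_constants():
    arr = np.zeros((4, 4, 3), np.float32)
    arr[..., 0] = 0.7
    arr[:2, :, 1] = 1.0  # half the positions
    m = mean_activation(LocalFeatureVolume(activations=arr))
    assert m[0] == pytest.approx(0.7, rel=1e-6)
    assert m[1] == pytest.approx(0.5)
    assert m[2] == 0.0


@settings(deadline=None, derandomize=True, max_examples=25)
@given(st.integers(0, 2**31 - 1))
def test_mean_activation_matches_brute_force(seed):
    rng = np.random.default_rng(seed)
    arr = rng.normal(size=(4, 4, 20)).astype(np.float32)
    m = mean_activation(LocalFeatureVolume(activations=arr))
    # independent summation oracle
    for k in range(20):
        total = 0.0
        for x in range(4):
            for y in range(4):
                total += float(arr[x, y, k])
        assert m[k] == pytest.approx(total / 16.0, rel=1e-10, abs=1e-12)


# ---------------------------------------------------------------------------
# checkpoints

def test_checkpoint_round_trip(trained_local, tmp_path):
    path = save_local_model(trained_local, tmp_path / "local.h5")
    back = load_local_model(path)
    assert back.model_hash == trained_local.model_hash
    assert back.config == trained_local.config
    x = np.random.default_rng(0).random((5, trained_local.input_dim))
    np.testing.assert_array_equal(back.ae.encode(x), trained_local.ae.encode(x))
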