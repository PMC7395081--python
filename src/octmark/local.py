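"""Stage one: per-A-scan auto-encoder and local feature maps.

Each depth column (A-scan, length D) of an OCT volume is mapped
independently through a dense auto-encoder to a 20-dimensional code.
Evaluated at every (x, y) scanning position this yields 20 en-face
feature maps (a1–a20) per volume; their per-map means form a compact
20-number summary of the whole scan.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np

from .errors import ValidationError
from .nn import DenseAutoencoder
from .volume import OCTVolume, ScanGeometry

LOCAL_FEATURE_NAMES = tuple(f"a{i}" for i in range(1, 21))


@dataclass(frozen=True)
class LocalTrainConfig:
    """Training configuration for the per-A-scan auto-encoder.

    ``columns_per_volume`` A-scans are sampled uniformly (without
    replacement) from each volume in every epoch, so training cost is
    independent of the 65,536 columns of a full-size cube.
    """

    code_dim: int = 20
    hidden: tuple[int, ...] = (256, 64)
    epochs: int = 30
    columns_per_volume: int = 128
    batch_size: int = 256
    lr: float = 1e-3

    def __post_init__(self) -> None:
        if self.code_dim < 1 or self.epochs < 1 or self.columns_per_volume < 1:
            raise ValidationError("code_dim, epochs and columns_per_volume must be >= 1")


@dataclass
class LocalEncoderModel:
    """A trained (or freshly initialised) per-A-scan auto-encoder."""

    ae: DenseAutoencoder
    input_dim: int
    config: LocalTrainConfig
    seed: int
    loss_trace: list[float] = field(default_factory=list)

    @property
    def code_dim(self) -> int:
        return self.ae.code_dim

    @property
    def model_hash(self) -> str:
        h = hashlib.sha256()
        for arr in self.ae.state_dict().values():
            h.update(np.ascontiguousarray(arr).tobytes())
        return h.hexdigest()[:16]


@dataclass
class LocalFeatureVolume:
    """Per-position 20-vector codes for one scan: shape (W, H, code_dim)."""

    activations: np.ndarray
    scan_id: str = ""
    model_hash: str = ""
    geometry: ScanGeometry | None = None

    def __post_init__(self) -> None:
        arr = np.asarray(self.activations, dtype=np.float32)
        if arr.ndim != 3:
            raise ValidationError("activations must be (W, H, code_dim)")
        if not np.all(np.isfinite(arr)):
            raise ValidationError("activations contain non-finite values")
        self.activations = arr

    @property
    def feature_names(self) -> tuple[str, ...]:
        return tuple(f"a{i}" for i in range(1, self.activations.shape[2] + 1))


def init_local_encoder(
    input_dim: int = 1024, config: LocalTrainConfig | None = None, seed: int = 0
) -> LocalEncoderModel:
    """Build a randomly initialised model without training (useful as the
    pre-training baseline in reconstruction comparisons)."""
    config = config or LocalTrainConfig()
    if config.code_dim >= input_dim:
        warnings.warn(
            f"code_dim {config.code_dim} >= input_dim {input_dim}: embedding is not compressive",
            stacklevel=2,
        )
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x10C4]))
    ae = DenseAutoencoder(
        input_dim=input_dim, hidden=config.hidden, code_dim=config.code_dim,
        rng=rng, lr=config.lr,
    )
    return LocalEncoderModel(ae=ae, input_dim=input_dim, config=config, seed=seed)


def sample_columns(
    volumes: Sequence[OCTVolume], per_volume: int, rng: np.random.Generator
) -> np.ndarray:
    """Uniformly sample A-scans: (n_volumes * per_volume, D) array."""
    cols = []
    for vol in volumes:
        w, h, d = vol.dims
        n = min(per_volume, w * h)
        idx = rng.choice(w * h, size=n, replace=False)
        flat = vol.intensities.reshape(w * h, d)
        cols.append(flat[idx])
    return np.concatenate(cols, axis=0)


def fit_local_encoder(
    volumes: Sequence[OCTVolume],
    config: LocalTrainConfig | None = None,
    seed: int = 0,
) -> LocalEncoderModel:
    """Train the per-A-scan auto-encoder on sampled depth columns.

    All volumes must share a common depth D (the network input length).
    Training is deterministic given ``seed``, the data and the config.
    """
    if not volumes:
        raise ValidationError("need at least one volume")
    depths = {vol.dims[2] for vol in volumes}
    if len(depths) != 1:
        raise ValidationError(f"volumes have inconsistent depths: {sorted(depths)}")
    config = config or LocalTrainConfig()
    input_dim = depths.pop()
    model = init_local_encoder(input_dim, config, seed)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x10C5]))
    for _ in range(config.epochs):
        x = sample_columns(volumes, config.columns_per_volume, rng)
        loss = model.ae.train_epoch(x, config.batch_size, rng)
        model.loss_trace.append(loss)
    return model


def encode_volume(model: LocalEncoderModel, vol: OCTVolume) -> LocalFeatureVolume:
    """Map every A-scan of ``vol`` through the encoder: (W, H, code_dim)."""
    w, h, d = vol.dims
    if d != model.input_dim:
        raise ValidationError(f"volume depth {d} != model input_dim {model.input_dim}")
    codes = model.ae.encode(vol.intensities.reshape(w * h, d))
    return LocalFeatureVolume(
        activations=codes.reshape(w, h, model.code_dim).astype(np.float32),
        scan_id=vol.scan_id,
        model_hash=model.model_hash,
        geometry=vol.geometry,
    )


def reconstruct_volume(model: LocalEncoderModel, features: LocalFeatureVolume) -> OCTVolume:
    """Decode a feature volume back to image space (clipped to [0, 1])."""
    arr = features.activations
    w, h, c = arr.shape
    if c != model.code_dim:
        raise ValidationError(f"feature depth {c} != model code_dim {model.code_dim}")
    recon = model.ae.decode(arr.reshape(w * h, c).astype(np.float64))
    recon = np.clip(recon, 0.0, 1.0).reshape(w, h, model.input_dim).astype(np.float32)
    geometry = features.geometry or ScanGeometry(dims=(w, h, model.input_dim))
    return OCTVolume(intensities=recon, geometry=geometry, scan_id=features.scan_id)


def mean_activation(features: LocalFeatureVolume) -> np.ndarray:
    """Per-feature mean over all W*H positions: the 20-number scan summary."""
    return np.asarray(features.activations, dtype=np.float64).mean(axis=(0, 1))


# ---------------------------------------------------------------------------
# checkpoints

def save_local_model(model: LocalEncoderModel, path: str | Path) -> Path:
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.attrs["kind"] = "octmark-local-encoder"
        f.attrs["input_dim"] = model.input_dim
        f.attrs["seed"] = model.seed
        f.attrs["config"] = json.dumps(
            {
                "code_dim": model.config.code_dim,
                "hidden": list(model.config.hidden),
                "epochs": model.config.epochs,
                "columns_per_volume": model.config.columns_per_volume,
                "batch_size": model.config.batch_size,
                "lr": model.config.lr,
            }
        )
        f.create_dataset("loss_trace", data=np.asarray(model.loss_trace))
        g = f.create_group("weights")
        for k, v in model.ae.state_dict().items():
            g.create_dataset(k, data=v)
    return path


def load_local_model(path: str | Path) -> LocalEncoderModel:
    with h5py.File(path, "r") as f:
        if f.attrs.get("kind") != "octmark-local-encoder":
            raise ValidationError(f"{path} is not a local-encoder checkpoint")
        cfg = json.loads(f.attrs["config"])
        config = LocalTrainConfig(
            code_dim=cfg["code_dim"], hidden=tuple(cfg["hidden"]), epochs=cfg["epochs"],
            columns_per_volume=cfg["columns_per_volume"], batch_size=cfg["batch_size"],
            lr=cfg["lr"],
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = init_local_encoder(int(f.attrs["input_dim"]), config, int(f.attrs["seed"]))
        model.ae.load_state_dict({k: v[()] for k, v in f["weights"].items()})
        model.loss_trace = list(f["loss_trace"][()])
    return model
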