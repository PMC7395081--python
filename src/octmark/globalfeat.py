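"""Stage two: volume-level auto-encoder over local feature volumes.

The (W, H, 20) grid of stage-one codes is average-pooled to a fixed
coarse en-face grid, standardised per feature over the training cohort,
flattened, and compressed by a second dense auto-encoder to 20 global
numbers per scan (v1–v20). Stage two consumes frozen stage-one codes;
the two stages are never trained jointly.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np
import pandas as pd

from .errors import ValidationError
from .local import LocalEncoderModel, LocalFeatureVolume, encode_volume, mean_activation
from .nn import DenseAutoencoder
from .volume import OCTVolume

GLOBAL_FEATURE_NAMES = tuple(f"v{i}" for i in range(1, 21))


@dataclass(frozen=True)
class GlobalTrainConfig:
    """Training configuration for the volume-level auto-encoder.

    ``pool_shape`` is the coarse (x, y) grid the feature maps are
    average-pooled to before the dense network; it makes the model
    independent of the exact acquisition grid while preserving coarse
    topography.
    """

    code_dim: int = 20
    pool_shape: tuple[int, int] = (16, 8)
    hidden: tuple[int, ...] = (256, 64)
    epochs: int = 60  # beyond this the net memorises desk-scale cohorts
    batch_size: int = 32
    lr: float = 1e-3

    def __post_init__(self) -> None:
        if self.code_dim < 1 or self.epochs < 1:
            raise ValidationError("code_dim and epochs must be >= 1")
        if min(self.pool_shape) < 1:
            raise ValidationError("pool_shape must be positive")


@dataclass
class GlobalEncoderModel:
    """A trained volume-level auto-encoder with its pooling/standardisation."""

    ae: DenseAutoencoder
    n_local_features: int
    feature_mean: np.ndarray  # (code_dim_local,) per-feature z-score stats
    feature_std: np.ndarray
    config: GlobalTrainConfig
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
        h.update(self.feature_mean.tobytes())
        h.update(self.feature_std.tobytes())
        return h.hexdigest()[:16]


@dataclass
class GlobalFeatureVector:
    """The 20 global numbers summarising one scan."""

    values: np.ndarray
    scan_id: str = ""
    model_hash: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64).ravel()
        if not np.all(np.isfinite(v)):
            raise ValidationError("global features must be finite")
        self.values = v


def pool_features(activations: np.ndarray, pool_shape: tuple[int, int]) -> np.ndarray:
    """Average-pool a (W, H, C) grid to (pw, ph, C) by block means."""
    arr = np.asarray(activations, dtype=np.float64)
    pw, ph = pool_shape
    blocks_x = np.array_split(np.arange(arr.shape[0]), pw)
    blocks_y = np.array_split(np.arange(arr.shape[1]), ph)
    out = np.empty((pw, ph, arr.shape[2]))
    for i, bx in enumerate(blocks_x):
        sub = arr[bx].mean(axis=0)
        for j, by in enumerate(blocks_y):
            out[i, j] = sub[by].mean(axis=0)
    return out


def _pooled_matrix(
    feature_volumes: Sequence[LocalFeatureVolume], pool_shape: tuple[int, int]
) -> np.ndarray:
    pooled = [pool_features(fv.activations, pool_shape) for fv in feature_volumes]
    return np.stack([p.reshape(-1) for p in pooled])  # (n, pw*ph*C)


def fit_global_encoder(
    feature_volumes: Sequence[LocalFeatureVolume],
    config: GlobalTrainConfig | None = None,
    seed: int = 0,
) -> GlobalEncoderModel:
    """Train the volume-level auto-encoder on pooled local feature volumes."""
    if not feature_volumes:
        raise ValidationError("need at least one feature volume")
    shapes = {fv.activations.shape for fv in feature_volumes}
    if len(shapes) != 1:
        raise ValidationError(f"feature volumes have inconsistent shapes: {sorted(shapes)}")
    config = config or GlobalTrainConfig()
    n_local = feature_volumes[0].activations.shape[2]
    x = _pooled_matrix(feature_volumes, config.pool_shape)
    # per local-feature z-score over the training cohort (pooled positions share stats)
    xc = x.reshape(len(feature_volumes), -1, n_local)
    mean = xc.mean(axis=(0, 1))
    std = xc.std(axis=(0, 1))
    std = np.where(std > 1e-12, std, 1.0)
    x = ((xc - mean) / std).reshape(len(feature_volumes), -1)

    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x610B]))
    ae = DenseAutoencoder(
        input_dim=x.shape[1], hidden=config.hidden, code_dim=config.code_dim,
        rng=rng, lr=config.lr,
    )
    model = GlobalEncoderModel(
        ae=ae, n_local_features=n_local, feature_mean=mean, feature_std=std,
        config=config, seed=seed,
    )
    for _ in range(config.epochs):
        model.loss_trace.append(ae.train_epoch(x, config.batch_size, rng))
    return model


def init_global_encoder(
    feature_volumes: Sequence[LocalFeatureVolume],
    config: GlobalTrainConfig | None = None,
    seed: int = 0,
) -> GlobalEncoderModel:
    """Randomly initialised stage-two model (pre-training baseline); the
    standardisation statistics are still computed from the given cohort."""
    config = config or GlobalTrainConfig()
    n_local = feature_volumes[0].activations.shape[2]
    x = _pooled_matrix(feature_volumes, config.pool_shape)
    xc = x.reshape(len(feature_volumes), -1, n_local)
    mean = xc.mean(axis=(0, 1))
    std = xc.std(axis=(0, 1))
    std = np.where(std > 1e-12, std, 1.0)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x610B]))
    ae = DenseAutoencoder(
        input_dim=x.shape[1], hidden=config.hidden, code_dim=config.code_dim,
        rng=rng, lr=config.lr,
    )
    return GlobalEncoderModel(
        ae=ae, n_local_features=n_local, feature_mean=mean, feature_std=std,
        config=config, seed=seed,
    )


def prepare_input(model: GlobalEncoderModel, features: LocalFeatureVolume) -> np.ndarray:
    """Pool + standardise one feature volume into the stage-two input vector."""
    arr = features.activations
    if arr.shape[2] != model.n_local_features:
        raise ValidationError(
            f"feature volume has {arr.shape[2]} local features, model expects {model.n_local_features}"
        )
    pooled = pool_features(arr, model.config.pool_shape)
    z = (pooled - model.feature_mean) / model.feature_std
    flat = z.reshape(-1)
    if flat.size != model.ae.input_dim:
        raise ValidationError(
            f"pooled input length {flat.size} != model input_dim {model.ae.input_dim}"
        )
    return flat


def encode_global(model: GlobalEncoderModel, features: LocalFeatureVolume) -> GlobalFeatureVector:
    """Compress one local feature volume to its global 20-vector."""
    flat = prepare_input(model, features)
    codes = model.ae.encode(flat[None, :])[0]
    return GlobalFeatureVector(values=codes, scan_id=features.scan_id, model_hash=model.model_hash)


def encode_cohort(
    local_model: LocalEncoderModel,
    global_model: GlobalEncoderModel,
    volumes: Sequence[OCTVolume],
) -> pd.DataFrame:
    """Encode a cohort with both representations.

    Returns one row per scan, in input order, with columns ``scan_id``,
    mean activations ``a1..aK`` and global features ``v1..vK``.
    """
    rows = []
    for vol in volumes:
        fv = encode_volume(local_model, vol)
        means = mean_activation(fv)
        gv = encode_global(global_model, fv)
        row = {"scan_id": vol.scan_id}
        row.update({f"a{i + 1}": means[i] for i in range(len(means))})
        row.update({f"v{i + 1}": gv.values[i] for i in range(len(gv.values))})
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# checkpoints

def save_global_model(model: GlobalEncoderModel, path: str | Path) -> Path:
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.attrs["kind"] = "octmark-global-encoder"
        f.attrs["seed"] = model.seed
        f.attrs["n_local_features"] = model.n_local_features
        f.attrs["input_dim"] = model.ae.input_dim
        f.attrs["config"] = json.dumps(
            {
                "code_dim": model.config.code_dim,
                "pool_shape": list(model.config.pool_shape),
                "hidden": list(model.config.hidden),
                "epochs": model.config.epochs,
                "batch_size": model.config.batch_size,
                "lr": model.config.lr,
            }
        )
        f.create_dataset("feature_mean", data=model.feature_mean)
        f.create_dataset("feature_std", data=model.feature_std)
        f.create_dataset("loss_trace", data=np.asarray(model.loss_trace))
        g = f.create_group("weights")
        for k, v in model.ae.state_dict().items():
            g.create_dataset(k, data=v)
    return path


def load_global_model(path: str | Path) -> GlobalEncoderModel:
    with h5py.File(path, "r") as f:
        if f.attrs.get("kind") != "octmark-global-encoder":
            raise ValidationError(f"{path} is not a global-encoder checkpoint")
        cfg = json.loads(f.attrs["config"])
        config = GlobalTrainConfig(
            code_dim=cfg["code_dim"], pool_shape=tuple(cfg["pool_shape"]),
            hidden=tuple(cfg["hidden"]), epochs=cfg["epochs"],
            batch_size=cfg["batch_size"], lr=cfg["lr"],
        )
        ae = DenseAutoencoder(
            input_dim=int(f.attrs["input_dim"]), hidden=config.hidden,
            code_dim=config.code_dim, lr=config.lr,
        )
        ae.load_state_dict({k: v[()] for k, v in f["weights"].items()})
        model = GlobalEncoderModel(
            ae=ae,
            n_local_features=int(f.attrs["n_local_features"]),
            feature_mean=f["feature_mean"][()],
            feature_std=f["feature_std"][()],
            config=config,
            seed=int(f.attrs["seed"]),
        )
        model.loss_trace = list(f["loss_trace"][()])
    return model
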