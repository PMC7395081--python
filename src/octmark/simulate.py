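"""Synthetic OCT cohort generator with controlled ground truth.

Because real neovascular-AMD trial imaging is proprietary, this module
fabricates the whole study substrate: OCT-like volumes with layered
retinal anatomy (two smooth random layer surfaces, per-layer base
reflectivities, multiplicative speckle), planted exudative lesions (IRC,
SRF, PED, SHRM) rendered as ellipsoidal intensity perturbations with
exact voxel masks, and a per-scan clinical metadata table whose
statistical linkage to lesion burden is controlled by construction:

    BCVA = intercept - sum_c w_c * burden_c + N(0, sd)

with the noise SD chosen (by default) so that the generative R^2 of
visual acuity on the true burdens hits a configured value. Lesion
burdens follow zero-inflated log-normal distributions per class so that
many scans lack a given lesion, mimicking clinical prevalence
heterogeneity. Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import markers as _markers
from .errors import ValidationError
from .volume import LESION_CLASSES, OCTVolume, ScanGeometry, SegmentationMaskSet, minmax_normalize


@dataclass(frozen=True)
class LesionSpec:
    """One planted ellipsoidal lesion.

    ``center`` and ``semi_axes`` are in voxel coordinates/units
    (x, y, z). ``intensity_offset`` is added inside the ellipsoid:
    negative = hyporeflective (fluid), positive = hyperreflective.
    """

    lesion_class: str
    center: tuple[float, float, float]
    semi_axes: tuple[float, float, float]
    intensity_offset: float

    def __post_init__(self) -> None:
        if self.lesion_class not in LESION_CLASSES:
            raise ValidationError(f"unknown lesion class {self.lesion_class!r}")
        if min(self.semi_axes) <= 0:
            raise ValidationError("semi_axes must be positive")


@dataclass(frozen=True)
class LesionClassModel:
    """Population model of one lesion class.

    ``prevalence`` is the probability a scan carries the lesion at all;
    burdens of affected scans are log-normal (parameters on the log-nl
    scale). ``aspect`` gives the relative physical semi-axis proportions
    (x, y, z) — exudative lesions spread laterally, so the defaults are
    flattened pancakes. ``vision_weight`` is the letter-score loss per nl
    in the functional generative model.
    """

    prevalence: float
    log_mean_nl: float
    log_sd_nl: float
    intensity_offset: float
    aspect: tuple[float, float, float]
    vision_weight: float


@dataclass(frozen=True)
class FunctionalModel:
    """Generative model of a visual-function score (letter scale)."""

    intercept: float
    weight_scale: float = 1.0  # multiplies each class's vision_weight
    noise_sd: float | None = None  # explicit noise SD, letters
    target_r2: float = 0.6  # used when noise_sd is None


DEFAULT_LESION_MODELS: dict[str, LesionClassModel] = {
    "IRC": LesionClassModel(0.55, np.log(60.0), 0.9, -0.35, (1.8, 1.8, 0.31), 0.045),
    "SRF": LesionClassModel(0.50, np.log(80.0), 0.9, -0.30, (2.2, 2.2, 0.21), 0.030),
    "PED": LesionClassModel(0.45, np.log(120.0), 0.9, +0.28, (1.5, 1.5, 0.44), 0.012),
    "SHRM": LesionClassModel(0.35, np.log(40.0), 0.8, +0.32, (1.6, 1.6, 0.39), 0.060),
}


@dataclass(frozen=True)
class CohortGenConfig:
    """Full configuration of a synthetic cohort.

    Defaults mirror the study scale: 1094 patients, split 985/109, one
    baseline scan per patient on a 512 x 128 x 1024 grid over 6 x 6 x 2 mm.
    (Multi-visit generation is a config option via ``scans_per_patient``;
    repeat visits are independent redraws of the same patient's lesions.)
    """

    n_patients: int = 1094
    split: tuple[int, int] = (985, 109)
    geometry: ScanGeometry = field(default_factory=ScanGeometry)
    lesion_models: dict[str, LesionClassModel] = field(
        default_factory=lambda: dict(DEFAULT_LESION_MODELS)
    )
    bcva_model: FunctionalModel = FunctionalModel(intercept=62.0, target_r2=0.6)
    llva_model: FunctionalModel = FunctionalModel(intercept=45.0, weight_scale=1.3, target_r2=0.7)
    rt_base_um: float = 300.0
    rt_base_sd_um: float = 35.0
    rt_burden_um_per_nl: float = 0.30  # IRC+SRF thicken the retina
    surface_amplitude_um: float = 60.0
    speckle_sd: float = 0.12
    intensity_gain: float = 1.0
    max_lesions_per_class: int = 3
    scans_per_patient: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValidationError("n_patients must be >= 1")
        if self.split[0] + self.split[1] != self.n_patients:
            raise ValidationError(
                f"split {self.split} does not sum to n_patients={self.n_patients}"
            )
        if self.speckle_sd < 0:
            raise ValidationError("speckle_sd must be >= 0")


def scaled_config(n_patients: int = 200, seed: int = 0, **overrides) -> CohortGenConfig:
    """Desk-scale study conditions: the default cohort scaled to 200
    patients (split 180/20) on a reduced 64 x 32 x 256 grid."""
    n_test = max(1, round(n_patients * 109 / 1094))
    cfg = CohortGenConfig(
        n_patients=n_patients,
        split=(n_patients - n_test, n_test),
        geometry=ScanGeometry(dims=(64, 32, 256)),
        seed=seed,
    )
    return replace(cfg, **overrides) if overrides else cfg


def external_site_config(n_patients: int = 100, seed: int = 1000, **overrides) -> CohortGenConfig:
    """A second acquisition site: different gain, noise and burden mix;
    stands in for an external test population."""
    models = {
        cls: replace(m, log_mean_nl=m.log_mean_nl + 0.3, prevalence=min(1.0, m.prevalence * 1.1))
        for cls, m in DEFAULT_LESION_MODELS.items()
    }
    cfg = CohortGenConfig(
        n_patients=n_patients,
        split=(0, n_patients),
        geometry=ScanGeometry(dims=(64, 32, 256)),
        lesion_models=models,
        bcva_model=FunctionalModel(intercept=55.0, target_r2=0.6),
        speckle_sd=0.18,
        intensity_gain=0.8,
        seed=seed,
    )
    return replace(cfg, **overrides) if overrides else cfg


# ---------------------------------------------------------------------------
# single-volume rendering

def _smooth_field(rng: np.random.Generator, w: int, h: int, n_harmonics: int = 3) -> np.ndarray:
    """Low-frequency random en-face field in roughly [-1, 1]: a sum of a
    few random low-order 2D harmonics (mimics retinal curvature)."""
    x = np.arange(w)[:, None] / w
    y = np.arange(h)[None, :] / h
    out = np.zeros((w, h))
    for k in range(n_harmonics):
        fx, fy = rng.uniform(0.3, 1.8, size=2)
        phase = rng.uniform(0, 2 * np.pi)
        out += (0.5**k) * np.cos(2 * np.pi * (fx * x + fy * y) + phase)
    peak = np.abs(out).max()
    return out / peak if peak > 0 else out


def _check_lesion_fits(lesion: LesionSpec, dims: tuple[int, int, int]) -> None:
    for c, r, d in zip(lesion.center, lesion.semi_axes, dims):
        if c - r < -0.5 or c + r > d - 0.5:
            raise ValidationError(
                f"{lesion.lesion_class} lesion at {lesion.center} with semi-axes "
                f"{lesion.semi_axes} does not fit inside grid {dims}"
            )


def ellipsoid_mask(
    center: tuple[float, float, float],
    semi_axes: tuple[float, float, float],
    dims: tuple[int, int, int],
) -> np.ndarray:
    """Boolean (W, H, D) grid of voxels inside the ellipsoid
    ((x-cx)/rx)^2 + ((y-cy)/ry)^2 + ((z-cz)/rz)^2 <= 1."""
    w, h, d = dims
    cx, cy, cz = center
    rx, ry, rz = semi_axes
    xs = ((np.arange(w) - cx) / rx) ** 2
    ys = ((np.arange(h) - cy) / ry) ** 2
    zs = ((np.arange(d) - cz) / rz) ** 2
    return xs[:, None, None] + ys[None, :, None] + zs[None, None, :] <= 1.0


def generate_volume(
    lesions: list[LesionSpec],
    geometry: ScanGeometry | None = None,
    seed: int = 0,
    *,
    base_thickness_um: float = 300.0,
    surface_amplitude_um: float = 60.0,
    speckle_sd: float = 0.12,
    intensity_gain: float = 1.0,
    scan_id: str = "",
    patient_id: str = "",
) -> tuple[OCTVolume, SegmentationMaskSet]:
    """Render one synthetic scan plus its exact ground-truth masks.

    The volume contains smooth random layer surfaces, banded per-layer
    reflectivities, each lesion as an ellipsoidal intensity perturbation,
    and multiplicative speckle applied before min-max normalisation.
    Masks mark exactly the perturbed voxels. Identical seed + lesion list
    give bit-identical output.
    """
    geometry = geometry or ScanGeometry()
    w, h, d = geometry.dims
    dz_um = geometry.spacing_um[2]
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x51E0]))

    # --- layer surfaces (voxel units along z)
    inner = 0.30 * d + (surface_amplitude_um / dz_um) * _smooth_field(rng, w, h)
    thickness_vox = (base_thickness_um / dz_um) * (1.0 + 0.08 * _smooth_field(rng, w, h))
    thickness_vox = np.maximum(thickness_vox, 3.0)
    rpe = inner + thickness_vox
    inner = np.clip(inner, 1.0, d - 3.0)
    rpe = np.clip(rpe, inner + 2.0, d - 2.0)

    # --- banded reflectivity profile
    z = np.arange(d)[None, None, :]
    inner3 = inner[:, :, None]
    rpe3 = rpe[:, :, None]
    t3 = rpe3 - inner3
    img = np.full((w, h, d), 0.06)  # vitreous
    in_retina = (z >= inner3) & (z < rpe3)
    frac = np.where(in_retina, (z - inner3) / t3, 0.0)
    img = np.where(in_retina & (frac < 0.15), 0.55, img)  # RNFL/inner bands
    img = np.where(in_retina & (frac >= 0.15) & (frac < 0.75), 0.40, img)
    img = np.where(in_retina & (frac >= 0.75), 0.35, img)  # outer nuclear
    rpe_band = max(2.0, 0.008 * d)
    img = np.where((z >= rpe3) & (z < rpe3 + rpe_band), 0.88, img)  # RPE
    below = z >= rpe3 + rpe_band
    img = np.where(below, 0.10 + 0.25 * np.exp(-(z - rpe3 - rpe_band) / (0.12 * d)), img)

    # --- lesions
    masks = {cls: np.zeros((w, h, d), dtype=bool) for cls in LESION_CLASSES}
    for lesion in lesions:
        _check_lesion_fits(lesion, geometry.dims)
        m = ellipsoid_mask(lesion.center, lesion.semi_axes, geometry.dims)
        img[m] += lesion.intensity_offset
        masks[lesion.lesion_class] |= m

    # --- speckle, gain, normalisation
    if speckle_sd > 0:
        img = img * (1.0 + speckle_sd * rng.standard_normal(size=img.shape))
    img = np.clip(img * intensity_gain, 0.0, None)
    vol = OCTVolume(
        intensities=minmax_normalize(img),
        geometry=geometry,
        scan_id=scan_id,
        patient_id=patient_id,
    )
    maskset = SegmentationMaskSet(
        masks=masks, inner_surface=inner, rpe_surface=rpe, geometry=geometry, scan_id=scan_id
    )
    return vol, maskset


# ---------------------------------------------------------------------------
# cohort-level sampling

def _sample_burdens(cfg: CohortGenConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Zero-inflated log-normal burden (nl) per patient and lesion class."""
    n = cfg.n_patients
    cols = {}
    for cls, m in cfg.lesion_models.items():
        present = rng.random(n) < m.prevalence
        sizes = np.exp(rng.normal(m.log_mean_nl, m.log_sd_nl, size=n))
        cols[cls] = np.where(present, sizes, 0.0)
    return pd.DataFrame(cols, index=[f"P{i:04d}" for i in range(n)])


def _functional_score(
    model: FunctionalModel,
    burdens: pd.DataFrame,
    lesion_models: dict[str, LesionClassModel],
    rng: np.random.Generator,
) -> tuple[np.ndarray, float]:
    """Letter score = intercept - weighted burden + Gaussian noise.

    When ``noise_sd`` is None it is derived from ``target_r2`` and the
    realised signal variance via R^2 = Var(signal)/(Var(signal)+SD^2).
    Returns (scores clipped to [0, 100], noise SD used).
    """
    signal = model.intercept - sum(
        model.weight_scale * lesion_models[cls].vision_weight * burdens[cls].to_numpy()
        for cls in burdens.columns
    )
    if model.noise_sd is not None:
        sd = model.noise_sd
    else:
        var_sig = float(np.var(signal))
        sd = float(np.sqrt(var_sig * (1.0 - model.target_r2) / model.target_r2))
    scores = signal + rng.normal(0.0, sd, size=len(signal))
    return np.clip(scores, 0.0, 100.0), sd


def sample_cohort_metadata(cfg: CohortGenConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw the cohort's ground-truth burdens and metadata table without
    rendering any volumes (fast path for statistical checks).

    Returns ``(burdens, metadata)``: burdens holds the intended per-class
    lesion volumes in nl; metadata is a cohort table whose RT/IRC/SRF/PED
    columns carry the intended (pre-discretisation) values.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0xC0B0]))
    burdens = _sample_burdens(cfg, rng)
    n = cfg.n_patients
    bcva, _ = _functional_score(cfg.bcva_model, burdens, cfg.lesion_models, rng)
    llva, _ = _functional_score(cfg.llva_model, burdens, cfg.lesion_models, rng)
    rt = (
        cfg.rt_base_um
        + rng.normal(0.0, cfg.rt_base_sd_um, size=n)
        + cfg.rt_burden_um_per_nl * (burdens["IRC"] + burdens["SRF"]).to_numpy()
    )
    rt = np.maximum(rt, 120.0)
    total = burdens.sum(axis=1).to_numpy()
    # angiographic areas: monotone, noisy functions of total burden
    lesion_area = (1.0 + 0.05 * total ** (2.0 / 3.0)) * np.exp(rng.normal(0.0, 0.25, size=n))
    leakage_area = (0.5 + 0.06 * total ** (2.0 / 3.0)) * np.exp(rng.normal(0.0, 0.30, size=n))
    meta = pd.DataFrame(
        {
            "scan_id": [f"{pid}_S1" for pid in burdens.index],
            "BCVA": bcva,
            "LLVA": llva,
            "RT": rt,
            "IRC": burdens["IRC"].to_numpy(),
            "SRF": burdens["SRF"].to_numpy(),
            "PED": burdens["PED"].to_numpy(),
            "lesion_area": lesion_area,
            "leakage_area": leakage_area,
        }
    )
    return burdens, meta


def _lesions_for_patient(
    burdens_nl: dict[str, float],
    cfg: CohortGenConfig,
    rt_um: float,
    rng: np.random.Generator,
) -> list[LesionSpec]:
    """Turn intended per-class burdens into concrete ellipsoid specs placed
    in anatomically legal compartments near the fovea."""
    geom = cfg.geometry
    w, h, d = geom.dims
    dx, dy, dz = geom.spacing_um
    ex, ey = geom.lateral_extent_mm
    inner_mid = 0.30 * d  # nominal surface positions used for placement
    rpe_mid = inner_mid + rt_um / dz
    lesions: list[LesionSpec] = []
    for cls, burden in burdens_nl.items():
        if burden <= 0:
            continue
        m = cfg.lesion_models[cls]
        n_lesions = 1 + rng.integers(0, cfg.max_lesions_per_class)
        parts = rng.dirichlet(np.ones(n_lesions)) * burden
        for part in parts:
            if part < 1e-3:
                continue
            vol_um3 = part * 1.0e6
            ax, ay, az = m.aspect
            r = (3.0 * vol_um3 / (4.0 * np.pi * ax * ay * az)) ** (1.0 / 3.0)
            rx = max(ax * r / dx, 0.6)
            ry = max(ay * r / dy, 0.6)
            rz = max(az * r / dz, 0.6)
            # cap at a quarter of each grid extent so lesions always fit
            rx = min(rx, 0.25 * w)
            ry = min(ry, 0.25 * h)
            rz = min(rz, 0.15 * d)
            # lateral position: concentrated around the fovea (field centre)
            cx = np.clip(
                (ex / 2 + rng.normal(0, 1.0)) / ex * w, rx + 0.1, w - 1.1 - rx
            )
            cy = np.clip(
                (ey / 2 + rng.normal(0, 1.0)) / ey * h, ry + 0.1, h - 1.1 - ry
            )
            if cls == "IRC":  # intraretinal: between the surfaces
                cz = inner_mid + rng.uniform(0.3, 0.6) * (rpe_mid - inner_mid)
            elif cls in ("SRF", "SHRM"):  # subretinal: just above the RPE
                cz = rpe_mid - rz - 1.0
            else:  # PED: dome just below the RPE
                cz = rpe_mid + 0.6 * rz + 1.0
            cz = float(np.clip(cz, rz + 0.1, d - 1.1 - rz))
            lesions.append(
                LesionSpec(
                    lesion_class=cls,
                    center=(float(cx), float(cy), cz),
                    semi_axes=(float(rx), float(ry), float(rz)),
                    intensity_offset=m.intensity_offset,
                )
            )
    return lesions


def generate_cohort(
    cfg: CohortGenConfig,
) -> tuple[list[tuple[OCTVolume, SegmentationMaskSet]], pd.DataFrame]:
    """Generate the full cohort: rendered scans, exact masks and metadata.

    The morphology columns of the metadata table (RT, IRC, SRF, PED) are
    measured from the rendered ground-truth masks/surfaces, so they carry
    the same discretisation a segmentation-based reading would; the
    functional scores (BCVA, LLVA) follow the generative model on the
    intended burdens.
    """
    burdens, meta = sample_cohort_metadata(cfg)
    meta = meta.set_index("scan_id")
    scans: list[tuple[OCTVolume, SegmentationMaskSet]] = []
    rows = []
    for i, pid in enumerate(burdens.index):
        for visit in range(cfg.scans_per_patient):
            scan_id = f"{pid}_S{visit + 1}"
            base_id = f"{pid}_S1"
            rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0xA11, i, visit]))
            rt_um = float(meta.loc[base_id, "RT"])
            lesions = _lesions_for_patient(
                {cls: float(burdens.loc[pid, cls]) for cls in burdens.columns},
                cfg, rt_um, rng,
            )
            vol_seed = int(rng.integers(0, 2**31 - 1))
            vol, maskset = generate_volume(
                lesions,
                cfg.geometry,
                seed=vol_seed,
                base_thickness_um=rt_um,
                surface_amplitude_um=cfg.surface_amplitude_um,
                speckle_sd=cfg.speckle_sd,
                intensity_gain=cfg.intensity_gain,
                scan_id=scan_id,
                patient_id=pid,
            )
            scans.append((vol, maskset))
            measured = _markers.total_volumes_nl(maskset)
            row = meta.loc[base_id].to_dict()
            row["scan_id"] = scan_id
            row["RT"] = _markers.mean_retinal_thickness_um(maskset)
            for cls in ("IRC", "SRF", "PED"):
                row[cls] = measured[cls]
            rows.append(row)
    table = pd.DataFrame(rows)
    cols = ["scan_id", "BCVA", "LLVA", "RT", "IRC", "SRF", "PED", "lesion_area", "leakage_area"]
    return scans, table[cols]


def split_scan_ids(table: pd.DataFrame, cfg: CohortGenConfig, seed: int | None = None) -> tuple[list[str], list[str]]:
    """Seeded random train/test partition of scan_ids per the config split."""
    ids = list(table["scan_id"])
    n_train, n_test = cfg.split
    if n_train + n_test != len(ids):
        raise ValidationError(
            f"split {cfg.split} inconsistent with {len(ids)} scans"
        )
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed if seed is None else seed, 0x5711]))
    order = rng.permutation(len(ids))
    train = [ids[i] for i in order[:n_train]]
    test = [ids[i] for i in order[n_train:]]
    return train, test
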