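"""End-to-end study orchestration.

Two entry points:

* :func:`run_study` — the whole experiment in memory: simulate a cohort,
  train both auto-encoder stages on the training split, encode every
  scan, quantify the 21 conventional zone markers, and run the full
  statistical validation (correlation screen, per-target elastic-net
  regressions for both learned representations, conventional-marker
  comparison models for visual function, paired Wilcoxon verdicts, and
  an optional external-site evaluation).
* :func:`run_pipeline` — the same experiment as eight file-based stages
  with a content-hash manifest, so re-runs skip completed stages and a
  deleted intermediate triggers exactly the downstream stages.
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

from . import io as _io
from . import markers as _markers
from . import stats as _stats
from .errors import ValidationError
from .globalfeat import (
    GlobalTrainConfig,
    encode_cohort,
    encode_global,
    fit_global_encoder,
    load_global_model,
    save_global_model,
)
from .local import (
    LocalTrainConfig,
    encode_volume,
    fit_local_encoder,
    load_local_model,
    save_local_model,
)
from .simulate import (
    CohortGenConfig,
    external_site_config,
    generate_cohort,
    scaled_config,
    split_scan_ids,
)

log = logging.getLogger("octmark")

#: Clinical targets regressed from the learned representations.
ALL_TARGETS = ("BCVA", "LLVA", "RT", "IRC", "SRF", "PED", "lesion_area", "leakage_area")

#: Targets predicted from the conventional markers (visual function only,
#: since the conventional morphology enters as the model input there).
FUNCTION_TARGETS = ("BCVA", "LLVA")

STAGES = (
    "simulate",
    "train-local",
    "encode-local",
    "train-global",
    "encode-global",
    "markers",
    "validate",
    "report",
)


@dataclass(frozen=True)
class PipelineConfig:
    """Everything needed to reproduce one study run."""

    cohort: CohortGenConfig = field(default_factory=scaled_config)
    local: LocalTrainConfig = field(default_factory=LocalTrainConfig)
    global_cfg: GlobalTrainConfig = field(default_factory=GlobalTrainConfig)
    zones: _markers.ZoneSpec = field(default_factory=_markers.ZoneSpec)
    l1_grid: tuple[float, ...] = _stats.L1_RATIO_GRID
    folds: int = 5
    include_external: bool = False
    external: CohortGenConfig | None = None
    seed: int = 0


@dataclass
class StudyResult:
    """In-memory outputs of one full run."""

    config: PipelineConfig
    metadata: pd.DataFrame
    features: pd.DataFrame  # scan_id, a1..a20, v1..v20
    conventional: pd.DataFrame  # scan_id + 21 zone markers
    split: tuple[list[str], list[str]]
    correlations: _stats.CorrelationTable
    regressions: list[_stats.RegressionResult]
    comparisons: list[_stats.PairedComparison]
    local_model: object
    global_model: object
    external_regression: _stats.RegressionResult | None = None
    report: _stats.ValidationReport | None = None


def _seed_for(cfg: PipelineConfig, stage: str) -> int:
    h = hashlib.sha256(f"{cfg.seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "little") % (2**31)


def _regression_suite(
    cfg: PipelineConfig,
    features: pd.DataFrame,
    conventional: pd.DataFrame,
    metadata: pd.DataFrame,
    split: tuple[list[str], list[str]],
) -> tuple[list[_stats.RegressionResult], list[_stats.PairedComparison]]:
    meta = metadata.set_index("scan_id")
    f = features.set_index("scan_id")
    a_cols = [c for c in f.columns if c.startswith("a")]
    v_cols = [c for c in f.columns if c.startswith("v")]
    conv = conventional.set_index("scan_id")
    seed = _seed_for(cfg, "cv")
    regs: list[_stats.RegressionResult] = []
    by_key: dict[tuple[str, str], _stats.RegressionResult] = {}
    sets = {"local_mean": f[a_cols], "global": f[v_cols], "conventional": conv}
    for name, table in sets.items():
        targets = FUNCTION_TARGETS if name == "conventional" else ALL_TARGETS
        for target in targets:
            res = _stats.fit_regression_cv(
                table, meta[target], split, grid=cfg.l1_grid, seed=seed,
                folds=cfg.folds, feature_set=name,
            )
            regs.append(res)
            by_key[(name, target)] = res
    comps = [
        _stats.compare_models(by_key[("global", t)], by_key[("conventional", t)])
        for t in FUNCTION_TARGETS
    ]
    return regs, comps


def run_study(cfg: PipelineConfig | None = None, outdir: str | Path | None = None) -> StudyResult:
    """Run the whole experiment in memory; optionally render the report
    bundle into ``outdir``."""
    cfg = cfg or PipelineConfig()
    t0 = time.time()
    log.info("simulating cohort: n=%d dims=%s", cfg.cohort.n_patients, cfg.cohort.geometry.dims)
    scans, metadata = generate_cohort(cfg.cohort)
    volumes = [v for v, _ in scans]
    masksets = [m for _, m in scans]
    train_ids, test_ids = split_scan_ids(metadata, cfg.cohort, seed=_seed_for(cfg, "split"))
    train_vols = [v for v in volumes if v.scan_id in set(train_ids)]

    log.info("training local encoder on %d volumes", len(train_vols))
    local_model = fit_local_encoder(train_vols, cfg.local, seed=_seed_for(cfg, "local"))
    train_features = [encode_volume(local_model, v) for v in train_vols]
    log.info("training global encoder")
    global_model = fit_global_encoder(train_features, cfg.global_cfg, seed=_seed_for(cfg, "global"))

    log.info("encoding cohort (%d scans)", len(volumes))
    features = encode_cohort(local_model, global_model, volumes)
    conventional = _markers.quantify_cohort(masksets, cfg.zones)

    log.info("statistical validation")
    correlations = _stats.pearson_screen(features, metadata)
    regressions, comparisons = _regression_suite(cfg, features, conventional, metadata, (train_ids, test_ids))

    external_res = None
    if cfg.include_external:
        ext_cfg = cfg.external or external_site_config()
        log.info("external-site evaluation: n=%d", ext_cfg.n_patients)
        ext_scans, ext_meta = generate_cohort(ext_cfg)
        ext_features = encode_cohort(local_model, global_model, [v for v, _ in ext_scans])
        bcva_global = next(
            r for r in regressions if r.feature_set == "global" and r.target == "BCVA"
        )
        v_cols = [c for c in ext_features.columns if c.startswith("v")]
        external_res = _stats.evaluate_on(
            bcva_global,
            ext_features.set_index("scan_id")[v_cols],
            ext_meta.set_index("scan_id")["BCVA"],
            feature_set="global(external)",
        )
        regressions = regressions + [external_res]

    report = None
    if outdir is not None:
        report = _stats.build_report(correlations, regressions, comparisons, outdir)
    log.info("run complete in %.1f s", time.time() - t0)
    return StudyResult(
        config=cfg,
        metadata=metadata,
        features=features,
        conventional=conventional,
        split=(train_ids, test_ids),
        correlations=correlations,
        regressions=regressions,
        comparisons=comparisons,
        local_model=local_model,
        global_model=global_model,
        external_regression=external_res,
        report=report,
    )


# ---------------------------------------------------------------------------
# file-based staged pipeline

def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def _stage_hash(cfg_part, upstream: str) -> str:
    payload = json.dumps({"cfg": _jsonable(cfg_part), "up": upstream}, sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


class _Manifest:
    def __init__(self, path: Path) -> None:
        self.path = path
        self.data: dict = {}
        if path.exists():
            self.data = json.loads(path.read_text())

    def fresh(self, stage: str, h: str) -> bool:
        entry = self.data.get(stage)
        return (
            entry is not None
            and entry.get("hash") == h
            and all(Path(p).exists() for p in entry.get("outputs", []))
        )

    def record(self, stage: str, h: str, outputs: list[Path]) -> None:
        self.data[stage] = {"hash": h, "outputs": [str(p) for p in outputs]}
        self.path.write_text(json.dumps(self.data, indent=2))


@dataclass
class _Layout:
    root: Path

    def __post_init__(self) -> None:
        self.root = Path(self.root)

    @property
    def volumes(self) -> Path:
        return self.root / "volumes"

    @property
    def masks(self) -> Path:
        return self.root / "masks"

    @property
    def features_local(self) -> Path:
        return self.root / "features_local"

    @property
    def models(self) -> Path:
        return self.root / "models"

    @property
    def validation(self) -> Path:
        return self.root / "validation"

    def cohort_csv(self) -> Path:
        return self.root / "cohort.csv"

    def split_json(self) -> Path:
        return self.root / "split.json"

    def features_csv(self) -> Path:
        return self.root / "features.csv"

    def markers_csv(self) -> Path:
        return self.root / "markers.csv"


def _scan_order(layout: _Layout) -> list[str]:
    return list(pd.read_csv(layout.cohort_csv())["scan_id"].astype(str))


def stage_simulate(cfg: PipelineConfig, layout: _Layout) -> list[Path]:
    layout.volumes.mkdir(parents=True, exist_ok=True)
    layout.masks.mkdir(parents=True, exist_ok=True)
    scans, metadata = generate_cohort(cfg.cohort)
    for vol, maskset in scans:
        _io.write_volume(vol, layout.volumes / f"{vol.scan_id}.raw")
        _io.write_masks(maskset, layout.masks / f"{vol.scan_id}.npz")
    _io.write_cohort(metadata, layout.cohort_csv())
    train_ids, test_ids = split_scan_ids(metadata, cfg.cohort, seed=_seed_for(cfg, "split"))
    layout.split_json().write_text(json.dumps({"train": train_ids, "test": test_ids}))
    return [layout.cohort_csv(), layout.split_json(), layout.volumes, layout.masks]


def stage_train_local(cfg: PipelineConfig, layout: _Layout) -> list[Path]:
    layout.models.mkdir(parents=True, exist_ok=True)
    split = json.loads(layout.split_json().read_text())
    train = set(split["train"])
    vols = [
        _io.read_volume(layout.volumes / f"{sid}.raw")
        for sid in _scan_order(layout)
        if sid in train
    ]
    model = fit_local_encoder(vols, cfg.local, seed=_seed_for(cfg, "local"))
    out = layout.models / "local.h5"
    save_local_model(model, out)
    return [out]


def stage_encode_local(cfg: PipelineConfig, layout: _Layout) -> list[Path]:
    layout.features_local.mkdir(parents=True, exist_ok=True)
    model = load_local_model(layout.models / "local.h5")
    for sid in _scan_order(layout):
        vol = _io.read_volume(layout.volumes / f"{sid}.raw")
        fv = encode_volume(model, vol)
        _io.write_feature_volume(fv.activations, sid, layout.features_local / f"{sid}.npz")
    return [layout.features_local]


def stage_train_global(cfg: PipelineConfig, layout: _Layout) -> list[Path]:
    from .local import LocalFeatureVolume

    split = json.loads(layout.split_json().read_text())
    train = set(split["train"])
    fvs = []
    for sid in _scan_order(layout):
        if sid in train:
            arr, _ = _io.read_feature_volume(layout.features_local / f"{sid}.npz")
            fvs.append(LocalFeatureVolume(activations=arr, scan_id=sid))
    model = fit_global_encoder(fvs, cfg.global_cfg, seed=_seed_for(cfg, "global"))
    out = layout.models / "global.h5"
    save_global_model(model, out)
    return [out]


def stage_encode_global(cfg: PipelineConfig, layout: _Layout) -> list[Path]:
    from .local import LocalFeatureVolume, mean_activation

    model = load_global_model(layout.models / "global.h5")
    rows = []
    for sid in _scan_order(layout):
        arr, _ = _io.read_feature_volume(layout.features_local / f"{sid}.npz")
        fv = LocalFeatureVolume(activations=arr, scan_id=sid)
        means = mean_activation(fv)
        gv = encode_global(model, fv)
        row = {"scan_id": sid}
        row.update({f"a{i + 1}": means[i] for i in range(len(means))})
        row.update({f"v{i + 1}": gv.values[i] for i in range(len(gv.values))})
        rows.append(row)
    pd.DataFrame(rows).to_csv(layout.features_csv(), index=False)
    return [layout.features_csv()]


def stage_markers(cfg: PipelineConfig, layout: _Layout) -> list[Path]:
    masksets = [_io.read_masks(layout.masks / f"{sid}.npz") for sid in _scan_order(layout)]
    df = _markers.quantify_cohort(masksets, cfg.zones)
    df.to_csv(layout.markers_csv(), index=False)
    return [layout.markers_csv()]


def stage_validate(cfg: PipelineConfig, layout: _Layout) -> list[Path]:
    layout.validation.mkdir(parents=True, exist_ok=True)
    features = pd.read_csv(layout.features_csv())
    conventional = pd.read_csv(layout.markers_csv())
    metadata = _io.read_cohort(layout.cohort_csv())
    mismatch = set(features["scan_id"]).symmetric_difference(metadata["scan_id"])
    if mismatch:
        raise ValidationError(f"scan_ids mismatch between features and metadata: {sorted(mismatch)[:10]}")
    split = json.loads(layout.split_json().read_text())
    correlations = _stats.pearson_screen(features, metadata)
    regressions, comparisons = _regression_suite(
        cfg, features, conventional, metadata, (split["train"], split["test"])
    )
    v = layout.validation
    correlations.r.to_csv(v / "correlation_r.csv")
    correlations.p.to_csv(v / "correlation_p.csv")
    correlations.significant.to_csv(v / "correlation_significant.csv")
    report = _stats.ValidationReport(correlations, regressions, comparisons)
    report.regression_table().to_csv(v / "regression_summary.csv", index=False)
    report.comparison_table().to_csv(v / "comparisons.csv", index=False)
    return [
        v / "correlation_r.csv",
        v / "correlation_p.csv",
        v / "correlation_significant.csv",
        v / "regression_summary.csv",
        v / "comparisons.csv",
    ]


def stage_report(cfg: PipelineConfig, layout: _Layout) -> list[Path]:
    v = layout.validation
    r = pd.read_csv(v / "correlation_r.csv", index_col=0)
    p = pd.read_csv(v / "correlation_p.csv", index_col=0)
    sig = pd.read_csv(v / "correlation_significant.csv", index_col=0).astype(bool)
    corr = _stats.CorrelationTable(r=r, p=p, significant=sig, undefined=r.isna(), n=r.notna().astype(int))
    heat = _stats._correlation_heatmap(corr, v / "correlation_heatmap.png")
    reg = pd.read_csv(v / "regression_summary.csv")
    comp = pd.read_csv(v / "comparisons.csv")
    html = (
        "<html><head><title>octmark validation report</title></head><body>"
        "<h1>Validation report</h1>"
        "<h2>Correlation screen</h2>" + r.round(3).to_html()
        + f'<p><img src="{heat.name}" alt="correlation heatmap"/></p>'
        "<h2>Regression (held-out)</h2>" + reg.round(4).to_html(index=False)
        + "<h2>Paired model comparisons</h2>" + comp.round(4).to_html(index=False)
        + "</body></html>"
    )
    (v / "report.html").write_text(html)
    return [v / "report.html", heat]


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "train-local": stage_train_local,
    "encode-local": stage_encode_local,
    "train-global": stage_train_global,
    "encode-global": stage_encode_global,
    "markers": stage_markers,
    "validate": stage_validate,
    "report": stage_report,
}

_STAGE_CFG = {
    "simulate": lambda c: c.cohort,
    "train-local": lambda c: (c.local, c.seed),
    "encode-local": lambda c: (c.local, c.seed),
    "train-global": lambda c: (c.global_cfg, c.seed),
    "encode-global": lambda c: (c.global_cfg, c.seed),
    "markers": lambda c: c.zones,
    "validate": lambda c: (c.zones, c.l1_grid, c.folds, c.seed),
    "report": lambda c: None,
}

# upstream dependencies used for hash chaining
_STAGE_DEPS = {
    "simulate": (),
    "train-local": ("simulate",),
    "encode-local": ("simulate", "train-local"),
    "train-global": ("encode-local",),
    "encode-global": ("encode-local", "train-global"),
    "markers": ("simulate",),
    "validate": ("encode-global", "markers"),
    "report": ("validate",),
}


def run_pipeline(cfg: PipelineConfig, outdir: str | Path) -> list[str]:
    """Run all eight stages into ``outdir``; returns the names of the
    stages actually executed (skipped stages are up to date per the
    manifest). A failing stage aborts with its name in the raised error;
    partial outputs are retained."""
    layout = _Layout(Path(outdir))
    layout.root.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(layout.root / "manifest.json")
    hashes: dict[str, str] = {}
    executed: list[str] = []
    for stage in STAGES:
        upstream = "|".join(hashes[d] for d in _STAGE_DEPS[stage])
        h = _stage_hash((_STAGE_CFG[stage](cfg), cfg.seed), upstream)
        hashes[stage] = h
        upstream_reran = any(d in executed for d in _STAGE_DEPS[stage])
        if manifest.fresh(stage, h) and not upstream_reran:
            log.info("stage %s up to date, skipping", stage)
            continue
        log.info("running stage %s", stage)
        t0 = time.time()
        try:
            outputs = _STAGE_FUNCS[stage](cfg, layout)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
        manifest.record(stage, h, outputs)
        executed.append(stage)
        log.info("stage %s done in %.1f s", stage, time.time() - t0)
    return executed
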