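"""Zone partition and quantification of the 21 conventional variables."""

from __future__ import annotations

import numpy as np
import pytest

from octmark.errors import ValidationError
from octmark.markers import (
    FEATURE_NAMES,
    ZONES,
    ZoneSpec,
    quantify,
    total_volumes_nl,
    zone_masks,
)
from octmark.volume import ScanGeometry, SegmentationMaskSet


def _maskset(geometry, lesions=(), inner=None, rpe=None):
    w, h, d = geometry.dims
    masks = {cls: np.zeros((w, h, d), bool) for cls in ("IRC", "SRF", "PED", "SHRM")}
    for cls, sl in lesions:
        masks[cls][sl] = True
    inner = np.full((w, h), 2.0) if inner is None else inner
    rpe = np.full((w, h), d - 2.0) if rpe is None else rpe
    return SegmentationMaskSet(masks=masks, inner_surface=inner, rpe_surface=rpe,
                               geometry=geometry)


def test_zone_partition_covers_grid():
    g = ScanGeometry(dims=(32, 16, 8))
    zm = zone_masks(ZoneSpec(), g)
    total = sum(zm[z].astype(int) for z in ZONES)
    assert np.all(total == 1)


def test_fovea_position_zone_membership():
    g = ScanGeometry(dims=(32, 16, 8))
    zm = zone_masks(ZoneSpec(fovea_center_mm=(3.0, 3.0)), g)
    # the position nearest the fovea centre is central
    xs = (np.arange(32) + 0.5) * (6.0 / 32)
    ys = (np.arange(16) + 0.5) * (6.0 / 16)
    i, j = np.argmin(np.abs(xs - 3.0)), np.argmin(np.abs(ys - 3.0))
    assert zm["central"][i, j]


def test_boundary_belongs_to_farther_zone():
    """A voxel centre at exactly 0.5 mm lies in the ring (half-open bins)."""
    g = ScanGeometry(dims=(12, 12, 4))  # centres at 0.25 + k*0.5 mm
    zones = ZoneSpec(fovea_center_mm=(0.75, 0.75))
    zm = zone_masks(zones, g)
    # position (2, 1) has centre (1.25, 0.75): distance exactly 0.5 mm
    assert zm["ring"][2, 1] and not zm["central"][2, 1]
    # distance exactly 1.5 mm -> outer: centre (2.25, 0.75)
    assert zm["outer"][4, 1]


def test_zone_counts_match_brute_force_8x8():
    g = ScanGeometry(dims=(8, 8, 4))
    zones = ZoneSpec(fovea_center_mm=(2.5, 3.5))
    zm = zone_masks(zones, g)
    counts = {z: 0 for z in ZONES}
    for i in range(8):
        for j in range(8):
            cx, cy = (i + 0.5) * 0.75, (j + 0.5) * 0.75
            dist = np.hypot(cx - 2.5, cy - 3.5)
            if dist < 0.5:
                counts["central"] += 1
            elif dist < 1.5:
                counts["ring"] += 1
            else:
                counts["outer"] += 1
    for z in ZONES:
        assert zm[z].sum() == counts[z]


def test_fovea_outside_field_rejected():
    g = ScanGeometry(dims=(8, 8, 4))
    with pytest.raises(ValidationError):
        zone_masks(ZoneSpec(fovea_center_mm=(7.0, 3.0)), g)


def test_flat_surfaces_closed_form_thickness():
    """Empty masks, surfaces 100 voxels apart at the default depth sampling
    (2000/1024 um per voxel) give RT = 195.3125 um in every zone."""
    g = ScanGeometry(dims=(16, 8, 1024))
    ms = _maskset(g, inner=np.full((16, 8), 300.0), rpe=np.full((16, 8), 400.0))
    vec = quantify(ms, ZoneSpec(), g)
    assert len(vec) == 21
    for zone in ZONES:
        assert vec[f"{zone}_RT_um"] == pytest.approx(100 * 2000 / 1024)  # 195.3125
        for cls in ("IRC", "SRF", "PED"):
            assert vec[f"{zone}_{cls}_nl"] == 0.0
            assert vec[f"{zone}_{cls}_mm2"] == 0.0


def test_feature_vector_has_21_named_components():
    assert len(FEATURE_NAMES) == 21
    g = ScanGeometry(dims=(8, 8, 16))
    vec = quantify(_maskset(g), ZoneSpec(), g)
    assert list(vec.index) == list(FEATURE_NAMES)


def test_central_lesion_counted_in_central_zone_only():
    g = ScanGeometry(dims=(32, 32, 16))
    zones = ZoneSpec(fovea_center_mm=(3.0, 3.0))
    zm = zone_masks(zones, g)
    # put IRC voxels in a small block of central-zone columns
    xs, ys = np.where(zm["central"])
    sl = (slice(xs[0], xs[0] + 2), slice(ys[0], ys[0] + 1), slice(4, 9))
    ms = _maskset(g, lesions=[("IRC", sl)])
    assert zm["central"][xs[0]:xs[0] + 2, ys[0]:ys[0] + 1].all()
    vec = quantify(ms, zones, g)
    k = ms.masks["IRC"].sum()
    # brute-force voxel iteration oracle
    brute = 0
    for x in range(32):
        for y in range(32):
            if zm["central"][x, y]:
                brute += int(ms.masks["IRC"][x, y].sum())
    assert k == brute
    assert vec["central_IRC_nl"] == pytest.approx(k * g.voxel_volume_nl, rel=1e-12)
    assert vec["ring_IRC_nl"] == 0.0 and vec["outer_IRC_nl"] == 0.0
    assert vec["central_IRC_mm2"] == pytest.approx(2 * g.pixel_area_mm2, rel=1e-12)


def test_zone_volumes_additive():
    rng = np.random.default_rng(0)
    g = ScanGeometry(dims=(16, 16, 12))
    ms = _maskset(g)
    for cls in ("IRC", "SRF", "PED"):
        ms.masks[cls] = rng.random((16, 16, 12)) < 0.15
    vec = quantify(ms, ZoneSpec(), g)
    totals = total_volumes_nl(ms, g)
    for cls in ("IRC", "SRF", "PED"):
        per_zone = sum(vec[f"{z}_{cls}_nl"] for z in ZONES)
        assert per_zone == pytest.approx(totals[cls], rel=1e-9)


def test_translation_consistency():
    """Shifting fovea and lesion by the same grid-aligned offset leaves all
    21 values unchanged."""
    g = ScanGeometry(dims=(32, 32, 12))  # 0.1875 mm lateral spacing
    sl = (slice(10, 13), slice(12, 14), slice(3, 7))
    ms = _maskset(g, lesions=[("SRF", sl)])
    vec1 = quantify(ms, ZoneSpec(fovea_center_mm=(2.0, 2.0)), g)
    shift_vox = 4  # 0.75 mm
    sl2 = (slice(14, 17), slice(16, 18), slice(3, 7))
    ms2 = _maskset(g, lesions=[("SRF", sl2)])
    vec2 = quantify(ms2, ZoneSpec(fovea_center_mm=(2.75, 2.75)), g)
    np.testing.assert_allclose(vec1.to_numpy(), vec2.to_numpy(), rtol=1e-12)


def test_adding_voxels_never_decreases_volumes():
    g = ScanGeometry(dims=(16, 16, 12))
    sl = (slice(4, 7), slice(4, 7), slice(3, 6))
    ms1 = _maskset(g, lesions=[("PED", sl)])
    ms2 = _maskset(g, lesions=[("PED", sl), ("PED", (slice(10, 12), slice(2, 4), slice(5, 8)))])
    v1 = quantify(ms1, ZoneSpec(), g)
    v2 = quantify(ms2, ZoneSpec(), g)
    vol_cols = [n for n in FEATURE_NAMES if n.endswith(("_nl", "_mm2"))]
    assert np.all(v2[vol_cols].to_numpy() >= v1[vol_cols].to_numpy())
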