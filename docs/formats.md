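# On-disk formats

## Raw volume dialect (`.raw` + `.hdr`)

The canonical, bit-exact interchange format. A volume named `scan` is
stored as two files side by side:

* `scan.raw` — the payload: W·H·D IEEE-754 binary32 values,
  little-endian, no header, no padding. The array is laid out in C
  order for axes (x, y, z): **z varies fastest**, then y, then x, i.e.
  element (x, y, z) sits at offset `4 * ((x*H + y)*D + z)` bytes.
* `scan.hdr` — a plain-text sidecar, one `key: value` pair per line:

```
dialect: octmark-raw-v1
width: 512
height: 128
depth: 1024
dtype: float32-le
order: xyz-c
lateral_extent_mm_x: 6.0
lateral_extent_mm_y: 6.0
depth_extent_mm: 2.0
scan_id: P0000_S1
patient_id: P0000
```

`width`, `height`, `depth` are required; extents default to the
6 × 6 × 2 mm macular cube. A payload whose length differs from
W·H·D is a corruption error; a missing sidecar is a format error.
Intensities are min–max normalised to [0, 1] on read; since written
volumes are already normalised float32, the raw dialect round-trips
bit-for-bit.

## TIFF stack (`.tif`)

One page per slice (the y axis); each page is a (depth, x) image,
grayscale float32. Physical extents and identifiers travel in a JSON
`ImageDescription` tag.

## NIfTI (`.nii`, `.nii.gz`)

Data array in (x, y, z) order; voxel spacing in mm in the affine
diagonal; `scan_id`/`patient_id` packed into the 80-byte `descrip`
field (truncated if long — use the raw dialect when identifiers
matter).

## Masks and feature volumes (`.npz`)

Segmentation mask sets are compressed npz containers with packed-bit
lesion masks (`mask_IRC` … `mask_SHRM`), float64 `inner_surface` /
`rpe_surface` depth maps, geometry and scan id. Local feature volumes
are npz with a float32 `activations` array of shape (W, H, code_dim).

## Cohort tables (CSV)

One row per scan: `scan_id, BCVA, LLVA, RT, IRC, SRF, PED,
lesion_area, leakage_area`. Letter scores in [0, 100]; volumes (nl) and
areas (mm²) non-negative; empty cells are explicit missing values.
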