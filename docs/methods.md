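# Methods

This note documents the models, the synthetic data they are exercised
on, the numerical choices, and what the tests do and do not demonstrate.

## Two-stage unsupervised embedding

**Stage one (local).** Each A-scan (a depth column of length D, default
1024) is treated as an independent sample. A symmetric fully connected
auto-encoder, by default 1024 → 256 → 64 → 20 → 64 → 256 → 1024, with
tanh on hidden layers (including the bottleneck, so codes are bounded in
(−1, 1)) and a linear output, is trained with mini-batch Adam on mean
squared reconstruction error. A 1D column at this length does not need
convolutional structure; dense layers are adequate and keep the model
transparent. Training samples a fixed number of columns per volume per
epoch (default 128) uniformly without replacement, so cost is
independent of the 65 536 columns of a full-size cube and the sampling
is unbiased. The exported "activation" of a feature map is the
bottleneck code value, evaluated at every (x, y) position.

**Stage two (global).** The (W, H, 20) grid of stage-one codes is
average-pooled to a fixed 16 × 8 en-face grid — making the model
independent of the acquisition grid while preserving coarse topography —
then standardised per local feature with training-cohort statistics
(stage-one code scales are arbitrary), flattened, and compressed by a
second dense auto-encoder (2560 → 256 → 64 → 20). Stage two consumes
frozen stage-one codes; there is no joint fine-tuning, keeping the two
representations separable and attributable.

Both stages are pure numpy with every random draw routed through a
seeded `numpy.random.Generator`; identical seed + data + config
reproduce the parameter trajectory bit-for-bit, which is what makes the
pipeline-level determinism contract (1e-9) testable.

**Epoch budgets.** The stage-one default is 30 epochs. The stage-two
default is 60 epochs: with cohorts of a few hundred scans and a
2560-dimensional input the second network starts memorising its
training set well before 200 epochs (training MSE falls an order of
magnitude while held-out MSE rises above the random-init baseline), and
60 epochs sits near the held-out reconstruction optimum. Both budgets
are config fields, not constants.

## Synthetic cohort generator

The generator is the study substrate, not a fixture: real neovascular
AMD trial imaging is proprietary, so every feature of the data the
pipeline is supposed to exploit is planted explicitly and is therefore
known exactly.

* **Anatomy.** Two layer surfaces (ILM and RPE) are low-frequency random
  fields — sums of three random low-order 2D harmonics — mimicking
  retinal curvature; any smooth two-surface model satisfying
  ILM ≤ RPE would do. Between them, three reflectivity bands stand in
  for inner retina, mid retina and the outer nuclear layer; a bright
  thin band is the RPE; below it, an exponentially decaying choroid.
* **Lesions.** IRC, SRF, PED and SHRM are ellipsoids in anatomically
  legal compartments (IRC intraretinal, SRF/SHRM just above the RPE,
  PED below it), with laterally flattened aspect ratios because
  exudation spreads in the retinal plane. Hyporeflective offsets for
  fluid, hyperreflective for PED/SHRM. Masks mark exactly the
  perturbed voxels, so mask-derived volumes are exact ground truth
  (1 nl = 10⁶ µm³, voxel volume = product of spacings).
* **Noise.** Multiplicative Gaussian speckle (default SD 0.12) applied
  before per-volume min–max normalisation; OCT noise is
  speckle-dominated, but no claim of physically realistic speckle
  statistics is made.
* **Burdens.** Per-class zero-inflated log-normal (prevalences
  0.35–0.55, log-SD ~0.9), so many scans lack a given lesion, mimicking
  clinical prevalence heterogeneity.
* **Metadata linkage.** Letter scores follow
  `BCVA = intercept − Σ w_c · burden_c + N(0, σ)`. When σ is not given
  it is derived from a target generative R² via
  R² = Var(signal)/(Var(signal)+σ²); the default target is 0.6 for BCVA
  and 0.7 for LLVA (low-luminance acuity is the more
  morphology-sensitive measure). SHRM carries the largest per-nl weight
  — it harms function while being invisible to the conventional marker
  set, which quantifies IRC/SRF/PED only. Retinal thickness is coupled
  to IRC+SRF burden; angiographic lesion/leakage areas are monotone
  noisy functions of total burden. In the rendered cohort the
  morphology columns (RT, IRC, SRF, PED) are re-measured from the
  generated masks and surfaces, so they carry the same discretisation a
  segmentation-based reading would.
* **External site.** A second config shifts acquisition gain (0.8),
  speckle (0.18), burden scale (+0.3 log-nl) and the BCVA intercept,
  standing in for an external test population.

Default cohort scale is 1094 patients split 985/109 with one baseline
scan per patient; `scaled_config(200)` gives the desk-scale reference
conditions (200 patients, 180/20 — the same 9:1 ratio — on a 64×32×256
grid) used by the test suite and the acceptance script, chosen so a full
study runs in about a minute. Multi-visit generation exists as a config
option but draws visits independently; no within-patient longitudinal
correlation model is implemented.

## Conventional markers

21 variables: {IRC, SRF, PED} × {volume (nl), en-face area (mm²)} plus
mean retinal thickness (µm), each in three fovea-centred zones (1 mm
disc, 1–3 mm ring, outside 3 mm), ordered zone-major. Conventions that
the underlying definitions leave open, fixed here and tested:

* zone membership by Euclidean distance of the voxel centre from the
  fovea, half-open bins [0, 0.5), [0.5, 1.5), [1.5, ∞) mm — a boundary
  point belongs to the farther zone;
* "area" counts positions whose column contains ≥ 1 lesion voxel
  (projection convention, as used by reading centres);
* retinal thickness is ILM-to-RPE (an ILM-to-Bruch's definition would
  differ in eyes with PED; the generator's surfaces make ILM-to-RPE the
  natural ground truth here);
* the fovea centre is a required input (ground truth in synthetic data);
  no automatic foveal detection.

## Statistical validation

* **Correlation screen:** Pearson r on pairwise-complete observations,
  two-sided p from the t transform with n−2 df. Constant columns give
  an explicitly flagged undefined cell, never a silent zero. No
  multiple-testing correction — an explorative screen should not
  inflate type II error; the report states this.
* **Regression:** the listed grid values [0.001 … 1] are interpreted as
  the elastic-net L1/L2 mixing ratio (they span (0, 1], the natural
  range of a mixing ratio); penalty strength is searched on an internal
  40-point logarithmic path per ratio, both selected by minimum mean CV
  squared error over 5 seeded folds. Features are standardised with
  train-split statistics; coefficients are reported back on the
  original scale. Missing targets are complete-case dropped with
  counted exclusions. R² = 1 − SSE/SST and MAE mean ± SD on the
  held-out split. The train/test split is simple seeded random
  sampling, unstratified.
* **Paired comparison:** two-sided Wilcoxon signed-rank on differences
  of absolute errors, zeros dropped, exact null for ≤ 25 remaining
  pairs, normal approximation with continuity correction above, α =
  0.05. All differences zero ⇒ the verdict is reported as degenerate
  rather than as a numeric p.

## Degenerate inputs and numerical conventions

* Constant volumes min–max normalise to all zeros; normalisation is
  idempotent and computed in float32 so the raw dialect round-trips
  bit-for-bit.
* Decoding the all-zero code is well-defined (the decoder bias image).
* An embedding with code_dim ≥ input_dim trains but warns (not
  compressive).
* Stage hashes in the file pipeline chain config hashes; a stage re-runs
  iff its own hash changed, an output is missing, or an upstream stage
  re-ran this invocation.

## What passing tests show — and what they do not

The synthetic cohort demonstrates *mechanism recovery*: the pipeline
finds planted structure (held-out R² for BCVA at the generative
R² = 0.6 conditions; at least one mean-activation feature tracking
lesion burden at |r| ≥ 0.5) and the statistical machinery agrees with
brute-force oracles to 1e-10. It does **not** demonstrate clinical
performance. In particular, on synthetic data the conventional markers
often *outperform* the learned features for visual function, because
synthetic acuity is generated directly from the burdens those markers
measure nearly perfectly — the opposite of what one expects on real
images, where conventional segmentations are an imperfect, incomplete
summary. Likewise the simulator omits vascular shadowing, motion
artifacts, realistic speckle statistics and longitudinal correlation,
so transfer of any tuning to real OCT is untested. The external-site
evaluation shows the expected degradation under distribution shift but
its magnitude is simulator-specific; at n_test = 20 individual R²
values carry a sampling SD of roughly 0.2, which is why the reference
conditions fix a seed.

## Known limitations

* Whether A-scans should be flattened/aligned to a retinal surface
  before stage one is an open modelling question; the package trains on
  normalised raw columns.
* Depth attribution of local features is not attempted; feature maps
  are en-face only, and global features have no spatial interpretation
  at all.
* The dense stage-two model, even pooled, is over-parameterised for
  cohorts of a few hundred scans; the epoch budget, not an explicit
  regulariser, controls memorisation.
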