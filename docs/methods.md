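# Methods

`hsin` classifies the nutrient status of plants — four treatments crossing
high/low nitrogen with high/low phosphorus (HNHP, HNLP, LNHP, LNLP) — from
hyperspectral imagery of the canopy. The pipeline is: scene simulation (or
ENVI ingest), radiometric calibration, vegetation-index segmentation,
spectral transformation, patch-library construction, CNN classification,
correlation-based waveband selection, and per-growth-stage retraining.

## Synthetic scenes

No public imagery exists for this problem, so the package ships a
first-class generator whose defaults define the study conditions for every
test.

**Spectral model.** A treatment's reflectance is a sum of parameterised
primitives on a 390–2500 nm grid:

- a Gaussian chlorophyll reflectance peak at 552 nm (sd 22 nm),
- a logistic red edge centred at 715 nm (width 12 nm) rising from the red
  level to the NIR plateau,
- Gaussian water-absorption dips at 1450 nm (sd 60 nm) and 1940 nm
  (sd 80 nm, 0.85× depth),
- a broad SWIR decline past ~1700 nm and a small upturn past 2250 nm, both
  proportional to the dip depth so that degenerate flat profiles stay exact.

The four default profiles encode the orderings nutrient trials report:
NIR plateau HNHP (0.65) > HNLP (0.55) and LNHP (0.50) > LNLP (0.42)
(healthy canopies reflect most in the NIR); red reflectance (600–700 nm)
higher under low N — chlorosis — with LNLP (0.15) highest and HNLP (0.05)
lowest; the green peak follows the red ordering; the water-dip depth is
larger under high P. Within-treatment spectral variance is not reported
anywhere we could anchor it, so the noise scales are free parameters fixed
once: per-pixel per-band Gaussian noise sd 0.01 (reflectance units),
per-scene additive baseline drift sd 0.005, and a per-scene multiplicative
illumination gain drawn uniformly from [0.9, 1.1] (present specifically so
SNV's scatter-correction claim is testable).

**Geometry.** A scene is a plant-shaped mask over a flat 0.15-reflectance
background: one large central ellipse (semi-axes 0.34–0.42 of the frame,
guaranteeing canopy in every quadrant) plus smaller random ellipses. Raw
sensor counts invert the calibration equation,
`raw = dark + reflectance·(white − dark)`, with white/dark reference
levels 10 000/100, so calibration downstream is an exact round trip
(verified to 1e-10 noiselessly).

**Grids.** Defaults are 155 VNIR bands (398–1014 nm, 4 nm) and 68 SWIR
bands (1040–2500 nm), giving the 223-band concatenated cube the classifier
assumes. The VNIR span is chosen so the red-edge index wavelengths
(705/750 nm) exist in-grid; the counts 155 + 68 are fixed configuration —
they cannot be derived from a down-sampling rule.

**What the generator does not emulate:** radiative-transfer realism
(no PROSAIL-style leaf optics), spatially correlated noise, leaf-angle or
shadow structure, mixed pixels at canopy edges beyond the binary mask, and
temporal growth beyond a per-stage contrast ramp (below). Passing tests
therefore demonstrate the pipeline's correctness and its behaviour under
the stated noise model — not field performance on real canopies.

## Preprocessing

Calibration is `(raw − dark)/(white − dark)` with references broadcast from
cubes, per-band spectra or scalars; a zero denominator names the offending
band. Spectral down-sampling averages half-open windows anchored at the
first wavelength (window centre becomes the output wavelength). Smoothing
is Savitzky–Golay, window 13 / order 2, with polynomial-fit edge handling
(`mode="interp"`), which preserves exact reproduction of polynomials up to
the fit order at the spectrum ends.

## Segmentation

VNIR: RENDVI = (R750 − R705)/(R750 + R705). SWIR: (R1141 − R1375)/
(R1141 + R1375), oriented so vegetation (high 1141 nm reflectance, strong
1375 nm water absorption) scores positive. Nearest-band lookup tolerates
half the local band spacing. The index histogram (256 bins over the
observed range) is thresholded by Otsu's criterion; pixels with zero
denominator are excluded and an all-background (constant-index) scene
raises a degenerate-input error rather than guessing. No morphological
cleanup is applied. On default scenes the mask recovers the ground truth
exactly without noise and with IoU > 0.95 under default noise.

## Spectral representations

- **raw** — calibrated reflectance.
- **SNV** — per-spectrum centring and scaling to unit *sample* variance
  (denominator p − 1). Constant spectra are flagged, never silently zeroed;
  the pipeline maps flagged (background, noiseless-only) pixels to 0 and
  counts them.
- **SDeri** — Savitzky–Golay second derivative (window 13, order 2 — the
  smoothing defaults, since nothing pins separate derivative parameters),
  scaled by the mean band spacing, applied per sensor segment so the
  VNIR/SWIR seam never enters one filter window.
- **LDA** — supervised projection to at most C − 1 = 3 discriminants
  (eigen-solver on the between/within scatter ratio; Ledoit–Wolf shrinkage
  when the within-scatter is singular). LDA is always fitted on training
  patch pixels only (subsampled to ≤ 50 000 rows, seeded) and applied to
  validation/test — the supervised transform is the one place leakage is
  possible.

SNV and SDeri act on individual pixel spectra, so applying them to
extracted patches is numerically identical to transforming the cube before
extraction; the implementation transforms patches, which also keeps the
LDA fit leakage-free. LDA output feeds the 3-D architectures as a
15×15×3 cube whose spectral axis holds the discriminants; the builders
clip a 3-D kernel or pool's spectral extent to the remaining depth when it
is shorter than the default (never triggered at 223 bands).

## Patch library and splits

Each scene is quadrant-tiled (odd dimensions give the first tiles the
extra row/column) and patches of 15×15 pixels through all bands are
sampled per quadrant, without replacement, from the grid of
non-overlapping positions whose plant-pixel fraction is ≥ 0.9 ("non-zero"
patches must represent canopy, but demanding 100 % would reject sparse
early-stage plants). When the non-overlapping supply is short the sampler
errors; callers may relax to unit-stride positions, and the relaxation is
recorded in each patch's provenance. The full study design — 20 patches ×
4 quadrants × 35 scenes × 4 treatments = 11 200 patches — and the
stratified split 2800 → 1680/420/700 per class (3:1 train–test, then
80:20 train–validation, floor rounding with the remainder to train) are
asserted in the acceptance tests. A scene-grouped split (all patches of a
scene in one fold) is available as the leakage-safe alternative; the
patch-level split is the default because it reproduces the reference
split arithmetic exactly. Augmentation duplicates a fraction (default 0.4) of training
patches with an in-plane rotation (uniform in ±20°, nearest-neighbour,
identical across bands, out-of-frame filled with the per-band median of
the patch border) and adds mirror copies; originals are always retained.

## Architectures

All four models are declarative layer lists with exact shape inference and
parameter counting; a NumPy runtime compiles them to trainable networks.

**Hybrid 3D-2D CNN** (the proposed model): three valid-padded ReLU 3-D
convolutions — 8, 8, 16 filters, all 3×3×3, batch-normalised after the
first two — then 2×2×2 max pooling, a reshape folding (bands × filters)
into 2-D channels in band-major order, a depthwise-separable 3×3
convolution with 32 filters, 2×2 max pooling, and dense 256 → 128 heads
with 0.5 dropout before a 4-way softmax. For a 15×15×223 patch the layer
table is 224 / 32 / 1736 / 32 / 3472 / 70880 / 8448 / 32896 / 516
parameters, 118 236 total of which 118 204 are trainable (batch-norm
running statistics are not) — comfortably under the 200 000 bound that
motivates the design.

**HybridSN**: 3-D convolutions of 8/16/32 filters (kernels 3×3×3, 3×3×5,
3×3×3), reshape, one 3×3 2-D convolution with 64 filters, dense 256/128
with 0.4 dropout. **3D-CNN**: four 3-D convolutions (3×3×3 then three
3×3×5; filters 8/16/32/64), max-pool + batch-norm after each pair,
dropout 0.5 after the first pool; the second pool is spectral-only
(1,1,2) because the spatial extent is exhausted. **2D-CNN**: LeNet-style,
bands as input channels — conv 3×3×6, average-pool 2×2 stride 2,
conv 3×3×12, average-pool, dense 120/140, softmax; shapes follow standard
valid-padding inference.

## Training runtime

With no deep-learning framework as a dependency, the layers (3-D/2-D/
separable convolution, batch normalisation, max/average pooling, dense,
dropout) carry hand-derived backward passes, verified against central
finite differences on kink-free configurations. Convolutions are
evaluated by kernel-offset accumulation — one small GEMM per kernel offset
— which keeps peak memory low on 223-band cubes; the gradient with respect
to the network input is skipped for the first layer. Training is
mini-batch Adam (defaults: lr 1e-3, batch 32, categorical cross-entropy,
100 epochs, early stopping with patience 10 on validation accuracy,
best-validation weights retained), deterministic under the seed on
single-threaded NumPy. Inputs are standardised per band with training-set
statistics stored on the model. Untrained networks predict near-uniform
probabilities (the softmax head uses a small Glorot initialisation);
argmax ties resolve to the lowest class index.

## Waveband selection

Class correlation of a band is the mean over classes of |Pearson r|
against the one-vs-rest indicator (the treatment label is nominal, so a
single correlation is undefined); a symmetric-uncertainty scorer is
available behind the same interface. Subsets are ranked by the CFS merit
k·r̄_cf / √(k + k(k−1)·r̄_ff) and grown by pure greedy forward search
(strict improvement, ties to the lowest band index, no backtracking).
Selection operates on patch-mean spectra of the training split. One
algebraic subtlety: duplicates of a single selected band leave the merit
exactly unchanged (k·c/√(k²) = c); the strict decrease that makes CFS
prefer uncorrelated bands appears from a base of two or more bands.

## Evaluation

Overall accuracy (trace/N), macro-averaged F1 (degenerate classes
contribute 0 with a warning; weighted averaging behind a flag — the
averaging rule for four classes is not pinned anywhere, and macro matches
the uneven-class-distribution motivation), Cohen's kappa
(P_o − P_c)/(1 − P_c), per-class recall, and repeated stratified k-fold
CV (default 10×5) reported as mean ± sd. Kappa and the confusion matrix
are cross-checked against scikit-learn in the tests.

## Experiment orchestration and problem sizes

`run_full_spectrum_experiment` executes the 4 architectures × 4 transforms
grid on one dataset with shared scenes, patch library and split
membership. `run_stagewise_experiment` emulates growth stages I–V by
ramping the between-treatment contrast of the profiles linearly from 0.6
(stage I, spectra barely diverged) to 1.0 (stage V), regenerating scenes
per stage, restricting the second-derivative data to the selected bands,
augmenting (rotation + flips) and retraining. This mirrors the empirical
pattern that early stages classify worse. "Full plant at full spatial
resolution" cannot feed a fixed-input CNN directly, so stagewise
retraining re-uses the patch machinery on the selected bands; a whole-
plant centre-crop mode was considered and rejected as an interpretation
the data cannot distinguish.

The package's own experiment scales are sized for a single CPU: 64×64
scenes, 4–5 patches per quadrant, and 10 scenes per treatment with 10
training epochs for the end-to-end check (the test uses batch 16 so the
run comprises enough optimiser steps to converge). The end-to-end check
uses the SNV representation: on the fine 223-band grid the second
derivative of smooth synthetic curves is small relative to the per-band
noise it amplifies, so SDeri needs a longer optimisation than the
end-to-end budget allows, while SNV and raw converge within it — a
property of the synthetic noise model (broad features, independent
per-band noise), not of the architectures. The full 11 200-patch
arithmetic checks run on a coarse 31-band grid; patch counts are
grid-independent.

## Known limitations

- The NumPy runtime is CPU-only and orders of magnitude slower than a GPU
  framework; it is sized for the package's synthetic experiments, not for
  glasshouse-scale archives.
- The generator's class separability is, by construction, favourable;
  reported synthetic accuracies say nothing quantitative about real
  canopies.
- ENVI support covers the common BIL/BIP/BSQ uncompressed rasters only.
- Max-pool gradients route ties to the first maximum; batch-norm uses
  per-batch statistics with momentum 0.9 running estimates.
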