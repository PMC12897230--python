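# Methods

This note documents the models and procedures implemented in `foveoct`, the
parameter choices that matter, what the synthetic phantoms do and do not
emulate, and the numerical decisions taken where the design was open.

## 1. Fovea localisation

### Procedure

For a volume of D B-scans (1-based slice indices, matching the on-disk
export convention):

1. **Central crop.** Columns `[floor(0.325·W), floor(0.675·W))` — a
   half-open integer interval of width ≈ 0.35·W for any W. The central 35%
   reliably contains the foveal and parafoveal region while excluding
   peripheral areas prone to shadowing and curvature artifacts.
2. **Blur.** 7×7 Gaussian, σ = 1.0, sampled at integer offsets and
   normalised, applied with symmetric (edge-reflecting) boundaries. Mild
   smoothing suppresses speckle-induced high-frequency structure without
   moving layer boundaries.
3. **Otsu binarisation.** The blurred crop is rounded to integer levels and
   thresholded on its 256-bin histogram; the threshold k ∈ [1, 255]
   maximises the between-class variance `w0·w1·(μ0 − μ1)²` with classes
   `{< k}` and `{≥ k}`; ties take the smallest k. Tissue mask: value ≥ k.
   A constant crop has no valid split; such slices get an all-zero mask and
   are marked degenerate.
4. **Column centroids.** With 1-based rows x = 1…H,
   `c_y(j) = Σ x·B(x,j) / Σ B(x,j)` when the column has tissue
   (`Σ B > ε = 1e-6`), else the sentinel H. The sentinel is the bottom row,
   so empty columns can never masquerade as a pit.
5. **Pit metric and penalty.** `M_pit(i) = min_j c_y(i,j)`; slices outside
   the preferred range [r_start, r_end] = [59, 69] receive `+P` with
   P = 200 pixel-rows. The penalty is additive and deliberately *not*
   rescaled with H: for tall images (H > 200) an out-of-range slice with an
   exceptionally strong pit signature can still win, which is the intended
   escape hatch for genuinely displaced foveae (exercised in the tests).
6. **Selection and extraction.** Arg-min of the penalised metric, ties to
   the lowest slice; the 33-slice window [i−16, i+16] is shifted (never
   truncated) into [1, D]. Volumes with D < 33 are returned whole with a
   flag. If *every* slice is degenerate the detector falls back to slice 64
   (clipped to [1, D]) and flags the result; this is the only fallback
   trigger — the criterion the mechanism needs but that is otherwise
   under-specified.

### Why the minimum and not the mean

A tilted retina shifts all column centroids of a slice by a linear ramp; a
per-slice *mean* centroid is dominated by that ramp and by retinal/choroidal
thickness differences between slices, both of which say nothing about the
fovea. The per-column *minimum* moves with the highest tissue point, which
the pit displaces far more than tilt displaces the crop-local extremum, so
slice-to-slice comparisons stay anchored to the pit. The test suite carries
a mean-centroid baseline as a foil and shows it mislocalises by up to ~7
slices on phantoms where the column-wise detector stays within ±1.

### Parameters

| parameter | default | units | rationale |
|---|---|---|---|
| n_adj | 16 | slices | 33-slice sub-volume ≈ 1.5 mm of macula |
| r_start, r_end | 59, 69 | slice index | expected fovea = mid-volume 64 ± 5 |
| P | 200 | pixel-rows | dominates plausible pit contrasts at typical H |
| central_frac | 0.35 | — | fovea + parafovea, excludes periphery |
| blur kernel, σ | 7×7, 1.0 | px | (kernel − 1)/6 ≈ 1.0 |
| ε | 1e-6 | — | guards the centroid division |
| fallback | 64 | slice index | mid-volume of the 128-slice protocol |

All defaults assume the 128-slice acquisition protocol; every value is a
constructor argument, and B-scan pixel dimensions are never assumed.

## 2. Synthetic retinal phantoms

Each phantom slice shows n_layers horizontal bright bands (default
intensities 210/120/180 on a background of 8) between a top and bottom
boundary. The foveal pit is an upward Gaussian displacement of the whole
band, with in-plane half-width 6 px, peak depth 14 px at the ground-truth
slice, and Gaussian decay along depth (σ = 2 slices). Tilt is an in-plane
rotation with border replication. Speckle is either multiplicative Gamma
(L = 4 looks by default — "moderate"; unit mean, the classical
fully-developed-speckle model) or additive Gaussian on unit-interval data
(the denoiser's training corruption). Drusen-like bumps are additive
Gaussian blobs at the upper surface.

The lower boundary additionally wobbles sinusoidally across slices
(amplitude 10 px, period 24 slices), emulating choroidal thickness variation
along the cube. This moves each slice's *mean* centroid around without
touching the upper surface — precisely the confound that breaks
global-centroid fovea detectors while leaving the column-wise minimum
untouched; it is what gives the baseline-vs-detector comparison its teeth.

What the phantoms do **not** emulate: coherent speckle statistics tied to a
point-spread function, vascular shadowing, motion artifacts, curved or
pathological layer topology. Passing phantom tests therefore demonstrates
the *mechanisms* (tilt invariance, penalty logic, volumetric noise
suppression, metric sign conventions), not clinical performance; phantom
noise levels are free parameters of the test conditions, not claims about
any scanner.

## 3. The volumetric denoiser

### Model

Working resolution 16×64×64 (in-plane bilinear resize; depth only ever
padded/cropped). Non-overlapping 3-D patches of (2, 4, 4) voxels are
linearly embedded to 48 channels (the exact strided-Conv3D equivalence),
giving an 8×16×16 token grid, plus factorised learned positional embeddings
(depth component + in-plane component). Four pre-norm transformer blocks
(2 stages × 2 blocks, MLP expansion 4, GELU, 4 heads) alternate window
orientation:

* **flop** blocks attend within 1×8×8 token windows — in-plane texture;
* **flip** blocks attend within depth-spanning windows of in-plane footprint
  2×2 — anatomical continuity across *all* slices at each location.

Making the flip windows span the full token depth (rather than a fixed
depth extent) means any even input depth is valid at inference; the depth
positional embedding is linearly interpolated when the inference depth
differs from the training grid. A single linear head maps each token back
to its 32 patch voxels and a terminal sigmoid pins the output to (0, 1); no
symmetric decoder exists. The default model has 128,912 parameters. The
blocks keep one token resolution throughout — at desk scale there is
nothing to gain from inter-stage downsampling, and a constant grid keeps
the depth-spanning windows valid for arbitrary depths.

### Training

Self-supervised: the raw (already speckled) volume is the target, the input
is that volume plus fresh `N(0, 0.15²)` noise clamped to [0, 1], redrawn
every optimisation step. Loss `MSE + 0.1·L1`; the L1 term favours sharp
layer boundaries. Optimiser Adam, fixed learning rate 1e-3, batch size 1,
shuffled volume order; everything derives from the config seed, so runs are
bit-reproducible. Identity mapping is avoided by the ever-changing
corruption together with the patch/attention bottleneck: the network can
only reduce the noise term by predicting structure from volumetric context.
On the desk-scale phantom corpus (8 volumes, 5 epochs ≈ 10 s on one CPU)
the loss falls monotonically by ~70% and held-out speckled phantoms show
the full improvement sign pattern (ΔLNV > 0, ΔISC > 0, ΔEntropy > 0,
ESPR ≈ 0.36).

Implementation is pure NumPy on a minimal reverse-mode autograd
(`foveoct.nn`) — tensors, broadcast arithmetic, batched matmul, softmax,
layer norm, GELU/sigmoid/tanh, Adam — with every analytic gradient checked
against central finite differences, including end-to-end through the full
network and hybrid loss.

### Inference

Deterministic (no corruption). Depth is padded to even by replicating the
last slice and cropped back afterwards, so odd-depth inputs (e.g. the
33-slice macular sub-volumes) come back with their depth intact; output
in-plane size is the working resolution.

## 4. Reference-free restoration metrics

For a noisy/denoised pair (noisy resized in-plane to the denoised geometry
when they differ; depth must match):

* **ΔLNV** = LNV(noisy) − LNV(denoised), where LNV is the mean per-voxel
  variance over a sliding 7×7 in-plane window (reflect-padded, never across
  slices). Window size is configurable; 7 matches the blur scale used
  elsewhere in the pipeline.
* **ESPR** = mean 3×3 Sobel gradient magnitude of denoised / noisy.
  Speckle itself carries large spurious gradients, so values well below 1
  are expected after effective denoising; (0, 1.5) is the plausible band,
  with values near 0 signalling over-smoothing.
* **ΔISC** = mean Pearson correlation of adjacent flattened slices,
  denoised − noisy. Constant slices make a pair undefined; such pairs are
  skipped with a logged count rather than zero-filled, and an all-skipped
  volume is an error.
* **ΔEntropy** = Shannon entropy (bits, 256 bins over [0, 1] or native
  uint8 levels) of noisy − denoised.

Positive deltas always mean improvement; ESPR is a ratio with
`espr(a,b) = 1/espr(b,a)`. An identical pair yields exactly (0, 1, 0, 0).
Reference-based metrics (PSNR/SSIM) are deliberately out of scope: no clean
reference exists for clinical OCT.

## 5. Diagnostic statistics

Per-class one-vs-rest counts feed sensitivity, specificity, precision and
F1 (zero denominators yield NaN, never a silent 0); summaries are overall
accuracy, balanced accuracy (mean sensitivity), macro precision/recall/F1
and support-weighted F1. Agreement uses the marginal-only multiclass MCC
(Gorodkin's R_K) and Cohen's kappa — both computable from the diagonal and
marginals alone, which is all a one-vs-rest table preserves; the marginal
form is verified against the full-matrix computation (scikit-learn) on
random confusion matrices. Degenerate cases (constant predictor/truth) are
defined as 0 with a flag, keeping batch evaluation total.

The paired McNemar test reports the continuity-corrected statistic
`(|b−c|−1)²/(b+c)`, the uncorrected `(b−c)²/(b+c)` (χ², 1 df), and an exact
two-sided binomial p-value computed as twice the smaller tail of
Binomial(b+c, ½) capped at 1 — verified against exhaustive enumeration for
b + c ≤ 12 and against statsmodels. With b = c the doubled tail caps at 1;
with b + c = 0 only the exact p (= 1) is defined and the result is flagged.
Report tables round half-up to 4 decimals; internal values keep full
precision.

## 6. Numerical choices and edge cases

* Slice files are 1-based on disk; in-memory arrays are 0-based with
  conversion only at I/O boundaries. Row coordinates inside the pit metric
  are 1-based so the empty-column sentinel is exactly H.
* Color slice images are accepted only when all channels are identical
  (single-channel extraction); genuine color is rejected rather than
  luminance-converted, which would shift Otsu thresholds.
* Depth padding replicates the last slice (not zeros) to preserve boundary
  inter-slice correlation.
* Unit-interval volumes written to 8-bit files are rounded to the nearest
  level — a documented lossy step; uint8 round-trips are bit-exact.
* Otsu and arg-min ties resolve to the smallest candidate, making every
  pipeline output deterministic.
* Float32 is used inside the network for speed; gradient-check tests run
  the same code in float64.

## 7. Problem sizes

The shipped test and reproduction conditions are desk-scale by design:
128×128×128 phantoms for the locator studies (50 seeded volumes, tilt
−8…8°, 4-look speckle), 16×64×64 phantoms for denoiser training (8 volumes,
5 epochs) and held-out evaluation (10 volumes), and 16×64×64 random volumes
for the exact naive-reference equivalence checks (20 volumes). These sizes
exercise every code path while keeping a full run in tens of seconds on a
single CPU core.

## 8. Known limitations

* The attention backbone is a documented generic variant; block counts,
  window shapes and embedding width are free parameters, and no claim is
  made about matching any particular proprietary micro-design or parameter
  count.
* The denoiser's working in-plane resolution (64×64 by default) bounds the
  detail it can restore; outputs are at working resolution, not native.
* Training at desk scale demonstrates convergence and the qualitative
  restoration effect, not clinical-grade restoration; no claims are made
  about real scanner data, which this package has never seen.
* Vendor container formats (DICOM-OPT, NAVIS-EX exports) and en-face
  fovea (x, y) localisation are out of scope.
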