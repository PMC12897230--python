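# foveoct

Fovea-centric preprocessing and self-supervised restoration for macular OCT
volumes, with the paired diagnostic statistics used to judge what restoration
buys downstream.

A macular OCT scan is a cube of up to 128 cross-sectional B-scans, most of
which lie outside the diagnostically relevant central macula, and all of
which are degraded by speckle — the granular interference noise inherent to
coherent imaging. `foveoct` addresses both problems for researchers building
automated AMD (age-related macular degeneration) analysis pipelines:

1. **Tilt-robust foveal slice localisation.** Each B-scan *i* is scored by a
   pit metric: crop the central 35% of columns, blur (7×7 Gaussian, σ = 1),
   binarise with Otsu's threshold, compute the tissue centroid
   `c_y(i, j) = M01 / M00` of every A-scan column *j*, and take

   `M_pit(i) = min_j c_y(i, j)`.

   The foveal pit is the thinnest point of the retina, so its slice has the
   highest (smallest-row) column centroid. Taking the *minimum* per column —
   rather than a global mean — makes the score insensitive to scan tilt and
   to retinal/choroidal thickness variation along the cube. An anatomical
   prior penalises slices outside the expected range [59, 69] by a constant
   P = 200 pixel-rows, and the arg-min slice anchors a standardized 33-slice
   sub-volume (fovea ± 16), shifted — never truncated — at volume borders.
   An all-degenerate volume falls back to the mid-volume slice 64.

2. **Self-supervised volumetric speckle denoising.** A decoder-free network
   (3-D patch embedding → transformer blocks whose windowed attention
   alternates between intra-slice "flop" and depth-spanning inter-slice
   "flip" orientations → linear reconstruction head → sigmoid) is trained to
   reconstruct each raw volume from a copy corrupted with fresh Gaussian
   noise (σ = 0.15) at every step, minimising `MSE + 0.1·L1`. Anatomy is
   continuous across slices and therefore predictable from volumetric
   context; speckle is independent across slices and is not — so the network
   learns to keep the former and suppress the latter, with no clean
   reference data. The network and its training loop are implemented in
   NumPy on a small reverse-mode autograd (`foveoct.nn`) whose gradients are
   finite-difference-checked in the test suite.

3. **Evaluation.** Reference-free restoration metrics for noisy/denoised
   pairs (ΔLNV local-variance drop, Sobel edge-strength preservation ratio,
   Δ inter-slice correlation, Δ Shannon entropy), and diagnostic statistics
   that survive class imbalance: per-class one-vs-rest rates, balanced
   accuracy, macro/weighted F1, multiclass Matthews correlation (marginal
   form), Cohen's kappa, and the paired McNemar test (continuity-corrected
   and exact binomial).

Seeded synthetic retinal phantoms — layered bright bands, a Gaussian foveal
pit at a known slice, controllable tilt, drusen-like bumps, and gamma or
Gaussian speckle — make every stage testable without clinical data.

## Worked example

```python
from foveoct import PhantomSpec, generate_phantom, add_speckle, locate_fovea

stack, truth = generate_phantom(PhantomSpec(pit_slice=62, tilt_deg=7.0, seed=11))
noisy = add_speckle(stack, "multiplicative_gamma", L=4.0, seed=3)
result = locate_fovea(noisy)
print(f"true pit slice: {truth}")
print(f"detected fovea: {result.fovea_index}  window: {result.window}")
```

```
true pit slice: 62
detected fovea: 62  window: (46, 78)
```

Despite 7° of tilt and heavy 4-look speckle, the column-wise minimum-centroid
metric recovers the ground-truth pit slice exactly, and the 33-slice window
(46–78) is centred on it.

The diagnostic statistics reproduce a published paired evaluation of a
frozen 3-class AMD classifier on 857 scans before and after denoising,
starting from nothing but the printed integer confusion counts
(`foveoct.datasets`):

```python
from foveoct import macro_summary, multiclass_agreement, mcnemar
from foveoct.datasets import example_ovr_counts, example_paired_table

counts = example_ovr_counts("noisy")
s = macro_summary(counts)
ag = multiclass_agreement(counts.marginals())
r = mcnemar(example_paired_table())
```

```
balanced accuracy 0.5715  macro F1 0.4496  MCC 0.2912  kappa 0.2426
McNemar chi2 (corrected) 262.0038  exact p 6.75e-80
```

Under noise the classifier's balanced accuracy (0.5715) is barely above
chance for the minority disease classes even though raw accuracy looks
acceptable — exactly the imbalance pathology these metrics are designed to
expose — and the McNemar test shows the 264-vs-0 split of discordant paired
outcomes is overwhelmingly significant.

## Command line

```
foveoct simulate       --spec spec.yaml --out DIR [--speckle gamma]
foveoct extract-fovea  --in SCAN_DIR --out DIR [--report report.json] [--batch]
foveoct denoise-train  --data ROOT --config cfg.yaml --out MODEL_DIR
foveoct denoise-apply  --model MODEL_DIR --in SCAN_DIR --out DIR
foveoct eval-restoration --noisy DIR --denoised DIR --out metrics.csv
foveoct eval-paired    --counts counts.csv --paired paired.csv --out report.json
foveoct convert        --in DIR --out DIR [--out-pattern STR]
```

Scans are folders of 8-bit grayscale BMP/PNG slices named `oct_c_{i}.bmp`
(1-based, configurable).

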