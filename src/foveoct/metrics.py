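"""Reference-free restoration metrics for paired noisy/denoised OCT volumes.

Clean ground truth does not exist for clinical OCT, so restoration quality is
judged by four complementary statistics computed on the noisy volume, the
denoised volume, or both:

* **delta LNV** — drop in mean local (windowed, per-slice) intensity variance;
  positive values mean residual speckle was removed.
* **ESPR** — edge-strength preservation ratio: mean Sobel gradient magnitude
  of the denoised volume over that of the noisy one.  Speckle itself carries
  large spurious gradients, so effective denoising typically yields a ratio
  well below 1 even when anatomical edges survive.
* **delta ISC** — gain in mean Pearson correlation between adjacent B-scans;
  anatomy is continuous along depth while speckle is not, so restoring
  structure raises inter-slice correlation.
* **delta entropy** — drop in Shannon entropy (bits, 256-bin histogram);
  suppressing stochastic noise concentrates the intensity distribution.

Sign conventions: delta LNV and delta entropy are noisy minus denoised,
delta ISC is denoised minus noisy — positive always means improvement.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.transform import resize as _sk_resize

from .volume_io import BScanStack

__all__ = [
    "RestorationMetrics",
    "local_noise_variance",
    "edge_strength",
    "inter_slice_correlation",
    "shannon_entropy",
    "compare_pair",
]

logger = logging.getLogger(__name__)

_SOBEL_X = np.array([[-1, 0, 1], [-2, 0, 2], [-1, 0, 1]], dtype=np.float64)


@dataclass
class RestorationMetrics:
    delta_lnv: float
    espr: float
    delta_isc: float
    delta_entropy: float
    scan_id: str = ""


def _as_float_volume(volume) -> np.ndarray:
    if isinstance(volume, BScanStack):
        arr = volume.slices.astype(np.float64)
        if volume.dtype_domain == "uint8":
            arr /= 255.0
        return arr
    arr = np.asarray(volume, dtype=np.float64)
    if arr.ndim != 3:
        raise ValueError("expected a (D, H, W) volume")
    return arr


def local_noise_variance(volume, window: int = 7) -> float:
    """Mean per-voxel variance over a sliding in-plane window (reflect pad)."""
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be an odd integer >= 3")
    arr = _as_float_volume(volume)
    if window > arr.shape[1] or window > arr.shape[2]:
        raise ValueError("window larger than the slice")
    size = (1, window, window)  # never smooth across slices
    mean = ndimage.uniform_filter(arr, size=size, mode="reflect")
    meansq = ndimage.uniform_filter(arr * arr, size=size, mode="reflect")
    var = np.maximum(meansq - mean * mean, 0.0)
    return float(var.mean())


def edge_strength(volume) -> float:
    """Mean 3x3 Sobel gradient magnitude over all voxels (per-slice, in plane)."""
    arr = _as_float_volume(volume)
    if arr.shape[1] < 3 or arr.shape[2] < 3:
        raise ValueError("slices must be at least 3x3")
    total = 0.0
    for s in arr:
        gx = ndimage.convolve(s, _SOBEL_X, mode="reflect")
        gy = ndimage.convolve(s, _SOBEL_X.T, mode="reflect")
        total += float(np.sqrt(gx * gx + gy * gy).mean())
    return total / arr.shape[0]


def inter_slice_correlation(volume) -> float:
    """Mean Pearson correlation of flattened adjacent slice pairs.

    Pairs in which either slice is constant have no defined correlation and
    are skipped (with a logged count); if every pair is skipped the statistic
    is undefined and an error is raised.
    """
    arr = _as_float_volume(volume)
    if arr.shape[0] < 2:
        raise ValueError("need at least two slices")
    flat = arr.reshape(arr.shape[0], -1)
    stds = flat.std(axis=1)
    corrs = []
    skipped = 0
    for i in range(arr.shape[0] - 1):
        if stds[i] == 0.0 or stds[i + 1] == 0.0:
            skipped += 1
            continue
        a = flat[i] - flat[i].mean()
        b = flat[i + 1] - flat[i + 1].mean()
        corrs.append(float(np.dot(a, b) / (np.linalg.norm(a) * np.linalg.norm(b))))
    if skipped:
        logger.warning("inter_slice_correlation: skipped %d constant-slice pairs", skipped)
    if not corrs:
        raise ValueError("all adjacent pairs involve a constant slice; correlation undefined")
    return float(np.mean(corrs))


def shannon_entropy(volume, bins: int = 256) -> float:
    """Shannon entropy in bits of the 256-bin intensity histogram.

    uint8 volumes use their native levels; unit-interval volumes are
    quantised as floor(v * bins) clipped to [0, bins - 1].
    """
    if isinstance(volume, BScanStack) and volume.dtype_domain == "uint8":
        levels = volume.slices.reshape(-1).astype(np.int64)
    else:
        arr = np.asarray(volume.slices if isinstance(volume, BScanStack) else volume, dtype=np.float64)
        levels = np.clip(np.floor(arr.reshape(-1) * bins), 0, bins - 1).astype(np.int64)
    counts = np.bincount(levels, minlength=bins).astype(np.float64)
    p = counts / counts.sum()
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def compare_pair(noisy: BScanStack, denoised: BScanStack, window: int = 7) -> RestorationMetrics:
    """All four statistics for one noisy/denoised pair.

    The two volumes must share depth; if their in-plane sizes differ (the
    denoiser works at a fixed resolution), the noisy volume is bilinearly
    resized to the denoised size so the comparison is spatially aligned.
    """
    a = _as_float_volume(noisy)
    b = _as_float_volume(denoised)
    if a.shape[0] != b.shape[0]:
        raise ValueError(f"depth mismatch: {a.shape[0]} vs {b.shape[0]}")
    if a.shape[1:] != b.shape[1:]:
        a = np.clip(
            np.stack(
                [
                    _sk_resize(s, b.shape[1:], order=1, mode="edge",
                               anti_aliasing=False, preserve_range=True)
                    for s in a
                ]
            ),
            0.0,
            1.0,
        )
    es_noisy = edge_strength(a)
    if es_noisy < 1e-12:  # flat volume up to float residue
        raise ValueError("noisy volume has zero edge strength; ESPR undefined")
    scan_id = getattr(denoised, "scan_id", "") or getattr(noisy, "scan_id", "")
    return RestorationMetrics(
        delta_lnv=local_noise_variance(a, window) - local_noise_variance(b, window),
        espr=edge_strength(b) / es_noisy,
        delta_isc=inter_slice_correlation(b) - inter_slice_correlation(a),
        delta_entropy=shannon_entropy(a) - shannon_entropy(b),
        scan_id=scan_id,
    )
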