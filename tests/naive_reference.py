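"""Deliberately naive per-pixel reference implementations used as oracles.

Everything here is written as plain loops over pixels, independent of the
vectorized library code paths it is used to check.  Slow on purpose.
"""

from __future__ import annotations

import numpy as np


def naive_blur(image: np.ndarray, size: int, sigma: float) -> np.ndarray:
    """7x7 (or any odd) Gaussian blur with symmetric boundary handling."""
    half = size // 2
    ax = np.arange(-half, half + 1, dtype=np.float64)
    kernel = np.exp(-(ax[:, None] ** 2 + ax[None, :] ** 2) / (2.0 * sigma**2))
    kernel /= kernel.sum()
    padded = np.pad(image.astype(np.float64), half, mode="symmetric")
    h, w = image.shape
    out = np.empty((h, w), dtype=np.float64)
    for i in range(h):
        for j in range(w):
            out[i, j] = float((padded[i : i + size, j : j + size] * kernel).sum())
    return out


def naive_otsu(image: np.ndarray) -> int | None:
    """Exhaustive search over thresholds k in [1, 255]; classes {<k}, {>=k}."""
    flat = image.reshape(-1).astype(np.int64)
    best_k, best_crit = None, -np.inf
    for k in range(1, 256):
        lo = flat[flat < k]
        hi = flat[flat >= k]
        if lo.size == 0 or hi.size == 0:
            continue
        crit = lo.size * hi.size * (lo.mean() - hi.mean()) ** 2
        if crit > best_crit:
            best_crit, best_k = crit, k
    return best_k


def naive_preprocess(image: np.ndarray, central_frac: float = 0.35,
                     size: int = 7, sigma: float = 1.0) -> tuple[np.ndarray, bool]:
    h, w = image.shape
    lo = int(np.floor((0.5 - central_frac / 2.0) * w))
    hi = int(np.floor((0.5 + central_frac / 2.0) * w))
    central = image[:, lo:hi]
    blurred = naive_blur(central, size, sigma)
    quant = np.clip(np.rint(blurred), 0, 255).astype(np.uint8)
    k = naive_otsu(quant)
    if k is None:
        return np.zeros_like(quant, dtype=bool), True
    return quant >= k, False


def naive_centroids(mask: np.ndarray, epsilon: float = 1e-6) -> np.ndarray:
    h, w = mask.shape
    out = np.empty(w, dtype=np.float64)
    for j in range(w):
        m00 = 0.0
        m01 = 0.0
        for i in range(h):
            if mask[i, j]:
                m00 += 1.0
                m01 += i + 1.0  # 1-based rows
        out[j] = m01 / m00 if m00 > epsilon else float(h)
    return out


def naive_locate(volume: np.ndarray, r_start: int, r_end: int, penalty: float,
                 fallback: int) -> tuple[int, list[float]]:
    """Full pipeline on a (D, H, W) uint8 volume; returns (1-based index, scores)."""
    scores: list[float] = []
    degenerate: list[bool] = []
    for k in range(volume.shape[0]):
        mask, flag = naive_preprocess(volume[k])
        if not flag and not mask.any():
            flag = True
        cy = naive_centroids(mask)
        raw = float(min(cy))
        i = k + 1
        scores.append(raw if r_start <= i <= r_end else raw + penalty)
        degenerate.append(flag)
    if all(degenerate):
        return min(max(fallback, 1), volume.shape[0]), scores
    best = 0
    for k in range(1, len(scores)):
        if scores[k] < scores[best]:
            best = k
    return best + 1, scores


def naive_local_variance(volume: np.ndarray, window: int) -> float:
    """Sliding-window variance per voxel via explicit patch loops."""
    half = window // 2
    total = 0.0
    count = 0
    for s in volume:
        padded = np.pad(np.asarray(s, dtype=np.float64), half, mode="symmetric")
        h, w = s.shape
        for i in range(h):
            for j in range(w):
                patch = padded[i : i + window, j : j + window]
                total += float(patch.var())
                count += 1
    return total / count


def naive_sobel_mean(volume: np.ndarray) -> float:
    """Mean Sobel magnitude via explicit 3x3 correlation at each pixel."""
    kx = np.array([[-1, 0, 1], [-2, 0, 2], [-1, 0, 1]], dtype=np.float64)
    ky = kx.T
    total = 0.0
    for s in volume:
        padded = np.pad(np.asarray(s, dtype=np.float64), 1, mode="symmetric")
        h, w = s.shape
        mag = 0.0
        for i in range(h):
            for j in range(w):
                patch = padded[i : i + 3, j : j + 3]
                # correlation (no kernel flip); both kernels are antisymmetric,
                # so convolution equals correlation with the sign flipped and
                # the magnitude is identical either way
                gx = float((patch * kx).sum())
                gy = float((patch * ky).sum())
                mag += np.hypot(gx, gy)
        total += mag / (h * w)
    return total / volume.shape[0]
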