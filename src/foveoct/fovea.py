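"""Tilt-robust foveal slice detection and 33-slice macular sub-volume extraction.

The detector scores every B-scan of a macular cube with a *pit metric*: the
central 35% of the slice width is cropped, mildly Gaussian-smoothed (7x7,
sigma 1.0), binarised with Otsu's threshold, and the intensity-weighted mean
row (centroid) of each A-scan column is computed.  The minimum column
centroid marks the highest point of the segmented tissue — at the fovea the
retina thins and its surface rises, so the slice showing the foveal pit has
the smallest minimum centroid.  Because the minimum is taken per column,
the score is insensitive to an overall in-plane tilt of the retina, which
shifts all column centroids by a linear ramp but barely moves the minimum
relative to other slices; a global (mean) centroid would instead be dominated
by tilt and by thickness variation elsewhere in the scan.

An anatomical prior is encoded as a penalty: slices outside the clinically
expected foveal range (59-69 in a 128-slice cube, i.e. mid-volume +/- 5) have
a constant P = 200 pixel-rows added to their score, so they can win only with
an exceptionally strong pit signature.  The arg-min slice anchors a fixed
33-slice sub-volume (fovea +/- 16); windows that would fall off either end of
the cube are shifted, never truncated, so every extraction has the same depth.

All slice indices in this module are 1-based, matching the on-disk export
convention; row coordinates inside the metric are 1-based as well so that the
"no tissue" sentinel equals the image height H.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import convolve as _nd_convolve

from .volume_io import BScanStack

__all__ = [
    "FoveaParams",
    "SlicePitProfile",
    "FoveaResult",
    "gaussian_kernel2d",
    "otsu_threshold",
    "preprocess_slice",
    "column_centroids",
    "slice_pit_metric",
    "locate_fovea",
    "extract_subvolume",
]


@dataclass(frozen=True)
class FoveaParams:
    """Tunables of the locator; defaults follow the 128-slice protocol."""

    n_adj: int = 16                 # slices kept on each side of the fovea
    total_slices: int = 128
    r_start: int = 59               # preferred foveal range, 1-based inclusive
    r_end: int = 69
    penalty: float = 200.0          # pixel-rows added outside [r_start, r_end]
    central_frac: float = 0.35      # width fraction analysed per slice
    blur_kernel: int = 7
    blur_sigma: float = 1.0
    epsilon: float = 1e-6           # guards the centroid division
    fallback_slice: int = 64        # mid-volume default when nothing is found

    def __post_init__(self) -> None:
        if not (1 <= self.r_start <= self.r_end <= self.total_slices):
            raise ValueError("need 1 <= r_start <= r_end <= total_slices")
        if not (0 < self.central_frac <= 1):
            raise ValueError("central_frac must lie in (0, 1]")
        if self.penalty < 0:
            raise ValueError("penalty must be >= 0")
        if 2 * self.n_adj + 1 > self.total_slices:
            raise ValueError("sub-volume cannot exceed the full volume")

    @property
    def window_size(self) -> int:
        return 2 * self.n_adj + 1


@dataclass
class SlicePitProfile:
    """Per-slice diagnostics: centroids plus raw and penalised pit metrics."""

    slice_index: int                # 1-based
    centroids: np.ndarray           # length Wc, 1-based row units, sentinel H
    raw_metric: float
    penalized_metric: float
    degenerate: bool = False        # all-zero tissue mask (sentinel-only slice)


@dataclass
class FoveaResult:
    fovea_index: int                          # 1-based
    window: tuple[int, int]                   # inclusive 1-based (k_start, k_end)
    profiles: list[SlicePitProfile] = field(default_factory=list)
    used_fallback: bool = False
    shifted_window: bool = False
    short_volume: bool = False                # D < 33: whole stack returned


def gaussian_kernel2d(size: int, sigma: float) -> np.ndarray:
    """Normalised odd-sized 2-D Gaussian kernel sampled at integer offsets."""
    if size % 2 != 1 or size < 1:
        raise ValueError("kernel size must be odd and positive")
    half = size // 2
    ax = np.arange(-half, half + 1, dtype=np.float64)
    g = np.exp(-(ax[:, None] ** 2 + ax[None, :] ** 2) / (2.0 * sigma**2))
    return g / g.sum()


def otsu_threshold(image: np.ndarray) -> int | None:
    """Otsu's threshold over a 256-bin histogram of an integer-valued image.

    Returns the smallest k in [1, 255] maximising the between-class variance
    w0(k) * w1(k) * (mu0 - mu1)^2, where class 0 holds values < k and class 1
    values >= k.  Returns ``None`` when the image is constant (no split
    leaves both classes populated).
    """
    hist = np.bincount(image.reshape(-1).astype(np.int64), minlength=256)[:256].astype(np.float64)
    total = hist.sum()
    csum = np.cumsum(hist)            # csum[k-1] = count of values < k
    cmoment = np.cumsum(hist * np.arange(256))
    w0 = csum[:-1]                    # candidate k = 1..255
    w1 = total - w0
    valid = (w0 > 0) & (w1 > 0)
    if not valid.any():
        return None
    mu0 = np.where(w0 > 0, cmoment[:-1] / np.maximum(w0, 1), 0.0)
    mu1 = np.where(w1 > 0, (cmoment[-1] - cmoment[:-1]) / np.maximum(w1, 1), 0.0)
    crit = np.where(valid, w0 * w1 * (mu0 - mu1) ** 2, -np.inf)
    return int(np.argmax(crit)) + 1   # first maximum wins


def central_bounds(width: int, central_frac: float = 0.35) -> tuple[int, int]:
    """Half-open column bounds of the central analysis region.

    [floor((0.5 - f/2) * W), floor((0.5 + f/2) * W)) — approximately f * W
    columns centred on the image, reproducible for every integer width.
    """
    lo = int(np.floor((0.5 - central_frac / 2.0) * width))
    hi = int(np.floor((0.5 + central_frac / 2.0) * width))
    return lo, hi


def preprocess_slice(image: np.ndarray, params: FoveaParams = FoveaParams()) -> tuple[np.ndarray, bool]:
    """Crop -> blur -> Otsu-binarise one B-scan.

    Returns ``(mask, degenerate)`` where ``mask`` is a boolean array over the
    central region (True = tissue) and ``degenerate`` flags a constant
    central region on which Otsu's criterion is undefined; such slices get an
    all-zero mask and feed the mid-volume fallback.
    """
    img = np.asarray(image)
    if img.ndim != 2:
        raise ValueError("expected a 2-D grayscale B-scan")
    h, w = img.shape
    if h < params.blur_kernel or w * params.central_frac < 1:
        raise ValueError("image too small for the configured crop/blur")
    lo, hi = central_bounds(w, params.central_frac)
    central = img[:, lo:hi].astype(np.float64)
    kernel = gaussian_kernel2d(params.blur_kernel, params.blur_sigma)
    blurred = _nd_convolve(central, kernel, mode="reflect")
    quant = np.clip(np.rint(blurred), 0, 255).astype(np.uint8)
    t = otsu_threshold(quant)
    if t is None:
        return np.zeros_like(quant, dtype=bool), True
    return quant >= t, False


def column_centroids(mask: np.ndarray, epsilon: float = 1e-6) -> np.ndarray:
    """Intensity-weighted mean row per column of a binary mask.

    Rows are 1-based (x = 1..H) so an empty column's sentinel value is
    exactly H, below any real centroid of a full column and above every
    centroid of a column with tissue anywhere but the bottom row.
    """
    m = np.asarray(mask, dtype=np.float64)
    h = m.shape[0]
    rows = np.arange(1, h + 1, dtype=np.float64)[:, None]
    m00 = m.sum(axis=0)
    m01 = (rows * m).sum(axis=0)
    return np.where(m00 > epsilon, m01 / np.where(m00 > epsilon, m00, 1.0), float(h))


def slice_pit_metric(
    cy: np.ndarray, slice_index: int, params: FoveaParams = FoveaParams()
) -> SlicePitProfile:
    """Minimum column centroid, penalised outside the preferred foveal range."""
    cy = np.asarray(cy, dtype=np.float64)
    if cy.size == 0:
        raise ValueError("centroid vector must be non-empty")
    raw = float(cy.min())
    in_range = params.r_start <= slice_index <= params.r_end
    penalized = raw if in_range else raw + params.penalty
    return SlicePitProfile(slice_index, cy, raw, penalized)


def locate_fovea(stack: BScanStack, params: FoveaParams = FoveaParams()) -> FoveaResult:
    """Score every slice and pick the arg-min of the penalised pit metric.

    Ties break toward the lowest slice index.  If every slice is degenerate
    (no tissue segmented anywhere — e.g. an all-black volume), the detector
    falls back to the mid-volume slice, clipped into [1, D], and flags it.
    """
    if stack.dtype_domain == "unit":
        data = np.clip(np.rint(stack.slices * 255.0), 0, 255).astype(np.uint8)
    else:
        data = stack.slices
    d = stack.depth
    profiles: list[SlicePitProfile] = []
    for k in range(d):
        mask, degenerate = preprocess_slice(data[k], params)
        if not degenerate and not mask.any():
            degenerate = True
        cy = column_centroids(mask, params.epsilon)
        prof = slice_pit_metric(cy, k + 1, params)
        prof.degenerate = degenerate
        profiles.append(prof)

    used_fallback = all(p.degenerate for p in profiles)
    if used_fallback:
        fovea_index = int(np.clip(params.fallback_slice, 1, d))
    else:
        scores = np.array([p.penalized_metric for p in profiles])
        fovea_index = int(np.argmin(scores)) + 1  # np.argmin returns the first minimum

    _, window, shifted, short = _extraction_window(d, fovea_index, params)
    return FoveaResult(
        fovea_index=fovea_index,
        window=window,
        profiles=profiles,
        used_fallback=used_fallback,
        shifted_window=shifted,
        short_volume=short,
    )


def _extraction_window(
    depth: int, fovea_index: int, params: FoveaParams
) -> tuple[slice, tuple[int, int], bool, bool]:
    size = params.window_size
    if depth < size:
        return slice(0, depth), (1, depth), False, True
    ks = fovea_index - params.n_adj
    ke = fovea_index + params.n_adj
    shifted = ks < 1 or ke > depth
    if ks < 1:
        ks, ke = 1, size
    if ke > depth:
        ks, ke = depth - size + 1, depth
    return slice(ks - 1, ke), (ks, ke), shifted, False


def extract_subvolume(
    stack: BScanStack, fovea_index: int, params: FoveaParams = FoveaParams()
) -> tuple[BScanStack, tuple[int, int]]:
    """Cut the fixed-width fovea-centred window out of a volume.

    The nominal window [fovea - 16, fovea + 16] is shifted (not truncated) to
    fit inside [1, D], so the result always has 2*n_adj + 1 slices.  Volumes
    shorter than the window are returned whole — a graceful answer to
    truncated real-world acquisitions.
    """
    if not (1 <= fovea_index <= stack.depth):
        raise ValueError(f"fovea_index {fovea_index} outside [1, {stack.depth}]")
    sl, window, _, _ = _extraction_window(stack.depth, fovea_index, params)
    sub = BScanStack(
        stack.slices[sl].copy(), dtype_domain=stack.dtype_domain, scan_id=stack.scan_id
    )
    return sub, window
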