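"""Seeded retinal phantoms for exercising the pipeline without clinical data.

A phantom volume emulates the gross appearance of a macular OCT cube: a stack
of B-scans, each showing horizontal hyper-reflective tissue bands on a dark
background.  A foveal pit is modelled as an upward (smaller-row) Gaussian
displacement of the layer surfaces, maximal at a known slice near
mid-volume and decaying along depth, so a column-wise minimum-centroid
criterion identifies it by construction.  Optional in-plane tilt, drusen-like
bumps, a slow per-slice wobble of the lower tissue boundary (emulating
choroidal thickness variation along the cube), and multiplicative or additive
speckle-like noise complete the picture.

These phantoms are deliberately schematic: they reproduce the geometric and
statistical features the fovea locator and denoiser rely on, not the physics
of coherent imaging.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from skimage.transform import rotate as _sk_rotate

from .volume_io import BScanStack

__all__ = ["PhantomSpec", "PhantomSpecError", "generate_phantom", "apply_tilt", "add_speckle"]


class PhantomSpecError(ValueError):
    """Inconsistent phantom geometry or invalid noise-model parameters."""


@dataclass
class PhantomSpec:
    """Geometry of one synthetic retinal volume.

    The defaults describe a 128-slice cube with a three-band retina and a
    14-pixel-deep pit at the mid-volume slice — a caricature of the standard
    fovea-centred acquisition protocol.  ``bottom_wobble_px`` adds a slow
    sinusoidal variation of the lower tissue boundary across slices; it moves
    the per-slice *mean* centroid around without touching the upper surface,
    which is exactly the confound that defeats global-centroid fovea
    detectors while leaving the column-wise minimum criterion unaffected.
    """

    D: int = 128
    H: int = 128
    W: int = 128
    n_layers: int = 3
    layer_intensities: tuple[float, ...] = (210.0, 120.0, 180.0)
    retina_top_row: int = 45
    retina_bottom_row: int = 95
    pit_slice: int = 64          # 1-based ground-truth foveal slice
    pit_depth_px: float = 14.0
    pit_halfwidth_px: float = 6.0
    pit_axial_sigma_slices: float = 2.0
    tilt_deg: float = 0.0
    drusen: tuple[tuple[int, int, float, float], ...] = ()  # (slice, col, radius, amplitude)
    bottom_wobble_px: float = 10.0
    bottom_wobble_period: float = 24.0
    background_level: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (1 <= self.pit_slice <= self.D):
            raise PhantomSpecError(f"pit_slice {self.pit_slice} outside [1, {self.D}]")
        if not (0 <= self.retina_top_row < self.retina_bottom_row < self.H):
            raise PhantomSpecError("need retina_top_row < retina_bottom_row < H")
        if self.n_layers < 2 or len(self.layer_intensities) != self.n_layers:
            raise PhantomSpecError("n_layers >= 2 with one intensity per layer")
        if any(not (0 <= v <= 255) for v in self.layer_intensities):
            raise PhantomSpecError("layer intensities must lie in [0, 255]")
        if self.pit_halfwidth_px <= 0 or self.pit_axial_sigma_slices <= 0:
            raise PhantomSpecError("pit half-width and axial sigma must be positive")
        if self.pit_depth_px < 0:
            raise PhantomSpecError("pit depth must be non-negative")


def generate_phantom(spec: PhantomSpec) -> tuple[BScanStack, int]:
    """Render a clean phantom volume; returns ``(stack, ground_truth_pit_slice)``.

    The same spec (including seed) always produces an identical volume.  Tilt
    requested through ``spec.tilt_deg`` is applied with :func:`apply_tilt`;
    noise is added separately with :func:`add_speckle`.
    """
    D, H, W = spec.D, spec.H, spec.W
    rows = np.arange(H, dtype=np.float64)[:, None]
    cols = np.arange(W, dtype=np.float64)[None, :]
    center = (W - 1) / 2.0
    radial = np.exp(-((cols - center) ** 2) / (2.0 * spec.pit_halfwidth_px**2))  # (1, W)

    vol = np.full((D, H, W), spec.background_level, dtype=np.float64)
    for k in range(D):
        i = k + 1  # 1-based slice index
        axial = np.exp(-((i - spec.pit_slice) ** 2) / (2.0 * spec.pit_axial_sigma_slices**2))
        lift = spec.pit_depth_px * axial * radial  # upward (smaller row) surface shift
        bottom = spec.retina_bottom_row + spec.bottom_wobble_px * np.sin(
            2.0 * np.pi * i / spec.bottom_wobble_period
        )
        top_edge = spec.retina_top_row - lift          # (1, W)
        bot_edge = bottom - lift
        thickness = bot_edge - top_edge
        img = vol[k]
        # integer layer index per pixel: n_layers equal bands between the edges
        inside = (rows >= top_edge) & (rows < bot_edge)
        frac = np.clip((rows - top_edge) / thickness, 0.0, 1.0 - 1e-12)
        layer_idx = np.floor(frac * spec.n_layers).astype(int)
        for li, intensity in enumerate(spec.layer_intensities):
            img[inside & (layer_idx == li)] = intensity
        for ds, dc, dr, da in spec.drusen:
            if ds == i:
                drow = float(spec.retina_top_row - lift[0, min(max(int(dc), 0), W - 1)])
                bump = da * np.exp(-(((cols - dc) ** 2) + ((rows - drow) ** 2)) / (2.0 * dr**2))
                img += bump
    vol = np.clip(np.rint(vol), 0, 255).astype(np.uint8)
    stack = BScanStack(vol, dtype_domain="uint8", scan_id=f"phantom-{spec.seed}")
    if spec.tilt_deg != 0.0:
        stack = apply_tilt(stack, spec.tilt_deg)
    return stack, spec.pit_slice


def apply_tilt(stack: BScanStack, theta_deg: float) -> BScanStack:
    """Rotate every B-scan in-plane by ``theta_deg`` about the image centre.

    Border replication avoids dark wedges at the corners; bilinear
    interpolation is used except for the exact ``theta == 0`` path, which is
    an interpolation-free identity.  Tilts beyond |15|° exceed what the
    locator's geometry argument covers and are rejected.
    """
    if abs(theta_deg) > 15.0:
        raise PhantomSpecError("|tilt| must be <= 15 degrees")
    if theta_deg == 0.0:
        return replace(stack, slices=stack.slices.copy())
    out = np.empty_like(stack.slices, dtype=np.float64)
    for k in range(stack.depth):
        out[k] = _sk_rotate(
            stack.slices[k].astype(np.float64),
            theta_deg,
            mode="edge",
            order=1,
            preserve_range=True,
        )
    if stack.dtype_domain == "uint8":
        out = np.clip(np.rint(out), 0, 255).astype(np.uint8)
    else:
        out = np.clip(out, 0.0, 1.0)
    return replace(stack, slices=out)


def add_speckle(
    stack: BScanStack,
    model: str = "multiplicative_gamma",
    *,
    L: float = 4.0,
    sigma: float = 0.15,
    seed: int = 0,
) -> BScanStack:
    """Add slice-independent speckle-like noise to a volume.

    ``multiplicative_gamma`` multiplies each voxel by an i.i.d. Gamma(L, 1/L)
    variate (unit mean; ``L`` is the number of looks — larger L means milder
    speckle), the classical fully-developed-speckle model for coherent
    imaging.  ``additive_gaussian`` adds N(0, sigma²) and requires a
    unit-interval stack; it matches the corruption used for self-supervised
    training.  Noise is uncorrelated across slices, mirroring the physical
    premise that a speckle granule in slice z says nothing about slice z+1.
    Output is clamped to the stack's valid intensity domain.
    """
    rng = np.random.default_rng(seed)
    data = stack.slices.astype(np.float64)
    if model == "multiplicative_gamma":
        if L < 1:
            raise PhantomSpecError("gamma speckle requires L >= 1")
        if np.isinf(L):
            noisy = data
        else:
            noisy = data * rng.gamma(shape=L, scale=1.0 / L, size=data.shape)
    elif model == "additive_gaussian":
        if sigma < 0:
            raise PhantomSpecError("sigma must be >= 0")
        if stack.dtype_domain != "unit":
            raise PhantomSpecError("additive Gaussian speckle requires a unit-interval stack")
        noisy = data if sigma == 0 else data + rng.normal(0.0, sigma, size=data.shape)
    else:
        raise PhantomSpecError(f"unknown speckle model {model!r}")

    if stack.dtype_domain == "uint8":
        if model == "multiplicative_gamma" and np.isinf(L):
            out = stack.slices.copy()
        else:
            out = np.clip(np.rint(noisy), 0, 255).astype(np.uint8)
    else:
        out = np.clip(noisy, 0.0, 1.0)
    return replace(stack, slices=out)
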