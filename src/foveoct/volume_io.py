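"""Reading and writing macular OCT volumes stored as per-slice image folders.

A volumetric macular scan is exported by the acquisition software as one
folder of 8-bit grayscale B-scan images named by slice index (by default
``oct_c_{i}.bmp`` with ``i`` starting at 1).  This module assembles such
folders into :class:`BScanStack` arrays, writes stacks back out, and provides
the intensity/depth normalisation helpers the denoiser relies on.

Slice files are 1-based on disk; all in-memory arrays are 0-based along the
depth axis.  The conversion happens only at the I/O boundary.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import imageio.v3 as iio
import numpy as np

__all__ = [
    "BScanStack",
    "GapError",
    "DimensionError",
    "EmptyScanError",
    "read_volume",
    "write_volume",
    "to_unit_interval",
    "pad_depth_even",
    "crop_depth",
    "DEFAULT_PATTERN",
]

DEFAULT_PATTERN = "oct_c_{i}.bmp"


class GapError(ValueError):
    """A slice index is missing from an otherwise contiguous 1..D run."""


class DimensionError(ValueError):
    """Slices in one scan folder do not share identical height/width."""


class EmptyScanError(ValueError):
    """A scan folder contains no slices matching the filename template.

    Callers batch-processing many scans may catch this and skip the folder.
    """


@dataclass
class BScanStack:
    """An ordered stack of equally sized grayscale B-scans (one OCT volume).

    Parameters
    ----------
    slices : ndarray, shape (D, H, W)
        Intensities, depth-major.  Either ``uint8`` in [0, 255] or a float
        array in [0, 1] depending on ``dtype_domain``.
    dtype_domain : {"uint8", "unit"}
    scan_id : str
        Opaque identifier (usually the folder name).
    """

    slices: np.ndarray
    dtype_domain: str = "uint8"
    scan_id: str = ""
    slice_index_base: int = field(default=1, repr=False)

    def __post_init__(self) -> None:
        arr = np.asarray(self.slices)
        if arr.ndim != 3:
            raise DimensionError(f"expected (D, H, W) array, got shape {arr.shape}")
        if arr.shape[0] < 1:
            raise DimensionError("a volume needs at least one slice")
        if self.dtype_domain == "uint8":
            if arr.dtype != np.uint8:
                if arr.min() < 0 or arr.max() > 255:
                    raise ValueError("uint8 domain requires values in [0, 255]")
                arr = arr.astype(np.uint8)
        elif self.dtype_domain == "unit":
            arr = np.asarray(arr, dtype=np.float64)
            if arr.size and (arr.min() < 0.0 or arr.max() > 1.0):
                raise ValueError("unit domain requires values in [0, 1]")
        else:
            raise ValueError(f"unknown dtype_domain {self.dtype_domain!r}")
        self.slices = arr

    @property
    def depth(self) -> int:
        return self.slices.shape[0]

    @property
    def height(self) -> int:
        return self.slices.shape[1]

    @property
    def width(self) -> int:
        return self.slices.shape[2]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.slices.shape


def _load_grayscale(path: Path) -> np.ndarray:
    """Load one slice image as 2-D uint8, rejecting genuinely colored inputs.

    Scans are grayscale by acquisition; a 3-channel file whose channels are
    identical is accepted (single-channel extraction), anything else is
    rejected rather than silently luminance-converted, because a luminance
    remap would shift downstream Otsu thresholds.
    """
    img = iio.imread(path)
    if img.ndim == 3:
        if img.shape[2] == 4:
            img = img[:, :, :3]
        if not (np.array_equal(img[:, :, 0], img[:, :, 1]) and np.array_equal(img[:, :, 0], img[:, :, 2])):
            raise DimensionError(f"{path.name}: color image with non-identical channels; expected grayscale")
        img = img[:, :, 0]
    if img.ndim != 2:
        raise DimensionError(f"{path.name}: expected 2-D grayscale image, got shape {img.shape}")
    if img.dtype != np.uint8:
        raise DimensionError(f"{path.name}: expected 8-bit image, got dtype {img.dtype}")
    return img


def read_volume(
    folder: str | Path,
    pattern: str = DEFAULT_PATTERN,
    expected_depth: int | None = None,
) -> BScanStack:
    """Assemble a per-slice image folder into a :class:`BScanStack`.

    Files are matched against ``pattern`` (a template containing ``{i}``),
    with indices starting at 1, and stacked in ascending index order.  A
    missing index inside the run raises :class:`GapError`; inconsistent slice
    dimensions raise :class:`DimensionError`; a folder with no matching files
    raises :class:`EmptyScanError`.
    """
    folder = Path(folder)
    if not folder.is_dir():
        raise EmptyScanError(f"scan folder does not exist: {folder}")

    regex = re.compile("^" + re.escape(pattern).replace(r"\{i\}", r"(\d+)") + "$")
    indexed: dict[int, Path] = {}
    for p in folder.iterdir():
        m = regex.match(p.name)
        if m:
            indexed[int(m.group(1))] = p
    if not indexed:
        raise EmptyScanError(f"no slices matching {pattern!r} in {folder}")

    lo, hi = min(indexed), max(indexed)
    if lo != 1:
        raise GapError(f"slice indices must start at 1; first found index is {lo}")
    for i in range(1, hi + 1):
        if i not in indexed:
            raise GapError(f"missing slice index {i} in {folder}")
    if expected_depth is not None and hi != expected_depth:
        raise DimensionError(f"expected {expected_depth} slices, found {hi}")

    slices = []
    shape: tuple[int, int] | None = None
    for i in range(1, hi + 1):
        img = _load_grayscale(indexed[i])
        if shape is None:
            shape = img.shape
        elif img.shape != shape:
            raise DimensionError(
                f"slice {i} has shape {img.shape}, expected {shape} (all slices must match)"
            )
        slices.append(img)
    return BScanStack(np.stack(slices), dtype_domain="uint8", scan_id=folder.name)


def write_volume(stack: BScanStack, folder: str | Path, pattern: str = DEFAULT_PATTERN) -> int:
    """Write a stack as one image file per slice; returns the file count.

    uint8 stacks round-trip bit-exactly through :func:`read_volume`.  Unit
    float stacks are scaled to the nearest uint8 first — an inherently lossy
    step forced by the 8-bit on-disk format.
    """
    folder = Path(folder)
    folder.mkdir(parents=True, exist_ok=True)
    if stack.dtype_domain == "unit":
        data = np.clip(np.rint(stack.slices * 255.0), 0, 255).astype(np.uint8)
    else:
        data = stack.slices
    for k in range(stack.depth):
        name = pattern.format(i=k + stack.slice_index_base)
        iio.imwrite(folder / name, data[k])
    return stack.depth


def to_unit_interval(stack: BScanStack) -> BScanStack:
    """Map a uint8 stack onto [0, 1] by dividing by 255 (order-preserving)."""
    if stack.dtype_domain == "unit":
        warnings.warn("stack already in unit interval; returning it unchanged", stacklevel=2)
        return stack
    return replace(stack, slices=stack.slices.astype(np.float64) / 255.0, dtype_domain="unit")


def pad_depth_even(stack: BScanStack) -> tuple[BScanStack, int]:
    """Pad an odd-depth stack to even depth by replicating the last slice.

    Attention-window partitioning along depth needs an even slice count; the
    replicate rule (rather than zero fill) keeps boundary inter-slice
    correlation statistics intact.  Returns the (possibly padded) stack and
    the original depth so :func:`crop_depth` can restore it exactly.
    """
    d = stack.depth
    if d % 2 == 0:
        return stack, d
    padded = np.concatenate([stack.slices, stack.slices[-1:]], axis=0)
    return replace(stack, slices=padded), d


def crop_depth(stack: BScanStack, original_depth: int) -> BScanStack:
    """Undo :func:`pad_depth_even`, restoring exactly ``original_depth`` slices."""
    if original_depth > stack.depth:
        raise DimensionError(f"cannot crop to {original_depth} from depth {stack.depth}")
    if original_depth == stack.depth:
        return stack
    return replace(stack, slices=stack.slices[:original_depth])
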