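"""Self-supervised volumetric speckle suppression with alternating attention.

The restoration network exploits a simple physical asymmetry of volumetric
OCT: retinal layers and lesions are continuous across neighbouring B-scans,
while speckle is statistically independent from slice to slice.  A network
that reconstructs a volume from a stochastically corrupted copy of itself is
therefore pushed toward the anatomy (predictable from volumetric context) and
away from the noise (not predictable), without ever seeing a clean reference.

Architecture (decoder-free): non-overlapping 3-D patch embedding (a strided
Conv3D, which for non-overlapping patches is exactly a linear map per patch),
a stack of pre-norm transformer blocks whose windowed multi-head
self-attention alternates between two orientations —

* **flop** (intra-slice): windows of extent 1 along depth and ``wh x ww`` in
  plane, modelling texture and edges within each B-scan;
* **flip** (inter-slice): depth-spanning windows with a small ``fh x fw``
  in-plane footprint, aggregating co-located patches across all slices —

followed by a single learned reconstruction head (a linear map from token to
patch voxels, the non-overlapping equivalent of ConvTranspose3D) and a
terminal sigmoid that pins intensities to (0, 1).  There is no symmetric
decoder.

Training corrupts the raw volume with fresh additive Gaussian noise
(sigma = 0.15, clamped to [0, 1]) at every optimisation step and minimises a
hybrid objective: mean squared error plus a lambda = 0.1 weighted mean
absolute error that favours sharp layer boundaries.  At inference no noise is
added; odd-depth volumes are padded by replicating the last slice and cropped
back after reconstruction.

Everything runs on NumPy via the small autograd in :mod:`foveoct.nn`; the
default configuration is desk-scale (16 x 64 x 64 inputs) and trains in
minutes on one CPU while exercising every code path.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
from skimage.transform import resize as _sk_resize

from . import nn
from .volume_io import BScanStack, crop_depth, pad_depth_even, to_unit_interval

__all__ = [
    "DenoiserConfig",
    "TrainingReport",
    "FFSwinDenoiser",
    "corrupt_volume",
    "hybrid_loss",
    "build_denoiser",
    "train_self_supervised",
    "denoise_volume",
]


class ConfigError(ValueError):
    """Window/patch geometry incompatible with the token grid."""


@dataclass(frozen=True)
class DenoiserConfig:
    """Hyperparameters of the volumetric restoration network.

    ``input_size`` is the working resolution: volumes are bilinearly resized
    in plane to (H, W); depth is never resampled, only padded/cropped.
    ``flip_window`` gives the in-plane footprint of the depth-spanning
    inter-slice windows (their depth extent is always the full token depth,
    so any even input depth is accepted at inference).
    """

    patch: tuple[int, int, int] = (2, 4, 4)       # (depth, height, width) of a 3-D patch
    embed_dim: int = 48
    n_stages: int = 2
    blocks_per_stage: int = 2
    flop_window: tuple[int, int] = (8, 8)          # in-plane window (token units)
    flip_window: tuple[int, int] = (2, 2)          # in-plane footprint of depth windows
    n_heads: int = 4
    noise_sigma: float = 0.15
    lambda_sharp: float = 0.1
    epochs: int = 50
    learning_rate: float = 1e-3
    batch_size: int = 1
    seed: int = 0
    input_size: tuple[int, int, int] = (16, 64, 64)

    def __post_init__(self) -> None:
        if self.noise_sigma < 0 or self.lambda_sharp < 0:
            raise ConfigError("noise_sigma and lambda_sharp must be >= 0")
        if self.embed_dim % self.n_heads != 0:
            raise ConfigError("embed_dim must be divisible by n_heads")
        d, h, w = self.input_size
        pd, ph, pw = self.patch
        if d % pd or h % ph or w % pw:
            raise ConfigError("input_size must be divisible by the patch size")
        nh, nw = h // ph, w // pw
        for name, (a, b) in {"flop_window": self.flop_window, "flip_window": self.flip_window}.items():
            if nh % a or nw % b:
                raise ConfigError(f"{name} {a}x{b} does not tile the {nh}x{nw} token grid")

    @property
    def n_blocks(self) -> int:
        return self.n_stages * self.blocks_per_stage


@dataclass
class TrainingReport:
    """Per-epoch mean reconstruction loss of one self-supervised run."""

    epoch_losses: list[float]
    seed: int
    config: dict = field(default_factory=dict)

    @property
    def loss_ratio(self) -> float:
        """Final-epoch mean loss over first-epoch mean loss."""
        return self.epoch_losses[-1] / self.epoch_losses[0]


def corrupt_volume(v: np.ndarray, sigma: float, seed: int | None = None,
                   rng: np.random.Generator | None = None) -> np.ndarray:
    """Add i.i.d. zero-mean Gaussian noise to a unit-interval volume and clamp.

    This is the stochastic corruption of the self-supervised pretext task: the
    network sees ``corrupt(v)`` and is asked to reproduce ``v`` itself.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    v = np.asarray(v)
    if sigma == 0:
        return v.copy()
    if rng is None:
        rng = np.random.default_rng(seed)
    noisy = v + rng.normal(0.0, sigma, size=v.shape)
    return np.clip(noisy, 0.0, 1.0).astype(v.dtype, copy=False)


def hybrid_loss(pred, target, lambda_sharp: float = 0.1):
    """MSE plus a lambda-weighted L1 sharpness term, averaged over voxels.

    Works on plain arrays (returns a float) and on autograd tensors (returns
    a scalar tensor usable as a training objective).
    """
    if isinstance(pred, nn.Tensor):
        if pred.shape != target.shape:
            raise ValueError(f"shape mismatch: {pred.shape} vs {target.shape}")
        diff = pred - target
        return (diff * diff).mean() + float(lambda_sharp) * diff.abs().mean()
    pred = np.asarray(pred, dtype=np.float64)
    target = np.asarray(target, dtype=np.float64)
    if pred.shape != target.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {target.shape}")
    diff = pred - target
    return float(np.mean(diff * diff) + lambda_sharp * np.mean(np.abs(diff)))


# ---------------------------------------------------------------------------
# network
# ---------------------------------------------------------------------------


class FFSwinDenoiser:
    """Decoder-free volumetric attention denoiser (see module docstring).

    Consecutive blocks alternate window orientation starting with an
    intra-slice (flop) block; each block is a standard pre-norm transformer
    block (windowed MHSA, then an MLP with expansion 4).  Learned absolute
    positional embeddings are factorised into a depth component and an
    in-plane component; the depth component is linearly interpolated when an
    inference volume has a different token depth than the training size.
    """

    def __init__(self, config: DenoiserConfig, dtype=np.float32):
        self.config = config
        self.dtype = dtype
        self.fitted = False
        rng = np.random.default_rng([config.seed, 0x5EED])
        c = config.embed_dim
        pd = int(np.prod(config.patch))
        nd = config.input_size[0] // config.patch[0]
        nh = config.input_size[1] // config.patch[1]
        nw = config.input_size[2] // config.patch[2]
        self._train_nd = nd

        def init(*shape):
            return nn.parameter(rng.normal(0.0, 0.02, size=shape).astype(dtype))

        def zeros(*shape):
            return nn.parameter(np.zeros(shape, dtype=dtype))

        def ones(*shape):
            return nn.parameter(np.ones(shape, dtype=dtype))

        p: dict[str, nn.Tensor] = {
            "embed.w": init(pd, c),
            "embed.b": zeros(c),
            "pos.depth": init(nd, 1, 1, c),
            "pos.plane": init(1, nh, nw, c),
            "head.w": init(c, pd),
            "head.b": zeros(pd),
        }
        for b in range(config.n_blocks):
            pre = f"block{b}."
            p[pre + "ln1.g"] = ones(c)
            p[pre + "ln1.b"] = zeros(c)
            for m in ("q", "k", "v"):
                p[pre + f"attn.w{m}"] = init(c, c)
                p[pre + f"attn.b{m}"] = zeros(c)
            p[pre + "attn.proj.w"] = init(c, c)
            p[pre + "attn.proj.b"] = zeros(c)
            p[pre + "ln2.g"] = ones(c)
            p[pre + "ln2.b"] = zeros(c)
            p[pre + "mlp.w1"] = init(c, 4 * c)
            p[pre + "mlp.b1"] = zeros(4 * c)
            p[pre + "mlp.w2"] = init(4 * c, c)
            p[pre + "mlp.b2"] = zeros(c)
        self.params = p

    # -- bookkeeping --------------------------------------------------------

    @property
    def parameter_count(self) -> int:
        return int(sum(t.data.size for t in self.params.values()))

    def save(self, folder: str | Path) -> None:
        folder = Path(folder)
        folder.mkdir(parents=True, exist_ok=True)
        np.savez(folder / "weights.npz", **{k: t.data for k, t in self.params.items()})
        meta = {"config": asdict(self.config), "fitted": self.fitted}
        (folder / "config.json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, folder: str | Path) -> "FFSwinDenoiser":
        folder = Path(folder)
        meta = json.loads((folder / "config.json").read_text())
        cfgd = meta["config"]
        for key in ("patch", "flop_window", "flip_window", "input_size"):
            cfgd[key] = tuple(cfgd[key])
        model = cls(DenoiserConfig(**cfgd))
        with np.load(folder / "weights.npz") as data:
            for k in model.params:
                model.params[k].data = data[k].astype(model.dtype)
        model.fitted = bool(meta.get("fitted", False))
        return model

    # -- forward ------------------------------------------------------------

    def _pos_depth(self, nd: int) -> nn.Tensor:
        pos = self.params["pos.depth"]
        if nd == pos.data.shape[0]:
            return pos
        # inference at a different depth: linear interpolation along depth,
        # outside the gradient path
        src = pos.data.reshape(pos.data.shape[0], -1)
        xi = np.linspace(0.0, src.shape[0] - 1.0, nd)
        out = np.stack([np.interp(xi, np.arange(src.shape[0]), src[:, j]) for j in range(src.shape[1])], axis=1)
        return nn.constant(out.reshape(nd, 1, 1, pos.data.shape[-1]).astype(self.dtype))

    def forward(self, volume: np.ndarray) -> nn.Tensor:
        """Map a (D, H, W) unit-interval array to a same-shape tensor in (0,1)."""
        cfg = self.config
        pd_, ph, pw = cfg.patch
        d, h, w = volume.shape
        if d % pd_ or h != cfg.input_size[1] or w != cfg.input_size[2]:
            raise ConfigError(
                f"forward expects in-plane size {cfg.input_size[1:]} and depth divisible "
                f"by {pd_}; got {volume.shape}"
            )
        nd, nh, nw = d // pd_, h // ph, w // pw
        c, heads = cfg.embed_dim, cfg.n_heads
        hd = c // heads
        patches = (
            volume.astype(self.dtype)
            .reshape(nd, pd_, nh, ph, nw, pw)
            .transpose(0, 2, 4, 1, 3, 5)
            .reshape(nd, nh, nw, pd_ * ph * pw)
        )
        x = nn.constant(patches) @ self.params["embed.w"] + self.params["embed.b"]
        x = x + self._pos_depth(nd) + self.params["pos.plane"]

        for b in range(cfg.n_blocks):
            pre = f"block{b}."
            mode = "flop" if b % 2 == 0 else "flip"
            y = x.layer_norm(self.params[pre + "ln1.g"], self.params[pre + "ln1.b"])
            if mode == "flop":
                wh, ww = cfg.flop_window
                gh, gw = nh // wh, nw // ww
                win = (
                    y.reshape(nd, gh, wh, gw, ww, c)
                    .transpose(0, 1, 3, 2, 4, 5)
                    .reshape(nd * gh * gw, wh * ww, c)
                )
            else:
                fh, fw = cfg.flip_window
                gh, gw = nh // fh, nw // fw
                win = (
                    y.reshape(nd, gh, fh, gw, fw, c)
                    .transpose(1, 3, 0, 2, 4, 5)
                    .reshape(gh * gw, nd * fh * fw, c)
                )
            nb, t = win.shape[0], win.shape[1]
            q = (win @ self.params[pre + "attn.wq"] + self.params[pre + "attn.bq"]).reshape(nb, t, heads, hd).transpose(0, 2, 1, 3)
            k = (win @ self.params[pre + "attn.wk"] + self.params[pre + "attn.bk"]).reshape(nb, t, heads, hd).transpose(0, 2, 1, 3)
            v = (win @ self.params[pre + "attn.wv"] + self.params[pre + "attn.bv"]).reshape(nb, t, heads, hd).transpose(0, 2, 1, 3)
            att = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(hd))
            out = att.softmax(-1) @ v
            out = out.transpose(0, 2, 1, 3).reshape(nb, t, c)
            out = out @ self.params[pre + "attn.proj.w"] + self.params[pre + "attn.proj.b"]
            if mode == "flop":
                out = (
                    out.reshape(nd, gh, gw, wh, ww, c)
                    .transpose(0, 1, 3, 2, 4, 5)
                    .reshape(nd, nh, nw, c)
                )
            else:
                out = (
                    out.reshape(gh, gw, nd, fh, fw, c)
                    .transpose(2, 0, 3, 1, 4, 5)
                    .reshape(nd, nh, nw, c)
                )
            x = x + out
            y2 = x.layer_norm(self.params[pre + "ln2.g"], self.params[pre + "ln2.b"])
            y2 = (y2 @ self.params[pre + "mlp.w1"] + self.params[pre + "mlp.b1"]).gelu()
            y2 = y2 @ self.params[pre + "mlp.w2"] + self.params[pre + "mlp.b2"]
            x = x + y2

        x = x @ self.params["head.w"] + self.params["head.b"]
        x = (
            x.reshape(nd, nh, nw, pd_, ph, pw)
            .transpose(0, 3, 1, 4, 2, 5)
            .reshape(d, h, w)
        )
        return x.sigmoid()

    # -- training -----------------------------------------------------------

    def fit(self, volumes: list[BScanStack | np.ndarray]) -> TrainingReport:
        """Self-supervised training; returns the per-epoch loss trace.

        Each optimisation step draws *fresh* corruption noise — the raw
        volume itself is the supervision signal, so the only thing the
        network cannot learn to copy is the ever-changing noise.
        """
        if not volumes:
            raise ValueError("need at least one training volume")
        cfg = self.config
        arrays = [self._prepare(v, training=True) for v in volumes]
        rng = np.random.default_rng([cfg.seed, 0x7EA1])
        opt = nn.Adam(self.params, lr=cfg.learning_rate)
        losses: list[float] = []
        n = len(arrays)
        for _epoch in range(cfg.epochs):
            order = rng.permutation(n)
            epoch_losses = []
            for start in range(0, n, cfg.batch_size):
                idx = order[start : start + cfg.batch_size]
                opt.zero_grad()
                total = None
                for j in idx:
                    target = arrays[j]
                    noisy = corrupt_volume(target, cfg.noise_sigma, rng=rng)
                    pred = self.forward(noisy)
                    loss = hybrid_loss(pred, nn.constant(target.astype(self.dtype)), cfg.lambda_sharp)
                    total = loss if total is None else total + loss
                total = total / len(idx)
                total.backward()
                opt.step()
                epoch_losses.append(float(total.data))
            losses.append(float(np.mean(epoch_losses)))
        self.fitted = True
        return TrainingReport(epoch_losses=losses, seed=cfg.seed, config=asdict(cfg))

    # -- inference ----------------------------------------------------------

    def denoise(self, stack: BScanStack) -> BScanStack:
        """Restore one volume: resize in plane, pad depth, forward, crop back.

        Inference is deterministic (no corruption is injected) and preserves
        the input's slice count; the in-plane size of the output is the
        model's working resolution.
        """
        if not self.fitted:
            raise RuntimeError("model has not been trained; call fit() first")
        cfg = self.config
        arr = self._prepare(stack, training=False)
        work = BScanStack(arr, dtype_domain="unit", scan_id=getattr(stack, "scan_id", ""))
        padded, original_depth = pad_depth_even(work)
        data = padded.slices
        pd_ = cfg.patch[0]
        while data.shape[0] % pd_:  # replicate further if patch depth > 2
            data = np.concatenate([data, data[-1:]], axis=0)
        out = self.forward(data.astype(self.dtype)).data.astype(np.float64)
        restored = BScanStack(np.clip(out, 0.0, 1.0), dtype_domain="unit",
                              scan_id=getattr(stack, "scan_id", ""))
        return crop_depth(restored, original_depth)

    # -- helpers ------------------------------------------------------------

    def _prepare(self, volume: BScanStack | np.ndarray, training: bool) -> np.ndarray:
        """Unit-interval array at the working in-plane resolution.

        Depth handling differs by phase: training volumes are replicate-padded
        or centre-cropped to the configured depth (fixed token grid); at
        inference the native depth is kept (padding happens in ``denoise``).
        """
        if isinstance(volume, BScanStack):
            if volume.dtype_domain == "uint8":
                volume = to_unit_interval(volume)
            arr = volume.slices
        else:
            arr = np.asarray(volume, dtype=np.float64)
            if arr.min() < 0 or arr.max() > 1:
                raise ValueError("expected a unit-interval volume")
        d_cfg, h_cfg, w_cfg = self.config.input_size
        if arr.shape[1:] != (h_cfg, w_cfg):
            arr = np.stack(
                [
                    _sk_resize(s, (h_cfg, w_cfg), order=1, mode="edge",
                               anti_aliasing=False, preserve_range=True)
                    for s in arr
                ]
            )
            arr = np.clip(arr, 0.0, 1.0)
        if training:
            d = arr.shape[0]
            if d > d_cfg:
                start = (d - d_cfg) // 2
                arr = arr[start : start + d_cfg]
            elif d < d_cfg:
                pad = np.repeat(arr[-1:], d_cfg - d, axis=0)
                arr = np.concatenate([arr, pad], axis=0)
        return np.ascontiguousarray(arr)


# ---------------------------------------------------------------------------
# functional surface
# ---------------------------------------------------------------------------


def build_denoiser(config: DenoiserConfig) -> tuple[FFSwinDenoiser, int]:
    """Construct the network; returns ``(model, parameter_count)``."""
    model = FFSwinDenoiser(config)
    return model, model.parameter_count


def train_self_supervised(
    volumes: list[BScanStack | np.ndarray], config: DenoiserConfig
) -> tuple[FFSwinDenoiser, TrainingReport]:
    model = FFSwinDenoiser(config)
    report = model.fit(volumes)
    return model, report


def denoise_volume(model: FFSwinDenoiser, stack: BScanStack,
                   config: DenoiserConfig | None = None) -> BScanStack:
    if config is not None and config != model.config:
        raise ValueError("config does not match the model it was trained with")
    return model.denoise(stack)
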