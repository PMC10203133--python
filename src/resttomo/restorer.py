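"""3D U-Net restoration: network definition, training, tiled prediction.

The network maps a normalized low-quality subvolume to a restored volume of
identical shape (voxel-wise regression).  Architecture: a symmetric
encoder–decoder with skip connections — two 3×3×3 convolution + leaky-ReLU
blocks per level, 2× max pooling on the way down, nearest-neighbour
upsampling plus channel concatenation on the way up, and a 1×1×1 output
convolution.  Channel width doubles per level.

Two presets are provided: the full-scale configuration (3 levels, 32 base
channels, 64-voxel patches) and a desk-scale configuration (2 levels, 8 base
channels, 32-voxel patches) sized so the whole train-restore-evaluate loop
runs in minutes on one CPU.  Both are implementation choices; the network is
fully convolutional, so a trained model can be applied to any patch size
divisible by ``pool_factor**depth``.

Whole tomograms are restored by tiled prediction: the volume is split into
overlapping patches, each patch is predicted independently, and the outputs
are recombined by central cropping (each voxel is produced by exactly one
tile, the one whose centre is nearest), which avoids seam averaging.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np

from .nn import Adam, Conv3d, LeakyReLU, MaxPool3d, Upsample3d
from .pair_factory import TrainingPair, normalize_volume
from .tomo_forward import DensityVolume

__all__ = [
    "UNetConfig",
    "TrainingConfig",
    "UNet3D",
    "TrainedRestorer",
    "build_network",
    "train",
    "restore_volume",
]

CHECKPOINT_FORMAT_VERSION = 1


@dataclass
class UNetConfig:
    """Architecture hyperparameters.

    ``patch_vox`` is the nominal training patch edge; it must be divisible
    by ``pool_factor ** depth``.
    """

    depth: int = 3
    base_channels: int = 32
    conv_kernel: int = 3
    pool_factor: int = 2
    patch_vox: int = 64

    def __post_init__(self) -> None:
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if self.pool_factor != 2:
            raise ValueError("only pool_factor 2 is implemented")
        if self.patch_vox % self.pool_factor**self.depth != 0:
            raise ValueError(
                f"patch_vox {self.patch_vox} must be divisible by "
                f"pool_factor**depth = {self.pool_factor ** self.depth}"
            )

    @classmethod
    def desk(cls) -> "UNetConfig":
        """Small configuration for CPU-scale experiments and the test suite."""
        return cls(depth=2, base_channels=8, patch_vox=32)


@dataclass
class TrainingConfig:
    """Optimisation hyperparameters for :func:`train`."""

    loss: str = "L2"
    learning_rate: float = 3e-4
    iterations: int = 500
    batch_size: int = 4
    seed: int = 0
    validation_fraction: float = 0.1
    crop_vox: int | None = None  # random-crop training patches to this edge

    def __post_init__(self) -> None:
        if self.loss not in ("L2", "L1"):
            raise ValueError("loss must be 'L2' or 'L1'")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if not 0.0 <= self.validation_fraction < 1.0:
            raise ValueError("validation_fraction must be in [0, 1)")


class UNet3D:
    """Encoder–decoder with skip connections; input and output shapes match."""

    def __init__(self, cfg: UNetConfig, seed: int = 0) -> None:
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        ch = cfg.base_channels
        k = cfg.conv_kernel
        self.enc_blocks: list[list] = []
        self.pools: list[MaxPool3d] = []
        c_in = 1
        enc_ch = []
        for level in range(cfg.depth):
            c_out = ch * 2**level
            self.enc_blocks.append(self._block(c_in, c_out, k, rng))
            enc_ch.append(c_out)
            self.pools.append(MaxPool3d())
            c_in = c_out
        c_bott = ch * 2**cfg.depth
        self.bottleneck = self._block(c_in, c_bott, k, rng)
        self.ups: list[Upsample3d] = []
        self.dec_blocks: list[list] = []
        c_in = c_bott
        for level in reversed(range(cfg.depth)):
            self.ups.append(Upsample3d())
            self.dec_blocks.append(self._block(c_in + enc_ch[level], enc_ch[level], k, rng))
            c_in = enc_ch[level]
        self.out_conv = Conv3d(c_in, 1, kernel=1, rng=rng)

    @staticmethod
    def _block(c_in: int, c_out: int, k: int, rng) -> list:
        return [Conv3d(c_in, c_out, k, rng), LeakyReLU(),
                Conv3d(c_out, c_out, k, rng), LeakyReLU()]

    # -- plumbing ----------------------------------------------------------

    def _layers(self):
        for blk in self.enc_blocks:
            yield from blk
        yield from self.bottleneck
        for blk in self.dec_blocks:
            yield from blk
        yield self.out_conv

    def params(self):
        out = []
        for layer in self._layers():
            out.extend(layer.params())
        return out

    @property
    def n_params(self) -> int:
        return sum(p.size for p, _ in self.params())

    # -- forward / backward ------------------------------------------------

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        """``x``: (N, 1, D, H, W) float32 with D, H, W divisible by 2**depth."""
        x = np.asarray(x, dtype=np.float32)
        for d in x.shape[2:]:
            if d % self.cfg.pool_factor**self.cfg.depth != 0:
                raise ValueError(
                    f"spatial size {x.shape[2:]} not divisible by "
                    f"{self.cfg.pool_factor ** self.cfg.depth}"
                )
        skips = []
        h = np.ascontiguousarray(x.transpose(0, 2, 3, 4, 1))  # channels-last
        for blk, pool in zip(self.enc_blocks, self.pools):
            for layer in blk:
                h = layer.forward(h, train)
            skips.append(h)
            h = pool.forward(h, train)
        for layer in self.bottleneck:
            h = layer.forward(h, train)
        self._concat_ch = []
        for up, blk, skip in zip(self.ups, self.dec_blocks, reversed(skips)):
            h = up.forward(h, train)
            self._concat_ch.append((h.shape[-1], skip.shape[-1]))
            h = np.concatenate([h, skip], axis=-1)
            for layer in blk:
                h = layer.forward(h, train)
        out = self.out_conv.forward(h, train)
        return np.ascontiguousarray(out.transpose(0, 4, 1, 2, 3))

    def backward(self, dy: np.ndarray) -> None:
        dy = np.ascontiguousarray(
            np.asarray(dy, dtype=np.float32).transpose(0, 2, 3, 4, 1)
        )
        g = self.out_conv.backward(dy)
        skip_grads = []
        for up, blk, (c_up, c_skip) in zip(
            reversed(self.ups), reversed(self.dec_blocks), reversed(self._concat_ch)
        ):
            for layer in reversed(blk):
                g = layer.backward(g)
            skip_grads.append(g[..., c_up:])
            g = up.backward(np.ascontiguousarray(g[..., :c_up]))
        for layer in reversed(self.bottleneck):
            g = layer.backward(g)
        # skip_grads were collected shallow-to-deep; encoder backward runs
        # deep-to-shallow
        for blk, pool, sg in zip(
            reversed(self.enc_blocks), reversed(self.pools), reversed(skip_grads)
        ):
            g = pool.backward(g) + sg
            for layer in reversed(blk):
                g = layer.backward(g)

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x, train=False)

    # -- weights -----------------------------------------------------------

    def get_weights(self) -> list[np.ndarray]:
        out = []
        for layer in self._layers():
            if isinstance(layer, Conv3d):
                out.extend([layer.weight, layer.bias])
        return out

    def set_weights(self, weights: Sequence[np.ndarray]) -> None:
        it = iter(weights)
        for layer in self._layers():
            if isinstance(layer, Conv3d):
                layer.weight[...] = next(it)
                layer.bias[...] = next(it)


def build_network(cfg: UNetConfig, seed: int = 0) -> UNet3D:
    """Construct an untrained U-Net for the given configuration."""
    return UNet3D(cfg, seed=seed)


# ---------------------------------------------------------------------------
# training


@dataclass
class TrainedRestorer:
    """Frozen weights + configuration; prediction is a pure function."""

    network: UNet3D
    unet_config: UNetConfig
    normalization: str = "zscore-per-volume"
    manifest_hash: str = ""

    def predict(self, volume: np.ndarray) -> np.ndarray:
        """Restore one (D, H, W) volume (already normalized)."""
        x = np.asarray(volume, dtype=np.float32)[None, None]
        return self.network.predict(x)[0, 0]

    def save(self, path) -> None:
        arrays = {f"w{i}": w for i, w in enumerate(self.network.get_weights())}
        meta = json.dumps(
            {
                "format_version": CHECKPOINT_FORMAT_VERSION,
                "unet_config": asdict(self.unet_config),
                "normalization": self.normalization,
                "manifest_hash": self.manifest_hash,
            }
        )
        np.savez(path, meta=np.frombuffer(meta.encode(), dtype=np.uint8), **arrays)

    @classmethod
    def load(cls, path) -> "TrainedRestorer":
        with np.load(path) as data:
            meta = json.loads(bytes(data["meta"]).decode())
            if meta["format_version"] != CHECKPOINT_FORMAT_VERSION:
                raise ValueError(
                    f"unsupported checkpoint format {meta['format_version']}"
                )
            cfg = UNetConfig(**meta["unet_config"])
            net = UNet3D(cfg, seed=0)
            n = len(net.get_weights())
            net.set_weights([data[f"w{i}"] for i in range(n)])
        return cls(net, cfg, meta["normalization"], meta["manifest_hash"])


def _pairs_to_arrays(pairs: Sequence[TrainingPair]) -> tuple[np.ndarray, np.ndarray]:
    shapes = {p.input_vol.values.shape for p in pairs}
    if len(shapes) != 1:
        raise ValueError(f"training pairs have mismatched shapes: {sorted(shapes)}")
    x = np.stack([p.input_vol.values for p in pairs]).astype(np.float32)[:, None]
    y = np.stack([p.target_vol.values for p in pairs]).astype(np.float32)[:, None]
    return x, y


def train(
    pairs: Sequence[TrainingPair],
    ucfg: UNetConfig,
    tcfg: TrainingConfig,
    manifest_hash: str = "",
    checkpoint_every: int | None = None,
    callback=None,
) -> tuple[TrainedRestorer, dict]:
    """Train a U-Net on normalized training pairs.

    Returns the trained restorer and a history dict with per-iteration
    training loss and periodic validation loss.  Fully deterministic for a
    fixed ``tcfg.seed`` (pure NumPy arithmetic).
    """
    if len(pairs) == 0:
        raise ValueError("at least one training pair is required")
    x, y = _pairs_to_arrays(pairs)
    rng = np.random.default_rng(tcfg.seed)
    net = UNet3D(ucfg, seed=int(rng.integers(0, 2**31 - 1)))
    n_val = int(round(tcfg.validation_fraction * len(pairs)))
    order = rng.permutation(len(pairs))
    val_idx, tr_idx = order[:n_val], order[n_val:]
    if len(tr_idx) == 0:
        raise ValueError("validation split leaves no training pairs")
    opt = Adam(net.params(), lr=tcfg.learning_rate)
    div = ucfg.pool_factor**ucfg.depth
    history: dict = {"train_loss": [], "val_loss": [], "val_iters": []}
    check = checkpoint_every or max(1, tcfg.iterations // 10)
    for it in range(tcfg.iterations):
        batch = rng.choice(tr_idx, size=min(tcfg.batch_size, len(tr_idx)), replace=False)
        xb, yb = x[batch], y[batch]
        if tcfg.crop_vox is not None and tcfg.crop_vox < x.shape[2]:
            cv = tcfg.crop_vox - tcfg.crop_vox % div
            lo = [rng.integers(0, x.shape[2 + a] - cv + 1) for a in range(3)]
            xb = xb[:, :, lo[0]:lo[0]+cv, lo[1]:lo[1]+cv, lo[2]:lo[2]+cv]
            yb = yb[:, :, lo[0]:lo[0]+cv, lo[1]:lo[1]+cv, lo[2]:lo[2]+cv]
        pred = net.forward(xb, train=True)
        resid = pred - yb
        if tcfg.loss == "L2":
            loss = float(np.mean(resid**2))
            grad = (2.0 / resid.size) * resid
        else:
            loss = float(np.mean(np.abs(resid)))
            grad = np.sign(resid) / resid.size
        opt.zero_grad()
        net.backward(grad.astype(np.float32))
        opt.step()
        history["train_loss"].append(loss)
        if (it + 1) % check == 0 or it == 0:
            if len(val_idx):
                vp = net.predict(x[val_idx])
                vl = float(np.mean((vp - y[val_idx]) ** 2))
            else:
                vl = loss
            history["val_loss"].append(vl)
            history["val_iters"].append(it + 1)
            if callback is not None:
                callback(it + 1, loss, vl, net)
    restorer = TrainedRestorer(net, ucfg, manifest_hash=manifest_hash)
    return restorer, history


# ---------------------------------------------------------------------------
# tiled prediction


def _tile_starts(length: int, patch: int, step: int) -> list[int]:
    if length <= patch:
        return [0]
    starts = list(range(0, length - patch + 1, step))
    if starts[-1] != length - patch:
        starts.append(length - patch)
    return starts


def _axis_regions(starts: list[int], patch: int, length: int) -> list[tuple[int, int]]:
    """Midpoint partition: voxel owned by the tile whose centre is nearest."""
    bounds = [0]
    for a, b in zip(starts[:-1], starts[1:]):
        bounds.append((a + patch + b) // 2)
    bounds.append(min(length, starts[-1] + patch))
    return [(bounds[i], bounds[i + 1]) for i in range(len(starts))]


def restore_volume(
    model: TrainedRestorer,
    tomogram: DensityVolume,
    patch: int = 64,
    overlap_vox: int = 16,
    normalize: bool = True,
) -> DensityVolume:
    """Restore a whole (possibly non-cubic) tomogram by tiled prediction.

    The tomogram is normalized (unless already), split into overlapping
    ``patch``³ tiles at stride ``patch - overlap_vox``, each tile predicted
    independently, and outputs recombined by central cropping.  Volumes
    smaller than ``patch`` on any axis are zero-padded, predicted, and
    cropped back.
    """
    div = model.unet_config.pool_factor ** model.unet_config.depth
    if patch % div != 0:
        raise ValueError(f"patch must be divisible by {div}")
    if not 0 <= overlap_vox < patch:
        raise ValueError("overlap_vox must be in [0, patch)")
    values = tomogram.values.astype(np.float32)
    if normalize:
        values = normalize_volume(DensityVolume(values, tomogram.voxel_A)).values.astype(
            np.float32
        )
    shape = values.shape
    pad = [max(0, patch - s) for s in shape]
    if any(pad):
        values = np.pad(values, [(0, p) for p in pad])
    work_shape = values.shape
    step = patch - overlap_vox
    starts = [_tile_starts(s, patch, step) for s in work_shape]
    regions = [
        _axis_regions(st, patch, s) for st, s in zip(starts, work_shape)
    ]
    out = np.empty(work_shape, dtype=np.float32)
    for iz, sz in enumerate(starts[0]):
        for iy, sy in enumerate(starts[1]):
            for ix, sx in enumerate(starts[2]):
                tile = values[sz:sz+patch, sy:sy+patch, sx:sx+patch]
                pred = model.predict(tile)
                (z0, z1) = regions[0][iz]
                (y0, y1) = regions[1][iy]
                (x0, x1) = regions[2][ix]
                out[z0:z1, y0:y1, x0:x1] = pred[
                    z0 - sz : z1 - sz, y0 - sy : y1 - sy, x0 - sx : x1 - sx
                ]
    out = out[: shape[0], : shape[1], : shape[2]]
    return DensityVolume(out, tomogram.voxel_A, tomogram.origin)
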