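"""Reduced U-Net segmentation model and its supervised training loop.

The network follows the encoder/decoder design used for the slide
pipeline: an encoder that contracts the input by a factor of 32 (1024 px
tiles reach a 32 px bottleneck) and a truncated decoder with only two
bilinear up-sampling levels, so the output is two per-class probability
heat maps (BD, SK) at 1/8 of the input resolution — each output pixel
summarises an 8 px x 8 px input region.  Training minimises focal loss
(gamma = 2 by default) with Adam, monitors intersection-over-union per
epoch, and splits tiles by slide so no slide leaks across the
train/validation boundary.

Two encoder presets exist: ``"paper"`` mirrors a ResNet34 stage layout
(3/4/6/3 residual blocks, widths 64/128/256/512) and ``"small"`` is a
plain 4-stage net (widths 16/32/64/128) sized for CPU-scale experiments.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from . import nn
from .core import LABEL_BD, LABEL_SK
from .tissue import TileCoord

__all__ = [
    "NetworkConfig",
    "AugmentConfig",
    "TrainingConfig",
    "TileHeatMap",
    "TrainingHistory",
    "SegNet",
    "ModelState",
    "build_network",
    "focal_loss",
    "iou",
    "augment",
    "split_by_slide",
    "TileDataset",
    "train",
    "predict_tile",
    "predict_tiles",
]

OUTPUT_STRIDE = 8
_BOTTLENECK_STRIDE = 32


@dataclass(frozen=True)
class NetworkConfig:
    input_side: int = 1024
    preset: str = "paper"  # "paper" (ResNet34-like) or "small"
    up_levels: int = 2
    out_channels: int = 2  # channel 0 = BD, channel 1 = SK
    output_stride: int = OUTPUT_STRIDE
    seed: int = 0

    def __post_init__(self) -> None:
        if self.input_side % _BOTTLENECK_STRIDE != 0:
            raise ValueError("input side must be divisible by 32")
        if self.preset not in ("paper", "small"):
            raise ValueError(f"unknown preset {self.preset!r}")

    @property
    def bottleneck_side(self) -> int:
        return self.input_side // _BOTTLENECK_STRIDE

    @property
    def output_side(self) -> int:
        return self.input_side // self.output_stride


@dataclass(frozen=True)
class AugmentConfig:
    rotate90: bool = True
    flip: bool = True
    elastic: bool = False
    elastic_alpha: float = 8.0
    elastic_sigma: float = 12.0
    noise: bool = True
    noise_sigma: float = 6.0
    blur: bool = False
    brightness_contrast: bool = True
    color: bool = True

    @classmethod
    def disabled(cls) -> "AugmentConfig":
        return cls(rotate90=False, flip=False, elastic=False, noise=False,
                   blur=False, brightness_contrast=False, color=False)


@dataclass(frozen=True)
class TrainingConfig:
    gamma: float = 2.0
    learning_rate: float = 1e-4
    batch_size: int = 8
    epochs: int = 40
    split_fraction: float = 0.8
    augment: AugmentConfig = field(default_factory=AugmentConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")
        if not 0.0 < self.split_fraction < 1.0:
            raise ValueError("split fraction must lie in (0, 1)")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "TrainingConfig":
        d = dict(d)
        d["augment"] = AugmentConfig(**d.get("augment", {}))
        return cls(**d)


@dataclass
class TileHeatMap:
    """Per-class probabilities at 1/8 tile resolution; channel 0=BD, 1=SK."""

    probs: np.ndarray  # (2, s, s) float32 in [0, 1]
    coord: TileCoord


@dataclass
class TrainingHistory:
    epoch_loss: list[float] = field(default_factory=list)
    train_iou: list[float] = field(default_factory=list)
    val_iou: list[float] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"epoch": np.arange(1, len(self.epoch_loss) + 1),
                             "loss": self.epoch_loss,
                             "train_iou": self.train_iou,
                             "val_iou": self.val_iou})


class _Sequential:
    def __init__(self, layers: list):
        self.layers = layers

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        for l in self.layers:
            x = l.forward(x, train)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for l in reversed(self.layers):
            dy = l.backward(dy)
        return dy

    def params(self):
        return [p for l in self.layers for p in l.params()]

    def grads(self):
        return [g for l in self.layers for g in l.grads()]


class _ResidualBlock:
    """Basic two-conv residual block; 1x1 projection when shape changes."""

    def __init__(self, cin: int, cout: int, stride: int, rng):
        self.conv1 = nn.Conv2d(cin, cout, 3, stride=stride, rng=rng)
        self.relu1 = nn.ReLU()
        self.conv2 = nn.Conv2d(cout, cout, 3, rng=rng)
        self.proj = (nn.Conv2d(cin, cout, 1, stride=stride, pad=0, rng=rng)
                     if (stride != 1 or cin != cout) else None)
        self.relu_out = nn.ReLU()

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        main = self.conv2.forward(self.relu1.forward(self.conv1.forward(x, train), train), train)
        short = self.proj.forward(x, train) if self.proj is not None else x
        return self.relu_out.forward(main + short, train)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        d = self.relu_out.backward(dy)
        dmain = self.conv1.backward(self.relu1.backward(self.conv2.backward(d)))
        dshort = self.proj.backward(d) if self.proj is not None else d
        return dmain + dshort

    def params(self):
        ps = self.conv1.params() + self.conv2.params()
        return ps + (self.proj.params() if self.proj else [])

    def grads(self):
        gs = self.conv1.grads() + self.conv2.grads()
        return gs + (self.proj.grads() if self.proj else [])


def _conv_relu(cin, cout, stride, rng):
    return [nn.Conv2d(cin, cout, 3, stride=stride, rng=rng), nn.ReLU()]


class SegNet:
    """Encoder-decoder network; skips taken at 1/8 and 1/16 resolution."""

    def __init__(self, cfg: NetworkConfig):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        if cfg.preset == "small":
            w = (16, 32, 64, 128, 128)
            levels = []
            cin = 3
            for i, cout in enumerate(w):
                levels.append(_Sequential(
                    _conv_relu(cin, cout, 2, rng)
                    + (_conv_relu(cout, cout, 1, rng) if i > 0 else [])))
                cin = cout
            dec_w = (64, 32)
        else:  # ResNet34-like: stem /2, first stage /4, then /8 /16 /32
            blocks = (3, 4, 6, 3)
            widths = (64, 128, 256, 512)
            levels = [_Sequential(_conv_relu(3, 64, 2, rng))]
            cin = 64
            for nb, cout in zip(blocks, widths):
                stage = [_ResidualBlock(cin, cout, 2, rng)]
                stage += [_ResidualBlock(cout, cout, 1, rng) for _ in range(nb - 1)]
                levels.append(_Sequential(stage))
                cin = cout
            dec_w = (256, 128)
        self.levels = levels  # strides /2 /4 /8 /16 /32
        ch = [self._level_width(i) for i in range(5)]
        self.up1 = nn.Upsample2xBilinear()
        self.dec1 = _Sequential(_conv_relu(ch[4] + ch[3], dec_w[0], 1, rng))
        self.up2 = nn.Upsample2xBilinear()
        self.dec2 = _Sequential(_conv_relu(dec_w[0] + ch[2], dec_w[1], 1, rng))
        self.head = nn.Conv2d(dec_w[1], cfg.out_channels, 1, pad=0, rng=rng)

    def _level_width(self, i: int) -> int:
        if self.cfg.preset == "small":
            return (16, 32, 64, 128, 128)[i]
        return (64, 64, 128, 256, 512)[i]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        """(N, 3, H, W) float32 -> (N, 2, H/8, W/8) logits."""
        acts = []
        for lvl in self.levels:
            x = lvl.forward(x, train)
            acts.append(x)
        skip8, skip16, bott = acts[2], acts[3], acts[4]
        d = self.up1.forward(bott, train)
        d = self.dec1.forward(np.concatenate([d, skip16], axis=1), train)
        d = self.up2.forward(d, train)
        d = self.dec2.forward(np.concatenate([d, skip8], axis=1), train)
        return self.head.forward(d, train)

    def backward(self, dlogits: np.ndarray) -> None:
        d = self.head.backward(dlogits)
        d = self.dec2.backward(d)
        w_dec1 = d.shape[1] - self._skip_w(2)
        d_dec, d_skip8 = d[:, :w_dec1], d[:, w_dec1:]
        d = self.up2.backward(d_dec)
        d = self.dec1.backward(d)
        w_bott = d.shape[1] - self._skip_w(3)
        d_bott, d_skip16 = d[:, :w_bott], d[:, w_bott:]
        d = self.up1.backward(np.ascontiguousarray(d_bott))
        d = self.levels[4].backward(d)
        d = self.levels[3].backward(d + d_skip16)
        d = self.levels[2].backward(d + d_skip8)
        d = self.levels[1].backward(d)
        self.levels[0].backward(d)

    def _skip_w(self, level: int) -> int:
        return self._level_width(level)

    def params(self):
        ps = [p for l in self.levels for p in l.params()]
        ps += self.dec1.params() + self.dec2.params() + self.head.params()
        return ps

    def grads(self):
        gs = [g for l in self.levels for g in l.grads()]
        gs += self.dec1.grads() + self.dec2.grads() + self.head.grads()
        return gs

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return nn.sigmoid(self.forward(x, train=False))


def build_network(cfg: NetworkConfig) -> SegNet:
    """Instantiate the network for a config (validates the 32-divisibility
    contract; output side = input side / 8)."""
    return SegNet(cfg)


@dataclass
class ModelState:
    """Serializable trained model: config + flat parameter list."""

    config: NetworkConfig
    weights: list[np.ndarray]

    def make_network(self) -> SegNet:
        net = build_network(self.config)
        for p, w in zip(net.params(), self.weights):
            p[...] = w
        return net

    def save(self, path: str | Path) -> None:
        path = Path(path)
        np.savez_compressed(path.with_suffix(".npz"),
                            **{f"p{i}": w for i, w in enumerate(self.weights)})
        path.with_suffix(".json").write_text(json.dumps(asdict(self.config)))

    @classmethod
    def load(cls, path: str | Path) -> "ModelState":
        path = Path(path)
        cfg = NetworkConfig(**json.loads(path.with_suffix(".json").read_text()))
        z = np.load(path.with_suffix(".npz"))
        weights = [z[f"p{i}"] for i in range(len(z.files))]
        return cls(config=cfg, weights=weights)


def focal_loss(pred: np.ndarray, target: np.ndarray, gamma: float = 2.0) -> float:
    """Mean focal loss -(1-p_t)^gamma log(p_t) over pixels and channels.

    ``pred`` holds probabilities (clamped to [1e-7, 1-1e-7]); at gamma=0
    this reduces exactly to binary cross-entropy.
    """
    return nn.focal_loss_value(pred, target, gamma)


def iou(pred_binary: np.ndarray, target_binary: np.ndarray) -> float:
    """Intersection over union; two empty masks score 1 by convention."""
    a = np.asarray(pred_binary, dtype=bool)
    b = np.asarray(target_binary, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("shape mismatch")
    union = np.count_nonzero(a | b)
    if union == 0:
        return 1.0
    return float(np.count_nonzero(a & b) / union)


def augment(tile: np.ndarray, mask: np.ndarray, seed: int,
            cfg: AugmentConfig = AugmentConfig()) -> tuple[np.ndarray, np.ndarray]:
    """Seeded paired augmentation.

    Geometric transforms (rot90/flip/elastic) hit tile and mask
    identically — the mask with nearest-neighbour interpolation —
    photometric transforms (noise, blur, brightness/contrast, colour)
    hit the tile only.  With everything disabled this is the identity.
    """
    rng = np.random.default_rng(seed)
    t = tile
    m = mask
    if cfg.rotate90:
        k = int(rng.integers(0, 4))
        if k:
            t = np.rot90(t, k, axes=(0, 1))
            m = np.rot90(m, k, axes=(0, 1))
    if cfg.flip and rng.random() < 0.5:
        t = t[:, ::-1]
        m = m[:, ::-1]
    if cfg.elastic:
        h, w = m.shape[:2]
        dy = ndimage.gaussian_filter(rng.standard_normal((h, w)), cfg.elastic_sigma) * cfg.elastic_alpha
        dx = ndimage.gaussian_filter(rng.standard_normal((h, w)), cfg.elastic_sigma) * cfg.elastic_alpha
        gy, gx = np.mgrid[0:h, 0:w].astype(np.float64)
        coords = [gy + dy, gx + dx]
        chans = [ndimage.map_coordinates(t[..., c].astype(np.float64), coords,
                                         order=1, mode="reflect")
                 for c in range(t.shape[2])]
        t = np.clip(np.stack(chans, axis=-1), 0, 255).astype(tile.dtype)
        m = ndimage.map_coordinates(m, coords, order=0, mode="reflect")
    x = t.astype(np.float64)
    if cfg.brightness_contrast:
        x = (x - 127.5) * rng.uniform(0.85, 1.15) + 127.5
        x = x * rng.uniform(0.9, 1.1)
    if cfg.color:
        x = x * rng.uniform(0.92, 1.08, size=(1, 1, 3))
    if cfg.blur and rng.random() < 0.5:
        x = ndimage.gaussian_filter(x, sigma=(rng.uniform(0.3, 1.0),) * 2 + (0,))
    if cfg.noise:
        x = x + rng.normal(0.0, cfg.noise_sigma, size=x.shape)
    t = np.clip(np.round(x), 0, 255).astype(tile.dtype)
    return t, np.ascontiguousarray(m)


def split_by_slide(manifest: pd.DataFrame, fraction: float = 0.8,
                   seed: int = 0) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Slide-disjoint train/validation partition of a manifest.

    Slides are shuffled with the seed and accumulated into the training
    part until its row share reaches ``fraction``; a manifest with a
    single slide cannot be split and raises ``ValueError``.
    """
    if len(manifest) == 0:
        raise ValueError("empty manifest")
    slides = manifest["slide_path"].unique().tolist()
    if len(slides) < 2:
        raise ValueError("need at least two slides for a slide-level split")
    rng = np.random.default_rng(seed)
    order = list(slides)
    rng.shuffle(order)
    total = len(manifest)
    train_slides: set[str] = set()
    count = 0
    for s in order[:-1]:  # always leave at least one slide for validation
        if count >= fraction * total:
            break
        train_slides.add(s)
        count += int((manifest["slide_path"] == s).sum())
    if not train_slides:
        train_slides.add(order[0])
    is_train = manifest["slide_path"].isin(train_slides)
    return manifest[is_train].copy(), manifest[~is_train].copy()


@dataclass
class TileDataset:
    """In-memory training tiles with full-resolution label rasters."""

    tiles: np.ndarray        # (N, side, side, 3) uint8
    labels: np.ndarray       # (N, side, side) uint8 class labels
    slide_ids: np.ndarray    # (N,) object/str

    def __post_init__(self) -> None:
        self._targets: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.tiles)

    @property
    def n_slides(self) -> int:
        return len(np.unique(self.slide_ids))

    @property
    def targets(self) -> np.ndarray:
        """Un-augmented (N, 2, side/8, side/8) binary targets, cached."""
        if self._targets is None:
            self._targets = np.stack([make_targets(l) for l in self.labels])
        return self._targets


def make_targets(label_tile: np.ndarray, stride: int = OUTPUT_STRIDE) -> np.ndarray:
    """Per-class binary targets, block-max downsampled by ``stride``.

    An output pixel is positive when any covered input pixel carries the
    class — matching the 8 px x 8 px receptive footprint of the output.
    """
    h, w = label_tile.shape
    hb, wb = h // stride, w // stride
    blocks = label_tile[:hb * stride, :wb * stride].reshape(hb, stride, wb, stride)
    out = np.zeros((2, hb, wb), dtype=np.float32)
    out[0] = (blocks == LABEL_BD).any(axis=(1, 3))
    out[1] = (blocks == LABEL_SK).any(axis=(1, 3))
    return out


def _normalize(batch_uint8: np.ndarray) -> np.ndarray:
    """(N, H, W, 3) uint8 -> (N, 3, H, W) float32 roughly in [-1, 1]."""
    x = batch_uint8.astype(np.float32) / 255.0
    x = (x - 0.5) / 0.25
    return np.ascontiguousarray(x.transpose(0, 3, 1, 2))


def _dataset_iou(net: SegNet, ds: TileDataset, idx: np.ndarray,
                 batch: int, threshold: float = 0.5) -> float:
    inter = union = 0
    for s in range(0, len(idx), batch):
        sel = idx[s:s + batch]
        p = net.predict_proba(_normalize(ds.tiles[sel])) >= threshold
        t = ds.targets[sel] >= 0.5
        inter += int(np.count_nonzero(p & t))
        union += int(np.count_nonzero(p | t))
    return 1.0 if union == 0 else inter / union


def train(dataset: TileDataset, net: SegNet,
          cfg: TrainingConfig) -> tuple[ModelState, TrainingHistory]:
    """Focal-loss/Adam training with slide-level 80/20 split and per-epoch
    IoU monitoring; returns the best-validation-IoU state."""
    if len(dataset) == 0:
        raise ValueError("empty dataset")
    if dataset.n_slides < 2:
        raise ValueError("training needs tiles from at least two slides")
    frame = pd.DataFrame({"slide_path": dataset.slide_ids,
                          "idx": np.arange(len(dataset))})
    tr, va = split_by_slide(frame, cfg.split_fraction, cfg.seed)
    tr_idx = tr["idx"].to_numpy()
    va_idx = va["idx"].to_numpy()

    rng = np.random.default_rng(cfg.seed)
    opt = nn.Adam(net.params(), net.grads(), lr=cfg.learning_rate)
    hist = TrainingHistory()
    best_iou = -1.0
    best_weights = [p.copy() for p in net.params()]
    for epoch in range(cfg.epochs):
        order = rng.permutation(tr_idx)
        losses = []
        for s in range(0, len(order), cfg.batch_size):
            sel = order[s:s + cfg.batch_size]
            tiles = np.empty((len(sel),) + dataset.tiles.shape[1:], dtype=np.uint8)
            targs = np.empty((len(sel),) + dataset.targets.shape[1:], dtype=np.float32)
            for j, i in enumerate(sel):
                aug_seed = int(rng.integers(0, 2**31 - 1))
                t, m = augment(dataset.tiles[i], dataset.labels[i],
                               aug_seed, cfg.augment)
                tiles[j] = t
                targs[j] = make_targets(m)
            logits = net.forward(_normalize(tiles), train=True)
            loss, dz = nn.focal_loss_grad_logits(logits, targs, cfg.gamma)
            net.backward(dz)
            opt.step()
            losses.append(loss)
        hist.epoch_loss.append(float(np.mean(losses)))
        hist.train_iou.append(_dataset_iou(net, dataset, tr_idx, cfg.batch_size))
        v = _dataset_iou(net, dataset, va_idx, cfg.batch_size)
        hist.val_iou.append(v)
        if v > best_iou:
            best_iou = v
            best_weights = [p.copy() for p in net.params()]
    return ModelState(config=net.cfg, weights=best_weights), hist


def predict_tile(state: SegNet | ModelState, tile: np.ndarray,
                 coord: TileCoord | None = None) -> TileHeatMap:
    """Run one tile (H, W, 3 uint8) through the network -> TileHeatMap."""
    net = state.make_network() if isinstance(state, ModelState) else state
    side = net.cfg.input_side
    if tile.shape[:2] != (side, side):
        raise ValueError(f"tile must be {side}x{side}, got {tile.shape[:2]}")
    probs = net.predict_proba(_normalize(tile[None]))[0].astype(np.float32)
    if coord is None:
        coord = TileCoord(0, 0, side, -1)
    return TileHeatMap(probs=probs, coord=coord)


def predict_tiles(net: SegNet, tiles: np.ndarray,
                  coords: list[TileCoord], batch: int = 8) -> list[TileHeatMap]:
    """Batched inference over a stack of (N, side, side, 3) tiles."""
    out: list[TileHeatMap] = []
    for s in range(0, len(tiles), batch):
        probs = net.predict_proba(_normalize(tiles[s:s + batch]))
        for j in range(probs.shape[0]):
            out.append(TileHeatMap(probs=probs[j].astype(np.float32),
                                   coord=coords[s + j]))
    return out
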