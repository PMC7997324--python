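"""Residual CNN observer for low-contrast object presence.

The network is a stack of residual levels: at level *i* a residual
block (two 3x3 convolutions, each followed by batch normalization,
ReLU activations, and an identity shortcut with a 1x1 projection when
the channel count changes) of ``filters_per_level[i]`` channels is
followed by 2x2 max-pooling that halves the spatial grid. After the
last level, the flattened feature map feeds a fully-connected layer
producing two softmax-normalized logits (absent / present). The
reference profile uses seven levels with 64, 128, 256, 512, 1024, 2048
and 4096 filters; ``width_scale`` shrinks every channel count
proportionally for desk-scale experiments.

With a 64-px input the halving chain reaches 1x1 after six poolings,
so the seventh level operates at 1x1 and its pooling is skipped
(floor-clamped); a 128-px input activates all seven poolings.

Training is plain minibatch Adam on the binary cross-entropy, from
scratch (initial learning rate 1e-4), with a fixed affine input
normalization (HU - 70)/25 so inference needs no batch statistics.
Grad-CAM heatmaps are produced from the gradient of a class logit with
respect to a residual block's output feature map.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import nn
from .errors import ArchitectureError, DegenerateTrainingError, InputError

__all__ = [
    "DetectorConfig",
    "ResidualDetector",
    "TrainedDetector",
    "build_detector",
    "train_detector",
    "predict_presence",
    "grad_cam",
    "spatial_trace",
    "save_checkpoint",
    "load_checkpoint",
]

REFERENCE_FILTERS = (64, 128, 256, 512, 1024, 2048, 4096)


@dataclass(frozen=True)
class DetectorConfig:
    """Architecture and training hyper-parameters.

    ``filters_per_level`` are the full-width channel counts; the
    realized network uses ``max(1, round(f * width_scale))`` channels
    per level. ``norm_center``/``norm_scale`` define the fixed affine
    input map applied before the first convolution.
    """

    n_levels: int = 7
    filters_per_level: tuple[int, ...] = REFERENCE_FILTERS
    width_scale: float = 0.125
    input_px: int = 64
    learning_rate: float = 1e-4
    epochs: int = 10
    batch_size: int = 32
    seed: int = 0
    norm_center: float = 70.0
    norm_scale: float = 25.0
    val_fraction: float = 0.1
    #: random 90-degree rotations/flips during training; the detection
    #: task is exactly symmetric under the dihedral group, so this is
    #: free regularization at desk-scale training-set sizes
    augment: bool = True

    def __post_init__(self) -> None:
        if len(self.filters_per_level) != self.n_levels:
            raise ArchitectureError(
                f"filters_per_level has {len(self.filters_per_level)} entries "
                f"for {self.n_levels} levels"
            )
        if self.width_scale <= 0:
            raise ArchitectureError("width_scale must be positive")
        if self.input_px < 8:
            raise ArchitectureError(
                f"input_px={self.input_px} leaves no spatial support for "
                f"{self.n_levels} pooling levels"
            )

    @property
    def scaled_filters(self) -> tuple[int, ...]:
        return tuple(
            max(1, int(round(f * self.width_scale))) for f in self.filters_per_level
        )


def spatial_trace(config: DetectorConfig) -> list[int]:
    """Spatial side length after each level's (possibly skipped) pooling.

    Pooling floor-halves; at size 1 it is skipped, so the trace for a
    64-px input over 7 levels is [32, 16, 8, 4, 2, 1, 1].
    """
    sizes = []
    s = config.input_px
    for _ in range(config.n_levels):
        if s >= 2:
            s = s // 2
        sizes.append(s)
    if sizes and sizes[-1] < 1:
        raise ArchitectureError("pooling chain collapses below 1 pixel")
    return sizes


class ResidualDetector:
    """The network object: residual levels + pooling flags + linear head."""

    def __init__(self, config: DetectorConfig) -> None:
        self.config = config
        rng = np.random.default_rng(np.random.SeedSequence((config.seed, 0xCAFE)))
        filters = config.scaled_filters
        trace = spatial_trace(config)
        self.blocks: list[nn.ResidualBlock] = []
        self.pools: list[nn.MaxPool2d | None] = []
        c_in = 1
        s = config.input_px
        for level, c_out in enumerate(filters):
            self.blocks.append(nn.ResidualBlock(c_in, c_out, rng))
            self.pools.append(nn.MaxPool2d() if s >= 2 else None)
            s = trace[level]
            c_in = c_out
        self.head = nn.Linear(filters[-1] * trace[-1] * trace[-1], 2, rng)
        self._feature_maps: list[np.ndarray] | None = None

    def layers(self) -> list[nn.Layer]:
        out: list[nn.Layer] = []
        for b in self.blocks:
            out.extend(b.sublayers())
        out.append(self.head)
        return out

    def normalize(self, images: np.ndarray) -> np.ndarray:
        x = (np.asarray(images, dtype=np.float32) - self.config.norm_center)
        x /= self.config.norm_scale
        return x[..., None]  # NHWC with one channel

    def forward(
        self, x: np.ndarray, train: bool, record_features: bool = False
    ) -> np.ndarray:
        if x.shape[1] != self.config.input_px or x.shape[2] != self.config.input_px:
            raise InputError(
                f"expected {self.config.input_px}-px square input, got {x.shape[1:3]}"
            )
        feats = [] if record_features else None
        for block, pool in zip(self.blocks, self.pools):
            x = block.forward(x, train)
            if feats is not None:
                feats.append(x)
            if pool is not None:
                x = pool.forward(x, train)
        self._head_in_shape = x.shape
        logits = self.head.forward(x.reshape(x.shape[0], -1), train)
        self._feature_maps = feats
        return logits

    def backward(self, dlogits: np.ndarray, stop_level: int | None = None) -> np.ndarray:
        """Backprop; with ``stop_level`` set, returns the gradient at
        that block's output feature map instead of at the input."""
        dx = self.head.backward(dlogits).reshape(self._head_in_shape)
        for level in range(len(self.blocks) - 1, -1, -1):
            if self.pools[level] is not None:
                dx = self.pools[level].backward(dx)
            if stop_level is not None and level == stop_level:
                return dx
            dx = self.blocks[level].backward(dx)
        return dx


@dataclass
class TrainedDetector:
    """A trained network plus its provenance (config, seed, history)."""

    net: ResidualDetector
    config: DetectorConfig
    history: list[dict] = field(default_factory=list)


def build_detector(config: DetectorConfig | None = None) -> ResidualDetector:
    return ResidualDetector(config or DetectorConfig())


def _stratified_split(
    labels: np.ndarray, val_fraction: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    train_idx, val_idx = [], []
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        idx = rng.permutation(idx)
        n_val = int(round(val_fraction * len(idx)))
        val_idx.append(idx[:n_val])
        train_idx.append(idx[n_val:])
    return np.sort(np.concatenate(train_idx)), np.sort(np.concatenate(val_idx))


def _augment_d4(images: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Random dihedral-group transform per image (rot90 x optional flip)."""
    out = np.empty_like(images)
    ks = rng.integers(0, 4, len(images))
    flips = rng.integers(0, 2, len(images))
    for i in range(len(images)):
        img = np.rot90(images[i], ks[i])
        out[i] = img[:, ::-1] if flips[i] else img
    return out


def train_detector(
    detector: ResidualDetector,
    manifest: pd.DataFrame,
    images: np.ndarray,
    config: DetectorConfig | None = None,
) -> TrainedDetector:
    """Train from scratch on binary present/absent ground truth.

    Holds out a seeded, label-stratified validation fraction; logs
    per-epoch mean training loss and validation AUC. Deterministic for
    a fixed config seed.
    """
    from .roc_stats import empirical_auc

    config = config or detector.config
    labels = manifest["present"].to_numpy().astype(np.int64)
    if len(np.unique(labels)) < 2:
        raise DegenerateTrainingError("training data contains a single class")
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 0x7EA1)))
    train_idx, val_idx = _stratified_split(labels, config.val_fraction, rng)
    opt = nn.Adam(detector.layers(), lr=config.learning_rate)
    history: list[dict] = []
    for epoch in range(config.epochs):
        order = rng.permutation(train_idx)
        losses = []
        for start in range(0, len(order), config.batch_size):
            batch = order[start : start + config.batch_size]
            batch_images = images[batch]
            if config.augment:
                batch_images = _augment_d4(batch_images, rng)
            x = detector.normalize(batch_images)
            logits = detector.forward(x, train=True)
            loss, dlogits = nn.softmax_cross_entropy(logits, labels[batch])
            detector.backward(dlogits)
            opt.step()
            losses.append(loss)
        entry = {"epoch": epoch + 1, "train_loss": float(np.mean(losses))}
        if len(val_idx):
            val_p = _predict_net(detector, images[val_idx])
            entry["val_auc"] = empirical_auc(
                val_p[labels[val_idx] == 1], val_p[labels[val_idx] == 0]
            ).auc
        history.append(entry)
    return TrainedDetector(net=detector, config=config, history=history)


def _predict_net(
    net: ResidualDetector, images: np.ndarray, batch_size: int = 64
) -> np.ndarray:
    probs = np.empty(len(images), dtype=np.float64)
    for start in range(0, len(images), batch_size):
        x = net.normalize(images[start : start + batch_size])
        logits = net.forward(x, train=False)
        probs[start : start + len(x)] = nn.softmax(logits)[:, 1]
    return probs


def predict_presence(trained: TrainedDetector, images: np.ndarray) -> np.ndarray:
    """Softmax probability of the present class, one per case."""
    images = np.asarray(images)
    if images.ndim == 2:
        images = images[None]
    if images.shape[1] != trained.config.input_px:
        raise InputError(
            f"image geometry {images.shape[1:]} does not match "
            f"config.input_px={trained.config.input_px}"
        )
    return _predict_net(trained.net, images)


def default_cam_level(trained: TrainedDetector, min_size: int = 16) -> int:
    """Deepest level whose block output is at least ``min_size`` pixels.

    The final block of the reference profile operates at 1x1 and its
    activation map carries no location information, so the heatmap
    defaults to the deepest level whose feature cells are still finer
    than the radius of the smallest test object (a 5-mm disk spans
    ~3 px at the default spacing, so a 16x16 map on a 64-px input).
    """
    sizes = [trained.config.input_px] + spatial_trace(trained.config)[:-1]
    candidates = [i for i, s in enumerate(sizes) if s >= min_size]
    return candidates[-1] if candidates else 0


def grad_cam(
    trained: TrainedDetector,
    image: np.ndarray,
    target_class: int = 1,
    level: int | None = None,
) -> np.ndarray:
    """Gradient-weighted class activation map, upsampled to input size.

    Channel weights are the spatial averages of the target-class logit
    gradient at the chosen residual block's output; the heatmap is the
    rectified weighted sum of that block's feature maps.
    """
    from scipy.ndimage import zoom

    if target_class not in (0, 1):
        raise InputError(f"target_class must be 0 or 1, got {target_class}")
    net = trained.net
    if level is None:
        level = default_cam_level(trained)
    if not 0 <= level < len(net.blocks):
        raise InputError(f"level {level} outside [0, {len(net.blocks)})")
    x = net.normalize(np.asarray(image)[None])
    net.forward(x, train=False, record_features=True)
    feats = net._feature_maps[level][0]  # (h, w, C)
    dlogits = np.zeros((1, 2), dtype=np.float32)
    dlogits[0, target_class] = 1.0
    dfeats = net.backward(dlogits, stop_level=level)[0]
    weights = dfeats.mean(axis=(0, 1))
    cam = np.maximum(feats @ weights, 0.0)
    factor = trained.config.input_px / cam.shape[0]
    if factor != 1:
        cam = zoom(cam, factor, order=1, grid_mode=True, mode="nearest")
    return cam.astype(np.float64)


def save_checkpoint(trained: TrainedDetector, path: str | Path) -> None:
    """Single-file parameter archive + JSON sidecar with the config."""
    path = Path(path)
    arrays: dict[str, np.ndarray] = {}
    for i, layer in enumerate(trained.net.layers()):
        for k, v in layer.params.items():
            arrays[f"layer{i}.{k}"] = v
        if isinstance(layer, nn.BatchNorm2d):
            arrays[f"layer{i}.running_mean"] = layer.running_mean
            arrays[f"layer{i}.running_var"] = layer.running_var
    np.savez(path, **arrays)
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(
        json.dumps({"config": asdict(trained.config), "history": trained.history})
    )


def load_checkpoint(path: str | Path) -> TrainedDetector:
    path = Path(path)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    cfg_dict = meta["config"]
    cfg_dict["filters_per_level"] = tuple(cfg_dict["filters_per_level"])
    config = DetectorConfig(**cfg_dict)
    net = ResidualDetector(config)
    with np.load(path if path.suffix == ".npz" else str(path)) as data:
        for i, layer in enumerate(net.layers()):
            for k in layer.params:
                layer.params[k] = data[f"layer{i}.{k}"]
            if isinstance(layer, nn.BatchNorm2d):
                layer.running_mean = data[f"layer{i}.running_mean"]
                layer.running_var = data[f"layer{i}.running_var"]
    return TrainedDetector(net=net, config=config, history=meta["history"])
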