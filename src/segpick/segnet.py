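"""Full-resolution residual network (FRRN) for micrograph segmentation.

The network processes the image in two coupled streams.  A residual
stream carries a full-resolution feature map throughout, preserving the
localization needed for per-pixel labels; a pooling stream descends
through max-pooled scales to learn abstract context.  The building
blocks are:

* the residual unit (RU), ``x_n = x_{n-1} + F(x_{n-1})`` where ``F`` is
  conv-BN-ReLU-conv-BN;
* the full-resolution residual unit (FRRU), which pools the residual
  stream to the pooling stream's scale, concatenates the two, applies
  two conv-BN-ReLU stages to produce the new pooled features ``z``
  (``z_n = H(y_{n-1}, z_{n-1})``), and adds a 1x1-projected, upsampled
  copy back into the residual stream (``y_n = y_{n-1} + G(...)``).  If
  the pooling function ``H`` is zero the FRRU reduces to an RU.

The default assembly uses five pooled scales on the way down and four
FRRU stages on the way up; max-pooling argmax indices are reused by the
unpooling steps so localization survives the round trip.  The up path
always returns to full resolution regardless of the configured stage
counts (missing stages are plain index-preserving unpools).

Training minimizes per-pixel cross-entropy with inverse-frequency class
weights (protein pixels are vastly outnumbered by background) using
Adam on random crops, and selects the epoch with the best validation
mean F1.
"""

from __future__ import annotations

import copy
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional, Sequence

import numpy as np

from .evalmetrics import pixel_metrics
from .io_formats import ClassMask, N_CLASSES
from .enhance import ThreeChannelImage
from .nnops import (
    Adam,
    BatchNorm2d,
    Conv2d,
    MaxPool2d,
    MaxUnpool2d,
    NearestUpsample,
    Param,
    ReLU,
    softmax,
    weighted_cross_entropy,
)

logger = logging.getLogger(__name__)

__all__ = [
    "FRRNConfig",
    "TrainConfig",
    "EpochRecord",
    "ResidualUnit",
    "FRRU",
    "FRRN",
    "build_frrn",
    "train",
    "predict",
    "save_model",
    "load_model",
]


@dataclass
class FRRNConfig:
    n_classes: int = 4
    n_pooling_stages: int = 5
    n_unpooling_stages: int = 4
    base_channels: int = 8
    input_channels: int = 3

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if self.n_pooling_stages < 1 or self.n_unpooling_stages < 1:
            raise ValueError("stage counts must be >= 1")
        if self.base_channels < 4:
            raise ValueError("base_channels must be >= 4")
        if self.input_channels != 3:
            raise ValueError("input_channels must be 3")

    @property
    def divisor(self) -> int:
        return 2 ** self.n_pooling_stages


@dataclass
class TrainConfig:
    epochs: int = 300
    train_fraction: float = 0.8
    seed: int = 0
    learning_rate: float = 1e-3
    batch_size: int = 1
    crop_size: int = 128

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if not (0.0 < self.train_fraction < 1.0):
            raise ValueError("train_fraction must be in (0, 1)")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.crop_size % 2:
            raise ValueError("crop_size must be even")


@dataclass
class EpochRecord:
    epoch: int
    f1_per_class: dict[int, float]
    mean_f1: float
    train_loss: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.mean_f1 <= 1.0):
            raise ValueError("mean F1 must be in [0, 1]")


class ResidualUnit:
    """RU: out = x + F(x) with F = conv3-BN-ReLU-conv3-BN."""

    def __init__(self, channels: int, rng: np.random.Generator, name: str = "ru"):
        self.conv1 = Conv2d(channels, channels, 3, rng, f"{name}.conv1")
        self.bn1 = BatchNorm2d(channels, name=f"{name}.bn1")
        self.relu = ReLU()
        self.conv2 = Conv2d(channels, channels, 3, rng, f"{name}.conv2")
        self.bn2 = BatchNorm2d(channels, name=f"{name}.bn2")

    def params(self) -> list[Param]:
        return self.conv1.params() + self.bn1.params() + self.conv2.params() + self.bn2.params()

    def layers(self):
        return [self.conv1, self.bn1, self.conv2, self.bn2]

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        f = self.relu.forward(self.bn1.forward(self.conv1.forward(x), training))
        f = self.bn2.forward(self.conv2.forward(f), training)
        return x + f

    def backward(self, dy: np.ndarray) -> np.ndarray:
        df = self.conv2.backward(self.bn2.backward(dy))
        df = self.conv1.backward(self.bn1.backward(self.relu.backward(df)))
        return dy + df


class FRRU:
    """Full-resolution residual unit coupling the two streams at scale 2^k."""

    def __init__(self, y_channels: int, z_in: int, z_out: int, scale: int,
                 rng: np.random.Generator, name: str = "frru"):
        self.scale = scale
        self.pool_y = MaxPool2d(scale)
        self.conv1 = Conv2d(y_channels + z_in, z_out, 3, rng, f"{name}.conv1")
        self.bn1 = BatchNorm2d(z_out, name=f"{name}.bn1")
        self.relu1 = ReLU()
        self.conv2 = Conv2d(z_out, z_out, 3, rng, f"{name}.conv2")
        self.bn2 = BatchNorm2d(z_out, name=f"{name}.bn2")
        self.relu2 = ReLU()
        self.proj = Conv2d(z_out, y_channels, 1, rng, f"{name}.proj")
        self.up = NearestUpsample(scale)
        self._split = y_channels

    def params(self) -> list[Param]:
        return (self.conv1.params() + self.bn1.params() + self.conv2.params()
                + self.bn2.params() + self.proj.params())

    def layers(self):
        return [self.conv1, self.bn1, self.conv2, self.bn2, self.proj]

    def forward(self, y: np.ndarray, z: np.ndarray, training: bool
                ) -> tuple[np.ndarray, np.ndarray]:
        if y.shape[2] != z.shape[2] * self.scale or y.shape[3] != z.shape[3] * self.scale:
            raise ValueError(
                f"pooled stream {z.shape[2:]} is not 1/{self.scale} of "
                f"residual stream {y.shape[2:]}"
            )
        yp = self.pool_y.forward(y)
        cat = np.concatenate([yp, z], axis=1)
        h = self.relu1.forward(self.bn1.forward(self.conv1.forward(cat), training))
        z_new = self.relu2.forward(self.bn2.forward(self.conv2.forward(h), training))
        y_new = y + self.up.forward(self.proj.forward(z_new))
        return y_new, z_new

    def backward(self, dy_new: np.ndarray, dz_new: np.ndarray
                 ) -> tuple[np.ndarray, np.ndarray]:
        # residual branch: y_new = y + up(proj(z_new))
        dz_total = dz_new + self.proj.backward(self.up.backward(dy_new))
        dh = self.conv2.backward(self.bn2.backward(self.relu2.backward(dz_total)))
        dcat = self.conv1.backward(self.bn1.backward(self.relu1.backward(dh)))
        dyp, dz = dcat[:, : self._split], dcat[:, self._split:]
        dy = dy_new + self.pool_y.backward(dyp)
        return dy, dz


class FRRN:
    """The assembled network.  Input (N, 3, H, W) -> logits (N, K, H, W)."""

    def __init__(self, config: FRRNConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        B = config.base_channels
        P = config.n_pooling_stages
        U = min(config.n_unpooling_stages, max(P - 1, 0))
        self._n_up_frru = U
        ch = [B] + [B * 2 ** min(k, 3) for k in range(1, P + 1)]  # z channels per scale

        self.stem_conv = Conv2d(config.input_channels, B, 3, rng, "stem.conv")
        self.stem_bn = BatchNorm2d(B, name="stem.bn")
        self.stem_relu = ReLU()
        self.stem_ru = ResidualUnit(B, rng, "stem.ru")
        self.y_proj = Conv2d(B, B, 1, rng, "y_proj")

        self.pools = [MaxPool2d(2) for _ in range(P)]
        self.down = [
            FRRU(B, ch[k - 1], ch[k], 2 ** k, rng, f"down{k}") for k in range(1, P + 1)
        ]
        # up path: scales P-1 .. 1, FRRUs on the first U of them
        self.unpools = [MaxUnpool2d(2) for _ in range(P)]
        self.adapts = [
            Conv2d(ch[k + 1], ch[k], 1, rng, f"adapt{k}") for k in range(P - 1, -1, -1)
        ]  # ordered by traversal: scale P-1 first, scale 0 last
        self.up_frrus = [
            FRRU(B, ch[k], ch[k], 2 ** k, rng, f"up{k}")
            for k in range(P - 1, P - 1 - U, -1)
        ]
        self.merge_conv = Conv2d(2 * B, B, 3, rng, "merge.conv")
        self.merge_bn = BatchNorm2d(B, name="merge.bn")
        self.merge_relu = ReLU()
        self.merge_ru = ResidualUnit(B, rng, "merge.ru")
        self.classifier = Conv2d(B, config.n_classes, 1, rng, "classifier")

    # -- parameter bookkeeping ------------------------------------------------

    def _blocks(self):
        blocks = [self.stem_conv, self.stem_bn, self.stem_ru, self.y_proj]
        blocks += self.down + self.adapts + self.up_frrus
        blocks += [self.merge_conv, self.merge_bn, self.merge_ru, self.classifier]
        return blocks

    def params(self) -> list[Param]:
        out: list[Param] = []
        for b in self._blocks():
            out.extend(b.params())
        return out

    def _bn_layers(self) -> list[BatchNorm2d]:
        bns = []
        for b in self._blocks():
            if isinstance(b, BatchNorm2d):
                bns.append(b)
            elif hasattr(b, "layers"):
                bns.extend(l for l in b.layers() if isinstance(l, BatchNorm2d))
        return bns

    @property
    def n_parameters(self) -> int:
        return sum(p.value.size for p in self.params())

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {p.name: p.value.copy() for p in self.params()}
        for i, bn in enumerate(self._bn_layers()):
            state[f"__bn{i}.running_mean"] = bn.running_mean.copy()
            state[f"__bn{i}.running_var"] = bn.running_var.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for p in self.params():
            p.value[...] = state[p.name]
        for i, bn in enumerate(self._bn_layers()):
            bn.running_mean[...] = state[f"__bn{i}.running_mean"]
            bn.running_var[...] = state[f"__bn{i}.running_var"]

    # -- forward / backward ---------------------------------------------------

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        h, w = x.shape[2], x.shape[3]
        d = self.config.divisor
        if h % d or w % d:
            raise ValueError(f"input {h}x{w} not divisible by 2^{self.config.n_pooling_stages}")
        s = self.stem_relu.forward(self.stem_bn.forward(self.stem_conv.forward(x), training))
        s = self.stem_ru.forward(s, training)
        y = self.y_proj.forward(s)
        z = s
        for pool, frru in zip(self.pools, self.down):
            z = pool.forward(z)
            y, z = frru.forward(y, z, training)
        P = self.config.n_pooling_stages
        for i in range(P):  # traversal i=0 -> scale P-1, ..., i=P-1 -> scale 0
            z = self.adapts[i].forward(z)
            z = self.unpools[i].forward(z, self.pools[P - 1 - i].indices)
            if i < self._n_up_frru:
                y, z = self.up_frrus[i].forward(y, z, training)
        m = np.concatenate([y, z], axis=1)
        m = self.merge_relu.forward(self.merge_bn.forward(self.merge_conv.forward(m), training))
        m = self.merge_ru.forward(m, training)
        return self.classifier.forward(m)

    def backward(self, dlogits: np.ndarray) -> None:
        dm = self.classifier.backward(dlogits)
        dm = self.merge_ru.backward(dm)
        dm = self.merge_conv.backward(self.merge_bn.backward(self.merge_relu.backward(dm)))
        B = self.config.base_channels
        dy, dz = dm[:, :B], dm[:, B:]
        P = self.config.n_pooling_stages
        for i in range(P - 1, -1, -1):
            if i < self._n_up_frru:
                dy, dz = self.up_frrus[i].backward(dy, dz)
            dz = self.unpools[i].backward(dz)
            dz = self.adapts[i].backward(dz)
        for pool, frru in zip(reversed(self.pools), reversed(self.down)):
            dy, dz = frru.backward(dy, dz)
            dz = pool.backward(dz)
        ds = dz + self.y_proj.backward(dy)
        ds = self.stem_ru.backward(ds)
        self.stem_conv.backward(self.stem_bn.backward(self.stem_relu.backward(ds)))

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        """Softmax probabilities (N, K, H, W) in inference mode."""
        return softmax(self.forward(x, training=False), axis=1)


def build_frrn(config: FRRNConfig | None = None, seed: int = 0) -> FRRN:
    """Instantiate an FRRN; logs the parameter count."""
    model = FRRN(config or FRRNConfig(), seed=seed)
    logger.info("FRRN built: %d parameters", model.n_parameters)
    return model


# ---------------------------------------------------------------------------
# input normalization, training, inference
# ---------------------------------------------------------------------------


def _to_input(image: ThreeChannelImage) -> np.ndarray:
    """(H, W, 3) uint8 -> (3, H, W) float in [-0.5, 0.5]."""
    return image.channels.astype(np.float64).transpose(2, 0, 1) / 255.0 - 0.5


def _class_weights(masks: Sequence[ClassMask], n_classes: int) -> np.ndarray:
    counts = np.zeros(n_classes)
    for m in masks:
        counts += np.bincount(m.labels.ravel(), minlength=n_classes)[:n_classes]
    present = counts > 0
    w = np.zeros(n_classes)
    w[present] = counts.sum() / (present.sum() * counts[present])
    return w


def _mean_val_f1(model: FRRN, val_pairs, n_classes: int) -> tuple[float, dict[int, float]]:
    """Mean F1 over classes present in the validation truth."""
    f1_sums: dict[int, list[float]] = {}
    for image, mask in val_pairs:
        prob = predict(model, image)
        pred = ClassMask(labels=np.argmax(prob, axis=2).astype(np.uint8))
        rep = pixel_metrics(pred, mask)
        present = set(np.unique(mask.labels).tolist())
        for c in range(n_classes):
            if c in present:
                f1_sums.setdefault(c, []).append(rep.f1[c])
    per_class = {c: float(np.mean(v)) for c, v in f1_sums.items()}
    mean_f1 = float(np.mean(list(per_class.values()))) if per_class else 0.0
    return mean_f1, per_class


def _random_crop(x: np.ndarray, t: np.ndarray, size: int, rng: np.random.Generator):
    h, w = t.shape
    if h <= size and w <= size:
        return x, t
    size_h, size_w = min(size, h), min(size, w)
    y0 = int(rng.integers(0, h - size_h + 1))
    x0 = int(rng.integers(0, w - size_w + 1))
    return x[:, y0 : y0 + size_h, x0 : x0 + size_w], t[y0 : y0 + size_h, x0 : x0 + size_w]


def train(
    model: FRRN,
    pairs: Sequence[tuple[ThreeChannelImage, ClassMask]],
    cfg: TrainConfig,
    val_metric_fn: Optional[Callable[[FRRN, list], tuple[float, dict[int, float]]]] = None,
) -> tuple[FRRN, list[EpochRecord]]:
    """Train with a deterministic seeded split and best-validation-F1 selection.

    The data are split ``train_fraction`` / rest by a seeded permutation
    (at least one image on each side; with a single pair it serves as
    both).  Each epoch cycles the training images in a seeded shuffled
    order, taking one random crop per image, and evaluates mean
    validation F1; the checkpoint with the highest mean F1 is returned
    (ties resolved to the earliest epoch).  ``val_metric_fn`` may
    override the validation metric (mainly for testing).
    """
    if len(pairs) == 0:
        raise ValueError("empty training set")
    for image, mask in pairs:
        if image.shape != mask.shape:
            raise ValueError("image/mask shape mismatch")
    n_classes = model.config.n_classes
    all_labels = np.unique(np.concatenate([m.labels.ravel() for _, m in pairs]))
    if len(all_labels) < 2:
        warnings.warn("all masks contain a single class; training is degenerate")

    rng = np.random.default_rng(cfg.seed)
    perm = rng.permutation(len(pairs))
    if len(pairs) == 1:
        train_idx = val_idx = [0]
    else:
        n_train = int(np.clip(round(cfg.train_fraction * len(pairs)), 1, len(pairs) - 1))
        train_idx = perm[:n_train].tolist()
        val_idx = perm[n_train:].tolist()
    train_pairs = [pairs[i] for i in train_idx]
    val_pairs = [pairs[i] for i in val_idx]
    logger.info("training on %d images, validating on %d", len(train_pairs), len(val_pairs))

    weights = _class_weights([m for _, m in train_pairs], n_classes)
    inputs = [(_to_input(im), mk.labels.astype(np.int64)) for im, mk in train_pairs]
    opt = Adam(model.params(), lr=cfg.learning_rate)
    evaluate = val_metric_fn or (lambda m, vp: _mean_val_f1(m, vp, n_classes))

    records: list[EpochRecord] = []
    best: tuple[float, int, Optional[dict]] = (-1.0, -1, None)
    d = model.config.divisor
    for epoch in range(cfg.epochs):
        order = rng.permutation(len(inputs))
        losses = []
        batch_x, batch_t = [], []
        for j in order:
            x, t = inputs[j]
            xc, tc = _random_crop(x, t, cfg.crop_size, rng)
            # crop to the largest divisible size
            hc = (tc.shape[0] // d) * d
            wc = (tc.shape[1] // d) * d
            if hc == 0 or wc == 0:
                raise ValueError("image smaller than the network's minimum size")
            batch_x.append(xc[:, :hc, :wc])
            batch_t.append(tc[:hc, :wc])
            if len(batch_x) < cfg.batch_size and j != order[-1]:
                continue
            shapes = {bx.shape for bx in batch_x}
            if len(shapes) > 1:  # ragged batch: step per item
                groups = [[i] for i in range(len(batch_x))]
            else:
                groups = [list(range(len(batch_x)))]
            for g in groups:
                xb = np.stack([batch_x[i] for i in g])
                tb = np.stack([batch_t[i] for i in g])
                logits = model.forward(xb, training=True)
                loss, dlogits = weighted_cross_entropy(logits, tb, weights)
                opt.zero_grad()
                model.backward(dlogits)
                opt.step()
                losses.append(loss)
            batch_x, batch_t = [], []
        mean_f1, per_class = evaluate(model, val_pairs)
        records.append(EpochRecord(
            epoch=epoch, f1_per_class=per_class, mean_f1=mean_f1,
            train_loss=float(np.mean(losses)),
        ))
        if mean_f1 > best[0]:
            best = (mean_f1, epoch, model.state_dict())
        logger.debug("epoch %d: loss %.4f val mean F1 %.4f", epoch, records[-1].train_loss, mean_f1)
    if best[2] is not None:
        model.load_state_dict(best[2])
    return model, records


def predict(
    model: FRRN,
    image: ThreeChannelImage,
    tile: int = 512,
    overlap: int = 32,
) -> np.ndarray:
    """Per-pixel class probabilities (H, W, K) for one image.

    The image is reflect-padded to the network's divisibility constraint
    and cropped back.  Images larger than ``tile`` are processed in
    overlapping tiles whose probabilities are averaged in the overlaps.
    """
    x = _to_input(image)
    _, h, w = x.shape
    d = model.config.divisor
    if max(h, w) > tile:
        return _predict_tiled(model, x, tile, overlap)
    ph = (d - h % d) % d
    pw = (d - w % d) % d
    xp = np.pad(x, ((0, 0), (0, ph), (0, pw)), mode="reflect")
    prob = model.predict_proba(xp[None])[0]
    return prob[:, :h, :w].transpose(1, 2, 0)


def _predict_tiled(model: FRRN, x: np.ndarray, tile: int, overlap: int) -> np.ndarray:
    _, h, w = x.shape
    d = model.config.divisor
    k = model.config.n_classes
    acc = np.zeros((k, h, w))
    cnt = np.zeros((h, w))
    step = tile - overlap
    for y0 in range(0, h, step):
        for x0 in range(0, w, step):
            y1, x1 = min(y0 + tile, h), min(x0 + tile, w)
            sub = x[:, y0:y1, x0:x1]
            ph = (d - sub.shape[1] % d) % d
            pw = (d - sub.shape[2] % d) % d
            sp = np.pad(sub, ((0, 0), (0, ph), (0, pw)), mode="reflect")
            p = model.predict_proba(sp[None])[0][:, : y1 - y0, : x1 - x0]
            acc[:, y0:y1, x0:x1] += p
            cnt[y0:y1, x0:x1] += 1
            if x1 == w:
                break
        if y1 == h:
            break
    return (acc / cnt).transpose(1, 2, 0)


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

_CKPT_VERSION = 1


def save_model(model: FRRN, path) -> None:
    """Single-file checkpoint: config JSON + all arrays (npz container)."""
    cfg = model.config
    meta = json.dumps({
        "version": _CKPT_VERSION,
        "n_classes": cfg.n_classes,
        "n_pooling_stages": cfg.n_pooling_stages,
        "n_unpooling_stages": cfg.n_unpooling_stages,
        "base_channels": cfg.base_channels,
        "input_channels": cfg.input_channels,
    })
    state = model.state_dict()
    np.savez(Path(path), __meta__=np.frombuffer(meta.encode(), dtype=np.uint8), **state)


def load_model(path) -> FRRN:
    data = np.load(Path(path))
    meta = json.loads(bytes(data["__meta__"]).decode())
    if meta.get("version") != _CKPT_VERSION:
        raise ValueError(f"unsupported checkpoint version {meta.get('version')}")
    cfg = FRRNConfig(
        n_classes=meta["n_classes"],
        n_pooling_stages=meta["n_pooling_stages"],
        n_unpooling_stages=meta["n_unpooling_stages"],
        base_channels=meta["base_channels"],
        input_channels=meta["input_channels"],
    )
    model = FRRN(cfg, seed=0)
    state = {k: data[k] for k in data.files if k != "__meta__"}
    model.load_state_dict(state)
    return model
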