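"""Four-class bone segmentation with a residual U-Net (18-layer encoder).

The network classifies every pixel of a normalized radiograph as femur,
fibula, tibia or background.  Its encoder is the standard 18-layer residual
topology (a 7x7 stem plus four stages of two basic blocks); the decoder
mirrors the encoder widths, upsampling and fusing each encoder stage through
skip connections, and ends in a 4-channel head with independent sigmoids
(multi-label formulation; no softmax).  Training minimizes per-channel
binary cross-entropy with Adam (lr 0.001, weight decay 1e-5), per-epoch
augmentation (rotation within +/-5 degrees, shifts within +/-10%, horizontal
flip, +/-10% contrast jitter) and early stopping once the validation loss
has not strictly improved for 10 epochs; the weights returned are those of
the best validation epoch.

The output channel order is (femur, fibula, tibia, background), mapping to
label classes (1, 3, 2, 0); the final label is the argmax over sigmoid
channels with ties broken toward the lowest class index.

Everything runs on CPU via the numpy autodiff in :mod:`kneejsw._nn`; a
50-layer bottleneck variant is provided for capacity comparisons only.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from . import _nn
from ._nn import Adam, Parameter, Tensor
from .imaging import LabelMask, Radiograph

__all__ = [
    "CHANNEL_CLASSES",
    "TrainingConfig",
    "ProbabilityMaps",
    "SegMetrics",
    "ResUNet",
    "build_resunet18",
    "build_resunet50",
    "parameter_count",
    "one_hot",
    "bce_loss",
    "train",
    "predict_probabilities",
    "predict_mask",
    "iou",
    "mean_iou",
    "evaluate",
    "overfitting_score",
    "save_checkpoint",
    "load_checkpoint",
]

# output channel -> label class: (femur, fibula, tibia, background)
CHANNEL_CLASSES = (1, 3, 2, 0)
_EPS = 1e-7


@dataclass
class TrainingConfig:
    """Optimization and augmentation settings."""

    learning_rate: float = 1e-3
    weight_decay: float = 1e-5
    early_stop_patience: int = 10
    max_epochs: int = 300
    batch_size: int = 4
    rotation_deg: float = 5.0      # +/- range, degrees
    shift_frac: float = 0.10       # +/- range, fraction of image side
    hflip: bool = True
    jitter: float = 0.10           # +/- multiplicative contrast amplitude
    seed: int = 0

    def __post_init__(self):
        if self.early_stop_patience < 1:
            raise ValueError("early_stop_patience must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.weight_decay < 0:
            raise ValueError("weight_decay must be non-negative")
        if self.batch_size < 1 or self.max_epochs < 1:
            raise ValueError("batch_size and max_epochs must be >= 1")


@dataclass
class ProbabilityMaps:
    """Per-channel sigmoid probabilities, shape (4, H, W), each in [0, 1].

    Channels are independent sigmoids and need not sum to one.
    """

    maps: np.ndarray
    channel_classes: tuple[int, ...] = CHANNEL_CLASSES

    def __post_init__(self):
        self.maps = np.asarray(self.maps, dtype=np.float32)
        if self.maps.ndim != 3 or self.maps.shape[0] != 4:
            raise ValueError(f"expected (4, H, W) maps, got {self.maps.shape}")


@dataclass
class SegMetrics:
    """Per-class and mean IoU plus the loss-based overfitting score."""

    per_class_iou: list[float]     # indexed by class id 0..3; NaN if absent
    mean_iou: float
    train_loss: float
    val_loss: float
    overfit_score: float


# ----------------------------------------------------------------- layers --

class _Conv:
    def __init__(self, rng, cin, cout, k, stride=1, padding=0, dilation=1, bias=False):
        fan_in = cin * k * k
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(cout, cin, k, k))
        self.w = Parameter(w.astype(np.float32))
        self.b = Parameter(np.zeros(cout, dtype=np.float32)) if bias else None
        self.stride, self.padding, self.dilation = stride, padding, dilation

    def __call__(self, x: Tensor) -> Tensor:
        return _nn.conv2d(x, self.w, self.b, stride=self.stride,
                          padding=self.padding, dilation=self.dilation)

    def parameters(self):
        return [self.w] + ([self.b] if self.b is not None else [])


class _BN:
    def __init__(self, channels):
        self.gamma = Parameter(np.ones(channels, dtype=np.float32))
        self.beta = Parameter(np.zeros(channels, dtype=np.float32))
        self.state = _nn.BatchNormState(channels)

    def __call__(self, x: Tensor, train: bool) -> Tensor:
        return _nn.batchnorm2d(x, self.gamma, self.beta, self.state, train)

    def parameters(self):
        return [self.gamma, self.beta]


class _BasicBlock:
    """Two 3x3 convolutions with an identity (or projected) shortcut."""

    def __init__(self, rng, cin, cout, stride=1, dilation=1):
        pad = dilation
        self.conv1 = _Conv(rng, cin, cout, 3, stride=stride, padding=pad,
                           dilation=dilation)
        self.bn1 = _BN(cout)
        self.conv2 = _Conv(rng, cout, cout, 3, padding=pad, dilation=dilation)
        self.bn2 = _BN(cout)
        self.down = None
        if stride != 1 or cin != cout:
            self.down = (_Conv(rng, cin, cout, 1, stride=stride), _BN(cout))

    def __call__(self, x: Tensor, train: bool) -> Tensor:
        out = _nn.relu(self.bn1(self.conv1(x), train))
        out = self.bn2(self.conv2(out), train)
        short = x if self.down is None else self.down[1](self.down[0](x), train)
        return _nn.relu(_nn.add(out, short))

    def parameters(self):
        ps = (self.conv1.parameters() + self.bn1.parameters()
              + self.conv2.parameters() + self.bn2.parameters())
        if self.down is not None:
            ps += self.down[0].parameters() + self.down[1].parameters()
        return ps


class _Bottleneck:
    """1x1 - 3x3 - 1x1 bottleneck block (50-layer variant), expansion 4."""

    def __init__(self, rng, cin, width, stride=1):
        cout = width * 4
        self.conv1, self.bn1 = _Conv(rng, cin, width, 1), _BN(width)
        self.conv2 = _Conv(rng, width, width, 3, stride=stride, padding=1)
        self.bn2 = _BN(width)
        self.conv3, self.bn3 = _Conv(rng, width, cout, 1), _BN(cout)
        self.down = None
        if stride != 1 or cin != cout:
            self.down = (_Conv(rng, cin, cout, 1, stride=stride), _BN(cout))

    def __call__(self, x: Tensor, train: bool) -> Tensor:
        out = _nn.relu(self.bn1(self.conv1(x), train))
        out = _nn.relu(self.bn2(self.conv2(out), train))
        out = self.bn3(self.conv3(out), train)
        short = x if self.down is None else self.down[1](self.down[0](x), train)
        return _nn.relu(_nn.add(out, short))

    def parameters(self):
        ps = (self.conv1.parameters() + self.bn1.parameters()
              + self.conv2.parameters() + self.bn2.parameters()
              + self.conv3.parameters() + self.bn3.parameters())
        if self.down is not None:
            ps += self.down[0].parameters() + self.down[1].parameters()
        return ps


class _DecoderStage:
    """Upsample, concatenate the encoder skip, fuse with a 3x3 convolution."""

    def __init__(self, rng, cin, cskip, cout):
        self.conv = _Conv(rng, cin + cskip, cout, 3, padding=1)
        self.bn = _BN(cout)

    def __call__(self, x: Tensor, skip: Tensor, train: bool) -> Tensor:
        up = _nn.upsample2x(x)
        return _nn.relu(self.bn(self.conv(_nn.concat(up, skip)), train))

    def parameters(self):
        return self.conv.parameters() + self.bn.parameters()


class ResUNet:
    """Residual encoder-decoder with skip connections and a 4-sigmoid head.

    ``depth`` selects the encoder: 18 (basic blocks, [2,2,2,2]) or 50
    (bottlenecks, [3,4,6,3]).  ``base_width`` is the stem channel count.
    ``dilated`` switches the deepest stage to dilation-2 (atrous) convolution
    (18-layer encoder only).  Inputs are (N, 1, H, W) with H = W divisible
    by 32.
    """

    def __init__(self, depth: int = 18, base_width: int = 64,
                 dilated: bool = False, seed: int = 0):
        if depth not in (18, 50):
            raise ValueError("depth must be 18 or 50")
        rng = np.random.default_rng(seed)
        b = base_width
        self.depth, self.base_width, self.dilated = depth, b, dilated

        self.stem = _Conv(rng, 1, b, 7, stride=2, padding=3)
        self.stem_bn = _BN(b)

        def stage_basic(cin, cout, n, stride, dilation=1):
            blocks = [_BasicBlock(rng, cin, cout, stride=stride, dilation=dilation)]
            blocks += [_BasicBlock(rng, cout, cout, dilation=dilation)
                       for _ in range(n - 1)]
            return blocks

        def stage_bottle(cin, width, n, stride):
            blocks = [_Bottleneck(rng, cin, width, stride=stride)]
            blocks += [_Bottleneck(rng, width * 4, width) for _ in range(n - 1)]
            return blocks

        if depth == 18:
            self.layer1 = stage_basic(b, b, 2, 1)
            self.layer2 = stage_basic(b, 2 * b, 2, 2)
            self.layer3 = stage_basic(2 * b, 4 * b, 2, 2)
            self.layer4 = stage_basic(4 * b, 8 * b, 2, 2,
                                      dilation=2 if dilated else 1)
            widths = (b, b, 2 * b, 4 * b, 8 * b)   # skip0..skip3, bottom
        else:
            self.layer1 = stage_bottle(b, b, 3, 1)
            self.layer2 = stage_bottle(4 * b, 2 * b, 4, 2)
            self.layer3 = stage_bottle(8 * b, 4 * b, 6, 2)
            self.layer4 = stage_bottle(16 * b, 8 * b, 3, 2)
            widths = (b, 4 * b, 8 * b, 16 * b, 32 * b)

        w0, w1, w2, w3, w4 = widths
        self.dec3 = _DecoderStage(rng, w4, w3, w3)
        self.dec2 = _DecoderStage(rng, w3, w2, w2)
        self.dec1 = _DecoderStage(rng, w2, w1, w1)
        self.dec0 = _DecoderStage(rng, w1, w0, max(w0 // 2, 8))
        head_mid = max(w0 // 4, 8)
        self.head_conv = _Conv(rng, max(w0 // 2, 8), head_mid, 3, padding=1)
        self.head_bn = _BN(head_mid)
        self.head_out = _Conv(rng, head_mid, 4, 1, bias=True)

    def parameters(self) -> list[Parameter]:
        ps = self.stem.parameters() + self.stem_bn.parameters()
        for layer in (self.layer1, self.layer2, self.layer3, self.layer4):
            for block in layer:
                ps += block.parameters()
        for stage in (self.dec3, self.dec2, self.dec1, self.dec0):
            ps += stage.parameters()
        ps += self.head_conv.parameters() + self.head_bn.parameters()
        ps += self.head_out.parameters()
        return ps

    def _bn_states(self) -> list[_nn.BatchNormState]:
        states = [self.stem_bn.state]
        for layer in (self.layer1, self.layer2, self.layer3, self.layer4):
            for block in layer:
                states += [block.bn1.state, block.bn2.state]
                if getattr(block, "bn3", None) is not None:
                    states.append(block.bn3.state)
                if block.down is not None:
                    states.append(block.down[1].state)
        for stage in (self.dec3, self.dec2, self.dec1, self.dec0):
            states.append(stage.bn.state)
        states.append(self.head_bn.state)
        return states

    def forward_logits(self, x: np.ndarray, train: bool = False) -> Tensor:
        """Logits tensor of shape (N, 4, H, W); requires side divisible by 32."""
        x = np.asarray(x, dtype=np.float32)
        if x.ndim == 2:
            x = x[None, None]
        elif x.ndim == 3:
            x = x[:, None]
        N, C, H, W = x.shape
        if C != 1:
            raise ValueError(f"expected 1-channel input, got {C}")
        if H != W or H % 32:
            raise ValueError(f"input must be square with side divisible by 32, got {H}x{W}")
        t = Tensor(x)
        s0 = _nn.relu(self.stem_bn(self.stem(t), train))           # 1/2, w0
        h = _nn.maxpool2x2(s0)                                     # 1/4
        for blk in self.layer1:
            h = blk(h, train)
        s1 = h                                                     # 1/4
        for blk in self.layer2:
            h = blk(h, train)
        s2 = h                                                     # 1/8
        for blk in self.layer3:
            h = blk(h, train)
        s3 = h                                                     # 1/16
        for blk in self.layer4:
            h = blk(h, train)                                      # 1/32
        h = self.dec3(h, s3, train)
        h = self.dec2(h, s2, train)
        h = self.dec1(h, s1, train)
        h = self.dec0(h, s0, train)
        h = _nn.upsample2x(h)                                      # full res
        h = _nn.relu(self.head_bn(self.head_conv(h), train))
        return self.head_out(h)

    # -- checkpoint state ---------------------------------------------------

    def get_state(self) -> dict:
        arrays = {f"p{i}": p.data.copy() for i, p in enumerate(self.parameters())}
        for i, st in enumerate(self._bn_states()):
            arrays[f"rm{i}"] = st.running_mean.copy()
            arrays[f"rv{i}"] = st.running_var.copy()
        return arrays

    def set_state(self, arrays: dict) -> None:
        for i, p in enumerate(self.parameters()):
            p.data = np.asarray(arrays[f"p{i}"], dtype=np.float32).copy()
        for i, st in enumerate(self._bn_states()):
            st.running_mean = np.asarray(arrays[f"rm{i}"], dtype=np.float32).copy()
            st.running_var = np.asarray(arrays[f"rv{i}"], dtype=np.float32).copy()


def build_resunet18(base_width: int = 64, dilated: bool = False, seed: int = 0) -> ResUNet:
    """The default segmentation backbone (18-layer residual encoder)."""
    return ResUNet(depth=18, base_width=base_width, dilated=dilated, seed=seed)


def build_resunet50(base_width: int = 64, seed: int = 0) -> ResUNet:
    """The heavier 50-layer bottleneck variant, for capacity comparison."""
    return ResUNet(depth=50, base_width=base_width, seed=seed)


def parameter_count(model: ResUNet) -> int:
    return int(sum(p.data.size for p in model.parameters()))


# ---------------------------------------------------------------- training --

def one_hot(mask: LabelMask | np.ndarray) -> np.ndarray:
    """(4, H, W) float32 one-hot target in the network's channel order."""
    labels = mask.labels if isinstance(mask, LabelMask) else np.asarray(mask)
    return np.stack([(labels == cls) for cls in CHANNEL_CLASSES]).astype(np.float32)


def bce_loss(pred, target) -> float:
    """Mean binary cross-entropy over all pixels and channels.

    ``pred`` holds probabilities in [0, 1] (clipped to [1e-7, 1-1e-7]);
    ``target`` is the matching 0/1 one-hot array.
    """
    p = pred.maps if isinstance(pred, ProbabilityMaps) else np.asarray(pred, dtype=np.float64)
    y = np.asarray(target, dtype=np.float64)
    if p.shape != y.shape:
        raise ValueError(f"shape mismatch: pred {p.shape} vs target {y.shape}")
    p = np.clip(p, _EPS, 1.0 - _EPS)
    return float(np.mean(-(y * np.log(p) + (1.0 - y) * np.log(1.0 - p))))


def _augment(img: np.ndarray, target: np.ndarray, cfg: TrainingConfig, rng):
    """Seeded per-sample augmentation; the target moves with the image."""
    if cfg.hflip and rng.random() < 0.5:
        img = img[:, ::-1]
        target = target[:, :, ::-1]
    angle = rng.uniform(-cfg.rotation_deg, cfg.rotation_deg)
    if abs(angle) > 1e-6:
        img = ndimage.rotate(img, angle, reshape=False, order=1, mode="nearest")
        target = np.stack([
            ndimage.rotate(ch, angle, reshape=False, order=0, mode="nearest")
            for ch in target])
    H, W = img.shape
    dr = rng.uniform(-cfg.shift_frac, cfg.shift_frac) * H
    dc = rng.uniform(-cfg.shift_frac, cfg.shift_frac) * W
    if abs(dr) > 0.5 or abs(dc) > 0.5:
        img = ndimage.shift(img, (dr, dc), order=1, mode="nearest")
        target = np.stack([
            ndimage.shift(ch, (dr, dc), order=0, mode="nearest") for ch in target])
    if cfg.jitter > 0:
        gain = rng.uniform(1 - cfg.jitter, 1 + cfg.jitter)
        contrast = rng.uniform(1 - cfg.jitter, 1 + cfg.jitter)
        mean = img.mean()
        img = np.clip((mean + (img - mean) * contrast) * gain, 0.0, 1.0)
    return np.ascontiguousarray(img), np.ascontiguousarray(target)


def _as_pair(item) -> tuple[np.ndarray, np.ndarray]:
    img, mask = item
    pixels = img.pixels if isinstance(img, Radiograph) else np.asarray(img)
    return pixels.astype(np.float32), one_hot(mask)


def _dataset_loss(model: ResUNet, pairs) -> float:
    total, npx = 0.0, 0
    for img, target in pairs:
        logits = model.forward_logits(img, train=False)
        loss = _nn.sigmoid_bce(logits, target[None])
        total += float(loss.data) * target.size
        npx += target.size
    return total / npx


def train(model: ResUNet, train_set, val_set, cfg: TrainingConfig,
          on_epoch_end=None):
    """Optimize the network with Adam, augmentation and early stopping.

    ``train_set`` / ``val_set`` are sequences of (radiograph, mask) pairs
    (either package containers or plain arrays).  Stops at ``max_epochs`` or
    when validation loss has not strictly decreased for
    ``early_stop_patience`` epochs, and restores the best-validation-loss
    weights.  ``on_epoch_end(epoch, history, model)`` may return True to
    stop early (e.g. when a target metric is reached).  Returns
    ``(model, history)`` with per-epoch loss curves and the best epoch.
    """
    if len(train_set) == 0 or len(val_set) == 0:
        raise ValueError("train and validation sets must be non-empty")
    rng = np.random.default_rng(cfg.seed)
    train_pairs = [_as_pair(item) for item in train_set]
    val_pairs = [_as_pair(item) for item in val_set]
    opt = Adam(model.parameters(), lr=cfg.learning_rate,
               weight_decay=cfg.weight_decay)
    history = {"train_loss": [], "val_loss": [], "best_epoch": -1}
    best_val = np.inf
    best_state = None
    stale = 0
    for epoch in range(cfg.max_epochs):
        order = rng.permutation(len(train_pairs))
        epoch_loss, seen = 0.0, 0
        for start in range(0, len(order), cfg.batch_size):
            batch = order[start: start + cfg.batch_size]
            imgs, targets = zip(*(
                _augment(train_pairs[i][0], train_pairs[i][1], cfg, rng)
                for i in batch))
            x = np.stack(imgs)
            y = np.stack(targets)
            logits = model.forward_logits(x, train=True)
            loss = _nn.sigmoid_bce(logits, y)
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch}: {float(loss.data)}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_loss += float(loss.data) * len(batch)
            seen += len(batch)
        val_loss = _dataset_loss(model, val_pairs)
        history["train_loss"].append(epoch_loss / seen)
        history["val_loss"].append(val_loss)
        if val_loss < best_val:
            best_val = val_loss
            best_state = model.get_state()
            history["best_epoch"] = epoch
            stale = 0
        else:
            stale += 1
        if on_epoch_end is not None and on_epoch_end(epoch, history, model):
            break
        if stale >= cfg.early_stop_patience:
            break
    if best_state is not None:
        model.set_state(best_state)
    return model, history


# --------------------------------------------------------------- inference --

def predict_probabilities(model: ResUNet, r: Radiograph | np.ndarray) -> ProbabilityMaps:
    pixels = r.pixels if isinstance(r, Radiograph) else np.asarray(r)
    logits = model.forward_logits(pixels.astype(np.float32), train=False)
    probs = 1.0 / (1.0 + np.exp(-logits.data.astype(np.float64)))
    return ProbabilityMaps(maps=probs[0])


def labels_from_probabilities(maps: ProbabilityMaps) -> LabelMask:
    """Argmax over sigmoid channels; ties go to the lowest class index."""
    class_order = np.argsort(CHANNEL_CLASSES)          # channels by class id
    stacked = maps.maps[class_order]                   # (4, H, W), class asc
    winner = stacked.argmax(axis=0)                    # first max = lowest class
    classes = np.array(CHANNEL_CLASSES)[class_order]
    return LabelMask(labels=classes[winner].astype(np.uint8))


def predict_mask(model: ResUNet, r: Radiograph | np.ndarray) -> LabelMask:
    return labels_from_probabilities(predict_probabilities(model, r))


# ----------------------------------------------------------------- metrics --

def iou(pred: LabelMask, truth: LabelMask, class_id: int) -> float:
    """Intersection over union for one class; NaN if absent from both."""
    p = (pred.labels if isinstance(pred, LabelMask) else np.asarray(pred)) == class_id
    t = (truth.labels if isinstance(truth, LabelMask) else np.asarray(truth)) == class_id
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {t.shape}")
    union = np.logical_or(p, t).sum()
    if union == 0:
        return float("nan")
    return float(np.logical_and(p, t).sum() / union)


def mean_iou(pred: LabelMask, truth: LabelMask) -> float:
    """Mean IoU over the classes present in either raster."""
    vals = [iou(pred, truth, c) for c in range(4)]
    return float(np.nanmean(vals))


def overfitting_score(val_loss: float, train_loss: float) -> float:
    """Relative generalization gap, (val - train) / val."""
    if val_loss <= 0:
        raise ValueError("val_loss must be positive")
    return (val_loss - train_loss) / val_loss


def evaluate(model: ResUNet, dataset, train_loss: float | None = None,
             val_loss: float | None = None) -> SegMetrics:
    """Aggregate IoU over a dataset (pixel counts pooled across images)."""
    inter = np.zeros(4)
    union = np.zeros(4)
    pairs = [_as_pair(item) for item in dataset]
    for img, target in pairs:
        pred = predict_mask(model, img).labels
        truth_labels = np.zeros(pred.shape, dtype=np.uint8)
        for ch, cls in enumerate(CHANNEL_CLASSES):
            truth_labels[target[ch] > 0.5] = cls
        for c in range(4):
            p, t = pred == c, truth_labels == c
            inter[c] += np.logical_and(p, t).sum()
            union[c] += np.logical_or(p, t).sum()
    per_class = [float(inter[c] / union[c]) if union[c] else float("nan")
                 for c in range(4)]
    if val_loss is None:
        val_loss = float("nan")
    if train_loss is None:
        train_loss = float("nan")
    score = overfitting_score(val_loss, train_loss) if val_loss and val_loss > 0 \
        else float("nan")
    return SegMetrics(per_class_iou=per_class,
                      mean_iou=float(np.nanmean(per_class)),
                      train_loss=train_loss, val_loss=val_loss,
                      overfit_score=score)


# -------------------------------------------------------------- checkpoint --

def save_checkpoint(model: ResUNet, path, history: dict | None = None) -> None:
    """Native weights (.npz) plus a JSON sidecar with config and history."""
    path = Path(path)
    np.savez_compressed(path, **model.get_state())
    sidecar = {
        "depth": model.depth,
        "base_width": model.base_width,
        "dilated": model.dilated,
        "history": history or {},
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))


def load_checkpoint(path) -> tuple[ResUNet, dict]:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    model = ResUNet(depth=sidecar["depth"], base_width=sidecar["base_width"],
                    dilated=sidecar["dilated"])
    with np.load(path) as data:
        model.set_state({k: data[k] for k in data.files})
    return model, sidecar.get("history", {})
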