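"""Residual tile classifier and its training protocol.

The network is a deliberately small ResNet-style CNN for two-class
histology tiles: a 7×7/32 stride-2 stem, 3×3 max pool (stride 2), two
residual blocks of 3×3×32 convolutions, three residual blocks of 3×3×64
convolutions (the first at stride 2), then global max pooling, a 16-unit
fully connected layer and a 2-way softmax.  Swish is used at every
activation site.  With 256×256 input the stem output is 128×128, the
first residual stage sees 64×64 and the second stage produces 32×32
feature maps.

Training uses Adam (lr 2e-4, batch 32), L2 weight penalty, per-epoch
shuffling, inverse-frequency class weights, model checkpointing on
validation loss and early stopping with a configurable patience.  Inputs
are scaled to [0, 1] before entering the network.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.transform import rotate as _sk_rotate
from skimage.color import rgb2hsv, hsv2rgb

from . import nn

LAYERS = ("conv3", "fc16", "logits")


class TrainingDivergence(RuntimeError):
    def __init__(self, epoch: int) -> None:
        super().__init__(f"non-finite loss at epoch {epoch}")
        self.epoch = epoch


@dataclass
class ModelSpec:
    input_size: int = 96
    l2: float = 1e-4


@dataclass
class AugmentConfig:
    flip: bool = True
    rotate: bool = True
    hsv_jitter: bool = False
    hue_delta: float = 0.05
    sat_delta: float = 0.2
    val_delta: float = 0.2
    cutout: bool = True
    cutout_prob: float = 0.5
    cutout_frac: tuple[float, float] = (0.1, 0.4)
    cutout_fill: int = 127


@dataclass
class TrainConfig:
    learning_rate: float = 2e-4
    batch_size: int = 32
    max_epochs: int = 100
    early_stop: bool = True
    patience: int = 50
    class_weighting: bool = True
    seed: int = 0
    augment: AugmentConfig = field(default_factory=AugmentConfig)
    # optional convergence stop: end training once validation loss falls
    # below this floor (0 disables); useful when a shortcut cue saturates
    # the model long before the epoch budget
    stop_val_loss: float = 0.0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.early_stop and self.patience < 1:
            raise ValueError("patience must be >= 1 when early stopping is on")


@dataclass
class Metrics:
    balanced_accuracy: float
    auc: float
    f1: float
    precision: float
    recall: float
    confusion: tuple[int, int, int, int]  # TP, FP, FN, TN
    auc_defined: bool = True

    def as_dict(self) -> dict:
        return {
            "balanced_accuracy": self.balanced_accuracy,
            "auc": self.auc,
            "f1": self.f1,
            "precision": self.precision,
            "recall": self.recall,
            "confusion": list(self.confusion),
            "auc_defined": self.auc_defined,
        }


class TileCNN:
    """The residual classifier with named access points for explanations.

    Named layers: ``conv3`` (output of the last stage-3 residual block,
    the deepest spatial feature map), ``fc16`` (the 16-d fully connected
    activation after Swish), ``logits`` (pre-softmax scores).
    """

    def __init__(self, spec: ModelSpec, seed: int = 0, dtype=np.float32) -> None:
        if spec.input_size % 8 != 0:
            raise ValueError("input size must be divisible by 8")
        self.spec = spec
        self.dtype = dtype
        rng = np.random.default_rng(seed)
        self.conv1 = nn.Conv2D(3, 32, 7, stride=2, pad=3, rng=rng, dtype=dtype)
        self.b2a = nn.ResidualBlock(32, 32, rng=rng, dtype=dtype)
        self.b2b = nn.ResidualBlock(32, 32, rng=rng, dtype=dtype)
        self.b3a = nn.ResidualBlock(32, 64, stride=2, rng=rng, dtype=dtype)
        self.b3b = nn.ResidualBlock(64, 64, rng=rng, dtype=dtype)
        self.b3c = nn.ResidualBlock(64, 64, rng=rng, dtype=dtype)
        self.fc16 = nn.Dense(64, 16, rng=rng, dtype=dtype)
        self.out = nn.Dense(16, 2, rng=rng, dtype=dtype)
        # (layer, tap name after this layer)
        self._seq: list[tuple[nn.Layer, str | None]] = [
            (self.conv1, None), (nn.Swish(), None),
            (nn.MaxPool2D(3, 2, 1), None),
            (self.b2a, None), (self.b2b, None),
            (self.b3a, None), (self.b3b, None), (self.b3c, "conv3"),
            (nn.GlobalMaxPool(), None),
            (self.fc16, None), (nn.Swish(), "fc16"),
            (self.out, "logits"),
        ]

    # -- parameters ---------------------------------------------------
    def param_layers(self) -> list[nn.Layer]:
        leaves: list[nn.Layer] = [self.conv1]
        for blk in (self.b2a, self.b2b, self.b3a, self.b3b, self.b3c):
            leaves.extend(blk.sublayers)
        leaves.extend([self.fc16, self.out])
        return leaves

    def get_weights(self) -> list[dict[str, np.ndarray]]:
        return [copy.deepcopy(l.params) for l in self.param_layers()]

    def set_weights(self, weights: list[dict[str, np.ndarray]]) -> None:
        for layer, p in zip(self.param_layers(), weights, strict=True):
            layer.params = copy.deepcopy(p)

    def save(self, path: str) -> None:
        arrays = {}
        for i, layer in enumerate(self.param_layers()):
            for name, p in layer.params.items():
                arrays[f"{i}:{name}"] = p
        np.savez(path, input_size=self.spec.input_size, l2=self.spec.l2,
                 **arrays)

    @classmethod
    def load(cls, path: str) -> "TileCNN":
        data = np.load(path)
        model = cls(ModelSpec(int(data["input_size"]), float(data["l2"])))
        for i, layer in enumerate(model.param_layers()):
            for name in layer.params:
                layer.params[name] = data[f"{i}:{name}"].astype(model.dtype)
        return model

    # -- forward / backward -------------------------------------------
    def forward(self, x: np.ndarray) -> np.ndarray:
        """x: (N,H,W,3) float in [0,1].  Returns logits; caches taps."""
        a = np.asarray(x, dtype=self.dtype)
        self._taps: dict[str, np.ndarray] = {}
        for layer, tap in self._seq:
            a = layer.forward(a)
            if tap is not None:
                self._taps[tap] = a
        return a

    def predict_proba(self, x: np.ndarray, batch: int = 64) -> np.ndarray:
        outs = [nn.softmax(self.forward(x[i:i + batch]))
                for i in range(0, len(x), batch)]
        return np.concatenate(outs, axis=0)

    def backward_to(self, glogits: np.ndarray, layer: str | None = None,
                    guided: bool = False) -> np.ndarray:
        """Backprop from the logits; return the gradient at a named tap,
        or at the input when ``layer`` is None."""
        if layer is not None and layer not in LAYERS:
            raise KeyError(f"unknown layer {layer!r}")
        g = glogits
        for lyr, tap in reversed(self._seq):
            if layer is not None and tap == layer and tap != "logits":
                return g
            g = lyr.backward(g, guided=guided)
            if layer == "logits" and tap == "logits":
                # gradient w.r.t. logits is the seed itself
                return glogits
        return g


def build_model(spec: ModelSpec | None = None, seed: int = 0) -> TileCNN:
    return TileCNN(spec or ModelSpec(), seed=seed)


# -- augmentation ------------------------------------------------------

def augment(img: np.ndarray, rng: np.random.Generator,
            cfg: AugmentConfig | None = None) -> np.ndarray:
    """Stochastic training augmentation on a uint8 RGB tile.

    Horizontal flip (p=0.5), rotation by a uniform angle in [0°, 360°),
    optional HSV jitter, and random cutout: one rectangle filled with a
    flat grey (127 on all channels), which desensitises the network to the
    grey canvases used for concept patches.
    """
    cfg = cfg or AugmentConfig()
    out = img
    if cfg.flip and rng.random() < 0.5:
        out = out[:, ::-1, :]
    if cfg.rotate:
        angle = rng.uniform(0.0, 360.0)
        rot = _sk_rotate(out.astype(np.float32) / 255.0, angle,
                         mode="reflect", order=1)
        out = np.clip(rot * 255.0, 0, 255).astype(np.uint8)
    if cfg.hsv_jitter:
        hsv = rgb2hsv(out)
        hsv[..., 0] = (hsv[..., 0] + rng.uniform(-cfg.hue_delta, cfg.hue_delta)) % 1.0
        hsv[..., 1] = np.clip(hsv[..., 1] * (1 + rng.uniform(-cfg.sat_delta, cfg.sat_delta)), 0, 1)
        hsv[..., 2] = np.clip(hsv[..., 2] * (1 + rng.uniform(-cfg.val_delta, cfg.val_delta)), 0, 1)
        out = np.clip(hsv2rgb(hsv) * 255.0, 0, 255).astype(np.uint8)
    if cfg.cutout and rng.random() < cfg.cutout_prob:
        h, w = out.shape[:2]
        side = int(round(rng.uniform(*cfg.cutout_frac) * h))
        side = max(side, 1)
        r = rng.integers(0, max(h - side, 0) + 1)
        c = rng.integers(0, max(w - side, 0) + 1)
        out = out.copy()
        out[r:r + side, c:c + side, :] = cfg.cutout_fill
    return out


# -- training ----------------------------------------------------------

def class_weights(y: np.ndarray) -> np.ndarray:
    """Per-class weights inversely proportional to class frequency."""
    counts = np.bincount(y, minlength=2).astype(float)
    n = counts.sum()
    with np.errstate(divide="ignore"):
        w = n / (2.0 * counts)
    w[~np.isfinite(w)] = 0.0
    return w


def train(model: TileCNN, x_train: np.ndarray, y_train: np.ndarray,
          x_val: np.ndarray, y_val: np.ndarray, cfg: TrainConfig
          ) -> pd.DataFrame:
    """Fit in place; restore the checkpoint with the lowest validation
    loss; return the per-epoch history."""
    if len(x_train) == 0 or len(x_val) == 0:
        raise ValueError("train and validation sets must be non-empty")
    rng = np.random.default_rng(cfg.seed)
    opt = nn.Adam(model.param_layers(), lr=cfg.learning_rate, l2=model.spec.l2)
    cw = class_weights(y_train) if cfg.class_weighting else np.ones(2)
    xv = x_val.astype(model.dtype) / 255.0
    best_loss, best_weights, best_epoch = np.inf, None, -1
    rows = []
    n = len(x_train)
    model.conv1.skip_input_grad = True  # input gradients unused while fitting
    for epoch in range(cfg.max_epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            xb = np.stack([augment(x_train[i], rng, cfg.augment) for i in idx])
            xb = xb.astype(model.dtype) / 255.0
            yb = y_train[idx]
            logits = model.forward(xb)
            loss, glog = nn.softmax_cross_entropy(logits, yb, cw[yb].astype(model.dtype))
            if not np.isfinite(loss):
                raise TrainingDivergence(epoch)
            losses.append(loss)
            model.backward_to(glog)
            opt.step()
        val_logits = np.concatenate(
            [model.forward(xv[i:i + 64]) for i in range(0, len(xv), 64)])
        val_loss, _ = nn.softmax_cross_entropy(val_logits, y_val)
        pred = val_logits.argmax(axis=1)
        val_bacc = balanced_accuracy(y_val, pred)
        rows.append({"epoch": epoch, "train_loss": float(np.mean(losses)),
                     "val_loss": val_loss, "val_bacc": val_bacc})
        if val_loss < best_loss:
            best_loss, best_weights, best_epoch = val_loss, model.get_weights(), epoch
        elif cfg.early_stop and epoch - best_epoch >= cfg.patience:
            break
        if cfg.stop_val_loss and val_loss <= cfg.stop_val_loss:
            break
    model.conv1.skip_input_grad = False
    if best_weights is not None:
        model.set_weights(best_weights)
    return pd.DataFrame(rows)


# -- evaluation --------------------------------------------------------

def balanced_accuracy(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    rec = tp / (tp + fn) if tp + fn else 0.0
    spec = tn / (tn + fp) if tn + fp else 0.0
    return 0.5 * (rec + spec)


def evaluate(model: TileCNN, x: np.ndarray, y: np.ndarray) -> Metrics:
    """Test-split metrics from argmax predictions and the positive-class
    probability (trapezoidal ROC for the AUC)."""
    if len(x) == 0:
        raise ValueError("empty evaluation set")
    xs = x.astype(model.dtype) / 255.0 if x.dtype == np.uint8 else x
    proba = model.predict_proba(xs)[:, 1]
    pred = (proba >= 0.5).astype(int)
    tp = int(np.sum((y == 1) & (pred == 1)))
    fp = int(np.sum((y == 0) & (pred == 1)))
    fn = int(np.sum((y == 1) & (pred == 0)))
    tn = int(np.sum((y == 0) & (pred == 0)))
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    specificity = tn / (tn + fp) if tn + fp else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    auc_defined = len(np.unique(y)) == 2
    auc = roc_auc(y, proba) if auc_defined else float("nan")
    return Metrics(0.5 * (recall + specificity), auc, f1, precision, recall,
                   (tp, fp, fn, tn), auc_defined)


def roc_auc(y_true: np.ndarray, score: np.ndarray) -> float:
    """Trapezoidal area under the ROC curve."""
    order = np.argsort(-score, kind="stable")
    y = np.asarray(y_true)[order]
    s = np.asarray(score)[order]
    # thresholds at distinct scores
    distinct = np.r_[np.nonzero(np.diff(s))[0], len(s) - 1]
    tps = np.cumsum(y == 1)[distinct]
    fps = np.cumsum(y == 0)[distinct]
    p, n = tps[-1], fps[-1]
    tpr = np.r_[0.0, tps / p]
    fpr = np.r_[0.0, fps / n]
    return float(np.trapezoid(tpr, fpr))


# -- explanation hooks -------------------------------------------------

def activations(model: TileCNN, layer: str, batch: np.ndarray,
                chunk: int = 64) -> np.ndarray:
    """Activation rows (or feature maps for conv taps) for a batch of
    [0,1]-scaled inputs."""
    if layer not in LAYERS:
        raise KeyError(f"unknown layer {layer!r}")
    outs = []
    for i in range(0, len(batch), chunk):
        model.forward(batch[i:i + chunk])
        outs.append(model._taps[layer].copy())
    return np.concatenate(outs, axis=0)


def class_gradient(model: TileCNN, layer: str, class_k: int,
                   batch: np.ndarray, chunk: int = 64,
                   target: str = "logit") -> np.ndarray:
    """Gradient of a class-k score w.r.t. the named layer's activations,
    one row (or map) per input.

    ``target='logit'`` differentiates the class-k pre-softmax logit;
    ``target='logodds'`` differentiates the log-odds of class k
    (logit_k minus the other logit) — the direction that actually
    increases the softmax prediction of class k in a 2-class head.
    """
    if layer not in LAYERS:
        raise KeyError(f"unknown layer {layer!r}")
    if target not in ("logit", "logodds"):
        raise ValueError(f"unknown gradient target {target!r}")
    outs = []
    for i in range(0, len(batch), chunk):
        xb = batch[i:i + chunk]
        logits = model.forward(xb)
        seed = np.zeros_like(logits)
        seed[:, class_k] = 1.0
        if target == "logodds":
            seed[:, 1 - class_k] = -1.0
        outs.append(model.backward_to(seed, layer=layer).copy())
    return np.concatenate(outs, axis=0)


def input_gradient(model: TileCNN, class_k: int, batch: np.ndarray,
                   guided: bool = False) -> np.ndarray:
    """Gradient of the class-k logit w.r.t. the input pixels; with
    ``guided=True`` applies the guided-backpropagation gating rule at
    every activation site."""
    model.conv1.skip_input_grad = False
    logits = model.forward(batch)
    seed = np.zeros_like(logits)
    seed[:, class_k] = 1.0
    return model.backward_to(seed, layer=None, guided=guided)
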