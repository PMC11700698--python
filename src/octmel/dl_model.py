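"""CNN classifier with a temporal ranking ("relative") loss.

The network maps a prepared B-scan X (H x W x 3, values in [0, 1]) to a single
logit; the sigmoid of the logit is the melanoma probability score in [0, 1].
Training minimizes

    Loss = w_bce * BCE(labels, scores) + w_rel * LossR(pairs),      w = 1 : 1

where LossR is the relative loss over temporal pairs (X1 earlier, X2 later,
same subject, interval >= 2 weeks):

    LossR = (1/N) * sum_i ReLU(Yhat1_i - Yhat2_i)

i.e. a hinge penalty whenever the predicted malignancy score *decreases* over
time for the same lesion.  Optimization is Adam; early stopping monitors
validation accuracy at threshold 0.5 with a patience of five epochs and keeps
the best-accuracy checkpoint (ties keep the earlier epoch).

Layers (convolution via im2col, max-pooling, dense) and backpropagation are
implemented directly on NumPy arrays.  Two backbones are available: the full
VGG16 topology (13 conv layers + 3 FC, final output dimension 1) and a
``tiny_vgg`` desk-scale variant (two conv/pool blocks) that accepts reduced
input sizes; ``tiny_vgg`` is the default and carries all experiments here.
ImageNet-pretrained VGG16 weights are not bundled; ``pretrained=True``
requires an external weights file.
"""

from __future__ import annotations

import copy
import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .io_prep import ImageDataset


class ConfigError(ValueError):
    pass


class SubjectLeakageError(ValueError):
    """A subject id appears on both sides of the train/test wall."""


# ----------------------------------------------------------------------------
# layers
# ----------------------------------------------------------------------------

class Layer:
    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self) -> None:
        self.params, self.grads = [], []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, gy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv2D(Layer):
    """3x3 same-padded convolution, NHWC layout, He-normal init."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator,
                 ksize: int = 3) -> None:
        super().__init__()
        self.ksize = ksize
        scale = np.sqrt(2.0 / (ksize * ksize * c_in))
        w = rng.normal(0.0, scale, size=(ksize, ksize, c_in, c_out)).astype(np.float32)
        b = np.zeros(c_out, dtype=np.float32)
        self.params = [w, b]
        self.grads = [np.zeros_like(w), np.zeros_like(b)]

    @staticmethod
    def _windows(x: np.ndarray, k: int) -> np.ndarray:
        pad = k // 2
        xp = np.pad(x, ((0, 0), (pad, pad), (pad, pad), (0, 0)))
        win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(1, 2))
        return win  # (N, H, W, C, k, k)

    def forward(self, x: np.ndarray) -> np.ndarray:
        w, b = self.params
        k = self.ksize
        n, h, wd, c = x.shape
        win = self._windows(x, k)
        self._cols = win.reshape(n * h * wd, c * k * k)
        wmat = w.transpose(2, 0, 1, 3).reshape(c * k * k, -1)  # (c*k*k, c_out)
        y = self._cols @ wmat + b
        self._xshape = x.shape
        return y.reshape(n, h, wd, -1)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        w, _ = self.params
        k = self.ksize
        n, h, wd, c = self._xshape
        c_out = w.shape[3]
        gmat = gy.reshape(n * h * wd, c_out)
        gw = (self._cols.T @ gmat).reshape(c, k, k, c_out).transpose(1, 2, 0, 3)
        self.grads[0] += gw
        self.grads[1] += gmat.sum(axis=0)
        # grad wrt input: correlate gy with the spatially flipped, c/o-swapped kernel
        wt = w[::-1, ::-1].transpose(0, 1, 3, 2)  # (k, k, c_out, c_in)
        gwin = self._windows(gy, k).reshape(n * h * wd, c_out * k * k)
        wtmat = wt.transpose(2, 0, 1, 3).reshape(c_out * k * k, c)
        gx = (gwin @ wtmat).reshape(n, h, wd, c)
        return gx


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, gy: np.ndarray) -> np.ndarray:
        return gy * self._mask


class MaxPool2D(Layer):
    """Non-overlapping max pooling; spatial dims must be divisible by k."""

    def __init__(self, k: int) -> None:
        super().__init__()
        self.k = k

    def forward(self, x: np.ndarray) -> np.ndarray:
        k = self.k
        n, h, w, c = x.shape
        if h % k or w % k:
            raise ValueError(f"spatial dims {h}x{w} not divisible by pool {k}")
        xr = x.reshape(n, h // k, k, w // k, k, c)
        xr = xr.transpose(0, 1, 3, 5, 2, 4).reshape(n, h // k, w // k, c, k * k)
        self._arg = xr.argmax(axis=4)
        self._xshape = x.shape
        return np.take_along_axis(xr, self._arg[..., None], axis=4)[..., 0]

    def backward(self, gy: np.ndarray) -> np.ndarray:
        k = self.k
        n, h, w, c = self._xshape
        gxr = np.zeros((n, h // k, w // k, c, k * k), dtype=gy.dtype)
        np.put_along_axis(gxr, self._arg[..., None], gy[..., None], axis=4)
        gx = gxr.reshape(n, h // k, w // k, c, k, k).transpose(0, 1, 4, 2, 5, 3)
        return gx.reshape(n, h, w, c)


class Flatten(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._xshape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        return gy.reshape(self._xshape)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator) -> None:
        super().__init__()
        scale = np.sqrt(2.0 / n_in)
        w = rng.normal(0.0, scale, size=(n_in, n_out)).astype(np.float32)
        b = np.zeros(n_out, dtype=np.float32)
        self.params = [w, b]
        self.grads = [np.zeros_like(w), np.zeros_like(b)]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        w, b = self.params
        return x @ w + b

    def backward(self, gy: np.ndarray) -> np.ndarray:
        w, _ = self.params
        self.grads[0] += self._x.T @ gy
        self.grads[1] += gy.sum(axis=0)
        return gy @ w.T


# ----------------------------------------------------------------------------
# model
# ----------------------------------------------------------------------------

@dataclass
class TrainConfig:
    backbone: str = "tiny_vgg"
    pretrained: bool = False
    weights_path: str | None = None
    input_size: int = 512
    conv_channels: tuple[int, ...] = (8, 16)  # tiny_vgg blocks
    pool: int = 4
    dense_units: int = 64
    learning_rate: float = 1e-4
    batch_size: int = 16
    loss_weight_bce: float = 1.0
    loss_weight_relative: float = 1.0
    patience: int = 5
    max_epochs: int = 50
    interval_min_weeks: int = 2
    pairs_per_batch: int = 8
    pair_groups: tuple[str, ...] = ("induced",)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.loss_weight_bce < 0 or self.loss_weight_relative < 0:
            raise ConfigError("loss weights must be >= 0")
        if self.patience < 1:
            raise ConfigError("patience must be >= 1")
        if self.backbone not in ("tiny_vgg", "vgg16"):
            raise ConfigError(f"unknown backbone {self.backbone!r}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["conv_channels"] = list(self.conv_channels)
        d["pair_groups"] = list(self.pair_groups)
        return d

    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:16]


VGG16_BLOCKS = ((64, 64), (128, 128), (256, 256, 256), (512, 512, 512),
                (512, 512, 512))


class Model:
    """Sequential CNN ending in a single logit."""

    def __init__(self, layers: list[Layer], config: TrainConfig) -> None:
        self.layers = layers
        self.config = config
        self.trained = False

    # -- forward / backward ---------------------------------------------------
    def forward(self, x: np.ndarray) -> np.ndarray:
        """Batch of images (N, S, S, 3) -> logits (N,)."""
        h = np.asarray(x, dtype=np.float32)
        for layer in self.layers:
            h = layer.forward(h)
        return h[:, 0]

    def backward(self, glogit: np.ndarray) -> np.ndarray:
        g = np.asarray(glogit, dtype=np.float32)[:, None]
        for layer in reversed(self.layers):
            g = layer.backward(g)
        return g

    def zero_grad(self) -> None:
        for layer in self.layers:
            for g in layer.grads:
                g[...] = 0.0

    # -- parameters -----------------------------------------------------------
    def parameters(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params]

    def gradients(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads]

    def get_state(self) -> list[np.ndarray]:
        return [p.copy() for p in self.parameters()]

    def set_state(self, state: list[np.ndarray]) -> None:
        for p, s in zip(self.parameters(), state):
            p[...] = s

    # -- inference ------------------------------------------------------------
    def predict_scores(self, images: np.ndarray, batch_size: int = 64) -> np.ndarray:
        """Sigmoid scores in [0, 1]; deterministic at inference."""
        images = np.asarray(images, dtype=np.float32)
        if images.ndim == 3:
            images = images[None]
        if images.shape[1:] != (self.config.input_size, self.config.input_size, 3):
            raise ValueError(
                f"expected images of shape (N, {self.config.input_size}, "
                f"{self.config.input_size}, 3), got {images.shape}")
        out = []
        for i in range(0, images.shape[0], batch_size):
            out.append(sigmoid(self.forward(images[i:i + batch_size])))
        return np.concatenate(out)

    def last_conv_relu_index(self) -> int:
        """Index of the ReLU following the last convolution (CAM target)."""
        idx = None
        for i, layer in enumerate(self.layers):
            if isinstance(layer, Conv2D):
                idx = i + 1
        if idx is None or not isinstance(self.layers[idx], ReLU):
            raise ValueError("model has no conv+ReLU block")
        return idx

    def activation_and_gradient(self, image: np.ndarray,
                                layer_index: int | None = None
                                ) -> tuple[np.ndarray, np.ndarray]:
        """Activation at a layer and d(logit)/d(activation), one image."""
        if layer_index is None:
            layer_index = self.last_conv_relu_index()
        h = np.asarray(image, dtype=np.float32)[None]
        acts = []
        for layer in self.layers:
            h = layer.forward(h)
            acts.append(h)
        g = np.ones((1, 1), dtype=np.float32)
        for i in reversed(range(len(self.layers))):
            if i == layer_index:
                return acts[layer_index][0], g[0]
            g = self.layers[i].backward(g)
        raise ValueError(f"layer_index {layer_index} out of range")


def sigmoid(z: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 + np.tanh(0.5 * np.asarray(z, dtype=np.float64)))


def build_model(config: TrainConfig) -> Model:
    """Construct the network described by ``config`` (untrained)."""
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(1)[0])
    layers: list[Layer] = []
    size = config.input_size
    if config.backbone == "tiny_vgg":
        c_in = 3
        for c_out in config.conv_channels:
            layers += [Conv2D(c_in, c_out, rng), ReLU(), MaxPool2D(config.pool)]
            if size % config.pool:
                raise ConfigError(f"input_size {config.input_size} not divisible "
                                  f"by pool {config.pool} at every block")
            size //= config.pool
            c_in = c_out
        layers += [Flatten(),
                   Dense(size * size * c_in, config.dense_units, rng), ReLU(),
                   Dense(config.dense_units, 1, rng)]
    else:  # vgg16
        if config.pretrained and not config.weights_path:
            raise ConfigError(
                "ImageNet-pretrained VGG16 weights are not bundled; supply "
                "weights_path or set pretrained=False")
        c_in = 3
        for block in VGG16_BLOCKS:
            for c_out in block:
                layers += [Conv2D(c_in, c_out, rng), ReLU()]
                c_in = c_out
            layers.append(MaxPool2D(2))
            size //= 2
        layers += [Flatten(),
                   Dense(size * size * c_in, 4096, rng), ReLU(),
                   Dense(4096, 4096, rng), ReLU(),
                   Dense(4096, 1, rng)]  # final FC output dimension = 1
        if config.weights_path:
            state = np.load(config.weights_path)
            model = Model(layers, config)
            model.set_state([state[k] for k in state.files])
            return model
    return Model(layers, config)


# ----------------------------------------------------------------------------
# losses
# ----------------------------------------------------------------------------

def bce_with_logits(logits: np.ndarray, labels: np.ndarray
                    ) -> tuple[float, np.ndarray]:
    """Mean binary cross-entropy and d(loss)/d(logit); numerically stable."""
    z = np.asarray(logits, dtype=np.float64)
    y = np.asarray(labels, dtype=np.float64)
    loss = float(np.mean(np.logaddexp(0.0, z) - y * z))
    grad = (sigmoid(z) - y) / z.size
    return loss, grad


def relative_loss(earlier_scores, later_scores) -> float:
    """Mean ReLU(earlier - later) over temporal pairs.

    Zero iff every later score is >= its earlier score, i.e. the predicted
    malignancy never decreases in time within a pair.
    """
    y1 = np.atleast_1d(np.asarray(earlier_scores, dtype=float))
    y2 = np.atleast_1d(np.asarray(later_scores, dtype=float))
    if y1.size == 0 or y1.shape != y2.shape:
        raise ValueError("need >= 1 pair with matching earlier/later scores")
    if np.any((y1 < 0) | (y1 > 1) | (y2 < 0) | (y2 > 1)):
        raise ValueError("scores must lie in [0, 1]")
    return float(np.mean(np.maximum(y1 - y2, 0.0)))


def relative_loss_grad(y1: np.ndarray, y2: np.ndarray
                       ) -> tuple[np.ndarray, np.ndarray]:
    """d LossR / d(earlier score), d LossR / d(later score)."""
    active = (y1 - y2 > 0).astype(np.float64)
    n = y1.size
    return active / n, -active / n


# ----------------------------------------------------------------------------
# temporal pair sampling
# ----------------------------------------------------------------------------

class PairSamplingError(RuntimeError):
    pass


def eligible_week_pairs(weeks, interval_min_weeks: int = 2) -> list[tuple[int, int]]:
    """All ordered week pairs (earlier, later) with the required interval."""
    weeks = sorted(set(int(w) for w in weeks))
    return [(a, b) for i, a in enumerate(weeks) for b in weeks[i + 1:]
            if b - a >= interval_min_weeks]


class PairSampler:
    """Uniformly samples subject, then ordered week pair, then slice.

    Pairs are drawn from induced subjects by default (progression is only
    defined there); both images of a pair use the same slice index (no
    registration).  Deterministic under the seed of the supplied generator.
    """

    def __init__(self, index: pd.DataFrame, interval_min_weeks: int = 2,
                 groups: tuple[str, ...] = ("induced",)) -> None:
        sub = index[index["group"].isin(groups)] if "group" in index else index
        self.rows_by_key: dict[tuple[str, int], pd.DataFrame] = {
            (str(s), int(w)): g for (s, w), g in sub.groupby(["subject_id", "week"])}
        self.subject_pairs: dict[str, list[tuple[int, int]]] = {}
        for subject, g in sub.groupby("subject_id"):
            pairs = eligible_week_pairs(g["week"].unique(), interval_min_weeks)
            pairs = [(a, b) for a, b in pairs
                     if self._common_slices(str(subject), a, b)]
            if pairs:
                self.subject_pairs[str(subject)] = pairs
        if not self.subject_pairs:
            observed = {str(s): sorted(g["week"].unique().tolist())
                        for s, g in sub.groupby("subject_id")}
            raise PairSamplingError(
                f"no subject has two weeks >= {interval_min_weeks} apart; "
                f"weeks observed: {observed}")
        self.subjects = sorted(self.subject_pairs)

    def _common_slices(self, subject: str, wa: int, wb: int) -> list[int]:
        a = self.rows_by_key.get((subject, wa))
        b = self.rows_by_key.get((subject, wb))
        if a is None or b is None:
            return []
        return sorted(set(a["slice"]) & set(b["slice"]))

    def sample_batch(self, n_pairs: int, rng: np.random.Generator
                     ) -> tuple[np.ndarray, np.ndarray]:
        """Row positions (into the full index) of earlier and later images."""
        early, late = [], []
        for _ in range(n_pairs):
            subject = self.subjects[rng.integers(len(self.subjects))]
            pairs = self.subject_pairs[subject]
            wa, wb = pairs[rng.integers(len(pairs))]
            slices = self._common_slices(subject, wa, wb)
            s = slices[rng.integers(len(slices))]
            a = self.rows_by_key[(subject, wa)]
            b = self.rows_by_key[(subject, wb)]
            early.append(int(a.index[a["slice"] == s][0]))
            late.append(int(b.index[b["slice"] == s][0]))
        return np.asarray(early), np.asarray(late)


# ----------------------------------------------------------------------------
# optimizer + training loop
# ----------------------------------------------------------------------------

class Adam:
    def __init__(self, params: list[np.ndarray], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8) -> None:
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m[...] = self.b1 * m + (1 - self.b1) * g
            v[...] = self.b2 * v + (1 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


@dataclass
class TrainHistory:
    train_loss: list[float] = field(default_factory=list)
    val_accuracy: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    best_epoch: int = -1
    best_val_accuracy: float = -1.0
    stopped_epoch: int = -1


def _check_subject_walls(train_subjects, val_subjects, test_subjects) -> None:
    trainval = set(train_subjects) | set(val_subjects)
    overlap = trainval & set(test_subjects or [])
    if overlap:
        raise SubjectLeakageError(
            f"subjects {sorted(overlap)} appear in both train/val and test")


def train(model: Model, train_ds: ImageDataset, val_ds: ImageDataset,
          config: TrainConfig | None = None,
          test_subjects: list[str] | None = None,
          pair_ds: ImageDataset | None = None) -> TrainHistory:
    """Train in place with BCE + relative loss; returns the history.

    Each step computes BCE on a shuffled image batch and, when
    ``loss_weight_relative > 0``, the relative loss on a concurrently sampled
    batch of temporal pairs; gradients of both terms are accumulated before a
    single Adam update.  With ``loss_weight_relative == 0`` the pair machinery
    is bypassed entirely, so the run is step-for-step identical to plain BCE
    training under the same seed.

    ``pair_ds`` supplies the temporal pairs (default: ``train_ds``).  Because
    the relative loss consumes no labels, it may span weeks outside the
    cleanly-labeled training period — but never test subjects, which is
    enforced here.
    """
    config = config or model.config
    if len(val_ds) == 0:
        raise ValueError("validation set must be non-empty")
    if len(np.unique(train_ds.index["label"])) < 2:
        raise ValueError("both classes must be present in training data")
    if pair_ds is None:
        pair_ds = train_ds
    _check_subject_walls(train_ds.index["subject_id"], val_ds.index["subject_id"],
                         test_subjects)
    _check_subject_walls(pair_ds.index["subject_id"], [], test_subjects)

    seqs = np.random.SeedSequence(config.seed).spawn(3)
    shuffle_rng = np.random.default_rng(seqs[1])
    pair_rng = np.random.default_rng(seqs[2])

    use_pairs = config.loss_weight_relative > 0
    sampler = None
    if use_pairs:
        sampler = PairSampler(pair_ds.index,
                              interval_min_weeks=config.interval_min_weeks,
                              groups=config.pair_groups)

    opt = Adam(model.parameters(), lr=config.learning_rate)
    labels = train_ds.index["label"].to_numpy(dtype=np.float64)
    n = len(train_ds)
    history = TrainHistory()
    best_state = model.get_state()
    no_improve = 0
    for epoch in range(config.max_epochs):
        order = shuffle_rng.permutation(n)
        epoch_loss, n_steps = 0.0, 0
        for start in range(0, n, config.batch_size):
            rows = order[start:start + config.batch_size]
            model.zero_grad()
            logits = model.forward(train_ds.images[rows])
            bloss, gz = bce_with_logits(logits, labels[rows])
            model.backward(config.loss_weight_bce * gz)
            loss = config.loss_weight_bce * bloss
            if use_pairs:
                e_rows, l_rows = sampler.sample_batch(config.pairs_per_batch, pair_rng)
                y1 = sigmoid(model.forward(pair_ds.images[e_rows]))
                y2 = sigmoid(model.forward(pair_ds.images[l_rows]))
                rloss = relative_loss(y1, y2)
                g1s, g2s = relative_loss_grad(y1, y2)
                # layer caches hold the later branch: backprop it first, then
                # re-forward the earlier branch to restore its caches
                model.backward(config.loss_weight_relative * g2s * y2 * (1 - y2))
                y1 = sigmoid(model.forward(pair_ds.images[e_rows]))
                model.backward(config.loss_weight_relative * g1s * y1 * (1 - y1))
                loss += config.loss_weight_relative * rloss
            opt.step(model.gradients())
            epoch_loss += loss
            n_steps += 1
        history.train_loss.append(epoch_loss / max(n_steps, 1))

        val_scores = model.predict_scores(val_ds.images)
        val_labels = val_ds.index["label"].to_numpy()
        acc = float(np.mean((val_scores > 0.5).astype(int) == val_labels))
        with np.errstate(divide="ignore"):
            vloss = float(-np.mean(val_labels * np.log(np.clip(val_scores, 1e-12, 1))
                                   + (1 - val_labels)
                                   * np.log(np.clip(1 - val_scores, 1e-12, 1))))
        history.val_accuracy.append(acc)
        history.val_loss.append(vloss)
        # checkpoint: best accuracy; equal-accuracy epochs tie-break on lower
        # validation BCE (accuracy alone saturates on well-separated data),
        # then on the earlier epoch.  Early stopping counts only accuracy.
        if acc > history.best_val_accuracy:
            history.best_val_accuracy = acc
            history.best_epoch = epoch
            best_vloss = vloss
            best_state = model.get_state()
            no_improve = 0
        else:
            if acc == history.best_val_accuracy and vloss < best_vloss:
                history.best_epoch = epoch
                best_vloss = vloss
                best_state = model.get_state()
            no_improve += 1
        if no_improve >= config.patience:
            break
    history.stopped_epoch = len(history.val_accuracy) - 1
    model.set_state(best_state)
    model.trained = True
    return history


def predict(model: Model, ds: ImageDataset) -> pd.DataFrame:
    """Score every image; returns the index with a ``score`` column."""
    out = ds.index.copy()
    out["score"] = model.predict_scores(ds.images)
    return out


# ----------------------------------------------------------------------------
# serialization
# ----------------------------------------------------------------------------

def save_model(model: Model, directory: Path | str,
               history: TrainHistory | None = None) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    state = {f"p{i:03d}": p for i, p in enumerate(model.parameters())}
    np.savez(directory / "weights.npz", **state)
    sidecar = {
        "config": model.config.to_dict(),
        "config_hash": model.config.hash(),
        "trained": model.trained,
    }
    if history is not None:
        sidecar["best_epoch"] = history.best_epoch
        sidecar["best_val_accuracy"] = history.best_val_accuracy
        sidecar["epochs_run"] = history.stopped_epoch + 1
    (directory / "model.json").write_text(json.dumps(sidecar, indent=2))
    return directory


def load_model(directory: Path | str) -> Model:
    directory = Path(directory)
    sidecar = json.loads((directory / "model.json").read_text())
    cfg = dict(sidecar["config"])
    cfg["conv_channels"] = tuple(cfg["conv_channels"])
    cfg["pair_groups"] = tuple(cfg["pair_groups"])
    config = TrainConfig(**cfg)
    model = build_model(config)
    state = np.load(directory / "weights.npz")
    model.set_state([state[k] for k in sorted(state.files)])
    model.trained = bool(sidecar.get("trained", False))
    return model
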