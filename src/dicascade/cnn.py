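"""Two-stage CNN cascade for dicentric-chromosome tiles.

Chromosome crops are aspect-preservingly rescaled onto 151x151 RGB tiles.
Stage 1 is an 8-layer network (5 conv + 3 fully connected) that screens
every tile; stage 2 shares the layout with wider filters and dropout
before the first two fully connected layers, and re-examines only the
tiles stage 1 called DIC — so the cascade can only remove positives, and
its false-positive count is bounded by stage 1's.  The softmax output is
read as the probability of the non-DIC class: 0 means DIC, 1 non-DIC,
ties at 0.5 resolve to non-DIC.

The layer engine below is a compact CPU implementation (float32,
channels-last jit-compiled direct convolutions, max-pool stride =
window, SGD with momentum and weight decay).  Convolutions are valid
(no padding, stride 1); with pool stride equal to the pool window the
spatial trace of a 151-px tile is 151-147-145-48-46-23-21-4-2 and the
flattened feature is 64*2*2 = 256.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from numba import njit
from skimage.transform import resize

TILE_SIZE = 151
TILE_BACKGROUND = 230


# ---------------------------------------------------------------------------
# Tiles
# ---------------------------------------------------------------------------

@dataclass
class ChromosomeTile:
    pixels: np.ndarray                    # (151, 151, 3) float32 in [0, 1]
    label: Optional[str] = None           # "DIC" | "nonDIC"
    source_id: str = ""


def normalize_tile(crop: np.ndarray, size: int = TILE_SIZE,
                   background: int = TILE_BACKGROUND) -> np.ndarray:
    """Rescale a crop so its longer side equals ``size`` (aspect ratio
    preserved, no stretch), centre it on a background-coloured square
    canvas, and scale intensities to [0, 1]."""
    crop = np.asarray(crop)
    if crop.size == 0:
        raise ValueError("empty crop")
    if crop.ndim == 2:
        crop = np.stack([crop] * 3, axis=-1)
    h, w = crop.shape[:2]
    scale = size / max(h, w)
    nh = max(1, int(round(h * scale)))
    nw = max(1, int(round(w * scale)))
    arr = crop.astype(np.float64)
    if arr.max() > 1.5:
        arr = arr / 255.0
    content = resize(arr, (nh, nw, 3), anti_aliasing=scale < 1.0,
                     preserve_range=True)
    canvas = np.full((size, size, 3), background / 255.0, dtype=np.float32)
    r0 = (size - nh) // 2
    c0 = (size - nw) // 2
    canvas[r0:r0 + nh, c0:c0 + nw] = content
    return np.clip(canvas, 0.0, 1.0).astype(np.float32)


def mirror(pixels: np.ndarray, axis: int = 1) -> np.ndarray:
    """Flip a tile left-right (axis=1) or top-bottom (axis=0)."""
    return np.flip(pixels, axis=axis).copy()


def pan(pixels: np.ndarray, dr: int, dc: int,
        fill: float = TILE_BACKGROUND / 255.0) -> np.ndarray:
    """Translate by (dr, dc) pixels, filling the vacated border."""
    out = np.full_like(pixels, fill)
    h, w = pixels.shape[:2]
    src_r = slice(max(0, -dr), min(h, h - dr))
    src_c = slice(max(0, -dc), min(w, w - dc))
    dst_r = slice(max(0, dr), min(h, h + dr))
    dst_c = slice(max(0, dc), min(w, w + dc))
    out[dst_r, dst_c] = pixels[src_r, src_c]
    return out


def add_noise(pixels: np.ndarray, sigma: float,
              rng: np.random.Generator) -> np.ndarray:
    if sigma == 0.0:
        return pixels.copy()
    return np.clip(pixels + rng.normal(0.0, sigma, pixels.shape),
                   0.0, 1.0).astype(np.float32)


def augment(tile: ChromosomeTile, seed: int | np.random.Generator = 0,
            pan_px: int = 5, noise_sigma: float = 0.02) -> list[ChromosomeTile]:
    """Mirrored, panned and noised variants; labels are preserved."""
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    px = tile.pixels
    variants = [
        mirror(px, axis=1),
        mirror(px, axis=0),
        pan(px, int(rng.integers(-pan_px, pan_px + 1)),
            int(rng.integers(-pan_px, pan_px + 1))),
        add_noise(px, noise_sigma, rng),
    ]
    return [ChromosomeTile(v, tile.label, tile.source_id + f"/aug{i}")
            for i, v in enumerate(variants)]


# ---------------------------------------------------------------------------
# Layer engine
# ---------------------------------------------------------------------------

@njit(cache=True, fastmath=True)
def _conv_fwd(x, Wr, b, y):        # pragma: no cover - jitted
    n_img, h, w, c_in = x.shape
    k = Wr.shape[0]
    n_out = Wr.shape[3]
    ho = h - k + 1
    wo = w - k + 1
    for n in range(n_img):
        for i in range(ho):
            for j in range(wo):
                acc = y[n, i, j]
                for o in range(n_out):
                    acc[o] = b[o]
                for u in range(k):
                    for v in range(k):
                        for c in range(c_in):
                            xv = x[n, i + u, j + v, c]
                            wrow = Wr[u, v, c]
                            for o in range(n_out):
                                acc[o] += xv * wrow[o]


@njit(cache=True, fastmath=True)
def _conv_bwd(x, dy, Wr, dWr, dx, need_dx):    # pragma: no cover - jitted
    n_img, h, w, c_in = x.shape
    k = Wr.shape[0]
    n_out = Wr.shape[3]
    ho = h - k + 1
    wo = w - k + 1
    for n in range(n_img):
        for i in range(ho):
            for j in range(wo):
                g = dy[n, i, j]
                for u in range(k):
                    for v in range(k):
                        for c in range(c_in):
                            xv = x[n, i + u, j + v, c]
                            wrow = Wr[u, v, c]
                            drow = dWr[u, v, c]
                            acc = np.float32(0.0)
                            for o in range(n_out):
                                drow[o] += xv * g[o]
                                acc += g[o] * wrow[o]
                            if need_dx:
                                dx[n, i + u, j + v, c] += acc


class Conv2D:
    """Valid convolution, stride 1, on channels-last (N, H, W, C) tensors.

    Direct jit-compiled loops with the output-channel axis innermost and
    contiguous, which vectorises well on one CPU core.  Weights are kept
    in the conventional (out, in, k, k) layout and repacked to
    (k, k, in, out) around each kernel call.
    """

    def __init__(self, in_ch: int, out_ch: int, k: int, rng: np.random.Generator):
        std = np.sqrt(2.0 / (in_ch * k * k))
        self.W = rng.normal(0.0, std, (out_ch, in_ch, k, k)).astype(np.float32)
        self.b = np.zeros(out_ch, dtype=np.float32)
        self.k = k

    def forward(self, x, train=False, rng=None):
        self.x = x
        n, h, w, _ = x.shape
        k = self.k
        y = np.empty((n, h - k + 1, w - k + 1, self.W.shape[0]),
                     dtype=np.float32)
        wr = np.ascontiguousarray(self.W.transpose(2, 3, 1, 0))
        _conv_fwd(x, wr, self.b, y)
        return y

    def backward(self, dy, need_dx: bool = True):
        x = self.x
        wr = np.ascontiguousarray(self.W.transpose(2, 3, 1, 0))
        dwr = np.zeros_like(wr)
        dx = np.zeros_like(x) if need_dx else np.empty((1, 1, 1, 1),
                                                       dtype=np.float32)
        _conv_bwd(x, dy, wr, dwr, dx, need_dx)
        self.dW = np.ascontiguousarray(dwr.transpose(3, 2, 0, 1))
        self.db = dy.sum(axis=(0, 1, 2)).astype(np.float32)
        del self.x
        return dx if need_dx else None

    def params(self):
        return [("W", self.W, self.dW), ("b", self.b, self.db)]


class ReLU:
    def forward(self, x, train=False, rng=None):
        self.mask = x > 0
        return x * self.mask

    def backward(self, dy):
        return dy * self.mask

    def params(self):
        return []


class MaxPool:
    """Max pooling with stride equal to the window (valid positions),
    channels last."""

    def __init__(self, win: int):
        self.win = win

    def forward(self, x, train=False, rng=None):
        w = self.win
        n, h, wd, c = x.shape
        ho, wo = (h - w) // w + 1, (wd - w) // w + 1
        self.in_shape = x.shape
        xr = (x[:, :ho * w, :wo * w, :]
              .reshape(n, ho, w, wo, w, c)
              .transpose(0, 1, 3, 2, 4, 5)
              .reshape(n, ho, wo, w * w, c))
        self.arg = xr.argmax(axis=3)
        return xr.max(axis=3)

    def backward(self, dy):
        w = self.win
        n, ho, wo, c = dy.shape
        dxr = np.zeros((n, ho, wo, w * w, c), dtype=np.float32)
        np.put_along_axis(dxr, self.arg[:, :, :, None, :], dy[:, :, :, None, :],
                          axis=3)
        dx = np.zeros(self.in_shape, dtype=np.float32)
        dx[:, :ho * w, :wo * w, :] = (dxr.reshape(n, ho, wo, w, w, c)
                                          .transpose(0, 1, 3, 2, 4, 5)
                                          .reshape(n, ho * w, wo * w, c))
        return dx

    def params(self):
        return []


class Dropout:
    def __init__(self, p: float):
        self.p = p

    def forward(self, x, train=False, rng=None):
        if not train or self.p <= 0:
            self.mask = None
            return x
        self.mask = (rng.random(x.shape) >= self.p).astype(np.float32) / (1 - self.p)
        return x * self.mask

    def backward(self, dy):
        return dy if self.mask is None else dy * self.mask

    def params(self):
        return []


class Flatten:
    def forward(self, x, train=False, rng=None):
        self.in_shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self.in_shape)

    def params(self):
        return []


class Dense:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        std = np.sqrt(2.0 / n_in)
        self.W = rng.normal(0.0, std, (n_out, n_in)).astype(np.float32)
        self.b = np.zeros(n_out, dtype=np.float32)

    def forward(self, x, train=False, rng=None):
        self.x = x
        return x @ self.W.T + self.b

    def backward(self, dy):
        self.dW = dy.T @ self.x
        self.db = dy.sum(axis=0)
        dx = dy @ self.W
        del self.x
        return dx

    def params(self):
        return [("W", self.W, self.dW), ("b", self.b, self.db)]


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, classes: np.ndarray):
    """Mean cross-entropy loss and its gradient w.r.t. the logits."""
    p = softmax(logits)
    n = logits.shape[0]
    loss = float(-np.log(np.maximum(p[np.arange(n), classes], 1e-12)).mean())
    grad = p.copy()
    grad[np.arange(n), classes] -= 1.0
    return loss, (grad / n).astype(np.float32)


# ---------------------------------------------------------------------------
# Declarative architectures
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CNNArchitecture:
    name: str
    layers: tuple            # of ("conv", out, k) | ("relu",) | ("pool", w)
    #                          | ("dropout", p) | ("flatten",) | ("fc", n)
    input_size: int = TILE_SIZE
    input_channels: int = 3

    def build(self, rng: np.random.Generator) -> "Network":
        built = []
        ch = self.input_channels
        size = self.input_size
        flat = None
        for spec in self.layers:
            op = spec[0]
            if op == "conv":
                _, out, k = spec
                built.append(Conv2D(ch, out, k, rng))
                ch, size = out, size - k + 1
            elif op == "relu":
                built.append(ReLU())
            elif op == "pool":
                built.append(MaxPool(spec[1]))
                size = (size - spec[1]) // spec[1] + 1
            elif op == "dropout":
                built.append(Dropout(spec[1]))
            elif op == "flatten":
                built.append(Flatten())
                flat = ch * size * size
            elif op == "fc":
                if flat is None:
                    raise ValueError("fc before flatten")
                built.append(Dense(flat, spec[1], rng))
                flat = spec[1]
            else:
                raise ValueError(f"unknown layer op {op!r}")
            if op in ("conv", "pool") and size < 1:
                raise ValueError("spatial size collapsed to < 1")
        return Network(built)

    def spatial_trace(self) -> list[int]:
        """Spatial side length after each conv/pool layer."""
        size = self.input_size
        trace = [size]
        for spec in self.layers:
            if spec[0] == "conv":
                size = size - spec[2] + 1
                trace.append(size)
            elif spec[0] == "pool":
                size = (size - spec[1]) // spec[1] + 1
                trace.append(size)
        return trace

    def to_json(self) -> str:
        return json.dumps({"name": self.name, "input_size": self.input_size,
                           "input_channels": self.input_channels,
                           "layers": [list(s) for s in self.layers]})

    @staticmethod
    def from_json(text: str) -> "CNNArchitecture":
        d = json.loads(text)
        return CNNArchitecture(d["name"], tuple(tuple(s) for s in d["layers"]),
                               d["input_size"], d["input_channels"])


def build_architecture(stage: int) -> CNNArchitecture:
    """The two published 8-layer stacks (5 conv + 3 fully connected)."""
    if stage == 1:
        layers = (("conv", 8, 5), ("relu",), ("conv", 8, 3), ("relu",),
                  ("pool", 3), ("conv", 16, 3), ("relu",), ("pool", 2),
                  ("conv", 32, 3), ("relu",), ("pool", 5),
                  ("conv", 64, 3), ("relu",), ("flatten",),
                  ("fc", 20), ("relu",), ("fc", 10), ("relu",), ("fc", 2))
        return CNNArchitecture("stage1", layers)
    if stage == 2:
        layers = (("conv", 16, 5), ("relu",), ("conv", 24, 3), ("relu",),
                  ("pool", 3), ("conv", 40, 3), ("relu",), ("pool", 2),
                  ("conv", 40, 3), ("relu",), ("pool", 5),
                  ("conv", 64, 3), ("relu",), ("flatten",),
                  ("dropout", 0.5), ("fc", 20), ("relu",),
                  ("dropout", 0.3), ("fc", 10), ("relu",), ("fc", 2))
        return CNNArchitecture("stage2", layers)
    raise ValueError("stage must be 1 or 2")


class Network:
    def __init__(self, layers: list):
        self.layers = layers
        self._velocity: dict[int, dict[str, np.ndarray]] = {}

    def forward(self, x: np.ndarray, train: bool = False,
                rng: Optional[np.random.Generator] = None) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train=train, rng=rng)
        return x

    def backward(self, dy: np.ndarray) -> Optional[np.ndarray]:
        for i, layer in enumerate(reversed(self.layers)):
            if i == len(self.layers) - 1 and isinstance(layer, Conv2D):
                return layer.backward(dy, need_dx=False)  # input layer
            dy = layer.backward(dy)
        return dy

    def sgd_step(self, lr: float, momentum: float, weight_decay: float) -> None:
        for i, layer in enumerate(self.layers):
            for name, w, g in layer.params():
                vel = self._velocity.setdefault(i, {})
                v = vel.get(name)
                if v is None:
                    v = np.zeros_like(w)
                v *= momentum
                v -= lr * (g + weight_decay * w)
                vel[name] = v
                w += v

    def state_arrays(self) -> dict[str, np.ndarray]:
        out = {}
        for i, layer in enumerate(self.layers):
            for name in ("W", "b"):
                if hasattr(layer, name):
                    out[f"layer{i}_{name}"] = getattr(layer, name)
        return out

    def load_state(self, arrays: dict[str, np.ndarray]) -> None:
        for key, val in arrays.items():
            idx, name = key.split("_")
            layer = self.layers[int(idx.removeprefix("layer"))]
            getattr(layer, name)[...] = val


# ---------------------------------------------------------------------------
# Training recipe
# ---------------------------------------------------------------------------

@dataclass
class TrainingConfig:
    lr: float = 0.001
    lr_drop_factor: float = 10.0     # applied after half the epochs
    momentum: float = 0.9
    weight_decay: float = 0.0001
    batch_size: int = 256
    epochs: int = 50
    dic_oversample: int = 3          # 3 for stage 1, 2 for stage 2
    split: tuple[int, int, int] = (7, 2, 1)
    seed: int = 0
    max_train_tiles: Optional[int] = None   # optional per-stage subsample

    def __post_init__(self):
        if sum(self.split) != 10:
            raise ValueError("split must sum to 10")
        for v in (self.lr, self.momentum, self.weight_decay,
                  self.batch_size, self.epochs, self.dic_oversample):
            if v <= 0:
                raise ValueError("training parameters must be positive")


@dataclass
class TrainedModel:
    architecture: CNNArchitecture
    network: Network
    training_history: list[dict] = field(default_factory=list)
    split_indices: Optional[tuple[np.ndarray, np.ndarray, np.ndarray]] = None

    def save(self, prefix: str | Path) -> None:
        prefix = Path(prefix)
        np.savez(prefix.with_suffix(".npz"), **self.network.state_arrays())
        prefix.with_suffix(".json").write_text(self.architecture.to_json())

    @staticmethod
    def load(prefix: str | Path) -> "TrainedModel":
        prefix = Path(prefix)
        arch = CNNArchitecture.from_json(prefix.with_suffix(".json").read_text())
        net = arch.build(np.random.default_rng(0))
        with np.load(prefix.with_suffix(".npz")) as data:
            net.load_state(dict(data))
        return TrainedModel(arch, net)


INPUT_CENTER = 0.85    # approximate corpus mean; centering speeds up SGD


def _as_batch(tiles: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """uint8 (n, H, W, 3) rows -> float32 channels-last, centered."""
    return tiles[idx].astype(np.float32) / 255.0 - INPUT_CENTER


def split_dataset(n: int, split: Sequence[int],
                  rng: np.random.Generator):
    """Seeded random 7:2:1 (or configured) partition of range(n)."""
    perm = rng.permutation(n)
    n_train = int(round(n * split[0] / 10))
    n_val = int(round(n * split[1] / 10))
    return (perm[:n_train], perm[n_train:n_train + n_val],
            perm[n_train + n_val:])


def oversample(indices: np.ndarray, labels: np.ndarray,
               factor: int) -> np.ndarray:
    """Duplicate DIC rows so their count in the stream is ``factor`` times
    the raw count (literal duplication before shuffling)."""
    dic = indices[labels[indices] == 1]
    return np.concatenate([indices] + [dic] * (factor - 1))


def _eval(net: Network, tiles: np.ndarray, idx: np.ndarray,
          classes: np.ndarray, batch: int):
    losses, correct = [], 0
    for i in range(0, len(idx), batch):
        sl = idx[i:i + batch]
        logits = net.forward(_as_batch(tiles, sl), train=False)
        loss, _ = softmax_cross_entropy(logits, classes[sl])
        losses.append(loss * len(sl))
        correct += int((logits.argmax(axis=1) == classes[sl]).sum())
    return float(np.sum(losses) / max(len(idx), 1)), correct / max(len(idx), 1)


def train_stage(arch: CNNArchitecture, tiles: np.ndarray, labels: np.ndarray,
                cfg: TrainingConfig,
                indices: Optional[np.ndarray] = None) -> TrainedModel:
    """Train one stage with the published recipe.

    ``tiles`` is uint8 (N, 151, 151, 3); ``labels`` is 1 for DIC, 0 for
    non-DIC.  Tiles are split 7:2:1 into train/validation/test; DIC tiles
    in train and validation are duplicated ``dic_oversample`` times; SGD
    uses momentum, weight decay and a x10 learning-rate drop after half
    the epochs.  All randomness (split, shuffling, init, dropout) flows
    from ``cfg.seed``.
    """
    labels = np.asarray(labels)
    if indices is None:
        indices = np.arange(len(labels))
    if np.unique(labels[indices]).size < 2:
        raise ValueError("training needs both DIC and non-DIC tiles")
    classes = 1 - labels          # class index: 0 = DIC, 1 = non-DIC
    rng = np.random.default_rng(cfg.seed)
    net = arch.build(rng)

    local = rng.permutation(indices)
    tr, va, te = split_dataset(len(local), cfg.split, rng)
    tr, va, te = local[tr], local[va], local[te]
    if cfg.max_train_tiles is not None and len(tr) > cfg.max_train_tiles:
        keep_dic = tr[labels[tr] == 1]
        keep_non = tr[labels[tr] == 0][:max(cfg.max_train_tiles - len(keep_dic), 0)]
        tr = rng.permutation(np.concatenate([keep_dic, keep_non]))
    tr_stream = oversample(tr, labels, cfg.dic_oversample)
    va_stream = oversample(va, labels, cfg.dic_oversample)
    # per-epoch validation metrics are tracked on a bounded subsample so
    # monitoring cost stays small next to training cost
    va_monitor = rng.permutation(va_stream)[:512]

    history: list[dict] = []
    for epoch in range(cfg.epochs):
        lr = cfg.lr / (cfg.lr_drop_factor if epoch >= cfg.epochs // 2 else 1.0)
        order = rng.permutation(tr_stream)
        ep_loss, ep_correct = 0.0, 0
        for i in range(0, len(order), cfg.batch_size):
            sl = order[i:i + cfg.batch_size]
            x = _as_batch(tiles, sl)
            logits = net.forward(x, train=True, rng=rng)
            loss, grad = softmax_cross_entropy(logits, classes[sl])
            net.backward(grad)
            net.sgd_step(lr, cfg.momentum, cfg.weight_decay)
            ep_loss += loss * len(sl)
            ep_correct += int((logits.argmax(axis=1) == classes[sl]).sum())
        val_loss, val_acc = _eval(net, tiles, va_monitor, classes, cfg.batch_size)
        history.append({
            "epoch": epoch, "lr": lr,
            "train_loss": ep_loss / len(order),
            "train_acc": ep_correct / len(order),
            "val_loss": val_loss, "val_acc": val_acc,
        })
    return TrainedModel(arch, net, history, (tr, va, te))


# ---------------------------------------------------------------------------
# Inference
# ---------------------------------------------------------------------------

def predict(model: TrainedModel, tiles: np.ndarray,
            batch_size: int = 256) -> np.ndarray:
    """Per-tile score in [0, 1]: softmax probability of the non-DIC class
    (0 = DIC, 1 = non-DIC).  The decision label is DIC iff score < 0.5."""
    tiles = np.asarray(tiles)
    if tiles.ndim == 3:
        tiles = tiles[None]
    scores = np.empty(len(tiles), dtype=np.float64)
    idx = np.arange(len(tiles))
    for i in range(0, len(tiles), batch_size):
        sl = idx[i:i + batch_size]
        logits = model.network.forward(_as_batch(tiles, sl), train=False)
        scores[sl] = softmax(logits)[:, 1]
    return scores


def is_dic(scores: np.ndarray) -> np.ndarray:
    """Score-to-label rule; the tie at exactly 0.5 goes to non-DIC."""
    return np.asarray(scores) < 0.5


def cascade_predict(stage1: TrainedModel, stage2: TrainedModel,
                    tiles: np.ndarray, batch_size: int = 256):
    """Cascade rule: stage-1 non-DIC is final; stage-1 DIC tiles go to
    stage 2, whose call is final.  Returns (final_is_dic, s1, s2) where
    s2 is NaN for tiles stage 2 never saw."""
    s1 = predict(stage1, tiles, batch_size)
    pos = is_dic(s1)
    s2 = np.full(len(s1), np.nan)
    final = np.zeros(len(s1), dtype=bool)
    if pos.any():
        s2[pos] = predict(stage2, tiles[pos], batch_size)
        final[pos] = is_dic(s2[pos])
    return final, s1, s2


def mine_stage2_training_set(stage1: TrainedModel, tiles: np.ndarray,
                             labels: np.ndarray,
                             batch_size: int = 256,
                             min_negatives: int = 150,
                             include_validation: bool = True,
                             scan_limit: Optional[int] = None) -> np.ndarray:
    """Stage-2 training pool: stage-1 false positives plus all DIC tiles,
    drawn from stage 1's train (and by default validation) splits; set
    ``include_validation=False`` to keep the validation split untouched
    for cascade evaluation.

    If stage 1 produced fewer than ``min_negatives`` false positives the
    pool is topped up with the non-DIC tiles scored closest to the DIC
    side (hard negatives), keeping the pool roughly class-balanced the
    way the full-scale stage-2 training set is."""
    tr, va, _ = stage1.split_indices
    pool = np.concatenate([tr, va]) if include_validation else tr
    dic_all = pool[labels[pool] == 1]
    if scan_limit is not None:
        pool = pool[:scan_limit]    # splits are pre-shuffled
    scores = predict(stage1, tiles[pool], batch_size)
    neg = labels[pool] == 0
    fp = pool[is_dic(scores) & neg]
    if len(fp) < min_negatives:
        order = np.argsort(scores[neg])      # lowest score = most DIC-like
        fp = pool[neg][order[:min_negatives]]
    return np.unique(np.concatenate([fp, dic_all]))


def train_cascade(tiles: np.ndarray, labels: np.ndarray,
                  cfg1: TrainingConfig, cfg2: TrainingConfig):
    """Train stage 1 on the full corpus, stage 2 on the mined hard set."""
    m1 = train_stage(build_architecture(1), tiles, labels, cfg1)
    pool = mine_stage2_training_set(m1, tiles, labels, cfg1.batch_size)
    m2 = train_stage(build_architecture(2), tiles, labels, cfg2, indices=pool)
    return m1, m2
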