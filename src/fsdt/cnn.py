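"""Compact convolutional classifier over the replicated section views.

Every section enters the network as a two-channel tensor: channel 0 is the
minimum-referenced view P and channel 1 the maximum-referenced view Q, both
bilinearly resized to a fixed square. The architecture is deliberately
small — a stack of conv(3x3, same) -> ReLU -> maxpool(2x2) blocks followed
by one ReLU dense layer and a sigmoid output — trained with Adam on binary
cross-entropy for a bounded number of mini-batch iterations (default 800)
with early stopping on validation loss.

The network is implemented directly on NumPy (im2col convolutions,
hand-written backward passes). This keeps training bit-reproducible for a
fixed (data, config, seed) triple on a given platform, which the pipeline's
determinism contract requires, and keeps the dependency surface to the
scientific stack.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from skimage.transform import resize

__all__ = ["ModelConfig", "TrainingRecord", "SegmentCNN", "build_model",
           "train", "predict_segment", "learning_curves"]


@dataclass(frozen=True)
class ModelConfig:
    """Architecture and training hyper-parameters.

    ``conv_blocks`` blocks double the filter count starting at
    ``base_filters``; sections are resized to ``input_side`` squared with
    ``channels`` input planes (min-view, max-view).
    """

    input_side: int = 32
    channels: int = 2
    conv_blocks: int = 2
    base_filters: int = 8
    dense_units: int = 32
    learning_rate: float = 1e-3
    max_iterations: int = 800
    batch_size: int = 32
    val_fraction: float = 0.2
    channel_dropout: float = 0.15
    eval_interval: int = 10
    patience: int = 50
    min_delta: float = 1e-4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.input_side < 2 ** self.conv_blocks:
            raise ValueError("input_side too small for the configured pooling depth")
        if self.channels < 1 or self.base_filters < 1 or self.dense_units < 1:
            raise ValueError("channels, base_filters and dense_units must be >= 1")


@dataclass
class TrainingRecord:
    """Per-iteration training curves and the run's summary statistics."""

    loss_curve: list[float]
    acc_curve: list[float]
    val_loss_curve: list[float]
    val_acc_curve: list[float]
    final_training_accuracy: float
    max_acc_reached: bool
    iterations_run: int
    eval_interval: int
    seed: int


# ---------------------------------------------------------------------------
# low-level layers (im2col convolution, 2x2 max-pool, dense)

def _im2col(x: np.ndarray, k: int = 3, pad: int = 1) -> np.ndarray:
    n, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    cols = np.empty((n, c, k, k, h, w), dtype=x.dtype)
    for i in range(k):
        for j in range(k):
            cols[:, :, i, j, :, :] = xp[:, :, i:i + h, j:j + w]
    return cols.reshape(n, c * k * k, h * w)


def _col2im(dcols: np.ndarray, xshape: tuple, k: int = 3, pad: int = 1) -> np.ndarray:
    n, c, h, w = xshape
    dxp = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=dcols.dtype)
    dcols = dcols.reshape(n, c, k, k, h, w)
    for i in range(k):
        for j in range(k):
            dxp[:, :, i:i + h, j:j + w] += dcols[:, :, i, j]
    return dxp[:, :, pad:h + pad, pad:w + pad]


class _Conv3x3:
    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator) -> None:
        scale = np.sqrt(2.0 / (c_in * 9))
        self.w = rng.normal(0.0, scale, size=(c_out, c_in * 9))
        self.b = np.zeros(c_out)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._xshape = x.shape
        self._cols = _im2col(x)
        n, _, h, w = x.shape
        out = np.einsum("fk,nkp->nfp", self.w, self._cols) + self.b[None, :, None]
        return out.reshape(n, self.w.shape[0], h, w)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, f, h, w = dout.shape
        dmat = dout.reshape(n, f, h * w)
        self.dw = np.einsum("nfp,nkp->fk", dmat, self._cols)
        self.db = dmat.sum(axis=(0, 2))
        dcols = np.einsum("fk,nfp->nkp", self.w, dmat)
        return _col2im(dcols, self._xshape)

    @property
    def params(self):
        return [("w", self.w), ("b", self.b)]


class _ReLU:
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


class _MaxPool2:
    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        h2, w2 = h // 2, w // 2
        xr = x.reshape(n, c, h2, 2, w2, 2).transpose(0, 1, 2, 4, 3, 5)
        xr = xr.reshape(n, c, h2, w2, 4)
        self._argmax = xr.argmax(axis=-1)        # ties -> first index, deterministic
        self._xshape = x.shape
        return np.take_along_axis(xr, self._argmax[..., None], axis=-1)[..., 0]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, h, w = self._xshape
        h2, w2 = h // 2, w // 2
        dxr = np.zeros((n, c, h2, w2, 4), dtype=dout.dtype)
        np.put_along_axis(dxr, self._argmax[..., None], dout[..., None], axis=-1)
        dxr = dxr.reshape(n, c, h2, w2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return dxr.reshape(n, c, h, w)


class _Dense:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator) -> None:
        self.w = rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_in, n_out))
        self.b = np.zeros(n_out)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.w + self.b

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.dw = self._x.T @ dout
        self.db = dout.sum(axis=0)
        return dout @ self.w.T

    @property
    def params(self):
        return [("w", self.w), ("b", self.b)]


# ---------------------------------------------------------------------------
# the model

class SegmentCNN:
    """Fixed-architecture binary classifier over 2-channel section tensors."""

    def __init__(self, config: ModelConfig) -> None:
        self.config = config
        rng = np.random.default_rng(config.seed & 0x7FFFFFFF)
        self._convs: list[_Conv3x3] = []
        self._pools: list[_MaxPool2] = []
        self._relus: list[_ReLU] = []
        c_in = config.channels
        side = config.input_side
        for k in range(config.conv_blocks):
            c_out = config.base_filters * (2 ** k)
            self._convs.append(_Conv3x3(c_in, c_out, rng))
            self._relus.append(_ReLU())
            self._pools.append(_MaxPool2())
            c_in = c_out
            side //= 2
        self._flat_dim = c_in * side * side
        self.dense1 = _Dense(self._flat_dim, config.dense_units, rng)
        self._relu_d = _ReLU()
        self.dense2 = _Dense(config.dense_units, 1, rng)

    # -- parameter bookkeeping --------------------------------------------
    def _layers_with_params(self):
        return [*self._convs, self.dense1, self.dense2]

    def parameter_arrays(self) -> list[np.ndarray]:
        return [p for layer in self._layers_with_params() for _, p in layer.params]

    def parameter_count(self) -> int:
        return sum(p.size for p in self.parameter_arrays())

    # -- forward / backward -----------------------------------------------
    def forward(self, x: np.ndarray) -> np.ndarray:
        """Probabilities for a batch (N, channels, side, side) -> (N,)."""
        h = x
        for conv, relu, pool in zip(self._convs, self._relus, self._pools):
            h = pool.forward(relu.forward(conv.forward(h)))
        self._pre_flat_shape = h.shape
        h = h.reshape(h.shape[0], -1)
        h = self._relu_d.forward(self.dense1.forward(h))
        logits = self.dense2.forward(h)[:, 0]
        # sigmoid, numerically stable on both tails
        self._probs = np.where(logits >= 0,
                               1.0 / (1.0 + np.exp(-logits)),
                               np.exp(logits) / (1.0 + np.exp(logits)))
        return self._probs

    def backward(self, y: np.ndarray) -> None:
        """Backprop of mean BCE given targets y in {0,1}; forward() must precede."""
        n = y.shape[0]
        dlogits = (self._probs - y)[:, None] / n
        dh = self.dense2.backward(dlogits)
        dh = self.dense1.backward(self._relu_d.backward(dh))
        dh = dh.reshape(self._pre_flat_shape)
        for conv, relu, pool in zip(reversed(self._convs), reversed(self._relus),
                                    reversed(self._pools)):
            dh = conv.backward(relu.backward(pool.backward(dh)))

    def gradient_arrays(self) -> list[np.ndarray]:
        grads = []
        for layer in self._layers_with_params():
            grads.extend([layer.dw, layer.db])
        return grads

    # -- persistence -------------------------------------------------------
    def save(self, path: str | Path) -> None:
        """Versioned checkpoint: JSON config header + raw parameter blocks."""
        header = {"format": "fsdt-model", "version": 1, "config": asdict(self.config)}
        arrays = {f"p{i}": p for i, p in enumerate(self.parameter_arrays())}
        buf = io.BytesIO()
        np.savez(buf, **arrays)
        with open(path, "wb") as fh:
            hdr = json.dumps(header).encode()
            fh.write(len(hdr).to_bytes(8, "little"))
            fh.write(hdr)
            fh.write(buf.getvalue())

    @classmethod
    def load(cls, path: str | Path) -> "SegmentCNN":
        with open(path, "rb") as fh:
            hlen = int.from_bytes(fh.read(8), "little")
            header = json.loads(fh.read(hlen).decode())
            if header.get("format") != "fsdt-model":
                raise ValueError(f"{path} is not an fsdt model checkpoint")
            data = np.load(io.BytesIO(fh.read()))
        model = cls(ModelConfig(**header["config"]))
        for i, p in enumerate(model.parameter_arrays()):
            p[...] = data[f"p{i}"]
        return model


def build_model(config: ModelConfig) -> SegmentCNN:
    """Construct a seeded, untrained classifier."""
    return SegmentCNN(config)


# ---------------------------------------------------------------------------
# training

def prepare_views(p_set, q_set, side: int) -> np.ndarray:
    """Stack (P, Q) view pairs into an (N, 2, side, side) tensor.

    Views are bilinearly resized; grid remainders make raw sections unequal
    in shape, so a fixed square is the common denominator.
    """
    if len(p_set) != len(q_set):
        raise ValueError("p_set and q_set must have equal length")
    out = np.empty((len(p_set), 2, side, side))
    for i, (p, q) in enumerate(zip(p_set, q_set)):
        if p.shape != q.shape:
            raise ValueError(f"view {i}: P shape {p.shape} != Q shape {q.shape}")
        out[i, 0] = resize(np.asarray(p, dtype=np.float64), (side, side),
                           order=1, anti_aliasing=False, preserve_range=True)
        out[i, 1] = resize(np.asarray(q, dtype=np.float64), (side, side),
                           order=1, anti_aliasing=False, preserve_range=True)
    return out


class _Adam:
    def __init__(self, params: list[np.ndarray], lr: float) -> None:
        self.params = params
        self.lr = lr
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray], b1: float = 0.9, b2: float = 0.999,
             eps: float = 1e-8) -> None:
        self.t += 1
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + eps)


def _bce(probs: np.ndarray, y: np.ndarray, eps: float = 1e-12) -> float:
    p = np.clip(probs, eps, 1 - eps)
    return float(-(y * np.log(p) + (1 - y) * np.log(1 - p)).mean())


def _stratified_split(labels: np.ndarray, val_fraction: float,
                      rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    train_idx, val_idx = [], []
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        idx = idx[rng.permutation(idx.size)]
        n_val = int(round(idx.size * val_fraction))
        n_val = min(n_val, idx.size - 1)       # keep >= 1 training example per class
        val_idx.extend(idx[:n_val])
        train_idx.extend(idx[n_val:])
    return np.sort(np.array(train_idx, dtype=int)), np.sort(np.array(val_idx, dtype=int))


def train(model: SegmentCNN, p_set, q_set, labels, config: ModelConfig | None = None,
          ) -> TrainingRecord:
    """Train on per-section (P, Q) view pairs with binary labels.

    Runs at most ``max_iterations`` mini-batch Adam steps on mean binary
    cross-entropy; stops early when the validation loss has not improved by
    ``min_delta`` for ``patience`` consecutive iterations. The loss/accuracy
    curves are per-batch; validation curves are sampled every
    ``eval_interval`` iterations. ``max_acc_reached`` records whether the
    training accuracy hit 1.0 at any iteration.
    """
    cfg = config or model.config
    y = np.asarray(labels, dtype=np.float64)
    if len(p_set) != len(q_set) or len(p_set) != y.size:
        raise ValueError("p_set, q_set and labels must have equal length")
    if y.size < 2:
        raise ValueError("need at least 2 labelled sections")
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("training requires both classes present")
    if not np.isin(classes, (0.0, 1.0)).all():
        raise ValueError("labels must be binary {0, 1}")

    x = prepare_views(p_set, q_set, cfg.input_side)
    rng = np.random.default_rng((cfg.seed & 0x7FFFFFFF) + 1)
    train_idx, val_idx = _stratified_split(y.astype(int), cfg.val_fraction, rng)
    x_tr, y_tr = x[train_idx], y[train_idx]
    x_val, y_val = x[val_idx], y[val_idx]

    opt = _Adam(model.parameter_arrays(), cfg.learning_rate)
    loss_curve: list[float] = []
    acc_curve: list[float] = []
    val_loss_curve: list[float] = []
    val_acc_curve: list[float] = []
    best_val = np.inf
    since_best = 0
    max_acc = False
    n_tr = x_tr.shape[0]
    bs = min(cfg.batch_size, n_tr)

    it = 0
    for it in range(1, cfg.max_iterations + 1):
        batch = rng.choice(n_tr, size=bs, replace=False)
        xb = x_tr[batch]
        if cfg.channel_dropout > 0 and cfg.channels == 2:
            # single-view augmentation: zero the P or Q channel on a fraction
            # of samples so P-only / Q-only ablation passes stay in-distribution
            xb = xb.copy()
            u = rng.random(bs)
            cd = cfg.channel_dropout
            xb[u < cd, 0] = 0.0
            xb[(u >= cd) & (u < 2 * cd), 1] = 0.0
        probs = model.forward(xb)
        loss = _bce(probs, y_tr[batch])
        if not np.isfinite(loss):
            raise RuntimeError(f"training diverged: non-finite loss at iteration {it}")
        model.backward(y_tr[batch])
        opt.step(model.gradient_arrays())
        acc = float(((probs >= 0.5) == (y_tr[batch] >= 0.5)).mean())
        loss_curve.append(loss)
        acc_curve.append(acc)
        if acc == 1.0:
            max_acc = True
        if it % cfg.eval_interval == 0 or it == cfg.max_iterations:
            if x_val.shape[0] > 0:
                vp = model.forward(x_val)
                vl = _bce(vp, y_val)
                va = float(((vp >= 0.5) == (y_val >= 0.5)).mean())
            else:                               # tiny datasets: fall back to train split
                vp = model.forward(x_tr)
                vl = _bce(vp, y_tr)
                va = float(((vp >= 0.5) == (y_tr >= 0.5)).mean())
            val_loss_curve.append(vl)
            val_acc_curve.append(va)
            if vl < best_val - cfg.min_delta:
                best_val = vl
                since_best = 0
            else:
                since_best += cfg.eval_interval
            if since_best >= cfg.patience:
                break

    final_probs = model.forward(x_tr)
    final_acc = float(((final_probs >= 0.5) == (y_tr >= 0.5)).mean())
    return TrainingRecord(
        loss_curve=loss_curve, acc_curve=acc_curve,
        val_loss_curve=val_loss_curve, val_acc_curve=val_acc_curve,
        final_training_accuracy=final_acc, max_acc_reached=max_acc,
        iterations_run=it, eval_interval=cfg.eval_interval, seed=cfg.seed,
    )


def predict_segment(model: SegmentCNN, p_view: np.ndarray, q_view: np.ndarray) -> float:
    """Probability that one section (given as its P and Q views) is tumor-bearing."""
    x = prepare_views([p_view], [q_view], model.config.input_side)
    return float(model.forward(x)[0])


def predict_batch(model: SegmentCNN, p_set, q_set) -> np.ndarray:
    """Vectorized :func:`predict_segment` over aligned view lists."""
    if len(p_set) == 0:
        return np.empty(0)
    x = prepare_views(p_set, q_set, model.config.input_side)
    return model.forward(x)


def _moving_average(v: np.ndarray, window: int) -> np.ndarray:
    if v.size < window:
        window = max(v.size, 1)
    kernel = np.ones(window) / window
    return np.convolve(v, kernel, mode="valid")


def learning_curves(record: TrainingRecord, csv_path: str | Path | None = None,
                    plot_path: str | Path | None = None, window: int = 25,
                    gap: float = 0.05):
    """Tabulate the run's curves and judge train/validation convergence.

    Returns ``(table, converged)`` where ``table`` is a pandas DataFrame of
    (iteration, loss, acc, val_loss, val_acc) — validation columns are NaN
    between evaluation points — and ``converged`` is True when the smoothed
    train accuracy and the validation accuracy agree within ``gap`` over the
    final window (the learning-curve convergence reading: neither over- nor
    under-fitting).
    """
    import pandas as pd

    if not record.loss_curve:
        raise ValueError("empty training record")
    n = len(record.loss_curve)
    table = pd.DataFrame({
        "iteration": np.arange(1, n + 1),
        "loss": record.loss_curve,
        "acc": record.acc_curve,
        "val_loss": np.nan,
        "val_acc": np.nan,
    })
    ev = record.eval_interval
    for k, (vl, va) in enumerate(zip(record.val_loss_curve, record.val_acc_curve)):
        row = min((k + 1) * ev, n) - 1
        table.loc[row, ["val_loss", "val_acc"]] = (vl, va)

    sm_acc = _moving_average(np.asarray(record.acc_curve), window)
    tail = min(window, sm_acc.size)
    if record.val_acc_curve:
        val_tail = record.val_acc_curve[-max(1, tail // ev):]
        converged = bool(abs(np.mean(sm_acc[-tail:]) - np.mean(val_tail)) < gap)
    else:
        converged = True

    if csv_path is not None:
        table.to_csv(csv_path, index=False)
    if plot_path is not None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(9, 3.2))
        ax1.plot(table["iteration"], table["loss"], lw=0.8, label="train")
        ax1.plot(table["iteration"], table["val_loss"], "o-", ms=2, label="val")
        ax1.set_xlabel("iteration"); ax1.set_ylabel("BCE loss"); ax1.legend()
        ax2.plot(table["iteration"], table["acc"], lw=0.8, label="train")
        ax2.plot(table["iteration"], table["val_acc"], "o-", ms=2, label="val")
        ax2.set_xlabel("iteration"); ax2.set_ylabel("accuracy"); ax2.legend()
        fig.tight_layout()
        fig.savefig(plot_path, dpi=110)
        plt.close(fig)
    return table, converged
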