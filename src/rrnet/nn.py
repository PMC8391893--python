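"""A 1D residual network for fixed-length RR-interval vectors, in numpy.

The architecture follows the standard time-series ResNet: three residual
blocks (64, 128, 128 filters; kernel sizes 8/5/3 within each block) of
conv -> batch-norm -> ReLU stages with an additive shortcut per block
(1-wide convolution + batch norm on the shortcut when channel widths
differ), global average pooling, and a dense softmax output. Forward and
backward passes are written directly against numpy; optimisation is Adam
on a categorical cross-entropy loss.

Training follows the cross-validation protocol of the surrounding pipeline:
per fold, the model is trained for a fixed number of epochs and the weights
of the epoch with the highest test accuracy are retained (earliest epoch on
ties). This "best-test-epoch" selection is deliberately part of the
replicated protocol; its optimistic bias is documented, not corrected.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

from .synthetic import CLASSES

__all__ = ["NetSpec", "TrainConfig", "TrainedFoldModel", "ResNet1D",
           "build_net", "train_fold", "predict"]

_DT = np.float32


@dataclass(frozen=True)
class NetSpec:
    """Architecture hyperparameters of the residual network."""

    input_length: int = 100
    n_classes: int = 3
    filters: tuple[int, ...] = (64, 128, 128)  # one entry per residual block
    kernel_sizes: tuple[int, ...] = (8, 5, 3)  # within each block

    def validate(self) -> None:
        if self.input_length < max(self.kernel_sizes):
            raise ValueError("input_length must be >= the largest kernel size")
        if self.n_classes < 2 or not self.filters or not self.kernel_sizes:
            raise ValueError("invalid network specification")


@dataclass(frozen=True)
class TrainConfig:
    """Optimisation protocol: 50 epochs, batch 16, Adam, cross-entropy."""

    epochs: int = 50
    batch_size: int = 16
    learning_rate: float = 1e-3
    seed: int = 0

    def validate(self) -> None:
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")


# ---------------------------------------------------------------------------
# layers

class _Conv1D:
    """Same-padded 1D convolution via an im2col matmul."""

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator):
        fan_in = k * c_in
        self.W = (rng.standard_normal((fan_in, c_out))
                  * np.sqrt(2.0 / fan_in)).astype(_DT)
        self.b = np.zeros(c_out, dtype=_DT)
        self.k, self.c_in, self.c_out = k, c_in, c_out
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        B, L, _ = x.shape
        k = self.k
        pl = (k - 1) // 2
        pr = k - 1 - pl
        xp = np.pad(x, ((0, 0), (pl, pr), (0, 0)))
        idx = np.arange(L)[:, None] + np.arange(k)[None, :]
        col = xp[:, idx, :].reshape(B * L, k * self.c_in)
        if train:
            self._col, self._shape, self._pads = col, (B, L), (pl, pr)
        y = col @ self.W + self.b
        return y.reshape(B, L, self.c_out)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        B, L = self._shape
        k, c_in = self.k, self.c_in
        pl, pr = self._pads
        dy2 = dy.reshape(B * L, self.c_out)
        self.dW += self._col.T @ dy2
        self.db += dy2.sum(axis=0)
        dcol = (dy2 @ self.W.T).reshape(B, L, k, c_in)
        dxp = np.zeros((B, L + k - 1, c_in), dtype=_DT)
        for j in range(k):
            dxp[:, j:j + L, :] += dcol[:, :, j, :]
        return dxp[:, pl:pl + L, :]


class _BatchNorm:
    """Per-channel batch normalisation over (batch, length)."""

    def __init__(self, c: int, momentum: float = 0.9, eps: float = 1e-3):
        self.gamma = np.ones(c, dtype=_DT)
        self.beta = np.zeros(c, dtype=_DT)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self.run_mean = np.zeros(c, dtype=_DT)
        self.run_var = np.ones(c, dtype=_DT)
        self.momentum, self.eps = momentum, eps

    def params(self):
        return [(self.gamma, self.dgamma), (self.beta, self.dbeta)]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 1))
            var = x.var(axis=(0, 1))
            self.run_mean = (self.momentum * self.run_mean
                             + (1 - self.momentum) * mean).astype(_DT)
            self.run_var = (self.momentum * self.run_var
                            + (1 - self.momentum) * var).astype(_DT)
            inv = 1.0 / np.sqrt(var + self.eps)
            xhat = (x - mean) * inv
            self._xhat, self._inv, self._n = xhat, inv, x.shape[0] * x.shape[1]
        else:
            inv = 1.0 / np.sqrt(self.run_var + self.eps)
            xhat = (x - self.run_mean) * inv
        return (self.gamma * xhat + self.beta).astype(_DT)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv, n = self._xhat, self._inv, self._n
        self.dgamma += (dy * xhat).sum(axis=(0, 1))
        self.dbeta += dy.sum(axis=(0, 1))
        dxhat = dy * self.gamma
        dx = (inv / n) * (n * dxhat
                          - dxhat.sum(axis=(0, 1))
                          - xhat * (dxhat * xhat).sum(axis=(0, 1)))
        return dx.astype(_DT)


class _ReLU:
    def params(self):
        return []

    def forward(self, x, train):
        if train:
            self._mask = x > 0
        return np.maximum(x, 0)

    def backward(self, dy):
        return dy * self._mask


class _ResidualBlock:
    """conv-bn-relu x2 -> conv-bn, plus (projected) shortcut, add, relu."""

    def __init__(self, c_in: int, c_out: int, kernels: tuple[int, ...],
                 rng: np.random.Generator):
        self.stages = []
        c = c_in
        for i, k in enumerate(kernels):
            self.stages.append((_Conv1D(c, c_out, k, rng), _BatchNorm(c_out),
                                _ReLU() if i < len(kernels) - 1 else None))
            c = c_out
        if c_in != c_out:
            self.short_conv = _Conv1D(c_in, c_out, 1, rng)
            self.short_bn = _BatchNorm(c_out)
        else:
            self.short_conv = self.short_bn = None
        self.out_relu = _ReLU()

    def params(self):
        ps = []
        for conv, bn, _ in self.stages:
            ps += conv.params() + bn.params()
        if self.short_conv is not None:
            ps += self.short_conv.params() + self.short_bn.params()
        return ps

    def forward(self, x, train):
        y = x
        for conv, bn, relu in self.stages:
            y = bn.forward(conv.forward(y, train), train)
            if relu is not None:
                y = relu.forward(y, train)
        if self.short_conv is not None:
            s = self.short_bn.forward(self.short_conv.forward(x, train), train)
        else:
            s = x
        return self.out_relu.forward(y + s, train)

    def backward(self, dy):
        dy = self.out_relu.backward(dy)
        ds = dy
        if self.short_conv is not None:
            ds = self.short_conv.backward(self.short_bn.backward(dy))
        dmain = dy
        for conv, bn, relu in reversed(self.stages):
            if relu is not None:
                dmain = relu.backward(dmain)
            dmain = conv.backward(bn.backward(dmain))
        return dmain + ds


class _Dense:
    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        self.W = (rng.standard_normal((c_in, c_out))
                  * np.sqrt(2.0 / c_in)).astype(_DT)
        self.b = np.zeros(c_out, dtype=_DT)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]

    def forward(self, x, train):
        if train:
            self._x = x
        return x @ self.W + self.b

    def backward(self, dy):
        self.dW += self._x.T @ dy
        self.db += dy.sum(axis=0)
        return dy @ self.W.T


# ---------------------------------------------------------------------------
# network

class ResNet1D:
    """The full network: residual blocks -> global average pool -> softmax."""

    def __init__(self, spec: NetSpec = NetSpec(), seed: int = 0):
        spec.validate()
        self.spec = spec
        rng = np.random.default_rng(seed)
        self.blocks = []
        c = 1
        for f in spec.filters:
            self.blocks.append(_ResidualBlock(c, f, spec.kernel_sizes, rng))
            c = f
        self.head = _Dense(c, spec.n_classes, rng)

    @property
    def n_residual_blocks(self) -> int:
        return len(self.blocks)

    def params(self):
        ps = []
        for b in self.blocks:
            ps += b.params()
        return ps + self.head.params()

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Map (batch, length[, 1]) vectors to per-class probabilities."""
        x = np.asarray(x, dtype=_DT)
        if x.ndim == 2:
            x = x[:, :, None]
        if x.shape[1] != self.spec.input_length:
            raise ValueError(
                f"expected vectors of length {self.spec.input_length}, "
                f"got {x.shape[1]}")
        for b in self.blocks:
            x = b.forward(x, train)
        pooled = x.mean(axis=1)
        if train:
            self._pool_len = self.spec.input_length
        logits = self.head.forward(pooled, train)
        z = logits - logits.max(axis=1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=1, keepdims=True)

    def _zero_grads(self):
        for _, g in self.params():
            g[...] = 0

    def train_step(self, x: np.ndarray, y_onehot: np.ndarray,
                   opt: "_Adam") -> float:
        """One Adam step on a minibatch; returns the mean cross-entropy."""
        self._zero_grads()
        probs = self.forward(x, train=True)
        n = x.shape[0]
        loss = float(-np.mean(np.log(np.sum(probs * y_onehot, axis=1) + 1e-12)))
        dlogits = (probs - y_onehot) / n
        dpooled = self.head.backward(dlogits.astype(_DT))
        dx = np.repeat(dpooled[:, None, :] / self._pool_len,
                       self._pool_len, axis=1).astype(_DT)
        for b in reversed(self.blocks):
            dx = b.backward(dx)
        opt.step(self.params())
        return loss

    def get_weights(self):
        return copy.deepcopy([p for p, _ in self.params()]) + [
            copy.deepcopy([(bn.run_mean, bn.run_var)
                           for bn in self._batchnorms()])]

    def set_weights(self, weights):
        *param_vals, bn_stats = weights
        for (p, _), v in zip(self.params(), param_vals):
            p[...] = v
        for bn, (m, v) in zip(self._batchnorms(), bn_stats):
            bn.run_mean[...] = m
            bn.run_var[...] = v

    def _batchnorms(self):
        bns = []
        for blk in self.blocks:
            for _, bn, _ in blk.stages:
                bns.append(bn)
            if blk.short_bn is not None:
                bns.append(blk.short_bn)
        return bns


class _Adam:
    def __init__(self, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m: dict[int, np.ndarray] = {}
        self.v: dict[int, np.ndarray] = {}

    def step(self, params):
        self.t += 1
        b1, b2 = self.b1, self.b2
        corr = np.sqrt(1 - b2**self.t) / (1 - b1**self.t)
        for p, g in params:
            key = id(p)
            if key not in self.m:
                self.m[key] = np.zeros_like(p)
                self.v[key] = np.zeros_like(p)
            m, v = self.m[key], self.v[key]
            m += (1 - b1) * (g - m)
            v += (1 - b2) * (g * g - v)
            p -= self.lr * corr * m / (np.sqrt(v) + self.eps)


# ---------------------------------------------------------------------------
# training protocol

@dataclass
class TrainedFoldModel:
    """A trained fold: selected-epoch weights plus the training history."""

    fold_index: int
    model: ResNet1D
    train_loss: list[float] = field(default_factory=list)
    test_accuracy: list[float] = field(default_factory=list)
    selected_epoch: int = 0  # 1-based
    scale: float = 1.0  # training-set std used to standardise inputs

    @property
    def selected_accuracy(self) -> float:
        return self.test_accuracy[self.selected_epoch - 1]

    def predict(self, vectors: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Probabilities and labels for raw (unscaled) detrended vectors."""
        return predict(self.model, np.asarray(vectors, dtype=_DT) / self.scale)


def build_net(spec: NetSpec = NetSpec(), seed: int = 0) -> ResNet1D:
    """Construct an untrained residual network for the given specification."""
    return ResNet1D(spec, seed=seed)


def _encode(labels: np.ndarray, classes=CLASSES) -> np.ndarray:
    lut = {c: i for i, c in enumerate(classes)}
    return np.asarray([lut[l] for l in labels], dtype=int)


def predict(model: ResNet1D, vectors: np.ndarray,
            batch_size: int = 256) -> tuple[np.ndarray, np.ndarray]:
    """Per-class probabilities and argmax labels (lowest index on ties)."""
    vectors = np.asarray(vectors, dtype=_DT)
    probs = np.concatenate([model.forward(vectors[i:i + batch_size])
                            for i in range(0, len(vectors), batch_size)])
    idx = np.argmax(probs, axis=1)
    if model.spec.n_classes == len(CLASSES):
        labels = np.asarray(CLASSES, dtype=object)[idx]
    else:
        labels = idx
    return probs, labels


def train_fold(fold, spec: NetSpec = NetSpec(),
               cfg: TrainConfig = TrainConfig(),
               classes=CLASSES, verbose: bool = False) -> TrainedFoldModel:
    """Train one cross-validation fold and keep the best-test-epoch weights.

    Inputs are standardised by the training set's global standard deviation
    (detrended vectors are already near zero mean). The per-epoch history of
    train loss and test accuracy has exactly ``cfg.epochs`` entries; the
    selected epoch is the first argmax of test accuracy.
    """
    cfg.validate()
    X_tr = np.asarray(fold.train_X, dtype=_DT)
    X_te = np.asarray(fold.test_X, dtype=_DT)
    if X_tr.size == 0:
        raise ValueError("empty training set")
    y_tr = _encode(fold.train_y, classes)
    y_te = _encode(fold.test_y, classes)
    scale = float(X_tr.std()) or 1.0
    X_tr = X_tr / scale
    X_te = X_te / scale
    onehot = np.eye(spec.n_classes, dtype=_DT)[y_tr]

    rng = np.random.default_rng(cfg.seed)
    model = build_net(spec, seed=int(rng.integers(2**31)))
    opt = _Adam(lr=cfg.learning_rate)
    out = TrainedFoldModel(fold_index=getattr(fold, "fold_index", 0), model=model)
    best_acc, best_weights = -1.0, None
    n = len(X_tr)
    for epoch in range(1, cfg.epochs + 1):
        order = rng.permutation(n)
        losses = []
        for s in range(0, n, cfg.batch_size):
            sel = order[s:s + cfg.batch_size]
            losses.append(model.train_step(X_tr[sel], onehot[sel], opt))
        probs, _ = predict(model, X_te)
        acc = float(np.mean(np.argmax(probs, axis=1) == y_te))
        out.train_loss.append(float(np.mean(losses)))
        out.test_accuracy.append(acc)
        if acc > best_acc:
            best_acc, best_weights = acc, model.get_weights()
            out.selected_epoch = epoch
        if verbose:
            print(f"epoch {epoch:3d}  loss {out.train_loss[-1]:.4f}  "
                  f"test acc {acc:.4f}")
    model.set_weights(best_weights)
    out.scale = scale
    return out
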