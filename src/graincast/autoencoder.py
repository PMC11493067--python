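"""Convolutional autoencoders compressing climate fields to 8-dimensional codes.

Two architectures are provided:

* ``spatial`` (sAE): two 2-D convolution layers, each followed by a ReLU,
  then a dense head mapping the flattened activations to the code.  Consumes
  one annual 2-D field (e.g. a province's heatwave-frequency map).
* ``spatiotemporal`` (stAE): three 3-D convolution layers (ReLU after each)
  plus a dense head.  Consumes one calendar year of monthly fields as a
  (12, H, W) block (e.g. monthly mean temperature).

The decoder is a small dense network mapping the code back to the
(standardized) field; reconstruction quality is measured by mean squared
error and parameters are trained with Adam.  Everything is plain numpy with
hand-written backpropagation, so training is deterministic given the seed.
"""

from __future__ import annotations

import json

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from sklearn.base import BaseEstimator, TransformerMixin

CODE_DIM = 8


class ArchitectureError(ValueError):
    """Input shape not reachable by the configured conv stack."""


class TrainingDivergenceError(RuntimeError):
    def __init__(self, epoch: int):
        super().__init__(f"loss became non-finite at epoch {epoch}")
        self.epoch = epoch


# --------------------------------------------------------------------------
# layers
# --------------------------------------------------------------------------


class _ConvNd:
    """k^nd convolution with stride and 'same'-style padding (p = k // 2)."""

    def __init__(self, ndim, c_in, c_out, kernel, stride, rng):
        self.ndim = ndim
        self.k = kernel
        self.s = stride
        self.p = kernel // 2
        fan_in = c_in * kernel**ndim
        self.W = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(c_out, fan_in))
        self.b = np.zeros(c_out)
        self.c_in, self.c_out = c_in, c_out

    def out_dims(self, dims):
        if all(d < 2 for d in dims):
            raise ArchitectureError(
                f"spatial dims {dims} fully collapsed before kernel={self.k}, "
                f"stride={self.s} convolution; input shape not reachable"
            )
        return tuple((d + 2 * self.p - self.k) // self.s + 1 for d in dims)

    def forward(self, x):
        n = x.shape[0]
        dims = x.shape[2:]
        odims = self.out_dims(dims)
        pad = [(0, 0), (0, 0)] + [(self.p, self.p)] * self.ndim
        xp = np.pad(x, pad)
        axes = tuple(range(2, 2 + self.ndim))
        win = sliding_window_view(xp, (self.k,) * self.ndim, axis=axes)
        slicer = (slice(None), slice(None)) + tuple(
            slice(None, None, self.s) for _ in range(self.ndim)
        )
        win = win[slicer]  # (n, c_in, *odims, *k^nd)
        # channels+kernel last, positions flattened
        perm = (0, *range(2, 2 + self.ndim), 1, *range(2 + self.ndim, 2 + 2 * self.ndim))
        cols = win.transpose(perm).reshape(n * int(np.prod(odims)), -1)
        out = cols @ self.W.T + self.b
        out = out.reshape(n, *odims, self.c_out)
        out = np.moveaxis(out, -1, 1)
        self._cache = (cols, x.shape, xp.shape, odims)
        return np.ascontiguousarray(out)

    def backward(self, dout):
        cols, xshape, xpshape, odims = self._cache
        n = xshape[0]
        do = np.moveaxis(dout, 1, -1).reshape(-1, self.c_out)
        self.dW = do.T @ cols
        self.db = do.sum(axis=0)
        dcols = do @ self.W  # (n * prod(odims), c_in * k^nd)
        dwin = dcols.reshape(n, *odims, self.c_in, *(self.k,) * self.ndim)
        # back to (n, c_in, *odims, *kernel)
        nd = self.ndim
        perm = (0, 1 + nd, *range(1, 1 + nd), *range(2 + nd, 2 + 2 * nd))
        dwin = dwin.transpose(perm)
        dxp = np.zeros(xpshape)
        for kidx in np.ndindex(*(self.k,) * nd):
            sl = (slice(None), slice(None)) + tuple(
                slice(ki, ki + self.s * od, self.s) for ki, od in zip(kidx, odims)
            )
            dxp[sl] += dwin[(Ellipsis,) + kidx]
        crop = (slice(None), slice(None)) + tuple(
            slice(self.p, self.p + d) for d in xshape[2:]
        )
        return dxp[crop]

    def params(self):
        return [("W", self), ("b", self)]


class _Dense:
    def __init__(self, n_in, n_out, rng):
        self.W = rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_out, n_in))
        self.b = np.zeros(n_out)

    def forward(self, x):
        self._x = x
        return x @ self.W.T + self.b

    def backward(self, dout):
        self.dW = dout.T @ self._x
        self.db = dout.sum(axis=0)
        return dout @ self.W

    def params(self):
        return [("W", self), ("b", self)]


class _ReLU:
    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask

    def params(self):
        return []


class _Flatten:
    def forward(self, x):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)

    def params(self):
        return []


class _Reshape:
    def __init__(self, shape):
        self.shape = shape

    def forward(self, x):
        return x.reshape(x.shape[0], *self.shape)

    def backward(self, dout):
        return dout.reshape(dout.shape[0], -1)

    def params(self):
        return []


class _Adam:
    def __init__(self, layers, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        self.entries = []
        for layer in layers:
            for name, owner in layer.params():
                p = getattr(owner, name)
                self.entries.append(
                    {"owner": owner, "name": name, "m": np.zeros_like(p), "v": np.zeros_like(p)}
                )
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0

    def step(self):
        if self.lr == 0.0:
            return
        self.t += 1
        for e in self.entries:
            g = getattr(e["owner"], "d" + e["name"])
            e["m"] = self.b1 * e["m"] + (1 - self.b1) * g
            e["v"] = self.b2 * e["v"] + (1 - self.b2) * g * g
            mhat = e["m"] / (1 - self.b1**self.t)
            vhat = e["v"] / (1 - self.b2**self.t)
            p = getattr(e["owner"], e["name"])
            setattr(e["owner"], e["name"], p - self.lr * mhat / (np.sqrt(vhat) + self.eps))


def _forward(layers, x):
    for layer in layers:
        x = layer.forward(x)
    return x


def _backward(layers, dout):
    for layer in reversed(layers):
        dout = layer.backward(dout)
    return dout


# --------------------------------------------------------------------------
# estimator
# --------------------------------------------------------------------------

_DEFAULT_CHANNELS = {"spatial": (8, 16), "spatiotemporal": (8, 16, 32)}
_NDIM = {"spatial": 2, "spatiotemporal": 3}


class ConvolutionalAutoencoder(BaseEstimator, TransformerMixin):
    """Conv encoder + dense decoder trained by Adam on reconstruction MSE.

    Parameters
    ----------
    architecture : {"spatial", "spatiotemporal"}
        "spatial" stacks two 2-D conv+ReLU layers for (N, H, W) inputs;
        "spatiotemporal" stacks three 3-D conv+ReLU layers for
        (N, 12, H, W) monthly blocks.
    code_dim : int, default 8
        Embedding width.
    channels : tuple or None
        Output channels per conv layer; length must equal the layer count
        fixed by the architecture (2 or 3).  Defaults (8, 16) / (8, 16, 32).
    kernel_size, stride : int
        Shared by all conv layers; padding is kernel_size // 2.
    hidden_dim : int
        Width of the decoder's hidden dense layer.
    epochs, batch_size, learning_rate
        Adam training schedule.
    standardize : bool
        Z-score inputs with the training-set mean/sd before encoding
        (recommended: reconstruction MSE is otherwise unit-dependent).
    random_state : int
        Seeds weight init and batch shuffling; training is deterministic.

    Attributes
    ----------
    training_log_ : list of per-epoch mean reconstruction MSE.
    initial_loss_ : reconstruction MSE at initialization.
    mean_, scale_ : standardization constants learned from the training set.
    """

    def __init__(
        self,
        architecture="spatial",
        code_dim=CODE_DIM,
        channels=None,
        kernel_size=3,
        stride=2,
        hidden_dim=64,
        epochs=200,
        batch_size=16,
        learning_rate=1e-3,
        standardize=True,
        random_state=0,
    ):
        self.architecture = architecture
        self.code_dim = code_dim
        self.channels = channels
        self.kernel_size = kernel_size
        self.stride = stride
        self.hidden_dim = hidden_dim
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.standardize = standardize
        self.random_state = random_state

    # -- construction ------------------------------------------------------
    def _build(self, field_shape, rng):
        nd = _NDIM[self.architecture]
        channels = self.channels or _DEFAULT_CHANNELS[self.architecture]
        if len(channels) != len(_DEFAULT_CHANNELS[self.architecture]):
            raise ArchitectureError(
                f"{self.architecture} architecture takes exactly "
                f"{len(_DEFAULT_CHANNELS[self.architecture])} conv layers"
            )
        enc = []
        c_in, dims = 1, field_shape
        for c_out in channels:
            conv = _ConvNd(nd, c_in, c_out, self.kernel_size, self.stride, rng)
            dims = conv.out_dims(dims)
            enc += [conv, _ReLU()]
            c_in = c_out
        flat = c_in * int(np.prod(dims))
        enc += [_Flatten(), _Dense(flat, self.code_dim, rng)]
        out_flat = int(np.prod(field_shape))
        dec = [
            _Dense(self.code_dim, self.hidden_dim, rng),
            _ReLU(),
            _Dense(self.hidden_dim, out_flat, rng),
            _Reshape((1, *field_shape)),
        ]
        return enc, dec

    def _validate(self, X):
        X = np.asarray(X, dtype=float)
        nd = _NDIM[self.architecture]
        if X.ndim != nd + 1:
            raise ArchitectureError(
                f"{self.architecture} expects {nd + 1}-d input (samples first), "
                f"got shape {X.shape}"
            )
        return X

    # -- API ---------------------------------------------------------------
    def fit(self, X, y=None):
        X = self._validate(X)
        if X.shape[0] == 0:
            raise ArchitectureError("dataset must be nonempty")
        self.field_shape_ = X.shape[1:]
        if self.standardize:
            self.mean_ = float(X.mean())
            sd = float(X.std())
            self.scale_ = sd if sd > 0 else 1.0
        else:
            self.mean_, self.scale_ = 0.0, 1.0
        rng = np.random.default_rng(self.random_state)
        self.encoder_, self.decoder_ = self._build(self.field_shape_, rng)
        layers = self.encoder_ + self.decoder_
        opt = _Adam(layers, self.learning_rate)
        Z = ((X - self.mean_) / self.scale_)[:, None]  # add channel axis
        n = Z.shape[0]
        self.initial_loss_ = float(np.mean((_forward(layers, Z) - Z) ** 2))
        self.training_log_ = []
        for epoch in range(self.epochs):
            order = rng.permutation(n)
            total, seen = 0.0, 0
            for start in range(0, n, self.batch_size):
                idx = order[start : start + self.batch_size]
                zb = Z[idx]
                zhat = _forward(layers, zb)
                resid = zhat - zb
                loss = float(np.mean(resid**2))
                if not np.isfinite(loss):
                    raise TrainingDivergenceError(epoch)
                _backward(layers, 2.0 * resid / resid.size)
                opt.step()
                total += loss * len(idx)
                seen += len(idx)
            self.training_log_.append(total / seen)
        return self

    def transform(self, X) -> np.ndarray:
        """Encode fields to (n_samples, code_dim) code vectors."""
        X = self._validate(X)
        self._check_shape(X)
        Z = ((X - self.mean_) / self.scale_)[:, None]
        return _forward(self.encoder_, Z)

    def inverse_transform(self, codes) -> np.ndarray:
        """Decode code vectors back to fields in natural units."""
        codes = np.asarray(codes, dtype=float)
        fields = _forward(self.decoder_, codes)[:, 0]
        return fields * self.scale_ + self.mean_

    def reconstruct(self, X) -> np.ndarray:
        return self.inverse_transform(self.transform(X))

    def reconstruction_mse(self, X) -> float:
        """Mean squared reconstruction error in standardized units."""
        X = self._validate(X)
        Z = (X - self.mean_) / self.scale_
        Zhat = (self.reconstruct(X) - self.mean_) / self.scale_
        return float(np.mean((Zhat - Z) ** 2))

    def _check_shape(self, X):
        if X.shape[1:] != self.field_shape_:
            raise ArchitectureError(
                f"field shape {X.shape[1:]} does not match fitted shape "
                f"{self.field_shape_}"
            )

    # -- persistence -------------------------------------------------------
    def save(self, path):
        """Serialize spec + weights to a single .npz file."""
        blobs = {}
        for i, layer in enumerate(self.encoder_ + self.decoder_):
            for name, owner in layer.params():
                blobs[f"l{i}_{name}"] = getattr(owner, name)
        meta = {
            "params": self.get_params(),
            "field_shape": list(self.field_shape_),
            "mean": self.mean_,
            "scale": self.scale_,
            "training_log": getattr(self, "training_log_", []),
            "initial_loss": getattr(self, "initial_loss_", None),
        }
        np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **blobs)

    @classmethod
    def load(cls, path) -> "ConvolutionalAutoencoder":
        with np.load(path) as data:
            meta = json.loads(bytes(data["__meta__"].tobytes()).decode())
            est = cls(**meta["params"])
            est.field_shape_ = tuple(meta["field_shape"])
            est.mean_, est.scale_ = meta["mean"], meta["scale"]
            est.training_log_ = meta["training_log"]
            est.initial_loss_ = meta["initial_loss"]
            rng = np.random.default_rng(est.random_state)
            est.encoder_, est.decoder_ = est._build(est.field_shape_, rng)
            for i, layer in enumerate(est.encoder_ + est.decoder_):
                for name, owner in layer.params():
                    setattr(owner, name, data[f"l{i}_{name}"])
        return est
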