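"""Compact convolutional network for raw-EEG classification.

The architecture follows the compact EEGNet design: Block 1 is a temporal
convolution (filter length = half the sampling rate, so the filters act as
learned band-pass kernels) followed by a depthwise spatial convolution across
electrodes constrained to max-norm 1, batch normalization, ELU, dropout and
average pooling; Block 2 is a separable convolution (depthwise temporal then
pointwise mixing), again BN/ELU/dropout/average pooling; the classifier is a
dense softmax layer with N units (max-norm 0.25).

Implemented self-contained on NumPy: explicit forward/backward passes for
every layer, Adam updates, and post-step max-norm projection.  Gradients are
verified against central finite differences in the test suite.  Everything
(weight init, batch shuffling, dropout) is driven by one seeded Generator, so
training is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.signal import fftconvolve

from .preprocess import SegmentDataset


@dataclass(frozen=True)
class CNNConfig:
    """Architecture and training hyper-parameters.

    ``temporal_kernel`` defaults to fs/2 samples.  ``f1`` temporal filters,
    ``depth`` spatial filters per temporal filter, ``f2`` pointwise filters.
    """

    fs: float = 128.0
    temporal_kernel: int | None = None
    f1: int = 8
    depth: int = 2
    f2: int = 16
    sep_kernel: int = 16
    pool1: int = 4
    pool2: int = 8
    dropout: float = 0.5
    max_norm: float = 1.0
    dense_max_norm: float = 0.25
    n_classes: int = 2
    epochs: int = 200
    batch_size: int = 16
    lr: float = 1e-3
    dtype: str = "float32"

    @property
    def kernel_len(self) -> int:
        return int(self.fs // 2) if self.temporal_kernel is None else self.temporal_kernel

    @classmethod
    def tiny(cls, fs: float = 128.0, epochs: int = 30, **kw) -> "CNNConfig":
        """Desk-scale profile for fast experiments and CI."""
        return cls(fs=fs, f1=4, depth=2, f2=8, epochs=epochs, batch_size=32, **kw)


@dataclass
class TrainReport:
    train_accuracy: list[float]
    val_accuracy: list[float]
    best_epoch: int
    test_accuracy: float | None = None


# ---------------------------------------------------------------------------
# conv primitives ("same" padding along the last axis)
# ---------------------------------------------------------------------------

def _pad_lr(k: int) -> tuple[int, int]:
    return (k - 1) // 2, k - 1 - (k - 1) // 2


def _conv_temporal_fw(x: np.ndarray, w: np.ndarray) -> np.ndarray:
    # x (N, C, T), w (F, K) -> (N, F, C, T); FFT cross-correlation, "same" pad
    k = w.shape[1]
    pl, _ = _pad_lr(k)
    t = x.shape[-1]
    full = fftconvolve(x[:, None, :, :], w[None, :, None, ::-1], axes=3)
    out = full[..., k - 1 - pl:k - 1 - pl + t]
    return np.ascontiguousarray(out, dtype=x.dtype)


def _conv_temporal_bw(x: np.ndarray, w: np.ndarray, dout: np.ndarray):
    k = w.shape[1]
    pl, pr = _pad_lr(k)
    t = x.shape[-1]
    xp = np.pad(x, ((0, 0), (0, 0), (pl, pr)))
    # dW[f, k] = sum_{n,c,t} dout[n,f,c,t] * xp[n,c,t+k]
    corr = fftconvolve(xp[:, None, :, :], dout[..., ::-1], axes=3)
    dw = corr[..., t - 1:t - 1 + k].sum(axis=(0, 2)).astype(w.dtype)
    # dx: full convolution of dout with the kernel, summed over filters
    dxfull = fftconvolve(dout, w[None, :, None, :], axes=3).sum(axis=1)
    return dxfull[:, :, pl:pl + t].astype(x.dtype), dw


def _conv_depthwise_fw(x: np.ndarray, w: np.ndarray) -> np.ndarray:
    # x (N, M, T), w (M, K) -> (N, M, T); per-map temporal conv
    k = w.shape[1]
    pl, pr = _pad_lr(k)
    xp = np.pad(x, ((0, 0), (0, 0), (pl, pr)))
    win = sliding_window_view(xp, k, axis=-1)          # (N, M, T, K)
    return np.einsum("nmtk,mk->nmt", win, w, optimize=True)


def _conv_depthwise_bw(x: np.ndarray, w: np.ndarray, dout: np.ndarray):
    k = w.shape[1]
    pl, pr = _pad_lr(k)
    xp = np.pad(x, ((0, 0), (0, 0), (pl, pr)))
    win = sliding_window_view(xp, k, axis=-1)
    dw = np.einsum("nmtk,nmt->mk", win, dout, optimize=True)
    dpad = np.pad(dout, ((0, 0), (0, 0), (k - 1, k - 1)))
    dwin = sliding_window_view(dpad, k, axis=-1)
    dxfull = np.einsum("nmtk,mk->nmt", dwin, w[:, ::-1], optimize=True)
    t = x.shape[-1]
    return dxfull[:, :, pl:pl + t], dw


def _elu(x: np.ndarray) -> np.ndarray:
    return np.where(x > 0, x, np.expm1(np.clip(x, None, 0.0)))


def _elu_grad(y: np.ndarray, x: np.ndarray) -> np.ndarray:
    return np.where(x > 0, 1.0, y + 1.0)


def _avgpool_fw(x: np.ndarray, p: int) -> np.ndarray:
    t = (x.shape[-1] // p) * p
    return x[..., :t].reshape(*x.shape[:-1], t // p, p).mean(axis=-1)


def _avgpool_bw(dout: np.ndarray, p: int, t_in: int) -> np.ndarray:
    dx = np.zeros((*dout.shape[:-1], t_in), dtype=dout.dtype)
    t = dout.shape[-1] * p
    dx[..., :t] = np.repeat(dout / p, p, axis=-1)
    return dx


class _BatchNorm:
    """Per-feature-map batch normalization with running statistics."""

    def __init__(self, n_maps: int, dtype, eps: float = 1e-5, momentum: float = 0.1):
        self.gamma = np.ones(n_maps, dtype=dtype)
        self.beta = np.zeros(n_maps, dtype=dtype)
        self.run_mean = np.zeros(n_maps, dtype=dtype)
        self.run_var = np.ones(n_maps, dtype=dtype)
        self.eps, self.momentum = eps, momentum

    def forward(self, x: np.ndarray, training: bool):
        # x (N, M, T); statistics over (N, T)
        if training:
            mu = x.mean(axis=(0, 2))
            var = x.var(axis=(0, 2))
            self.run_mean = (1 - self.momentum) * self.run_mean + self.momentum * mu
            self.run_var = (1 - self.momentum) * self.run_var + self.momentum * var
        else:
            mu, var = self.run_mean, self.run_var
        ivstd = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu[None, :, None]) * ivstd[None, :, None]
        y = self.gamma[None, :, None] * xhat + self.beta[None, :, None]
        cache = (xhat, ivstd)
        return y, cache

    def backward(self, dout: np.ndarray, cache):
        xhat, ivstd = cache
        nt = dout.shape[0] * dout.shape[2]
        dgamma = np.einsum("nmt,nmt->m", dout, xhat, optimize=True)
        dbeta = dout.sum(axis=(0, 2))
        dxhat = dout * self.gamma[None, :, None]
        dx = (ivstd[None, :, None] / nt) * (
            nt * dxhat
            - dxhat.sum(axis=(0, 2))[None, :, None]
            - xhat * dgamma[None, :, None]
        )
        return dx, dgamma, dbeta


class EEGNetModel:
    """Self-contained NumPy implementation of the compact CNN above."""

    def __init__(self, n_channels: int, n_samples: int, cfg: CNNConfig, seed: int = 0):
        if n_channels < 1:
            raise ValueError("need at least one channel")
        k1 = cfg.kernel_len
        if n_samples < k1:
            raise ValueError(f"n_samples={n_samples} shorter than temporal kernel {k1}")
        t1 = n_samples // cfg.pool1
        t2 = t1 // cfg.pool2
        if t2 < 1:
            raise ValueError("pooling chain leaves no time points")
        self.cfg = cfg
        self.n_channels, self.n_samples = n_channels, n_samples
        self.t1, self.t2 = t1, t2
        self.m = cfg.f1 * cfg.depth
        self.dtype = np.dtype(cfg.dtype)
        rng = np.random.default_rng(seed)

        def glorot(*shape):
            fan = sum(shape) / 2.0
            return rng.normal(0.0, np.sqrt(1.0 / fan), size=shape).astype(self.dtype)

        self.params: dict[str, np.ndarray] = {
            "w_temporal": glorot(cfg.f1, k1),
            "w_spatial": glorot(cfg.f1, cfg.depth, n_channels),
            "w_sep_depth": glorot(self.m, cfg.sep_kernel),
            "w_sep_point": glorot(cfg.f2, self.m),
            "w_dense": glorot(cfg.n_classes, cfg.f2 * t2),
            "b_dense": np.zeros(cfg.n_classes, dtype=self.dtype),
        }
        self.bn1 = _BatchNorm(self.m, self.dtype)
        self.bn2 = _BatchNorm(cfg.f2, self.dtype)
        self._project_max_norm()
        # per-channel standardization fitted on the training data
        self.in_mean = np.zeros((n_channels, 1), dtype=self.dtype)
        self.in_std = np.ones((n_channels, 1), dtype=self.dtype)

    # -- normalization -----------------------------------------------------
    def fit_scaler(self, X: np.ndarray) -> None:
        self.in_mean = X.mean(axis=(0, 2), keepdims=True)[0].astype(self.dtype)
        std = X.std(axis=(0, 2), keepdims=True)[0]
        self.in_std = np.where(std > 0, std, 1.0).astype(self.dtype)

    def _scale(self, X: np.ndarray) -> np.ndarray:
        return ((X - self.in_mean) / self.in_std).astype(self.dtype)

    # -- forward / backward ------------------------------------------------
    def forward(self, x: np.ndarray, training: bool = False,
                rng: np.random.Generator | None = None):
        p = self.params
        cfg = self.cfg
        cache: dict = {"x": x}
        h = _conv_temporal_fw(x, p["w_temporal"])                 # (N,F1,C,T)
        cache["h_t"] = h
        z = np.einsum("fdc,nfct->nfdt", p["w_spatial"], h, optimize=True)
        z = z.reshape(x.shape[0], self.m, self.n_samples)          # (N,M,T)
        z1, cache["bn1"] = self.bn1.forward(z, training)
        a1 = _elu(z1)
        cache["z1"], cache["a1"] = z1, a1
        if training and cfg.dropout > 0:
            mask1 = (rng.random(a1.shape) >= cfg.dropout) / (1.0 - cfg.dropout)
            a1 = a1 * mask1.astype(self.dtype)
            cache["mask1"] = mask1
        p1 = _avgpool_fw(a1, cfg.pool1)                            # (N,M,T1)
        cache["p1_in_t"] = a1.shape[-1]
        s = _conv_depthwise_fw(p1, p["w_sep_depth"])               # (N,M,T1)
        cache["p1"], cache["s"] = p1, s
        q = np.einsum("fm,nmt->nft", p["w_sep_point"], s, optimize=True)
        z2, cache["bn2"] = self.bn2.forward(q, training)
        a2 = _elu(z2)
        cache["z2"], cache["a2"] = z2, a2
        if training and cfg.dropout > 0:
            mask2 = (rng.random(a2.shape) >= cfg.dropout) / (1.0 - cfg.dropout)
            a2 = a2 * mask2.astype(self.dtype)
            cache["mask2"] = mask2
        p2 = _avgpool_fw(a2, cfg.pool2)                            # (N,F2,T2)
        cache["p2_in_t"] = a2.shape[-1]
        flat = p2.reshape(x.shape[0], -1)
        cache["flat"] = flat
        logits = flat @ p["w_dense"].T + p["b_dense"]
        return logits, cache

    def backward(self, dlogits: np.ndarray, cache) -> dict[str, np.ndarray]:
        p = self.params
        cfg = self.cfg
        g: dict[str, np.ndarray] = {}
        g["w_dense"] = dlogits.T @ cache["flat"]
        g["b_dense"] = dlogits.sum(axis=0)
        dflat = dlogits @ p["w_dense"]
        dp2 = dflat.reshape(-1, cfg.f2, self.t2)
        da2 = _avgpool_bw(dp2, cfg.pool2, cache["p2_in_t"])
        if "mask2" in cache:
            da2 = da2 * cache["mask2"]
        dz2 = da2 * _elu_grad(cache["a2"], cache["z2"])  # a2 cached pre-dropout
        dq, g["bn2_gamma"], g["bn2_beta"] = self.bn2.backward(dz2, cache["bn2"])
        g["w_sep_point"] = np.einsum("nft,nmt->fm", dq, cache["s"], optimize=True)
        ds = np.einsum("fm,nft->nmt", p["w_sep_point"], dq, optimize=True)
        dp1, g["w_sep_depth"] = _conv_depthwise_bw(cache["p1"], p["w_sep_depth"], ds)
        da1 = _avgpool_bw(dp1, cfg.pool1, cache["p1_in_t"])
        if "mask1" in cache:
            da1 = da1 * cache["mask1"]
        dz1 = da1 * _elu_grad(cache["a1"], cache["z1"])
        dz, g["bn1_gamma"], g["bn1_beta"] = self.bn1.backward(dz1, cache["bn1"])
        dzr = dz.reshape(-1, cfg.f1, cfg.depth, self.n_samples)
        g["w_spatial"] = np.einsum("nfdt,nfct->fdc", dzr, cache["h_t"], optimize=True)
        dh = np.einsum("fdc,nfdt->nfct", p["w_spatial"], dzr, optimize=True)
        _, g["w_temporal"] = _conv_temporal_bw(cache["x"], p["w_temporal"], dh)
        return g

    # -- constraints & prediction ------------------------------------------
    def _project_max_norm(self) -> None:
        cfg = self.cfg
        w = self.params["w_spatial"]
        norms = np.linalg.norm(w, axis=2, keepdims=True)
        np.divide(w, np.maximum(norms / cfg.max_norm, 1.0), out=w)
        wd = self.params["w_dense"]
        dnorms = np.linalg.norm(wd, axis=1, keepdims=True)
        np.divide(wd, np.maximum(dnorms / cfg.dense_max_norm, 1.0), out=wd)

    def predict_proba(self, X: np.ndarray, batch_size: int = 256) -> np.ndarray:
        out = []
        Xs = self._scale(np.asarray(X))
        for i in range(0, len(Xs), batch_size):
            logits, _ = self.forward(Xs[i:i + batch_size], training=False)
            out.append(_softmax(logits))
        return np.concatenate(out)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.predict_proba(X).argmax(axis=1)

    def state(self) -> dict[str, np.ndarray]:
        st = {k: v.copy() for k, v in self.params.items()}
        for name, bn in (("bn1", self.bn1), ("bn2", self.bn2)):
            st[f"{name}_gamma"] = bn.gamma.copy()
            st[f"{name}_beta"] = bn.beta.copy()
            st[f"{name}_rm"] = bn.run_mean.copy()
            st[f"{name}_rv"] = bn.run_var.copy()
        return st

    def load_state(self, st: dict[str, np.ndarray]) -> None:
        for k in self.params:
            self.params[k][...] = st[k]
        for name, bn in (("bn1", self.bn1), ("bn2", self.bn2)):
            bn.gamma[...] = st[f"{name}_gamma"]
            bn.beta[...] = st[f"{name}_beta"]
            bn.run_mean[...] = st[f"{name}_rm"]
            bn.run_var[...] = st[f"{name}_rv"]


def save_checkpoint(model: EEGNetModel, path) -> None:
    """Persist weights, BN statistics and the input scaler as an .npz file."""
    st = model.state()
    st["in_mean"], st["in_std"] = model.in_mean, model.in_std
    np.savez(path, **st)


def load_checkpoint(model: EEGNetModel, path) -> EEGNetModel:
    """Restore a checkpoint into a model built with the same configuration."""
    with np.load(path) as st:
        model.in_mean = st["in_mean"]
        model.in_std = st["in_std"]
        model.load_state({k: st[k] for k in st.files if k not in ("in_mean", "in_std")})
    return model


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def build_model(n_channels: int, n_samples: int, cfg: CNNConfig, seed: int = 0) -> EEGNetModel:
    return EEGNetModel(n_channels, n_samples, cfg, seed=seed)


class _Adam:
    def __init__(self, params, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params, grads):
        self.t += 1
        corr1 = 1 - self.b1 ** self.t
        corr2 = 1 - self.b2 ** self.t
        for k, g in grads.items():
            if k not in params:
                continue
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            params[k] -= self.lr * (self.m[k] / corr1) / (np.sqrt(self.v[k] / corr2) + self.eps)


def _batches(n: int, batch_size: int, rng: np.random.Generator) -> Iterator[np.ndarray]:
    order = rng.permutation(n)
    for i in range(0, n, batch_size):
        yield order[i:i + batch_size]


def train(model: EEGNetModel, train_set: SegmentDataset, val_set: SegmentDataset,
          cfg: CNNConfig | None = None, seed: int = 0) -> TrainReport:
    """Mini-batch Adam training with best-validation-accuracy checkpointing.

    The weights of the epoch with the highest validation accuracy are restored
    into the model on return (ties resolved to the earliest such epoch).
    """
    cfg = cfg or model.cfg
    if cfg.epochs < 1:
        raise ValueError("epochs must be >= 1")
    if len(train_set) == 0 or len(val_set) == 0:
        raise ValueError("train and validation sets must be non-empty")
    if len(np.unique(train_set.y)) < 2:
        raise ValueError("training partition contains a single class")
    rng = np.random.default_rng(seed)
    model.fit_scaler(np.asarray(train_set.X, dtype=float))
    Xtr = model._scale(train_set.X)
    ytr = np.asarray(train_set.y, dtype=int)
    opt = _Adam(model.params, cfg.lr)
    adam_bn = _Adam({"bn1_gamma": model.bn1.gamma, "bn1_beta": model.bn1.beta,
                     "bn2_gamma": model.bn2.gamma, "bn2_beta": model.bn2.beta}, cfg.lr)
    bn_params = {"bn1_gamma": model.bn1.gamma, "bn1_beta": model.bn1.beta,
                 "bn2_gamma": model.bn2.gamma, "bn2_beta": model.bn2.beta}
    train_curve, val_curve = [], []
    best_val, best_epoch, best_state = -1.0, -1, None
    for epoch in range(cfg.epochs):
        correct = 0
        for idx in _batches(len(ytr), cfg.batch_size, rng):
            xb, yb = Xtr[idx], ytr[idx]
            logits, cache = model.forward(xb, training=True, rng=rng)
            probs = _softmax(logits)
            correct += int((logits.argmax(axis=1) == yb).sum())
            dlogits = probs.copy()
            dlogits[np.arange(len(yb)), yb] -= 1.0
            dlogits /= len(yb)
            grads = model.backward(dlogits.astype(model.dtype), cache)
            opt.step(model.params, grads)
            adam_bn.step(bn_params, grads)
            model._project_max_norm()
        train_curve.append(correct / len(ytr))
        val_acc = evaluate(model, val_set)
        val_curve.append(val_acc)
        if val_acc > best_val:
            best_val, best_epoch, best_state = val_acc, epoch, model.state()
    model.load_state(best_state)
    return TrainReport(train_curve, val_curve, best_epoch)


def evaluate(model: EEGNetModel, test_set: SegmentDataset) -> float:
    """Fraction of correct argmax predictions on a held-out set."""
    if len(test_set) == 0:
        raise ValueError("empty evaluation set")
    return float((model.predict(test_set.X) == test_set.y).mean())


def train_eval_masked(ds_train: SegmentDataset, ds_val: SegmentDataset,
                      ds_test: SegmentDataset, mask: np.ndarray,
                      cfg: CNNConfig, seed: int = 0) -> float:
    """Train on exactly the masked channels and return test accuracy."""
    tr = ds_train.select_channels(mask)
    va = ds_val.select_channels(mask)
    te = ds_test.select_channels(mask)
    model = build_model(tr.n_channels, tr.n_samples, cfg, seed=seed)
    train(model, tr, va, cfg, seed=seed)
    return evaluate(model, te)
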