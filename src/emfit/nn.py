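"""Minimal 3-D convolutional network engine in numpy.

Implements exactly what the voxel segmenter needs: 3³ convolutions (stride 1
or 2) via im2col + GEMM with hand-written backprop, nearest-neighbor
upsampling, class-weighted softmax cross-entropy, and an Adam optimizer with
reduce-on-plateau learning-rate scheduling.  Single float32 sample per pass
(volumes are large); all randomness comes from an explicit seeded generator.

Layout note: activations are (C, D, H, W) and the patch matrix is kept
channel-major, (C·27, voxels), so every GEMM runs directly on contiguous
arrays — no transposed copies, which otherwise dominate the runtime at these
sizes.  The layer set is deliberately small: a purpose-built engine for one
architecture family, not a general autodiff framework.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Conv3d", "relu", "relu_grad", "upsample2", "downsample_grad2",
           "softmax_cross_entropy", "Adam", "PlateauSchedule"]


class _BufferPool:
    """Reusable scratch arrays keyed by (name, shape).

    im2col patch matrices run to tens of MB; allocating them afresh on every
    call makes page faults, not GEMM, the dominant cost.
    """

    def __init__(self) -> None:
        self._store: dict = {}

    def get(self, name: str, shape: tuple, zero: bool = False) -> np.ndarray:
        key = (name, shape)
        buf = self._store.get(key)
        if buf is None:
            buf = np.zeros(shape, dtype=np.float32)
            self._store[key] = buf
        elif zero:
            buf.fill(0.0)
        return buf


def _out_dims(d: int, h: int, w: int, stride: int) -> tuple[int, int, int]:
    return ((d + stride - 1) // stride, (h + stride - 1) // stride,
            (w + stride - 1) // stride)


def _im2col(x: np.ndarray, stride: int, pool: _BufferPool
            ) -> tuple[np.ndarray, tuple[int, int, int]]:
    """(C, D, H, W) -> (C*27, out_voxels) patch matrix for a 3³ same-pad conv."""
    c, d, h, w = x.shape
    od, oh, ow = _out_dims(d, h, w, stride)
    xp = pool.get("xp", (c, d + 2, h + 2, w + 2))
    xp[:, 1:-1, 1:-1, 1:-1] = x
    col = pool.get("col", (c, 27, od, oh, ow))
    k = 0
    for dz in range(3):
        for dy in range(3):
            for dx in range(3):
                col[:, k] = xp[:, dz : dz + d : stride, dy : dy + h : stride,
                               dx : dx + w : stride]
                k += 1
    return col.reshape(c * 27, od * oh * ow), (od, oh, ow)


def _col2im(dcol: np.ndarray, in_shape: tuple[int, int, int, int],
            stride: int, pool: _BufferPool) -> np.ndarray:
    """Adjoint of ``_im2col``: scatter patch gradients back onto the input."""
    c, d, h, w = in_shape
    od, oh, ow = _out_dims(d, h, w, stride)
    dcol = dcol.reshape(c, 27, od, oh, ow)
    dxp = pool.get("dxp", (c, d + 2, h + 2, w + 2), zero=True)
    k = 0
    for dz in range(3):
        for dy in range(3):
            for dx in range(3):
                dxp[:, dz : dz + d : stride, dy : dy + h : stride,
                    dx : dx + w : stride] += dcol[:, k]
                k += 1
    return dxp[:, 1:-1, 1:-1, 1:-1].copy()


class Conv3d:
    """3³ convolution, same padding, stride 1 or 2 (or 1³ when kernel=1)."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator,
                 stride: int = 1, kernel: int = 3) -> None:
        if kernel not in (1, 3):
            raise ValueError("kernel must be 1 or 3")
        self.c_in, self.c_out = c_in, c_out
        self.stride, self.kernel = stride, kernel
        fan_in = c_in * kernel**3
        # He initialization for ReLU nets
        self.w = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                            size=(c_out, fan_in)).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)
        self._cache = None
        self._pool = _BufferPool()

    def forward(self, x: np.ndarray) -> np.ndarray:
        if self.kernel == 1:
            c, d, h, w = x.shape
            col = x.reshape(c, -1)
            out_shape = (d, h, w)
        else:
            col, out_shape = _im2col(x, self.stride, self._pool)
        y = self.w @ col
        y += self.b[:, None]
        self._cache = (col, x.shape)
        return y.reshape(self.c_out, *out_shape)

    def backward(self, dy: np.ndarray, need_dx: bool = True) -> np.ndarray | None:
        col, in_shape = self._cache
        dyf = dy.reshape(self.c_out, -1)
        self.dw = dyf @ col.T
        self.db = dyf.sum(axis=1)
        if not need_dx:
            return None
        dcol = self.w.T @ dyf
        if self.kernel == 1:
            return dcol.reshape(in_shape)
        return _col2im(dcol, in_shape, self.stride, self._pool)

    @property
    def params(self):
        return [self.w, self.b]

    @property
    def grads(self):
        return [self.dw, self.db]


def relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def relu_grad(dy: np.ndarray, y: np.ndarray) -> np.ndarray:
    return np.where(y > 0, dy, np.float32(0.0))


def upsample2(x: np.ndarray) -> np.ndarray:
    """Nearest-neighbor ×2 upsampling of a (C, D, H, W) volume."""
    return np.repeat(np.repeat(np.repeat(x, 2, axis=1), 2, axis=2), 2, axis=3)


def downsample_grad2(dy: np.ndarray) -> np.ndarray:
    """Adjoint of ``upsample2``: sum gradients over each 2³ block."""
    c, d, h, w = dy.shape
    return dy.reshape(c, d // 2, 2, h // 2, 2, w // 2, 2).sum(axis=(2, 4, 6))


def softmax_cross_entropy(
    logits: np.ndarray,
    labels: np.ndarray,
    class_weights: np.ndarray,
) -> tuple[float, np.ndarray, np.ndarray]:
    """Class-weighted cross entropy over voxels.

    ``logits`` is (K, D, H, W); ``labels`` is (D, H, W) integer classes.
    Returns (mean weighted loss, dlogits, per-voxel probabilities).
    """
    k = logits.shape[0]
    flat = logits.reshape(k, -1).astype(np.float32)
    flat = flat - flat.max(axis=0)
    e = np.exp(flat)
    p = e / e.sum(axis=0)
    lab = labels.reshape(-1)
    cols = np.arange(lab.size)
    w = class_weights.astype(np.float64)[lab]
    wsum = w.sum()
    nll = -np.log(np.maximum(p[lab, cols], 1e-12).astype(np.float64))
    loss = float((w * nll).sum() / wsum)
    dflat = p.copy()
    dflat[lab, cols] -= 1.0
    dflat *= (w / wsum).astype(np.float32)
    return loss, dflat.reshape(logits.shape), p.reshape(logits.shape)


class Adam:
    """Adam with per-parameter moment buffers."""

    def __init__(self, params: list[np.ndarray], lr: float = 5e-4,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8) -> None:
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.beta1
            m += (1 - self.beta1) * g
            v *= self.beta2
            v += (1 - self.beta2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


class PlateauSchedule:
    """Halve the learning rate when validation loss stops improving."""

    def __init__(self, lr_init: float, lr_min: float,
                 factor: float = 0.5, patience: int = 5) -> None:
        self.lr = lr_init
        self.lr_min = lr_min
        self.factor = factor
        self.patience = patience
        self.best = np.inf
        self.bad_epochs = 0

    def step(self, valid_loss: float) -> float:
        """Record a validation loss; return the learning rate to use next."""
        if valid_loss < self.best - 1e-6:
            self.best = valid_loss
            self.bad_epochs = 0
        else:
            self.bad_epochs += 1
            if self.bad_epochs > self.patience:
                self.lr = max(self.lr * self.factor, self.lr_min)
                self.bad_epochs = 0
        return self.lr
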