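"""Minimal neural-network core: numpy layers with explicit backpropagation.

All tensors are ``float32`` arrays laid out ``(batch, channels, H, W)``; for
skeleton clips ``H`` is time and ``W`` is joints, for EEG epochs ``H`` is the
electrode axis and ``W`` is time.  Each layer caches what its backward pass
needs during ``forward`` and therefore supports exactly one in-flight
forward/backward pair, which is all sequential training requires.

Only the operations the gait and EEG networks use are provided: 2-D
convolutions whose kernels extend along a single axis, batch normalization,
elementwise nonlinearities, dropout, global pooling, an affine head, and a
momentum SGD optimizer with softmax cross-entropy.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import scipy.fft as _fft

F32 = np.float32


class Param:
    """A learnable array with an accumulated gradient."""

    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = "") -> None:
        self.value = np.asarray(value, dtype=F32)
        self.grad = np.zeros_like(self.value)
        self.name = name

    @property
    def size(self) -> int:
        return int(self.value.size)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Param({self.name}, shape={self.value.shape})"


class Layer:
    """Interface: ``forward(x, train)`` then ``backward(gy)``."""

    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, gy: np.ndarray) -> np.ndarray:
        raise NotImplementedError


def he_normal(rng: np.random.Generator, shape: tuple, fan_in: int) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(F32)


def parameter_count(params: Iterable[Param]) -> int:
    """Total number of learnable scalars."""
    return int(sum(p.size for p in params))


# ---------------------------------------------------------------------------
# convolution
# ---------------------------------------------------------------------------


def _pad_amounts(size: int, k: int, s: int, padding: str) -> tuple[int, int, int]:
    """(pad_before, pad_after, out_size) for one axis."""
    if padding == "same":
        out = -(-size // s)
        total = max((out - 1) * s + k - size, 0)
        return total // 2, total - total // 2, out
    if k > size:
        raise ValueError(f"kernel {k} larger than input extent {size}")
    return 0, 0, (size - k) // s + 1


class Conv2d(Layer):
    """2-D convolution (cross-correlation) with 'same' or 'valid' padding.

    Short kernels run as a sum over kernel taps (one GEMM per tap).  Long
    one-dimensional kernels — the 33-sample temporal filters of the EEG
    network, or the 15-electrode spatial filter — are evaluated in the
    frequency domain, which avoids materializing every shifted copy of the
    input.  Both paths compute the identical cross-correlation.
    """

    _FFT_MIN_TAPS = 8

    def __init__(
        self,
        in_ch: int,
        out_ch: int,
        kernel: tuple[int, int],
        stride: tuple[int, int] = (1, 1),
        padding: str = "same",
        rng: np.random.Generator | None = None,
        bias: bool = True,
        name: str = "conv",
    ) -> None:
        if padding not in ("same", "valid"):
            raise ValueError(f"unknown padding {padding!r}")
        kh, kw = kernel
        rng = rng if rng is not None else np.random.default_rng(0)
        self.in_ch, self.out_ch = in_ch, out_ch
        self.kernel = (kh, kw)
        self.stride = stride
        self.padding = padding
        self.W = Param(he_normal(rng, (out_ch, in_ch, kh, kw), in_ch * kh * kw), f"{name}.W")
        self.b = Param(np.zeros(out_ch), f"{name}.b") if bias else None
        self._cache: tuple | None = None

    def params(self) -> list[Param]:
        return [self.W] + ([self.b] if self.b is not None else [])

    def _fft_axis(self) -> int | None:
        """Axis (2 or 3) eligible for the frequency-domain path, else None.

        Worthwhile only for long 1-D kernels with few channel pairs: the
        spectral channel contraction loops over in/out channel pairs.
        """
        if self.in_ch * self.out_ch > 256:
            return None
        kh, kw = self.kernel
        if kw == 1 and kh >= self._FFT_MIN_TAPS and self.stride[1] == 1:
            return 2
        if kh == 1 and kw >= self._FFT_MIN_TAPS and self.stride[0] == 1:
            return 3
        return None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        x = np.ascontiguousarray(x, dtype=F32)
        B, C, H, W = x.shape
        if C != self.in_ch:
            raise ValueError(f"expected {self.in_ch} input channels, got {C}")
        kh, kw = self.kernel
        sh, sw = self.stride
        ph0, ph1, Ho = _pad_amounts(H, kh, sh, self.padding)
        pw0, pw1, Wo = _pad_amounts(W, kw, sw, self.padding)
        if ph0 or ph1 or pw0 or pw1:
            xp = np.pad(x, ((0, 0), (0, 0), (ph0, ph1), (pw0, pw1)))
        else:
            xp = x
        axis = self._fft_axis()
        if axis is not None:
            y = self._forward_fft(xp, axis, (B, C, H, W), (Ho, Wo), (ph0, pw0))
        else:
            y = np.zeros((B, self.out_ch, Ho, Wo), dtype=F32)
            Wv = self.W.value
            for i in range(kh):
                for j in range(kw):
                    xs = xp[:, :, i : i + sh * Ho : sh, j : j + sw * Wo : sw]
                    y += np.tensordot(Wv[:, :, i, j], xs, axes=(1, 1)).transpose(1, 0, 2, 3)
            self._cache = ("taps", xp, (B, C, H, W), (Ho, Wo), (ph0, pw0))
        if self.b is not None:
            y += self.b.value[None, :, None, None]
        return y

    def backward(self, gy: np.ndarray) -> np.ndarray:
        gy = np.ascontiguousarray(gy, dtype=F32)
        if self.b is not None:
            self.b.grad += gy.sum(axis=(0, 2, 3))
        if self._cache[0] == "fft":
            return self._backward_fft(gy)
        _, xp, (B, C, H, W), (Ho, Wo), (ph0, pw0) = self._cache
        kh, kw = self.kernel
        sh, sw = self.stride
        Wv = self.W.value
        gxp = np.zeros_like(xp)
        for i in range(kh):
            for j in range(kw):
                xs = xp[:, :, i : i + sh * Ho : sh, j : j + sw * Wo : sw]
                self.W.grad[:, :, i, j] += np.tensordot(gy, xs, axes=([0, 2, 3], [0, 2, 3]))
                gxp[:, :, i : i + sh * Ho : sh, j : j + sw * Wo : sw] += np.tensordot(
                    gy, Wv[:, :, i, j], axes=(1, 0)
                ).transpose(0, 3, 1, 2)
        return gxp[:, :, ph0 : ph0 + H, pw0 : pw0 + W]

    # -- frequency-domain path -------------------------------------------
    #
    # For a 1-D kernel w of K taps along one axis, the cross-correlation
    # y[t] = sum_k w[k] x[t + k] equals irfft(rfft(x) * conj(rfft(w))) as
    # long as the transform length covers padded-input + K - 1 samples,
    # so the circular wrap lands on zero-padding only.  Transforms run along
    # the conv axis in the native (B, C, H, W) layout; the channel
    # contraction is an explicit loop over (out, in) pairs of broadcast
    # multiplies, which beats any transpose-heavy batched GEMM for the
    # small channel counts this path is gated to.

    def _kernel_1d(self, n: int, axis: int) -> np.ndarray:
        w = self.W.value[:, :, :, 0] if axis == 2 else self.W.value[:, :, 0, :]
        return _fft.rfft(w, n=n, axis=-1)  # (Co, Ci, F)

    @staticmethod
    def _bcast(wf_oi: np.ndarray, axis: int) -> np.ndarray:
        # shape a (F,) spectrum for broadcasting over (B, H_f, W) or (B, H, W_f)
        return wf_oi[:, None] if axis == 2 else wf_oi[None, :]

    def _forward_fft(self, xp, axis, in_shape, out_hw, pads):
        kh, kw = self.kernel
        K = kh if axis == 2 else kw
        s = self.stride[0] if axis == 2 else self.stride[1]
        Lo = out_hw[0] if axis == 2 else out_hw[1]
        Lp = xp.shape[axis]
        B = xp.shape[0]
        n = _fft.next_fast_len(Lp + K - 1)
        Xf = _fft.rfft(xp, n=n, axis=axis)  # (B, Ci, ., .) complex64
        Wf = self._kernel_1d(n, axis).conj()
        Zf = np.empty((B, self.out_ch) + Xf.shape[2:], dtype=Xf.dtype)
        for o in range(self.out_ch):
            acc = Xf[:, 0] * self._bcast(Wf[o, 0], axis)
            for i in range(1, self.in_ch):
                acc += Xf[:, i] * self._bcast(Wf[o, i], axis)
            Zf[:, o] = acc
        z = _fft.irfft(Zf, n=n, axis=axis)
        sl = [slice(None)] * 4
        sl[axis] = slice(0, s * Lo, s)
        y = np.ascontiguousarray(z[tuple(sl)], dtype=F32)
        self._cache = ("fft", Xf, (n, K, s, Lo, Lp, axis), in_shape, pads)
        return y

    def _backward_fft(self, gy: np.ndarray) -> np.ndarray:
        _, Xf, (n, K, s, Lo, Lp, axis), in_shape, pads = self._cache
        _, C, H, W = in_shape
        up_shape = list(gy.shape)
        up_shape[axis] = Lp
        up = np.zeros(up_shape, dtype=F32)
        sl = [slice(None)] * 4
        sl[axis] = slice(0, s * Lo, s)
        up[tuple(sl)] = gy
        Gf = _fft.rfft(up, n=n, axis=axis)  # (B, Co, ., .)
        Wf = self._kernel_1d(n, axis)
        # within a (B, H, W) channel slice the transformed axis sits at
        # position axis-1; sum the other two out
        sum_axes = (0, 1) if axis == 3 else (0, 2)
        # weight gradient: gW[o,i,k] = irfft(sum_b,other Xf[:,i] conj(Gf[:,o]))[k]
        gWf = np.empty((self.out_ch, self.in_ch, Xf.shape[axis]), dtype=Xf.dtype)
        for o in range(self.out_ch):
            Gconj = Gf[:, o].conj()
            for i in range(self.in_ch):
                gWf[o, i] = (Xf[:, i] * Gconj).sum(axis=sum_axes)
        gw = _fft.irfft(gWf, n=n, axis=-1)[..., :K]
        if axis == 2:
            self.W.grad += gw[:, :, :, None]
        else:
            self.W.grad += gw[:, :, None, :]
        # input gradient: convolve (not correlate) the grad with the kernel
        gXf = np.empty((Gf.shape[0], self.in_ch) + Gf.shape[2:], dtype=Gf.dtype)
        for i in range(self.in_ch):
            acc = Gf[:, 0] * self._bcast(Wf[0, i], axis)
            for o in range(1, self.out_ch):
                acc += Gf[:, o] * self._bcast(Wf[o, i], axis)
            gXf[:, i] = acc
        gxp = _fft.irfft(gXf, n=n, axis=axis)
        ph0, pw0 = pads
        return np.ascontiguousarray(
            gxp[:, :, ph0 : ph0 + H, pw0 : pw0 + W], dtype=F32
        )


# ---------------------------------------------------------------------------
# normalization, nonlinearities, dropout
# ---------------------------------------------------------------------------


class BatchNorm2d(Layer):
    """Per-channel batch statistics over (batch, H, W) with running averages."""

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5, name: str = "bn") -> None:
        self.gamma = Param(np.ones(channels), f"{name}.gamma")
        self.beta = Param(np.zeros(channels), f"{name}.beta")
        self.running_mean = np.zeros(channels, dtype=F32)
        self.running_var = np.ones(channels, dtype=F32)
        self.momentum = momentum
        self.eps = eps
        self._cache: tuple | None = None

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        x = np.asarray(x, dtype=F32)
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv_std[None, :, None, None]
        self._cache = (xhat, inv_std, train)
        return self.gamma.value[None, :, None, None] * xhat + self.beta.value[None, :, None, None]

    def backward(self, gy: np.ndarray) -> np.ndarray:
        xhat, inv_std, trained = self._cache
        gy = np.asarray(gy, dtype=F32)
        self.gamma.grad += (gy * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += gy.sum(axis=(0, 2, 3))
        g = self.gamma.value[None, :, None, None] * inv_std[None, :, None, None]
        if not trained:
            return gy * g
        n = gy.shape[0] * gy.shape[2] * gy.shape[3]
        sum_gy = gy.sum(axis=(0, 2, 3), keepdims=True)
        sum_gy_xhat = (gy * xhat).sum(axis=(0, 2, 3), keepdims=True)
        return g * (gy - sum_gy / n - xhat * sum_gy_xhat / n)


class ReLU(Layer):
    def forward(self, x, train=False):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0).astype(F32)

    def backward(self, gy):
        return (gy * self._mask).astype(F32)


class ELU(Layer):
    """Exponential linear unit with alpha = 1."""

    def forward(self, x, train=False):
        x = np.asarray(x, dtype=F32)
        neg = np.expm1(np.minimum(x, 0.0), dtype=F32)
        self._cache = (x > 0, neg)
        return np.where(x > 0, x, neg)

    def backward(self, gy):
        pos, neg = self._cache
        return (gy * np.where(pos, 1.0, neg + 1.0)).astype(F32)


class Sigmoid(Layer):
    def forward(self, x, train=False):
        out = 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=F32)))
        self._out = out
        return out

    def backward(self, gy):
        return (gy * self._out * (1.0 - self._out)).astype(F32)


class Dropout(Layer):
    """Inverted dropout; identity when evaluating or when p == 0."""

    def __init__(self, p: float, rng: np.random.Generator) -> None:
        self.p = float(p)
        self.rng = rng
        self._mask: np.ndarray | None = None

    def forward(self, x, train=False):
        if not train or self.p <= 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.p
        self._mask = (self.rng.random(x.shape) < keep).astype(F32) / keep
        return x * self._mask

    def backward(self, gy):
        if self._mask is None:
            return gy
        return gy * self._mask


# ---------------------------------------------------------------------------
# pooling / reshaping / affine
# ---------------------------------------------------------------------------


class GlobalAvgPool(Layer):
    """(B, C, H, W) -> (B, C) by averaging the spatial axes."""

    def forward(self, x, train=False):
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, gy):
        B, C, H, W = self._shape
        return np.broadcast_to(gy[:, :, None, None] / (H * W), self._shape).astype(F32)


class Flatten(Layer):
    def forward(self, x, train=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, gy):
        return gy.reshape(self._shape)


class Linear(Layer):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator | None = None, name: str = "fc") -> None:
        rng = rng if rng is not None else np.random.default_rng(0)
        self.W = Param(he_normal(rng, (out_dim, in_dim), in_dim), f"{name}.W")
        self.b = Param(np.zeros(out_dim), f"{name}.b")

    def params(self):
        return [self.W, self.b]

    def forward(self, x, train=False):
        x = np.ascontiguousarray(x, dtype=F32)
        self._x = x
        return x @ self.W.value.T + self.b.value

    def backward(self, gy):
        gy = np.asarray(gy, dtype=F32)
        self.W.grad += gy.T @ self._x
        self.b.grad += gy.sum(axis=0)
        return gy @ self.W.value


class UpsampleH(Layer):
    """Nearest-neighbor repetition along the H axis by an integer factor."""

    def __init__(self, factor: int) -> None:
        self.factor = int(factor)

    def forward(self, x, train=False):
        return np.repeat(x, self.factor, axis=2)

    def backward(self, gy):
        B, C, Hf, W = gy.shape
        return gy.reshape(B, C, Hf // self.factor, self.factor, W).sum(axis=3)


class CropH(Layer):
    """Crop the H axis down to a target length (backward zero-pads)."""

    def __init__(self, target: int) -> None:
        self.target = int(target)

    def forward(self, x, train=False):
        self._full = x.shape[2]
        return x[:, :, : self.target, :]

    def backward(self, gy):
        pad = self._full - gy.shape[2]
        if pad == 0:
            return gy
        return np.pad(gy, ((0, 0), (0, 0), (0, pad), (0, 0)))


class Sequential(Layer):
    def __init__(self, layers: Sequence[Layer]) -> None:
        self.layers = list(layers)

    def params(self):
        out: list[Param] = []
        for layer in self.layers:
            out.extend(layer.params())
        return out

    def forward(self, x, train=False):
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, gy):
        for layer in reversed(self.layers):
            gy = layer.backward(gy)
        return gy


# ---------------------------------------------------------------------------
# loss and optimizer
# ---------------------------------------------------------------------------


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(
    logits: np.ndarray,
    labels: np.ndarray,
    class_weights: np.ndarray | None = None,
) -> tuple[float, np.ndarray, np.ndarray]:
    """Mean cross-entropy; returns (loss, probabilities, dloss/dlogits)."""
    probs = softmax(np.asarray(logits, dtype=np.float64))
    n = logits.shape[0]
    idx = np.arange(n)
    logp = -np.log(np.maximum(probs[idx, labels], 1e-12))
    if class_weights is None:
        w = np.ones(n)
    else:
        w = np.asarray(class_weights, dtype=np.float64)[labels]
    wsum = w.sum()
    loss = float((w * logp).sum() / wsum)
    grad = probs.copy()
    grad[idx, labels] -= 1.0
    grad *= (w / wsum)[:, None]
    return loss, probs.astype(F32), grad.astype(F32)


class SGD:
    """Stochastic gradient descent with classical momentum."""

    def __init__(self, params: Sequence[Param], lr: float, momentum: float = 0.9) -> None:
        self.params = list(params)
        self.lr = float(lr)
        self.momentum = float(momentum)
        self._velocity = [np.zeros_like(p.value) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0

    def step(self) -> None:
        for p, v in zip(self.params, self._velocity):
            v *= self.momentum
            v -= self.lr * p.grad
            p.value += v
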