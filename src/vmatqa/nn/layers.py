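"""Neural-network layers on the autograd core: linear, layer norm, dropout,
2-D convolution and pooling, 1-D convolution/max-pooling (sequence
distilling), and a stacked LSTM."""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, cat, make_op


class Module:
    """Parameter container with recursive collection."""

    def parameters(self) -> dict[str, Tensor]:
        out: dict[str, Tensor] = {}
        for name, val in vars(self).items():
            if isinstance(val, Tensor) and val.requires_grad:
                out[name] = val
            elif isinstance(val, Module):
                for k, v in val.parameters().items():
                    out[f"{name}.{k}"] = v
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        for k, v in item.parameters().items():
                            out[f"{name}.{i}.{k}"] = v
        return out

    def zero_grad(self) -> None:
        for p in self.parameters().values():
            p.grad = None


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int, shape) -> np.ndarray:
    lim = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-lim, lim, size=shape)


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.w = Tensor(_glorot(rng, n_in, n_out, (n_in, n_out)), requires_grad=True)
        self.b = Tensor(np.zeros(n_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        # flatten leading dims so the matmul is a single 2-D GEMM
        if x.ndim > 2:
            lead = x.shape[:-1]
            out = x.reshape(-1, x.shape[-1]) @ self.w + self.b
            return out.reshape(*lead, self.w.shape[1])
        return x @ self.w + self.b


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(dim), requires_grad=True)
        self.beta = Tensor(np.zeros(dim), requires_grad=True)
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        return xc * (var + self.eps).pow(-0.5) * self.gamma + self.beta


class Dropout(Module):
    """Inverted dropout; identity in eval mode."""

    def __init__(self, p: float):
        self.p = p

    def __call__(self, x: Tensor, rng: np.random.Generator | None,
                 training: bool) -> Tensor:
        if not training or self.p <= 0 or rng is None:
            return x
        mask = (rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * Tensor(mask)


class Conv2d(Module):
    """Same-padded 2-D convolution via im2col; input (B, C, H, W)."""

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator):
        fan_in = c_in * kernel * kernel
        self.w = Tensor(_glorot(rng, fan_in, c_out, (c_out, c_in, kernel, kernel)),
                        requires_grad=True)
        self.b = Tensor(np.zeros(c_out), requires_grad=True)
        self.k = kernel

    def __call__(self, x: Tensor) -> Tensor:
        k = self.k
        pad = k // 2
        B, C, H, W = x.shape
        xp = np.pad(x.data, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
        win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
        # win: (B, C, H, W, k, k) -> cols (B, H, W, C*k*k)
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(B, H, W, C * k * k)
        wmat = self.w.data.reshape(self.w.shape[0], -1)  # (O, C*k*k)
        out_data = cols @ wmat.T + self.b.data  # (B, H, W, O)
        out_data = out_data.transpose(0, 3, 1, 2)

        x_t, w_t, b_t = x, self.w, self.b

        def backward(g):  # g: (B, O, H, W)
            gh = g.transpose(0, 2, 3, 1)  # (B, H, W, O)
            if b_t.requires_grad:
                b_t._acc(gh.sum(axis=(0, 1, 2)))
            if w_t.requires_grad:
                gw = np.einsum("bhwo,bhwc->oc", gh, cols)
                w_t._acc(gw.reshape(w_t.shape))
            if x_t.requires_grad:
                gcols = gh @ wmat  # (B, H, W, C*k*k)
                gcols = gcols.reshape(B, H, W, C, k, k)
                gxp = np.zeros_like(xp)
                for di in range(k):
                    for dj in range(k):
                        gxp[:, :, di:di + H, dj:dj + W] += gcols[:, :, :, :, di, dj].transpose(0, 3, 1, 2)
                x_t._acc(gxp[:, :, pad:pad + H, pad:pad + W])

        return make_op(out_data, (x, self.w, self.b), backward)


def avg_pool2d(x: Tensor, k: int = 2) -> Tensor:
    """Non-overlapping average pooling with floor truncation; (B, C, H, W).
    Identity when the spatial extent is already below the kernel."""
    B, C, H, W = x.shape
    if H < k or W < k:
        return x
    Hk, Wk = (H // k) * k, (W // k) * k
    xc = x[:, :, :Hk, :Wk]
    xr = xc.reshape(B, C, Hk // k, k, Wk // k, k)
    return xr.mean(axis=5).mean(axis=3)


def conv1d_same(x: Tensor, lin: Linear) -> Tensor:
    """Kernel-3 same-padded 1-D convolution over axis 1 of (B, L, D),
    expressed as a linear map on the unfolded [x_{t-1}, x_t, x_{t+1}]."""
    B, L, D = x.shape
    zero = Tensor(np.zeros((B, 1, D)))
    left = cat([zero, x[:, :-1, :]], axis=1)
    right = cat([x[:, 1:, :], zero], axis=1)
    return lin(cat([left, x, right], axis=2))


def max_pool1d(x: Tensor, kernel: int = 3, stride: int = 2, pad: int = 1) -> Tensor:
    """Max pooling over axis 1 of (B, L, D); L_out = ceil(L / stride)."""
    B, L, D = x.shape
    xp = np.pad(x.data, ((0, 0), (pad, pad), (0, 0)),
                constant_values=-np.inf)
    starts = np.arange(0, L + 2 * pad - kernel + 1, stride)
    win = np.stack([xp[:, s:s + kernel, :] for s in starts], axis=1)  # (B,Lo,k,D)
    arg = win.argmax(axis=2)  # (B, Lo, D)
    out_data = np.take_along_axis(win, arg[:, :, None, :], axis=2)[:, :, 0, :]

    def backward(g):  # (B, Lo, D)
        if not x.requires_grad:
            return
        gxp = np.zeros((B, L + 2 * pad, D))
        bi, di = np.meshgrid(np.arange(B), np.arange(D), indexing="ij")
        for j, s in enumerate(starts):
            pos = s + arg[:, j, :]  # (B, D)
            np.add.at(gxp, (bi, pos, di), g[:, j, :])
        x._acc(gxp[:, pad:pad + L, :])

    return make_op(out_data, (x,), backward)


class LSTM(Module):
    """Stacked LSTM; input (B, L, D), returns the last hidden state of the
    top layer, shape (B, H)."""

    def __init__(self, n_in: int, hidden: int, n_layers: int,
                 rng: np.random.Generator):
        self.hidden = hidden
        self.cells = [
            _LSTMCell(n_in if i == 0 else hidden, hidden, rng)
            for i in range(n_layers)
        ]

    def __call__(self, x: Tensor) -> Tensor:
        B, L, _ = x.shape
        seq = [x[:, t, :] for t in range(L)]
        for cell in self.cells:
            h = Tensor(np.zeros((B, cell.hidden)))
            c = Tensor(np.zeros((B, cell.hidden)))
            outs = []
            for t in range(L):
                h, c = cell(seq[t], h, c)
                outs.append(h)
            seq = outs
        return seq[-1]


class _LSTMCell(Module):
    def __init__(self, n_in: int, hidden: int, rng: np.random.Generator):
        self.hidden = hidden
        self.lin = Linear(n_in + hidden, 4 * hidden, rng)
        # forget-gate bias of 1 for stable early training
        self.lin.b.data[hidden:2 * hidden] = 1.0

    def __call__(self, x: Tensor, h: Tensor, c: Tensor):
        z = self.lin(cat([x, h], axis=1))
        H = self.hidden
        i = z[:, :H].sigmoid()
        f = z[:, H:2 * H].sigmoid()
        g = z[:, 2 * H:3 * H].tanh()
        o = z[:, 3 * H:].sigmoid()
        c_new = f * c + i * g
        return o * c_new.tanh(), c_new
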