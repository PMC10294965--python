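"""Neural-network building blocks on the autodiff tape.

Recurrent and convolutional layers are implemented as *fused* tape
primitives: the forward pass caches intermediate activations and the
backward closure runs the hand-derived adjoint recursion in vectorized
numpy.  This keeps the tape shallow (one node per layer instead of one per
timestep), which matters for CPU training of back-propagation-through-time.
All adjoints are checked against central finite differences in the tests.
"""

from __future__ import annotations

import numpy as np

from ._autodiff import Tensor, _grad_enabled

__all__ = ["Linear", "GRULayer", "gru", "Conv1d", "Adam", "cross_entropy", "init_rng"]


def init_rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)


def _uniform(rng, shape, scale):
    return rng.uniform(-scale, scale, size=shape)


class Linear:
    """Affine map y = x W + b with Glorot-uniform init."""

    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        s = np.sqrt(6.0 / (d_in + d_out))
        self.W = Tensor(_uniform(rng, (d_in, d_out), s), requires_grad=True)
        self.b = Tensor(np.zeros(d_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b

    @property
    def params(self):
        return [self.W, self.b]


def _sigmoid(x):
    return 0.5 * (1.0 + np.tanh(0.5 * x))


class GRULayer:
    """One direction of a gated recurrent unit layer.

    Gate layout in the packed matrices is (reset, update, candidate).
    ``b`` is the input-side bias (3H); ``bh`` the hidden-side bias of the
    candidate gate (H), matching the standard GRU parameterization where
    the reset gate multiplies the *hidden* contribution of the candidate.
    """

    def __init__(self, d_in: int, hidden: int, rng: np.random.Generator):
        s_in = np.sqrt(6.0 / (d_in + hidden))
        s_h = np.sqrt(6.0 / (2 * hidden))
        self.W = Tensor(_uniform(rng, (d_in, 3 * hidden), s_in), requires_grad=True)
        self.U = Tensor(_uniform(rng, (hidden, 3 * hidden), s_h), requires_grad=True)
        self.b = Tensor(np.zeros(3 * hidden), requires_grad=True)
        self.bh = Tensor(np.zeros(hidden), requires_grad=True)
        self.hidden = hidden

    @property
    def params(self):
        return [self.W, self.U, self.b, self.bh]


def gru(x: Tensor, layer: GRULayer, h0: Tensor | None = None,
        reverse: bool = False) -> Tensor:
    """Run a GRU over ``x`` (B, T, D) -> hidden sequence (B, T, H).

    Fused primitive: forward caches gate activations, backward runs the
    BPTT recursion and accumulates into W, U, b, bh, x and h0.
    """
    W, U, b, bh = layer.W, layer.U, layer.b, layer.bh
    H = layer.hidden
    xd = x.data[:, ::-1, :] if reverse else x.data
    B, T, D = xd.shape
    h_prev = np.zeros((B, H)) if h0 is None else h0.data
    # input-side contributions for all steps at once
    xw = xd.reshape(B * T, D) @ W.data + b.data
    xw = xw.reshape(B, T, 3 * H)
    hs = np.empty((B, T, H))
    cache_r = np.empty((B, T, H))
    cache_z = np.empty((B, T, H))
    cache_n = np.empty((B, T, H))
    cache_hun = np.empty((B, T, H))
    cache_hprev = np.empty((B, T, H))
    Ur, Uz, Un = U.data[:, :H], U.data[:, H:2 * H], U.data[:, 2 * H:]
    h = h_prev
    for t in range(T):
        hu = h @ U.data
        r = _sigmoid(xw[:, t, :H] + hu[:, :H])
        z = _sigmoid(xw[:, t, H:2 * H] + hu[:, H:2 * H])
        hun = hu[:, 2 * H:] + bh.data
        n = np.tanh(xw[:, t, 2 * H:] + r * hun)
        cache_hprev[:, t] = h
        h = (1.0 - z) * n + z * h
        hs[:, t] = h
        cache_r[:, t] = r
        cache_z[:, t] = z
        cache_n[:, t] = n
        cache_hun[:, t] = hun

    out_data = hs[:, ::-1, :] if reverse else hs

    parents = tuple(p for p in (x, W, U, b, bh) + ((h0,) if h0 is not None else ())
                    if p.requires_grad)
    req = _grad_enabled and bool(parents)

    def bwd(g_out):
        g = g_out[:, ::-1, :] if reverse else g_out
        dW = np.zeros_like(W.data)
        dU = np.zeros_like(U.data)
        db = np.zeros_like(b.data)
        dbh = np.zeros_like(bh.data)
        dxw = np.empty((B, T, 3 * H))
        dh = np.zeros((B, H))
        for t in range(T - 1, -1, -1):
            dh = dh + g[:, t]
            r, z, n = cache_r[:, t], cache_z[:, t], cache_n[:, t]
            hun, hp = cache_hun[:, t], cache_hprev[:, t]
            dz = dh * (hp - n)
            dpre_z = dz * z * (1.0 - z)
            dn = dh * (1.0 - z)
            dpre_n = dn * (1.0 - n * n)
            dr = dpre_n * hun
            dpre_r = dr * r * (1.0 - r)
            dhun = dpre_n * r
            dxw[:, t, :H] = dpre_r
            dxw[:, t, H:2 * H] = dpre_z
            dxw[:, t, 2 * H:] = dpre_n
            dbh += dhun.sum(axis=0)
            dU[:, :H] += hp.T @ dpre_r
            dU[:, H:2 * H] += hp.T @ dpre_z
            dU[:, 2 * H:] += hp.T @ dhun
            dh = (dh * z + dpre_r @ Ur.T + dpre_z @ Uz.T + dhun @ Un.T)
        dxw_flat = dxw.reshape(B * T, 3 * H)
        if W.requires_grad:
            dW += xd.reshape(B * T, D).T @ dxw_flat
            W._accum(dW)
        if U.requires_grad:
            U._accum(dU)
        if b.requires_grad:
            b._accum(dxw_flat.sum(axis=0) + db)
        if bh.requires_grad:
            bh._accum(dbh)
        if x.requires_grad:
            dx = (dxw_flat @ W.data.T).reshape(B, T, D)
            x._accum(dx[:, ::-1, :] if reverse else dx)
        if h0 is not None and h0.requires_grad:
            h0._accum(dh)

    return Tensor(out_data, requires_grad=req, _parents=parents,
                  _backward=bwd if req else None)


class Conv1d:
    """Dilated temporal convolution with zero 'same' padding.

    x: (B, T, D) -> (B, T, F); weight (K, D, F), kernel centered.
    """

    def __init__(self, d_in: int, d_out: int, kernel: int, dilation: int,
                 rng: np.random.Generator):
        s = np.sqrt(6.0 / (kernel * d_in + d_out))
        self.W = Tensor(_uniform(rng, (kernel, d_in, d_out), s), requires_grad=True)
        self.b = Tensor(np.zeros(d_out), requires_grad=True)
        self.kernel = kernel
        self.dilation = dilation

    @property
    def params(self):
        return [self.W, self.b]

    def __call__(self, x: Tensor) -> Tensor:
        W, b = self.W, self.b
        K, d, dil = self.kernel, self.dilation, self.dilation
        B, T, D = x.data.shape
        c = K // 2
        pad = c * dil
        xp = np.zeros((B, T + 2 * pad, D))
        xp[:, pad:pad + T] = x.data
        out_data = np.broadcast_to(b.data, (B, T, W.data.shape[2])).copy()
        for k in range(K):
            off = k * dil
            out_data += xp[:, off:off + T] @ W.data[k]

        parents = tuple(p for p in (x, W, b) if p.requires_grad)
        req = _grad_enabled and bool(parents)

        def bwd(g):
            gf = g.reshape(B * T, -1)
            if b.requires_grad:
                b._accum(gf.sum(axis=0))
            dW = np.zeros_like(W.data) if W.requires_grad else None
            dxp = np.zeros_like(xp) if x.requires_grad else None
            for k in range(K):
                off = k * dil
                if dW is not None:
                    dW[k] = xp[:, off:off + T].reshape(B * T, D).T @ gf
                if dxp is not None:
                    dxp[:, off:off + T] += g @ W.data[k].T
            if dW is not None:
                W._accum(dW)
            if dxp is not None:
                x._accum(dxp[:, pad:pad + T])

        return Tensor(out_data, requires_grad=req, _parents=parents,
                      _backward=bwd if req else None)


def cross_entropy(logits: Tensor, targets: np.ndarray,
                  weights: np.ndarray | None = None,
                  smoothing: float = 0.0) -> Tensor:
    """Mean (optionally class-weighted, label-smoothed) negative log-likelihood.

    logits: (N, C) tensor; targets: (N,) int array.  With smoothing s the
    per-example loss is (1-s) * NLL(target) + s * mean_c(-log p_c), which
    keeps trained softmax outputs away from saturation.
    """
    logp = logits.log_softmax(axis=-1)
    idx = (np.arange(targets.shape[0]), targets)
    nll = -logp[idx]
    if smoothing > 0.0:
        nll = (1.0 - smoothing) * nll + smoothing * (-logp).mean(axis=-1)
    if weights is not None:
        w = weights[targets]
        return (nll * w).sum() / float(w.sum())
    return nll.mean()


class Adam:
    """Adam with bias correction; state keyed by parameter identity."""

    def __init__(self, params, lr=1e-2, betas=(0.9, 0.999), eps=1e-8,
                 weight_decay=0.0):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / b1t
            vhat = self.v[i] / b2t
            if self.weight_decay:
                p.data -= self.lr * self.weight_decay * p.data   # decoupled
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
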