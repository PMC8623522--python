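"""Compact numpy neural-network primitives.

Implements exactly what the predictor needs: 1-D convolutions over the
window axis (via im2col), dense layers, a truncated bidirectional tanh-RNN,
sigmoid/binary-cross-entropy, Adam, and patience-based early stopping with
best-weight restoration. Gradients are hand-derived and verified against
numerical differentiation in the test suite.
"""

from __future__ import annotations

import numpy as np

EPS = 1e-12


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def bce_loss(p: np.ndarray, y: np.ndarray) -> float:
    p = np.clip(p, EPS, 1.0 - EPS)
    return float(-np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))


def _im2col(x: np.ndarray, width: int) -> np.ndarray:
    """(n, L, c) -> (n, L-width+1, width*c) sliding windows along axis 1."""
    n, L, c = x.shape
    out_len = L - width + 1
    windows = np.lib.stride_tricks.sliding_window_view(x, width, axis=1)
    # windows: (n, out_len, c, width) -> (n, out_len, width, c)
    return windows.transpose(0, 1, 3, 2).reshape(n, out_len, width * c)


class Adam:
    """Adam optimiser over a dict of parameter arrays (updated in place)."""

    def __init__(self, params: dict, lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, grads: dict) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k, g in grads.items():
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1 ** self.t)
            vhat = self.v[k] / (1 - b2 ** self.t)
            self.params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class EarlyStopper:
    """Patience-based stopper tracking the best validation loss.

    ``update`` returns True when the best loss has not improved for
    ``patience`` consecutive epochs; the epoch of the best loss is kept so
    the caller can restore those weights.
    """

    def __init__(self, patience: int = 10, min_delta: float = 0.0):
        if patience < 1:
            raise ValueError("patience must be >= 1")
        self.patience = patience
        self.min_delta = min_delta
        self.best_loss = np.inf
        self.best_epoch = -1
        self.epochs_since_best = 0
        self.epoch = -1

    def update(self, loss: float) -> bool:
        self.epoch += 1
        if loss < self.best_loss - self.min_delta:
            self.best_loss = loss
            self.best_epoch = self.epoch
            self.epochs_since_best = 0
        else:
            self.epochs_since_best += 1
        return self.epochs_since_best >= self.patience


# ---------------------------------------------------------------------------
# window convolution net


def init_convnet(window: int, n_features: int, channels=(32, 16),
                 kernel: int = 3, rng: np.random.Generator | None = None) -> dict:
    """He-initialised parameters for the two-conv + dense window scorer."""
    rng = rng if rng is not None else np.random.default_rng(0)
    c1, c2 = channels
    fan1 = kernel * n_features
    fan2 = kernel * c1
    p = {
        "W1": rng.normal(0, np.sqrt(2.0 / fan1), (fan1, c1)),
        "b1": np.zeros(c1),
        "W2": rng.normal(0, np.sqrt(2.0 / fan2), (fan2, c2)),
        "b2": np.zeros(c2),
        "W3": rng.normal(0, np.sqrt(2.0 / c2), (c2, 1)),
        "b3": np.zeros(1),
    }
    p["_kernel"] = np.array([kernel])
    return p


def convnet_forward(params: dict, X: np.ndarray, cache: dict | None = None):
    """Forward pass. X: (n, window, n_features) -> probabilities (n,)."""
    k = int(params["_kernel"][0])
    X1 = _im2col(X, k)
    Z1 = X1 @ params["W1"] + params["b1"]
    A1 = np.maximum(Z1, 0.0)
    X2 = _im2col(A1, k)
    Z2 = X2 @ params["W2"] + params["b2"]
    A2 = np.maximum(Z2, 0.0)
    pooled = A2.mean(axis=1)
    logits = pooled @ params["W3"] + params["b3"]
    p = sigmoid(logits[:, 0])
    if cache is not None:
        cache.update(X1=X1, Z1=Z1, A1=A1, X2=X2, Z2=Z2, A2=A2,
                     pooled=pooled, p=p, k=k, in_shape=X.shape)
    return p


def _col2im(dcols: np.ndarray, width: int, L: int, c: int) -> np.ndarray:
    """Adjoint of :func:`_im2col`."""
    n, out_len, _ = dcols.shape
    dcols = dcols.reshape(n, out_len, width, c)
    dx = np.zeros((n, L, c))
    for w in range(width):
        dx[:, w : w + out_len] += dcols[:, :, w]
    return dx


def convnet_backward(params: dict, cache: dict, y: np.ndarray) -> dict:
    """Gradients of mean BCE w.r.t. parameters."""
    n = len(y)
    k = cache["k"]
    dlogits = (cache["p"] - y)[:, None] / n  # sigmoid+BCE shortcut
    grads = {
        "W3": cache["pooled"].T @ dlogits,
        "b3": dlogits.sum(axis=0),
    }
    dpooled = dlogits @ params["W3"].T
    out2 = cache["A2"].shape[1]
    dA2 = np.repeat(dpooled[:, None, :], out2, axis=1) / out2
    dZ2 = dA2 * (cache["Z2"] > 0)
    grads["W2"] = np.einsum("nlf,nlc->fc", cache["X2"], dZ2)
    grads["b2"] = dZ2.sum(axis=(0, 1))
    dX2 = dZ2 @ params["W2"].T
    L1, c1 = cache["A1"].shape[1], cache["A1"].shape[2]
    dA1 = _col2im(dX2, k, L1, c1)
    dZ1 = dA1 * (cache["Z1"] > 0)
    grads["W1"] = np.einsum("nlf,nlc->fc", cache["X1"], dZ1)
    grads["b1"] = dZ1.sum(axis=(0, 1))
    return grads


# ---------------------------------------------------------------------------
# truncated bidirectional RNN


def init_birnn(n_inputs: int, hidden: int = 8, lookback: int = 12,
               rng: np.random.Generator | None = None) -> dict:
    rng = rng if rng is not None else np.random.default_rng(0)
    s_in = np.sqrt(1.0 / n_inputs)
    s_h = np.sqrt(1.0 / hidden)
    p = {}
    for d in ("f", "b"):
        p[f"Wx{d}"] = rng.normal(0, s_in, (n_inputs, hidden))
        p[f"Wh{d}"] = rng.normal(0, s_h, (hidden, hidden))
        p[f"bh{d}"] = np.zeros(hidden)
    p["Wo"] = rng.normal(0, s_h, (2 * hidden, 1))
    p["bo"] = np.zeros(1)
    p["_lookback"] = np.array([lookback])
    return p


def birnn_forward(params: dict, U: np.ndarray, cache: dict | None = None):
    """U: (n, 2*lookback+1, d) windows centered on the scored residue.

    The forward pass consumes positions 0..lookback (ending at the center),
    the backward pass positions 2*lookback..lookback; hidden states are
    concatenated and mapped through a dense sigmoid head. Output depends on
    nothing outside the window, which realises the truncated-lookback
    contract exactly.
    """
    n, w, d = U.shape
    T = int(params["_lookback"][0])
    if w != 2 * T + 1:
        raise ValueError(f"window width {w} != 2*lookback+1 = {2 * T + 1}")
    hidden = params["Whf"].shape[0]
    hs_f, hs_b = [], []
    h = np.zeros((n, hidden))
    for t in range(T + 1):
        h = np.tanh(U[:, t] @ params["Wxf"] + h @ params["Whf"] + params["bhf"])
        hs_f.append(h)
    hf = h
    h = np.zeros((n, hidden))
    for t in range(2 * T, T - 1, -1):
        h = np.tanh(U[:, t] @ params["Wxb"] + h @ params["Whb"] + params["bhb"])
        hs_b.append(h)
    hb = h
    concat = np.concatenate([hf, hb], axis=1)
    logits = concat @ params["Wo"] + params["bo"]
    p = sigmoid(logits[:, 0])
    if cache is not None:
        cache.update(hs_f=hs_f, hs_b=hs_b, concat=concat, p=p, T=T, U=U)
    return p


def birnn_backward(params: dict, cache: dict, y: np.ndarray) -> dict:
    n = len(y)
    T = cache["T"]
    U = cache["U"]
    hidden = params["Whf"].shape[0]
    dlogits = (cache["p"] - y)[:, None] / n
    grads = {
        "Wo": cache["concat"].T @ dlogits,
        "bo": dlogits.sum(axis=0),
    }
    dconcat = dlogits @ params["Wo"].T
    for d, hs, times in (
        ("f", cache["hs_f"], list(range(T + 1))),
        ("b", cache["hs_b"], list(range(2 * T, T - 1, -1))),
    ):
        gWx = np.zeros_like(params[f"Wx{d}"])
        gWh = np.zeros_like(params[f"Wh{d}"])
        gbh = np.zeros_like(params[f"bh{d}"])
        dh = dconcat[:, :hidden] if d == "f" else dconcat[:, hidden:]
        for step in range(len(times) - 1, -1, -1):
            t = times[step]
            h = hs[step]
            dz = dh * (1.0 - h * h)
            gWx += U[:, t].T @ dz
            gbh += dz.sum(axis=0)
            h_prev = hs[step - 1] if step > 0 else np.zeros((n, hidden))
            gWh += h_prev.T @ dz
            dh = dz @ params[f"Wh{d}"].T
        grads[f"Wx{d}"] = gWx
        grads[f"Wh{d}"] = gWh
        grads[f"bh{d}"] = gbh
    return grads


# ---------------------------------------------------------------------------
# shared training loop


def train_loop(
    params: dict,
    forward,
    backward,
    X: np.ndarray,
    y: np.ndarray,
    X_val: np.ndarray,
    y_val: np.ndarray,
    lr: float = 1e-3,
    batch_size: int = 64,
    max_epochs: int = 150,
    patience: int = 10,
    rng: np.random.Generator | None = None,
):
    """Minibatch Adam with patience-based early stopping.

    Returns ``(best_params, history)``; ``history`` is a list of per-epoch
    ``(train_loss, val_loss)``. The returned parameters are those of the
    best validation epoch.
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    trainable = {k: v for k, v in params.items() if not k.startswith("_")}
    opt = Adam(trainable, lr=lr)
    stopper = EarlyStopper(patience=patience)
    best = {k: v.copy() for k, v in params.items()}
    history = []
    n = len(y)
    for _epoch in range(max_epochs):
        order = rng.permutation(n)
        losses = []
        for s in range(0, n, batch_size):
            idx = order[s : s + batch_size]
            cache: dict = {}
            p = forward(params, X[idx], cache)
            losses.append(bce_loss(p, y[idx]) * len(idx))
            opt.step(backward(params, cache, y[idx]))
        val_p = forward(params, X_val, None)
        val_loss = bce_loss(val_p, y_val)
        history.append((sum(losses) / n, val_loss))
        improved = val_loss < stopper.best_loss
        stop = stopper.update(val_loss)
        if improved:
            best = {k: v.copy() for k, v in params.items()}
        if stop:
            break
    return best, history
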