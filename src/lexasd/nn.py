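"""Minimal numpy neural-network core: Bi-LSTM, Adam, logistic losses.

The tagger and the DNN classifiers share this module.  Everything is plain
numpy with hand-derived gradients, which keeps training bitwise-reproducible
from a seed on a single device; the backward pass is verified against central
finite differences in the test suite.

Conventions: batches are padded to the batch maximum length; ``lengths`` gives
the true token count per sequence.  Padded positions are never read — the
forward recursion simply runs over them and every consumer (loss, last-state
extraction) indexes real positions only, so their gradient contribution is
exactly zero.
"""

from __future__ import annotations

import numpy as np


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=np.float64)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def bce_with_logits(logits: np.ndarray, targets: np.ndarray):
    """Numerically stable binary cross-entropy; returns (per-cell loss, dloss/dlogit)."""
    loss = np.maximum(logits, 0) - logits * targets + np.log1p(np.exp(-np.abs(logits)))
    grad = sigmoid(logits) - targets
    return loss, grad


def reverse_padded(x: np.ndarray, lengths: np.ndarray) -> np.ndarray:
    """Reverse each sequence within its true length, keeping padding in place."""
    out = x.copy()
    for b, n in enumerate(lengths):
        out[b, :n] = x[b, :n][::-1]
    return out


# ---------------------------------------------------------------------------
# Single-direction LSTM
# ---------------------------------------------------------------------------

def lstm_init(rng: np.random.Generator, in_dim: int, hidden: int) -> dict:
    """Uniform(-k, k) with k = 1/sqrt(hidden); forget-gate bias starts at 1."""
    k = 1.0 / np.sqrt(hidden)
    params = {
        "W": rng.uniform(-k, k, size=(in_dim, 4 * hidden)),
        "U": rng.uniform(-k, k, size=(hidden, 4 * hidden)),
        "b": np.zeros(4 * hidden),
    }
    params["b"][hidden : 2 * hidden] = 1.0  # forget gate
    return params


def lstm_forward(x: np.ndarray, params: dict):
    """Run an LSTM over x (B, L, D); returns hidden states (B, L, H) and a cache."""
    W, U, b = params["W"], params["U"], params["b"]
    B, L, _ = x.shape
    H = U.shape[0]
    h = np.zeros((B, H))
    c = np.zeros((B, H))
    gates_i = np.empty((B, L, H))
    gates_f = np.empty((B, L, H))
    gates_g = np.empty((B, L, H))
    gates_o = np.empty((B, L, H))
    cells = np.empty((B, L, H))
    tanh_c = np.empty((B, L, H))
    hs = np.empty((B, L, H))
    xw = x @ W  # precompute input projections for all steps
    for t in range(L):
        z = xw[:, t] + h @ U + b
        i = sigmoid(z[:, :H])
        f = sigmoid(z[:, H : 2 * H])
        g = np.tanh(z[:, 2 * H : 3 * H])
        o = sigmoid(z[:, 3 * H :])
        c = f * c + i * g
        tc = np.tanh(c)
        h = o * tc
        gates_i[:, t], gates_f[:, t], gates_g[:, t], gates_o[:, t] = i, f, g, o
        cells[:, t], tanh_c[:, t], hs[:, t] = c, tc, h
    cache = {
        "x": x, "i": gates_i, "f": gates_f, "g": gates_g, "o": gates_o,
        "c": cells, "tanh_c": tanh_c, "h": hs,
    }
    return hs, cache


def lstm_backward(d_hs: np.ndarray, cache: dict, params: dict):
    """Backprop through :func:`lstm_forward`.

    ``d_hs`` is the gradient w.r.t. the emitted hidden states (zero at padded
    positions).  Returns (grads dict for W/U/b, gradient w.r.t. the inputs x).
    """
    W, U = params["W"], params["U"]
    x = cache["x"]
    B, L, H = cache["h"].shape
    dW = np.zeros_like(W)
    dU = np.zeros_like(U)
    db = np.zeros_like(params["b"])
    dx = np.zeros_like(x)
    dh_next = np.zeros((B, H))
    dc_next = np.zeros((B, H))
    for t in range(L - 1, -1, -1):
        i, f, g, o = (cache[k][:, t] for k in ("i", "f", "g", "o"))
        tc = cache["tanh_c"][:, t]
        c_prev = cache["c"][:, t - 1] if t > 0 else np.zeros((B, H))
        h_prev = cache["h"][:, t - 1] if t > 0 else np.zeros((B, H))
        dh = d_hs[:, t] + dh_next
        do = dh * tc
        dc = dc_next + dh * o * (1.0 - tc * tc)
        di = dc * g
        df = dc * c_prev
        dg = dc * i
        dz = np.concatenate(
            [di * i * (1 - i), df * f * (1 - f), dg * (1 - g * g), do * o * (1 - o)],
            axis=1,
        )
        dW += x[:, t].T @ dz
        dU += h_prev.T @ dz
        db += dz.sum(axis=0)
        dx[:, t] = dz @ W.T
        dh_next = dz @ U.T
        dc_next = dc * f
    return {"W": dW, "U": dU, "b": db}, dx


# ---------------------------------------------------------------------------
# Bi-LSTM
# ---------------------------------------------------------------------------

def bilstm_init(rng: np.random.Generator, in_dim: int, hidden: int) -> dict:
    fwd = lstm_init(rng, in_dim, hidden)
    bwd = lstm_init(rng, in_dim, hidden)
    return {f"fwd_{k}": v for k, v in fwd.items()} | {
        f"bwd_{k}": v for k, v in bwd.items()
    }


def _split(params: dict, prefix: str) -> dict:
    return {k[len(prefix):]: v for k, v in params.items() if k.startswith(prefix)}


def bilstm_forward(x: np.ndarray, lengths: np.ndarray, params: dict):
    """Bidirectional LSTM.

    Returns ``(h_tokens, h_last, cache)`` where ``h_tokens`` (B, L, 2H) holds
    per-token forward||backward states aligned to the original order and
    ``h_last`` (B, 2H) concatenates the forward state at the last real token
    with the backward state at the first token.
    """
    B = x.shape[0]
    rows = np.arange(B)
    last = lengths - 1
    hf, cache_f = lstm_forward(x, _split(params, "fwd_"))
    xr = reverse_padded(x, lengths)
    hb_r, cache_b = lstm_forward(xr, _split(params, "bwd_"))
    hb = reverse_padded(hb_r, lengths)
    h_tokens = np.concatenate([hf, hb], axis=2)
    h_last = np.concatenate([hf[rows, last], hb_r[rows, last]], axis=1)
    cache = {"f": cache_f, "b": cache_b, "lengths": lengths}
    return h_tokens, h_last, cache


def bilstm_backward(
    d_tokens: np.ndarray | None,
    d_last: np.ndarray | None,
    cache: dict,
    params: dict,
):
    """Backprop through :func:`bilstm_forward`; returns (grads, dx)."""
    lengths = cache["lengths"]
    B, L, H = cache["f"]["h"].shape
    rows = np.arange(B)
    last = lengths - 1
    d_hf = np.zeros((B, L, H))
    d_hb_r = np.zeros((B, L, H))
    if d_tokens is not None:
        d_hf += d_tokens[:, :, :H]
        d_hb_r += reverse_padded(d_tokens[:, :, H:], lengths)
    if d_last is not None:
        d_hf[rows, last] += d_last[:, :H]
        d_hb_r[rows, last] += d_last[:, H:]
    grads_f, dx_f = lstm_backward(d_hf, cache["f"], _split(params, "fwd_"))
    grads_b, dx_r = lstm_backward(d_hb_r, cache["b"], _split(params, "bwd_"))
    dx = dx_f + reverse_padded(dx_r, lengths)
    grads = {f"fwd_{k}": v for k, v in grads_f.items()} | {
        f"bwd_{k}": v for k, v in grads_b.items()
    }
    return grads, dx


# ---------------------------------------------------------------------------
# Dense layer and optimiser
# ---------------------------------------------------------------------------

def linear_init(rng: np.random.Generator, in_dim: int, out_dim: int) -> dict:
    k = 1.0 / np.sqrt(in_dim)
    return {"W": rng.uniform(-k, k, size=(in_dim, out_dim)), "b": np.zeros(out_dim)}


class Adam:
    """Adam with bias correction (beta1=0.9, beta2=0.999, eps=1e-8)."""

    def __init__(self, params: dict, lr: float = 0.001,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, grads: dict) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1 ** self.t
        bias2 = 1.0 - b2 ** self.t
        for key, g in grads.items():
            m = self.m[key]
            v = self.v[key]
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            self.params[key] -= self.lr * (m / bias1) / (np.sqrt(v / bias2) + self.eps)


def minibatch_indices(n: int, batch_size: int, rng: np.random.Generator):
    order = rng.permutation(n)
    for start in range(0, n, batch_size):
        yield order[start : start + batch_size]
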