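"""A small self-attention sequence encoder in NumPy with hand-written backprop.

The backbone: token + learned position embeddings, a residual width-``w``
1-D convolution stem (so short motifs are visible to single learned filters),
``n_layers`` pre-norm transformer blocks (multi-head self-attention + ReLU
feed-forward), a final LayerNorm, PAD-masked mean pooling, and a 2-way linear
head.  Long token streams are processed as non-overlapping windows whose
logits are averaged; training backpropagates through that average, so the
optimization is end-to-end at the sequence level.

Optimization is AdamW (decoupled weight decay on matrix-shaped parameters)
with linear warmup followed by linear decay, and cross-entropy loss.  All
randomness flows through explicitly passed ``numpy.random.Generator``
instances, so training is bit-reproducible on a single worker.

Gradient correctness is checked against central finite differences in the
test suite.
"""
from __future__ import annotations

import math
from typing import Dict, Optional, Tuple

import numpy as np

NEG_INF = -1e9

Params = Dict[str, np.ndarray]


# ---------------------------------------------------------------------------
# Initialization


def init_params(vocab_size: int, cfg, rng: np.random.Generator, dtype=np.float32) -> Params:
    d, f, w = cfg.hidden_dim, cfg.ffn_dim, cfg.conv_width

    def W(*shape):
        return rng.normal(0.0, 0.02, size=shape).astype(dtype)

    def zeros(*shape):
        return np.zeros(shape, dtype=dtype)

    def ones(*shape):
        return np.ones(shape, dtype=dtype)

    p: Params = {
        "tok_emb": W(vocab_size, d),
        "pos_emb": W(cfg.max_seq_length, d),
        "conv_W": W(w * d, d),
        "conv_b": zeros(d),
        "lnf_g": ones(d),
        "lnf_b": zeros(d),
        # head reads [masked mean ; masked max] pooled features (or mean only)
        "head_W": W(2 * d if cfg.pooling == "mean_max" else d, 2),
        "head_b": zeros(2),
    }
    for i in range(cfg.n_layers):
        p[f"l{i}_ln1_g"] = ones(d)
        p[f"l{i}_ln1_b"] = zeros(d)
        for nm in ("q", "k", "v", "o"):
            p[f"l{i}_W{nm}"] = W(d, d)
            p[f"l{i}_b{nm}"] = zeros(d)
        p[f"l{i}_ln2_g"] = ones(d)
        p[f"l{i}_ln2_b"] = zeros(d)
        p[f"l{i}_W1"] = W(d, f)
        p[f"l{i}_b1"] = zeros(f)
        p[f"l{i}_W2"] = W(f, d)
        p[f"l{i}_b2"] = zeros(d)
    return p


# ---------------------------------------------------------------------------
# Primitive ops (forward returns cache for backward)


def _layernorm_fwd(x, g, b, eps=1e-5):
    mu = x.mean(-1, keepdims=True)
    xc = x - mu
    var = (xc * xc).mean(-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = xc * inv
    return xhat * g + b, (xhat, inv, g)


def _layernorm_bwd(dy, cache):
    xhat, inv, g = cache
    dg = (dy * xhat).sum(axis=tuple(range(dy.ndim - 1)))
    db = dy.sum(axis=tuple(range(dy.ndim - 1)))
    dxhat = dy * g
    m1 = dxhat.mean(-1, keepdims=True)
    m2 = (dxhat * xhat).mean(-1, keepdims=True)
    dx = inv * (dxhat - m1 - xhat * m2)
    return dx, dg, db


def _linear_fwd(x, W, b):
    d_in = x.shape[-1]
    y = x.reshape(-1, d_in) @ W
    return (y + b).reshape(*x.shape[:-1], W.shape[1])


def _linear_bwd(x, W, dy):
    d_in, d_out = W.shape
    x2 = x.reshape(-1, d_in)
    dy2 = dy.reshape(-1, d_out)
    dW = x2.T @ dy2
    db = dy2.sum(0)
    dx = (dy2 @ W.T).reshape(x.shape)
    return dx, dW, db


def _softmax(x, axis=-1):
    m = x.max(axis=axis, keepdims=True)
    e = np.exp(x - m)
    return e / e.sum(axis=axis, keepdims=True)


def _conv_windows(E, w):
    # zero-pad so output length == input length ("same" convolution)
    p0 = w // 2
    p1 = w - 1 - p0
    Ep = np.pad(E, ((0, 0), (p0, p1), (0, 0)))
    win = np.lib.stride_tricks.sliding_window_view(Ep, w, axis=1)  # (B,L,d,w)
    return np.ascontiguousarray(win.transpose(0, 1, 3, 2))  # (B,L,w,d)


def _conv_scatter(dwin, B, L, d, w):
    """Scatter window gradients back onto the (unpadded) input."""
    p0 = w // 2
    dE = np.zeros((B, L, d), dtype=dwin.dtype)
    for j in range(w):
        # window element j of output position i reads input position i + j - p0
        src_lo = max(0, p0 - j)
        src_hi = min(L, L + p0 - j)
        if src_lo < src_hi:
            dE[:, src_lo + j - p0 : src_hi + j - p0] += dwin[:, src_lo:src_hi, j]
    return dE


# ---------------------------------------------------------------------------
# Full forward / backward over one batch of fixed-length windows


def forward(
    p: Params,
    ids: np.ndarray,
    cfg,
    pad_id: int,
    train: bool = False,
    rng: Optional[np.random.Generator] = None,
) -> Tuple[np.ndarray, dict]:
    """Forward pass over a (B, L) batch of token-id windows.

    Returns per-window logits (B, 2) and a cache sufficient for ``backward``.
    """
    B, L = ids.shape
    d = cfg.hidden_dim
    h = cfg.n_heads
    dh = d // h
    w = cfg.conv_width
    dtype = p["tok_emb"].dtype
    mask = ids != pad_id  # (B, L)
    maskf = mask.astype(dtype)[..., None]

    def dropout(x, key):
        if train and cfg.dropout > 0.0:
            keep = (rng.random(x.shape) >= cfg.dropout).astype(dtype)
            cache["drop_" + key] = keep
            return x * keep / (1.0 - cfg.dropout)
        return x

    cache: dict = {"ids": ids, "mask": mask, "train": train}

    E0 = p["tok_emb"][ids] + p["pos_emb"][None, :L, :]
    E = E0 * maskf
    cache["E"] = E

    win = _conv_windows(E, w)  # (B,L,w,d)
    cache["conv_win"] = win
    C = win.reshape(B, L, w * d) @ p["conv_W"] + p["conv_b"]
    cache["conv_pre"] = C
    Crelu = np.maximum(C, 0.0)
    if cfg.pooling == "mean_max":
        # motif-detector pooling: max conv activation per filter, taken before
        # LayerNorm so a single strong motif hit keeps its magnitude
        Cmasked = np.where(mask[..., None], Crelu, -np.inf)
        conv_argmax = Cmasked.argmax(axis=1)  # (B, d)
        max_pool = np.take_along_axis(Crelu, conv_argmax[:, None, :], axis=1)[:, 0, :]
        cache["pool_argmax"] = conv_argmax
        cache["max_pool"] = max_pool
    H = E + dropout(Crelu, "conv")
    scale = 1.0 / math.sqrt(dh)
    key_bias = np.where(mask[:, None, None, :], 0.0, NEG_INF).astype(dtype)

    for i in range(cfg.n_layers):
        cache[f"l{i}_in"] = H
        A, ln1c = _layernorm_fwd(H, p[f"l{i}_ln1_g"], p[f"l{i}_ln1_b"])
        cache[f"l{i}_ln1"] = (A, ln1c)
        Q = _linear_fwd(A, p[f"l{i}_Wq"], p[f"l{i}_bq"])
        K = _linear_fwd(A, p[f"l{i}_Wk"], p[f"l{i}_bk"])
        V = _linear_fwd(A, p[f"l{i}_Wv"], p[f"l{i}_bv"])
        Qh = Q.reshape(B, L, h, dh).transpose(0, 2, 1, 3)
        Kh = K.reshape(B, L, h, dh).transpose(0, 2, 1, 3)
        Vh = V.reshape(B, L, h, dh).transpose(0, 2, 1, 3)
        S = np.matmul(Qh, Kh.transpose(0, 1, 3, 2)) * scale + key_bias
        P = _softmax(S)
        cache[f"l{i}_attn"] = (Qh, Kh, Vh, P)
        Oh = np.matmul(P, Vh)  # (B,h,L,dh)
        O = Oh.transpose(0, 2, 1, 3).reshape(B, L, d)
        cache[f"l{i}_O"] = O
        attn_out = _linear_fwd(O, p[f"l{i}_Wo"], p[f"l{i}_bo"])
        H = H + dropout(attn_out, f"attn{i}")

        cache[f"l{i}_mid"] = H
        Z, ln2c = _layernorm_fwd(H, p[f"l{i}_ln2_g"], p[f"l{i}_ln2_b"])
        cache[f"l{i}_ln2"] = (Z, ln2c)
        F1 = _linear_fwd(Z, p[f"l{i}_W1"], p[f"l{i}_b1"])
        F1r = np.maximum(F1, 0.0)
        cache[f"l{i}_ffn"] = (F1, F1r)
        F2 = _linear_fwd(F1r, p[f"l{i}_W2"], p[f"l{i}_b2"])
        H = H + dropout(F2, f"ffn{i}")

    cache["pre_lnf"] = H
    Hf, lnfc = _layernorm_fwd(H, p["lnf_g"], p["lnf_b"])
    cache["lnf"] = (Hf, lnfc)
    counts = maskf.sum(axis=1)  # (B,1)
    mean_pool = (Hf * maskf).sum(axis=1) / counts
    cache["counts"] = counts
    if cfg.pooling == "mean_max":
        pooled = np.concatenate([mean_pool, cache["max_pool"]], axis=1)
    else:
        pooled = mean_pool
    cache["pooled"] = pooled
    logits = pooled @ p["head_W"] + p["head_b"]
    return logits, cache


def backward(
    p: Params, cfg, cache: dict, dlogits: np.ndarray
) -> Tuple[Params, np.ndarray]:
    """Backpropagate from per-window logit gradients.

    Returns (parameter gradients, gradient w.r.t. the masked embedding E),
    the latter for gradient-times-input attribution.
    """
    B, L = cache["ids"].shape
    d = cfg.hidden_dim
    h = cfg.n_heads
    dh = d // h
    w = cfg.conv_width
    dtype = p["tok_emb"].dtype
    mask = cache["mask"]
    maskf = mask.astype(dtype)[..., None]
    scale = 1.0 / math.sqrt(dh)
    g: Params = {}

    def drop_bwd(dx, key):
        keep = cache.get("drop_" + key)
        if keep is not None:
            return dx * keep / (1.0 - cfg.dropout)
        return dx

    pooled = cache["pooled"]
    g["head_W"] = pooled.T @ dlogits
    g["head_b"] = dlogits.sum(0)
    dpooled = dlogits @ p["head_W"].T
    dmean = dpooled[:, :d]
    dHf = dmean[:, None, :] * maskf / cache["counts"][:, None, :]
    dH, g["lnf_g"], g["lnf_b"] = _layernorm_bwd(dHf, cache["lnf"][1])

    for i in reversed(range(cfg.n_layers)):
        # FFN block
        dF2 = drop_bwd(dH, f"ffn{i}")
        F1, F1r = cache[f"l{i}_ffn"]
        Z = cache[f"l{i}_ln2"][0]
        dF1r, g[f"l{i}_W2"], g[f"l{i}_b2"] = _linear_bwd(F1r, p[f"l{i}_W2"], dF2)
        dF1 = dF1r * (F1 > 0)
        dZ, g[f"l{i}_W1"], g[f"l{i}_b1"] = _linear_bwd(Z, p[f"l{i}_W1"], dF1)
        dmid, g[f"l{i}_ln2_g"], g[f"l{i}_ln2_b"] = _layernorm_bwd(dZ, cache[f"l{i}_ln2"][1])
        dH = dH + dmid

        # attention block
        dattn_out = drop_bwd(dH, f"attn{i}")
        O = cache[f"l{i}_O"]
        dO, g[f"l{i}_Wo"], g[f"l{i}_bo"] = _linear_bwd(O, p[f"l{i}_Wo"], dattn_out)
        dOh = dO.reshape(B, L, h, dh).transpose(0, 2, 1, 3)
        Qh, Kh, Vh, P = cache[f"l{i}_attn"]
        dP = np.matmul(dOh, Vh.transpose(0, 1, 3, 2))
        dVh = np.matmul(P.transpose(0, 1, 3, 2), dOh)
        dS = P * (dP - (dP * P).sum(-1, keepdims=True))
        dQh = np.matmul(dS, Kh) * scale
        dKh = np.matmul(dS.transpose(0, 1, 3, 2), Qh) * scale
        dQ = dQh.transpose(0, 2, 1, 3).reshape(B, L, d)
        dK = dKh.transpose(0, 2, 1, 3).reshape(B, L, d)
        dV = dVh.transpose(0, 2, 1, 3).reshape(B, L, d)
        A = cache[f"l{i}_ln1"][0]
        dA_q, g[f"l{i}_Wq"], g[f"l{i}_bq"] = _linear_bwd(A, p[f"l{i}_Wq"], dQ)
        dA_k, g[f"l{i}_Wk"], g[f"l{i}_bk"] = _linear_bwd(A, p[f"l{i}_Wk"], dK)
        dA_v, g[f"l{i}_Wv"], g[f"l{i}_bv"] = _linear_bwd(A, p[f"l{i}_Wv"], dV)
        dA = dA_q + dA_k + dA_v
        din, g[f"l{i}_ln1_g"], g[f"l{i}_ln1_b"] = _layernorm_bwd(dA, cache[f"l{i}_ln1"][1])
        dH = dH + din

    # conv stem: H0 = E + dropout(relu(conv(E))); max pool reads relu(conv(E))
    dCrelu = drop_bwd(dH, "conv")
    if cfg.pooling == "mean_max":
        argmax = cache["pool_argmax"]
        np.put_along_axis(
            dCrelu, argmax[:, None, :],
            np.take_along_axis(dCrelu, argmax[:, None, :], axis=1)
            + dpooled[:, None, d:],
            axis=1,
        )
    dC = dCrelu * (cache["conv_pre"] > 0)
    win = cache["conv_win"].reshape(B, L, w * d)
    dC2 = dC.reshape(-1, d)
    g["conv_W"] = win.reshape(-1, w * d).T @ dC2
    g["conv_b"] = dC2.sum(0)
    dwin = (dC2 @ p["conv_W"].T).reshape(B, L, w, d)
    dE = dH + _conv_scatter(dwin, B, L, d, w)

    dE0 = dE * maskf
    g["tok_emb"] = np.zeros_like(p["tok_emb"])
    np.add.at(g["tok_emb"], cache["ids"], dE0)
    g["pos_emb"] = np.zeros_like(p["pos_emb"])
    g["pos_emb"][:L] = dE0.sum(0)
    return g, dE0


# ---------------------------------------------------------------------------
# Sequence-level aggregation over windows
#
# Each window yields a scalar evidence score d = logit(lncRNA) - logit(other);
# a sequence's score is the log-mean-exp of its window scores — a smooth max,
# so one strongly informative window suffices to call the sequence positive
# (the multiple-instance reading of "this locus contains lncRNA signal").
# For single-window sequences this reduces exactly to the 2-way softmax.


def window_evidence(logits_c: np.ndarray) -> np.ndarray:
    return (logits_c[:, 1] - logits_c[:, 0]).astype(np.float64)


def aggregate_evidence(
    d: np.ndarray, seg: np.ndarray, n_seqs: int
) -> Tuple[np.ndarray, np.ndarray]:
    """Log-mean-exp of window evidence per sequence.

    Returns (per-sequence scores, per-window softmax weights); the weights
    are d(score)/d(window evidence), used by backprop and attribution.
    """
    m = np.full(n_seqs, -np.inf)
    np.maximum.at(m, seg, d)
    e = np.exp(d - m[seg])
    s = np.zeros(n_seqs)
    np.add.at(s, seg, e)
    counts = np.bincount(seg, minlength=n_seqs).astype(np.float64)
    scores = m + np.log(s) - np.log(counts)
    weights = e / s[seg]
    return scores, weights


def log_mean_exp(d: np.ndarray) -> float:
    m = float(np.max(d))
    return m + float(np.log(np.mean(np.exp(d - m))))


def _sigmoid(x):
    return 0.5 * (1.0 + np.tanh(0.5 * x))


def sequence_scores(
    p: Params,
    chunk_ids: np.ndarray,
    seg: np.ndarray,
    n_seqs: int,
    cfg,
    pad_id: int,
    train: bool = False,
    rng: Optional[np.random.Generator] = None,
) -> Tuple[np.ndarray, np.ndarray, dict]:
    """Per-sequence evidence scores; p(lncRNA) = sigmoid(score)."""
    logits_c, cache = forward(p, chunk_ids, cfg, pad_id, train=train, rng=rng)
    scores, weights = aggregate_evidence(window_evidence(logits_c), seg, n_seqs)
    return scores, weights, cache


def binary_cross_entropy(
    scores: np.ndarray, labels: np.ndarray
) -> Tuple[float, np.ndarray]:
    p = _sigmoid(scores)
    n = len(labels)
    eps = 1e-12
    loss = -float(
        np.mean(labels * np.log(p + eps) + (1 - labels) * np.log(1 - p + eps))
    )
    return loss, (p - labels) / n


def train_step(
    p: Params,
    chunk_ids: np.ndarray,
    seg: np.ndarray,
    labels: np.ndarray,
    cfg,
    pad_id: int,
    rng: np.random.Generator,
) -> Tuple[float, Params]:
    n_seqs = len(labels)
    scores, weights, cache = sequence_scores(
        p, chunk_ids, seg, n_seqs, cfg, pad_id, train=True, rng=rng
    )
    loss, dscores = binary_cross_entropy(scores, labels)
    dd_c = dscores[seg] * weights  # d loss / d window evidence
    dtype = p["tok_emb"].dtype
    dlogits_c = np.stack([-dd_c, dd_c], axis=1).astype(dtype)
    grads, _ = backward(p, cfg, cache, dlogits_c)
    return loss, grads


# ---------------------------------------------------------------------------
# AdamW with linear warmup + linear decay


class AdamW:
    def __init__(self, params: Params, lr: float, weight_decay: float,
                 total_steps: int, warmup_fraction: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr = lr
        self.weight_decay = weight_decay
        self.total_steps = max(total_steps, 1)
        self.warmup_steps = int(math.ceil(warmup_fraction * self.total_steps))
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def current_lr(self) -> float:
        t = self.t
        if self.warmup_steps > 0 and t <= self.warmup_steps:
            return self.lr * t / self.warmup_steps
        denom = max(self.total_steps - self.warmup_steps, 1)
        return self.lr * max(self.total_steps - t, 0) / denom

    def step(self, params: Params, grads: Params) -> None:
        self.t += 1
        lr = self.current_lr()
        b1, b2 = self.beta1, self.beta2
        c1 = 1.0 - b1 ** self.t
        c2 = 1.0 - b2 ** self.t
        for k, g in grads.items():
            m = self.m[k]
            v = self.v[k]
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * (g * g)
            update = (m / c1) / (np.sqrt(v / c2) + self.eps)
            if self.weight_decay > 0 and params[k].ndim >= 2:
                update = update + self.weight_decay * params[k]
            params[k] -= lr * update
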