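"""Multi-label attention coder: embedding, Multi-CNN, label-wise attention.

Architecture, for a note of ``n`` token indices and ``l_g`` candidate
codes:

1. **Embedding** — look up each token in a learnable table
   ``W ∈ R^{v×d}`` (PAD row fixed at zero), giving ``X ∈ R^{n×d}``.
2. **Multi-CNN** — parallel 1-D convolutions with kernel widths
   ``{4,5,6}`` (``d_f`` channels each), elementwise nonlinearity, and
   max-pooling with window/stride ``p``.  Pooling shortens the position
   axis but keeps it: maps from different kernel widths are right-padded
   with zeros to a common length ``n'`` and concatenated on the feature
   axis, ``H' ∈ R^{n'×d_e}`` with ``d_e = m·d_f``.  Each pooled position
   ``t`` summarises source tokens ``[t·p, t·p + k_max + p − 1)``, which
   is what ties attention weights back to text spans.
3. **Label representation** — each code's graph embedding (a row of
   ``y_g ∈ R^{l_g×d_g}``) is mapped into feature space,
   ``D = W_g·y_gᵀ + b ∈ R^{d_e×l_g}``.
4. **Label-wise attention** — per code ``i``, scores ``H'·D_i`` are
   softmax-normalised over positions into weights ``a_i`` (rows sum
   to 1) and pooled: ``v_i = a_i·H' ∈ R^{d_e}``.
5. **Output** — per-code logit ``⟨v_i, W_o[i]⟩ + b_o[i]`` through a
   sigmoid gives independent probabilities; a code is predicted when
   its probability strictly exceeds 0.5.

Everything is NumPy; :meth:`ModelState.backward` is the analytic
reverse pass (checked against numerical differentiation in the test
suite) and also returns the gradient with respect to the embedded input
``X``, which adversarial training perturbs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Mapping

import numpy as np

from .corpus import PAD_INDEX

_ACTIVATIONS = {
    "relu": (lambda z: np.maximum(z, 0.0), lambda z, a: (z > 0).astype(z.dtype)),
    "tanh": (np.tanh, lambda z, a: 1.0 - a * a),
    "linear": (lambda z: z, lambda z, a: np.ones_like(z)),
}


@dataclass(frozen=True)
class ModelConfig:
    vocab_size: int
    n_labels: int
    d: int = 100                     # token embedding dimension
    d_g: int = 128                   # graph (label) embedding dimension
    d_f: int = 50                    # conv out-channels per kernel width
    kernel_sizes: tuple[int, ...] = (4, 5, 6)
    pool: int = 2                    # max-pool window and stride
    dropout: float = 0.4             # applied to H' during training only
    max_len: int = 1800
    activation: str = "relu"
    use_label_bias: bool = True      # D = W_g y_g + b; False drops the bias

    def __post_init__(self) -> None:
        if self.vocab_size < 2 or self.n_labels < 1:
            raise ValueError("vocab_size >= 2 and n_labels >= 1 required")
        if not self.kernel_sizes or any(k < 1 or k > self.max_len for k in self.kernel_sizes):
            raise ValueError("kernel sizes must be in [1, max_len]")
        if self.pool < 1 or not (0.0 <= self.dropout < 1.0):
            raise ValueError("pool >= 1 and dropout in [0,1) required")
        if self.activation not in _ACTIVATIONS:
            raise ValueError(f"unknown activation {self.activation!r}")

    @property
    def d_e(self) -> int:
        return len(self.kernel_sizes) * self.d_f

    def pooled_length(self, n: int, k: int) -> int:
        # valid convolution then ceil max-pooling (last partial window kept)
        return -(-(n - k + 1) // self.pool)

    def n_positions(self, n: int) -> int:
        return max(self.pooled_length(n, k) for k in self.kernel_sizes)

    def position_span(self, t: int) -> tuple[int, int]:
        """Source-token span ``[start, end)`` covered by pooled position ``t``."""
        return t * self.pool, t * self.pool + max(self.kernel_sizes) + self.pool - 1


# ---------------------------------------------------------------------------
# spec-surface single-instance operations
# ---------------------------------------------------------------------------

def embed(token_indices: np.ndarray, W: np.ndarray) -> np.ndarray:
    """Token index sequence -> ``n×d`` matrix of embedding rows."""
    idx = np.asarray(token_indices)
    if idx.min() < 0 or idx.max() >= W.shape[0]:
        raise IndexError("token index out of vocabulary range")
    return W[idx]


def label_representation(y_g: np.ndarray, W_g: np.ndarray, b: np.ndarray | None) -> np.ndarray:
    """Map code embeddings into feature space: ``D = W_g·y_gᵀ + b`` (d_e×l_g)."""
    D = W_g @ np.asarray(y_g).T
    if b is not None:
        D = D + np.asarray(b)[:, None]
    return D


def attend(H: np.ndarray, D: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Label-wise attention over positions.

    Returns ``(A, V)`` with ``A ∈ R^{l_g×n'}`` row-stochastic and
    ``V = A·H' ∈ R^{l_g×d_e}``.
    """
    H = np.asarray(H, dtype=np.float64)
    D = np.asarray(D, dtype=np.float64)
    if H.shape[1] != D.shape[0]:
        raise ValueError("feature dimensions of H' and D disagree")
    scores = H @ D  # (n', l_g)
    scores = scores - scores.max(axis=0, keepdims=True)
    e = np.exp(scores)
    A = (e / e.sum(axis=0, keepdims=True)).T  # (l_g, n')
    return A, A @ H


def predict(V: np.ndarray, W_o: np.ndarray, bias: np.ndarray) -> np.ndarray:
    """Per-label sigmoid of ``⟨v_i, W_o[i]⟩ + b_i``."""
    V = np.asarray(V, dtype=np.float64)
    if not np.all(np.isfinite(V)):
        raise ValueError("non-finite attended vectors")
    logits = np.sum(V * W_o, axis=-1) + bias
    return 1.0 / (1.0 + np.exp(-logits))


def multi_cnn(X: np.ndarray, cfg: ModelConfig, params: Mapping[str, np.ndarray]) -> np.ndarray:
    """Single-instance Multi-CNN encoding: ``n×d`` -> ``n'×d_e``."""
    H, _ = _multi_cnn_batch(np.asarray(X, dtype=np.float64)[None], cfg, params)
    return H[0]


# ---------------------------------------------------------------------------
# batched forward / backward
# ---------------------------------------------------------------------------

def _windows(X: np.ndarray, k: int) -> np.ndarray:
    # (B, n, d) -> (B, n-k+1, k*d) sliding windows
    B, n, d = X.shape
    w = np.lib.stride_tricks.sliding_window_view(X, k, axis=1)  # (B, n-k+1, d, k)
    return np.ascontiguousarray(w.transpose(0, 1, 3, 2)).reshape(B, n - k + 1, k * d)


def _multi_cnn_batch(X: np.ndarray, cfg: ModelConfig, params: Mapping[str, np.ndarray]):
    B, n, _ = X.shape
    if n < max(cfg.kernel_sizes):
        raise ValueError("sequence shorter than the widest kernel")
    act, _ = _ACTIVATIONS[cfg.activation]
    p = cfg.pool
    n_pos = cfg.n_positions(n)
    maps, cache = [], []
    for k in cfg.kernel_sizes:
        win = _windows(X, k)
        Z = win @ params[f"Wc{k}"] + params[f"bc{k}"]
        C = act(Z)
        L = Z.shape[1]
        P = cfg.pooled_length(n, k)
        pad = P * p - L
        Cp = np.concatenate([C, np.full((B, pad, cfg.d_f), -np.inf)], axis=1) if pad else C
        Cp = Cp.reshape(B, P, p, cfg.d_f)
        arg = Cp.argmax(axis=2)
        pooled = np.take_along_axis(Cp, arg[:, :, None, :], axis=2)[:, :, 0, :]
        if P < n_pos:
            pooled = np.concatenate([pooled, np.zeros((B, n_pos - P, cfg.d_f))], axis=1)
        maps.append(pooled)
        cache.append({"k": k, "win": win, "Z": Z, "C": C, "L": L, "P": P, "arg": arg})
    return np.concatenate(maps, axis=2), cache


@dataclass
class ModelState:
    """All learnable parameters plus the fixed code embedding matrix y_g."""

    config: ModelConfig
    params: dict[str, np.ndarray]
    y_g: np.ndarray  # (l_g, d_g), produced by the graph embedder; not trained

    #: parameters subject to L2 regularization (weights, not biases)
    WEIGHT_KEYS_STATIC = ("W", "Wg", "Wo")

    @classmethod
    def init(cls, config: ModelConfig, y_g: np.ndarray, seed: int = 0) -> "ModelState":
        y_g = np.asarray(y_g, dtype=np.float64)
        if y_g.shape != (config.n_labels, config.d_g):
            raise ValueError("y_g shape must be (n_labels, d_g)")
        rng = np.random.default_rng(seed)
        p: dict[str, np.ndarray] = {}
        p["W"] = rng.uniform(-0.1, 0.1, size=(config.vocab_size, config.d))
        p["W"][PAD_INDEX] = 0.0
        for k in config.kernel_sizes:
            lim = np.sqrt(6.0 / (k * config.d + config.d_f))
            p[f"Wc{k}"] = rng.uniform(-lim, lim, size=(k * config.d, config.d_f))
            p[f"bc{k}"] = np.zeros(config.d_f)
        lim = np.sqrt(6.0 / (config.d_e + config.d_g))
        p["Wg"] = rng.uniform(-lim, lim, size=(config.d_e, config.d_g))
        p["bg"] = np.zeros(config.d_e)
        lim = np.sqrt(6.0 / (config.d_e + 1))
        p["Wo"] = rng.uniform(-lim, lim, size=(config.n_labels, config.d_e))
        p["bo"] = np.zeros(config.n_labels)
        return cls(config, p, y_g)

    @property
    def weight_keys(self) -> tuple[str, ...]:
        return self.WEIGHT_KEYS_STATIC + tuple(f"Wc{k}" for k in self.config.kernel_sizes)

    def weight_sq_norm(self) -> float:
        return float(sum(np.sum(self.params[k] ** 2) for k in self.weight_keys))

    # -- forward ----------------------------------------------------------
    def forward(
        self,
        idx: np.ndarray,
        X_override: np.ndarray | None = None,
        train: bool = False,
        rng: np.random.Generator | None = None,
    ) -> tuple[np.ndarray, np.ndarray, dict]:
        """Run the model on a batch of index sequences.

        Returns ``(yhat, A, cache)``: probabilities ``(B, l_g)``,
        attention maps ``(B, l_g, n')`` and the cache the backward pass
        consumes.  ``X_override`` replaces the embedded input (used for
        adversarial samples); dropout only acts when ``train`` is true.
        """
        cfg = self.config
        idx = np.atleast_2d(np.asarray(idx, dtype=np.int64))
        X = embed(idx, self.params["W"]) if X_override is None else np.asarray(X_override, dtype=np.float64)
        H0, conv_cache = _multi_cnn_batch(X, cfg, self.params)

        if train and cfg.dropout > 0.0:
            if rng is None:
                raise ValueError("training-mode forward needs an rng for dropout")
            keep = 1.0 - cfg.dropout
            mask = (rng.random(H0.shape) < keep) / keep
            H = H0 * mask
        else:
            mask = None
            H = H0

        D = label_representation(self.y_g, self.params["Wg"], self.params["bg"] if cfg.use_label_bias else None)
        scores = H @ D  # (B, n', l_g)
        scores = scores - scores.max(axis=1, keepdims=True)
        e = np.exp(scores)
        A_pos = e / e.sum(axis=1, keepdims=True)  # softmax over positions
        V = np.einsum("btl,bte->ble", A_pos, H)
        logits = np.einsum("ble,le->bl", V, self.params["Wo"]) + self.params["bo"]
        yhat = 1.0 / (1.0 + np.exp(-logits))

        cache = {
            "idx": idx, "X": X, "conv": conv_cache, "mask": mask,
            "H": H, "D": D, "A_pos": A_pos, "V": V, "yhat": yhat,
        }
        return yhat, np.transpose(A_pos, (0, 2, 1)), cache

    # -- backward ---------------------------------------------------------
    def backward(
        self, cache: dict, y: np.ndarray, l2: float = 0.0
    ) -> tuple[dict[str, np.ndarray], np.ndarray]:
        """Gradients of mean-over-batch BCE + L2 w.r.t. all parameters and X.

        ``y`` is the ``(B, l_g)`` binary label matrix.  Returns
        ``(grads, dX)``; ``dX`` is what FGM normalises into the
        adversarial perturbation.
        """
        cfg = self.config
        p = self.params
        y = np.atleast_2d(np.asarray(y, dtype=np.float64))
        B = y.shape[0]
        H, D, A_pos, V, yhat = cache["H"], cache["D"], cache["A_pos"], cache["V"], cache["yhat"]
        _, dact = _ACTIVATIONS[cfg.activation]

        grads: dict[str, np.ndarray] = {}
        dlogits = (yhat - y) / B
        grads["Wo"] = np.einsum("bl,ble->le", dlogits, V)
        grads["bo"] = dlogits.sum(axis=0)
        dV = dlogits[:, :, None] * p["Wo"][None]

        dA = np.einsum("ble,bte->btl", dV, H)
        dH = np.einsum("ble,btl->bte", dV, A_pos)
        ds = A_pos * (dA - np.sum(dA * A_pos, axis=1, keepdims=True))
        dH += ds @ D.T
        dD = np.einsum("btl,bte->el", ds, H)
        grads["Wg"] = dD @ self.y_g
        grads["bg"] = dD.sum(axis=1) if cfg.use_label_bias else np.zeros_like(p["bg"])

        if cache["mask"] is not None:
            dH = dH * cache["mask"]

        X = cache["X"]
        dX = np.zeros_like(X)
        for m, kc in enumerate(cache["conv"]):
            k, L, P, arg = kc["k"], kc["L"], kc["P"], kc["arg"]
            dHk = dH[:, :P, m * cfg.d_f : (m + 1) * cfg.d_f]
            dCp = np.zeros((B, P, cfg.pool, cfg.d_f))
            np.put_along_axis(dCp, arg[:, :, None, :], dHk[:, :, None, :], axis=2)
            dC = dCp.reshape(B, P * cfg.pool, cfg.d_f)[:, :L, :]
            dZ = dC * dact(kc["Z"], kc["C"])
            grads[f"Wc{k}"] = np.einsum("blw,blf->wf", kc["win"], dZ)
            grads[f"bc{k}"] = dZ.sum(axis=(0, 1))
            dwin = (dZ @ p[f"Wc{k}"].T).reshape(B, L, k, cfg.d)
            for j in range(k):
                dX[:, j : j + L, :] += dwin[:, :, j, :]

        dW = np.zeros_like(p["W"])
        np.add.at(dW, cache["idx"], dX)
        dW[PAD_INDEX] = 0.0
        grads["W"] = dW

        if l2 > 0.0:
            for key in self.weight_keys:
                grads[key] = grads[key] + 2.0 * l2 * p[key]
            grads["W"][PAD_INDEX] = 0.0
        return grads, dX

    # -- convenience ------------------------------------------------------
    def predict_proba(self, idx: np.ndarray, batch_size: int = 64) -> np.ndarray:
        idx = np.atleast_2d(np.asarray(idx, dtype=np.int64))
        out = np.empty((idx.shape[0], self.config.n_labels))
        for s in range(0, idx.shape[0], batch_size):
            out[s : s + batch_size] = self.forward(idx[s : s + batch_size])[0]
        return out

    def copy(self) -> "ModelState":
        return ModelState(self.config, {k: v.copy() for k, v in self.params.items()}, self.y_g.copy())

    # -- checkpointing ----------------------------------------------------
    def save(self, path: str | Path, manifest: dict | None = None) -> None:
        """Single-file checkpoint with a manifest guarding silent mismatches."""
        meta = {
            "config": asdict(self.config),
            "manifest": manifest or {},
        }
        np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
                 y_g=self.y_g, **self.params)

    @classmethod
    def load(cls, path: str | Path, expect_manifest: dict | None = None) -> "ModelState":
        with np.load(path) as z:
            meta = json.loads(bytes(z["__meta__"].tobytes()).decode())
            cfg_d = meta["config"]
            cfg_d["kernel_sizes"] = tuple(cfg_d["kernel_sizes"])
            cfg = ModelConfig(**cfg_d)
            params = {k: z[k] for k in z.files if k not in ("__meta__", "y_g")}
            y_g = z["y_g"]
        if expect_manifest:
            stored = meta["manifest"]
            for key, val in expect_manifest.items():
                if stored.get(key) != val:
                    raise ValueError(f"checkpoint manifest mismatch on {key!r}")
        return cls(cfg, params, y_g)


def state_manifest(codes, vocab) -> dict:
    """Stable hashes of the code set and vocabulary for checkpoint manifests."""
    import hashlib

    code_h = hashlib.sha256("\n".join(codes.codes).encode()).hexdigest()[:16]
    vocab_items = sorted(vocab.token_to_index.items(), key=lambda kv: kv[1])
    vocab_h = hashlib.sha256("\n".join(t for t, _ in vocab_items).encode()).hexdigest()[:16]
    return {"codes_sha": code_h, "vocab_sha": vocab_h, "l_g": len(codes), "v": vocab.size}
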