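"""Loss, FGM adversarial training, and the optimization loop.

The objective is multi-label binary cross-entropy summed over codes
(mean over the batch) plus an L2 penalty on the weight matrices.

Adversarial training uses FGM (fast gradient method): after the clean
backward pass, the gradient ``g`` of the loss with respect to the
embedded input ``X`` is normalised to an L2 ball of radius epsilon,
``r_adv = eps * g / ||g||2``, a second forward/backward runs on
``X + r_adv``, the embedding table is left untouched (the perturbation
lives on the activations, never written back), and one optimizer update
applies the summed clean + adversarial gradients.  The intent is
robustness to per-author writing-style variation.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .corpus import EncodedRecord
from .model import ModelConfig, ModelState

_EPS_CLAMP = 1e-7


@dataclass
class TrainConfig:
    """Optimization hyperparameters; defaults follow the reference setup."""

    lr: float = 0.001
    batch_size: int = 16
    epochs: int = 30
    l2: float = 1e-5          # lambda, L2 regularization
    epsilon: float = 1.0      # FGM perturbation radius (no canonical value; logged)
    adversarial: bool = True
    per_example_norm: bool = False  # normalise r_adv per record instead of per batch
    seed: int = 0
    val_fraction: float = 0.2
    patience: int = 5         # early stop on validation micro-F1
    p_at_k: int = 5

    def __post_init__(self) -> None:
        if min(self.lr, self.batch_size, self.epochs) <= 0 or self.l2 < 0 or self.epsilon < 0:
            raise ValueError("lr, batch_size, epochs must be positive; l2, epsilon >= 0")
        if not (0.0 < self.val_fraction < 1.0):
            raise ValueError("val_fraction must be in (0,1)")


class Adam:
    """Plain Adam over a dict of parameter arrays (keys match gradients)."""

    def __init__(self, lr: float = 0.001, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m: dict[str, np.ndarray] = {}
        self.v: dict[str, np.ndarray] = {}

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for key, g in grads.items():
            if key not in self.m:
                self.m[key] = np.zeros_like(params[key])
                self.v[key] = np.zeros_like(params[key])
            self.m[key] = b1 * self.m[key] + (1 - b1) * g
            self.v[key] = b2 * self.v[key] + (1 - b2) * g * g
            mhat = self.m[key] / (1 - b1 ** self.t)
            vhat = self.v[key] / (1 - b2 ** self.t)
            params[key] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def bce_l2_loss(
    yhat: np.ndarray, y: np.ndarray, weight_sq_norm: float = 0.0, l2: float = 0.0
) -> float:
    """Binary cross-entropy summed over labels, mean over records, + L2.

    Probabilities are clamped to ``[1e-7, 1-1e-7]`` for numerical
    stability before the logs.
    """
    yhat = np.clip(np.atleast_2d(yhat), _EPS_CLAMP, 1.0 - _EPS_CLAMP)
    y = np.atleast_2d(y)
    per_record = -(y * np.log(yhat) + (1 - y) * np.log(1 - yhat)).sum(axis=1)
    return float(per_record.mean() + l2 * weight_sq_norm)


def fgm_perturb(g: np.ndarray, epsilon: float, per_example: bool = False) -> np.ndarray:
    """FGM perturbation ``eps * g / ||g||2``; zero gradient maps to zero.

    By default the norm is the Frobenius norm of the whole batch
    gradient (one shared perturbation direction per step); with
    ``per_example`` each record's slice is normalised separately.
    """
    g = np.asarray(g, dtype=np.float64)
    if not np.all(np.isfinite(g)):
        raise ValueError("non-finite gradient passed to FGM")
    if per_example and g.ndim == 3:
        norms = np.sqrt(np.sum(g * g, axis=(1, 2), keepdims=True))
        return np.where(norms > 0, epsilon * g / np.where(norms > 0, norms, 1.0), 0.0)
    norm = float(np.sqrt(np.sum(g * g)))
    if norm == 0.0:
        return np.zeros_like(g)
    return epsilon * g / norm


def adversarial_step(
    state: ModelState,
    idx_batch: np.ndarray,
    y_batch: np.ndarray,
    cfg: TrainConfig,
    adam: Adam,
    rng: np.random.Generator,
) -> float:
    """One FGM training step; returns the clean-batch loss.

    (1) clean forward/backward, (2) build ``r_adv`` from the input
    gradient, (3) forward/backward on the perturbed embeddings,
    (4) the embedding table was never modified — nothing to restore —
    and (5) a single Adam update with the summed gradients.
    """
    yhat, _, cache = state.forward(idx_batch, train=True, rng=rng)
    loss = bce_l2_loss(yhat, y_batch, state.weight_sq_norm(), cfg.l2)
    grads, dX = state.backward(cache, y_batch, cfg.l2)

    r_adv = fgm_perturb(dX, cfg.epsilon, per_example=cfg.per_example_norm)
    yhat_adv, _, cache_adv = state.forward(
        idx_batch, X_override=cache["X"] + r_adv, train=True, rng=rng
    )
    grads_adv, _ = state.backward(cache_adv, y_batch, cfg.l2)

    total = {k: grads[k] + grads_adv[k] for k in grads}
    adam.step(state.params, total)
    state.params["W"][0] = 0.0  # PAD row stays pinned at zero
    if not np.isfinite(loss):
        raise RuntimeError(f"training diverged: loss={loss!r}")
    return loss


def plain_step(
    state: ModelState,
    idx_batch: np.ndarray,
    y_batch: np.ndarray,
    cfg: TrainConfig,
    adam: Adam,
    rng: np.random.Generator,
) -> float:
    yhat, _, cache = state.forward(idx_batch, train=True, rng=rng)
    loss = bce_l2_loss(yhat, y_batch, state.weight_sq_norm(), cfg.l2)
    grads, _ = state.backward(cache, y_batch, cfg.l2)
    adam.step(state.params, grads)
    state.params["W"][0] = 0.0
    if not np.isfinite(loss):
        raise RuntimeError(f"training diverged: loss={loss!r}")
    return loss


def stack_records(records: Sequence[EncodedRecord]) -> tuple[np.ndarray, np.ndarray]:
    idx = np.stack([r.token_indices for r in records]).astype(np.int64)
    y = np.stack([r.label_vector for r in records]).astype(np.float64)
    return idx, y


def train(
    records: Sequence[EncodedRecord],
    y_g: np.ndarray,
    model_cfg: ModelConfig,
    cfg: TrainConfig | None = None,
    val_records: Sequence[EncodedRecord] | None = None,
) -> tuple[ModelState, list[dict]]:
    """Train the coder; returns the best-validation state and history.

    When ``val_records`` is not given, a seeded shuffle splits off
    ``val_fraction`` of the records for validation.  Each epoch logs
    train loss and validation micro-F1 / micro-AUC / P@k; the checkpoint
    with the best validation micro-F1 is returned, and training stops
    early after ``patience`` epochs without improvement.
    """
    from .evaluation import confusion, micro_auc, micro_prf, precision_at_k

    cfg = cfg or TrainConfig()
    rng = np.random.default_rng(cfg.seed)

    if val_records is None:
        order = rng.permutation(len(records))
        n_val = max(1, int(round(cfg.val_fraction * len(records))))
        val_records = [records[i] for i in order[:n_val]]
        records = [records[i] for i in order[n_val:]]
    if not records or not val_records:
        raise ValueError("both train and validation splits must be non-empty")

    idx_tr, y_tr = stack_records(records)
    idx_va, y_va = stack_records(val_records)

    state = ModelState.init(model_cfg, y_g, seed=cfg.seed)
    adam = Adam(lr=cfg.lr)
    step_fn = adversarial_step if cfg.adversarial else plain_step

    history: list[dict] = []
    best_f1, best_state, stall = -1.0, state.copy(), 0
    k = min(cfg.p_at_k, model_cfg.n_labels)

    for epoch in range(1, cfg.epochs + 1):
        order = rng.permutation(len(records))
        losses = []
        for s in range(0, len(order), cfg.batch_size):
            sel = order[s : s + cfg.batch_size]
            losses.append(step_fn(state, idx_tr[sel], y_tr[sel], cfg, adam, rng))

        scores = state.predict_proba(idx_va)
        prec, rec, f1 = micro_prf(confusion(scores, y_va))
        auc = micro_auc(scores, y_va)
        row = {
            "epoch": epoch,
            "train_loss": float(np.mean(losses)),
            "val_micro_f1": f1,
            "val_micro_auc": auc if auc is not None else float("nan"),
            "val_p_at_5": precision_at_k(scores, y_va, k),
        }
        history.append(row)

        if f1 > best_f1:
            best_f1, best_state, stall = f1, state.copy(), 0
        else:
            stall += 1
            if stall >= cfg.patience:
                break
    return best_state, history


def write_history(history: Sequence[dict], path: str | Path) -> None:
    cols = ["epoch", "train_loss", "val_micro_f1", "val_micro_auc", "val_p_at_5"]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for row in history:
            fh.write("\t".join(f"{row[c]:.6g}" if c != "epoch" else str(row[c]) for c in cols) + "\n")


# ---------------------------------------------------------------------------
# flat key:value config files
# ---------------------------------------------------------------------------

_CONFIG_KEYS = {
    "d": int, "d_g": int, "d_f": int, "lr": float, "dp": float, "lambda": float,
    "filter_sizes": str, "max_len": int, "batch_size": int, "epsilon": float,
    "seed": int, "epochs": int, "pool": int, "adversarial": int,
}


def read_config(path: str | Path) -> dict:
    """Parse a flat ``key: value`` config file (hyperparameter names as keys)."""
    out: dict = {}
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            key, _, val = line.partition(":")
            key, val = key.strip(), val.strip()
            if key not in _CONFIG_KEYS:
                raise KeyError(f"unknown config key {key!r}")
            out[key] = _CONFIG_KEYS[key](val)
    if "filter_sizes" in out:
        out["filter_sizes"] = tuple(int(x) for x in out["filter_sizes"].replace(",", " ").split())
    return out


def configs_from_mapping(
    mapping: dict, vocab_size: int, n_labels: int
) -> tuple[ModelConfig, TrainConfig]:
    """Build model/train configs from a flat config mapping, defaults elsewhere."""
    mc = ModelConfig(
        vocab_size=vocab_size,
        n_labels=n_labels,
        d=mapping.get("d", 100),
        d_g=mapping.get("d_g", 128),
        d_f=mapping.get("d_f", 50),
        kernel_sizes=tuple(mapping.get("filter_sizes", (4, 5, 6))),
        pool=mapping.get("pool", 2),
        dropout=mapping.get("dp", 0.4),
        max_len=mapping.get("max_len", 1800),
    )
    tc = TrainConfig(
        lr=mapping.get("lr", 0.001),
        batch_size=mapping.get("batch_size", 16),
        epochs=mapping.get("epochs", 30),
        l2=mapping.get("lambda", 1e-5),
        epsilon=mapping.get("epsilon", 1.0),
        adversarial=bool(mapping.get("adversarial", 1)),
        seed=mapping.get("seed", 0),
    )
    return mc, tc
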