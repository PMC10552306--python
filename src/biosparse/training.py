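"""Focal-loss training with Adam.

The case/control imbalance is handled by a weighted focal binary
cross-entropy: per sample, ``-w_y * (1 - p_t)^gamma * log(p_t)`` with
``p_t = p`` for cases and ``1 - p`` for controls, ``w_1 = alpha`` and
``w_0 = 1 - alpha``.  With cases the majority class, ``alpha`` set to the
control fraction down-weights them; the focusing exponent ``gamma``
additionally down-weights well-classified samples.
"""

from __future__ import annotations

import json
import math
import time
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

from .architectures import GeneModuleSpec, HeadSpec, Model, build_model

__all__ = [
    "TrainConfig",
    "focal_alpha_from_counts",
    "focal_loss",
    "focal_loss_grad",
    "train",
    "AdamState",
    "NNEstimator",
]

_EPS = 1e-7


@dataclass
class TrainConfig:
    """Optimisation settings.

    ``focal_alpha=None`` computes alpha from the training-label counts
    (control fraction).  ``l1_pathway_penalty`` adds an L1 penalty on the
    gene-pathway layer's weights (used when learning sparsity arrangements).
    """

    learning_rate: float = 0.001
    batch_size: int = 128
    epochs: int = 30
    focal_alpha: float | None = None
    focal_gamma: float = 2.0
    weight_decay: float = 0.0
    dropout: float = 0.0
    l1_pathway_penalty: float = 0.0
    seed: int = 0
    log_path: str | None = None

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.focal_gamma < 0:
            raise ValueError("focal_gamma must be >= 0")
        if self.focal_alpha is not None and not (0.0 < self.focal_alpha < 1.0):
            raise ValueError("focal_alpha must be in (0, 1)")


def focal_alpha_from_counts(n_controls: int, n_cases: int) -> float:
    """alpha = controls / (controls + cases); e.g. 480/(480+3318) = 0.12638."""
    if n_controls <= 0 or n_cases <= 0:
        raise ValueError("both class counts must be positive")
    return n_controls / (n_controls + n_cases)


def _check_labels(y: np.ndarray) -> np.ndarray:
    y = np.asarray(y)
    if not np.isin(y, (0, 1)).all():
        raise ValueError("labels must be 0/1")
    return y.astype(np.float64)


def focal_loss(
    p: np.ndarray, y: np.ndarray, alpha: float = 0.5, gamma: float = 2.0
) -> float:
    """Mean weighted focal binary cross-entropy over the batch."""
    y = _check_labels(y)
    p = np.clip(np.asarray(p, dtype=np.float64), _EPS, 1.0 - _EPS)
    pt = np.where(y == 1.0, p, 1.0 - p)
    w = np.where(y == 1.0, alpha, 1.0 - alpha)
    loss = -w * (1.0 - pt) ** gamma * np.log(pt)
    return float(loss.mean())


def focal_loss_grad(
    p: np.ndarray, y: np.ndarray, alpha: float, gamma: float
) -> np.ndarray:
    """d(mean focal loss)/d(pre-sigmoid score), per sample.

    Derivation: with p_t the probability of the true class and s the
    pre-sigmoid score, dp_t/ds = +/- p_t(1-p_t), giving
    ``w * sign * (gamma * p_t * (1-p_t)^gamma * log(p_t) - (1-p_t)^(gamma+1))``
    which for gamma=0 reduces to the usual (p - y) weighted by w.
    """
    y = _check_labels(y)
    p = np.clip(np.asarray(p, dtype=np.float64), _EPS, 1.0 - _EPS)
    pt = np.where(y == 1.0, p, 1.0 - p)
    w = np.where(y == 1.0, alpha, 1.0 - alpha)
    sign = np.where(y == 1.0, 1.0, -1.0)
    core = gamma * pt * (1.0 - pt) ** gamma * np.log(pt) - (1.0 - pt) ** (gamma + 1.0)
    return (w * sign * core / p.size).astype(np.float32)


@dataclass
class AdamState:
    """First/second-moment accumulators, exposed so mask-update hooks can
    reset the state of rewired connections."""

    m: dict = field(default_factory=dict)
    v: dict = field(default_factory=dict)
    t: int = 0

    def step(self, params: dict, grads: dict, lr: float,
             beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8) -> None:
        self.t += 1
        b1t = 1.0 - beta1 ** self.t
        b2t = 1.0 - beta2 ** self.t
        for k, g in grads.items():
            if k not in params:
                continue  # auxiliary gradients (e.g. dense view of a masked layer)
            if k not in self.m:
                self.m[k] = np.zeros_like(params[k])
                self.v[k] = np.zeros_like(params[k])
            self.m[k] = beta1 * self.m[k] + (1.0 - beta1) * g
            self.v[k] = beta2 * self.v[k] + (1.0 - beta2) * g * g
            mhat = self.m[k] / b1t
            vhat = self.v[k] / b2t
            params[k] -= (lr * mhat / (np.sqrt(vhat) + eps)).astype(params[k].dtype)


def _is_weight(name: str) -> bool:
    return not name.endswith("_b") and not name.endswith("_b1") and not name.endswith("_b2")


def train(
    model: Model,
    X_train,
    y_train,
    cfg: TrainConfig,
    step_hook: Callable | None = None,
) -> tuple[Model, list[float]]:
    """Seeded mini-batch training; returns the model and per-epoch mean loss.

    The run is fully determined by ``(cfg.seed, data, initial parameters)``:
    shuffling and dropout use generators derived from the seed.
    """
    X = model._coerce(X_train)
    y = _check_labels(y_train)
    n = X.shape[0]
    if y.shape[0] != n:
        raise ValueError("X and y length mismatch")
    alpha = cfg.focal_alpha
    if alpha is None:
        n_cases = int(y.sum())
        alpha = focal_alpha_from_counts(n - n_cases, n_cases)

    dropout = cfg.dropout if cfg.dropout > 0 else model.head.dropout
    shuffle_rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 11]))
    drop_rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 13]))
    opt = AdamState()
    history: list[float] = []
    log_fh = open(cfg.log_path, "a") if cfg.log_path else None
    step = 0
    try:
        for epoch in range(cfg.epochs):
            t0 = time.time()
            order = shuffle_rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, cfg.batch_size):
                idx = order[start : start + cfg.batch_size]
                xb, yb = X[idx], y[idx]
                prob, _, cache = model.forward(xb, dropout=dropout, rng=drop_rng)
                loss = focal_loss(prob, yb, alpha, cfg.focal_gamma)
                if not math.isfinite(loss):
                    raise RuntimeError(
                        f"non-finite training loss at epoch {epoch}, batch {start // cfg.batch_size}"
                    )
                epoch_loss += loss * len(idx)
                dscore = focal_loss_grad(prob, yb, alpha, cfg.focal_gamma)
                grads = model.backward(cache, dscore)
                if cfg.weight_decay:
                    for k in grads:
                        if k in model.params and _is_weight(k):
                            grads[k] = grads[k] + cfg.weight_decay * model.params[k]
                if cfg.l1_pathway_penalty and "pw_W" in model.params:
                    grads["pw_W"] = grads["pw_W"] + cfg.l1_pathway_penalty * np.sign(
                        model.params["pw_W"]
                    )
                opt.step(model.params, grads, cfg.learning_rate)
                if model.mask_matrix is not None:
                    model.params["pw_W"] *= model.mask_matrix
                if model.gg_mask is not None:
                    model.params["gg_W"] *= model.gg_mask
                step += 1
                if step_hook is not None:
                    step_hook(step, model, grads, opt)
            history.append(epoch_loss / n)
            if log_fh:
                log_fh.write(
                    json.dumps(
                        {"epoch": epoch, "loss": history[-1], "wall_time": time.time() - t0}
                    )
                    + "\n"
                )
    finally:
        if log_fh:
            log_fh.close()
    model._n_steps = step
    return model, history


class NNEstimator:
    """sklearn-style wrapper so the CV harness treats gene-module networks
    and baseline fitters identically.

    ``head`` may be a fixed :class:`HeadSpec` or a callable ``seed ->
    HeadSpec`` (used when the head's sparsity mask itself is randomised per
    fit, e.g. random-degree masks).
    """

    def __init__(
        self,
        gm: GeneModuleSpec,
        head,
        gene_ids: Sequence[str],
        train_cfg: TrainConfig,
        seed: int = 0,
    ):
        self.gm = gm
        self.head = head
        self.gene_ids = list(gene_ids)
        self.train_cfg = train_cfg
        self.seed = seed
        self.model_: Model | None = None
        self.history_: list[float] | None = None

    def fit(self, X, y):
        head = self.head(self.seed) if callable(self.head) else self.head
        model = build_model(self.gm, head, self.gene_ids, seed=self.seed)
        cfg = replace(self.train_cfg, seed=self.seed)
        self.model_, self.history_ = train(model, X, y, cfg)
        return self

    def predict_proba(self, X) -> np.ndarray:
        if self.model_ is None:
            raise RuntimeError("estimator is not fitted")
        return self.model_.predict_proba(X)
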