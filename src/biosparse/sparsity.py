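"""Connection arrangements for the sparse gene-pathway layer.

Four ways to choose which gene neuron feeds which hidden (pathway) neuron:

* ``knowledge``  — each gene wired to one of its annotated pathways (picked
  uniformly at random among its memberships; orphans to the dummy pathway);
* ``random``     — a chosen fraction of genes wired to uniformly random
  hidden neurons, one connection per connected gene;
* ``l1_learned`` — connections kept by magnitude after training a dense
  layer under an L1 penalty;
* ``rigl``       — connections evolved during training by magnitude-based
  drop and gradient-based grow steps at constant connection count.

``full_membership`` additionally wires every gene to *all* of its pathways
(the multi-connection variant).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .encoding import DUMMY_PATHWAY, PathwayMap

__all__ = [
    "SparsityMask",
    "knowledge_mask",
    "random_mask",
    "full_membership_mask",
    "l1_learned_mask",
    "rigl_train",
    "RigLConfig",
]


@dataclass
class SparsityMask:
    """Binary gene x hidden connectivity with provenance metadata."""

    matrix: np.ndarray  # (n_genes, n_hidden) of {0,1}
    gene_ids: list[str]
    hidden_ids: list[str]
    provenance: str  # knowledge | random | l1_learned | rigl | full_membership
    seed: int | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float32)
        if self.matrix.shape != (len(self.gene_ids), len(self.hidden_ids)):
            raise ValueError("mask shape inconsistent with gene/hidden ids")
        if not np.isin(self.matrix, (0.0, 1.0)).all():
            raise ValueError("mask entries must be 0 or 1")

    @property
    def n_connections(self) -> int:
        return int(self.matrix.sum())

    @property
    def gene_degrees(self) -> np.ndarray:
        return self.matrix.sum(axis=1).astype(int)

    @property
    def n_connected_genes(self) -> int:
        return int((self.gene_degrees > 0).sum())

    def save(self, path: str | Path) -> None:
        """Sparse coordinate TSV plus a JSON header."""
        path = Path(path)
        rows = np.nonzero(self.matrix)
        lines = [
            f"{self.gene_ids[g]}\t{self.hidden_ids[h]}"
            for g, h in zip(rows[0], rows[1])
        ]
        path.with_suffix(".tsv").write_text("\n".join(lines) + "\n")
        header = {
            "provenance": self.provenance,
            "seed": self.seed,
            "n_connections": self.n_connections,
            "gene_ids": self.gene_ids,
            "hidden_ids": self.hidden_ids,
            "meta": self.meta,
        }
        path.with_suffix(".json").write_text(json.dumps(header))

    @classmethod
    def load(cls, path: str | Path) -> "SparsityMask":
        path = Path(path)
        header = json.loads(path.with_suffix(".json").read_text())
        gene_ids = header["gene_ids"]
        hidden_ids = header["hidden_ids"]
        gi = {g: i for i, g in enumerate(gene_ids)}
        hi = {h: i for i, h in enumerate(hidden_ids)}
        m = np.zeros((len(gene_ids), len(hidden_ids)), dtype=np.float32)
        for line in path.with_suffix(".tsv").read_text().splitlines():
            if not line.strip():
                continue
            g, h = line.split("\t")
            m[gi[g], hi[h]] = 1.0
        return cls(
            matrix=m,
            gene_ids=gene_ids,
            hidden_ids=hidden_ids,
            provenance=header["provenance"],
            seed=header["seed"],
            meta=header.get("meta", {}),
        )


def knowledge_mask(pm: PathwayMap, genes: Sequence[str], seed: int = 0) -> SparsityMask:
    """One connection per gene, to a uniformly chosen member pathway.

    ``pm`` must be finalized against ``genes`` so that every gene (orphans
    included, via the dummy pathway) has at least one membership.
    """
    if not pm.finalized:
        pm = pm.finalize(genes)
    rng = np.random.default_rng(seed)
    genes = list(genes)
    chosen: dict[str, str] = {}
    for g in genes:
        members = sorted(pm.pathways_of(g))
        if not members:
            members = [pm.dummy_id]
        chosen[g] = members[rng.integers(len(members))]
    hidden_ids = [p for p in pm.pathway_ids if p in set(chosen.values())]
    if pm.dummy_id in set(chosen.values()) and pm.dummy_id not in hidden_ids:
        hidden_ids.append(pm.dummy_id)
    hi = {p: j for j, p in enumerate(hidden_ids)}
    m = np.zeros((len(genes), len(hidden_ids)), dtype=np.float32)
    for i, g in enumerate(genes):
        m[i, hi[chosen[g]]] = 1.0
    return SparsityMask(
        matrix=m, gene_ids=genes, hidden_ids=hidden_ids,
        provenance="knowledge", seed=seed,
    )


def random_mask(
    n_genes: int,
    n_hidden: int,
    gene_fraction: float = 1.0,
    seed: int = 0,
    gene_ids: Sequence[str] | None = None,
) -> SparsityMask:
    """Connect ``round(gene_fraction * n_genes)`` genes, one random hidden
    neuron each; the remaining genes have degree 0 (dropped from the model)."""
    if not (0.0 < gene_fraction <= 1.0):
        raise ValueError("gene_fraction must be in (0, 1]")
    if n_hidden < 1:
        raise ValueError("n_hidden must be >= 1")
    rng = np.random.default_rng(seed)
    n_connected = int(round(gene_fraction * n_genes))
    picked = rng.choice(n_genes, size=n_connected, replace=False)
    targets = rng.integers(n_hidden, size=n_connected)
    m = np.zeros((n_genes, n_hidden), dtype=np.float32)
    m[picked, targets] = 1.0
    if gene_ids is None:
        gene_ids = [f"g{i}" for i in range(n_genes)]
    return SparsityMask(
        matrix=m,
        gene_ids=list(gene_ids),
        hidden_ids=[f"h{j}" for j in range(n_hidden)],
        provenance="random",
        seed=seed,
        meta={"gene_fraction": gene_fraction},
    )


def full_membership_mask(pm: PathwayMap, genes: Sequence[str]) -> SparsityMask:
    """All gene-pathway relations: mask[g, p] = 1 iff p in memberships(g)."""
    if not pm.finalized:
        pm = pm.finalize(genes)
    genes = list(genes)
    hidden_ids = list(pm.pathway_ids)
    hi = {p: j for j, p in enumerate(hidden_ids)}
    m = np.zeros((len(genes), len(hidden_ids)), dtype=np.float32)
    for i, g in enumerate(genes):
        for p in pm.pathways_of(g):
            m[i, hi[p]] = 1.0
    return SparsityMask(
        matrix=m, gene_ids=genes, hidden_ids=hidden_ids,
        provenance="full_membership",
    )


def l1_learned_mask(
    train_data: tuple[np.ndarray, np.ndarray],
    base_model_config: dict,
    l1_strength: float = 1e-3,
    budget: int | None = None,
    seed: int = 0,
) -> SparsityMask:
    """Learn a sparsity arrangement by L1-penalised dense training.

    Trains a dense gene-pathway layer with an L1 penalty on its weights, then
    keeps the ``budget`` largest-magnitude connections subject to at most one
    connection per gene (so the result is comparable, at equal budget and
    hidden width, with the degree-1 arrangements).
    """
    from .architectures import GeneModuleSpec, HeadSpec, build_model
    from .training import TrainConfig, train

    X, y = train_data
    n_genes = X.shape[1]
    n_hidden = base_model_config.get("n_hidden", 10)
    if budget is None:
        budget = n_genes
    if budget <= 0:
        raise ValueError("budget must be a positive connection count")
    if budget > n_genes:
        raise ValueError(
            "budget exceeds n_genes: at most one connection per gene is kept"
        )
    gm = GeneModuleSpec(
        input_dim=X.shape[2],
        hidden_units=base_model_config.get("gene_hidden", 8),
    )
    head = HeadSpec(kind="dense", hidden_units=n_hidden)
    model = build_model(
        gm, head,
        gene_ids=base_model_config.get("gene_ids", [f"g{i}" for i in range(n_genes)]),
        seed=seed,
    )
    cfg = TrainConfig(
        epochs=base_model_config.get("epochs", 50),
        learning_rate=base_model_config.get("learning_rate", 1e-2),
        batch_size=base_model_config.get("batch_size", 128),
        l1_pathway_penalty=l1_strength,
        seed=seed,
    )
    model, history = train(model, X, y, cfg)
    if not all(math.isfinite(h) for h in history):
        raise RuntimeError("non-finite training loss during L1 mask learning")

    w = np.abs(model.params["pw_W"])
    order = np.argsort(-w, axis=None, kind="stable")  # ties: lowest flat index first
    m = np.zeros_like(w, dtype=np.float32)
    used_genes: set[int] = set()
    taken = 0
    for flat in order:
        g, h = divmod(int(flat), w.shape[1])
        if g in used_genes:
            continue
        m[g, h] = 1.0
        used_genes.add(g)
        taken += 1
        if taken == budget:
            break
    return SparsityMask(
        matrix=m,
        gene_ids=model.gene_ids,
        hidden_ids=[f"h{j}" for j in range(n_hidden)],
        provenance="l1_learned",
        seed=seed,
        meta={"l1_strength": l1_strength, "budget": budget},
    )


@dataclass
class RigLConfig:
    """Drop/grow schedule for dynamic sparse training.

    ``drop_fraction`` is cosine-annealed from its initial value to 0 at
    ``stop_iteration``; mask updates happen every ``update_interval``
    optimizer steps and cease after ``stop_iteration`` (defaulting to 75% of
    the training run when None).
    """

    update_interval: int = 100
    drop_fraction: float = 0.3
    stop_iteration: int | None = None

    def fraction_at(self, step: int) -> float:
        if self.stop_iteration in (None, 0):
            return self.drop_fraction
        t = min(step / self.stop_iteration, 1.0)
        return self.drop_fraction / 2.0 * (1.0 + math.cos(math.pi * t))


def rigl_update(
    mask: np.ndarray,
    weights: np.ndarray,
    dense_grad: np.ndarray,
    drop_fraction: float,
) -> tuple[np.ndarray, np.ndarray]:
    """One RigL step: drop the lowest-|w| active connections, grow the same
    number of inactive positions with the largest |gradient|.

    Ties break toward the lowest flat (gene, hidden) index.  Returns the new
    mask and the indices grown (weights there should restart at zero).
    """
    if not (0.0 <= drop_fraction < 1.0):
        raise ValueError("drop fraction must be in [0, 1)")
    active = np.flatnonzero(mask.ravel() > 0)
    n_drop = int(drop_fraction * active.size)
    if n_drop == 0:
        return mask.copy(), np.empty(0, dtype=int)
    w_mag = np.abs(weights.ravel()[active])
    drop_order = np.lexsort((active, w_mag))  # by magnitude, then index
    dropped = active[drop_order[:n_drop]]

    new_mask = mask.copy().ravel()
    new_mask[dropped] = 0.0
    # grow only among positions inactive before this update (a connection
    # dropped now is not immediately regrown)
    inactive = np.flatnonzero(mask.ravel() == 0)
    g_mag = np.abs(dense_grad.ravel()[inactive])
    grow_order = np.lexsort((inactive, -g_mag))  # by -|grad|, then index
    grown = inactive[grow_order[:n_drop]]
    new_mask[grown] = 1.0
    return new_mask.reshape(mask.shape), grown


def rigl_train(
    model,
    train_data: tuple[np.ndarray, np.ndarray],
    rigl_config: RigLConfig,
    train_cfg=None,
    seed: int = 0,
):
    """Train a sparse-layer model while evolving its mask with RigL.

    The connection count is invariant across updates; after ``stop_iteration``
    the mask is frozen and training continues to the configured epoch budget.
    Returns ``(trained model, final SparsityMask)``.
    """
    from .training import TrainConfig, train

    if model.mask_matrix is None:
        raise ValueError("RigL requires a model with a sparse gene-pathway layer")
    if not (0.0 <= rigl_config.drop_fraction < 1.0):
        raise ValueError("drop fraction must be in [0, 1)")
    X, y = train_data
    if train_cfg is None:
        train_cfg = TrainConfig(seed=seed)
    cfg = rigl_config
    if cfg.stop_iteration is None:
        steps_per_epoch = max(1, math.ceil(X.shape[0] / train_cfg.batch_size))
        cfg = RigLConfig(
            update_interval=cfg.update_interval,
            drop_fraction=cfg.drop_fraction,
            stop_iteration=int(0.75 * steps_per_epoch * train_cfg.epochs),
        )

    count0 = int(model.mask_matrix.sum())

    def hook(step, mdl, grads, opt_state):
        if step == 0 or step % cfg.update_interval != 0:
            return
        if cfg.stop_iteration is not None and step > cfg.stop_iteration:
            return
        frac = cfg.fraction_at(step)
        new_mask, grown = rigl_update(
            mdl.mask_matrix, mdl.params["pw_W"], grads["pw_W_dense"], frac
        )
        assert int(new_mask.sum()) == count0  # connection count is invariant
        mdl.set_mask_matrix(new_mask)
        if grown.size:
            flat_w = mdl.params["pw_W"].ravel()
            flat_w[grown] = 0.0
            for state in (opt_state.m.get("pw_W"), opt_state.v.get("pw_W")):
                if state is not None:
                    state.ravel()[grown] = 0.0

    model, history = train(model, X, y, train_cfg, step_hook=hook)
    final = SparsityMask(
        matrix=model.mask_matrix.copy(),
        gene_ids=model.gene_ids,
        hidden_ids=model.hidden_ids,
        provenance="rigl",
        seed=seed,
        meta={
            "update_interval": cfg.update_interval,
            "drop_fraction": cfg.drop_fraction,
            "stop_iteration": cfg.stop_iteration,
        },
    )
    return model, final
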