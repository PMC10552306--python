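"""Ensembles of randomly sparsified networks.

Instead of subsampling samples or features, ensemble diversity comes from
the connectivity itself: each member uses its own random gene-pathway mask
(and its own initialisation/shuffling seed), all members are trained on the
identical training set, and predictions are averaged.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.special import expit, logit

from .architectures import GeneModuleSpec, HeadSpec, Model, build_model
from .sparsity import random_mask
from .training import TrainConfig, train

__all__ = ["Ensemble", "train_ensemble", "predict_ensemble"]


@dataclass
class Ensemble:
    members: list  # list[Model]
    member_seeds: list
    gene_fraction: float
    n_hidden: int
    base_seed: int
    aggregate: str = "probability"  # or "logit"
    stats: object | None = None  # shared standardization stats, if any

    def __post_init__(self) -> None:
        if len(self.members) < 1:
            raise ValueError("an ensemble needs at least one member")

    @property
    def n_members(self) -> int:
        return len(self.members)

    def member_predictions(self, X) -> np.ndarray:
        """(n_members, n_samples) member case probabilities."""
        return np.stack([m.predict_proba(X) for m in self.members])

    def predict_proba(self, X) -> np.ndarray:
        preds = self.member_predictions(X)
        if self.aggregate == "probability":
            return preds.mean(axis=0)
        if self.aggregate == "logit":
            return expit(logit(np.clip(preds, 1e-7, 1 - 1e-7)).mean(axis=0))
        raise ValueError(f"unknown aggregation {self.aggregate!r}")

    def save(self, directory: str | Path) -> None:
        """Directory of member checkpoints plus a manifest."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for i, m in enumerate(self.members):
            m.save(directory / f"member_{i:04d}.npz")
        manifest = {
            "member_seeds": [int(s) for s in self.member_seeds],
            "gene_fraction": self.gene_fraction,
            "n_hidden": self.n_hidden,
            "base_seed": self.base_seed,
            "aggregate": self.aggregate,
            "n_members": self.n_members,
        }
        (directory / "manifest.json").write_text(json.dumps(manifest))

    @classmethod
    def load(cls, directory: str | Path) -> "Ensemble":
        directory = Path(directory)
        manifest = json.loads((directory / "manifest.json").read_text())
        members = [
            Model.load(directory / f"member_{i:04d}.npz")
            for i in range(manifest["n_members"])
        ]
        return cls(
            members=members,
            member_seeds=manifest["member_seeds"],
            gene_fraction=manifest["gene_fraction"],
            n_hidden=manifest["n_hidden"],
            base_seed=manifest["base_seed"],
            aggregate=manifest["aggregate"],
        )


def train_ensemble(
    X,
    y,
    n_members: int = 100,
    gene_fraction: float = 1.0,
    n_hidden: int = 10,
    train_cfg: TrainConfig | None = None,
    base_seed: int = 0,
    gene_ids=None,
    gm: GeneModuleSpec | None = None,
    aggregate: str = "probability",
) -> Ensemble:
    """Train ``n_members`` randomly sparsified networks on the full training
    set; member i's mask uses seed ``base_seed + i``."""
    X = np.asarray(X, dtype=np.float32)
    n_genes = X.shape[1]
    if gene_ids is None:
        gene_ids = [f"g{i}" for i in range(n_genes)]
    if gm is None:
        gm = GeneModuleSpec(input_dim=X.shape[2])
    if train_cfg is None:
        train_cfg = TrainConfig()
    members, seeds = [], []
    for i in range(n_members):
        seed = base_seed + i
        mask = random_mask(
            n_genes, n_hidden, gene_fraction=gene_fraction, seed=seed,
            gene_ids=gene_ids,
        )
        head = HeadSpec(kind="biosparse", mask=mask)
        model = build_model(gm, head, gene_ids, seed=seed)
        cfg = TrainConfig(**{**train_cfg.__dict__, "seed": seed})
        try:
            model, _ = train(model, X, y, cfg)
        except Exception as err:  # surface which member failed
            raise RuntimeError(f"training failed for ensemble member {i}") from err
        members.append(model)
        seeds.append(seed)
    return Ensemble(
        members=members,
        member_seeds=seeds,
        gene_fraction=gene_fraction,
        n_hidden=n_hidden,
        base_seed=base_seed,
        aggregate=aggregate,
    )


def predict_ensemble(ens: Ensemble, X) -> np.ndarray:
    """Unweighted arithmetic mean of member case probabilities."""
    return ens.predict_proba(X)
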