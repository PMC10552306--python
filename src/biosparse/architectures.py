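"""Gene-module networks of graded expressivity.

Every model shares the same front end: a small MLP (the *gene module*)
applied with tied weights to each gene's C-dimensional mutational-load
histogram, producing one latent value G_i per gene.  The heads differ in how
gene neurons may interact on the way to the output:

* ``logreg``   — G wired straight to the output (a logistic regression over
  gene neurons; no gene-gene interaction at all);
* ``biosparse``— a sparse gene->pathway layer, at most one outgoing
  connection per gene, so two genes interact in at most one tanh neuron
  (enough for magnitude epistasis, not for sign-reversing interactions);
* ``dense``    — a fully connected hidden layer (universal approximator);
* ``linear``   — the biosparse wiring with every activation replaced by the
  identity, i.e. an additive model in the flattened input;
* ``multiconnect``       — sparse layer carrying *all* gene-pathway
  relations (genes may have degree > 1);
* ``stacked_interactome``— a sparse gene-gene interaction layer feeding a
  sparse gene-pathway layer.

The output neuron is a sigmoid, so predictions are case probabilities.

The forward/backward passes are implemented directly in NumPy; gradients are
exact and the parameter store is a plain dict of arrays, which keeps the
models deterministic, cheap to checkpoint, and easy to audit.
"""

from __future__ import annotations


import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.special import expit

from .encoding import GeneCentricTensor, VocabularyError
from .sparsity import SparsityMask

__all__ = [
    "GeneModuleSpec",
    "HeadSpec",
    "Model",
    "build_model",
    "predict_proba",
    "count_parameters",
]

HEAD_KINDS = (
    "logreg",
    "biosparse",
    "dense",
    "linear",
    "multiconnect",
    "stacked_interactome",
)


@dataclass(frozen=True)
class GeneModuleSpec:
    """The shared per-gene MLP: C inputs -> ``hidden_units`` -> 1 scalar G_i.

    With the defaults (16 inputs, 50 hidden units) the module has
    16*50 + 50*1 = 850 weights and 50 + 1 = 51 biases, shared across all
    genes regardless of how many there are.
    """

    input_dim: int = 16
    hidden_units: int = 50
    activation: str = "tanh"  # "tanh" or "identity"

    def __post_init__(self) -> None:
        if self.activation not in ("tanh", "identity"):
            raise ValueError(f"unknown activation {self.activation!r}")


@dataclass(frozen=True)
class HeadSpec:
    """Wiring between gene neurons and the sigmoid output."""

    kind: str
    hidden_units: int | None = None  # |P|, for dense heads
    mask: SparsityMask | None = None  # for sparse kinds
    gg_adjacency: np.ndarray | None = None  # for stacked_interactome
    activation: str = "tanh"
    dropout: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in HEAD_KINDS:
            raise ValueError(f"unknown head kind {self.kind!r}")


def _act(name: str):
    if name == "tanh":
        return np.tanh, lambda out: 1.0 - out * out
    return (lambda x: x), (lambda out: np.ones_like(out))


class Model:
    """A gene-module network with one of the heads above.

    Parameters live in ``self.params`` (name -> float32 array).  Masked
    connections are structurally absent: their weights are pinned at zero,
    their gradients masked, and they are excluded from parameter counts.
    """

    def __init__(
        self,
        gm: GeneModuleSpec,
        head: HeadSpec,
        gene_ids: Sequence[str],
        seed: int = 0,
    ):
        self.gm = gm
        self.head = head
        self.gene_ids = list(gene_ids)
        self.seed = seed
        G = len(self.gene_ids)
        C, H = gm.input_dim, gm.hidden_units

        linear = head.kind == "linear"
        self._act_gm = "identity" if linear else gm.activation
        self._act_head = "identity" if linear else head.activation

        self.mask_matrix: np.ndarray | None = None
        self.gg_mask: np.ndarray | None = None
        self.hidden_ids: list[str] = []

        if head.kind in ("biosparse", "linear", "multiconnect", "stacked_interactome"):
            if head.mask is None:
                raise ValueError(f"head kind {head.kind!r} requires a SparsityMask")
            if list(head.mask.gene_ids) != self.gene_ids:
                raise ValueError("mask gene ids do not match the model's gene vocabulary")
            deg = head.mask.gene_degrees
            if head.kind in ("biosparse", "linear") and np.any(deg > 1):
                bad = [self.gene_ids[i] for i in np.nonzero(deg > 1)[0][:5]]
                raise ValueError(
                    f"degree-1 head requires gene degree <= 1; offenders: {bad}"
                )
            self.mask_matrix = head.mask.matrix.astype(np.float32).copy()
            self.hidden_ids = list(head.mask.hidden_ids)
        elif head.kind == "dense":
            if not head.hidden_units:
                raise ValueError("dense head requires hidden_units")
            self.hidden_ids = [f"h{j}" for j in range(head.hidden_units)]
        if head.kind == "stacked_interactome":
            if head.gg_adjacency is None:
                raise ValueError("stacked_interactome head requires gg_adjacency")
            if head.gg_adjacency.shape != (G, G):
                raise ValueError("gg_adjacency shape mismatch with gene vocabulary")
            self.gg_mask = head.gg_adjacency.astype(np.float32).copy()

        rng = np.random.default_rng(seed)

        def uinit(shape, fan_in):
            b = 1.0 / np.sqrt(max(1, fan_in))
            return rng.uniform(-b, b, size=shape).astype(np.float32)

        P = len(self.hidden_ids)
        p: dict[str, np.ndarray] = {
            "gm_W1": uinit((C, H), C),
            "gm_b1": np.zeros(H, dtype=np.float32),
            "gm_w2": uinit((H,), H),
            "gm_b2": np.zeros((), dtype=np.float32),
        }
        if self.gg_mask is not None:
            fan = max(1.0, self.gg_mask.sum() / G)
            p["gg_W"] = uinit((G, G), fan) * self.gg_mask
            p["gg_b"] = np.zeros(G, dtype=np.float32)
        if head.kind == "logreg":
            p["out_w"] = uinit((G,), G)
            p["out_b"] = np.zeros((), dtype=np.float32)
        else:
            if self.mask_matrix is not None:
                fan = max(1.0, self.mask_matrix.sum() / max(1, P))
                p["pw_W"] = uinit((G, P), fan) * self.mask_matrix
            else:
                p["pw_W"] = uinit((G, P), G)
            p["pw_b"] = np.zeros(P, dtype=np.float32)
            p["out_w"] = uinit((P,), max(1, P))
            p["out_b"] = np.zeros((), dtype=np.float32)
        self.params = p

    # -- structural helpers -------------------------------------------------

    def set_mask_matrix(self, new_mask: np.ndarray) -> None:
        """Replace the gene-pathway mask (RigL); weights outside it are zeroed."""
        if self.mask_matrix is None:
            raise ValueError("model has no sparse gene-pathway layer")
        self.mask_matrix = new_mask.astype(np.float32)
        self.params["pw_W"] *= self.mask_matrix

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    # -- forward / backward -------------------------------------------------

    def _coerce(self, X) -> np.ndarray:
        if isinstance(X, GeneCentricTensor):
            if not X.standardized:
                raise ValueError("input tensor must be standardized with training stats")
            if list(X.gene_ids) != self.gene_ids:
                raise VocabularyError("input gene vocabulary does not match the model")
            X = X.counts
        X = np.asarray(X, dtype=np.float32)
        if X.ndim != 3 or X.shape[1] != self.n_genes or X.shape[2] != self.gm.input_dim:
            raise ValueError(
                f"expected input of shape (n, {self.n_genes}, {self.gm.input_dim})"
            )
        return X

    def forward(self, X, dropout: float = 0.0, rng: np.random.Generator | None = None):
        """Forward pass; returns (probabilities, pre-sigmoid score, cache)."""
        X = self._coerce(X)
        n, G = X.shape[0], self.n_genes
        p = self.params
        act_gm, _ = _act(self._act_gm)
        act_hd, _ = _act(self._act_head)

        Xf = X.reshape(n * G, self.gm.input_dim)
        A1 = Xf @ p["gm_W1"] + p["gm_b1"]
        H1 = act_gm(A1)
        A2 = H1 @ p["gm_w2"] + p["gm_b2"]
        Gg = act_gm(A2).reshape(n, G)

        keep = None
        Gd = Gg
        if dropout > 0.0 and rng is not None:
            keep = (rng.random(Gg.shape) >= dropout).astype(np.float32) / (1.0 - dropout)
            Gd = Gg * keep

        cache = {"X": Xf, "H1": H1, "Gg": Gg, "Gd": Gd, "keep": keep, "n": n}

        Z = Gd
        if self.gg_mask is not None:
            Wgg = self.gg_mask * p["gg_W"]
            Ag = Gd @ Wgg + p["gg_b"]
            Gi = act_hd(Ag)
            cache.update(Gi=Gi, Wgg=Wgg)
            Z = Gi

        if self.head.kind == "logreg":
            s = Z @ p["out_w"] + p["out_b"]
            cache["Z"] = Z
        else:
            Wm = p["pw_W"] if self.mask_matrix is None else self.mask_matrix * p["pw_W"]
            Ap = Z @ Wm + p["pw_b"]
            Hp = act_hd(Ap)
            keep2 = None
            Hd = Hp
            if dropout > 0.0 and rng is not None:
                keep2 = (rng.random(Hp.shape) >= dropout).astype(np.float32) / (1.0 - dropout)
                Hd = Hp * keep2
            s = Hd @ p["out_w"] + p["out_b"]
            cache.update(Z=Z, Wm=Wm, Hp=Hp, Hd=Hd, keep2=keep2)
        prob = expit(s)
        return prob, s, cache

    def backward(self, cache: dict, dscore: np.ndarray) -> dict:
        """Gradients of the loss w.r.t. every parameter given dL/dscore.

        For masked layers the dict also carries the *dense* gradient
        (``pw_W_dense``), which dynamic sparse training uses to pick growth
        sites.
        """
        p = self.params
        _, der_gm = _act(self._act_gm)
        _, der_hd = _act(self._act_head)
        g: dict[str, np.ndarray] = {}

        if self.head.kind == "logreg":
            Z = cache["Z"]
            g["out_w"] = Z.T @ dscore
            g["out_b"] = dscore.sum()
            dZ = np.outer(dscore, p["out_w"])
        else:
            Hd, Hp, keep2 = cache["Hd"], cache["Hp"], cache["keep2"]
            g["out_w"] = Hd.T @ dscore
            g["out_b"] = dscore.sum()
            dHd = np.outer(dscore, p["out_w"])
            dHp = dHd if keep2 is None else dHd * keep2
            dAp = dHp * der_hd(Hp)
            dense = cache["Z"].T @ dAp
            if self.mask_matrix is not None:
                g["pw_W_dense"] = dense
                g["pw_W"] = dense * self.mask_matrix
            else:
                g["pw_W"] = dense
            g["pw_b"] = dAp.sum(axis=0)
            dZ = dAp @ cache["Wm"].T

        if self.gg_mask is not None:
            Gi = cache["Gi"]
            dAg = dZ * der_hd(Gi)
            g["gg_W"] = (cache["Gd"].T @ dAg) * self.gg_mask
            g["gg_b"] = dAg.sum(axis=0)
            dGd = dAg @ cache["Wgg"].T
        else:
            dGd = dZ

        keep = cache["keep"]
        dGg = dGd if keep is None else dGd * keep

        n, G = cache["n"], self.n_genes
        Gg_flat = cache["Gg"].reshape(n * G)
        dA2 = dGg.reshape(n * G) * der_gm(Gg_flat)
        H1 = cache["H1"]
        g["gm_w2"] = H1.T @ dA2
        g["gm_b2"] = dA2.sum()
        dH1 = np.outer(dA2, p["gm_w2"])
        dA1 = dH1 * der_gm(H1)
        g["gm_W1"] = cache["X"].T @ dA1
        g["gm_b1"] = dA1.sum(axis=0)
        return g

    # -- prediction ---------------------------------------------------------

    def predict_proba(self, X) -> np.ndarray:
        prob, _, _ = self.forward(X)
        return prob

    def decision_score(self, X) -> np.ndarray:
        """Pre-sigmoid score (the log-odds the model assigns)."""
        _, s, _ = self.forward(X)
        return s

    def gene_activations(self, X) -> np.ndarray:
        """The per-gene latent values G_i, shape (n, |G|)."""
        _, _, cache = self.forward(X)
        return cache["Gg"]

    # -- accounting ---------------------------------------------------------

    def count_parameters(self) -> tuple[int, int]:
        """(n_weights, n_biases) of trainable parameters.

        Masked-out connections are excluded; biases are the b-vectors of each
        layer plus the output bias.
        """
        gm = self.gm
        weights = gm.input_dim * gm.hidden_units + gm.hidden_units
        biases = gm.hidden_units + 1
        if self.gg_mask is not None:
            weights += int(self.gg_mask.sum())
            biases += self.n_genes
        if self.head.kind == "logreg":
            weights += self.n_genes
            biases += 1
        else:
            P = len(self.hidden_ids)
            if self.mask_matrix is not None:
                weights += int(self.mask_matrix.sum())
            else:
                weights += self.n_genes * P
            weights += P
            biases += P + 1
        return weights, biases

    # -- persistence --------------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Single-file checkpoint (npz archive with a JSON spec record)."""
        head_meta = {
            "kind": self.head.kind,
            "hidden_units": self.head.hidden_units,
            "activation": self.head.activation,
            "dropout": self.head.dropout,
            "hidden_ids": self.hidden_ids,
        }
        meta = {
            "gm": {
                "input_dim": self.gm.input_dim,
                "hidden_units": self.gm.hidden_units,
                "activation": self.gm.activation,
            },
            "head": head_meta,
            "gene_ids": self.gene_ids,
            "seed": self.seed,
        }
        arrays = {f"param_{k}": v for k, v in self.params.items()}
        if self.mask_matrix is not None:
            arrays["mask"] = self.mask_matrix
        if self.gg_mask is not None:
            arrays["gg_mask"] = self.gg_mask
        arrays["meta"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
        with open(path, "wb") as fh:
            np.savez_compressed(fh, **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "Model":
        data = np.load(path)
        meta = json.loads(bytes(data["meta"]).decode())
        gm = GeneModuleSpec(**meta["gm"])
        hm = meta["head"]
        mask = None
        if "mask" in data:
            mask = SparsityMask(
                matrix=data["mask"],
                gene_ids=meta["gene_ids"],
                hidden_ids=hm["hidden_ids"],
                provenance="checkpoint",
            )
        head = HeadSpec(
            kind=hm["kind"],
            hidden_units=hm["hidden_units"],
            mask=mask,
            gg_adjacency=data["gg_mask"] if "gg_mask" in data else None,
            activation=hm["activation"],
            dropout=hm["dropout"],
        )
        model = cls(gm, head, meta["gene_ids"], seed=meta["seed"])
        for k in model.params:
            model.params[k] = data[f"param_{k}"].copy()
        return model


def build_model(
    gm: GeneModuleSpec,
    head: HeadSpec,
    gene_ids: Sequence[str],
    seed: int = 0,
) -> Model:
    """Assemble a trainable model from a gene-module spec and a head spec."""
    return Model(gm, head, gene_ids, seed=seed)


def predict_proba(model: Model, X) -> np.ndarray:
    """Case probability per sample, in (0, 1)."""
    return model.predict_proba(X)


def count_parameters(model: Model) -> tuple[int, int]:
    """(n_weights, n_biases); masked-out connections contribute nothing."""
    return model.count_parameters()


def count_gene_module_parameters(model_or_spec) -> tuple[int, int]:
    """(n_weights, n_biases) of the shared gene module alone, by walking its
    parameter arrays (the module is shared, so the count is independent of
    the number of genes)."""
    if isinstance(model_or_spec, GeneModuleSpec):
        model = Model(model_or_spec, HeadSpec(kind="logreg"), ["g0"])
    else:
        model = model_or_spec
    weights = sum(model.params[k].size for k in ("gm_W1", "gm_w2"))
    biases = sum(model.params[k].size for k in ("gm_b1", "gm_b2"))
    return int(weights), int(biases)
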