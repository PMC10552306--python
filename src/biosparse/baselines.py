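"""Comparison models: penalised additive (logistic) regression on individual
variants and Random Forests on several input representations.

These are not this package's contribution, so they wrap scikit-learn
fitters; they share the fit/predict_proba contract of the gene-module
networks so the CV harness treats everything identically.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression

from .architectures import Model
from .encoding import AnnotatedVariantTable, ClassVocabulary, GeneCentricTensor

__all__ = [
    "VariantMatrix",
    "additive_baseline",
    "AdditiveBaseline",
    "rf_baseline",
    "RFBaseline",
]


@dataclass
class VariantMatrix:
    """n_samples x n_variants count matrix at variant granularity.

    Columns are the distinct ``gene|class`` keys emitted by the variant
    table (the finest granularity the gene-centric representation retains).
    """

    values: np.ndarray
    variant_ids: list[str]
    sample_ids: list[str]

    @classmethod
    def from_table(
        cls, table: AnnotatedVariantTable, sample_ids: Sequence[str] | None = None
    ) -> "VariantMatrix":
        if sample_ids is None:
            sample_ids = table.sample_ids
        sample_ids = list(sample_ids)
        frame = table.frame
        key = frame["gene_id"].astype(str) + "|" + frame["functional_class"].astype(str)
        variant_ids = sorted(key.unique())
        vi = {v: i for i, v in enumerate(variant_ids)}
        si = {s: i for i, s in enumerate(sample_ids)}
        values = np.zeros((len(sample_ids), len(variant_ids)), dtype=np.float64)
        np.add.at(
            values,
            (frame["sample_id"].map(si).to_numpy(), key.map(vi).to_numpy()),
            1.0,
        )
        return cls(values=values, variant_ids=variant_ids, sample_ids=sample_ids)

    @classmethod
    def from_tensor(cls, tensor: GeneCentricTensor) -> "VariantMatrix":
        """Flatten a (raw-count) tensor to variant granularity, keeping only
        (gene, class) columns observed at least once."""
        n, G, C = tensor.counts.shape
        flat = tensor.counts.reshape(n, G * C)
        keep = np.flatnonzero(flat.sum(axis=0) > 0)
        ids = [
            f"{tensor.gene_ids[k // C]}|{tensor.vocab.classes[k % C]}" for k in keep
        ]
        return cls(
            values=flat[:, keep].astype(np.float64),
            variant_ids=ids,
            sample_ids=list(tensor.sample_ids),
        )


class AdditiveBaseline:
    """L1/L2-penalised logistic regression over individual variants."""

    def __init__(self, penalty: str = "l2", strength: float = 1.0, seed: int = 0):
        if penalty not in ("l1", "l2", "L1", "L2"):
            raise ValueError("penalty must be 'l1' or 'l2'")
        self.penalty = penalty.lower()
        self.strength = strength
        self.seed = seed
        self.clf_: LogisticRegression | None = None
        self.n_features_: int | None = None

    def fit(self, X, y):
        X = _flatten(X)
        y = np.asarray(y).astype(int)
        if len(np.unique(y)) < 2:
            raise ValueError("both classes must be present to fit the baseline")
        self.clf_ = LogisticRegression(
            l1_ratio=1 if self.penalty == "l1" else 0,
            C=1.0 / self.strength,
            solver="liblinear" if self.penalty == "l1" else "lbfgs",
            max_iter=2000,
            random_state=self.seed,
        )
        self.clf_.fit(X, y)
        self.n_features_ = X.shape[1]
        return self

    def predict_proba(self, X) -> np.ndarray:
        return self.clf_.predict_proba(_flatten(X))[:, 1]

    def decision_score(self, X) -> np.ndarray:
        return self.clf_.decision_function(_flatten(X))

    @property
    def n_parameters(self) -> int:
        """One weight per variant plus the intercept."""
        if self.n_features_ is None:
            raise RuntimeError("baseline is not fitted")
        return self.n_features_ + 1


def _flatten(X) -> np.ndarray:
    if isinstance(X, VariantMatrix):
        return X.values
    X = np.asarray(X)
    if X.ndim == 3:
        return X.reshape(X.shape[0], -1)
    return X


def additive_baseline(
    X, y, penalty: str = "l2", strength: float = 1.0, seed: int = 0
) -> AdditiveBaseline:
    """Fit the additive (penalised logistic) baseline on variant counts."""
    return AdditiveBaseline(penalty=penalty, strength=strength, seed=seed).fit(X, y)


RF_INPUT_MODES = ("variants", "summed_gene_vectors", "learned_gene_activations")


class RFBaseline:
    """Random Forest on one of three input representations.

    * ``variants``: the variant-granularity count matrix;
    * ``summed_gene_vectors``: per-gene total mutational load (n x |G|); set
      ``flatten_histograms=True`` for the per-gene 16-vector reading
      (n x |G|*C);
    * ``learned_gene_activations``: the gene-neuron outputs G_i of a trained
      network (n x |G|).
    """

    def __init__(
        self,
        input_mode: str = "summed_gene_vectors",
        n_estimators: int = 10_000,
        max_depth: int | None = 3,
        seed: int = 0,
        model: Model | None = None,
        flatten_histograms: bool = False,
    ):
        if input_mode not in RF_INPUT_MODES:
            raise ValueError(f"input_mode must be one of {RF_INPUT_MODES}")
        if input_mode == "learned_gene_activations" and model is None:
            raise ValueError("learned_gene_activations requires a trained model")
        self.input_mode = input_mode
        self.n_estimators = n_estimators
        self.max_depth = max_depth
        self.seed = seed
        self.model = model
        self.flatten_histograms = flatten_histograms
        self.clf_: RandomForestClassifier | None = None

    def _features(self, X) -> np.ndarray:
        if self.input_mode == "variants":
            return _flatten(X)
        X = np.asarray(X) if not isinstance(X, VariantMatrix) else X.values
        if self.input_mode == "summed_gene_vectors":
            if X.ndim != 3:
                raise ValueError("summed_gene_vectors requires an (n, |G|, C) tensor")
            if self.flatten_histograms:
                return X.reshape(X.shape[0], -1)
            return X.sum(axis=2)
        # learned_gene_activations
        if X.ndim != 3:
            raise ValueError("learned_gene_activations requires an (n, |G|, C) tensor")
        return self.model.gene_activations(X)

    def fit(self, X, y):
        self.clf_ = RandomForestClassifier(
            n_estimators=self.n_estimators,
            max_depth=self.max_depth,
            random_state=self.seed,
            n_jobs=1,
        )
        self.clf_.fit(self._features(X), np.asarray(y).astype(int))
        return self

    def predict_proba(self, X) -> np.ndarray:
        return self.clf_.predict_proba(self._features(X))[:, 1]


def rf_baseline(input_mode: str, X, y, rf_config: dict | None = None) -> RFBaseline:
    """Fit a Random Forest baseline; ``rf_config`` passes estimator count,
    depth, seed, a trained ``model`` (for learned activations) and the
    ``flatten_histograms`` switch."""
    rf_config = dict(rf_config or {})
    est = RFBaseline(input_mode=input_mode, **rf_config)
    return est.fit(X, y)
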