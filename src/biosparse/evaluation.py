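"""Evaluation protocol: repeated stratified k-fold CV, ROC AUC, and the
variance-corrected resampled t-test.

Performance is summarised as the mean and standard deviation of the test-set
ROC AUC over repeated stratified 3-fold cross-validation (10 repetitions by
default), with identical splits across the models being compared.  Because
the training sets of CV folds overlap, AUC differences are correlated; the
paired comparison therefore inflates the variance by ``1/m + n_test/n_train``
(the corrected resampled t-test), which restores approximately nominal
type-I error.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.model_selection import StratifiedKFold

from .encoding import GeneCentricTensor

__all__ = [
    "roc_auc",
    "CVResult",
    "repeated_stratified_cv",
    "TTestResult",
    "corrected_t_test",
    "LearningCurve",
    "learning_curve",
]


def roc_auc(scores, labels) -> float:
    """Area under the ROC curve: the Mann-Whitney probability that a random
    case outscores a random control, ties counted 1/2."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    if not np.isin(labels, (0, 1)).all():
        raise ValueError("labels must be 0/1")
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to compute ROC AUC")
    ranks = sps.rankdata(scores)  # average ranks handle ties as 1/2
    rank_sum_pos = ranks[labels == 1].sum()
    u = rank_sum_pos - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


@dataclass
class CVResult:
    """Test AUCs from repeated stratified k-fold CV (reps x k matrix)."""

    aucs: np.ndarray
    model: str = ""
    base_seed: int = 0

    @property
    def reps(self) -> int:
        return self.aucs.shape[0]

    @property
    def k(self) -> int:
        return self.aucs.shape[1]

    @property
    def mean(self) -> float:
        return float(self.aucs.mean())

    @property
    def sd(self) -> float:
        return float(self.aucs.std(ddof=1)) if self.aucs.size > 1 else 0.0

    def to_frame(self, fraction: float | None = None) -> pd.DataFrame:
        recs = [
            {"model": self.model, "rep": r, "fold": f, "auc": self.aucs[r, f]}
            for r in range(self.reps)
            for f in range(self.k)
        ]
        frame = pd.DataFrame(recs)
        if fraction is not None:
            frame.insert(1, "fraction", fraction)
        return frame

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _as_array(X) -> np.ndarray:
    if isinstance(X, GeneCentricTensor):
        if X.standardized:
            raise ValueError(
                "pass raw counts: standardization is refit inside each training fold"
            )
        return X.counts
    return np.asarray(X)


def _standardize_fold(Xtr: np.ndarray, Xte: np.ndarray, mode: str | None):
    """Z-score with train-fold moments only (no test leakage)."""
    if mode is None:
        return Xtr.astype(np.float32), Xte.astype(np.float32)
    if mode == "per_class" and Xtr.ndim == 3:
        axis = (0, 1)
    elif mode in ("per_class", "columns"):
        axis = (0,)
    else:
        raise ValueError(f"unknown standardization mode {mode!r}")
    mean = Xtr.mean(axis=axis, dtype=np.float64)
    sd = Xtr.std(axis=axis, dtype=np.float64)
    sd_safe = np.where(sd > 0, sd, 1.0)

    def z(a):
        out = (a.astype(np.float64) - mean) / sd_safe
        return np.where(sd > 0, out, 0.0).astype(np.float32)

    return z(Xtr), z(Xte)


def cv_splits(y: np.ndarray, k: int, reps: int, base_seed: int):
    """The (rep, fold) -> (train_idx, test_idx) partition schedule.

    Deterministic in ``(y, k, reps, base_seed)``, so two model factories
    evaluated with the same seed receive identical splits.
    """
    out = []
    for rep in range(reps):
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=base_seed + rep)
        out.append([(tr, te) for tr, te in skf.split(np.zeros_like(y), y)])
    return out


def _fold_seed(base_seed: int, rep: int, fold: int) -> int:
    return int(np.random.SeedSequence([base_seed, rep, fold]).generate_state(1)[0] % (2**31))


def repeated_stratified_cv(
    model_factory: Callable[[int], object],
    X,
    y,
    k: int = 3,
    reps: int = 10,
    base_seed: int = 0,
    standardize: str | None = "per_class",
) -> CVResult:
    """Repeated stratified k-fold CV of ``model_factory`` (a callable
    ``seed -> estimator`` with fit/predict_proba).

    Standardization statistics are refit on each training fold and applied
    to its test fold.  ``X`` is raw counts, (n, |G|, C) for gene-module
    models or (n, p) for flat-feature baselines.
    """
    X = _as_array(X)
    y = np.asarray(y).astype(int)
    counts = np.bincount(y, minlength=2)
    if counts.min() < k:
        raise ValueError("each class needs at least k samples to stratify")
    aucs = np.zeros((reps, k))
    for rep, folds in enumerate(cv_splits(y, k, reps, base_seed)):
        for fold, (tr, te) in enumerate(folds):
            Xtr, Xte = _standardize_fold(X[tr], X[te], standardize)
            est = model_factory(_fold_seed(base_seed, rep, fold))
            est.fit(Xtr, y[tr])
            scores = np.asarray(est.predict_proba(Xte))
            if scores.ndim == 2:
                scores = scores[:, 1]
            aucs[rep, fold] = roc_auc(scores, y[te])
    return CVResult(aucs=aucs, base_seed=base_seed)


@dataclass(frozen=True)
class TTestResult:
    t: float
    p: float
    degenerate: bool = False


def corrected_t_test(
    auc_a: np.ndarray, auc_b: np.ndarray, n_train: int, n_test: int
) -> TTestResult:
    """Two-sided paired t-test on CV AUC differences with the resampling
    variance correction ``1/m + n_test/n_train`` and m-1 degrees of freedom.
    """
    auc_a = np.asarray(auc_a, dtype=np.float64)
    auc_b = np.asarray(auc_b, dtype=np.float64)
    if auc_a.shape != auc_b.shape:
        raise ValueError("AUC matrices must have identical shape")
    d = (auc_a - auc_b).ravel()
    m = d.size
    if m < 2:
        raise ValueError("need at least two paired measurements")
    var = d.var(ddof=1)
    mean = d.mean()
    if var == 0.0:
        if mean == 0.0:
            return TTestResult(t=0.0, p=1.0)
        return TTestResult(t=math_inf_sign(mean), p=0.0, degenerate=True)
    t = mean / np.sqrt((1.0 / m + n_test / n_train) * var)
    p = 2.0 * sps.t.sf(abs(t), df=m - 1)
    return TTestResult(t=float(t), p=float(p))


def math_inf_sign(x: float) -> float:
    return float(np.inf if x > 0 else -np.inf)


@dataclass
class LearningCurve:
    """Per-fraction CV results per model, on nested stratified subsets."""

    fractions: list
    results: dict  # model tag -> {fraction -> CVResult}
    subset_indices: dict = field(default_factory=dict)  # fraction -> indices

    def mean(self, model: str, fraction: float) -> float:
        return self.results[model][fraction].mean

    def to_frame(self) -> pd.DataFrame:
        frames = []
        for tag, by_frac in self.results.items():
            for frac, res in by_frac.items():
                f = res.to_frame(fraction=frac)
                f["model"] = tag
                frames.append(f)
        return pd.concat(frames, ignore_index=True)

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def nested_stratified_subsets(
    y: np.ndarray, fractions: Sequence[float], base_seed: int
) -> dict:
    """Stratified subsets, nested across fractions for a given seed (the
    subset at a smaller fraction is contained in every larger one)."""
    rng = np.random.default_rng(np.random.SeedSequence([base_seed, 97]))
    per_class_order = {
        c: rng.permutation(np.flatnonzero(y == c)) for c in np.unique(y)
    }
    out = {}
    for f in fractions:
        if not (0.0 < f <= 1.0):
            raise ValueError("fractions must be in (0, 1]")
        idx = np.concatenate(
            [order[: max(1, int(round(f * order.size)))] for order in per_class_order.values()]
        )
        out[f] = np.sort(idx)
    return out


def learning_curve(
    model_factories: Mapping[str, Callable[[int], object]],
    X,
    y,
    fractions: Sequence[float] = (0.1, 0.2, 0.4, 0.6, 0.8, 1.0),
    k: int = 3,
    reps: int = 10,
    base_seed: int = 0,
    standardize: str | None = "per_class",
) -> LearningCurve:
    """CV performance as a function of the available sample size.

    Each fraction draws a nested stratified subset and runs
    :func:`repeated_stratified_cv` with identical splits for all factories;
    fraction 1.0 reproduces CV on the full dataset exactly.
    """
    X = _as_array(X)
    y = np.asarray(y).astype(int)
    subsets = nested_stratified_subsets(y, fractions, base_seed)
    smallest = min(fractions)
    if np.bincount(y[subsets[smallest]], minlength=2).min() < k:
        raise ValueError(
            f"fraction {smallest} leaves fewer than k={k} samples in a class"
        )
    results: dict = {tag: {} for tag in model_factories}
    for f in fractions:
        idx = subsets[f]
        for tag, factory in model_factories.items():
            res = repeated_stratified_cv(
                factory, X[idx], y[idx], k=k, reps=reps,
                base_seed=base_seed, standardize=standardize,
            )
            res.model = tag
            results[tag][f] = res
    return LearningCurve(
        fractions=list(fractions), results=results, subset_indices=subsets
    )
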