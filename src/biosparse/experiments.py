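"""Desk-scale expressivity-ladder experiment.

One synthetic cohort per epistasis regime (additive, shared-pathway
magnitude epistasis, reciprocal sign), evaluated with repeated stratified
3-fold CV using identical splits for every model.  The architectures span
the expressivity ladder: additive in the gene neurons (logreg head), one
shared tanh neuron per gene pair (degree-1 sparse head), universal (dense
head), plus the all-identity control (linear) and a penalised logistic
regression on individual variant counts as the additive baseline.

The gene module is scaled down to 8 hidden units and training budgets are
tightened relative to the full-cohort defaults so a whole ladder runs on a
laptop-class CPU; the frozen settings live in :data:`LADDER_TRAIN` and
:func:`ladder_scenarios`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np

from .architectures import GeneModuleSpec, HeadSpec
from .baselines import AdditiveBaseline
from .evaluation import repeated_stratified_cv
from .simulate import (
    SimConfig,
    scenario_additive,
    scenario_magnitude_epistasis,
    scenario_reciprocal_sign,
    simulate_tensor,
)
from .sparsity import knowledge_mask
from .training import NNEstimator, TrainConfig

__all__ = ["LADDER_GM", "LADDER_TRAIN", "ladder_scenarios", "run_ladder", "LadderResult"]

# desk-scale gene module: same shape as the full model, fewer hidden units
LADDER_GM = GeneModuleSpec(input_dim=16, hidden_units=8)

# per-architecture optimisation settings (epochs within the 20-75 budget
# band; the dense head gets a longer budget and an L1 penalty on its wide
# gene-hidden layer, its main overfitting surface)
LADDER_TRAIN: dict[str, TrainConfig] = {
    "logreg": TrainConfig(epochs=20, learning_rate=0.005),
    "biosparse": TrainConfig(epochs=20, learning_rate=0.005),
    "linear": TrainConfig(epochs=20, learning_rate=0.005),
    "dense": TrainConfig(epochs=75, learning_rate=0.003, l1_pathway_penalty=3e-4),
}
LADDER_DENSE_HIDDEN = 20


def ladder_scenarios(seed: int = 0) -> dict[str, SimConfig]:
    """The three frozen study conditions, seeded off ``seed``."""
    return {
        "additive": scenario_additive(seed=seed * 3 + 11),
        "magnitude": scenario_magnitude_epistasis(seed=seed * 3 + 12),
        "reciprocal_sign": scenario_reciprocal_sign(seed=seed * 3 + 13),
    }


@dataclass
class LadderResult:
    """Mean CV AUC per (scenario, model), plus the raw CV matrices."""

    means: dict = field(default_factory=dict)  # scenario -> model -> float
    cv: dict = field(default_factory=dict)  # scenario -> model -> CVResult

    def gap(self, scenario: str, model_a: str, model_b: str) -> float:
        return self.means[scenario][model_a] - self.means[scenario][model_b]


def _nn_factories(tensor, pm) -> Mapping[str, Callable[[int], object]]:
    gene_ids = tensor.gene_ids

    def with_knowledge(kind):
        def factory(seed):
            head = lambda s: HeadSpec(
                kind=kind, mask=knowledge_mask(pm, gene_ids, seed=s)
            )
            return NNEstimator(LADDER_GM, head, gene_ids, LADDER_TRAIN[kind], seed=seed)

        return factory

    def plain(kind, head):
        return lambda seed: NNEstimator(
            LADDER_GM, head, gene_ids, LADDER_TRAIN[kind], seed=seed
        )

    return {
        "logreg": plain("logreg", HeadSpec(kind="logreg")),
        "biosparse": with_knowledge("biosparse"),
        "dense": plain(
            "dense", HeadSpec(kind="dense", hidden_units=LADDER_DENSE_HIDDEN)
        ),
        "linear": with_knowledge("linear"),
    }


# the "best additive model" is reported as the maximum over a small family,
# mirroring the practice of trying several additive alternatives and keeping
# the best: an L2 logistic on individual variant counts (strongly ridged;
# 3,200 noisy columns) and an L2 logistic on per-gene total burdens
ADDITIVE_BASELINES = ("variant_l2", "burden_l2")


def _baseline_factory(tag: str):
    strength = 1000.0 if tag == "variant_l2" else 1.0
    return lambda seed: AdditiveBaseline(penalty="l2", strength=strength, seed=seed)


def run_ladder(
    seed: int = 0,
    reps: int = 10,
    k: int = 3,
    scenarios: Mapping[str, SimConfig] | None = None,
    models_per_scenario: Mapping[str, tuple] | None = None,
) -> LadderResult:
    """Run the ladder; every model sees identical CV splits per scenario.

    ``models_per_scenario`` restricts which models run where (the default
    runs every model everywhere except the dense head on the magnitude
    scenario, where no claim involves it).
    """
    if scenarios is None:
        scenarios = ladder_scenarios(seed)
    if models_per_scenario is None:
        all_models = ("logreg", "biosparse", "dense", "linear") + ADDITIVE_BASELINES
        models_per_scenario = {
            "additive": all_models,
            "magnitude": ("logreg", "biosparse", "linear") + ADDITIVE_BASELINES,
            "reciprocal_sign": all_models,
        }
    result = LadderResult()
    for name, cfg in scenarios.items():
        tensor, y, pm, _ = simulate_tensor(cfg)
        factories = dict(_nn_factories(tensor, pm))
        result.means[name] = {}
        result.cv[name] = {}
        for tag in models_per_scenario.get(name, ()):
            if tag in ADDITIVE_BASELINES:
                n, G, C = tensor.counts.shape
                Xflat = (
                    tensor.counts.reshape(n, G * C)
                    if tag == "variant_l2"
                    else tensor.counts.sum(axis=2)
                )
                res = repeated_stratified_cv(
                    _baseline_factory(tag), Xflat, y, k=k, reps=reps,
                    base_seed=seed, standardize="columns",
                )
            else:
                res = repeated_stratified_cv(
                    factories[tag], tensor.counts, y, k=k, reps=reps,
                    base_seed=seed, standardize="per_class",
                )
            res.model = tag
            result.means[name][tag] = res.mean
            result.cv[name][tag] = res
    return result


def best_additive_baseline(result: LadderResult, scenario: str) -> float:
    """Mean CV AUC of the best additive model for a scenario."""
    return max(result.means[scenario][t] for t in ADDITIVE_BASELINES)


# ---------------------------------------------------------------------------
# XOR micro-motif: the minimal two-gene network of the expressivity argument
# ---------------------------------------------------------------------------

def xor_motif_comparison(
    n_restarts: int = 10, n: int = 200, epochs: int = 600, seed: int = 0
) -> dict:
    """Train the two-gene motif on noiseless XOR data.

    A single tanh hidden unit receiving both gene neurons computes a
    monotone ridge function, which cannot exceed chance concordance on XOR;
    two hidden units can compose an OR with a NOT-AND and solve it.  The
    focal focusing term (gamma=2) is kept on: by up-weighting the
    misclassified corner it reliably steers optimisation out of the
    OR-only local minimum.  Returns training AUCs per restart for both
    motifs.
    """
    from .evaluation import roc_auc
    from .sparsity import SparsityMask
    from .training import train as _train

    rng = np.random.default_rng(seed)
    bits = rng.integers(0, 2, size=(n, 2))
    y = bits[:, 0] ^ bits[:, 1]
    X = (2.0 * bits - 1.0).astype(np.float32).reshape(n, 2, 1)
    genes = ["gA", "gB"]
    gm = GeneModuleSpec(input_dim=1, hidden_units=1, activation="tanh")
    mask1 = SparsityMask(
        matrix=np.ones((2, 1), dtype=np.float32), gene_ids=genes,
        hidden_ids=["h0"], provenance="knowledge",
    )
    cfg = TrainConfig(
        epochs=epochs, learning_rate=0.03, batch_size=16,
        focal_alpha=0.5, focal_gamma=2.0,
    )
    out = {"one_hidden": [], "two_hidden": []}
    from .architectures import build_model

    for r in range(n_restarts):
        m1 = build_model(gm, HeadSpec(kind="biosparse", mask=mask1), genes, seed=seed + 100 + r)
        m1, _ = _train(m1, X, y, TrainConfig(**{**cfg.__dict__, "seed": seed + 100 + r}))
        out["one_hidden"].append(roc_auc(m1.predict_proba(X), y))
        m2 = build_model(gm, HeadSpec(kind="dense", hidden_units=2), genes, seed=seed + 200 + r)
        m2, _ = _train(m2, X, y, TrainConfig(**{**cfg.__dict__, "seed": seed + 200 + r}))
        out["two_hidden"].append(roc_auc(m2.predict_proba(X), y))
    return out


# ---------------------------------------------------------------------------
# Null calibration of the corrected resampled t-test
# ---------------------------------------------------------------------------

def null_ttest_calibration(
    n_repetitions: int = 1000,
    n_samples: int = 240,
    n_genes: int = 12,
    reps: int = 2,
    k: int = 3,
    alpha_level: float = 0.05,
    seed: int = 0,
) -> float:
    """Type-I error of the corrected t-test under label permutation.

    One simulated cohort; each repetition permutes the labels (destroying
    any signal), compares two additive fitters by repeated stratified k-fold
    CV on identical splits, and applies the variance-corrected test.
    Returns the fraction of repetitions with p < ``alpha_level``.
    """
    from .evaluation import corrected_t_test, repeated_stratified_cv
    from .simulate import SimConfig, simulate_tensor

    cfg = SimConfig(
        n_samples=n_samples, n_genes=n_genes, n_pathways=3, prevalence=0.5,
        additive=[(0, 1.0)], noise_sd=0.5, seed=seed,
    )
    tensor, y0, _, _ = simulate_tensor(cfg)
    burdens = tensor.counts.sum(axis=2).astype(np.float64)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 41]))
    n_test = n_samples // k
    n_train = n_samples - n_test
    rejections = 0
    for rep in range(n_repetitions):
        y = y0[rng.permutation(n_samples)]
        res_a = repeated_stratified_cv(
            lambda s: AdditiveBaseline("l2", 1.0, s), burdens, y,
            k=k, reps=reps, base_seed=rep, standardize="columns",
        )
        res_b = repeated_stratified_cv(
            lambda s: AdditiveBaseline("l1", 10.0, s), burdens, y,
            k=k, reps=reps, base_seed=rep, standardize="columns",
        )
        t = corrected_t_test(res_a.aucs, res_b.aucs, n_train=n_train, n_test=n_test)
        rejections += t.p < alpha_level
    return rejections / n_repetitions


# ---------------------------------------------------------------------------
# Ensemble-of-random-masks benefit
# ---------------------------------------------------------------------------

def ensemble_benefit(
    n_repetitions: int = 10,
    n_members: int = 25,
    n_samples: int = 2000,
    n_genes: int = 100,
    n_hidden: int = 10,
    seed: int = 0,
) -> dict:
    """Ensemble vs single randomly sparsified network, repeated CV runs.

    Planted positive-epistasis cohort; each repetition is a stratified
    3-fold CV (identical splits for ensemble and single model).  Returns
    per-repetition mean AUCs and the number of repetitions where the
    ensemble is at least as good.
    """
    from .ensemble import predict_ensemble, train_ensemble
    from .evaluation import cv_splits, roc_auc
    from .simulate import scenario_magnitude_epistasis, simulate_tensor
    from .sparsity import random_mask

    cfg = scenario_magnitude_epistasis(
        n_samples=n_samples, n_genes=n_genes, n_pairs=6, seed=seed,
    )
    tensor, y, _, _ = simulate_tensor(cfg)
    X = tensor.counts
    gene_ids = tensor.gene_ids
    gm = LADDER_GM
    member_cfg = TrainConfig(epochs=10, learning_rate=0.005)
    ens_means, single_means = [], []
    for rep in range(n_repetitions):
        folds = cv_splits(np.asarray(y), k=3, reps=1, base_seed=seed * 1000 + rep)[0]
        ens_aucs, single_aucs = [], []
        for fold, (tr, te) in enumerate(folds):
            mu = X[tr].mean(axis=(0, 1), dtype=np.float64)
            sd = X[tr].std(axis=(0, 1), dtype=np.float64)
            sds = np.where(sd > 0, sd, 1.0)
            Ztr = ((X[tr] - mu) / sds).astype(np.float32)
            Zte = ((X[te] - mu) / sds).astype(np.float32)
            base = seed * 100000 + rep * 1000 + fold * 40
            ens = train_ensemble(
                Ztr, y[tr], n_members=n_members, gene_fraction=1.0,
                n_hidden=n_hidden, train_cfg=member_cfg, base_seed=base,
                gene_ids=gene_ids, gm=gm,
            )
            ens_aucs.append(roc_auc(predict_ensemble(ens, Zte), y[te]))
            # single model: same architecture family, its own random mask
            mask = random_mask(n_genes, n_hidden, 1.0, seed=base + n_members, gene_ids=gene_ids)
            est = NNEstimator(
                gm, HeadSpec(kind="biosparse", mask=mask), gene_ids,
                member_cfg, seed=base + n_members,
            ).fit(Ztr, y[tr])
            single_aucs.append(roc_auc(est.predict_proba(Zte), y[te]))
        ens_means.append(float(np.mean(ens_aucs)))
        single_means.append(float(np.mean(single_aucs)))
    wins = sum(e >= s for e, s in zip(ens_means, single_means))
    return {"ensemble": ens_means, "single": single_means, "wins": wins}
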