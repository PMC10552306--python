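"""Synthetic case-control cohorts with a controllable genetic architecture.

The generator emulates the statistical structure that gene-centric
mutational-load models assume: per-sample, per-gene variant counts by
functional class (Poisson by default), a latent liability built from gene
burdens, and a liability-threshold labelling calibrated to a target case
prevalence.  Three kinds of signal can be planted:

* additive      — ``beta * b~_g`` per signal gene (b~ is the centered,
  scaled burden);
* magnitude (positive/negative) epistasis — a saturating synergy of two
  genes' summed centered burdens, ``sign * effect *
  tanh(slope * (b~_i + b~_j - shift))``.  This is exactly the function one
  tanh pathway neuron receiving both gene neurons can represent, so a
  degree-1 sparse model whose mask routes the pair together can in
  principle fit it, while a purely additive head cannot;
* reciprocal sign epistasis — ``effect * XOR(b_i > tau, b_j > tau)``, a
  nonlinearly separable pattern that no single monotone hidden neuron can
  represent.

The realized generating architecture is returned as a :class:`SimTruth`,
whose noiseless liability is the Bayes-optimal score for the cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.optimize import brentq

from .encoding import (
    DEFAULT_CLASSES_16,
    DUMMY_PATHWAY,
    AnnotatedVariantTable,
    ClassVocabulary,
    GeneCentricTensor,
    PathwayMap,
)

__all__ = [
    "MagnitudePair",
    "XorPair",
    "SimConfig",
    "SimTruth",
    "simulate_cohort",
    "simulate_tensor",
    "bayes_score",
    "scenario_additive",
    "scenario_magnitude_epistasis",
    "scenario_reciprocal_sign",
    "scenario_null",
]


@dataclass(frozen=True)
class MagnitudePair:
    """Positive/negative (magnitude) epistasis between two genes."""

    gene_i: int
    gene_j: int
    effect: float = 1.0
    sign: str = "positive"  # "positive" or "negative"
    same_pathway: bool = True

    def __post_init__(self) -> None:
        if self.sign not in ("positive", "negative"):
            raise ValueError("sign must be 'positive' or 'negative'")
        if self.gene_i == self.gene_j:
            raise ValueError("epistatic pair must involve two distinct genes")


@dataclass(frozen=True)
class XorPair:
    """Reciprocal sign epistasis: risk iff exactly one burden is high."""

    gene_i: int
    gene_j: int
    effect: float = 1.0
    tau: float = 1.0  # burden threshold

    def __post_init__(self) -> None:
        if self.gene_i == self.gene_j:
            raise ValueError("epistatic pair must involve two distinct genes")


@dataclass
class SimConfig:
    """Generating architecture of a synthetic cohort.

    ``rate`` is the per-gene per-class Poisson rate: a scalar, or an array of
    shape (n_genes,) (per gene, split evenly across classes) or
    (n_genes, C).  ``additive`` is a list of ``(gene_index, beta)``.
    """

    n_samples: int = 3798
    n_genes: int = 200
    n_pathways: int = 10
    class_vocab: ClassVocabulary = field(default_factory=lambda: DEFAULT_CLASSES_16)
    rate: float | np.ndarray = 0.125
    prevalence: float = 3318 / 3798
    additive: list = field(default_factory=list)
    magnitude_pairs: list = field(default_factory=list)
    xor_pairs: list = field(default_factory=list)
    noise_sd: float = 1.0
    seed: int = 0
    count_model: str = "poisson"  # or "negbin"
    negbin_dispersion: float = 5.0
    burden_weights: np.ndarray | None = None  # per-class weights, default 1
    mag_slope: float = 2.0
    mag_shift: float = 1.5
    orphan_fraction: float = 0.2

    def __post_init__(self) -> None:
        if not (0.0 < self.prevalence < 1.0):
            raise ValueError("prevalence must be in (0, 1)")
        if self.n_pathways < 1:
            raise ValueError("need at least one real pathway (plus the dummy)")
        if self.count_model not in ("poisson", "negbin"):
            raise ValueError("count_model must be 'poisson' or 'negbin'")
        for g, _ in self.additive:
            self._check_gene(g)
        for p in self.magnitude_pairs + self.xor_pairs:
            self._check_gene(p.gene_i)
            self._check_gene(p.gene_j)

    def _check_gene(self, g: int) -> None:
        if not (0 <= g < self.n_genes):
            raise ValueError(f"effect references gene index {g} outside [0, {self.n_genes})")

    @property
    def gene_ids(self) -> list[str]:
        return [f"g{i:05d}" for i in range(self.n_genes)]

    def rate_matrix(self) -> np.ndarray:
        C = self.class_vocab.size
        r = np.asarray(self.rate, dtype=np.float64)
        if r.ndim == 0:
            return np.full((self.n_genes, C), float(r))
        if r.ndim == 1:
            if r.shape[0] != self.n_genes:
                raise ValueError("per-gene rate vector has wrong length")
            return np.repeat((r / C)[:, None], C, axis=1)
        if r.shape != (self.n_genes, C):
            raise ValueError("rate matrix has wrong shape")
        return r

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        d["magnitude_pairs"] = [
            MagnitudePair(**p) if isinstance(p, dict) else p
            for p in d.get("magnitude_pairs", [])
        ]
        d["xor_pairs"] = [
            XorPair(**p) if isinstance(p, dict) else p for p in d.get("xor_pairs", [])
        ]
        d["additive"] = [tuple(a) for a in d.get("additive", [])]
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        import yaml

        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass
class SimTruth:
    """The realized generating architecture, enabling oracle scoring."""

    config: SimConfig
    gene_ids: list
    sample_ids: list
    counts: np.ndarray  # (n, G, C) raw counts
    signal: np.ndarray  # noiseless liability (the Bayes score)
    liability: np.ndarray  # signal + noise
    threshold: float
    labels: np.ndarray
    burden_mean: np.ndarray  # theoretical per-gene burden mean
    burden_sd: np.ndarray
    pathway_map: PathwayMap | None = None


def _burden_moments(cfg: SimConfig) -> tuple[np.ndarray, np.ndarray]:
    rates = cfg.rate_matrix()
    w = (
        np.ones(cfg.class_vocab.size)
        if cfg.burden_weights is None
        else np.asarray(cfg.burden_weights, dtype=np.float64)
    )
    mean = rates @ w
    if cfg.count_model == "poisson":
        var = rates @ (w * w)
    else:  # negative binomial: var = mu + mu^2 / r
        var = (rates + rates**2 / cfg.negbin_dispersion) @ (w * w)
    return mean, np.sqrt(np.maximum(var, 1e-12))


def _signal_from_counts(counts: np.ndarray, cfg: SimConfig,
                        mean: np.ndarray, sd: np.ndarray) -> np.ndarray:
    w = (
        np.ones(cfg.class_vocab.size)
        if cfg.burden_weights is None
        else np.asarray(cfg.burden_weights, dtype=np.float64)
    )
    burden = counts.astype(np.float64) @ w  # (n, G)
    centered = (burden - mean) / sd
    signal = np.zeros(counts.shape[0])
    for g, beta in cfg.additive:
        signal += beta * centered[:, g]
    for pr in cfg.magnitude_pairs:
        s = 1.0 if pr.sign == "positive" else -1.0
        signal += s * pr.effect * np.tanh(
            cfg.mag_slope * (centered[:, pr.gene_i] + centered[:, pr.gene_j] - cfg.mag_shift)
        )
    for pr in cfg.xor_pairs:
        hi = burden[:, pr.gene_i] > pr.tau
        hj = burden[:, pr.gene_j] > pr.tau
        signal += pr.effect * (hi ^ hj)
    return signal


def _build_pathway_map(cfg: SimConfig, rng: np.random.Generator) -> PathwayMap:
    genes = cfg.gene_ids
    pathway_ids = [f"pw{j:03d}" for j in range(cfg.n_pathways)]
    memberships: dict = {}
    next_dedicated = 0
    # magnitude pairs flagged same_pathway get an exclusive shared pathway, so
    # a knowledge-based mask deterministically routes both genes together
    for pr in cfg.magnitude_pairs:
        if pr.same_pathway:
            if next_dedicated >= cfg.n_pathways:
                raise ValueError("not enough pathways for the same_pathway pairs")
            p = pathway_ids[next_dedicated]
            next_dedicated += 1
            memberships[genes[pr.gene_i]] = {p}
            memberships[genes[pr.gene_j]] = {p}
        else:
            if cfg.n_pathways - next_dedicated < 2:
                raise ValueError("not enough pathways to separate a cross-pathway pair")
            rest = pathway_ids[next_dedicated:]
            pi, pj = rng.choice(len(rest), size=2, replace=False)
            memberships[genes[pr.gene_i]] = {rest[pi]}
            memberships[genes[pr.gene_j]] = {rest[pj]}
    # reciprocal-sign pairs sit in different pathways: a degree-1 mask then
    # gives each partner its own hidden neuron, so the pair cannot interact
    for pr in cfg.xor_pairs:
        if cfg.n_pathways - next_dedicated < 2:
            raise ValueError("not enough pathways to separate a reciprocal-sign pair")
        rest = pathway_ids[next_dedicated:]
        pi, pj = rng.choice(len(rest), size=2, replace=False)
        memberships.setdefault(genes[pr.gene_i], {rest[pi]})
        memberships.setdefault(genes[pr.gene_j], {rest[pj]})
    free = pathway_ids[next_dedicated:]
    for g in genes:
        if g in memberships:
            continue
        if not free or rng.random() < cfg.orphan_fraction:
            continue  # orphan: finalization routes it to the dummy pathway
        k = 1 + int(rng.random() < 0.25)  # a quarter of members sit in 2 pathways
        picks = rng.choice(len(free), size=min(k, len(free)), replace=False)
        memberships[g] = {free[int(i)] for i in np.atleast_1d(picks)}
    pm = PathwayMap(
        memberships={g: frozenset(m) for g, m in memberships.items()},
        pathway_ids=pathway_ids,
    )
    return pm.finalize(genes)


def _draw_counts(cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    rates = cfg.rate_matrix()
    shape = (cfg.n_samples, cfg.n_genes, cfg.class_vocab.size)
    if cfg.count_model == "poisson":
        counts = rng.poisson(np.broadcast_to(rates, shape))
    else:
        r = cfg.negbin_dispersion
        lam = rng.gamma(shape=r, scale=rates / r, size=shape)
        counts = rng.poisson(lam)
    return counts.astype(np.int16)


def simulate_truth(cfg: SimConfig) -> SimTruth:
    """Draw genotypes, liabilities and labels; no variant table materialised."""
    rng = np.random.default_rng(cfg.seed)
    if cfg.n_samples * min(cfg.prevalence, 1 - cfg.prevalence) < 2:
        raise ValueError("prevalence target infeasible at this sample size")
    counts = _draw_counts(cfg, rng)
    mean, sd = _burden_moments(cfg)
    signal = _signal_from_counts(counts, cfg, mean, sd)
    noise = rng.normal(0.0, cfg.noise_sd, size=cfg.n_samples) if cfg.noise_sd > 0 else 0.0
    liability = signal + noise
    # threshold at the candidate value whose realized case fraction is
    # closest to the target; for continuous liabilities this is the
    # (1 - prevalence) quantile, and for discrete ones (e.g. a noiseless
    # XOR liability) it lands between the tie blocks
    sorted_l = np.sort(liability)
    uniq = np.unique(liability)
    frac_gt = 1.0 - np.searchsorted(sorted_l, uniq, side="right") / cfg.n_samples
    threshold = float(uniq[np.argmin(np.abs(frac_gt - cfg.prevalence))])
    labels = (liability > threshold).astype(np.int64)
    if labels.min() == labels.max():
        raise ValueError(
            "degenerate labelling: prevalence target infeasible for this liability"
        )
    pm = _build_pathway_map(cfg, rng)
    sample_ids = [f"s{i:06d}" for i in range(cfg.n_samples)]
    return SimTruth(
        config=cfg,
        gene_ids=cfg.gene_ids,
        sample_ids=sample_ids,
        counts=counts,
        signal=signal,
        liability=liability,
        threshold=threshold,
        labels=labels,
        burden_mean=mean,
        burden_sd=sd,
        pathway_map=pm,
    )


def _materialize_table(truth: SimTruth) -> AnnotatedVariantTable:
    cfg = truth.config
    s, g, c = np.nonzero(truth.counts)
    reps = truth.counts[s, g, c].astype(int)
    s = np.repeat(s, reps)
    g = np.repeat(g, reps)
    c = np.repeat(c, reps)
    samples = pd.Categorical.from_codes(s, categories=truth.sample_ids)
    genes = pd.Categorical.from_codes(g, categories=truth.gene_ids)
    classes = pd.Categorical.from_codes(c, categories=list(cfg.class_vocab.classes))
    frame = pd.DataFrame(
        {"sample_id": samples, "gene_id": genes, "functional_class": classes}
    )
    return AnnotatedVariantTable(frame=frame, vocab=cfg.class_vocab)


def simulate_cohort(cfg: SimConfig):
    """Generate a cohort: (variant table, labels, pathway map, truth)."""
    truth = simulate_truth(cfg)
    table = _materialize_table(truth)
    return table, truth.labels.copy(), truth.pathway_map, truth


def simulate_tensor(cfg: SimConfig):
    """Like :func:`simulate_cohort` but returns the counts tensor directly
    (identical to encoding the materialised table)."""
    truth = simulate_truth(cfg)
    tensor = GeneCentricTensor(
        counts=truth.counts.astype(np.int64),
        sample_ids=truth.sample_ids,
        gene_ids=truth.gene_ids,
        vocab=cfg.class_vocab,
    )
    return tensor, truth.labels.copy(), truth.pathway_map, truth


def bayes_score(genotypes, truth: SimTruth) -> np.ndarray:
    """The noiseless liability of ``genotypes`` under the generating
    architecture; its AUC upper-bounds any learned model's expected AUC."""
    if isinstance(genotypes, GeneCentricTensor):
        if genotypes.standardized:
            raise ValueError("bayes_score expects raw counts")
        if list(genotypes.gene_ids) != list(truth.gene_ids):
            raise ValueError("gene vocabulary does not match the generating config")
        counts = genotypes.counts
    else:
        counts = np.asarray(genotypes)
    if counts.ndim != 3 or counts.shape[1:] != truth.counts.shape[1:]:
        raise ValueError("genotype tensor shape does not match the generating config")
    return _signal_from_counts(counts, truth.config, truth.burden_mean, truth.burden_sd)


# ---------------------------------------------------------------------------
# Frozen desk-scale scenarios (the study conditions of the expressivity
# ladder): one dataset per epistasis regime.
# ---------------------------------------------------------------------------

def _solve_rate_for_indicator_prob(p_high: float, tau: float, C: int) -> float:
    """Per-class Poisson rate making P(total burden > tau) = ``p_high``."""
    total = brentq(lambda lam: sps.poisson.sf(tau, lam) - p_high, 1e-3, 60.0)
    return total / C


def scenario_null(n_samples: int = 2000, n_genes: int = 50, seed: int = 0) -> SimConfig:
    """Labels independent of genotype (pure noise liability)."""
    return SimConfig(
        n_samples=n_samples, n_genes=n_genes, n_pathways=5,
        prevalence=0.5, noise_sd=1.0, seed=seed,
    )


def scenario_additive(
    n_samples: int = 4000, n_genes: int = 200, n_signal: int = 20,
    beta: float = 0.35, noise_sd: float = 1.0, prevalence: float = 0.3,
    seed: int = 0,
) -> SimConfig:
    """Purely additive signal spread over ``n_signal`` genes."""
    return SimConfig(
        n_samples=n_samples,
        n_genes=n_genes,
        n_pathways=20,
        prevalence=prevalence,
        additive=[(g, beta) for g in range(n_signal)],
        noise_sd=noise_sd,
        seed=seed,
    )


def scenario_magnitude_epistasis(
    n_samples: int = 4000, n_genes: int = 200, n_pairs: int = 10,
    effect: float = 1.5, noise_sd: float = 0.7, prevalence: float = 0.3,
    seed: int = 0,
) -> SimConfig:
    """Positive (synergistic) epistasis between pairs sharing a pathway."""
    pairs = [
        MagnitudePair(2 * k, 2 * k + 1, effect=effect, sign="positive", same_pathway=True)
        for k in range(n_pairs)
    ]
    return SimConfig(
        n_samples=n_samples,
        n_genes=n_genes,
        n_pathways=max(20, n_pairs + 5),
        prevalence=prevalence,
        magnitude_pairs=pairs,
        noise_sd=noise_sd,
        seed=seed,
    )


def scenario_reciprocal_sign(
    n_samples: int = 4000, n_genes: int = 200, n_pairs: int = 3,
    effect: float = 2.0, noise_sd: float = 0.3, prevalence: float = 0.45,
    tau: float = 1.0, indicator_prob: float = 0.70, seed: int = 0,
) -> SimConfig:
    """XOR-type (reciprocal sign) signal concentrated in a few pairs.

    Signal-gene rates are solved so the high-burden indicator has
    probability ``indicator_prob``.  The mild asymmetry away from 1/2 gives
    every model a small additive foothold (as real risk alleles would),
    while the sign-flipping joint structure remains accessible only to
    heads where two genes can interact through more than one hidden neuron.
    """
    cfg0 = SimConfig(n_genes=n_genes)  # for C and default rate
    C = cfg0.class_vocab.size
    r_sig = _solve_rate_for_indicator_prob(indicator_prob, tau, C)
    rates = np.full((n_genes, C), 0.125)
    pairs = []
    for k in range(n_pairs):
        i, j = 2 * k, 2 * k + 1
        rates[i, :] = r_sig
        rates[j, :] = r_sig
        pairs.append(XorPair(i, j, effect=effect, tau=tau))
    return SimConfig(
        n_samples=n_samples,
        n_genes=n_genes,
        n_pathways=20,
        prevalence=prevalence,
        rate=rates,
        xor_pairs=pairs,
        noise_sd=noise_sd,
        seed=seed,
    )
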