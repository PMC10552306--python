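# biosparse

Biologically sparsified neural networks for gene-centric genome
interpretation, with a synthetic case–control cohort simulator that plants
additive, magnitude-epistatic, and reciprocal-sign-epistatic genetic
architectures.

## The problem

Whole-exome case–control studies are deeply underdetermined: a cohort of a
few thousand samples carries millions of variants (p ≫ n), which has made
regularised additive models the default for genotype→phenotype prediction
even though epistasis — non-additive interaction between loci — is
biologically ubiquitous. This package implements a family of small neural
networks whose *expressivity is graded on purpose*, so that the kind of
interaction a model can represent maps onto the kind of epistasis it can
detect:

1. **Gene-centric encoding.** Each sample is an `n_genes × C` histogram of
   variant counts per functional class (C = 16 by default: UTR3, UTR5,
   splicing, intronic, exonic stopgain, …) — the gene's *mutational load*.
2. **Shared gene module.** One small MLP (C inputs → 50 tanh hidden units →
   scalar G_i) is applied with tied weights to every gene. With the default
   shape it holds exactly **850 weights and 51 biases** no matter how many
   genes the cohort has.
3. **Heads of increasing expressivity** over the gene neurons
   G = (G_1 … G_|G|):
   - `NN_logreg` — G wired straight to a sigmoid output: additive in the
     gene neurons, no interactions;
   - `NN_biosparse` — a sparse gene→pathway layer (each gene connected to
     exactly one tanh pathway neuron P_j, chosen from its KEGG-style
     memberships; orphan genes share one *dummy* neuron). Two genes can
     interact in at most one monotone neuron: enough for
     positive/negative (magnitude) epistasis, structurally unable to fit
     non-linearly separable patterns;
   - `NN_dense` — a fully connected hidden layer: a universal
     approximator that can also model reciprocal sign epistasis
     (XOR-like: two alleles individually risk, jointly protective, or
     vice versa);
   - `NN_linear` — NN_biosparse wiring with every tanh replaced by the
     identity: an additive control for the encoding itself.

Training uses Adam with a weighted focal binary cross-entropy,
`α = n_controls/(n_controls + n_cases)` (0.12638 for a 480/3,318 cohort) and
γ = 2, to counter class imbalance. Evaluation is repeated stratified 3-fold
cross-validation with identical splits across models, summarised as mean
(sd) test ROC AUC, and model comparisons use the variance-corrected
resampled t-test (`t = d̄ / sqrt((1/m + n_test/n_train)·s²_d)`, m = reps·k).

Sparsity arrangements beyond pathway knowledge are available for the
gene→hidden layer: random degree-1 masks (a configurable fraction of genes
connected), masks learned by heavy L1 regularisation, and RigL-style
dynamic sparse training (magnitude-based drop, gradient-based grow, at
constant connection count). An ensemble module trains many randomly
sparsified networks on the same data and averages their predicted
probabilities.

Because the real cohorts this method targets sit behind controlled access,
the `simulate` module generates cohorts with known ground truth: Poisson
(optionally negative-binomial) per-gene, per-class variant counts, a
liability built from centred gene burdens
(`additive + tanh-saturating synergies + XOR terms + noise`), and
liability-threshold labels calibrated to a target prevalence. The returned
`SimTruth` exposes the noiseless liability as a Bayes-optimal score, so
every detectability claim can be checked against a ceiling.

## Worked example

Simulate a cohort in which four gene pairs interact synergistically inside
shared pathways, then ask whether the degree-1 sparse network detects what
the additive-in-G model cannot:

```python
from biosparse import (
    GeneModuleSpec, HeadSpec, NNEstimator, TrainConfig,
    corrected_t_test, knowledge_mask, repeated_stratified_cv,
    scenario_magnitude_epistasis, simulate_tensor,
)

cfg = scenario_magnitude_epistasis(n_samples=1500, n_genes=60, n_pairs=4, seed=7)
tensor, labels, pathways, truth = simulate_tensor(cfg)

gm = GeneModuleSpec(input_dim=16, hidden_units=8)
train_cfg = TrainConfig(epochs=20, learning_rate=0.005)
factories = {
    "NN_logreg": lambda seed: NNEstimator(
        gm, HeadSpec(kind="logreg"), tensor.gene_ids, train_cfg, seed=seed),
    "NN_biosparse": lambda seed: NNEstimator(
        gm, lambda s: HeadSpec(kind="biosparse",
                               mask=knowledge_mask(pathways, tensor.gene_ids, seed=s)),
        tensor.gene_ids, train_cfg, seed=seed),
}
results = {}
for name, factory in factories.items():
    res = repeated_stratified_cv(factory, tensor.counts, labels, k=3, reps=5, base_seed=0)
    results[name] = res
    print(f"{name}: mean test AUC {res.mean:.3f} (sd {res.sd:.3f})")

t = corrected_t_test(results["NN_biosparse"].aucs, results["NN_logreg"].aucs,
                     n_train=1000, n_test=500)
print(f"corrected t-test: t = {t.t:.2f}, p = {t.p:.4f}")
```

Output:

```
NN_logreg: mean test AUC 0.822 (sd 0.015)
NN_biosparse: mean test AUC 0.854 (sd 0.026)
corrected t-test: t = 1.64, p = 0.1230
```

The sparse nonlinear head gains ~0.03 AUC by routing each interacting pair
through its shared pathway neuron, where the tanh saturation can express
the planted synergy; the additive head cannot represent it at all. (At
this small cohort size the corrected t-test — deliberately conservative
about overlapping CV training sets — does not yet call the gap
significant; the acceptance suite reruns the comparison at n = 4,000 where
it is unambiguous.)

A command-line entry point covers cohort generation and encoding:

```bash
biosparse simulate config.yaml --seed 1 --out cohort/
biosparse encode cohort/variants.tsv --out cohort/tensor
```

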