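# Methods

## Gene-centric mutational-load encoding

Annotated exome variants (one record per sample × gene × functional class)
are aggregated into an `n × |G| × C` count tensor: entry (s, g, c) is the
number of variants of class c mapping to gene g in sample s. The default
class vocabulary has C = 16. The canonical Annovar-style list enumerates 17
names; to obtain a 16-dimensional histogram the shipped default merges the
two rare translation-boundary classes ("exonic stoploss" and "exonic
startloss") into one, chosen because they are by far the rarest categories
and biologically adjacent (both destroy a translation boundary). The full
17-name vocabulary is available as `CLASSES_17` for users who prefer not to
merge.

Counts are z-scored with one mean/sd per functional class, pooled across
genes and training samples. Pooling per class (rather than per gene ×
class) avoids hundreds of thousands of zero-variance cells at realistic
gene counts and treats "one intronic variant" identically wherever it
lands; a per-(gene, class) mode exists behind `mode="per_gene_class"`.
Standardization statistics are always fit on training folds only and
applied frozen to test folds; features with zero training variance map to
0. The transform stores its statistics and is exactly invertible for
sd > 0 features.

## Architectures

Every model shares a **gene module**: an MLP with C inputs, one hidden
layer (default 50 units, tanh), and a scalar output G_i, applied with tied
weights to every gene. Tying decouples the parameter count from the number
of genes: the default module has 16·50 + 50 = 850 weights and 50 + 1 = 51
biases, totals the test suite re-derives by enumerating the parameter
store. The gene-module activation is tanh, matching the pathway layer; the
output neuron is a sigmoid so the loss can be a binary cross-entropy
variant and predictions are probabilities.

Heads, in order of expressivity:

- **logreg** — the gene neurons feed the output directly; the model is
  additive in G and cannot represent any gene–gene interaction.
- **biosparse** — a sparse gene→pathway layer with *at most one outgoing
  connection per gene* (degree-0 genes are allowed and simply drop out of
  the model, as produced by partial random masks). Two genes can interact
  only inside one tanh neuron, i.e. through a monotone ridge function:
  sufficient for magnitude (positive/negative) epistasis, structurally
  insufficient for sign-reversing interactions.
- **dense** — full G×P connectivity; with enough hidden units this is a
  universal approximator and can represent reciprocal sign epistasis.
- **linear** — identical wiring to biosparse with every activation
  replaced by the identity; its pre-sigmoid score is affine in the
  flattened input (checked numerically by a superposition test), so it is
  an additive control for the encoding.
- **multiconnect** — the sparse layer carries *all* gene–pathway
  relations (degree > 1 allowed).
- **stacked_interactome** — a sparse gene–gene layer (adjacency from an
  edge list, with self-edges added so no gene is discarded) feeding a
  sparse gene–pathway layer; pairs can then reach the output through more
  than one path.

Genes with no pathway membership are routed to a single shared **dummy
pathway neuron** rather than being dropped.

The networks are implemented directly in NumPy: exact analytic gradients,
Adam, and a plain dict-of-arrays parameter store. Masked connections are
structural — weights pinned at zero, gradients masked, excluded from
parameter counts. Initialisation is fan-in-scaled uniform with zero
biases, fully determined by a seed. Checkpoints are single-file npz
archives whose reload reproduces predictions bit-identically on the same
platform.

## Training

Weighted focal binary cross-entropy:
`loss = −w_y · (1 − p_t)^γ · log(p_t)`, with `p_t = p` for cases and
`1 − p` for controls, `w_1 = α`, `w_0 = 1 − α`. α defaults to the control
fraction of the training labels — 480/(480+3,318) = 0.12638 for the
motivating cohort composition — which *down-weights the majority (case)
class*; γ defaults to 2. Probabilities are clamped at 1e-7 for numerical
stability. Optimisation is Adam (lr 0.001, batch 128 by default), with
optional L2 weight decay on weight matrices, inverted dropout after the
gene-neuron layer and after the hidden layer, and an optional L1 penalty
restricted to the gene→hidden layer (used when learning sparsity
arrangements and as the dense head's anti-memorisation regulariser).
Training is deterministic given (seed, data): shuffling and dropout use
generators derived from the config seed. There is no early stopping;
epoch budgets are fixed per architecture within a 20–75 range.

## Sparsity arrangements

- **knowledge** — each gene is wired to one of its member pathways,
  chosen uniformly with a seed; orphans go to the dummy neuron.
- **random** — `round(fraction · |G|)` genes chosen without replacement,
  one uniform hidden neuron each.
- **l1_learned** — a dense layer is trained under an L1 penalty; the
  `budget` largest-magnitude connections are kept subject to at most one
  per gene. The per-gene cap is a deliberate choice so the learned
  arrangement is comparable, at equal budget and width, with the degree-1
  arrangements; the selection therefore needs `budget ≤ |G|`.
- **rigl** — dynamic sparse training: every `update_interval` steps the
  lowest-|w| fraction of active connections is dropped and the same
  number of inactive positions with the largest |gradient| (computed on
  the dense view of the layer) is grown, weights restarting at zero and
  Adam moments reset at rewired positions. The drop fraction is
  cosine-annealed and updates stop at 75% of training by default. Ties in
  both drop and grow break toward the lowest (gene, hidden) flat index
  for determinism. Connection count is invariant at every update by
  construction.

All builders given the same budget produce masks with identical connection
counts, the precondition for comparing arrangements at fixed capacity.

## Evaluation

ROC AUC is computed by average ranks (Mann–Whitney with ties counted 1/2)
and cross-checked against exhaustive concordant-pair counting. Model
evaluation is repeated stratified k-fold CV (default 10 × 3-fold);
partitions depend only on (labels, k, reps, base seed), so different model
factories receive byte-identical splits, and standardization is refit
inside every training fold. Paired comparisons use the corrected resampled
t-test: on the m = reps·k fold differences d,
`t = d̄ / sqrt((1/m + n_test/n_train) · s²_d)` with m − 1 degrees of
freedom; n_test/n_train uses the fold sizes (1/2 for k = 3). The
`1/m`-only (uncorrected) statistic would badly inflate significance
because CV training sets overlap; the acceptance suite verifies the
corrected test's type-I error under label permutation (≤ 0.07 at the 0.05
level over 1,000 repetitions). A zero-variance, non-zero-mean difference
vector is reported as p = 0 with a degenerate flag.

Learning curves draw stratified subsets that are nested across fractions
for a given seed (smaller ⊂ larger), reducing between-fraction variance;
fraction 1.0 reproduces plain CV exactly.

## Ensembles

`train_ensemble` trains N networks (default 100) that differ only in their
random degree-1 mask and their init/shuffle seed, all on the identical
training set — diversity by connectivity instead of bagging — and averages
predicted probabilities (logit averaging behind a flag). Members train
sequentially; seeds are assigned `base_seed + i` so any parallel execution
would leave results unchanged.

## The cohort simulator

The simulator generates what the encoder consumes: per-sample, per-gene,
per-class variant counts, plus labels, a pathway map (GMT-writable), and a
`SimTruth` oracle.

- **Counts**: Poisson with a configurable per-gene × per-class rate matrix
  (default 0.125/class, i.e. burdens ~ Poisson(2)); a gamma-mixed
  (negative-binomial) switch models the overdispersion of real exome
  loads but is not the tested default.
- **Burdens**: b_g = (optionally class-weighted) count sum, centred and
  scaled by its theoretical moments.
- **Liability**: `L = Σ β_g b̃_g + Σ s·e·tanh(slope·(b̃_i + b̃_j − shift))
  + Σ e·XOR(b_i > τ, b_j > τ) + N(0, σ²)`.
  The magnitude-epistasis term is a saturating synergy of the *summed*
  centred burdens (slope 2, shift 1.5 by default): exactly the function
  one tanh pathway neuron receiving both gene neurons can represent, so
  detectability by the degree-1 sparse model is a fair test of routing,
  not of misspecification. A product of centred burdens was rejected for
  this role: products are sign-symmetric (high·high and low·low both
  positive), which no single monotone ridge neuron can express — that is
  precisely the reciprocal-sign regime, which the XOR term covers
  explicitly.
- **Labels**: liability-threshold. The threshold is the candidate value
  whose realized case fraction is closest to the target prevalence — for
  continuous liabilities this is the (1 − prevalence) quantile; for
  discrete ones (noiseless XOR) it falls between tie blocks, so labels
  equal the XOR indicator exactly.
- **Pathway map**: magnitude pairs flagged `same_pathway` receive an
  exclusive shared pathway (a knowledge mask then deterministically
  routes them together); reciprocal-sign pairs are placed in *different*
  pathways (a degree-1 mask then cannot let them interact, which is the
  claim under test); background genes get one or two random memberships
  or none (default 20% orphans, exercising the dummy-neuron path).

`bayes_score` returns the noiseless liability, an upper bound on any
learned model's expected discrimination.

What the simulator does **not** emulate: linkage disequilibrium and
haplotype structure, population stratification, batch effects, and
variant-level allele frequencies. Passing the acceptance experiments
therefore demonstrates that the architectures detect (or provably fail to
detect) the planted interaction *types* under idealised sampling — not
that equally sized real cohorts would show the same margins.

## Desk-scale study conditions

The expressivity ladder runs at n = 4,000 samples, 200 genes, 20 hidden
(pathway) neurons, repeated 10 × 3-fold CV, with an 8-unit gene module —
sizes chosen so the complete ladder runs in minutes on one CPU while every
effect is far from sampling noise. Scenario defaults were fixed once, for
detectability at this scale (they are not calibrated to any real
phenotype):

- *additive*: 20 signal genes, β = 0.35, noise sd 1.0, prevalence 0.3
  (Bayes AUC ≈ 0.92);
- *magnitude*: 10 positive same-pathway pairs, effect 1.5, noise sd 0.7,
  prevalence 0.3;
- *reciprocal sign*: 3 XOR pairs, effect 2.0, τ = 1, noise sd 0.3,
  prevalence 0.45, with signal-gene rates solved (by root-finding on the
  Poisson survival function) so the high-burden indicator has
  probability 0.70. The mild asymmetry away from 1/2 mirrors real risk
  alleles and gives gradient descent a first-order trail to the
  interacting genes; with exactly balanced indicators the pair is
  statistically present but not findable by any of these optimisers at
  this n, and every architecture stays at chance.

Per-architecture optimisation at desk scale: 20 epochs at lr 0.005 for the
logreg/biosparse/linear heads; 75 epochs at lr 0.003 with a 3e-4 L1 penalty
on the wide gene→hidden layer for the dense head (its main overfitting
surface; without it the dense net memorises the training folds before
finding pair structure). The "best additive model" reference is the better
of two L2 logistic regressions — on individual variant counts (strongly
ridged) and on per-gene total burdens — mirroring the practice of trying
several additive alternatives and reporting the best.

The ensemble experiment runs at 25 members, n = 2,000, 100 genes and 10
hidden neurons (10 CV repetitions), and the t-test null calibration at
n = 240, 12 genes, with two additive fitters compared over 1,000 label
permutations — again sizes chosen so the complete suite runs in minutes
while the effects under test remain unambiguous.

The XOR micro-motif (2 inputs, 1 vs 2 tanh hidden units, noiseless XOR,
n = 200) trains with γ = 2 focal loss, lr 0.03, batch 16, 600 epochs: the
focusing term up-weights the one misclassified corner and reliably steers
the 2-unit network out of the OR-only local minimum, while the 1-unit
network is bounded near chance regardless (a monotone ridge cannot rank
XOR corners).

## Known limitations

- The NumPy implementation targets small sparse models; a dense layer over
  tens of thousands of genes would be better served by a GPU framework.
- The ladder's margins are specific to the frozen synthetic conditions;
  changing rates, effects, or noise requires re-checking detectability
  against the Bayes ceiling.
- RigL and L1 mask learning are implemented for the single gene→hidden
  layer, not for arbitrary layers of the stacked variants.
- The corrected t-test treats fold differences as exchangeable; it is
  conservative, and at small n genuine gaps may not reach significance
  (see the README example).
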