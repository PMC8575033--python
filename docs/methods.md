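# Methods

## Model

`xomivae` embeds an expression profile x ∈ [0,1]^G with a variational
autoencoder and classifies it from the posterior mean. The encoder (a ReLU
MLP, default one hidden layer of 1024 units) outputs μ and log σ² of the
approximate posterior q(z|x) = N(μ, diag σ²); a sample z = μ + σ ⊙ ε
(ε ~ N(0, I)) feeds a mirrored decoder whose sigmoid output parameterizes
an elementwise Bernoulli likelihood. Training minimizes the negative
evidence lower bound

    L_vae = BCE(x, x̂)  +  w_KL · KL( N(μ, diag σ²) ‖ N(0, I) ),

with the binary cross-entropy summed over genes and averaged over the
batch — appropriate for unit-interval-normalized expression (mean-squared
error is available behind `recon_loss="mse"`). A softmax classifier with
two hidden layers (128, 64) reads μ directly — never a sample — so
prediction and attribution are deterministic. Training runs in two phases:
`epochs_unsupervised` epochs on L_vae alone, then `epochs_supervised`
epochs on α·L_vae + β·L_class, where L_class is the categorical
cross-entropy. Optimization is Adam at learning rate 1e-3, batch 32;
epochs default to 50 + 100. All randomness (initialization, batch order,
ε draws, splits) flows from a single integer seed through one generator,
so a seed fully determines the trained parameters.

Numerical choices: σ is parameterized as exp(½ logvar) with logvar clipped
to ±8 (gradient masked at the clip); the BCE is computed from decoder
logits for stability; a stratified 20% of samples is held out before
training and recorded on the model.

### KL weight

With the reconstruction term summed over thousands of genes, a unit KL
weight lets the posterior noise (σ ≈ 1) drown weakly expressed factors:
in our experiments the single sex-driver gene was simply never encoded
(max |corr(μ_j, sex)| ≈ 0.07). `kl_weight` (default 0.1) down-weights the
KL term, a β-VAE-style choice common in expression VAEs; with it the sex
driver is reconstructed at r ≈ 0.99 and a clear sex dimension appears.
The standalone `vae_loss` function keeps the canonical unweighted
negative-ELBO definition; the weight applies to the training objective.

### Latent canonicalization

Latent units are arbitrary — any per-dimension affine map of μ can be
absorbed by the adjoining layers without changing any network output.
After training, `train()` therefore canonicalizes μ to zero mean and unit
variance over the training samples (`standardize_latent`, default on);
the μ head, the classifier and decoder first layers, and the logvar-head
bias absorb the map exactly (logits verified identical to ~1e-14). This
gives latent-space statistics and interventions a fixed scale: the
sign-flip ablation (below) replaces μ_j with ∓1, i.e. a one-standard-
deviation value of the opposite sign, rather than a value whose severity
depends on an accidental training-run scale. Attribution rankings, Welch
statistics and predictions are invariant to this map.

## Attribution

The engine implements difference-from-reference attribution with the
DeepLIFT rescale rule (the propagation rule underlying Deep SHAP).
Multipliers start at 1 on the target scalar and propagate backward:
linear layers by the transposed weights, an elementwise nonlinearity f by
the slope (f(a) − f(a_ref)) / (a − a_ref), with the local gradient
substituted when |a − a_ref| < 1e-7. Contributions are m ⊙ (x − r). By
construction the contributions satisfy summation-to-delta — they sum to
f(x) − f(r) per (sample, reference) pair — and reduce to w_eff ⊙ (x − r)
on purely linear networks; both are enforced by tests. Only the rescale
rule is implemented (no RevealCancel), matching Deep SHAP's published
behaviour.

Targets are class *logits* (pre-activation; softmax saturates and
distorts credit) or latent coordinates μ_j, over either the input genes
or the classifier's μ input (the latent → class mode intercepts the
classifier sub-network). The stochastic sampling node lies outside every
explained sub-graph, so attributions are deterministic.

With k references the engine attributes against each reference separately
and averages the k per-reference score vectors — not against the averaged
reference, which differs on nonlinear networks. The default reference set
is 100 random training profiles; phenotype-matched references (e.g.
normal tissue, or the opposite sex) are supported and give deliberately
different rankings — which reference is "right" is a scientific choice,
not a bug, and both options are exposed.

Per-class gene rankings take the mean of |scores| over the explained
samples of that class (absolute first, so positive and negative
contributions cannot cancel across samples), sorted descending with ties
broken by gene id.

Gradient baselines (saliency |∂f/∂x|, input×gradient, gradient-SHAP with
uniform interpolation draws from the reference set) share the interface
but do not satisfy summation-to-delta; they exist for comparison, in
particular to demonstrate the saturation failure: a unit driven past a
ReLU hinge for the explained samples has zero gradient but non-zero
difference-from-reference contribution.

## Latent tools

Welch's t-test per latent dimension ranks dimensions separating two
sample groups: t = (m_A − m_B)/√(s²_A/n_A + s²_B/n_B) with the
Welch–Satterthwaite degrees of freedom and a two-sided p-value; ranking
is by p ascending, ties by |t| descending then dimension index. A
dimension with zero variance in both groups has no defined statistic and
is flagged with p = 1. p-values are used for ranking, not inference, so
no multiplicity correction is applied across dimensions.

Sign-flip ablation replaces μ_j > 0 by −1 and μ_j < 0 by +1 (exactly 0
is left alone — the rule defines only the signed cases), guaranteeing the
value moves regardless of sign. The wrapper always recomputes the flip
from the clean encoder output, so re-ablating an ablated model with the
same spec is a no-op. The ablation study reports one-vs-rest recall
changes per class on the recorded held-out split, with each class ablated
by its own dimension ranking, plus mean ± sd across classes.

## Synthetic data

The generator emulates normalized bulk pan-cancer expression at desk
scale: background genes are Gaussian around 0.5 (sd `noise_sd`, default
0.1) clipped to [0,1]; each class's `planted_genes_per_class` (disjoint
across classes) are shifted up by `effect_size` (default 0.4) in that
class's samples; one designated gene sits near 1 for one sex and near 0
for the other (the XIST-style driver); `na_rate` of cells are masked
missing. The default study fixture is 600 samples × 2000 genes, 4
balanced classes, 25 planted genes each — preserving the genes ≫ samples
shape while trainable on one CPU in about a minute.

What the generator does *not* emulate: count noise and library-size
effects, correlated co-expression modules, batch structure, class
imbalance, and sex signals spread over many genes. Passing tests
therefore demonstrate that the pipeline recovers *planted, independent,
mean-shift* signal — a necessary condition, not evidence about correlated
real-data structure.

At fixture scale the model uses latent_dim 16 and one 256-unit encoder
layer — scaled down with the input width and with the class count (the
reference configuration uses 128 latent dimensions for 33 classes, about
4 per class, and 16/4 preserves that ratio) — while keeping the reference
learning rate, batch size and epoch counts.

## Evaluation protocols

* **Ranked-gene ROC**: at gene-count cutoffs spaced evenly from 1 to G
  (default 100 thresholds, both endpoints forced), TPR = |top-k ∩ truth| /
  |truth| and FPR = |top-k \ truth| / (G − |truth|); AUC by trapezoid with
  the (0,0) origin included.
* **Top-k retraining**: a fresh model on only the top-k ranked genes
  versus k random genes (one model per seed, default 10), same
  hyperparameters except input width, fresh training seed per arm;
  one-vs-rest F1/PPV/TPR/AUC for the target class and the macro-average
  over the remaining classes, evaluated on each retrained model's own
  held-out split. Random arms sample genes without replacement.
* **Rank-sum combination**: per-class ranks summed per gene; ascending
  order (lowest sum = most important overall), ties by gene id; the
  bottom-k accessor gives the overall least-important arm.
* **Overlap**: exact intersection size and Jaccard index of two gene
  lists.

## Known limitations

* The attribution engine supports dense linear layers and elementwise
  nonlinearities (ReLU, sigmoid, tanh) — the architectures this model
  family uses; anything else is rejected with the layer named.
* Reference-set averaging loops over references; very large k_refs on
  very wide inputs trades memory for time.
* The two-phase trainer is plain Adam without schedulers or early
  stopping; α and β of the joint phase default to 1 and are exposed, as
  the right balance is dataset-dependent.
* Retraining-protocol metrics on classes with very few held-out samples
  are coarse-grained (a single sample moves recall by 1/n).
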