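# Methods

This note records the model, its parameters, the numerical choices made
where the design was genuinely open, and what the synthetic benchmark does
and does not demonstrate.

## Model

The predictor treats microbe–drug association discovery as bipartite link
prediction on a heterogeneous network. Its core assumption is *guilt by
shared profile*: drugs (microbes) with similar binary interaction profiles
are likely to associate with the same partners, and side information
(disease associations, chemical/functional similarity) carries a
consistent signal.

**Similarities.** Two kernels are computed on interaction profiles and
averaged. The Gaussian interaction profile (GIP) kernel
`exp(−γ‖p_i − p_j‖²)` uses a single bandwidth per node type,
`γ = 1 / mean_i ‖p_i‖²`; the mean includes all-zero profiles, and two
all-zero profiles have similarity 1 (distance zero) — both are
formula-faithful consequences accepted as-is. The Hamming similarity
divides the count of differing positions by the *profile length* (not the
number of ones), which keeps it in [0, 1] for any binary profile,
including all-zero ones. The heterogeneous network
`N = [[S_r, A], [Aᵀ, S_m]]` has unit diagonal by construction, so every
node has a self-loop and no attention neighbour set is empty.

**Topological embeddings.** One graph-attention layer, one head; node
input features are the rows of `N` themselves (input dimension
`n_r + n_m`). Attention logits pass through LeakyReLU (slope 0.2,
conventional) and are normalised by an explicit softmax over the
neighbour set `{j : N(i,j) ≠ 0}`. The embedding activation is ELU — the
nonlinearity is an open choice; ELU keeps negative coordinates informative
for the inner-product decoder. The decoder is `sigmoid(ZZᵀ)` and the loss
is the mean per-node squared reconstruction error against `N`, minimised
by Adam (β₁ = 0.9, β₂ = 0.999, ε = 1e-8). Weight initialisation is Glorot
uniform from a seeded generator; training is full-graph, so same-seed runs
are bit-identical.

**Random walk with restart.** The transition matrix column-normalises the
fused similarity (all-zero columns become uniform teleports) — the
standard column-stochastic convention consistent with the left
multiplication `q ← φMq + (1−φ)ε`. φ defaults to 0.1; iteration stops when
the per-column L1 change drops below 1e-6 or after 1000 iterations (a
warning is emitted and the last iterate returned if the cap is hit —
convergence is geometric with rate φ, so at the default this never
triggers). The iterative path is cross-checked in tests against the closed
form `(1−φ)(I − φM)⁻¹`.

**Sparse autoencoder.** Both layers use the logistic sigmoid: the hidden
activations must live in (0, 1) for the Bernoulli-KL penalty
`Σ_t KL(ρ‖ρ̂_t)` to be well defined, and the output layer reconstructs
inputs min-max scaled to [0, 1] per column. `ρ̂_t` is the full-batch mean
activation of hidden unit `t`, clamped to [1e-6, 1−1e-6] before the
logarithms; the penalty gradient is taken through the batch mean (zero on
the clamp boundary). The sparsity target ρ = 0.05 is the classical
convention; the penalty weight β = 0.1. Drugs and microbes get independent
autoencoders (their input widths differ), seeded distinctly from the model
seed.

**Missing side information.** When the external chemical (functional)
similarity is absent, the fused interaction-profile similarity fills its
slot and the substitution is recorded in the attribute block layout; when
disease files are absent, the disease profile is empty and the cosine
block degenerates to the identity (all-zero rows are defined to have
similarity 0 off-diagonal, 1 on it, avoiding 0/0).

**Scoring.** Feature blocks are concatenated exactly as listed, unscaled —
embeddings are unbounded while similarity blocks sit in [0, 1], and no
rescaling is applied by default; column standardisation is available via
`standardize_features=True` / `features.standardize`. The sigmoid of the
inner product is monotone, so in exact arithmetic it orders pairs exactly
as the raw inner product does; in double precision, however, the sigmoid
rounds to 1.0 once the inner product exceeds ~37, which at these feature
widths can tie large swaths of the top-ranked pairs. Rankings and
cross-validation metrics therefore use the sigmoid's argument (the raw
inner products, carried on the results object alongside the scores), and
the fixed accuracy threshold is mapped to the equivalent log-odds cut;
the reported scores remain the sigmoid values.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `gat.embed_dim` (l) | 128 | topological embedding width |
| `gat.lr` | 0.01 | Adam step size, GAT |
| `gat.epochs` | 500 | full-graph training epochs |
| `gat.slope` (μ) | 0.2 | LeakyReLU negative slope |
| `sae.hidden_dim` (k) | 32 | attribute code width |
| `sae.rho` | 0.05 | target mean hidden activation |
| `sae.beta` | 0.1 | sparsity penalty weight |
| `sae.lr` | 0.01 | Adam step size, SAE |
| `rwr.restart_prob` (φ) | 0.1 | walk-continuation probability |
| `cv.n_folds` / `cv.n_repeats` | 5 / 10 | evaluation protocol |
| `cv.accuracy_threshold` | 0.5 | fixed-threshold accuracy cut |

The dimension defaults (l = 128, k = 32) and both learning rates (0.01)
are the operating point at which held-out AUC peaks in the published
sensitivity analysis; epochs, slope and ρ are this package's own
defaults, as the training schedule, initialisation and activation choices
were left open.

## Evaluation protocol

Known pairs are partitioned into five folds; unknown pairs are
partitioned likewise, so each fold tests on 20% of knowns and 20% of
unknowns, disjoint across folds within a repeat. With
`mask_similarities=True` (default) the fold's known pairs are zeroed
*before* any similarity, network, or autoencoder computation — the
held-out labels are invisible to every training stage. Setting it False
reproduces the laxer protocol in which similarities come from the full
matrix. Precision is TP/(TP+FP); accuracy is reported both at a fixed
score threshold and as the best achievable over all test-score cuts
("best accuracy"), since the sigmoid scores are uncalibrated and
heavily right-shifted. AUROC/AUPR come from scikit-learn and are
cross-checked in the test suite against brute-force pairwise and step-sum
oracles.

## Synthetic data

The generator plants a bipartite block model: drugs, microbes and diseases
are assigned round-robin to `n_blocks` communities; associations are
Bernoulli(p_in) within matched communities and Bernoulli(p_out) otherwise,
then flipped with probability `noise`. Disease associations follow the
same communities (rates 0.4 in / 0.02 out), and the stand-in external
similarity matrices are noisy block indicators (baseline 0.1, Gaussian
noise sd 0.1, symmetrised, unit diagonal). A block model was chosen over a
low-rank Gaussian because the interaction-profile kernels respond directly
to shared binary profiles, so planted signal is recoverable by
construction. The benchmark conditions — 120 drugs × 40 microbes, 4
blocks, p_in = 0.6, p_out = 0.02, noise = 0.01 — are fixed as the
generator defaults. `mdad_shaped()` / `abiofilm_shaped()` reproduce the
shapes and densities of the two public resources (1373×173 with ≈2470
associations; 1720×140 with ≈2884) for scale testing only.

What the synthetic benchmark does **not** emulate: the heavy-tailed degree
distributions of curated databases (a few drugs with dozens of partners,
many with one), realistic chemical-similarity distributions, correlated
annotation biases, or identifier noise. Passing the planted-recovery test
shows the pipeline can extract block-structured signal end to end under
leakage control; it does not certify the headline performance attainable
on the real curated datasets.

## Benchmark problem sizes and frozen values

Tests and the acceptance script run the cross-validated benchmark at
reduced training schedules (100 epochs for both autoencoders, one CV
repeat), a deliberate small-problem operating point that completes in
seconds while leaving the planted signal clearly recoverable. Under the
fixed benchmark seed the mean five-fold AUC measured on the first
calibration run (0.8316) is frozen in the test suite as a regression
pin; across other generator seeds the mean AUC sits around 0.81-0.83.

## Known limitations

- All matrices are dense; memory grows as (n_r + n_m)², fine at the scale
  of curated resources (≤ ~2000 nodes) but not beyond.
- Scores are uncalibrated; only their order is meaningful, and no decision
  threshold for "calling" an association is defined.
- Single attention head and single GAT layer; no mini-batching or GPU
  path.
- Identifier matching is exact-string; no chemical or taxonomic
  normalisation is attempted.
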