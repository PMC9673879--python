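# gsamda

Microbe–drug association prediction with a graph-attention autoencoder and
a sparse autoencoder over a heterogeneous similarity network (the GSAMDA
method).

Clinically verified microbe–drug associations are sparse, and screening
candidate pairs in the lab is slow and expensive. Given a binary
association matrix `A` (rows = drugs, columns = microbes) and optional side
information (drug–disease and microbe–disease associations, external drug
chemical-structure and microbe functional similarities), this package
scores every unobserved drug–microbe pair so that likely associations rank
first. It is aimed at computational biologists prioritising candidates for
experimental follow-up, and at method developers who need a reproducible
reference implementation with an evaluation harness.

## Method

1. **Heterogeneous network.** Each drug/microbe is summarised by its binary
   interaction profile (its row/column of `A`). Two profile kernels are
   fused per node type — the Gaussian interaction profile kernel
   `S_GIP(i,j) = exp(−γ‖p_i − p_j‖²)`, with bandwidth `γ` the reciprocal
   mean squared profile norm, and the Hamming similarity
   `S_HIP(i,j) = 1 − (#differing positions)/(profile length)` — into
   `S = (S_GIP + S_HIP)/2`, and assembled with `A` into the block matrix
   `N = [[S_r, A], [Aᵀ, S_m]]` over all `n_r + n_m` nodes.
2. **Topological embeddings.** A single-layer graph-attention autoencoder
   (attention `α_ij = softmax_j LeakyReLU(a·[Wh_i ‖ Wh_j])` over the
   neighbour set, ELU output, inner-product decoder `sigmoid(ZZᵀ)`) is
   trained with Adam to reconstruct `N`, yielding `Z ∈ R^{(n_r+n_m)×l}`,
   `l = 128` by default.
3. **Attribute embeddings.** Attribute matrices
   `A_r = [A | S_che | S_mm | S_dis]` and `A_m = [Aᵀ | S_f | S_rr | S_dis]`
   (with `S_mm`, `S_rr` the random-walk-with-restart smoothing of the fused
   similarities and `S_dis` the cosine similarity of disease profiles) are
   compressed by a sparse autoencoder — one sigmoid hidden layer of `k = 32`
   units with a Bernoulli-KL sparsity penalty
   `β·Σ_t KL(ρ ‖ ρ̂_t)`, `β = 0.1` — into attribute codes `Ã`.
4. **Scoring.** Feature matrices `F_r = [Z_r|Ã_r|S_che|A|S_dis|A|S_mm|A]`
   and `F_m = [Z_m|Ã_m|Aᵀ|S_f|Aᵀ|S_dis|Aᵀ|S_rr]` (equal width
   `l + k + 3(n_r + n_m)`) score every pair by
   `S(i,j) = sigmoid(F_r(i)·F_m(j))`.

Evaluation is repeated five-fold cross-validation: each fold holds out 20%
of known and 20% of unknown pairs, and every similarity is recomputed from
the masked training matrix so no held-out label leaks into training.

Both autoencoders are implemented in numpy with hand-derived gradients and
a built-in Adam optimiser; fits are bit-reproducible given a seed.

## Worked example

```python
from gsamda import (GSAMDA, GATParams, SAEParams, SynthConfig, generate)

ds, truth = generate(SynthConfig(n_r=60, n_m=20, n_d=15, seed=4))
model = GSAMDA(ds, gat_params=GATParams(embed_dim=64, epochs=100),
               sae_params=SAEParams(hidden_dim=16, epochs=100))
res = model.fit(seed=0)
print(res.summary())
for partner, score in res.rank("drug_0", top_n=5):
    print(partner, f"{score:.4f}")
```

prints

```
GSAMDA association model results
================================================
drugs:              60
microbes:           20
known associations: 188
topological dim l:  64
attribute dim k:    16
feature width:      320
GAT final loss:     6.299002 (100 epochs)
SAE final loss:     5.976547 (drugs) / 6.291525 (microbes)
score range:        [0.5234, 1.0000]
mean score known:   1.0000
mean score unknown: 0.9653
fit time:           0.1 s
microbe_0 1.0000
microbe_16 1.0000
microbe_8 1.0000
microbe_4 0.9998
microbe_5 0.9689
```

Known pairs score visibly above unknown ones, and the top-ranked partners
for `drug_0` (planted community 0) are the community-0 microbes — the
planted structure is recovered. `res.rank` excludes already-known partners
by default, mirroring how candidate lists are compiled for literature
follow-up. Scores order candidates; they are not calibrated probabilities.

The same pipeline is available from a shell:

```sh
gsamda synth --preset small --seed 3 --out data/
gsamda predict --assoc data/associations.tsv --out scores.tsv
gsamda rank --assoc data/associations.tsv --anchor drug_0 --top 20
gsamda evaluate --assoc data/associations.tsv --repeats 10
```

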