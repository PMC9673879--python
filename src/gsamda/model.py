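"""The GSAMDA model: heterogeneous-network microbe-drug association scoring.

:class:`GSAMDA` bundles the full pipeline behind a statsmodels-style
surface: construct it from an :class:`~gsamda.datasets.AssociationDataset`
(or a pair-list DataFrame via :meth:`GSAMDA.from_frame`), call
:meth:`~GSAMDA.fit`, and receive a :class:`GSAMDAResults` carrying the
score matrix, embeddings, training diagnostics and ranking helpers.

Fitting proceeds in five stages:

1. fuse Gaussian and Hamming interaction-profile similarities for drugs and
   microbes and assemble the heterogeneous network ``N``;
2. train a graph-attention autoencoder on ``N`` for topological embeddings;
3. smooth the fused similarities by random walk with restart, take cosine
   similarities of disease profiles, assemble attribute matrices, and train
   one sparse autoencoder per node type for attribute embeddings;
4. concatenate embeddings with the raw attribute blocks into the drug and
   microbe feature matrices;
5. score every pair by the sigmoid inner product of its feature rows.
"""

from __future__ import annotations

import time

import numpy as np
import pandas as pd

from .datasets import AssociationDataset, write_score_matrix
from .features import FeatureMatrix, build_feature_matrices, rank_candidates, score_pairs
from .gat import EmbeddingMatrix, GATParams, train_gat
from .sae import (
    SAEParams,
    build_drug_attributes,
    build_microbe_attributes,
    train_sae,
)
from .similarity import (
    RWRParams,
    build_heterogeneous_network,
    cosine_profile_similarity,
    fused_profile_similarity,
    rwr_smooth,
)

__all__ = ["GSAMDA", "GSAMDAResults"]

_SEED_MOD = 2**31


class GSAMDA:
    """Microbe-drug association model over a heterogeneous network.

    Parameters
    ----------
    dataset
        Associations plus optional side matrices. When the external drug
        chemical similarity (or microbe functional similarity) is absent,
        the fused interaction-profile similarity stands in for it and the
        substitution is recorded in the attribute block layout.
    gat_params, sae_params, rwr_params
        Hyperparameters of the three learned/iterative stages; defaults are
        the published operating point (l=128, k=32, lr=0.01, beta=0.1,
        restart probability 0.1).
    standardize_features
        If True, z-score feature columns before the inner-product scorer
        (off by default: blocks are concatenated as-is).
    """

    def __init__(
        self,
        dataset: AssociationDataset,
        gat_params: GATParams | None = None,
        sae_params: SAEParams | None = None,
        rwr_params: RWRParams | None = None,
        standardize_features: bool = False,
    ):
        self.dataset = dataset
        self.gat_params = gat_params or GATParams()
        self.sae_params = sae_params or SAEParams()
        self.rwr_params = rwr_params or RWRParams()
        self.standardize_features = standardize_features

    @classmethod
    def from_frame(cls, pairs: pd.DataFrame, **kwargs) -> "GSAMDA":
        """Build from a two-column (drug id, microbe id) DataFrame."""
        drugs = pairs.iloc[:, 0].astype(str).tolist()
        microbes = pairs.iloc[:, 1].astype(str).tolist()
        drug_ids = list(dict.fromkeys(drugs))
        microbe_ids = list(dict.fromkeys(microbes))
        A = np.zeros((len(drug_ids), len(microbe_ids)))
        di = {d: i for i, d in enumerate(drug_ids)}
        mi = {m: j for j, m in enumerate(microbe_ids)}
        for d, m in zip(drugs, microbes):
            A[di[d], mi[m]] = 1.0
        ds = AssociationDataset(drug_ids=drug_ids, microbe_ids=microbe_ids, A=A)
        return cls(ds, **kwargs)

    def fit(self, seed: int | None = None, A_override: np.ndarray | None = None) -> "GSAMDAResults":
        """Run the full pipeline and return results.

        ``seed`` overrides both autoencoder seeds (the two sparse
        autoencoders get distinct seeds derived from it); ``A_override``
        substitutes a (possibly masked) association matrix for the
        dataset's, used by the cross-validation harness.
        """
        t0 = time.perf_counter()
        ds = self.dataset
        A = ds.A if A_override is None else np.asarray(A_override, dtype=float)
        if A.shape != ds.A.shape:
            raise ValueError("A_override must match the dataset's association shape")

        gat_p = self.gat_params
        sae_p = self.sae_params
        if seed is not None:
            gat_p = GATParams(**{**gat_p.__dict__, "seed": seed % _SEED_MOD})

        # stage 1: similarities and heterogeneous network
        S_r = fused_profile_similarity(A, "drug")
        S_m = fused_profile_similarity(A, "microbe")
        network = build_heterogeneous_network(S_r, S_m, A)

        # stage 2: topological embeddings
        Z, gat_losses = train_gat(network, gat_p)

        # stage 3: attribute matrices and embeddings
        S_mm = rwr_smooth(S_r, self.rwr_params).values
        S_rr = rwr_smooth(S_m, self.rwr_params).values
        D_r = ds.drug_disease if ds.drug_disease is not None else np.zeros((ds.n_drugs, 0))
        D_m = ds.microbe_disease if ds.microbe_disease is not None else np.zeros((ds.n_microbes, 0))
        S_dis_r = cosine_profile_similarity(D_r, "drug").values
        S_dis_m = cosine_profile_similarity(D_m, "microbe").values
        che_sub = ds.drug_chemical_sim is None
        f_sub = ds.microbe_functional_sim is None
        S_che = S_r.values if che_sub else ds.drug_chemical_sim
        S_f = S_m.values if f_sub else ds.microbe_functional_sim
        attr_r = build_drug_attributes(A, S_che, S_mm, S_dis_r, che_substituted=che_sub)
        attr_m = build_microbe_attributes(A.T, S_f, S_rr, S_dis_m, f_substituted=f_sub)
        base = sae_p.seed if seed is None else seed
        sae_p_r = SAEParams(**{**sae_p.__dict__, "seed": (base + 1) % _SEED_MOD})
        sae_p_m = SAEParams(**{**sae_p.__dict__, "seed": (base + 2) % _SEED_MOD})
        Atil_r, sae_losses_r = train_sae(attr_r, sae_p_r)
        Atil_m, sae_losses_m = train_sae(attr_m, sae_p_m)

        # stages 4-5: feature assembly and scoring
        F_r, F_m = build_feature_matrices(
            Z, Atil_r, Atil_m, A, S_che, S_dis_r, S_mm, S_f, S_dis_m, S_rr
        )
        if self.standardize_features:
            F_r = _standardize(F_r)
            F_m = _standardize(F_m)
        scores = score_pairs(F_r, F_m)
        inner = F_r.values @ F_m.values.T

        return GSAMDAResults(
            model=self,
            A_used=A,
            scores=scores,
            inner_products=inner,
            topo_embedding=Z,
            attr_embedding_drugs=Atil_r,
            attr_embedding_microbes=Atil_m,
            feature_matrices=(F_r, F_m),
            gat_loss=gat_losses,
            sae_loss_drugs=sae_losses_r,
            sae_loss_microbes=sae_losses_m,
            fit_seconds=time.perf_counter() - t0,
        )


def _standardize(F: FeatureMatrix) -> FeatureMatrix:
    V = F.values
    mu = V.mean(axis=0)
    sd = V.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    return FeatureMatrix((V - mu) / sd, F.block_layout)


class GSAMDAResults:
    """Fitted scores, embeddings and diagnostics.

    ``scores`` is the (n_drugs x n_microbes) matrix of sigmoid-squashed
    association scores; scores order candidate pairs, they are not
    calibrated probabilities. ``inner_products`` holds the sigmoid's
    argument ``F_r F_m^T``: the sigmoid is monotone, so both order pairs
    identically in exact arithmetic, but the raw inner products retain
    resolution where the sigmoid saturates to 1.0 in double precision —
    rankings and evaluation therefore use them.
    """

    def __init__(
        self,
        model: GSAMDA,
        A_used: np.ndarray,
        scores: np.ndarray,
        inner_products: np.ndarray,
        topo_embedding: EmbeddingMatrix,
        attr_embedding_drugs: np.ndarray,
        attr_embedding_microbes: np.ndarray,
        feature_matrices: tuple[FeatureMatrix, FeatureMatrix],
        gat_loss: list[float],
        sae_loss_drugs: list[float],
        sae_loss_microbes: list[float],
        fit_seconds: float,
    ):
        self.model = model
        self.A_used = A_used
        self.scores = scores
        self.inner_products = inner_products
        self.topo_embedding = topo_embedding
        self.attr_embedding_drugs = attr_embedding_drugs
        self.attr_embedding_microbes = attr_embedding_microbes
        self.feature_matrices = feature_matrices
        self.gat_loss = gat_loss
        self.sae_loss_drugs = sae_loss_drugs
        self.sae_loss_microbes = sae_loss_microbes
        self.fit_seconds = fit_seconds

    @property
    def dataset(self) -> AssociationDataset:
        return self.model.dataset

    def rank(self, anchor: str, top_n: int = 20, exclude_known: bool = True):
        """Top candidate partners for a drug or microbe id.

        Ordering uses the raw inner products (saturation-free); the
        returned scores are the sigmoid-squashed values.
        """
        ranked = rank_candidates(
            self.inner_products,
            self.dataset.drug_ids,
            self.dataset.microbe_ids,
            anchor,
            top_n=top_n,
            exclude_known=exclude_known,
            A=self.A_used,
        )
        sig = lambda x: 1.0 / (1.0 + np.exp(-x))
        return [(p, float(sig(v))) for p, v in ranked]

    def score_frame(self) -> pd.DataFrame:
        """Long-format (drug_id, microbe_id, score, known) DataFrame."""
        ds = self.dataset
        return pd.DataFrame(
            {
                "drug_id": np.repeat(ds.drug_ids, ds.n_microbes),
                "microbe_id": np.tile(ds.microbe_ids, ds.n_drugs),
                "score": self.scores.ravel(),
                "known": self.A_used.ravel().astype(int),
            }
        )

    def to_tsv(self, path) -> None:
        write_score_matrix(
            self.scores, self.dataset.drug_ids, self.dataset.microbe_ids, path, self.A_used
        )

    def summary(self) -> str:
        ds = self.dataset
        F_r, F_m = self.feature_matrices
        known = self.A_used == 1
        lines = [
            "GSAMDA association model results",
            "=" * 48,
            f"drugs:              {ds.n_drugs}",
            f"microbes:           {ds.n_microbes}",
            f"known associations: {int(self.A_used.sum())}",
            f"topological dim l:  {self.topo_embedding.dim}",
            f"attribute dim k:    {self.attr_embedding_drugs.shape[1]}",
            f"feature width:      {F_r.width}",
            f"GAT final loss:     {self.gat_loss[-1]:.6f} ({len(self.gat_loss)} epochs)",
            f"SAE final loss:     {self.sae_loss_drugs[-1]:.6f} (drugs) / "
            f"{self.sae_loss_microbes[-1]:.6f} (microbes)",
            f"score range:        [{self.scores.min():.4f}, {self.scores.max():.4f}]",
            f"mean score known:   {self.scores[known].mean():.4f}"
            if known.any()
            else "mean score known:   n/a",
            f"mean score unknown: {self.scores[~known].mean():.4f}"
            if (~known).any()
            else "mean score unknown: n/a",
            f"fit time:           {self.fit_seconds:.1f} s",
        ]
        return "\n".join(lines)
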