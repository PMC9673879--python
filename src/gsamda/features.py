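"""Final feature assembly and pair scoring.

The drug and microbe feature matrices concatenate the topological embedding,
the attribute embedding, and the raw attribute blocks, with the association
matrix interleaved between the square similarity blocks:

    F_r = [Z_r | Atil_r | S_che | A | S_dis | A | S_mm | A]
    F_m = [Z_m | Atil_m | A^T | S_f | A^T | S_dis | A^T | S_rr]

Both widths equal ``l + k + 3 n_r + 3 n_m`` — the interleaved association
blocks are what makes the two widths match, which the inner-product scorer

    S[i, j] = sigmoid(F_r[i] . F_m[j])

requires. Scores are used for ranking candidate partners; no hard decision
threshold is attached to them here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .gat import EmbeddingMatrix, _sigmoid

__all__ = ["FeatureMatrix", "build_feature_matrices", "score_pairs", "rank_candidates"]


@dataclass
class FeatureMatrix:
    values: np.ndarray
    block_layout: list[tuple[str, int]]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.isfinite(self.values).all():
            raise ValueError("feature matrix contains non-finite entries")
        if sum(w for _, w in self.block_layout) != self.values.shape[1]:
            raise ValueError("block layout does not tile the feature width")

    @property
    def width(self) -> int:
        return self.values.shape[1]


def _as_array(x) -> np.ndarray:
    if isinstance(x, EmbeddingMatrix):
        return x.Z
    return np.asarray(x, dtype=float)


def build_feature_matrices(
    Z: EmbeddingMatrix,
    Atil_r: np.ndarray | EmbeddingMatrix,
    Atil_m: np.ndarray | EmbeddingMatrix,
    A: np.ndarray,
    S_che: np.ndarray,
    S_dis_r: np.ndarray,
    S_mm: np.ndarray,
    S_f: np.ndarray,
    S_dis_m: np.ndarray,
    S_rr: np.ndarray,
) -> tuple[FeatureMatrix, FeatureMatrix]:
    """Assemble the drug and microbe feature matrices.

    Raises if the resulting widths disagree (which indicates mis-shaped
    inputs rather than a legal configuration).
    """
    A = np.asarray(A, dtype=float)
    n_r, n_m = A.shape
    Zr, Zm = Z.drugs, Z.microbes
    Ar, Am = _as_array(Atil_r), _as_array(Atil_m)
    if Ar.shape[0] != n_r or Am.shape[0] != n_m:
        raise ValueError("attribute embeddings do not match association shape")
    if Ar.shape[1] != Am.shape[1]:
        raise ValueError("drug and microbe attribute embeddings must share dim k")

    drug_blocks = [
        ("Z_r", Zr), ("Atil_r", Ar), ("S_che", np.asarray(S_che, float)),
        ("A", A), ("S_dis", np.asarray(S_dis_r, float)), ("A", A),
        ("S_mm", np.asarray(S_mm, float)), ("A", A),
    ]
    microbe_blocks = [
        ("Z_m", Zm), ("Atil_m", Am), ("At", A.T),
        ("S_f", np.asarray(S_f, float)), ("At", A.T),
        ("S_dis", np.asarray(S_dis_m, float)), ("At", A.T),
        ("S_rr", np.asarray(S_rr, float)),
    ]
    F_r = FeatureMatrix(
        np.hstack([B for _, B in drug_blocks]),
        [(name, B.shape[1]) for name, B in drug_blocks],
    )
    F_m = FeatureMatrix(
        np.hstack([B for _, B in microbe_blocks]),
        [(name, B.shape[1]) for name, B in microbe_blocks],
    )
    if F_r.width != F_m.width:
        raise ValueError(
            f"feature widths disagree ({F_r.width} vs {F_m.width}); "
            "check similarity block shapes"
        )
    return F_r, F_m


def score_pairs(F_r: FeatureMatrix, F_m: FeatureMatrix) -> np.ndarray:
    """Score every drug-microbe pair: ``sigmoid(F_r F_m^T)``, shape (n_r, n_m)."""
    if F_r.width != F_m.width:
        raise ValueError("feature matrices must share width")
    return _sigmoid(F_r.values @ F_m.values.T)


def rank_candidates(
    scores: np.ndarray,
    drug_ids: list[str],
    microbe_ids: list[str],
    anchor: str,
    top_n: int = 20,
    exclude_known: bool = True,
    A: np.ndarray | None = None,
) -> list[tuple[str, float]]:
    """Top-scoring partners for one anchor drug or microbe.

    The anchor may be either a drug id (ranks microbes) or a microbe id
    (ranks drugs). With ``exclude_known`` (requires ``A``), pairs already
    known are removed before ranking. Ties are broken by partner id; if
    fewer than ``top_n`` candidates remain, all are returned.
    """
    scores = np.asarray(scores, dtype=float)
    if anchor in drug_ids:
        i = drug_ids.index(anchor)
        vec = scores[i, :]
        partners = microbe_ids
        known = A[i, :] if A is not None else None
    elif anchor in microbe_ids:
        j = microbe_ids.index(anchor)
        vec = scores[:, j]
        partners = drug_ids
        known = A[:, j] if A is not None else None
    else:
        raise KeyError(f"anchor {anchor!r} is neither a drug nor a microbe id")
    if exclude_known:
        if known is None:
            raise ValueError("exclude_known requires the association matrix A")
        keep = known == 0
    else:
        keep = np.ones(len(partners), dtype=bool)
    ranked = sorted(
        ((partners[t], float(vec[t])) for t in np.flatnonzero(keep)),
        key=lambda kv: (-kv[1], kv[0]),
    )
    return ranked[:top_n]
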