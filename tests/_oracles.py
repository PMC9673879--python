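"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately written as naive elementwise loops or
closed-form linear algebra, sharing no code with the package.
"""

from __future__ import annotations

import numpy as np


def gip_oracle(P: np.ndarray) -> np.ndarray:
    """Gaussian interaction-profile kernel by explicit double loop."""
    n = P.shape[0]
    gamma = 1.0 / (np.mean([np.dot(P[i], P[i]) for i in range(n)]))
    S = np.empty((n, n))
    for i in range(n):
        for j in range(n):
            d = P[i] - P[j]
            S[i, j] = np.exp(-gamma * np.dot(d, d))
    return S


def hip_oracle(P: np.ndarray) -> np.ndarray:
    """Hamming interaction-profile similarity by explicit counting."""
    n, L = P.shape
    S = np.empty((n, n))
    for i in range(n):
        for j in range(n):
            diff = sum(1 for t in range(L) if P[i, t] != P[j, t])
            S[i, j] = 1.0 - diff / L
    return S


def cosine_oracle(D: np.ndarray) -> np.ndarray:
    """Cosine similarity of rows; zero rows -> 0 off-diagonal, 1 diagonal."""
    n = D.shape[0]
    S = np.empty((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                S[i, j] = 1.0
                continue
            ni, nj = np.linalg.norm(D[i]), np.linalg.norm(D[j])
            S[i, j] = 0.0 if ni == 0 or nj == 0 else float(np.dot(D[i], D[j]) / (ni * nj))
    return S


def rwr_closed_form(S: np.ndarray, phi: float) -> np.ndarray:
    """Stationary RWR distributions via the direct linear solve
    q_i = (1 - phi) (I - phi M)^{-1} e_i, rows = q_i."""
    n = S.shape[0]
    colsum = S.sum(axis=0)
    M = np.empty_like(S, dtype=float)
    for j in range(n):
        M[:, j] = S[:, j] / colsum[j] if colsum[j] > 0 else 1.0 / n
    Q = (1.0 - phi) * np.linalg.inv(np.eye(n) - phi * M)
    return Q.T  # column q_i -> row i


def pairwise_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Mann-Whitney AUC: fraction of (positive, negative) pairs ranked
    correctly, ties counted 0.5."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))


def stepsum_aupr(scores: np.ndarray, labels: np.ndarray) -> float:
    """Average precision as the step-sum over the PR curve, grouping tied
    scores into single thresholds."""
    thresholds = np.unique(scores)[::-1]
    n_pos = int((labels == 1).sum())
    ap = 0.0
    prev_recall = 0.0
    for t in thresholds:
        pred = scores >= t
        tp = int(((labels == 1) & pred).sum())
        fp = int(((labels == 0) & pred).sum())
        precision = tp / (tp + fp)
        recall = tp / n_pos
        ap += (recall - prev_recall) * precision
        prev_recall = recall
    return ap


def kl_scalar(rho: float, rho_hat: float) -> float:
    return rho * np.log(rho / rho_hat) + (1 - rho) * np.log((1 - rho) / (1 - rho_hat))
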