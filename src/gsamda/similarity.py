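"""Interaction-profile similarity kernels and the heterogeneous network.

Every drug (microbe) is summarised by its binary interaction profile — its
row (column) of the association matrix ``A``. Two kernels are computed on
profiles:

* the Gaussian interaction profile (GIP) kernel,
  ``S[i, j] = exp(-gamma * ||p_i - p_j||^2)`` with the bandwidth ``gamma``
  set to the reciprocal of the mean squared profile norm, and
* the Hamming interaction profile (HIP) similarity,
  ``S[i, j] = 1 - (# differing positions) / (profile length)``.

The two are fused by an elementwise mean into the within-type similarity
blocks ``S_r`` (drugs) and ``S_m`` (microbes) of the heterogeneous network

    N = [[S_r, A], [A^T, S_m]],

a single graph over all drug and microbe nodes in which an edge exists
wherever ``N[i, j] != 0``.

Two further similarities feed the attribute matrices: cosine similarity of
disease-association profiles, and a random-walk-with-restart (RWR)
smoothing of the fused similarity, whose i-th row is the stationary
visiting-probability vector of a walker restarting at node i.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "SimilarityMatrix",
    "HeterogeneousNetwork",
    "RWRParams",
    "gip_similarity",
    "hip_similarity",
    "fuse_similarity",
    "cosine_profile_similarity",
    "rwr_smooth",
    "build_heterogeneous_network",
]

_UNIT_INTERVAL_KINDS = frozenset({"GIP", "HIP", "fused", "cosine"})
_SYMMETRIC_KINDS = frozenset({"GIP", "HIP", "fused"})


@dataclass
class SimilarityMatrix:
    """Square similarity matrix with provenance tag.

    ``kind`` is one of ``GIP | HIP | fused | cosine | rwr | external``;
    ``axis`` records whether rows index drugs or microbes.
    """

    values: np.ndarray
    kind: str
    axis: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        V = self.values
        if V.ndim != 2 or V.shape[0] != V.shape[1]:
            raise ValueError(f"similarity matrix must be square, got {V.shape}")
        if not np.isfinite(V).all():
            raise ValueError("similarity matrix contains non-finite entries")
        if self.kind in _UNIT_INTERVAL_KINDS:
            if V.size and (V.min() < -1e-12 or V.max() > 1 + 1e-12):
                raise ValueError(f"{self.kind} similarity entries must lie in [0, 1]")
        if self.kind in _SYMMETRIC_KINDS and V.size:
            if np.abs(V - V.T).max() > 1e-10:
                raise ValueError(f"{self.kind} similarity must be symmetric")

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass
class HeterogeneousNetwork:
    """Block adjacency ``N = [[S_r, A], [A^T, S_m]]`` over drug+microbe nodes."""

    N: np.ndarray
    n_r: int
    n_m: int

    def __post_init__(self) -> None:
        self.N = np.asarray(self.N, dtype=float)
        n = self.n_r + self.n_m
        if self.N.shape != (n, n):
            raise ValueError(f"N must be {n}x{n}, got {self.N.shape}")

    @property
    def n_nodes(self) -> int:
        return self.n_r + self.n_m

    @property
    def S_r(self) -> np.ndarray:
        return self.N[: self.n_r, : self.n_r]

    @property
    def S_m(self) -> np.ndarray:
        return self.N[self.n_r :, self.n_r :]

    @property
    def A(self) -> np.ndarray:
        return self.N[: self.n_r, self.n_r :]


@dataclass
class RWRParams:
    """Random-walk-with-restart parameters.

    ``restart_prob`` is the probability of continuing the walk (the
    iteration is ``q <- restart_prob * M q + (1 - restart_prob) * e_i``),
    default 0.1.
    """

    restart_prob: float = 0.1
    max_iter: int = 1000
    tol: float = 1e-6

    def __post_init__(self) -> None:
        if not 0.0 < self.restart_prob < 1.0:
            raise ValueError("restart_prob must lie in (0, 1)")
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")


def _profiles(A: np.ndarray, axis: str) -> np.ndarray:
    A = np.asarray(A, dtype=float)
    if axis == "drug":
        return A
    if axis == "microbe":
        return A.T
    raise ValueError(f"axis must be 'drug' or 'microbe', got {axis!r}")


def gip_similarity(A: np.ndarray, axis: str) -> SimilarityMatrix:
    """Gaussian interaction profile kernel over rows (drugs) or columns
    (microbes) of the association matrix.

    The bandwidth is ``gamma = 1 / mean_i ||p_i||^2``; an all-zero
    association matrix leaves ``gamma`` undefined and raises.
    """
    P = _profiles(A, axis)
    mean_sq = (P * P).sum(axis=1).mean()
    if mean_sq == 0:
        raise ValueError(
            "GIP bandwidth undefined: association matrix has no associations "
            "(at least one association is required)"
        )
    gamma = 1.0 / mean_sq
    sq = (P * P).sum(axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * P @ P.T
    np.maximum(d2, 0.0, out=d2)
    S = np.exp(-gamma * d2)
    S = (S + S.T) / 2.0
    np.fill_diagonal(S, 1.0)
    return SimilarityMatrix(S, kind="GIP", axis=axis)


def hip_similarity(A: np.ndarray, axis: str) -> SimilarityMatrix:
    """Hamming interaction profile similarity: one minus the fraction of
    positions at which two binary profiles differ."""
    P = _profiles(A, axis)
    if P.shape[1] < 1:
        raise ValueError("profiles must have length >= 1")
    # for binary profiles, # differing positions = squared distance
    diff = (P[:, None, :] != P[None, :, :]).sum(axis=2) if P.shape[0] <= 256 else None
    if diff is None:
        sq = (P * P).sum(axis=1)
        diff = np.rint(sq[:, None] + sq[None, :] - 2.0 * P @ P.T)
    S = 1.0 - diff / P.shape[1]
    S = (S + S.T) / 2.0
    np.fill_diagonal(S, 1.0)
    return SimilarityMatrix(S, kind="HIP", axis=axis)


def fuse_similarity(S_gip: SimilarityMatrix, S_hip: SimilarityMatrix) -> SimilarityMatrix:
    """Elementwise mean of the GIP and HIP similarity matrices."""
    if S_gip.values.shape != S_hip.values.shape:
        raise ValueError("similarity matrices to fuse must share shape")
    if S_gip.axis != S_hip.axis:
        raise ValueError("similarity matrices to fuse must share axis")
    return SimilarityMatrix(
        (S_gip.values + S_hip.values) / 2.0, kind="fused", axis=S_gip.axis
    )


def fused_profile_similarity(A: np.ndarray, axis: str) -> SimilarityMatrix:
    """Convenience: fused (GIP+HIP)/2 similarity straight from ``A``."""
    return fuse_similarity(gip_similarity(A, axis), hip_similarity(A, axis))


def build_heterogeneous_network(
    S_r: SimilarityMatrix | np.ndarray,
    S_m: SimilarityMatrix | np.ndarray,
    A: np.ndarray,
) -> HeterogeneousNetwork:
    """Assemble ``N = [[S_r, A], [A^T, S_m]]``."""
    Sr = S_r.values if isinstance(S_r, SimilarityMatrix) else np.asarray(S_r, float)
    Sm = S_m.values if isinstance(S_m, SimilarityMatrix) else np.asarray(S_m, float)
    A = np.asarray(A, dtype=float)
    n_r, n_m = A.shape
    if Sr.shape != (n_r, n_r) or Sm.shape != (n_m, n_m):
        raise ValueError(
            f"block shapes incompatible: S_r {Sr.shape}, S_m {Sm.shape}, A {A.shape}"
        )
    N = np.block([[Sr, A], [A.T, Sm]])
    return HeterogeneousNetwork(N=N, n_r=n_r, n_m=n_m)


def cosine_profile_similarity(D: np.ndarray, axis: str = "drug") -> SimilarityMatrix:
    """Cosine similarity between rows of a binary disease-profile matrix.

    All-zero rows would give 0/0; they are defined to have similarity 0 to
    every other node and 1 to themselves, so downstream attribute matrices
    stay finite.
    """
    D = np.asarray(D, dtype=float)
    if D.ndim != 2:
        raise ValueError("profile matrix must be 2-dimensional")
    norms = np.linalg.norm(D, axis=1)
    safe = np.where(norms > 0, norms, 1.0)
    S = (D @ D.T) / np.outer(safe, safe)
    zero = norms == 0
    S[zero, :] = 0.0
    S[:, zero] = 0.0
    np.clip(S, 0.0, 1.0, out=S)
    np.fill_diagonal(S, 1.0)
    return SimilarityMatrix(S, kind="cosine", axis=axis)


def _transition_matrix(S: np.ndarray) -> np.ndarray:
    """Column-normalize ``S`` into a column-stochastic transition matrix;
    all-zero columns become uniform teleports."""
    S = np.asarray(S, dtype=float)
    colsum = S.sum(axis=0)
    M = np.empty_like(S)
    nz = colsum > 0
    M[:, nz] = S[:, nz] / colsum[nz]
    if (~nz).any():
        M[:, ~nz] = 1.0 / S.shape[0]
    return M


def rwr_smooth(S: SimilarityMatrix | np.ndarray, params: RWRParams | None = None) -> SimilarityMatrix:
    """Random walk with restart on a similarity matrix.

    Returns the matrix whose i-th row is the converged visiting-probability
    vector ``q_i`` for the walker restarting at node i: iterate
    ``q <- phi * M q + (1 - phi) * e_i`` with ``M`` the column-stochastic
    transition matrix of ``S``, until the L1 change drops below ``tol``.
    Every output row sums to 1.
    """
    if params is None:
        params = RWRParams()
    V = S.values if isinstance(S, SimilarityMatrix) else np.asarray(S, float)
    if V.size and V.min() < 0:
        raise ValueError("RWR requires a nonnegative similarity matrix")
    axis = S.axis if isinstance(S, SimilarityMatrix) else "drug"
    M = _transition_matrix(V)
    phi = params.restart_prob
    n = V.shape[0]
    # all restart vectors at once: columns of Q are the q_i
    Q = np.eye(n)
    E = (1.0 - phi) * np.eye(n)
    for _ in range(params.max_iter):
        Q_next = phi * (M @ Q) + E
        if np.abs(Q_next - Q).sum(axis=0).max() < params.tol:
            Q = Q_next
            break
        Q = Q_next
    else:
        warnings.warn(
            f"RWR did not converge within {params.max_iter} iterations",
            RuntimeWarning,
            stacklevel=2,
        )
    return SimilarityMatrix(Q.T, kind="rwr", axis=axis)
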