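"""KL-divergence non-negative matrix factorization with Brunet-style
multiplicative updates, multi-restart consensus clustering, and cophenetic
model-order selection.

The factorization minimises the generalized Kullback-Leibler divergence

    D(X || WH) = sum_ij [ X_ij log(X_ij / (WH)_ij) - X_ij + (WH)_ij ]

(with the convention 0 log 0 = 0) via the multiplicative updates

    H_aj <- H_aj * sum_i W_ia X_ij/(WH)_ij / sum_i W_ia
    W_ia <- W_ia * sum_j H_aj X_ij/(WH)_ij / sum_j H_aj

which are non-increasing in D at every step. The number of clusters k is
chosen by running many randomly restarted factorizations, averaging the
binary sample-connectivity matrices into a consensus matrix, and scoring
each k by the cophenetic correlation of the consensus: stable clusterings
give near-binary consensus matrices and a cophenetic coefficient near 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import cophenet, linkage
from scipy.spatial.distance import squareform
from scipy.special import xlogy

from .errors import DimeError, UsageError

EPS = 1e-12

__all__ = [
    "Factorization",
    "ConsensusResult",
    "kl_divergence",
    "nmf_kl",
    "connectivity_matrix",
    "consensus_cophenetic",
    "cophenetic_profile",
    "select_k",
]


@dataclass
class Factorization:
    """Result of one KL-NMF run: X (m x n) ~= W (m x k) @ H (k x n)."""

    W: np.ndarray
    H: np.ndarray
    k: int
    seed: int
    divergence_trace: list[float]
    n_iter: int
    converged: bool

    @property
    def divergence(self) -> float:
        return self.divergence_trace[-1]


@dataclass
class ConsensusResult:
    k: int
    consensus: np.ndarray
    cophenetic: float
    n_runs: int
    seeds: list[int] = field(default_factory=list)


def kl_divergence(X: np.ndarray, WH: np.ndarray) -> float:
    """Generalized KL divergence D(X || WH) >= 0, zero iff X == WH."""
    X = np.asarray(X, dtype=float)
    WH = np.asarray(WH, dtype=float)
    if X.shape != WH.shape:
        raise DimeError(f"shape mismatch {X.shape} vs {WH.shape}")
    WH = np.maximum(WH, EPS)
    # xlogy implements the 0 * log 0 = 0 convention
    return float(np.sum(xlogy(X, X) - xlogy(X, WH) - X + WH))


def _check_input(X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise DimeError("X must be a 2-D matrix")
    if (X < 0).any():
        raise DimeError("X must be non-negative")
    zero_rows = np.flatnonzero(X.sum(axis=1) == 0)
    if zero_rows.size:
        raise DimeError(f"all-zero row(s) at index {zero_rows.tolist()}")
    zero_cols = np.flatnonzero(X.sum(axis=0) == 0)
    if zero_cols.size:
        raise DimeError(f"all-zero column(s) at index {zero_cols.tolist()}")
    return X


def nmf_kl(
    X: np.ndarray,
    k: int,
    seed: int = 0,
    max_iter: int = 2000,
    tol: float = 1e-6,
) -> Factorization:
    """Factor X into non-negative W, H by multiplicative KL updates.

    Initialisation is uniform random scaled by mean(X). Iteration stops when
    the relative divergence change over a 10-iteration window falls below
    ``tol``, or at ``max_iter``.
    """
    X = _check_input(X)
    m, n = X.shape
    if not (1 <= k <= min(m, n)):
        raise UsageError(f"k={k} out of range for a {m}x{n} matrix")
    rng = np.random.default_rng(seed)
    scale = float(X.mean())
    W = np.maximum(scale * rng.random((m, k)), EPS)
    H = np.maximum(scale * rng.random((k, n)), EPS)

    trace = [kl_divergence(X, W @ H)]
    converged = False
    window = 10
    for it in range(1, max_iter + 1):
        WH = np.maximum(W @ H, EPS)
        H *= (W.T @ (X / WH)) / np.maximum(W.sum(axis=0)[:, None], EPS)
        H = np.maximum(H, EPS)
        WH = np.maximum(W @ H, EPS)
        W *= ((X / WH) @ H.T) / np.maximum(H.sum(axis=1)[None, :], EPS)
        W = np.maximum(W, EPS)
        trace.append(kl_divergence(X, W @ H))
        if it >= window:
            prev = trace[-1 - window]
            if abs(prev - trace[-1]) < tol * max(abs(prev), EPS):
                converged = True
                break
    return Factorization(
        W=W, H=H, k=k, seed=seed, divergence_trace=trace,
        n_iter=len(trace) - 1, converged=converged,
    )


def cluster_assignments(f: Factorization) -> np.ndarray:
    """Column (sample) assignments: argmax over H rows; ties take the lowest
    cluster index."""
    return np.argmax(f.H, axis=0)


def connectivity_matrix(f: Factorization) -> np.ndarray:
    """Binary n x n matrix: 1 iff two columns share an argmax-H cluster."""
    a = cluster_assignments(f)
    return (a[:, None] == a[None, :]).astype(float)


def _cophenetic_coefficient(consensus: np.ndarray) -> float:
    """Pearson correlation between consensus distances (1 - consensus) and the
    cophenetic distances of their average-linkage dendrogram. A constant
    distance vector (perfect consensus) is defined as 1."""
    d = 1.0 - consensus
    np.fill_diagonal(d, 0.0)
    condensed = squareform(d, checks=False)
    if condensed.size == 0 or np.ptp(condensed) == 0:
        return 1.0
    Z = linkage(condensed, method="average")
    coph = cophenet(Z)
    if np.ptp(coph) == 0:
        return 1.0
    return float(np.corrcoef(condensed, coph)[0, 1])


def consensus_cophenetic(
    X: np.ndarray,
    k: int,
    n_runs: int = 30,
    base_seed: int = 0,
    max_iter: int = 2000,
    tol: float = 1e-6,
) -> ConsensusResult:
    """Average the connectivity matrices of ``n_runs`` seeded restarts and
    score the stability of the consensus by its cophenetic correlation."""
    if k < 2:
        raise UsageError("consensus clustering needs k >= 2")
    if n_runs < 2:
        raise UsageError("n_runs must be >= 2")
    seeds = [int(base_seed) + i for i in range(n_runs)]
    n = np.asarray(X).shape[1]
    consensus = np.zeros((n, n))
    for s in seeds:
        f = nmf_kl(X, k, seed=s, max_iter=max_iter, tol=tol)
        consensus += connectivity_matrix(f)
    consensus /= n_runs
    np.fill_diagonal(consensus, 1.0)
    return ConsensusResult(
        k=k, consensus=consensus, cophenetic=_cophenetic_coefficient(consensus),
        n_runs=n_runs, seeds=seeds,
    )


def _default_k_range(X: np.ndarray, k_max: int = 7) -> list[int]:
    hi = min(k_max, min(np.asarray(X).shape) - 1)
    return list(range(2, hi + 1))


def cophenetic_profile(
    X: np.ndarray,
    k_range: list[int] | None = None,
    n_runs: int = 30,
    base_seed: int = 0,
    max_iter: int = 2000,
    tol: float = 1e-6,
) -> dict[int, float]:
    """Cophenetic coefficient for every candidate k (the k-selection table)."""
    if k_range is None:
        k_range = _default_k_range(X)
    if not k_range:
        raise UsageError("empty k_range")
    profile: dict[int, float] = {}
    for k in k_range:
        if k >= min(np.asarray(X).shape):
            raise UsageError(f"k={k} infeasible for shape {np.asarray(X).shape}")
        # decorrelate restart seeds across k values
        res = consensus_cophenetic(
            X, k, n_runs=n_runs, base_seed=base_seed + 7919 * k,
            max_iter=max_iter, tol=tol,
        )
        profile[k] = res.cophenetic
    return profile


def select_k(
    X: np.ndarray,
    k_range: list[int] | None = None,
    n_runs: int = 30,
    base_seed: int = 0,
    max_iter: int = 2000,
    tol: float = 1e-6,
) -> int:
    """Smallest k attaining the maximum cophenetic coefficient over
    ``k_range`` (default 2..min(7, min(dims)-1)).

    Coefficients within ``COPHENETIC_TIE_TOL`` of the maximum are treated as
    tied (correlations that close are numerically indistinguishable) and the
    tie breaks to the smallest k.
    """
    profile = cophenetic_profile(
        X, k_range=k_range, n_runs=n_runs, base_seed=base_seed,
        max_iter=max_iter, tol=tol,
    )
    return _smallest_k_at_max(profile)


COPHENETIC_TIE_TOL = 1e-7


def _smallest_k_at_max(profile: dict[int, float]) -> int:
    best = max(profile.values())
    return min(k for k, c in profile.items() if c >= best - COPHENETIC_TIE_TOL)
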