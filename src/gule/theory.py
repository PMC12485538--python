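"""Numeric diagnostics for the perturbation analysis of the rescaled graph.

The rescaled credibility matrix G = D^{-b/2} A D^{-b/2} is treated as a
perturbation of an ideal block-diagonal matrix G0 whose diagonal blocks
are each class's adjacency rescaled by its OWN row sums.  The diagnostics
compute, for a graph and a ground-truth labeling:

* the perturbation E = G - G0 and the spectral-norm bound
  ||E||_2 <= (1 + b) * ||rho(b)||_inf, where rho(b) stacks each point's
  off-block row sum divided by its within-block row sum to the power b;
* the ideal basis U0 (one per-block Perron vector per class) and the
  eigen-gap delta_K = lambda_K(G0) - lambda_{K+1}(G0);
* the subspace bound min_Q ||U0 - U Q||_F <= 2 sqrt(2K) ||E||_2 / delta_K
  (the minimizing orthogonal Q found by Procrustes alignment);
* the mislabel bound p: with eps = b ||rho||_F + tau^{b/2} ||rho(b)||_F
  and tau the ratio of extreme degrees, at most p points can be
  mislabeled, where p is the largest count of ascending-sorted rotated
  entries u~_ik^2 (k the true class of i) summing to <= 8 eps^2/delta_K^2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse.csgraph import connected_components

from .acut import rescale_graph
from .exceptions import DataError
from .graph import CredibilityGraph


@dataclass
class IdealGraphDecomposition:
    G0: np.ndarray
    E: np.ndarray
    beta: float
    truth: np.ndarray  # 1..K
    rho: np.ndarray  # per-point off-block/within-block row-sum ratios
    rho_beta: np.ndarray  # with the within sum raised to beta
    bound: float  # (1 + beta) * max |rho_beta|
    tau: float  # max_i r_i(A) / min_j r_j(A)
    eps: float  # beta ||rho||_F + tau^{beta/2} ||rho_beta||_F
    U0: np.ndarray  # ideal basis: per-class Perron vectors
    eigvals_G0: np.ndarray  # descending
    delta_K: float  # lambda_K(G0) - lambda_{K+1}(G0)
    disconnected_classes: list = field(default_factory=list)

    @property
    def E_norm(self) -> float:
        return float(np.linalg.norm(self.E, 2))

    @property
    def K(self) -> int:
        return self.U0.shape[1]


def _perron(block: np.ndarray) -> np.ndarray:
    """Nonnegative dominant eigenvector of a symmetric nonnegative block."""
    w, V = np.linalg.eigh(block)
    v = V[:, -1]
    return np.abs(v)


def ideal_decomposition(G: CredibilityGraph, truth) -> IdealGraphDecomposition:
    """Split the rescaled graph into its ideal block part and the error."""
    truth = np.asarray(truth).ravel()
    n = G.n
    if truth.shape[0] != n:
        raise DataError("truth labeling must cover all points")
    beta = G.beta
    A = np.asarray(G.A.todense())
    Gfull = np.asarray(rescale_graph(G, beta).todense())
    classes = np.unique(truth)
    K = classes.size

    G0 = np.zeros_like(Gfull)
    rho = np.zeros(n)
    rho_beta = np.zeros(n)
    U0 = np.zeros((n, K))
    disconnected = []
    for k, cls in enumerate(classes):
        idx = np.where(truth == cls)[0]
        Akk = A[np.ix_(idx, idx)]
        r_within = Akk.sum(axis=1)
        # mathematically >= 0; clamp away subtraction rounding
        r_off = np.maximum(A[idx].sum(axis=1) - r_within, 0.0)
        if np.any(r_within <= 0):
            raise DataError(f"class {cls} has a point with zero within-class "
                            "weight; the ideal block is undefined for it")
        scale = r_within ** (-beta / 2.0)
        Gbar = scale[:, None] * Akk * scale[None, :]
        G0[np.ix_(idx, idx)] = Gbar
        rho[idx] = r_off / r_within
        rho_beta[idx] = r_off / r_within ** beta
        # Perron vector per connected sub-block of the class
        from scipy.sparse import csr_matrix

        ncomp, comp = connected_components(csr_matrix(Akk != 0), directed=False)
        if ncomp == 1:
            U0[idx, k] = _perron(Gbar)
        else:
            disconnected.append(int(cls))
            warnings.warn(f"class {cls} splits into {ncomp} connected "
                          "sub-blocks; using the dominant sub-block's "
                          "Perron vector", stacklevel=2)
            best = None
            for c in range(ncomp):
                sub = np.where(comp == c)[0]
                blk = Gbar[np.ix_(sub, sub)]
                lam = np.linalg.eigvalsh(blk)[-1]
                if best is None or lam > best[0]:
                    best = (lam, sub, blk)
            _, sub, blk = best
            U0[idx[sub], k] = _perron(blk)

    E = Gfull - G0
    bound = (1.0 + beta) * float(np.max(np.abs(rho_beta))) if n else 0.0
    r_all = A.sum(axis=1)
    tau = float(r_all.max() / r_all.min())
    eps = beta * float(np.linalg.norm(rho)) + tau ** (beta / 2.0) * float(
        np.linalg.norm(rho_beta))
    w0 = np.sort(np.linalg.eigvalsh(G0))[::-1]
    delta_K = float(w0[K - 1] - w0[K]) if K < n else np.nan
    return IdealGraphDecomposition(
        G0=G0, E=E, beta=beta, truth=truth, rho=rho, rho_beta=rho_beta,
        bound=bound, tau=tau, eps=eps, U0=U0, eigvals_G0=w0,
        delta_K=delta_K, disconnected_classes=disconnected,
    )


def procrustes_align(U: np.ndarray, U0: np.ndarray) -> np.ndarray:
    """Orthogonal Q minimizing ||U0 - U Q||_F (SVD of U^T U0)."""
    P, _, Rt = np.linalg.svd(U.T @ U0)
    return P @ Rt


def subspace_bound(dec: IdealGraphDecomposition) -> float:
    """2 sqrt(2K) ||E||_2 / delta_K — the subspace perturbation bound."""
    if dec.delta_K <= 0:
        return np.inf
    return 2.0 * np.sqrt(2.0 * dec.K) * dec.E_norm / dec.delta_K


def mislabel_bound(dec: IdealGraphDecomposition, Utilde: np.ndarray) -> float:
    """Largest p such that the p smallest true-class entries u~_ik^2 sum to
    at most 8 eps^2 / delta_K^2; at most p points can be mislabeled.

    ``Utilde`` must be column-aligned with the ideal basis (class k in
    column k), e.g. U rotated by the Procrustes Q against ``dec.U0``.
    Returns ``inf`` with a warning when the eigen-gap vanishes.
    """
    if not (dec.delta_K > 0):
        warnings.warn("delta_K <= 0: the mislabel bound is undefined",
                      stacklevel=2)
        return np.inf
    classes = np.unique(dec.truth)
    col = np.searchsorted(classes, dec.truth)
    eta2 = np.sort(Utilde[np.arange(dec.truth.size), col] ** 2)
    budget = 8.0 * dec.eps ** 2 / dec.delta_K ** 2
    return int(np.searchsorted(np.cumsum(eta2), budget, side="right"))
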