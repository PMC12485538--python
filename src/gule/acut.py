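"""Adaptive graph cutting (Acut) via degree-rescaled spectral projection.

The discrete objective

    Acut(C; beta) = sum_k ( sum_{i,j in C_k} a_ij ) / ( sum_{t in C_k} d_t^beta )

interpolates between ratio association (beta = 0) and normalized cut
(beta = 1).  Its continuous relaxation maximizes trace(U^T G U) over
orthonormal U with G = D^{-beta/2} A D^{-beta/2}, solved by the K
dominant eigenvectors of G.  Rows of U are the projected points fed to
the next layer or to the CPF labeling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import ArpackNoConvergence, eigsh

from .exceptions import DataError
from .graph import CredibilityGraph

#: above this size the iterative sparse solver is used instead of dense eigh
DENSE_LIMIT = 2000


@dataclass
class SpectralProjection:
    """Dominant eigenbasis of the rescaled credibility graph."""

    U: np.ndarray  # n x K, orthonormal columns; rows are the projected points
    eigvals: np.ndarray  # K+1 leading eigenvalues, descending
    beta: float

    @property
    def K(self) -> int:
        return self.U.shape[1]

    @property
    def gap(self) -> float:
        """Eigen-gap delta_K = lambda_K - lambda_{K+1}."""
        return float(self.eigvals[self.K - 1] - self.eigvals[self.K])


def rescale_graph(G: CredibilityGraph, beta: float | None = None):
    """Return ``D^{-beta/2} A D^{-beta/2}`` as a sparse matrix."""
    if beta is None:
        beta = G.beta
    d = G.degrees
    if np.any(d <= 0):
        raise DataError("zero degree encountered; graph must keep self-loops")
    if beta == 0.0:
        return G.A.copy()
    scale = d ** (-beta / 2.0)
    Dh = sp.diags(scale)
    return (Dh @ G.A @ Dh).tocsr()


def _fix_signs(U: np.ndarray) -> np.ndarray:
    """Orient each column so its largest-magnitude entry (lowest index on
    ties) is positive — a deterministic sign convention."""
    U = U.copy()
    for k in range(U.shape[1]):
        m = int(np.argmax(np.abs(U[:, k])))
        if U[m, k] < 0:
            U[:, k] = -U[:, k]
    return U


def _top_eigs(M, m: int) -> tuple[np.ndarray, np.ndarray]:
    """The m algebraically largest eigenpairs, eigenvalues descending."""
    n = M.shape[0]
    m = min(m, n)
    if n <= DENSE_LIMIT or m >= n - 1:
        w, V = np.linalg.eigh(np.asarray(M.todense()) if sp.issparse(M) else M)
        idx = np.argsort(w)[::-1][:m]
        # stable ordering on exact ties: keep ascending original index
        return w[idx], V[:, idx]
    v0 = np.full(n, 1.0 / np.sqrt(n))
    try:
        w, V = eigsh(M, k=m, which="LA", v0=v0, tol=1e-10)
    except ArpackNoConvergence:
        warnings.warn("sparse eigensolver did not converge; dense fallback",
                      stacklevel=2)
        w, V = np.linalg.eigh(np.asarray(M.todense()))
    idx = np.argsort(w)[::-1][:m]
    return w[idx], V[:, idx]


def spectral_project(G: CredibilityGraph, K: int, beta: float | None = None) -> SpectralProjection:
    """Project onto the K dominant eigenvectors of the rescaled graph.

    The rescaled matrix is block-diagonal across connected components, so
    the eigenproblem is solved exactly per component and the eigenpairs
    are pooled; this keeps every eigenvector supported on a single
    component instead of letting near-degenerate eigenvalues mix basis
    vectors across components numerically.  When the graph decomposes
    into exactly K components the component structure already resolves
    the cut, and the projection is the ideal basis: one Perron vector
    per component.
    """
    from scipy.sparse.csgraph import connected_components

    n = G.n
    if not (1 <= K < n):
        raise DataError(f"need 1 <= K < n, got K={K}, n={n}")
    if beta is None:
        beta = G.beta
    M = rescale_graph(G, beta).tocsr()
    ncomp, comp = connected_components(G.A, directed=False)
    if ncomp == 1:
        w, V = _top_eigs(M, K + 1)
        U = _fix_signs(V[:, :K])
        return SpectralProjection(U=U, eigvals=w, beta=beta)

    # pooled exact eigendecomposition: top min(m, K+1) pairs per component
    pool = []  # (eigval, comp id, rank within comp, index set, vector)
    for c in range(ncomp):
        idx = np.where(comp == c)[0]
        sub = M[np.ix_(idx, idx)]
        wc, Vc = _top_eigs(sub, min(idx.size, K + 1))
        for r in range(wc.size):
            pool.append((wc[r], c, r, idx, Vc[:, r]))
    pool.sort(key=lambda t: (-t[0], t[1], t[2]))
    eigvals = np.array([t[0] for t in pool[: K + 1]])

    U = np.zeros((n, K))
    if ncomp == K:
        # ideal case: one Perron vector per component, ordered by eigenvalue.
        # A connected component's Perron vector is strictly positive, so |.|
        # only strips sub-epsilon sign noise, and entries that underflowed to
        # exact zero are floored to keep the support structurally correct.
        perron = sorted((t for t in pool if t[2] == 0), key=lambda t: -t[0])
        for k, (_, _, _, idx, v) in enumerate(perron):
            v = np.abs(v)
            vmax = v.max()
            if vmax > 0:
                v = np.maximum(v, vmax * 1e-300)
            U[idx, k] = v
    else:
        for k, (_, _, _, idx, v) in enumerate(pool[:K]):
            U[idx, k] = v
    return SpectralProjection(U=_fix_signs(U), eigvals=eigvals, beta=beta)


def acut_objective(G: CredibilityGraph, labels: np.ndarray, beta: float) -> float:
    """Discrete Acut score of a labeling (brute-force verification aid).

    Within-class weight sums include the self-loops; degrees are raised to
    ``beta`` in the denominators.
    """
    labels = np.asarray(labels)
    if labels.shape[0] != G.n:
        raise DataError("labels length disagrees with graph size")
    d = G.degrees
    A = G.A
    score = 0.0
    for k in np.unique(labels):
        idx = np.where(labels == k)[0]
        if idx.size == 0:
            raise DataError(f"empty class {k}")
        within = A[np.ix_(idx, idx)].sum()
        score += float(within) / float(np.sum(d[idx] ** beta))
    return score
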