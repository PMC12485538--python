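"""Credibility graph construction, connection strength, and the adaptive exponent.

An undirected edge is placed between i and j whenever j is in i's
estimated neighborhood or vice versa, weighted by the enhanced
credibility of the normalized distance gamma_ij = d(i,j) / max(omega_i,
omega_j) (weight zero beyond gamma > 1).  Self-loops carry weight 1
(gamma_ii = 0), which keeps every degree strictly positive so the
degree rescaling of the adaptive cut is always defined.

The average connection strength

    s = mean_i  (sum_{j != i} a_ij) / (|N(i)| - 1)

estimates how strongly each point is tied to its class members and sets
the adaptive cut exponent beta = 1 - s: sparse weakly-connected graphs
(s small) are cut like a normalized cut, dense strongly-connected graphs
(s near 1) like a ratio association.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .distances import DistanceMatrix
from .exceptions import ConfigError, DataError
from .local_extraction import NeighborhoodSet, enhanced_credibility

_S_FLOOR = 1e-12


@dataclass
class CredibilityGraph:
    """Sparse symmetric weighted adjacency with strength/exponent metadata."""

    A: sp.csr_matrix  # entries in [0, 1], unit diagonal
    alpha: float
    layer: int
    s: float = np.nan  # average connection strength in (0, 1]
    beta: float = np.nan  # adaptive exponent 1 - s

    @property
    def n(self) -> int:
        return self.A.shape[0]

    @property
    def degrees(self) -> np.ndarray:
        return np.asarray(self.A.sum(axis=1)).ravel()

    def to_mtx(self, path) -> None:
        """Export the adjacency as a Matrix-Market sparse file."""
        from scipy.io import mmwrite

        mmwrite(str(path), sp.coo_matrix(self.A))


def build_graph(D: DistanceMatrix, N: NeighborhoodSet, alpha: float) -> CredibilityGraph:
    """Assemble the symmetric enhanced-credibility adjacency.

    For every unordered neighbor pair, gamma = d / max(omega_i, omega_j)
    (defined as 0 for coincident pairs where both are 0); the weight is
    the enhanced credibility when gamma <= 1, else 0.
    """
    n = D.n
    if N.n != n:
        raise DataError("neighborhood set size disagrees with distance matrix")
    if n == 0 or all(len(nb) == 0 for nb in N.neighbors):
        raise DataError("empty neighborhood set")
    pairs = set()
    for i in range(n):
        for j in N.neighbors[i][1:]:
            pairs.add((min(i, int(j)), max(i, int(j))))
    rows, cols, vals = [], [], []
    for i, j in pairs:
        om = max(N.omega[i], N.omega[j])
        d = D.D[i, j]
        if om == 0.0:
            gamma = 0.0 if d == 0.0 else np.inf
        else:
            gamma = d / om
        if gamma <= 1.0:
            a = enhanced_credibility(gamma, alpha)
            rows += [i, j]
            cols += [j, i]
            vals += [a, a]
    rows += list(range(n))
    cols += list(range(n))
    vals += [1.0] * n
    A = sp.csr_matrix((vals, (rows, cols)), shape=(n, n))
    G = CredibilityGraph(A=A, alpha=alpha, layer=N.layer)
    G.s = estimate_strength(G, N)
    G.beta = beta_from_strength(G.s)
    return G


def estimate_strength(G: CredibilityGraph, N: NeighborhoodSet) -> float:
    """Average per-point connection strength s in (0, 1].

    s_i sums all off-diagonal edge weights of i (symmetrization included)
    divided by |N(i)| - 1; points with a singleton neighborhood contribute
    s_i = 0 with a warning.  The mean is clipped into (0, 1].
    """
    offdiag = G.degrees - G.A.diagonal()
    sizes = N.sizes
    si = np.zeros(G.n)
    ok = sizes >= 2
    if not ok.all():
        warnings.warn(f"{int((~ok).sum())} isolated point(s) with a singleton "
                      "neighborhood contribute zero strength", stacklevel=2)
    si[ok] = offdiag[ok] / (sizes[ok] - 1)
    s = float(np.mean(si))
    if s <= 0.0:
        warnings.warn("graph has no off-diagonal edge weight; strength floored",
                      stacklevel=2)
        return _S_FLOOR
    return min(s, 1.0)


def beta_from_strength(s: float) -> float:
    """Adaptive cut exponent beta = 1 - s."""
    if not (0.0 < s <= 1.0):
        raise ConfigError(f"strength must lie in (0, 1], got {s}")
    return 1.0 - s


def self_tuning_graph(D: DistanceMatrix, kprime: int = 7, layer: int = 1) -> CredibilityGraph:
    """Locally scaled Gaussian affinity (Zelnik-Manor & Perona style), for ablation.

    s_ij = exp(-d^2 / (sigma_i sigma_j)) for i != j when d < max(sigma_i,
    sigma_j), where sigma_i is the distance of i to its kprime-th nearest
    other point.  A unit diagonal is added so every degree is positive.
    """
    n = D.n
    kprime = min(kprime, n - 1)
    Dsort = np.sort(D.D, axis=1)
    sigma = Dsort[:, kprime]  # column 0 is the self distance 0
    if np.any(sigma == 0):
        warnings.warn("zero local scale at some points; affinities there are "
                      "limited to exact duplicates", stacklevel=2)
    smax = np.maximum.outer(sigma, sigma)
    prod = np.outer(sigma, sigma)
    with np.errstate(divide="ignore", invalid="ignore"):
        S = np.exp(-np.square(D.D) / prod)
    S[~(D.D < smax)] = 0.0
    S[~np.isfinite(S)] = 0.0
    np.fill_diagonal(S, 1.0)
    A = sp.csr_matrix(S)
    s = np.nan
    G = CredibilityGraph(A=A, alpha=np.nan, layer=layer)
    # strength computed over the kprime-sized geometric neighborhoods
    offdiag = G.degrees - A.diagonal()
    s = float(np.clip(np.mean(offdiag / max(kprime, 1)), _S_FLOOR, 1.0))
    G.s = s
    G.beta = 1.0 - s
    return G
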