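import warnings

import numpy as np
import pytest
import scipy.sparse as sp

from gule.distances import compute_distance_matrix
from gule.graph import CredibilityGraph, build_graph
from gule.local_extraction import (
    alpha_for_layer,
    estimate_neighborhoods_layer1,
    neighborhood_size,
)


@pytest.fixture(autouse=True)
def _quiet_warnings():
    """Degenerate-input warnings are exercised deliberately in the suite."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        yield


@pytest.fixture
def collinear_graph():
    """Three collinear points at 0, 1, 2 with kc=2 and alpha=2 (hand case)."""
    X = np.array([[0.0], [1.0], [2.0]])
    D = compute_distance_matrix(X, "euclidean")
    N = estimate_neighborhoods_layer1(D, 2)
    G = build_graph(D, N, 2.0)
    return D, N, G


def layer1_graph(X, K, metric="euclidean", alpha=None):
    """Helper: full layer-1 graph construction at paper defaults."""
    D = compute_distance_matrix(X, metric)
    n = X.shape[0]
    N = estimate_neighborhoods_layer1(D, neighborhood_size(n, K))
    if alpha is None:
        alpha = alpha_for_layer(n, K, 1)
    return D, N, build_graph(D, N, alpha)


def block_graph(sizes, rng, in_lo=0.5, in_hi=1.0, off_scale=0.0):
    """Random symmetric block graph with unit diagonal; off-block mass is
    scaled to ``off_scale`` times the in-block mass (0 = ideal)."""
    n = int(np.sum(sizes))
    labels = np.repeat(np.arange(1, len(sizes) + 1), sizes)
    A = np.zeros((n, n))
    for k in range(1, len(sizes) + 1):
        idx = np.where(labels == k)[0]
        B = rng.uniform(in_lo, in_hi, (idx.size, idx.size))
        A[np.ix_(idx, idx)] = (B + B.T) / 2
    np.fill_diagonal(A, 1.0)
    if off_scale > 0:
        off = rng.uniform(0, 1, (n, n))
        off = (off + off.T) / 2
        off[labels[:, None] == labels[None, :]] = 0.0
        off *= off_scale * A.sum() / max(off.sum(), 1e-12)
        A = A + off
    G = CredibilityGraph(A=sp.csr_matrix(A), alpha=np.nan, layer=1)
    offd = G.degrees - A.diagonal()
    s = float(np.clip(np.mean(offd / max(n - 1, 1)), 1e-12, 1.0))
    G.s, G.beta = s, 1.0 - s
    return G, labels
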