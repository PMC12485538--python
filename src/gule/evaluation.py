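"""External and internal clustering indices.

External: clustering accuracy (ACC, optimal one-to-one class matching by
the Hungarian algorithm on the confusion matrix), NMI (arithmetic-mean
normalization) and the adjusted Rand index.  Internal: silhouette
coefficient, neighborhood purity (fraction of estimated neighbors sharing
the point's label) and graph score (within-class share of the
off-diagonal edge mass).
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import linear_sum_assignment
from sklearn import metrics as _skm

from .exceptions import DataError
from .graph import CredibilityGraph
from .local_extraction import NeighborhoodSet


def _check_pair(pred, truth):
    pred = np.asarray(pred).ravel()
    truth = np.asarray(truth).ravel()
    if pred.size == 0 or truth.size == 0:
        raise DataError("labelings must be non-empty")
    if pred.shape != truth.shape:
        raise DataError(f"length mismatch: {pred.size} vs {truth.size}")
    return pred, truth


def confusion_matrix(truth, pred):
    """Count matrix, rows = true classes, columns = predicted classes.

    Returns ``(C, true_ids, pred_ids)``.
    """
    pred, truth = _check_pair(pred, truth)
    tids, ti = np.unique(truth, return_inverse=True)
    pids, pi = np.unique(pred, return_inverse=True)
    C = np.zeros((tids.size, pids.size), dtype=int)
    np.add.at(C, (ti, pi), 1)
    return C, tids, pids


def clustering_accuracy(pred, truth) -> float:
    """ACC: best fraction of agreements over one-to-one class matchings."""
    pred, truth = _check_pair(pred, truth)
    C, _, _ = confusion_matrix(truth, pred)
    m = max(C.shape)
    Cs = np.zeros((m, m), dtype=int)
    Cs[: C.shape[0], : C.shape[1]] = C
    r, c = linear_sum_assignment(-Cs)
    return float(Cs[r, c].sum() / pred.size)


def nmi(pred, truth) -> float:
    """Normalized mutual information (arithmetic-mean normalization)."""
    pred, truth = _check_pair(pred, truth)
    return float(_skm.normalized_mutual_info_score(
        truth, pred, average_method="arithmetic"))


def ari(pred, truth) -> float:
    """Adjusted Rand index."""
    pred, truth = _check_pair(pred, truth)
    return float(_skm.adjusted_rand_score(truth, pred))


def neighborhood_purity(N: NeighborhoodSet, labels) -> float:
    """Mean fraction of each point's estimated neighbors (self excluded)
    sharing its label."""
    labels = np.asarray(labels).ravel()
    fracs = []
    for i, nb in enumerate(N.neighbors):
        others = nb[1:]
        if len(others) == 0:
            continue
        fracs.append(np.mean(labels[others] == labels[i]))
    if not fracs:
        raise DataError("no point has a non-trivial neighborhood")
    return float(np.mean(fracs))


def graph_score(G: CredibilityGraph, labels) -> float:
    """Within-class fraction of the off-diagonal edge mass, in [0, 1]."""
    labels = np.asarray(labels).ravel()
    A = G.A.tocoo()
    off = A.row != A.col
    total = A.data[off].sum()
    if total == 0:
        raise DataError("graph has no off-diagonal edges")
    within = A.data[off & (labels[A.row] == labels[A.col])].sum()
    return float(within / total)


def _silhouette(X, D, labels) -> float | None:
    labels = np.asarray(labels).ravel()
    uniq = np.unique(labels)
    if uniq.size < 2:
        return None  # undefined for a single class
    n = labels.size
    if uniq.size >= n:  # all-singleton clusters: silhouette of a singleton is 0
        return 0.0
    if D is not None:
        return float(_skm.silhouette_score(D, labels, metric="precomputed"))
    return float(_skm.silhouette_score(X, labels))


def internal_indices(
    X=None,
    labels=None,
    D=None,
    graph: CredibilityGraph | None = None,
    neighborhoods: NeighborhoodSet | None = None,
) -> dict:
    """Silhouette, neighborhood purity and graph score for one labeling.

    ``X`` or a precomputed distance matrix ``D`` drives the silhouette;
    purity needs ``neighborhoods`` and the graph score needs ``graph``
    (indices whose inputs are missing are reported as ``None``).
    """
    if labels is None:
        raise DataError("labels are required")
    out = {
        "silhouette": _silhouette(X, D, labels) if (X is not None or D is not None) else None,
        "neighborhood_purity": (
            neighborhood_purity(neighborhoods, labels) if neighborhoods else None
        ),
        "graph_score": graph_score(graph, labels) if graph is not None else None,
    }
    return out
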