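"""Pairwise distance computation and consensus-based metric selection.

Supported metrics: ``euclidean``, ``cosine``, ``correlation`` and
``spearman``.  The cosine distance is ``1 - <u,v>/(||u|| ||v||)``, the
correlation distance ``1 - Pearson r``, and the Spearman distance
``1 - Spearman rank correlation`` (midrank ties), so the latter three are
bounded by 2.

When no ground truth is available the metric can be chosen by consensus:
the full clustering pipeline is run once per candidate metric and each
metric is scored by the mean NMI of its labeling against every other
candidate's labeling; the highest-scoring metric wins.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata
from sklearn.metrics import normalized_mutual_info_score

from .exceptions import ConfigError, DataError

logger = logging.getLogger(__name__)

METRICS = ("euclidean", "cosine", "correlation", "spearman")

#: metrics whose distances are bounded above by 2
_BOUNDED = frozenset({"cosine", "correlation", "spearman"})


@dataclass
class DistanceMatrix:
    """Symmetric pairwise dissimilarities under a named metric."""

    D: np.ndarray
    metric_name: str

    @property
    def n(self) -> int:
        return self.D.shape[0]


def _validate_input(X: np.ndarray, metric: str) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise DataError(f"need a 2-D matrix with at least 2 rows, got shape {X.shape}")
    if not np.isfinite(X).all():
        bad = np.argwhere(~np.isfinite(X))
        raise DataError(
            f"input contains missing/non-finite values, first at row {bad[0][0]}, "
            f"column {bad[0][1]}"
        )
    if metric in ("cosine", "correlation"):
        zero = np.where(~X.any(axis=1))[0]
        if zero.size:
            raise DataError(
                f"all-zero row {zero[0]} has undefined {metric} distance"
            )
    if metric in ("correlation", "spearman"):
        const = np.where(np.ptp(X, axis=1) == 0)[0]
        if const.size:
            raise DataError(
                f"constant row {const[0]} has undefined {metric} distance"
            )
    return X


def compute_distance_matrix(X: np.ndarray, metric: str = "euclidean") -> DistanceMatrix:
    """Compute the full ``n x n`` distance matrix of the rows of ``X``.

    Parameters
    ----------
    X : array of shape (n, p)
        Feature matrix, rows are samples.
    metric : str
        One of ``euclidean``, ``cosine``, ``correlation``, ``spearman``.
    """
    if metric not in METRICS:
        raise ConfigError(f"unknown metric {metric!r}; choose from {METRICS}")
    X = _validate_input(X, metric)
    if metric == "spearman":
        # rank-transform each row (midrank ties), then Pearson on ranks
        R = rankdata(X, axis=1)
        d = pdist(R, metric="correlation")
    elif metric == "correlation":
        d = pdist(X, metric="correlation")
    elif metric == "cosine":
        d = pdist(X, metric="cosine")
    else:
        d = pdist(X, metric="euclidean")
    D = squareform(np.clip(d, 0.0, 2.0 if metric in _BOUNDED else np.inf))
    np.fill_diagonal(D, 0.0)
    return DistanceMatrix(D=D, metric_name=metric)


def consensus_scores(labelings: dict[str, np.ndarray]) -> dict[str, float]:
    """Mean pairwise NMI of each labeling against all the others."""
    names = list(labelings)
    if len(names) < 2:
        raise ConfigError("consensus needs at least 2 labelings")
    scores = {}
    for d in names:
        others = [
            normalized_mutual_info_score(
                labelings[d], labelings[dp], average_method="arithmetic"
            )
            for dp in names
            if dp != d
        ]
        scores[d] = float(np.mean(others))
    return scores


def consensus_select_metric(
    X: np.ndarray,
    K: int,
    candidates: tuple[str, ...] = METRICS,
    config=None,
) -> tuple[str, dict[str, float]]:
    """Choose a metric by running the full pipeline once per candidate.

    Each candidate metric is scored by the mean NMI of its labels against
    every other surviving candidate's labels; ties are broken by candidate
    order.  Candidates whose pipeline run fails are excluded (logged); if
    fewer than two survive the selection aborts.
    """
    from .pipeline import GULEConfig, run_gule  # deferred: cross-module call

    if len(candidates) < 2:
        raise ConfigError("consensus selection needs at least 2 candidate metrics")
    if config is None:
        config = GULEConfig()
    labelings: dict[str, np.ndarray] = {}
    for m in candidates:
        cfg = config.replace(metric=m)
        try:
            labelings[m] = run_gule(X, K, cfg).labels
        except GuleErrorTuple as exc:  # pragma: no cover - defensive
            logger.warning("metric %s excluded from consensus: %s", m, exc)
    if len(labelings) < 2:
        raise DataError(
            f"consensus aborted: only {len(labelings)} candidate metric(s) "
            "produced a labeling"
        )
    scores = consensus_scores(labelings)
    best = max(labelings, key=lambda m: scores[m])  # first-in-order wins ties
    return best, scores


# failures of a single-metric pipeline run that should merely exclude it
GuleErrorTuple = (DataError, ConfigError, np.linalg.LinAlgError)
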