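"""Coupled-distance preparation for topology-preserving embeddings.

The clustering projection removes inter-class connections but flattens
each class onto an axis; the raw distances keep within-class topology but
mix classes.  Their convex combination

    D_coupled = lam * D_raw / max(D_raw) + (1 - lam) * D_cos(U rows) / 2

(both terms normalized into [0, 1]) widens inter-class separation while
preserving intra-class structure, and is handed to t-SNE or UMAP through
their precomputed-distance interfaces.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .distances import DistanceMatrix
from .exceptions import ConfigError, DataError


@dataclass
class CoupledDistance:
    D: np.ndarray  # symmetric, zero diagonal, entries in [0, 1]
    lam: float  # weight on the normalized raw distances
    layer: int  # projection layer the cosine term came from


def coupled_distance(
    Draw: DistanceMatrix | np.ndarray,
    U: np.ndarray,
    lam: float = 0.5,
    layer: int = 2,
) -> CoupledDistance:
    """Convex combination of normalized raw and projection-cosine distances."""
    if not (0.0 <= lam <= 1.0):
        raise ConfigError(f"lambda must lie in [0, 1], got {lam}")
    D = Draw.D if isinstance(Draw, DistanceMatrix) else np.asarray(Draw, float)
    dmax = D.max()
    if dmax == 0:
        raise DataError("all raw distances are zero (coincident points)")
    from .pipeline import _cosine_distance_rows

    Dcos = _cosine_distance_rows(np.asarray(U, float)).D
    Dc = lam * (D / dmax) + (1.0 - lam) * (Dcos / 2.0)
    np.fill_diagonal(Dc, 0.0)
    return CoupledDistance(D=Dc, lam=lam, layer=layer)


def embed(Dcoupled: CoupledDistance | np.ndarray, method: str = "tsne",
          seed: int = 0) -> np.ndarray:
    """2-D embedding of a precomputed coupled distance matrix."""
    D = Dcoupled.D if isinstance(Dcoupled, CoupledDistance) else np.asarray(Dcoupled)
    if D.shape[0] != D.shape[1] or not np.allclose(D, D.T):
        raise DataError("coupled distance matrix must be square symmetric")
    n = D.shape[0]
    if method == "tsne":
        from sklearn.manifold import TSNE

        perplexity = min(30.0, max(1.0, (n - 1) / 3.0))
        ts = TSNE(n_components=2, metric="precomputed", init="random",
                  perplexity=perplexity, random_state=seed)
        return ts.fit_transform(D)
    if method == "umap":
        try:
            import umap
        except ImportError as exc:  # pragma: no cover
            raise ConfigError(
                "umap-learn is not installed; install it or use method='tsne'"
            ) from exc
        red = umap.UMAP(n_components=2, metric="precomputed", random_state=seed)
        return red.fit_transform(D)
    raise ConfigError(f"unknown embedding method {method!r}")
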