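"""Class-consistent neighborhood estimation and credibility weighting.

Layer 1 takes, for every point, the ``kc`` nearest points (the point
itself included) as its class-consistent neighborhood, with

    kc = k0 + floor(log2(n / K)),   k0 = 5 by default.

Layer 2 operates on the spectrally projected points, where class
consistency has been propagated: each point's neighborhood size ``ki`` is
found adaptively by the largest forward gap in its sorted distances,
capped by the average class size ``floor(n / K)``.

The credibility of a neighbor at normalized distance ``gamma = d / omega``
(``omega`` = the larger of the two exclusion radii) is the sigmoid-lifted
Gaussian ``2 / (1 + exp((alpha * gamma)^2 / 2))``: equal to 1 at the
center and decaying towards the neighborhood boundary, with ``alpha``
controlling how sharply boundary neighbors are discounted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from .distances import DistanceMatrix
from .exceptions import ConfigError, DataError


@dataclass
class NeighborhoodSet:
    """Per-point ordered class-consistent neighbor lists with exclusion radii."""

    layer: int
    kc: int
    neighbors: list  # per point: ordered index array, the point itself first
    omega: np.ndarray  # distance to the first excluded neighbor
    k0: int = 5

    @property
    def sizes(self) -> np.ndarray:
        return np.array([len(nb) for nb in self.neighbors])

    @property
    def n(self) -> int:
        return len(self.neighbors)


def neighborhood_size(n: int, K: int, k0: int = 5) -> int:
    """Conservative base neighborhood size ``kc = k0 + floor(log2(n/K))``.

    Clamped to ``n - 1`` so the first excluded neighbor always exists.
    """
    if K < 1 or n < K:
        raise DataError(f"need n >= K >= 1, got n={n}, K={K}")
    if k0 < 1:
        raise ConfigError(f"k0 must be >= 1, got {k0}")
    kc = k0 + int(np.floor(np.log2(n / K)))
    return min(kc, n - 1)


def _sorted_order(drow: np.ndarray, i: int) -> np.ndarray:
    """Indices sorted by ascending distance to point ``i``, ties broken by
    ascending index, with ``i`` itself forced first."""
    n = drow.shape[0]
    order = np.lexsort((np.arange(n), drow))
    order = order[order != i]
    return np.concatenate(([i], order))


def estimate_neighborhoods_layer1(D: DistanceMatrix, kc: int) -> NeighborhoodSet:
    """Fixed-size neighborhoods: the ``kc`` nearest points including self."""
    n = D.n
    kc = min(kc, n - 1)
    if kc < 1:
        raise DataError("kc must be at least 1")
    neighbors = []
    omega = np.empty(n)
    for i in range(n):
        order = _sorted_order(D.D[i], i)
        neighbors.append(order[:kc])
        omega[i] = D.D[i, order[kc]]  # the (kc+1)-st nearest point
    if np.all(omega == 0):
        warnings.warn("degenerate input: all exclusion radii are zero "
                      "(coincident points)", stacklevel=2)
    return NeighborhoodSet(layer=1, kc=kc, neighbors=neighbors, omega=omega)


def estimate_neighborhoods_layer2(
    Dcos: DistanceMatrix, kc: int, n: int, K: int
) -> NeighborhoodSet:
    """Adaptive neighborhoods on projected points via the largest distance gap.

    With the sorted distances ``d_1 <= d_2 <= ...`` (``d_1 = 0``, self), the
    size is ``ki = min(argmax_j (d_{j+1} - d_j), floor(n/K))`` where the gap
    is scanned over ``j in [kc, min(n-1, 2*floor(n/K))]``; argmax ties go to
    the smallest ``j``.  If ``kc`` already exceeds ``floor(n/K)`` every
    ``ki`` is clamped to ``kc``.
    """
    if Dcos.n != n:
        raise DataError("distance matrix size disagrees with n")
    if n <= kc:
        raise DataError(f"need n > kc, got n={n}, kc={kc}")
    navg = n // K
    W = min(n - 1, 2 * navg)
    neighbors = []
    omega = np.empty(n)
    for i in range(n):
        order = _sorted_order(Dcos.D[i], i)
        ds = Dcos.D[i, order]
        if kc > navg:
            ki = kc
        else:
            gaps = ds[kc : W + 1] - ds[kc - 1 : W]  # gap at j = d_{j+1} - d_j
            ki = kc + int(np.argmax(gaps)) if gaps.size else kc
            ki = min(ki, navg)
        neighbors.append(order[:ki])
        omega[i] = ds[ki]
    return NeighborhoodSet(layer=2, kc=kc, neighbors=neighbors, omega=omega)


def alpha_for_layer(n: int, K: int, layer: int) -> float:
    """Credibility sharpness: 9 (or 6 for large classes) in layer 1, 2 in layer 2."""
    if layer == 1:
        return 9.0 if n / K <= 100 else 6.0
    if layer == 2:
        return 2.0
    raise ConfigError(f"layer must be 1 or 2, got {layer}")


def credibility(gamma, alpha: float):
    """Gaussian credibility ``exp(-(alpha*gamma)^2 / 2)``."""
    gamma = np.asarray(gamma, dtype=float)
    return np.exp(-np.square(alpha * gamma) / 2.0)


def enhanced_credibility(gamma, alpha: float):
    """Sigmoid-lifted credibility ``2 / (1 + exp((alpha*gamma)^2 / 2))``.

    Equals ``2c/(1+c)`` with ``c`` the Gaussian credibility; bounded in
    (0, 1], strictly decreasing in ``gamma`` and (for ``gamma > 0``) in
    ``alpha``.  Overflow-safe for huge ``alpha * gamma``.
    """
    gamma = np.asarray(gamma, dtype=float)
    out = 2.0 * expit(-np.square(alpha * gamma) / 2.0)
    return float(out) if out.ndim == 0 else out
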