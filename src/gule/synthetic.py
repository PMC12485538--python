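"""Seeded 2-D synthetic benchmark generators.

These emulate the structural features the clustering benchmarks are
designed around rather than any particular published point cloud:

* ``blobs`` — isotropic Gaussian control clusters with a guaranteed
  center separation.
* ``entangled`` — three interlocking spiral arms: connectivity-separable
  but neither linearly nor radially separable, so centroid methods fail.
* ``compounded`` — classes of strongly differing densities and sizes: a
  dense compact cluster enclosed by a sparse ring, plus two detached
  blobs of unequal spread.
* ``rounded`` — two compact clusters partially wrapped by one curved
  (arc) cluster.

Every generator is bitwise-reproducible from (name, parameters, seed),
and the default parameters keep each class internally connected at the
pipeline's neighborhood sizes (nearest cross-class gap well above the
within-class point spacing).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import DataError


@dataclass
class SyntheticDataset:
    X: np.ndarray
    truth: np.ndarray  # 1..K
    name: str
    seed: int
    params: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def K(self) -> int:
        return int(np.unique(self.truth).size)


def _balanced_sizes(n: int, K: int) -> np.ndarray:
    """Class sizes as equal as possible, remainder to the earliest classes."""
    base, rem = divmod(n, K)
    return np.array([base + (1 if k < rem else 0) for k in range(K)])


def make_blobs(
    n: int,
    K: int,
    p: int = 2,
    separation: float = 20.0,
    spread: float = 1.0,
    seed: int = 0,
) -> SyntheticDataset:
    """Isotropic Gaussian clusters with pairwise center distance >= separation."""
    if n < K:
        raise DataError(f"need n >= K, got n={n}, K={K}")
    if separation <= 0:
        raise DataError("separation must be positive")
    rng = np.random.default_rng(seed)
    centers = np.zeros((K, p))
    if K > 1:
        # equally spaced on a circle in the first two coordinates: adjacent
        # chord length equals `separation` exactly, others are larger
        R = separation / (2.0 * np.sin(np.pi / K))
        ang = 2.0 * np.pi * np.arange(K) / K
        centers[:, 0] = R * np.cos(ang)
        centers[:, 1] = R * np.sin(ang) if p > 1 else 0.0
    sizes = _balanced_sizes(n, K)
    X = np.vstack([
        centers[k] + spread * rng.standard_normal((sizes[k], p))
        for k in range(K)
    ])
    truth = np.repeat(np.arange(1, K + 1), sizes)
    return SyntheticDataset(X, truth, "blobs", seed,
                            dict(n=n, K=K, p=p, separation=separation,
                                 spread=spread))


def make_entangled(n: int, noise: float = 0.15, seed: int = 0) -> SyntheticDataset:
    """Three interlocking spiral arms with Gaussian jitter of sd ``noise``.

    The arms are phase-shifted copies of the Archimedean spiral r = t over
    t in [pi/2, 5pi/2]; the noiseless radial gap between arms (2*pi/3) is
    far above 3x the default noise, so the classes stay
    connectivity-separable while overlapping in any convex sense.
    """
    if n < 60:
        raise DataError(f"need n >= 60, got {n}")
    if noise < 0:
        raise DataError("noise must be nonnegative")
    rng = np.random.default_rng(seed)
    sizes = _balanced_sizes(n, 3)
    b = 1.5  # radial pitch: inter-arm clearance 2*pi*b/3 ~ 3.1
    Xs, ys = [], []
    for k in range(3):
        m = sizes[k]
        t = 0.6 * np.pi + 1.6 * np.pi * (np.arange(m) + 0.5) / m
        phi = 2.0 * np.pi * k / 3.0
        arm = b * np.column_stack([t * np.cos(t + phi), t * np.sin(t + phi)])
        Xs.append(arm + noise * rng.standard_normal(arm.shape))
        ys.append(np.full(m, k + 1))
    return SyntheticDataset(np.vstack(Xs), np.concatenate(ys), "entangled",
                            seed, dict(n=n, noise=noise))


def make_compounded(n: int, seed: int = 0) -> SyntheticDataset:
    """Four classes of strongly differing densities (ratio well above 5).

    A dense compact cluster sits inside a sparse enclosing ring; two
    detached blobs of unequal spread complete the picture.  Class sizes
    are deliberately unbalanced.
    """
    if n < 100:
        raise DataError(f"need n >= 100, got {n}")
    rng = np.random.default_rng(seed)
    n1 = round(0.20 * n)          # dense core
    n2 = round(0.35 * n)          # sparse enclosing ring
    n3 = round(0.25 * n)          # detached blob
    n4 = n - n1 - n2 - n3         # sparse detached blob
    X1 = 0.25 * rng.standard_normal((n1, 2))
    ang = 2.0 * np.pi * (np.arange(n2) + 0.5) / n2
    rad = 5.0 + 0.25 * rng.standard_normal(n2)
    X2 = np.column_stack([rad * np.cos(ang), rad * np.sin(ang)])
    X3 = np.array([16.0, 0.0]) + 0.7 * rng.standard_normal((n3, 2))
    X4 = np.array([0.0, 16.0]) + 1.1 * rng.standard_normal((n4, 2))
    X = np.vstack([X1, X2, X3, X4])
    truth = np.repeat([1, 2, 3, 4], [n1, n2, n3, n4])
    return SyntheticDataset(X, truth, "compounded", seed, dict(n=n))


def make_rounded(n: int, seed: int = 0) -> SyntheticDataset:
    """Two compact clusters plus one curved (arc) cluster wrapping them."""
    if n < 100:
        raise DataError(f"need n >= 100, got {n}")
    rng = np.random.default_rng(seed)
    n_arc = round(0.4 * n)
    n_b = (n - n_arc) // 2
    n_c = n - n_arc - n_b
    Xb = np.array([-2.5, 0.0]) + 0.5 * rng.standard_normal((n_b, 2))
    Xc = np.array([2.5, 0.0]) + 0.5 * rng.standard_normal((n_c, 2))
    # 240-degree arc of radius 7 around both blobs
    ang = np.deg2rad(-30.0) + np.deg2rad(240.0) * (np.arange(n_arc) + 0.5) / n_arc
    arc = 7.0 * np.column_stack([np.cos(ang), np.sin(ang)])
    Xa = arc + 0.2 * rng.standard_normal(arc.shape)
    X = np.vstack([Xb, Xc, Xa])
    truth = np.repeat([1, 2, 3], [n_b, n_c, n_arc])
    return SyntheticDataset(X, truth, "rounded", seed, dict(n=n))


GENERATORS = {
    "blobs": make_blobs,
    "entangled": make_entangled,
    "compounded": make_compounded,
    "rounded": make_rounded,
}


def make_dataset(name: str, n: int, seed: int = 0, **kw) -> SyntheticDataset:
    """Dispatch by generator name (blobs needs K, others fix their own)."""
    if name not in GENERATORS:
        raise DataError(f"unknown dataset {name!r}; choose from {sorted(GENERATORS)}")
    if name == "blobs":
        kw.setdefault("K", 3)
        return make_blobs(n, seed=seed, **kw)
    return GENERATORS[name](n, seed=seed, **kw)
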