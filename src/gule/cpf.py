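"""CPF clustering: rotate the eigenbasis toward a nonnegative ideal basis.

For an ideal block graph the dominant eigenbasis U0 is nonnegative (one
per-block Perron vector per column), and U U^T then has a completely
positive factorization U0 U0^T.  The rotation Q carrying the computed
basis U onto that nonnegative basis is found by minimizing

    f(Q) = 1/4 ||Q Q^T - I||_F^2 + (K/n) ||(U Q)^-||_F^2,

where (M)^- keeps only the negative entries.  Labels are read off the
rotated basis as argmax_k |(U Q)_{ik}|.

The solver is a plain gradient descent with backtracking (the objective
is smooth and only K x K-dimensional) restarted from the identity and a
few seeded random orthogonal matrices; the best restart is returned.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .exceptions import DataError


@dataclass
class CPFResult:
    Q: np.ndarray  # K x K, approximately orthogonal
    Utilde: np.ndarray  # U @ Q
    labels: np.ndarray  # 1..K
    objective_trace: list = field(default_factory=list)
    restarts_used: int = 0
    converged: bool = True


def _neg(M: np.ndarray) -> np.ndarray:
    return np.minimum(M, 0.0)


def epm_objective(Q: np.ndarray, U: np.ndarray) -> float:
    """Orthogonality + negativity penalty of a candidate rotation."""
    n, K = U.shape
    if Q.shape != (K, K):
        raise DataError(f"Q must be {K}x{K}, got {Q.shape}")
    ortho = 0.25 * np.linalg.norm(Q @ Q.T - np.eye(K)) ** 2
    neg = (K / n) * np.linalg.norm(_neg(U @ Q)) ** 2
    return float(ortho + neg)


def _epm_gradient(Q: np.ndarray, U: np.ndarray) -> np.ndarray:
    n, K = U.shape
    return (Q @ Q.T - np.eye(K)) @ Q + (2.0 * K / n) * U.T @ _neg(U @ Q)


def _descend(Q0, U, step, max_iter, tol):
    Q = Q0.copy()
    f = epm_objective(Q, U)
    trace = [f]
    for _ in range(max_iter):
        g = _epm_gradient(Q, U)
        s = step
        fnew, Qnew = None, None
        while s > 1e-14:
            cand = Q - s * g
            fc = epm_objective(cand, U)
            if fc <= f:
                fnew, Qnew = fc, cand
                break
            s /= 2.0
        if Qnew is None:
            return Q, trace, True  # no descent direction progress: converged
        moved = f - fnew
        Q, f = Qnew, fnew
        trace.append(f)
        if moved < tol:
            return Q, trace, True
    return Q, trace, False


def epm_solve(
    U: np.ndarray,
    K: int | None = None,
    seed: int = 0,
    restarts: int = 5,
    step: float = 0.1,
    max_iter: int = 2000,
    tol: float = 1e-10,
) -> CPFResult:
    """Multi-restart gradient descent for the CPF rotation.

    Restarts are the identity plus ``restarts - 1`` random orthogonal
    matrices (QR of seeded Gaussian draws); the restart with the lowest
    final objective wins, so the result never scores worse than Q = I.
    """
    U = np.asarray(U, dtype=float)
    if U.ndim != 2:
        raise DataError("U must be 2-D")
    n, Kd = U.shape
    if K is None:
        K = Kd
    if K != Kd:
        raise DataError(f"U has {Kd} columns but K={K}")
    rng = np.random.default_rng(seed)
    starts = [np.eye(K)]
    for _ in range(max(restarts - 1, 0)):
        Qr, _ = np.linalg.qr(rng.standard_normal((K, K)))
        starts.append(Qr)
    best = None
    any_converged = False
    for Q0 in starts:
        Q, trace, conv = _descend(Q0, U, step, max_iter, tol)
        any_converged = any_converged or conv
        if best is None or trace[-1] < best[1][-1]:
            best = (Q, trace)
    if not any_converged:
        warnings.warn("EPM did not converge in any restart; returning the "
                      "best iterate", stacklevel=2)
    Q, trace = best
    Ut = U @ Q
    return CPFResult(
        Q=Q,
        Utilde=Ut,
        labels=cpf_labels(Ut),
        objective_trace=trace,
        restarts_used=len(starts),
        converged=any_converged,
    )


def cpf_labels(Utilde: np.ndarray) -> np.ndarray:
    """Labels 1..K by the largest-magnitude entry per row (ties: smallest k)."""
    Utilde = np.asarray(Utilde)
    if Utilde.ndim != 2:
        raise DataError("Utilde must be 2-D")
    if np.any(~Utilde.any(axis=1)):
        warnings.warn("all-zero row(s) in the rotated basis labeled as class 1",
                      stacklevel=2)
    return np.argmax(np.abs(Utilde), axis=1) + 1
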