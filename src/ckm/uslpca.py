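"""Row-cardinality sparse PCA (modified USLPCA).

Solves

    min_{H, P}  ||X - H P'||_F^2
    s.t.        H'H = I_K,   exactly V rows of P are all zero

by alternating least squares.  The P-step sets ``P = X'H`` and zeroes the V
rows with the smallest squared norm (the least-squares-optimal cardinality
projection, with ties broken toward the lowest variable index); the H-step
is an orthogonal Procrustes update ``H = U W'`` from the thin SVD
``X P = U S W'``.  The single rational start is the leading K left singular
vectors of X.

The all-zero rows of the converged loading matrix form the initial
irrelevant-variable set used by the CKM outer loop; the scores ``H`` span
the reduced space in which the clusters live.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .core_math import DataMatrix

__all__ = ["SpcaState", "uslpca_fit", "initial_sets"]


@dataclass
class SpcaState:
    """A converged sparse-PCA solution."""

    scores: np.ndarray  # N x K, orthonormal columns
    loadings: np.ndarray  # J x K, exactly V all-zero rows
    loss: float
    zero_rows: np.ndarray  # sorted indices of the V zeroed rows
    loss_path: list[float] = field(default_factory=list)
    n_iter: int = 0
    converged: bool = False

    @property
    def n_zero_rows(self) -> int:
        return int(self.zero_rows.size)

    def to_dict(self) -> dict:
        return {
            "loss": self.loss,
            "zero_rows": self.zero_rows.tolist(),
            "n_iter": self.n_iter,
            "converged": self.converged,
            "loss_path": list(self.loss_path),
        }


def _leading_left_singular_vectors(X: np.ndarray, K: int) -> np.ndarray:
    """First K left singular vectors via an eigendecomposition of the
    smaller-side Gram matrix (deterministic, no iterative solver)."""
    N, J = X.shape
    if N <= J:
        w, U = np.linalg.eigh(X @ X.T)
        return U[:, ::-1][:, :K]
    w, V = np.linalg.eigh(X.T @ X)
    w, V = w[::-1][:K], V[:, ::-1][:, :K]
    w = np.maximum(w, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        U = (X @ V) / np.sqrt(w)
    # complete any null directions deterministically
    bad = ~np.isfinite(U).all(axis=0)
    if bad.any():
        U[:, bad] = 0.0
        U = _complete_orthonormal(U)
    return U


def _complete_orthonormal(U: np.ndarray) -> np.ndarray:
    """Replace zero/degenerate columns so that U'U = I (QR-based)."""
    Q, _ = np.linalg.qr(np.hstack([U, np.eye(U.shape[0])]))
    keep = []
    j = 0
    for k in range(U.shape[1]):
        if np.linalg.norm(U[:, k]) > 1e-8:
            keep.append(U[:, k] / np.linalg.norm(U[:, k]))
        else:
            while j < Q.shape[1]:
                cand = Q[:, j]
                j += 1
                if all(abs(cand @ v) < 1e-8 for v in keep):
                    keep.append(cand)
                    break
    return np.column_stack(keep)


def _procrustes(M: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Return (H, s): H = U W' maximizing Tr(H'M) over H'H=I, s = singular values."""
    U, s, Wt = np.linalg.svd(M, full_matrices=False)
    # sign convention: largest-|entry| of each W column positive
    flip = np.sign(Wt[np.arange(Wt.shape[0]), np.abs(Wt).argmax(axis=1)])
    flip[flip == 0] = 1.0
    U = U * flip
    Wt = Wt * flip[:, None]
    if s.size and s[-1] <= 1e-12 * max(s[0], 1.0):
        warnings.warn("rank-deficient score update; orthonormal basis completed "
                      "deterministically", RuntimeWarning, stacklevel=3)
    return U @ Wt, s


def uslpca_fit(
    X: DataMatrix | np.ndarray,
    K: int,
    V: int,
    tol: float = 1e-8,
    max_iter: int = 200,
    n_random_starts: int = 0,
    seed: int | None = None,
) -> SpcaState:
    """Fit the row-cardinality sparse PCA of rank `K` with `V` zero rows.

    Parameters
    ----------
    X : DataMatrix or ndarray (N, J)
        Column-centered data.
    K : int
        Number of components (clusters), ``1 <= K < min(N, J - V)``.
    V : int
        Number of all-zero loading rows, ``0 <= V <= J - 2``.
    tol : float
        Relative loss-decrease threshold for convergence.
    max_iter : int
        Iteration cap for the alternating updates.
    n_random_starts : int
        Extra random orthonormal starts (research option); the default is
        the single rational SVD start.
    seed : int, optional
        Seed for the random starts (unused when ``n_random_starts == 0``).

    Returns
    -------
    SpcaState
    """
    Xv = X.values if isinstance(X, DataMatrix) else np.asarray(X, dtype=float)
    N, J = Xv.shape
    if not 0 <= V <= J - 2:
        raise ValueError(f"V must be in [0, J-2]; got V={V}, J={J}")
    if not 1 <= K <= min(N - 1, J - V):
        raise ValueError(f"need 1 <= K <= min(N-1, J-V); got K={K}, N={N}, J={J}, V={V}")

    starts = [_leading_left_singular_vectors(Xv, K)]
    if n_random_starts:
        rng = np.random.default_rng(seed)
        for _ in range(n_random_starts):
            Q, _ = np.linalg.qr(rng.standard_normal((N, K)))
            starts.append(Q)

    best: SpcaState | None = None
    for H0 in starts:
        state = _als(Xv, H0, K, V, tol, max_iter)
        if best is None or state.loss < best.loss:
            best = state
    return best


def _als(Xv: np.ndarray, H: np.ndarray, K: int, V: int, tol: float, max_iter: int) -> SpcaState:
    xnorm2 = float((Xv**2).sum())
    loss_path: list[float] = []
    prev = np.inf
    converged = False
    zero_rows = np.empty(0, dtype=int)
    P = np.zeros((Xv.shape[1], K))
    for it in range(1, max_iter + 1):
        P = Xv.T @ H
        if V > 0:
            row_norms = np.einsum("jk,jk->j", P, P)
            order = np.argsort(row_norms, kind="stable")  # ties -> lowest index
            zero_rows = np.sort(order[:V])
            P[zero_rows] = 0.0
        H, s = _procrustes(Xv @ P)
        loss = xnorm2 - 2.0 * float(s.sum()) + float((P**2).sum())
        loss_path.append(loss)
        if prev - loss <= tol * max(abs(prev), 1.0):
            converged = True
            break
        prev = loss
    return SpcaState(
        scores=H,
        loadings=P,
        loss=loss_path[-1],
        zero_rows=zero_rows,
        loss_path=loss_path,
        n_iter=len(loss_path),
        converged=converged,
    )


def initial_sets(state: SpcaState) -> tuple[np.ndarray, np.ndarray]:
    """The irrelevant set g0 (zeroed loading rows) and its complement s0."""
    J = state.loadings.shape[0]
    g0 = np.asarray(state.zero_rows, dtype=int)
    s0 = np.setdiff1d(np.arange(J), g0, assume_unique=True)
    return g0, s0
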