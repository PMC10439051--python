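"""Standardization, partition algebra and sum-of-squares decompositions.

The clustering criterion used throughout the package is the total
within-cluster sum of squares of a column-centered data matrix, optionally
restricted to a subset of *signaling* variables.  For a centered column ``j``
the total sum of squares splits exactly into a between-cluster part

    b_j = sum_k N_k * m_kj**2

and a within-cluster part ``w_j = sum_i (x_ij - m_{c(i),j})**2``.  Every
other module (the sparse-PCA initializer, the alternating CKM updates, the
Gap statistic) consumes this decomposition, so it lives here together with
the two container types it operates on.

Variable indices are 0-based throughout the Python API; cluster labels are
contiguous integers ``1..K``.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DataMatrix",
    "Partition",
    "SsDecomposition",
    "standardize",
    "partition_from_labels",
    "ss_decompose",
    "ckm_loss",
    "read_matrix",
    "write_matrix",
]

#: modes accepted by :func:`standardize`
UNIT_VARIANCE = "unit-variance"
UNIT_SS = "unit-sum-of-squares"


@dataclass(frozen=True)
class DataMatrix:
    """An observations x variables matrix with optional standardization state.

    Attributes
    ----------
    values : ndarray of shape (n_obs, n_vars)
        The data, float64, no missing values.
    var_ids : tuple of str
        One label per variable (column).
    standardized : str or None
        ``"unit-variance"``, ``"unit-sum-of-squares"`` or ``None`` (raw).
    """

    values: np.ndarray
    var_ids: tuple[str, ...]
    standardized: str | None = None

    @property
    def n_obs(self) -> int:
        return self.values.shape[0]

    @property
    def n_vars(self) -> int:
        return self.values.shape[1]

    def validate(self, atol_mean: float = 1e-10, atol_scale: float = 1e-8) -> None:
        """Check structural invariants; raise ``ValueError`` on violation."""
        X = self.values
        if X.ndim != 2:
            raise ValueError("values must be 2-D")
        if self.n_obs < 2:
            raise ValueError("need at least 2 observations")
        if self.n_vars < 3:
            raise ValueError("need at least 3 variables")
        if len(self.var_ids) != self.n_vars:
            raise ValueError("var_ids length mismatch")
        _check_finite(X)
        if self.standardized is not None:
            means = X.mean(axis=0)
            if np.abs(means).max() > atol_mean:
                raise ValueError("columns not centered")
            if self.standardized == UNIT_VARIANCE:
                scale = X.var(axis=0, ddof=1)
            elif self.standardized == UNIT_SS:
                scale = (X**2).sum(axis=0)
            else:
                raise ValueError(f"unknown standardization {self.standardized!r}")
            if np.abs(scale - 1.0).max() > atol_scale:
                raise ValueError("columns do not have the declared scale")


def _check_finite(X: np.ndarray) -> None:
    bad = ~np.isfinite(X)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(f"missing or non-finite value at row {i}, column {j}")


def _default_ids(J: int) -> tuple[str, ...]:
    return tuple(f"x{j + 1}" for j in range(J))


def standardize(
    raw: np.ndarray | pd.DataFrame | "DataMatrix",
    mode: str = UNIT_VARIANCE,
    var_ids: Sequence[str] | None = None,
) -> DataMatrix:
    """Center every column and rescale it to the requested scale.

    Parameters
    ----------
    raw : array-like of shape (N, J) or (N,)
        Raw data; a 1-D array is treated as a single column.
    mode : {"unit-variance", "unit-sum-of-squares"}
        ``unit-variance`` divides by the sample standard deviation (N-1
        denominator); ``unit-sum-of-squares`` rescales each centered column
        to squared norm 1.
    var_ids : sequence of str, optional
        Variable labels; defaults to ``x1..xJ`` (or the DataFrame columns).

    Returns
    -------
    DataMatrix
        Centered, rescaled copy with ``standardized`` set to `mode`.
    """
    if isinstance(raw, DataMatrix):
        if var_ids is None:
            var_ids = raw.var_ids
        raw = raw.values
    if isinstance(raw, pd.DataFrame):
        if var_ids is None:
            var_ids = [str(c) for c in raw.columns]
        raw = raw.to_numpy()
    X = np.array(raw, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.ndim != 2:
        raise ValueError("input must be 1-D or 2-D")
    if X.shape[0] < 2:
        raise ValueError("need at least 2 observations to standardize")
    if mode not in (UNIT_VARIANCE, UNIT_SS):
        raise ValueError(f"unknown standardization mode {mode!r}")
    _check_finite(X)
    ids = tuple(var_ids) if var_ids is not None else _default_ids(X.shape[1])
    Xc = X - X.mean(axis=0)
    if mode == UNIT_VARIANCE:
        scale = Xc.std(axis=0, ddof=1)
    else:
        scale = np.sqrt((Xc**2).sum(axis=0))
    zero = np.flatnonzero(scale <= 0)
    if zero.size:
        raise ValueError(f"constant column: variable {ids[zero[0]]!r} has zero variance")
    return DataMatrix(Xc / scale, ids, standardized=mode)


def as_data_matrix(X) -> DataMatrix:
    """Coerce an array/DataFrame into a (possibly unstandardized) DataMatrix."""
    if isinstance(X, DataMatrix):
        return X
    if isinstance(X, pd.DataFrame):
        return DataMatrix(np.asarray(X, dtype=float), tuple(map(str, X.columns)))
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("expected a 2-D matrix")
    return DataMatrix(X, _default_ids(X.shape[1]))


# ---------------------------------------------------------------------------
# Partitions


@dataclass
class Partition:
    """A hard partition of N observations into K non-empty clusters.

    ``assign`` holds contiguous labels ``1..K``; ``external_labels[k-1]`` is
    the original label mapped to internal cluster ``k``.  ``centroids`` (and
    the cached ``within_ss``) refer to whatever matrix the partition was
    last fit to and may be ``None``.
    """

    assign: np.ndarray
    K: int
    sizes: np.ndarray
    centroids: np.ndarray | None = None
    external_labels: tuple | None = None
    within_ss: float | None = None

    @property
    def n_obs(self) -> int:
        return self.assign.shape[0]

    def indicator(self, scaled: bool = True) -> np.ndarray:
        """The N x K cluster indicator H; scaled columns satisfy H'H = I_K."""
        H = np.zeros((self.n_obs, self.K))
        H[np.arange(self.n_obs), self.assign - 1] = 1.0
        if scaled:
            H /= np.sqrt(self.sizes)[self.assign - 1][:, None]
        return H

    def centroids_for(self, X: np.ndarray) -> np.ndarray:
        """K x J matrix of cluster means of `X` under this partition."""
        X = np.asarray(X, dtype=float)
        M = np.zeros((self.K, X.shape[1]))
        np.add.at(M, self.assign - 1, X)
        return M / self.sizes[:, None]

    def with_centroids(self, X: np.ndarray) -> "Partition":
        X = np.asarray(X, dtype=float)
        M = self.centroids_for(X)
        w = float(((X - M[self.assign - 1]) ** 2).sum())
        return replace(self, centroids=M, within_ss=w)

    def canonical_assign(self) -> np.ndarray:
        """Relabel clusters by order of first appearance (for comparisons)."""
        out = np.empty_like(self.assign)
        seen: dict[int, int] = {}
        for i, a in enumerate(self.assign):
            if a not in seen:
                seen[a] = len(seen) + 1
            out[i] = seen[a]
        return out

    def same_partition(self, other: "Partition") -> bool:
        return bool(np.array_equal(self.canonical_assign(), other.canonical_assign()))


def partition_from_labels(labels: Sequence) -> Partition:
    """Build a :class:`Partition` from an arbitrary label vector.

    Labels are mapped to contiguous internal labels ``1..K`` in sorted
    order of the distinct external labels.
    """
    labels = np.asarray(labels)
    if labels.ndim != 1 or labels.size == 0:
        raise ValueError("labels must be a non-empty 1-D vector")
    uniq, inv = np.unique(labels, return_inverse=True)
    sizes = np.bincount(inv, minlength=uniq.size).astype(int)
    return Partition(
        assign=(inv + 1).astype(int),
        K=int(uniq.size),
        sizes=sizes,
        external_labels=tuple(uniq.tolist()),
    )


# ---------------------------------------------------------------------------
# Sum-of-squares decompositions


@dataclass(frozen=True)
class SsDecomposition:
    """Per-variable total / between / within sums of squares."""

    per_var_total: np.ndarray
    per_var_between: np.ndarray
    per_var_within: np.ndarray

    @property
    def total(self) -> float:
        return float(self.per_var_total.sum())

    @property
    def between(self) -> float:
        return float(self.per_var_between.sum())

    @property
    def within(self) -> float:
        return float(self.per_var_within.sum())


def _centered_values(X) -> np.ndarray:
    # defensive re-centering: the SS identities presume grand mean 0
    V = X.values if isinstance(X, DataMatrix) else np.asarray(X, dtype=float)
    return V - V.mean(axis=0)


def ss_decompose(X, part: Partition) -> SsDecomposition:
    """Decompose each (centered) column's total SS into between + within.

    ``b_j = sum_k N_k m_kj^2`` equals the ranking quantity
    ``sum_k sum_{i in cluster k} (x_ij^2 - (x_ij - m_kj)^2)`` by algebra.
    """
    Xc = _centered_values(X)
    if part.n_obs != Xc.shape[0]:
        raise ValueError("partition length does not match matrix rows")
    if (part.sizes < 1).any():
        raise ValueError("partition contains an empty cluster")
    M = part.centroids_for(Xc)
    total = (Xc**2).sum(axis=0)
    between = (part.sizes[:, None] * M**2).sum(axis=0)
    within = ((Xc - M[part.assign - 1]) ** 2).sum(axis=0)
    return SsDecomposition(total, between, within)


def validate_irrelevant_set(g, n_vars: int) -> np.ndarray:
    """Normalize an irrelevant-variable index set; enforce |g| <= J - 2."""
    g = np.unique(np.asarray(g, dtype=int)) if len(np.atleast_1d(g)) else np.empty(0, dtype=int)
    if g.size and (g.min() < 0 or g.max() >= n_vars):
        raise ValueError("irrelevant-variable index out of range")
    if g.size > n_vars - 2:
        raise ValueError(
            "at least two signaling variables are required "
            f"(got |g|={g.size} with J={n_vars})"
        )
    return g


def ckm_loss(X, part: Partition, g) -> float:
    """The CKM objective: ||X_g||^2 + within-SS over the signaling variables.

    Evaluated through the identity ``loss = total SS - between SS over the
    signaling columns`` (exact for centered data).
    """
    dm = as_data_matrix(X)
    g = validate_irrelevant_set(g, dm.n_vars)
    dec = ss_decompose(dm, part)
    signaling = np.setdiff1d(np.arange(dm.n_vars), g, assume_unique=True)
    return float(dec.per_var_total.sum() - dec.per_var_between[signaling].sum())


# ---------------------------------------------------------------------------
# Matrix IO


def _infer_sep(path: str, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    ext = os.path.splitext(str(path))[1].lower()
    return "\t" if ext in (".tsv", ".tab", ".txt") else ","


def read_matrix(
    path,
    delimiter: str | None = None,
    header: bool = True,
    row_ids: bool = True,
) -> DataMatrix:
    """Read a delimited observations x variables matrix.

    The delimiter is inferred from the extension (``.tsv``/``.tab``/``.txt``
    -> tab, otherwise comma) unless given explicitly.
    """
    df = pd.read_csv(
        path,
        sep=_infer_sep(path, delimiter),
        header=0 if header else None,
        index_col=0 if row_ids else None,
    )
    ids = [str(c) for c in df.columns] if header else None
    values = df.to_numpy(dtype=float)
    _check_finite(values)
    return DataMatrix(values, tuple(ids) if ids else _default_ids(values.shape[1]))


def write_matrix(X: DataMatrix, path, delimiter: str | None = None) -> None:
    """Write a DataMatrix as delimited text with a header row and row ids."""
    df = pd.DataFrame(X.values, columns=list(X.var_ids))
    df.index = [f"obs{i + 1}" for i in range(X.n_obs)]
    df.to_csv(path, sep=_infer_sep(path, delimiter))
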