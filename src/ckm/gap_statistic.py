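"""Permutation-reference Gap statistic over the between-cluster SS.

For a candidate number of irrelevant variables V (or a candidate number of
clusters K), the observed statistic is the between-cluster sum of squares
O of the fitted partition on the selected signaling columns.  The reference
distribution is obtained by independently permuting the observations within
each of those columns B times (which destroys any cluster structure while
preserving the marginals) and clustering each permuted matrix with plain
multi-start k-means.  The statistic is

    Gap = log O - mean_b log O_b,

with standard error ``sd(log O_b) * sqrt(1 + 1/B)``.  Larger Gap values
indicate more salient cluster structure than expected under the
no-structure null.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .ckm_core import KmOptions, ckm_fit, kmeans_multistart
from .core_math import as_data_matrix, ss_decompose

__all__ = ["CandidateGap", "GapProfile", "permute_within_columns",
           "gap_for_candidate", "gap_profile"]


def permute_within_columns(X: np.ndarray, seed=None) -> np.ndarray:
    """Permute the rows of each column independently and uniformly.

    `seed` may be an int, a ``numpy.random.Generator`` or ``None``; column
    multisets are preserved exactly.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    X = np.asarray(X, dtype=float)
    # iid uniforms argsorted per column give independent uniform permutations
    order = np.argsort(rng.random(X.shape), axis=0)
    return np.take_along_axis(X, order, axis=0)


@dataclass
class CandidateGap:
    """Gap record for one candidate value (a V or a K)."""

    candidate: int
    gap: float
    se: float
    observed_log_o: float
    permuted_log_o: np.ndarray
    observed_between: float
    signaling: np.ndarray | None = None
    assign: np.ndarray | None = None
    loss: float | None = None


@dataclass
class GapProfile:
    """Gap records over an ordered list of candidates."""

    candidates: np.ndarray
    records: list[CandidateGap]
    B: int
    seed: int | None = None

    @property
    def gap(self) -> np.ndarray:
        return np.array([r.gap for r in self.records])

    @property
    def gap_se(self) -> np.ndarray:
        return np.array([r.se for r in self.records])

    def best(self) -> CandidateGap:
        """The record with the largest Gap; ties favor the lowest candidate."""
        order = np.argsort(self.candidates, kind="stable")
        best = order[0]
        for i in order:
            if self.records[i].gap > self.records[best].gap:
                best = i
        return self.records[best]

    def to_dict(self) -> dict:
        return {
            "B": self.B,
            "seed": self.seed,
            "candidates": self.candidates.tolist(),
            "gap": self.gap.tolist(),
            "gap_se": self.gap_se.tolist(),
            "observed_log_o": [r.observed_log_o for r in self.records],
            "permuted_log_o": [r.permuted_log_o.tolist() for r in self.records],
        }


def _keyed_seed(seed, *key: int) -> np.random.SeedSequence:
    # keyed derivation: a candidate's stream does not depend on the order in
    # which candidates are evaluated (zoom-in == full grid, bit for bit)
    entropy = 0 if seed is None else int(seed)
    return np.random.SeedSequence(entropy=entropy, spawn_key=tuple(int(k) for k in key))


def _seed_to_int(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1)[0] % (2**31 - 1))


def reference_between_ss(
    X: np.ndarray,
    signaling: np.ndarray,
    K: int,
    B: int,
    opts: KmOptions,
    seed: int | None,
) -> np.ndarray:
    """Between-SS of plain k-means on B within-column permutations of the
    signaling columns of `X`.

    Common random numbers: the permutation of a column and the k-means seeds
    are keyed by (K, b) and by the column's identity in the *full* matrix,
    not by the candidate under evaluation — so reference noise is shared
    across candidates and Gap comparisons between nearby candidates are not
    dominated by Monte-Carlo scatter.
    """
    from dataclasses import replace

    N, J = X.shape
    Xc = X[:, signaling] - X[:, signaling].mean(axis=0)
    total = float((Xc**2).sum())
    out = np.empty(B)
    for b in range(B):
        keys = np.random.default_rng(_keyed_seed(seed, K, 555, b)).random((N, J))
        order = np.argsort(keys[:, signaling], axis=0)
        Xp = np.take_along_axis(Xc, order, axis=0)
        km_seed = _seed_to_int(_keyed_seed(seed, K, 666, b))
        part = kmeans_multistart(Xp, K, replace(opts, seed=km_seed))
        out[b] = total - part.within_ss
    return out


def gap_for_candidate(
    X,
    K: int,
    V: int,
    B: int = 20,
    opts: KmOptions | None = None,
    seed: int | None = None,
    refit: bool = True,
) -> CandidateGap:
    """Fit CKM at (K, V) and compute its permutation Gap statistic.

    Returns the record with the fitted partition, signaling set, observed
    between-SS and the B reference values.
    """
    dm = as_data_matrix(X)
    if B < 1:
        raise ValueError("B must be >= 1")
    opts = opts or KmOptions()
    fit_seed = _seed_to_int(_keyed_seed(seed, K, V))
    from dataclasses import replace

    model = ckm_fit(dm, K, V, opts=replace(opts, seed=fit_seed), refit=refit)
    dec = ss_decompose(dm, model.partition)
    observed = float(dec.per_var_between[model.signaling].sum())
    if observed <= 0.0:
        # no separation at all: deprioritize this candidate
        return CandidateGap(V, -math.inf, 0.0, -math.inf, np.full(B, np.nan),
                            observed, model.signaling, model.partition.assign, model.loss)
    ref = reference_between_ss(dm.values, model.signaling, K, B, opts, seed)
    log_o = math.log(observed)
    log_ref = np.log(ref)
    gap = log_o - float(log_ref.mean())
    se = float(log_ref.std(ddof=1) * math.sqrt(1.0 + 1.0 / B)) if B > 1 else 0.0
    return CandidateGap(V, gap, se, log_o, log_ref, observed,
                        model.signaling, model.partition.assign, model.loss)


def gap_profile(
    X,
    K: int,
    candidates,
    B: int = 20,
    opts: KmOptions | None = None,
    seed: int | None = None,
) -> GapProfile:
    """Evaluate :func:`gap_for_candidate` over a list of V candidates."""
    dm = as_data_matrix(X)
    candidates = np.asarray(sorted(int(v) for v in np.atleast_1d(candidates)))
    if candidates.size and (candidates.min() < 0 or candidates.max() > dm.n_vars - 2):
        raise ValueError("candidates must lie in [0, J-2]")
    records = [gap_for_candidate(dm, K, int(v), B=B, opts=opts, seed=seed)
               for v in candidates]
    return GapProfile(candidates, records, B, seed)
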