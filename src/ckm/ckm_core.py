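"""The cardinality k-means (CKM) solver and its multi-start k-means engine.

CKM minimizes, over a partition ``c`` into K clusters and a set ``g`` of V
irrelevant variables,

    ||X_g||_F^2  +  sum_k sum_{i in c^-1(k)} sum_{j not in g} (x_ij - m_kj)^2.

The solver pipeline is

1. row-cardinality sparse PCA (:func:`ckm.uslpca.uslpca_fit`) for the
   initial irrelevant set ``g0``;
2. a 10-start k-means on the signaling columns (or, optionally, on the
   sparse-PCA scores) for the initial partition;
3. alternating conditional minimizers — Lloyd-to-convergence on the
   signaling columns for ``c``, then ``g`` = the V columns with the
   smallest between-cluster SS — until neither changes;
4. an optional extra 10-start k-means refit on the final signaling columns,
   kept only if it lowers the objective.

Both updates are exact conditional minimizers, so the objective is
non-increasing and the alternation terminates at a fixed point.

Lloyd iterations themselves are delegated to scikit-learn's ``KMeans``
(``init="random"`` draws K distinct observations; empty clusters are
repaired internally by relocating the worst-fit points).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.cluster import KMeans

from .core_math import (
    DataMatrix,
    Partition,
    as_data_matrix,
    ckm_loss,
    partition_from_labels,
    ss_decompose,
    validate_irrelevant_set,
)
from .uslpca import initial_sets, uslpca_fit

__all__ = ["KmOptions", "CkmModel", "kmeans_multistart", "lloyd_from_partition",
           "update_g", "ckm_fit"]


@dataclass(frozen=True)
class KmOptions:
    """Options for the multi-start k-means engine.

    ``n_starts`` random (Forgy) starts; ``seed`` makes runs reproducible;
    ``tol=0`` runs Lloyd to exact label convergence (subject to ``max_iter``).
    """

    n_starts: int = 10
    max_iter: int = 100
    seed: int | None = None
    tol: float = 0.0
    empty_cluster_policy: str = "relocate-worst"

    def __post_init__(self):
        if self.n_starts < 1:
            raise ValueError("n_starts must be >= 1")
        if self.empty_cluster_policy != "relocate-worst":
            # the Lloyd engine repairs empty clusters by re-seeding them with
            # the points farthest from their centroids; no other policy yet
            raise ValueError("unsupported empty_cluster_policy")


def _seed_int(seed) -> int | None:
    if seed is None:
        return None
    return int(np.random.SeedSequence(seed).generate_state(1)[0] % (2**31 - 1))


def _finish(X: np.ndarray, labels: np.ndarray) -> Partition:
    return partition_from_labels(labels).with_centroids(X)


def kmeans_multistart(
    X: np.ndarray | DataMatrix,
    K: int,
    opts: KmOptions | None = None,
    init: Partition | None = None,
) -> Partition:
    """Best-of-``n_starts`` Lloyd k-means, optionally also trying a supplied
    initial partition; returns the partition with the smallest within-SS."""
    Xv = X.values if isinstance(X, DataMatrix) else np.asarray(X, dtype=float)
    opts = opts or KmOptions()
    N = Xv.shape[0]
    if K > N:
        raise ValueError(f"K={K} exceeds the number of observations N={N}")
    if K == N:
        return _finish(Xv, np.arange(N) + 1)
    km = KMeans(
        n_clusters=K,
        init="random",
        n_init=opts.n_starts,
        max_iter=opts.max_iter,
        tol=opts.tol,
        random_state=_seed_int(opts.seed),
        algorithm="lloyd",
    ).fit(Xv)
    best = _finish(Xv, km.labels_)
    if init is not None:
        cand = lloyd_from_partition(Xv, init, opts)
        if cand.within_ss < best.within_ss:
            best = cand
    return best


def lloyd_from_partition(
    X: np.ndarray | DataMatrix,
    init: Partition,
    opts: KmOptions | None = None,
) -> Partition:
    """Run Lloyd to convergence on `X` starting from the centroids of `init`."""
    Xv = X.values if isinstance(X, DataMatrix) else np.asarray(X, dtype=float)
    opts = opts or KmOptions()
    centers = init.centroids_for(Xv)
    km = KMeans(
        n_clusters=init.K,
        init=centers,
        n_init=1,
        max_iter=opts.max_iter,
        tol=opts.tol,
        algorithm="lloyd",
    ).fit(Xv)
    return _finish(Xv, km.labels_)


def update_g(X, part: Partition, V: int) -> np.ndarray:
    """The size-V irrelevant set minimizing the CKM loss given the partition.

    The loss is separable over variables, so the conditional optimum is the
    V variables with the smallest between-cluster SS (ties broken toward
    the lowest index).
    """
    dm = as_data_matrix(X)
    if not 0 <= V <= dm.n_vars - 2:
        raise ValueError(f"V must be in [0, J-2]; got V={V}, J={dm.n_vars}")
    if V == 0:
        return np.empty(0, dtype=int)
    b = ss_decompose(dm, part).per_var_between
    order = np.argsort(b, kind="stable")
    return np.sort(order[:V])


@dataclass
class CkmModel:
    """A fitted CKM solution."""

    partition: Partition
    g: np.ndarray  # irrelevant variable indices (sorted, 0-based)
    signaling: np.ndarray  # complement of g
    loss: float
    n_outer_iter: int
    converged: bool
    extra_refit_used: bool
    loss_path: list[float] = field(default_factory=list)
    var_ids: tuple[str, ...] | None = None

    @property
    def V(self) -> int:
        return int(self.g.size)

    def to_dict(self) -> dict:
        d = {
            "schema_version": 1,
            "assign": self.partition.assign.tolist(),
            "K": self.partition.K,
            "g": self.g.tolist(),
            "signaling": self.signaling.tolist(),
            "loss": self.loss,
            "n_outer_iter": self.n_outer_iter,
            "converged": self.converged,
            "extra_refit_used": self.extra_refit_used,
        }
        if self.var_ids is not None:
            d["signaling_ids"] = [self.var_ids[j] for j in self.signaling]
        return d


def ckm_fit(
    X,
    K: int,
    V: int,
    opts: KmOptions | None = None,
    refit: bool = True,
    init_space: str = "data",
    max_outer: int = 100,
    spca_tol: float = 1e-8,
    spca_max_iter: int = 200,
) -> CkmModel:
    """Fit cardinality k-means with `K` clusters and `V` irrelevant variables.

    Parameters
    ----------
    X : DataMatrix or ndarray (N, J)
        Standardized (at least column-centered) data.
    K, V : int
        Number of clusters (``2 <= K <= N - 1``) and of irrelevant
        variables (``0 <= V <= J - 2``).
    opts : KmOptions
        Multi-start options (10 Forgy starts by default) and the seed that
        drives every random draw of the fit.
    refit : bool
        Run the extra 10-start k-means on the final signaling columns and
        keep it if it lowers the loss (recovery over speed).
    init_space : {"data", "scores"}
        Take the initial partition from k-means on the signaling columns of
        the data (default) or on the sparse-PCA scores.
    """
    dm = as_data_matrix(X)
    Xv = dm.values
    N, J = Xv.shape
    if not 2 <= K <= N - 1:
        raise ValueError(f"need 2 <= K <= N-1; got K={K}, N={N}")
    if not 0 <= V <= J - 2:
        raise ValueError(f"V must be in [0, J-2]; got V={V}, J={J}")
    if init_space not in ("data", "scores"):
        raise ValueError("init_space must be 'data' or 'scores'")
    opts = opts or KmOptions()
    children = np.random.SeedSequence(opts.seed).spawn(2)
    seed_init, seed_refit = (int(c.generate_state(1)[0] % (2**31 - 1)) for c in children)

    # the sparse-PCA initializer needs rank <= min(N - 1, J - V); clamp it
    # for extreme V (the clustering itself still uses the requested K)
    k_spca = min(K, J - V, N - 1)
    state = uslpca_fit(Xv, k_spca, V, tol=spca_tol, max_iter=spca_max_iter)
    g, signaling = initial_sets(state)
    init_matrix = state.scores if init_space == "scores" else Xv[:, signaling]
    part = kmeans_multistart(init_matrix, K, replace(opts, seed=seed_init))
    part = part.with_centroids(Xv)
    loss = ckm_loss(dm, part, g)
    loss_path = [loss]

    converged = False
    n_outer = 0
    for n_outer in range(1, max_outer + 1):
        part_new = lloyd_from_partition(Xv[:, signaling] if V else Xv, part, opts)
        g_new = update_g(dm, part_new, V)
        loss = ckm_loss(dm, part_new, g_new)
        loss_path.append(loss)
        same = part.same_partition(part_new) and np.array_equal(g, g_new)
        part, g = part_new, g_new
        signaling = np.setdiff1d(np.arange(J), g, assume_unique=True)
        if same:
            converged = True
            break
    if not converged:
        warnings.warn("CKM outer loop hit the iteration cap without converging",
                      RuntimeWarning, stacklevel=2)

    extra_refit_used = False
    if refit:
        alt = kmeans_multistart(Xv[:, signaling], K, replace(opts, seed=seed_refit))
        alt_loss = ckm_loss(dm, alt, g)
        if alt_loss < loss:
            part, loss = alt, alt_loss
            loss_path.append(loss)
            extra_refit_used = True

    part = part.with_centroids(Xv)
    return CkmModel(
        partition=part,
        g=validate_irrelevant_set(g, J),
        signaling=signaling,
        loss=loss,
        n_outer_iter=n_outer,
        converged=converged,
        extra_refit_used=extra_refit_used,
        loss_path=loss_path,
        var_ids=dm.var_ids,
    )
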