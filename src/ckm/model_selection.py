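"""Model selection: tune V per K, extract the stable set, select K.

The three-step procedure:

1. For each candidate number of clusters K (2..K_max by default) the number
   of irrelevant variables V_K is tuned by maximizing the permutation Gap
   statistic — over the full grid 0..J-2 when J is small, otherwise with an
   iterative "zoom-in" grid of ten evenly spaced candidates that narrows
   around the current argmax.  The tuned signaling set is s_K.
2. The stable set is the intersection of the s_K over all K: variables
   deemed signaling no matter how many clusters are assumed.
3. K is chosen by clustering the stable-set columns with multi-start
   k-means and applying one of four criteria: globalGap (argmax of the Gap
   curve), firstGap (first local maximum), the Krzanowski-Lai index, or the
   Dindex (second differences of the mean within-cluster distance curve).

An optional elbow refinement re-examines ten V values around the tuned
V_opt and picks the point of maximum perpendicular distance to the chord of
the (V, between-SS) curve.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import numpy as np

from .ckm_core import KmOptions, kmeans_multistart
from .core_math import as_data_matrix
from .gap_statistic import CandidateGap, GapProfile, gap_for_candidate

__all__ = ["SelectionResult", "select_v_for_k", "elbow_refine", "stable_set",
           "select_k", "run_model_selection"]

CRITERIA = ("globalGap", "firstGap", "KL", "Dindex")


@dataclass
class SelectionResult:
    """Outcome of the full three-step selection procedure."""

    k_range: tuple[int, ...]
    per_k: dict  # K -> (V_K, s_K ndarray, GapProfile)
    stable: np.ndarray
    criterion: str
    criterion_values: dict  # K -> criterion value
    K_opt: int
    V_opt: int
    s_opt: np.ndarray
    V_refined: int | None = None

    def to_dict(self) -> dict:
        return {
            "schema_version": 1,
            "k_range": list(self.k_range),
            "criterion": self.criterion,
            "criterion_values": {str(k): v for k, v in self.criterion_values.items()},
            "stable_set": self.stable.tolist(),
            "K_opt": self.K_opt,
            "V_opt": self.V_opt,
            "V_refined": self.V_refined,
            "s_opt": self.s_opt.tolist(),
            "per_k": {
                str(k): {"V": int(v), "signaling": s.tolist(),
                         "gap_profile": prof.to_dict()}
                for k, (v, s, prof) in self.per_k.items()
            },
        }


def _argmax_lowest(candidates: np.ndarray, values: np.ndarray) -> int:
    """Index of the max value; ties resolved toward the lowest candidate."""
    order = np.lexsort((candidates,))
    best = order[0]
    for i in order:
        if values[i] > values[best]:
            best = i
    return int(best)


def select_v_for_k(
    X,
    K: int,
    strategy: str = "zoom",
    B: int = 20,
    opts: KmOptions | None = None,
    seed: int | None = None,
    full_threshold: int = 100,
    include_zero: bool = True,
) -> tuple[int, np.ndarray, GapProfile]:
    """Tune the number of irrelevant variables for a fixed K.

    ``strategy="full"`` evaluates every V in the grid (only allowed when
    J <= `full_threshold`); ``strategy="zoom"`` uses the iterative ten-point
    grid.  Returns ``(V_K, s_K, profile)`` where the profile collects every
    candidate actually evaluated (in increasing V order).
    """
    dm = as_data_matrix(X)
    J = dm.n_vars
    lo_bound = 0 if include_zero else 1
    hi_bound = J - 2
    cache: dict[int, CandidateGap] = {}

    def ev(v: int) -> CandidateGap:
        if v not in cache:
            cache[v] = gap_for_candidate(dm, K, v, B=B, opts=opts, seed=seed)
        return cache[v]

    if strategy == "full":
        if J > full_threshold:
            raise ValueError(
                f"full-grid search with J={J} > {full_threshold} is computationally "
                "prohibitive; use strategy='zoom'")
        for v in range(lo_bound, hi_bound + 1):
            ev(v)
    elif strategy == "zoom":
        lo, hi = lo_bound, hi_bound
        while hi - lo + 1 > 10:
            cand = np.unique(np.round(np.linspace(lo, hi, 10)).astype(int))
            gaps = np.array([ev(int(v)).gap for v in cand])
            i = _argmax_lowest(cand, gaps)
            if cand.size < 3:
                break
            if i == 0:
                lo2, hi2 = int(cand[0]), int(cand[1]) - 1
            elif i == cand.size - 1:
                lo2, hi2 = int(cand[-2]) + 1, int(cand[-1])
            else:
                lo2, hi2 = int(cand[i - 1]) + 1, int(cand[i + 1]) - 1
            if (lo2, hi2) == (lo, hi):
                break
            lo, hi = lo2, hi2
        for v in range(lo, hi + 1):
            ev(v)
    else:
        raise ValueError("strategy must be 'full' or 'zoom'")

    vs = np.array(sorted(cache))
    records = [cache[int(v)] for v in vs]
    profile = GapProfile(vs, records, B, seed)
    best = profile.best()
    return int(best.candidate), np.asarray(best.signaling), profile


def elbow_refine(
    X,
    K: int,
    v_hat: int,
    window: int = 10,
    opts: KmOptions | None = None,
    seed: int | None = None,
    between_fn=None,
) -> int:
    """Refine V around `v_hat` with an elbow rule on the between-SS curve.

    `window` candidate values centered on `v_hat` (clamped to [0, J-2]) are
    examined; the elbow is the candidate with the largest perpendicular
    distance to the chord joining the first and last points of the
    normalized (V, between-SS) curve.  A flat curve returns `v_hat` with a
    warning.  ``between_fn(v) -> float`` may be injected (testing hook);
    the default refits CKM at each candidate.
    """
    dm = as_data_matrix(X)
    if window < 3:
        raise ValueError("window must be >= 3")
    J = dm.n_vars
    lo = max(0, min(v_hat - window // 2, J - 2 - (window - 1)))
    cand = np.unique(np.clip(np.arange(lo, lo + window), 0, J - 2))
    if between_fn is None:
        def between_fn(v: int) -> float:
            rec = gap_for_candidate(dm, K, int(v), B=1, opts=opts, seed=seed)
            return rec.observed_between
    ys = np.array([between_fn(int(v)) for v in cand], dtype=float)
    if cand.size < 3:
        return int(v_hat)
    # normalize both axes so the geometry is scale-free
    x = (cand - cand[0]) / max(cand[-1] - cand[0], 1)
    span = ys.max() - ys.min()
    if span <= 1e-12 * max(abs(ys).max(), 1.0):
        warnings.warn("flat between-SS curve; keeping the tuned V", RuntimeWarning)
        return int(v_hat)
    y = (ys - ys.min()) / span
    # perpendicular distance to the chord between the end points
    dx, dy = x[-1] - x[0], y[-1] - y[0]
    norm = math.hypot(dx, dy)
    dist = np.abs(dy * (x - x[0]) - dx * (y - y[0])) / norm
    if dist.max() <= 1e-12:
        warnings.warn("between-SS curve is linear; keeping the tuned V", RuntimeWarning)
        return int(v_hat)
    return int(cand[_argmax_lowest(cand, dist)])


def stable_set(per_k: dict) -> np.ndarray:
    """Intersection of the signaling sets over all K (the stable set)."""
    if not per_k:
        raise ValueError("per_k is empty")
    sets = []
    for v in per_k.values():
        s = v[1] if isinstance(v, tuple) else v
        sets.append(np.asarray(s, dtype=int))
    out = sets[0]
    for s in sets[1:]:
        out = np.intersect1d(out, s)
    if out.size == 0:
        raise ValueError(
            "the stable set is empty; consider a smaller K_max so that the "
            "per-K signaling sets overlap")
    return out


def _within_profile(Xs: np.ndarray, ks: list[int], opts: KmOptions, seed) -> dict:
    """k-means fits over a list of K values on the stable-set columns."""
    rng = np.random.SeedSequence(0 if seed is None else int(seed), spawn_key=(901,))
    seeds = rng.generate_state(len(ks)) % (2**31 - 1)
    fits = {}
    for k, s in zip(ks, seeds):
        if k == 1:
            Xc = Xs - Xs.mean(axis=0)
            part = None
            w = float((Xc**2).sum())
            d = float(np.linalg.norm(Xc, axis=1).mean())
        else:
            part = kmeans_multistart(Xs, k, replace(opts, seed=int(s)))
            w = part.within_ss
            resid = Xs - part.centroids[part.assign - 1]
            d = float(np.linalg.norm(resid, axis=1).mean())
        fits[k] = {"part": part, "within": w, "mean_dist": d}
    return fits


def _gap_over_k(Xs: np.ndarray, ks: list[int], fits: dict, B: int,
                opts: KmOptions, seed) -> dict:
    """Classical Gap statistic over K on the stable-set columns.

    Within-SS form, ``Gap(K) = mean_b log W_b(K) - log W(K)``, with B
    uniform reference data sets drawn in the principal-axis bounding box of
    the data (the clusGap construction) and shared across all K.  The
    principal-axis box stretches along the cluster-separation directions,
    so the reference within-SS keeps dropping at K beyond the truth and the
    Gap curve peaks there instead of plateauing.
    """
    Xc = Xs - Xs.mean(axis=0)
    ss = np.random.SeedSequence(0 if seed is None else int(seed), spawn_key=(902,))
    ref_seed, km_seed = (int(c.generate_state(1)[0] % (2**31 - 1)) for c in ss.spawn(2))
    rng = np.random.default_rng(ref_seed)
    _, _, Vt = np.linalg.svd(Xc, full_matrices=False)
    Z = Xc @ Vt.T
    lo, hi = Z.min(axis=0), Z.max(axis=0)
    refs = [rng.uniform(lo, hi, size=Z.shape) @ Vt for _ in range(B)]
    km_rng = np.random.default_rng(km_seed)
    gap = {}
    for k in ks:
        logs = []
        for Xp in refs:
            part = kmeans_multistart(Xp, k, replace(opts, seed=int(km_rng.integers(2**31 - 1))))
            logs.append(math.log(max(part.within_ss, 1e-300)))
        gap[k] = float(np.mean(logs)) - math.log(max(fits[k]["within"], 1e-300))
    return gap


def select_k(
    X,
    stable,
    k_range,
    criterion: str = "globalGap",
    B: int = 20,
    opts: KmOptions | None = None,
    seed: int | None = None,
) -> tuple[int, dict]:
    """Select the number of clusters on the stable-set columns.

    Returns ``(K_opt, criterion_values)`` where `criterion_values` maps each
    K in `k_range` to its criterion value (Gap, KL ratio or Dindex second
    difference depending on `criterion`).
    """
    dm = as_data_matrix(X)
    stable = np.asarray(stable, dtype=int)
    if stable.size == 0:
        raise ValueError("stable set is empty")
    if criterion not in CRITERIA:
        raise ValueError(f"criterion must be one of {CRITERIA}")
    ks = sorted(int(k) for k in k_range)
    if len(ks) == 1:
        return ks[0], {ks[0]: float("nan")}
    opts = opts or KmOptions()
    Xs = dm.values[:, stable]
    N = Xs.shape[0]

    eval_ks = list(ks)
    if criterion in ("KL", "Dindex"):
        if ks[0] - 1 >= 1:
            eval_ks = [ks[0] - 1] + eval_ks
        if ks[-1] + 1 <= N - 1:
            eval_ks = eval_ks + [ks[-1] + 1]
    fits = _within_profile(Xs, eval_ks, opts, seed)

    if criterion in ("globalGap", "firstGap"):
        gap = _gap_over_k(Xs, ks, fits, B, opts, seed)
        values = {k: gap[k] for k in ks}
        if criterion == "globalGap":
            arr = np.array([values[k] for k in ks])
            K_opt = ks[_argmax_lowest(np.array(ks), arr)]
        else:
            K_opt = ks[-1]
            for a, b in zip(ks[:-1], ks[1:]):
                if values[a] >= values[b]:
                    K_opt = a
                    break
        return int(K_opt), values

    p = Xs.shape[1]
    W = {k: fits[k]["within"] for k in eval_ks}
    if criterion == "KL":
        def diff(k):
            return (k - 1) ** (2 / p) * W[k - 1] - k ** (2 / p) * W[k]
        values = {}
        for k in ks:
            if (k - 1 in W) and (k + 1 in W):
                denom = diff(k + 1)
                values[k] = abs(diff(k)) / max(abs(denom), 1e-300)
            else:
                values[k] = -math.inf
        arr = np.array([values[k] for k in ks])
        return int(ks[_argmax_lowest(np.array(ks), arr)]), values

    # Dindex: maximize the second difference of the mean within-cluster distance
    d = {k: fits[k]["mean_dist"] for k in eval_ks}
    values = {}
    for k in ks:
        if (k - 1 in d) and (k + 1 in d):
            values[k] = (d[k - 1] - d[k]) - (d[k] - d[k + 1])
        else:
            values[k] = -math.inf
    arr = np.array([values[k] for k in ks])
    return int(ks[_argmax_lowest(np.array(ks), arr)]), values


def run_model_selection(
    X,
    K_max: int = 10,
    K_min: int = 2,
    strategy: str = "zoom",
    criterion: str = "globalGap",
    B: int = 20,
    opts: KmOptions | None = None,
    seed: int | None = None,
    elbow: bool = False,
    full_threshold: int = 100,
) -> SelectionResult:
    """Run the full three-step selection of (K, V, signaling set)."""
    dm = as_data_matrix(X)
    if K_min < 2 or K_max < K_min:
        raise ValueError("need 2 <= K_min <= K_max")
    ks = list(range(K_min, K_max + 1))
    base = 0 if seed is None else int(seed)
    per_k = {}
    for k in ks:
        k_seed = int(np.random.SeedSequence(base, spawn_key=(17, k)).generate_state(1)[0]
                     % (2**31 - 1))
        per_k[k] = select_v_for_k(dm, k, strategy=strategy, B=B, opts=opts,
                                  seed=k_seed, full_threshold=full_threshold)
    stable = stable_set(per_k)
    K_opt, values = select_k(dm, stable, ks, criterion=criterion, B=B, opts=opts,
                             seed=base)
    V_opt, s_opt, _ = per_k[K_opt]
    V_refined = None
    if elbow:
        V_refined = elbow_refine(dm, K_opt, V_opt, opts=opts, seed=base)
    return SelectionResult(
        k_range=tuple(ks),
        per_k=per_k,
        stable=stable,
        criterion=criterion,
        criterion_values=values,
        K_opt=int(K_opt),
        V_opt=int(V_opt),
        s_opt=np.asarray(s_opt),
        V_refined=V_refined,
    )
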