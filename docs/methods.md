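# Methods

## Objective and algebra

All analysis operates on a column-standardized matrix (mean 0; unit sample
variance with the N−1 denominator by default, or unit sum of squares —
`standardize(mode=...)`).  For centered columns the total sum of squares of
variable j splits exactly into a between part `b_j = Σ_k N_k m_kj²` and a
within part; the CKM objective

    L(c, g) = ||X_g||² + Σ_{j∉g} w_j(c) = total SS − Σ_{j∉g} b_j(c)

is evaluated through the right-hand identity.  A partition is represented by
a scaled indicator H with orthonormal columns (`H'H = I_K`), which links
k-means to PCA: for fixed c, the within-SS equals `||X||² − Tr H'XX'H`.

## The solver

1. **Row-cardinality sparse PCA.**  `min ||X − ĤP'||²` with `Ĥ'Ĥ = I_K` and
   exactly V all-zero rows of P, solved by alternating least squares from a
   single rational start (the leading K left singular vectors, computed from
   the smaller-side Gram matrix).  The P-step is `P = X'Ĥ` followed by
   zeroing the V rows of smallest squared norm — the least-squares-optimal
   cardinality projection; ties break toward the lowest column index.  The
   Ĥ-step is orthogonal Procrustes via the thin SVD of XP (rank deficiencies
   are completed deterministically and flagged with a warning).  Both steps
   are exact conditional minimizers, so the loss is non-increasing;
   convergence is declared at a relative loss decrease below 1e-8 (cap 200
   iterations).  Extra random orthonormal starts are available
   (`n_random_starts`) but off by default: they cost much and rarely help.
   When V is so large that the rank constraint K ≤ J−V cannot hold, the
   initializer's rank is clamped to min(K, J−V, N−1); the clustering itself
   always uses the requested K.
2. **Initial partition.**  Multi-start k-means (10 Forgy starts) on the
   signaling columns selected by the sparse PCA; `init_space="scores"`
   instead clusters the N×K score matrix.
3. **Alternating updates.**  Lloyd-to-convergence on the signaling columns
   (initialized at the current partition), then `g` = the V columns with
   the smallest between-cluster SS (the exact conditional minimizer of L).
   The loop stops when neither the partition (as a set partition) nor `g`
   changes; both updates are conditional minimizers over a finite state
   space, so termination is guaranteed (cap 100 outer iterations).
4. **Refit.**  One extra 10-start k-means on the final signaling columns,
   kept only if it lowers L (recovery over speed; `refit=False` disables).

Lloyd iterations are delegated to scikit-learn's `KMeans`
(`algorithm="lloyd"`, `init="random"` = distinct observations, `tol=0` so
runs stop only at label convergence); its empty-cluster repair relocates the
points that fit worst, matching the intended policy.  All randomness
descends from one seed through keyed `SeedSequence` splitting, so adding
components never perturbs existing streams and equal seeds give
byte-identical results.

## Tuning V: the permutation Gap statistic

For a candidate V, CKM is fit, the between-cluster SS of its partition on
its signaling columns is the observed statistic O(V), and the reference
distribution comes from B (default 20) data sets obtained by independently
permuting the observations within each signaling column and clustering each
with plain 10-start k-means:

    Gap(V) = log O(V) − (1/B) Σ_b log O_b(V),   SE = sd(log O_b)·√(1 + 1/B).

The V maximizing Gap wins; ties go to the smallest V (parsimony).  The grid
includes V = 0, so plain k-means is nested in the search.  With J ≤ 100 the
full grid 0..J−2 can be searched; otherwise the zoom-in scheme evaluates ten
evenly spaced candidates, narrows to the interval bracketing the argmax
(clamped at the boundaries), and finishes exhaustively once the interval has
at most ten points.  Candidate draws are keyed by (seed, K, V) and the
permutation/reference draws by (seed, K, replicate, original column id) —
common random numbers, so (a) the zoom-in search is bit-identical to the
full grid wherever they overlap, and (b) comparisons between nearby
candidates are not dominated by reference noise.  A candidate with zero
observed separation gets Gap = −∞ and is never selected.

Known behavior: because `g` is updated to *minimize* the retained
between-SS, a handful of noise columns whose between-SS is inflated by
selection can keep the Gap argmax a few units below the true V in the
hardest cells (many irrelevant variables, small centroid gaps).  The elbow
refinement (`elbow_refine`, ten candidates around the tuned V, maximum
perpendicular distance to the chord of the normalized (V, between-SS)
curve) exists for exactly this; flat or linear curves return the tuned V
with a warning.

## Selecting K: stable set + criterion

`run_model_selection` tunes (V_K, s_K) for every K in 2..K_max (default 10;
use 11..19 when ~15 clusters are plausible), intersects the signaling sets
into the stable set (an empty intersection raises, advising a smaller
K_max), and selects K by clustering the stable-set columns:

* **globalGap / firstGap** — the classical within-SS Gap statistic,
  `Gap(K) = mean_b log W_b(K) − log W(K)`, with B uniform reference draws in
  the principal-axis bounding box of the stable-set data (the `clusGap`
  construction), shared across all K.  globalGap takes the global argmax,
  firstGap the first K with Gap(K) ≥ Gap(K+1) (the last K if the curve is
  monotone; an SE-banded variant was considered and dropped for scope).
  The between-SS permutation form used for tuning V is *not* applied over
  K: measured on generated data it is monotone decreasing in K and always
  selects K = 2, while the principal-axis reference recovers the generating
  K with clear margins — the reference box stretches along the separation
  directions, so reference within-SS keeps falling beyond the true K and
  the curve peaks there.
* **KL** — Krzanowski–Lai ratio `|DIFF(K)| / |DIFF(K+1)|` with
  `DIFF(K) = (K−1)^{2/p} W_{K−1} − K^{2/p} W_K`, boundary fits added as
  needed (K = 1 uses the total SS).
* **Dindex** — the second difference of the mean within-cluster distance
  curve.  On evenly spaced mean ladders this criterion is conservative
  (merging adjacent clusters is cheap), so it often prefers smaller K; it is
  provided for completeness, not as the default.

The tuned (V, signaling set) of the selected K are returned; an optional
final elbow refinement of V is available.

## Synthetic data

`generate(SimSpec(...))` draws K equal clusters of `n_per_cluster`
observations (default 50).  Every signaling variable (default 50) shares one
ladder of cluster means, evenly spaced with neighbor gap `delta_mu` and
grand mean 0 (K=3, Δμ=0.6 → −0.6, 0, 0.6), plus unit normal noise;
irrelevant variables (V ∈ {5, 50, 250, 1000} in the study designs) are
i.i.d. standard normal.  Matrices are generated raw and standardized at
analysis time (switchable).  This emulates the evaluation designs exactly
but not several features of real data — correlated noise, per-cluster or
per-variable variance differences, unequal cluster sizes, variables relevant
to only some clusters — so passing tests demonstrate correctness of the
procedure under its own model, not robustness to those departures.

Evaluation metrics: classification error CE = pairwise co-membership
disagreement (= 1 − Rand index; 0 iff equal up to relabeling), the
proportion of true signaling variables recovered, and exactness of the
selected set.  Note that with many clusters the co-membership base rate is
~1/K, which compresses pairwise CE: at K = 30 even a random balanced
partition scores ≈ 0.06, so CE values from partitions of many clusters are
not comparable to matching-based misclassification rates.

## Problem sizes used by scripts/acceptance.py

Chosen as desk-scale versions of the 40-replicate study designs: study 1 at
10 replicates per cell (both 16-cell grids, K = 3 and 5); study 2 at 2
replicates per cell on the K ∈ {3,5} grids plus one replicate at each of
Δμ ∈ {0.6, 1.0} for the K = 30, V = 1000 stress cell; study 3 at one
replicate of K ∈ {3,5} for a balanced sample of cells covering all four V
and both extreme Δμ values ((V, Δμ) ∈ {(50,.6), (1000,.6), (5,1), (250,1)}),
with K_max = 10, zoom-in search and B = 20 throughout.

## Limitations

* Continuous variables only; no missing data (both rejected with errors).
* One partition and one global irrelevant set; no per-cluster relevance.
* The alternating solver finds local optima; quality rests on the sparse-PCA
  start (brute-force-verified only on tiny instances).
* Gap-based V tuning can over-select a few noise columns near the optimum
  (see above); use the elbow refinement when exactness matters.
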