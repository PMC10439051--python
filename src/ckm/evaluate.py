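"""Partition and variable-selection accuracy metrics.

Classification error (CE) is the pairwise co-membership disagreement rate
between two partitions,

    CE = sum_{i > i'} | 1[c_true(i)=c_true(i')] - 1[c_est(i)=c_est(i')] |
         / (N (N-1) / 2),

which is 0 iff the partitions agree up to relabeling and equals one minus
the Rand index.  Variable recovery is the proportion of true signaling
variables contained in the estimated signaling set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["EvalReport", "classification_error", "variable_recovery"]


@dataclass(frozen=True)
class EvalReport:
    """Accuracy summary for one fitted model against the known truth."""

    ce: float | None
    signal_recovery_rate: float | None
    exact_recovery: bool | None
    n_selected: int | None


def classification_error(c_true, c_est) -> float:
    """Pairwise co-membership disagreement rate between two label vectors."""
    a = np.asarray(c_true)
    b = np.asarray(c_est)
    if a.ndim != 1 or b.ndim != 1 or a.shape != b.shape:
        raise ValueError("label vectors must be 1-D and of equal length")
    n = a.size
    if n < 2:
        raise ValueError("need at least 2 observations")
    same_a = a[:, None] == a[None, :]
    same_b = b[:, None] == b[None, :]
    iu = np.triu_indices(n, k=1)
    return float((same_a[iu] != same_b[iu]).mean())


def variable_recovery(true_signal, est_signal) -> EvalReport:
    """Recovery rate and exactness of an estimated signaling set."""
    truth = np.unique(np.asarray(true_signal, dtype=int))
    est = np.unique(np.asarray(est_signal, dtype=int))
    if truth.size == 0:
        raise ValueError("the true signaling set is empty")
    rate = np.intersect1d(truth, est).size / truth.size
    exact = bool(truth.size == est.size and np.array_equal(truth, est))
    return EvalReport(
        ce=None,
        signal_recovery_rate=float(rate),
        exact_recovery=exact,
        n_selected=int(est.size),
    )
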