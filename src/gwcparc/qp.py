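"""Closed-form solvers for the two simplex-constrained quadratic programs.

Both subproblems of the graph-learning objective reduce to Euclidean
projections onto the probability simplex:

* ``project_simplex`` solves  min ||x - v||^2  s.t.  x >= 0, 1'x = 1
  by the classic sort-and-threshold construction (used for the feature
  weights alpha).

* ``sparse_simplex_update`` solves, for one graph column s with cost
  vector p,  min p's + beta s's  s.t.  s >= 0, 1's = 1, with the
  regularizer beta chosen implicitly so the solution has exactly k
  nonzeros — the adaptive-neighbors construction. With the k smallest
  costs p_(1) <= ... <= p_(k) and the next cost p_(k+1),

      s_(j)  = (p_(k+1) - p_(j)) / (k p_(k+1) - sum_{h<=k} p_(h)),
      beta   = (k p_(k+1) - sum_{h<=k} p_(h)) / 2.

  The self index is excluded (a zero self-cost would absorb all mass).
  Ties at the k-th cost break toward the lower index; if the smallest
  k + 1 costs are all equal the solution degenerates to uniform 1/k on
  the tied entries with beta = 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["SimplexSolution", "project_simplex", "sparse_simplex_update"]

_SUM_TOL = 1e-10


@dataclass
class SimplexSolution:
    """A point on the probability simplex plus the implied beta (if any)."""

    s: np.ndarray
    support: np.ndarray
    beta: float | None = None

    def __post_init__(self) -> None:
        assert abs(float(self.s.sum()) - 1.0) < _SUM_TOL
        assert float(self.s.min()) >= 0.0


def project_simplex(v: np.ndarray) -> SimplexSolution:
    """Euclidean projection of ``v`` onto the probability simplex."""
    v = np.asarray(v, dtype=float).ravel()
    if v.size == 0:
        raise ValueError("cannot project an empty vector")
    if not np.all(np.isfinite(v)):
        raise ValueError("non-finite entries in projection input")
    u = np.sort(v)[::-1]
    css = np.cumsum(u) - 1.0
    rho = np.nonzero(u * np.arange(1, v.size + 1) > css)[0][-1]
    theta = css[rho] / (rho + 1.0)
    s = np.maximum(v - theta, 0.0)
    s /= s.sum()  # tidy rounding so the simplex invariant holds exactly
    return SimplexSolution(s=s, support=np.nonzero(s)[0])


def sparse_simplex_update(
    p: np.ndarray, k: int, exclude: int | None = None
) -> SimplexSolution:
    """k-sparse simplex minimizer of ``p's + beta s's`` (beta implied by k)."""
    p = np.asarray(p, dtype=float).ravel()
    n = p.size
    if exclude is not None and not (0 <= exclude < n):
        raise ValueError("exclude index out of range")
    cand = np.arange(n) if exclude is None else np.delete(np.arange(n), exclude)
    if not 1 <= k <= cand.size - 1:
        raise ValueError(
            f"need 1 <= k <= {cand.size - 1} (k+1 candidate costs), got k = {k}"
        )
    costs = p[cand]
    order = np.argsort(costs, kind="stable")  # stable: ties to lower index
    sel = order[:k]
    p_sel = costs[sel]
    p_next = costs[order[k]]
    den = k * p_next - p_sel.sum()
    s = np.zeros(n)
    if den <= 0.0:
        # p_(1) = ... = p_(k+1): uniform mass on the k lowest-index ties
        s[cand[sel]] = 1.0 / k
        beta = 0.0
    else:
        s[cand[sel]] = (p_next - p_sel) / den
        s[cand[sel]] /= s[cand[sel]].sum()
        beta = den / 2.0
    return SimplexSolution(s=s, support=np.nonzero(s)[0], beta=beta)
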