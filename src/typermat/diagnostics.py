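"""Metric diagnostics for gene-cluster distance matrices.

The diagnostics answer three nested structural questions about a labelled
distance matrix ``D`` and a candidate gene order:

* four-point condition — is ``D`` an additive tree metric?
* Kalmanson condition  — is ``D`` circular decomposable w.r.t. a circular
  order (the structure produced by unequal crossing over within genes)?
* Robinson condition   — do distances grow monotonically away from the
  diagonal in a linear order (which makes that order a shortest Hamiltonian
  path)?

All checks are inequality systems; ``tol`` is an absolute slack so that
empirical (noisy) matrices can be tested meaningfully. ``worst_violation`` is
the signed slack of the tightest inequality: ``<= tol`` means the property
holds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np

from .distmat import DistanceMatrix

__all__ = [
    "CheckReport",
    "path_length",
    "cycle_length",
    "check_four_point",
    "check_kalmanson",
    "check_robinson",
]


@dataclass(frozen=True)
class CheckReport:
    """Outcome of an inequality-system check.

    Attributes
    ----------
    holds : bool
        True iff ``worst_violation <= tol``.
    worst_violation : float
        Signed slack of the tightest inequality (positive = violated).
    tol : float
        Absolute tolerance the check was run with.
    witnesses : list of tuple
        Label tuples achieving the worst violation (at most one unless the
        full list was requested).
    n_violations : int
        Number of inequalities with slack exceeding ``tol``.
    """

    holds: bool
    worst_violation: float
    tol: float
    witnesses: list = field(default_factory=list)
    n_violations: int = 0

    def __bool__(self) -> bool:
        return self.holds


def path_length(D: DistanceMatrix, order: Sequence[str]) -> float:
    """Length of the Hamiltonian path visiting the labels in `order`.

    ``L(pi) = sum_i d(pi[i-1], pi[i])``, the total genetic distance walked
    along the cluster in that order.
    """
    order = list(order)
    if len(set(order)) != len(order):
        raise ValueError("repeated label in order")
    if set(order) != set(D.labels):
        raise ValueError("order must be a permutation of the labels")
    idx = D.indices(order)
    return float(D.values[idx[:-1], idx[1:]].sum())


def cycle_length(D: DistanceMatrix, order: Sequence[str]) -> float:
    """Length of the Hamiltonian cycle through `order` (path + closing edge)."""
    return path_length(D, order) + D[order[-1], order[0]]


def _report(worst: float, tol: float, witnesses, n_viol: int) -> CheckReport:
    return CheckReport(
        holds=bool(worst <= tol),
        worst_violation=float(worst),
        tol=tol,
        witnesses=witnesses,
        n_violations=n_viol,
    )


def check_four_point(
    D: DistanceMatrix, tol: float = 1e-9, *, full_witnesses: bool = False
) -> CheckReport:
    """Four-point condition: is ``D`` an additive tree metric?

    For every quadruple the three pairing sums ``d_xy+d_uv``, ``d_xu+d_yv``,
    ``d_xv+d_yu`` must have their two largest values equal (within `tol`).
    Matrices with fewer than 4 points hold trivially.
    """
    n = D.n
    if n < 4:
        return _report(-np.inf, tol, [], 0)
    v = D.values
    worst = -np.inf
    witnesses: list = []
    n_viol = 0
    for q in combinations(range(n), 4):
        x, y, u, w = q
        sums = sorted(
            (v[x, y] + v[u, w], v[x, u] + v[y, w], v[x, w] + v[y, u])
        )
        slack = sums[2] - sums[1]
        if slack > tol:
            n_viol += 1
        if slack > worst:
            worst = slack
            witnesses = [tuple(D.labels[i] for i in q)]
        elif full_witnesses and slack == worst and slack > tol:
            witnesses.append(tuple(D.labels[i] for i in q))
    return _report(worst, tol, witnesses, n_viol)


def check_kalmanson(
    D: DistanceMatrix,
    order: Sequence[str],
    tol: float = 1e-9,
    *,
    full_witnesses: bool = False,
) -> CheckReport:
    """Kalmanson condition of ``D`` w.r.t. `order` treated as a circular order.

    For every ``i < j < k < l`` in (one linearization of) the circular order:

        max(d_ij + d_kl, d_il + d_jk) <= d_ik + d_jl + tol

    Rotation and reversal of `order` leave the verdict unchanged. Holds
    trivially for fewer than 4 points.
    """
    idx = D._permutation_indices(order)
    n = len(idx)
    if n < 4:
        return _report(-np.inf, tol, [], 0)
    v = D.values[np.ix_(idx, idx)]
    worst = -np.inf
    witnesses: list = []
    n_viol = 0
    labels = list(order)
    for i, j, k, l in combinations(range(n), 4):
        slack = max(v[i, j] + v[k, l], v[i, l] + v[j, k]) - (v[i, k] + v[j, l])
        if slack > tol:
            n_viol += 1
        if slack > worst:
            worst = slack
            witnesses = [(labels[i], labels[j], labels[k], labels[l])]
        elif full_witnesses and slack == worst and slack > tol:
            witnesses.append((labels[i], labels[j], labels[k], labels[l]))
    return _report(worst, tol, witnesses, n_viol)


def check_robinson(
    D: DistanceMatrix,
    order: Sequence[str],
    tol: float = 1e-9,
    *,
    full_witnesses: bool = False,
) -> CheckReport:
    """Robinson condition of ``D`` w.r.t. the *linear* order `order`.

    For every ``i < j < k``:  ``max(d_ij, d_jk) <= d_ik + tol``, i.e.
    distances never shrink when moving away from the diagonal. A Robinsonian
    order is a shortest Hamiltonian path.
    """
    idx = D._permutation_indices(order)
    n = len(idx)
    v = D.values[np.ix_(idx, idx)]
    worst = -np.inf
    witnesses: list = []
    n_viol = 0
    labels = list(order)
    for i, j, k in combinations(range(n), 3):
        slack = max(v[i, j], v[j, k]) - v[i, k]
        if slack > tol:
            n_viol += 1
        if slack > worst:
            worst = slack
            witnesses = [(labels[i], labels[j], labels[k])]
        elif full_witnesses and slack == worst and slack > tol:
            witnesses.append((labels[i], labels[j], labels[k]))
    return _report(worst, tol, witnesses, n_viol)
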