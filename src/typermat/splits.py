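"""Circular split decomposition of Kalmanson metrics.

A metric satisfies the Kalmanson condition w.r.t. a circular order iff it is
*circular decomposable*: it can be written exactly as a nonnegative
combination of split pseudometrics of circular-interval splits (a Crofton
formula),

    d(x, y) = sum_S alpha_S * [S separates x and y],

where each split ``S`` cuts the circular order into two arcs and ``alpha_S``
is its *isolation index*. These split systems are the substrate of
split-network methods such as NeighborNet; :func:`write_nexus_splits` in
:mod:`typermat.io` exports them for SplitsTree.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .distmat import DistanceMatrix

__all__ = ["Split", "SplitSystem", "isolation_indices", "crofton_reconstruct"]


@dataclass(frozen=True)
class Split:
    """One circular-interval split: `block` vs. the remaining labels."""

    block: tuple[str, ...]      # a circular interval of the system's order
    alpha: float                # isolation index (weight), >= 0 after filtering

    def separates(self, x: str, y: str) -> bool:
        return (x in self.block) != (y in self.block)


@dataclass
class SplitSystem:
    """Weighted circular splits of a distance matrix.

    Attributes
    ----------
    order : tuple of str
        Circular order of the labels (stored as one linearization).
    splits : list of Split
        Retained splits with positive isolation indices.
    residual : float
        Max absolute entry of ``D - sum(alpha * delta_S)`` over the retained
        splits; ~0 for a Kalmanson matrix in its Kalmanson order.
    min_alpha : float
        Smallest isolation index seen *before* clipping/filtering. Values
        below ``-tol`` signal a Kalmanson violation of the input.
    """

    order: tuple[str, ...]
    splits: list[Split] = field(default_factory=list)
    residual: float = 0.0
    min_alpha: float = 0.0

    def __len__(self) -> int:
        return len(self.splits)

    def weight_of(self, block) -> float:
        """Total weight of splits whose block equals `block` (as a set)."""
        want = frozenset(block)
        return sum(
            s.alpha
            for s in self.splits
            if frozenset(s.block) in (want, frozenset(self.order) - want)
        )


def isolation_indices(
    D: DistanceMatrix,
    order: Sequence[str],
    tol: float = 1e-9,
) -> SplitSystem:
    """Crofton decomposition of ``D`` along the circular order `order`.

    For the split whose block is the circular interval ``order[i+1..j]`` the
    isolation index is

        alpha_ij = 1/2 * (d(o_i, o_j) + d(o_{i+1}, o_{j+1})
                          - d(o_i, o_{j+1}) - d(o_{i+1}, o_j)),

    indices mod n. All ``n(n-1)/2`` circular splits are evaluated; splits with
    ``alpha <= tol`` are dropped (indices in ``(-tol, 0)`` count as 0), and
    more negative indices are reported via ``min_alpha`` rather than raised,
    since empirical matrices may violate the Kalmanson condition.
    """
    if D.n < 3:
        raise ValueError("need at least 3 labels for a split decomposition")
    idx = D._permutation_indices(order)
    n = len(idx)
    v = D.values[np.ix_(idx, idx)]
    order = tuple(order)

    splits: list[Split] = []
    min_alpha = np.inf
    for i in range(n):
        for j in range(i + 1, n):
            i1, j1 = (i + 1) % n, (j + 1) % n
            alpha = 0.5 * (v[i, j] + v[i1, j1] - v[i, j1] - v[i1, j])
            min_alpha = min(min_alpha, alpha)
            if alpha > tol:
                splits.append(Split(block=order[i + 1 : j + 1], alpha=float(alpha)))

    system = SplitSystem(order=order, splits=splits, min_alpha=float(min_alpha))
    recon = crofton_reconstruct(system, labels=D.labels)
    system.residual = float(np.max(np.abs(D.values - recon.values))) if splits else (
        float(np.max(np.abs(D.values)))
    )
    return system


def crofton_reconstruct(
    S: SplitSystem, labels: Sequence[str] | None = None
) -> DistanceMatrix:
    """Distance matrix implied by the split system: ``sum(alpha * delta_S)``.

    `labels` fixes the row/column order of the result (default: the system's
    circular order). With no retained splits the result is the zero matrix.
    """
    labels = tuple(labels) if labels is not None else S.order
    if set(labels) != set(S.order):
        raise ValueError("labels must match the split system's label set")
    n = len(labels)
    m = np.zeros((n, n))
    idx = {lab: i for i, lab in enumerate(labels)}
    for s in S.splits:
        side = np.zeros(n, dtype=bool)
        for lab in s.block:
            side[idx[lab]] = True
        sep = side[:, None] != side[None, :]
        m[sep] += s.alpha
    return DistanceMatrix(labels, m, _validate=False)
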