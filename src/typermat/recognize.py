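"""Recognition of type R distance matrices and event-history reconstruction.

A *type R* matrix arises from repeated recombinant insertion (a new gene
``z`` that is a hybrid of adjacent parents ``x`` and ``y`` in proportions
``a : 1 - a``) followed by independent per-gene divergence increments
``delta``. Faithful copies are the special case ``a in {0, 1}``, so additive
tree metrics are type R as well.

The recognizer peels the history in reverse time. For the most recent event
``(x, y : z)`` the data determine everything:

* ``2*delta_z = d(x,z) + d(y,z) - d(x,y)`` — because the recombinant starts
  on the segment between its parents, the triangle slack of ``z`` is pure
  post-event divergence.
* ``f(a) = d(u,z) - a*d(u,x) - (1-a)*d(u,y)`` is *independent of the witness
  u* — the fingerprint of a recombinant. Equating it for two witnesses
  ``u, v`` yields the crossover fraction

      a = ((d_uz + d_vy) - (d_vz + d_uy)) / ((d_ux + d_vy) - (d_vx + d_uy)),

  which must agree across all witness pairs (needs n >= 5); the spread of
  these estimates is the candidate's residual and, for n > 5, the
  over-determination that makes recognition sharp.
* ``2a(1-a) d_xy = f(a) - 2*delta_z + a*d(x,z) + (1-a)*d(y,z)`` recovers the
  ancestral parent distance, and then
  ``delta_x = d(x,z) - (1-a)*d_xy - delta_z``,
  ``delta_y = d(y,z) - a*d_xy - delta_z``.

Divergence of non-participants cannot be attributed to a specific event, so
``delta_u = 0`` for ``u`` outside the triple (the remaining length is charged
to earlier events). Peeling ``z`` and rolling back ``delta_x, delta_y`` gives
the ancestral matrix, and the recursion continues. At ``n = 4`` witnesses run
out: the matrix is a "box" whose circular order is unique but whose four
corner triples are provably equivalent, so recognition reports the box
instead of guessing. At ``n = 3`` every metric is type R.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from statistics import median
from typing import Literal

import numpy as np

from .distmat import DistanceMatrix
from .ordering import Triple, TripleSet

__all__ = [
    "RecoveredEvent",
    "RecognitionResult",
    "BoxParameters",
    "estimate_a",
    "peel_event",
    "peel_copy",
    "is_cherry",
    "box_parameters",
    "recognize_type_r",
    "enumerate_histories",
]


class PeelError(ValueError):
    """A candidate triple is inconsistent with being the last event."""


@dataclass(frozen=True)
class RecoveredEvent:
    """One reconstructed duplication event.

    For a recombinant event ``z`` is the hybrid of ``x`` and ``y`` with
    crossover fraction ``a`` (fraction identical to ``x``); for a copy event
    ``y`` is None, ``a`` is 1.0 and the second flanking gene is unknown.
    ``residual`` is the maximal inconsistency over witness pairs (crossover
    fraction) and single witnesses (``f(a)``); exactly 0 for exact inputs.
    """

    kind: Literal["recombinant", "copy"]
    x: str
    y: str | None
    z: str
    a: float
    f_a: float
    delta_x: float
    delta_y: float
    delta_z: float
    d_xy_ancestral: float
    residual: float

    @property
    def triple(self) -> tuple[str, str | None, str]:
        return (self.x, self.y, self.z)

    def normalized(self) -> tuple[frozenset, str, float]:
        """(parents, child, a-with-parents-sorted) for set comparison."""
        if self.y is None:
            return (frozenset({self.x}), self.z, self.a)
        if self.y < self.x:
            return (frozenset({self.x, self.y}), self.z, 1.0 - self.a)
        return (frozenset({self.x, self.y}), self.z, self.a)


@dataclass(frozen=True)
class BoxParameters:
    """Box-graph representation of a 4-point metric.

    Every 4-point metric is realized by four pendant edges ``h`` hanging off
    a rectangle with half-side lengths ``u >= v >= 0``. The three pairing
    sums satisfy ``A <= B <= C``; ``2u = C - A`` and ``2v = C - B``. The pairs
    summed in ``C`` sit at diagonally opposite corners, which fixes the
    circular order of the four points; the four triples placing each point
    between its circular neighbours are equivalent last events.
    """

    A: float
    B: float
    C: float
    u: float
    v: float
    h: dict[str, float]
    circular_order: tuple[str, str, str, str]
    equivalent_triples: tuple[tuple[str, str, str], ...]

    @property
    def is_tree_like(self) -> bool:
        """Degenerate box (v = 0): the quartet satisfies the 4-point condition."""
        return self.v == 0.0


@dataclass
class RecognitionResult:
    """Outcome of type R recognition.

    ``events`` are in peeling order, i.e. *reverse* temporal order (one valid
    reverse-temporal order; independent events are not disambiguated).
    ``terminal_matrix`` is the 3- or 4-point matrix left when witnesses run
    out; at size 4 ``box`` carries the circular order and the four equivalent
    final triples. ``assumed_genomic_order`` records whether the input label
    order was trusted as the genomic order (the package's input convention);
    ``ambiguous_candidates`` lists same-level ties within tol.
    """

    is_type_r: bool
    events: list[RecoveredEvent] = field(default_factory=list)
    terminal_matrix: DistanceMatrix | None = None
    box: BoxParameters | None = None
    tol: float = 1e-9
    assumed_genomic_order: bool = True
    failure_reason: str | None = None
    ambiguous_candidates: list[list[tuple[str, str, str]]] = field(default_factory=list)

    def __bool__(self) -> bool:
        return self.is_type_r

    def triple_set(self) -> TripleSet:
        """Betweenness triples (temporal order) plus the terminal backbone.

        Under the genomic-order convention the terminal backbone is the
        matrix's own label order (exact); otherwise only the box's circular
        order is known, leaving a rotation/reflection ambiguity.
        """
        triples = []
        for ev in reversed(self.events):
            if ev.kind == "recombinant":
                triples.append(Triple(x=ev.x, y=ev.y, z=ev.z, generic=True))
            else:
                triples.append(Triple(x=ev.x, y=None, z=ev.z, generic=False))
        backbone = self.terminal_matrix.labels if self.terminal_matrix else None
        circular = False
        exact = self.assumed_genomic_order
        if self.box is not None and not self.assumed_genomic_order:
            backbone = self.box.circular_order
            circular = True
        return TripleSet(
            triples=triples,
            backbone=backbone,
            backbone_circular=circular,
            backbone_exact=exact,
        )


# ---------------------------------------------------------------------------
# per-triple estimators
# ---------------------------------------------------------------------------

def estimate_a(
    D: DistanceMatrix, x: str, y: str, z: str, tol: float = 1e-9
) -> tuple[float, float]:
    """Estimate the crossover fraction for candidate triple ``(x, y : z)``.

    Computes the witness-pair formula for every unordered pair ``{u, v}``
    disjoint from the triple and returns ``(median, max spread)``. Pairs with
    near-zero denominator are skipped.

    Raises
    ------
    ValueError
        If ``n < 5`` or every denominator is degenerate (near-tree-like data:
        the crossover fraction is then unconstrained by these witnesses).
    """
    if D.n < 5:
        raise ValueError("estimating a needs at least 5 points (two witnesses)")
    if len({x, y, z}) != 3:
        raise ValueError("x, y, z must be distinct")
    others = [w for w in D.labels if w not in (x, y, z)]
    den_eps = max(tol, 1e-13 * max(D.d_max, 1.0))
    estimates = []
    for u, v in combinations(others, 2):
        num = (D[u, z] + D[v, y]) - (D[v, z] + D[u, y])
        den = (D[u, x] + D[v, y]) - (D[v, x] + D[u, y])
        if abs(den) < den_eps:
            continue
        estimates.append(num / den)
    if not estimates:
        raise ValueError(
            f"all witness denominators degenerate for ({x},{y}:{z}); "
            "data are tree-like around this triple"
        )
    a = float(median(estimates))
    spread = max(abs(e - a) for e in estimates)
    return a, float(spread)


def _f_values(D: DistanceMatrix, x: str, y: str, z: str, a: float) -> list[float]:
    return [
        D[u, z] - a * D[u, x] - (1.0 - a) * D[u, y]
        for u in D.labels
        if u not in (x, y, z)
    ]


def peel_event(
    D: DistanceMatrix,
    x: str,
    y: str,
    z: str,
    a: float,
    tol: float = 1e-9,
    *,
    require_metric: bool = True,
    a_spread: float = 0.0,
) -> tuple[RecoveredEvent, DistanceMatrix]:
    """Undo the recombinant event ``(x, y : z)`` with crossover fraction `a`.

    Recovers ``delta_z``, ``f(a)`` (consistency-checked over all witnesses),
    the ancestral parent distance and ``delta_x, delta_y``, then returns the
    event and the ancestral matrix (``z`` removed, parent rows rolled back).

    Raises
    ------
    PeelError
        If a recovered quantity is negative beyond `tol`, the witnesses
        disagree, or the reduced matrix is not a valid (metric) distance
        matrix — all signals that ``(x, y : z)`` was not the last event.
    """
    tol_a = 1e-6
    if not tol_a < a < 1.0 - tol_a:
        raise PeelError(
            "crossover fraction at the boundary: the parent distance is "
            "unidentifiable (2a(1-a) = 0); use peel_copy instead"
        )
    if D.n < 4:
        raise ValueError("peeling needs at least 4 points")

    delta_z = 0.5 * (D[x, z] + D[y, z] - D[x, y])
    fs = _f_values(D, x, y, z, a)
    f_a = float(median(fs))
    f_spread = max(abs(v - f_a) for v in fs)
    residual = float(max(a_spread, f_spread))

    d_xy = (f_a - 2.0 * delta_z + a * D[x, z] + (1.0 - a) * D[y, z]) / (
        2.0 * a * (1.0 - a)
    )
    delta_x = D[x, z] - (1.0 - a) * d_xy - delta_z
    delta_y = D[y, z] - a * d_xy - delta_z

    for name, val in (
        ("delta_z", delta_z),
        ("delta_x", delta_x),
        ("delta_y", delta_y),
        ("ancestral d(x,y)", d_xy),
    ):
        if val < -tol:
            raise PeelError(f"recovered {name} is negative ({val:.3g})")

    # roll back: remove z, subtract the parents' post-event divergence
    reduced = D.drop(z)
    vals = reduced.values.copy()
    ix, iy = reduced.index(x), reduced.index(y)
    for j in range(reduced.n):
        if j not in (ix, iy):
            vals[ix, j] -= delta_x
            vals[j, ix] = vals[ix, j]
            vals[iy, j] -= delta_y
            vals[j, iy] = vals[iy, j]
    vals[ix, iy] = vals[iy, ix] = d_xy
    if vals.min() < -tol:
        raise PeelError("reduced matrix has negative entries")
    np.clip(vals, 0.0, None, out=vals)
    reduced = DistanceMatrix(reduced.labels, vals, _validate=False)
    if require_metric and not reduced.is_metric(max(tol, 1e-9)):
        raise PeelError("reduced matrix violates the triangle inequality")

    event = RecoveredEvent(
        kind="recombinant", x=x, y=y, z=z, a=float(a), f_a=f_a,
        delta_x=float(delta_x), delta_y=float(delta_y), delta_z=float(delta_z),
        d_xy_ancestral=float(d_xy), residual=residual,
    )
    return event, reduced


def peel_copy(
    D: DistanceMatrix, parent: str, z: str, tol: float = 1e-9
) -> tuple[RecoveredEvent, DistanceMatrix]:
    """Remove ``z``, a faithful copy of `parent` (crossover fraction 0 or 1).

    The copy's own post-event divergence is its pendant length
    ``delta_z = 1/2 min_{u,v} (d(z,u) + d(z,v) - d(u,v))``; the parent's
    share is unidentifiable and stays absorbed in earlier events. The second
    flanking gene of the insertion is unknown.
    """
    others = [u for u in D.labels if u != z]
    if len(others) >= 2:
        delta_z = 0.5 * min(
            D[z, u] + D[z, v] - D[u, v] for u, v in combinations(others, 2)
        )
    else:
        delta_z = D[z, others[0]]
    diffs = [D[z, u] - D[parent, u] for u in D.labels if u not in (parent, z)]
    residual = (max(diffs) - min(diffs)) if diffs else 0.0
    event = RecoveredEvent(
        kind="copy", x=parent, y=None, z=z, a=1.0, f_a=0.0,
        delta_x=0.0, delta_y=0.0, delta_z=float(delta_z),
        d_xy_ancestral=float("nan"), residual=float(residual),
    )
    return event, D.drop(z)


def is_cherry(D: DistanceMatrix, p: str, q: str, tol: float = 1e-12) -> bool:
    """Do ``p`` and ``q`` hang off a common neighbour in the underlying tree?

    True iff ``min_{x,y} (d(p,x) + d(q,y)) - (d(p,q) + d(x,y)) >= -tol`` over
    distinct ``x, y`` outside the pair. The slack is strictly positive for a
    cherry of a binary tree with positive branch lengths; degenerate trees
    (e.g. a star, where every pair is equally a cherry) sit exactly at zero,
    hence the tolerance.
    """
    if D.n < 4:
        raise ValueError("cherry test needs at least 4 points")
    others = [w for w in D.labels if w not in (p, q)]
    best = min(
        (D[p, x] + D[q, y]) - (D[p, q] + D[x, y])
        for x in others
        for y in others
        if x != y
    )
    return best >= -tol


def box_parameters(D: DistanceMatrix) -> BoxParameters:
    """Box-graph parameters of a 4-point metric (the ``n = 4`` base case)."""
    if D.n != 4:
        raise ValueError("box representation is defined for exactly 4 points")
    if not D.is_metric(1e-9):
        raise ValueError("input is not a metric")
    p, q, r, s = D.labels
    pairings = [
        (D[p, q] + D[r, s], ((p, q), (r, s))),
        (D[p, r] + D[q, s], ((p, r), (q, s))),
        (D[p, s] + D[q, r], ((p, s), (q, r))),
    ]
    pairings.sort(key=lambda t: t[0])
    (A, _), (B, _), (C, diag) = pairings
    u = 0.5 * (C - A)
    v = 0.5 * (C - B)
    h = {}
    for x in D.labels:
        others = [w for w in D.labels if w != x]
        h[x] = 0.5 * min(
            D[x, a] + D[x, b] - D[a, b] for a, b in combinations(others, 2)
        )
    # the C-pairs are the diagonals: interleave them into the circular order
    (c0, c2), (c1, c3) = diag
    order = (c0, c1, c2, c3)
    triples = tuple(
        (order[(i - 1) % 4], order[(i + 1) % 4], order[i]) for i in range(4)
    )
    return BoxParameters(
        A=float(A), B=float(B), C=float(C), u=float(u), v=float(v), h=h,
        circular_order=order, equivalent_triples=triples,
    )


# ---------------------------------------------------------------------------
# the recognizer
# ---------------------------------------------------------------------------

def _find_copy(D: DistanceMatrix, tol: float, *, adjacent_only: bool):
    """Scan for a faithful-copy pair; returns (parent, z) or None.

    A copy pair shows a constant shift ``d(z, u) - d(p, u) = delta_z -
    delta_p`` across all witnesses ``u``. Under the genomic-order convention
    only adjacent pairs qualify (a tandem copy whose pair was never split by
    a later insertion is still adjacent).
    """
    n = D.n
    v = D.values
    pairs = (
        ((i, i + 1) for i in range(n - 1))
        if adjacent_only
        else ((i, j) for i in range(n) for j in range(i + 1, n))
    )
    for i, j in pairs:
        mask = np.ones(n, dtype=bool)
        mask[[i, j]] = False
        diffs = v[j, mask] - v[i, mask]
        if diffs.size and diffs.max() - diffs.min() <= 2.0 * tol:
            return D.labels[i], D.labels[j]
    return None


def _candidate_triples(work: DistanceMatrix, genomic: bool):
    """Candidate triples (x, y : z) for the last event, in scan order.

    Under the genomic-order convention the child of a peelable (most
    recent or maximal) event must sit directly between its parents — any
    gene inserted into the gap later would descend from the child, making
    the event non-maximal — so only consecutive label triples qualify.
    Without the convention every triple with ``x`` before ``y`` is tried.
    """
    labels = work.labels
    if genomic:
        for i in range(1, work.n - 1):
            yield labels[i - 1], labels[i + 1], labels[i]
    else:
        for ix in range(work.n):
            for iy in range(ix + 1, work.n):
                for z in labels:
                    if z not in (labels[ix], labels[iy]):
                        yield labels[ix], labels[iy], z


def recognize_type_r(
    D: DistanceMatrix,
    tol: float = 1e-9,
    *,
    use_genomic_order: bool = True,
    require_metric: bool = True,
    collect_ties: bool = False,
) -> RecognitionResult:
    """Decide whether ``D`` is type R and reconstruct its event history.

    Candidate triples ``(x, y : z)`` are scored by the witness-consistency
    residual plus peel feasibility; the best candidate within `tol` is
    peeled and the search recurses. Copy pairs (constant row shift) are
    peeled first. Terminates at ``n = 3`` (always type R) or at ``n = 4``
    with the box base case.

    By default the label order is trusted as the genomic order (the
    package's input convention), which restricts candidates to consecutive
    triples — this is what lets block-duplication histories be rejected,
    and it resolves the cut ambiguity of the circular order: without it a
    gene at either end of the cluster whose lineage runs through a single
    event can be "rotated past the cut", yielding an equally exact but
    different event history. With ``use_genomic_order=False`` all triples
    are searched (worst case ``O(n^6)`` as for the restricted scan the
    per-level work drops to ``O(n^3)``) and the result may be any of the
    equivalent histories.

    With `collect_ties`, same-level candidates within `tol` of the accepted
    one are reported in ``ambiguous_candidates`` instead of silently dropped.
    """
    if D.n < 3:
        raise ValueError("recognition needs at least 3 points")
    if not D.is_metric(max(tol, 1e-9)):
        raise ValueError("input is not a metric")

    work = D.copy()
    events: list[RecoveredEvent] = []
    ambiguous: list[list[tuple[str, str, str]]] = []

    while work.n >= 4:
        copy_pair = _find_copy(work, tol, adjacent_only=use_genomic_order)
        if copy_pair is not None:
            parent, z = copy_pair
            ev, work = peel_copy(work, parent, z, tol)
            events.append(ev)
            continue

        if work.n == 4:
            break  # witnesses exhausted: box base case below

        best = None  # (residual, scan_pos, event, reduced)
        ties: list[tuple[str, str, str]] = []
        for scan_pos, (x, y, z) in enumerate(
            _candidate_triples(work, use_genomic_order)
        ):
            try:
                a, spread = estimate_a(work, x, y, z, tol)
            except ValueError:
                continue
            if not -1e-6 <= a <= 1.0 + 1e-6 or spread > tol:
                continue
            a = min(max(a, 0.0), 1.0)
            try:
                ev, reduced = peel_event(
                    work, x, y, z, a, tol,
                    require_metric=require_metric, a_spread=spread,
                )
            except PeelError:
                continue
            if ev.residual <= tol:
                if best is None or ev.residual < best[0]:
                    if best is not None and collect_ties:
                        ties.append(best[2].triple)
                    best = (ev.residual, scan_pos, ev, reduced)
                elif collect_ties:
                    ties.append((x, y, z))
        if best is None:
            return RecognitionResult(
                is_type_r=False,
                events=events,
                terminal_matrix=work,
                tol=tol,
                assumed_genomic_order=use_genomic_order,
                failure_reason=(
                    f"no feasible last event among {work.n} genes: no "
                    "candidate triple has a witness-consistent crossover "
                    "fraction and nonnegative rollback"
                ),
                ambiguous_candidates=ambiguous,
            )
        if ties:
            ambiguous.append(ties)
        events.append(best[2])
        work = best[3]

    box = None
    if work.n == 4:
        box = box_parameters(work)
    return RecognitionResult(
        is_type_r=True,
        events=events,
        terminal_matrix=work,
        box=box,
        tol=tol,
        assumed_genomic_order=use_genomic_order,
        ambiguous_candidates=ambiguous,
    )


# ---------------------------------------------------------------------------
# exhaustive history enumeration
# ---------------------------------------------------------------------------

def _feasible_moves(work: DistanceMatrix, tol: float, genomic: bool):
    """All exactly feasible peels (copies and recombinants) of one level."""
    moves = []
    n = work.n
    labels = work.labels
    v = work.values
    pairs = (
        ((i, i + 1) for i in range(n - 1))
        if genomic
        else ((i, j) for i in range(n) for j in range(i + 1, n))
    )
    for i, j in pairs:
        mask = np.ones(n, dtype=bool)
        mask[[i, j]] = False
        diffs = v[j, mask] - v[i, mask]
        if diffs.size and diffs.max() - diffs.min() <= 2.0 * tol:
            moves.append(peel_copy(work, labels[i], labels[j], tol))
    if n >= 5:
        for x, y, z in _candidate_triples(work, genomic):
            try:
                a, spread = estimate_a(work, x, y, z, tol)
            except ValueError:
                continue
            if not -1e-6 <= a <= 1.0 + 1e-6 or spread > tol:
                continue
            try:
                ev, reduced = peel_event(
                    work, x, y, z, min(max(a, 0.0), 1.0), tol, a_spread=spread
                )
            except PeelError:
                continue
            if ev.residual <= tol:
                moves.append((ev, reduced))
    return moves


def enumerate_histories(
    D: DistanceMatrix,
    tol: float = 1e-9,
    *,
    use_genomic_order: bool = True,
    cap: int = 200,
) -> list[list[RecoveredEvent]]:
    """All exact event histories of a type R matrix, up to `cap` of them.

    The event history of a type R matrix is in general *not* unique: a
    nested chain — ``w`` born of ``(x, y)``, then ``v`` born of ``(x, w)`` —
    yields exactly the same distances as the re-attributed chain ``v`` born
    of ``(x, y)`` then ``w`` of ``(v, y)``, with suitably transformed
    crossover fractions and divergence increments. This function explores
    every exactly feasible peel by depth-first search and returns the
    distinct complete histories (each a list of events in peeling order,
    deduplicated by event multiset). :func:`recognize_type_r` returns one
    canonical member of this set.
    """
    if D.n < 3:
        raise ValueError("enumeration needs at least 3 points")
    histories: list[list[RecoveredEvent]] = []
    seen: set[frozenset] = set()

    def key(events) -> frozenset:
        return frozenset(ev.normalized() for ev in events)

    def dfs(work: DistanceMatrix, events: list[RecoveredEvent]):
        if len(histories) >= cap:
            return
        if work.n <= 4:
            moves = _feasible_moves(work, tol, use_genomic_order) if work.n == 4 else []
            terminal_ok = work.n == 3 or (
                work.n == 4 and work.is_metric(max(tol, 1e-9))
            )
            if terminal_ok:
                k = key(events)
                if k not in seen:
                    seen.add(k)
                    histories.append(list(events))
            for ev, reduced in moves:  # n=4 copy peels still possible
                if ev.kind == "copy":
                    dfs(reduced, events + [ev])
            return
        for ev, reduced in _feasible_moves(work, tol, use_genomic_order):
            dfs(reduced, events + [ev])

    dfs(D.copy(), [])
    return histories
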