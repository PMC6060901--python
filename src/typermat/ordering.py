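"""Assembly of genomic gene orders from betweenness triples.

Every recombinant event contributes a betweenness triple ``(x, y : z)`` — the
hybrid ``z`` sits between its parents in the genomic order. General
betweenness sorting is NP-complete, but type R histories carry far more
structure: each triple has at most one predecessor, so the triples form
paths that can be concatenated end-to-end in linear time.

Faithful copies (``a`` of 0 or 1) only say "adjacent to the parent at
insertion time" with an unknown side. Clones of the same parent that no
later hybrid event resolves therefore have no defined relative order; the
assembler returns an ordered backbone plus unordered clone groups instead of
enumerating the (potentially exponential) set of linear extensions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import permutations
from typing import Sequence

__all__ = [
    "Triple",
    "TripleSet",
    "LinearityResult",
    "assemble_linear_order",
    "colinearity_score",
    "triples_from_log",
]


@dataclass(frozen=True)
class Triple:
    """Betweenness fact ``(x, y : z)``: z lies between x and y.

    For a copy event (``generic=False``) the second flank is unknown:
    ``y is None`` and the fact degrades to "z adjacent to x at insertion".
    """

    x: str
    y: str | None
    z: str
    generic: bool = True

    def parents(self) -> frozenset:
        return frozenset({self.x}) if self.y is None else frozenset({self.x, self.y})


@dataclass
class TripleSet:
    """Triples of a history, optionally with the terminal backbone.

    ``backbone`` holds labels whose events are older than any triple (the
    two ancestral genes of a simulation log, or the 3-/4-point terminal
    matrix of recognition; ``backbone_circular`` marks the 4-point box whose
    linearization is only fixed up to rotation/reflection).
    """

    triples: list[Triple] = field(default_factory=list)
    backbone: tuple[str, ...] | None = None
    backbone_circular: bool = False
    backbone_exact: bool = False  # backbone is the known genomic (sub)order

    def labels(self) -> set[str]:
        out = set(self.backbone or ())
        for t in self.triples:
            out.add(t.x)
            out.add(t.z)
            if t.y is not None:
                out.add(t.y)
        return out


@dataclass
class LinearityResult:
    """Outcome of linear-order assembly.

    ``orders`` lists admissible genomic orders (canonical orientation:
    lexicographically smaller endpoint first); a single entry means the
    order is unique up to reversal. ``clone_groups`` maps a parent to clones
    with no defined order among themselves; ``ambiguity_flags`` explains any
    remaining freedom. ``join_ops`` counts path-join operations (one per
    triple — the linear-time contract).
    """

    is_linear: bool
    orders: list[tuple[str, ...]] = field(default_factory=list)
    clone_groups: dict[str, tuple[str, ...]] = field(default_factory=dict)
    ambiguity_flags: list[str] = field(default_factory=list)
    join_ops: int = 0

    def __bool__(self) -> bool:
        return self.is_linear

    @property
    def order(self) -> tuple[str, ...] | None:
        return self.orders[0] if self.orders else None


def _canonical(order: Sequence[str]) -> tuple[str, ...]:
    order = tuple(order)
    return order if order[0] <= order[-1] else order[::-1]


def triples_from_log(log) -> TripleSet:
    """Ground-truth triples of a simulation :class:`~typermat.simulate.EventLog`."""
    triples: list[Triple] = []
    for e in log.events:
        if e.time_index == 0:
            continue  # the ancestral duplication; its pair is the backbone
        if e.kind == "recombinant":
            triples.append(Triple(x=e.parents[0], y=e.parents[1], z=e.child, generic=True))
        elif e.kind == "tandem":
            triples.append(Triple(x=e.parents[0], y=None, z=e.child, generic=False))
        else:
            raise ValueError(
                "block events do not yield betweenness triples (the history "
                "is not linear type R)"
            )
    return TripleSet(triples=triples, backbone=log.initial_labels)


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------

def assemble_linear_order(
    T: TripleSet,
    *,
    enumerate_orders: bool = False,
    cap: int = 256,
) -> LinearityResult:
    """Assemble the genomic order implied by a set of betweenness triples.

    Generic triples are resolved by the path-concatenation construction:
    the adjacencies of the final order are exactly the parent-child pairs
    ``{x, z}``, ``{z, y}`` that no later event subdivided, found with O(1)
    hash-map work per triple. The result is linear iff those adjacencies
    form a single path visiting every label once.

    Copy triples are attached as clone groups next to their parent; with
    `enumerate_orders` the admissible placements are enumerated up to `cap`
    orders, otherwise one representative order is returned with the
    ambiguity flagged.

    A triple set with a backbone of more than two labels (recognition
    output, where the oldest events are unresolvable) is assembled by
    forward replay instead: every admissible linearization of the backbone
    is grown by inserting each child between its parents; linearizations
    that ever require non-adjacent parents are rejected.
    """
    children = [t.z for t in T.triples]
    if len(set(children)) != len(children):
        raise ValueError("a label appears as offspring of more than one event")

    has_copies = any(not t.generic for t in T.triples)
    has_generic = any(t.generic for t in T.triples)
    if T.backbone is not None and (
        len(T.backbone) > 2 or (has_copies and has_generic)
    ):
        # mixed copy/hybrid histories and recognition output (unresolvable
        # terminal core) are assembled by capped forward replay
        return _assemble_by_replay(T, cap=cap)

    generic = [t for t in T.triples if t.generic]
    copies = [t for t in T.triples if not t.generic]
    labels = T.labels()

    parent_keys = {t.parents() for t in generic}
    adjacencies: list[frozenset] = []
    join_ops = 0
    for t in generic:
        join_ops += 1
        for pair in (frozenset({t.x, t.z}), frozenset({t.z, t.y})):
            if pair not in parent_keys:
                adjacencies.append(pair)
    if T.backbone is not None and len(T.backbone) == 2:
        root = frozenset(T.backbone)
        if root not in parent_keys and not copies:
            adjacencies.append(root)

    backbone_labels = set()
    for pair in adjacencies:
        backbone_labels |= pair

    clone_groups: dict[str, list[str]] = {}
    flags: list[str] = []
    resolved_parent: dict[str, str] = {}
    for t in copies:
        p = t.x
        while p in resolved_parent:
            p = resolved_parent[p]
        if t.z in backbone_labels:
            continue  # a later hybrid event pinned this clone down
        resolved_parent[t.z] = p
        clone_groups.setdefault(p, []).append(t.z)

    if not adjacencies:
        # no generic structure at all (pure tandem history or single pair)
        if T.backbone is not None and len(T.backbone) == 2:
            backbone_order = list(T.backbone)
        elif len(labels) - sum(len(v) for v in clone_groups.values()) <= 1:
            roots = sorted(labels - set(resolved_parent))
            backbone_order = roots
        else:
            return LinearityResult(is_linear=False, join_ops=join_ops)
    else:
        backbone_order = _path_from_adjacencies(adjacencies, backbone_labels)
        if backbone_order is None:
            return LinearityResult(is_linear=False, join_ops=join_ops)

    loose = labels - set(backbone_order) - set(resolved_parent)
    if loose:
        return LinearityResult(
            is_linear=False,
            join_ops=join_ops,
            ambiguity_flags=[f"labels not reachable from any triple: {sorted(loose)}"],
        )
    for p in clone_groups:
        if p not in backbone_order:
            return LinearityResult(
                is_linear=False,
                join_ops=join_ops,
                ambiguity_flags=[f"clone parent {p!r} not on the backbone"],
            )

    groups = {p: tuple(sorted(g)) for p, g in clone_groups.items()}
    if groups:
        for p, g in groups.items():
            flags.append(
                f"clones of {p!r} have no defined order among themselves: {list(g)}"
            )

    orders = _place_clones(
        backbone_order, groups, enumerate_orders=enumerate_orders, cap=cap
    )
    orders = sorted({_canonical(o) for o in orders})
    return LinearityResult(
        is_linear=True,
        orders=orders,
        clone_groups=groups,
        ambiguity_flags=flags,
        join_ops=join_ops,
    )


def _path_from_adjacencies(adjacencies, labels) -> list[str] | None:
    """Walk the adjacency pairs into a single simple path, or None."""
    if len(adjacencies) != len(set(adjacencies)):
        return None
    nbrs: dict[str, list[str]] = {lab: [] for lab in labels}
    for pair in adjacencies:
        a, b = tuple(pair)
        nbrs[a].append(b)
        nbrs[b].append(a)
    if len(adjacencies) != len(labels) - 1:
        return None
    ends = [lab for lab, ns in nbrs.items() if len(ns) == 1]
    if len(ends) != 2 or any(len(ns) > 2 for ns in nbrs.values()):
        return None
    start = min(ends)
    order = [start]
    prev = None
    while True:
        nxt = [w for w in nbrs[order[-1]] if w != prev]
        if not nxt:
            break
        prev = order[-1]
        order.append(nxt[0])
    return order if len(order) == len(labels) else None


def _place_clones(backbone, groups, *, enumerate_orders, cap):
    """Insert clone groups contiguously next to their parent."""
    if not groups:
        return [tuple(backbone)]
    if not enumerate_orders:
        order = []
        for lab in backbone:
            order.append(lab)
            order.extend(groups.get(lab, ()))
        return [tuple(order)]
    # enumerate: per group, every permutation and every left/right split
    results = [list(backbone)]
    for p, g in groups.items():
        new_results = []
        for base in results:
            i = base.index(p)
            for perm in permutations(g):
                for split in range(len(perm) + 1):
                    left, right = perm[:split], perm[split:]
                    cand = base[:i] + list(left) + [p] + list(right) + base[i + 1 :]
                    new_results.append(cand)
                    if len(new_results) >= cap:
                        break
                if len(new_results) >= cap:
                    break
            if len(new_results) >= cap:
                break
        results = new_results
    return [tuple(r) for r in results]


def _assemble_by_replay(T: TripleSet, cap: int) -> LinearityResult:
    """Grow candidate orders from a 3-/4-point backbone by forward insertion."""
    backbone = tuple(T.backbone)
    if T.backbone_exact:
        seeds = [backbone]
    elif T.backbone_circular:
        rots = [backbone[i:] + backbone[:i] for i in range(len(backbone))]
        seeds = rots + [r[::-1] for r in rots]
    else:
        seeds = list(permutations(backbone))
    seeds = [list(s) for s in seeds]

    states = seeds
    join_ops = 0
    for t in T.triples:  # temporal order
        join_ops += 1
        new_states = []
        for order in states:
            if t.generic:
                ix, iy = order.index(t.x), order.index(t.y)
                if abs(ix - iy) != 1:
                    continue
                pos = max(ix, iy)
                new_states.append(order[:pos] + [t.z] + order[pos:])
            else:
                i = order.index(t.x)
                new_states.append(order[:i] + [t.z] + order[i:])
                new_states.append(order[: i + 1] + [t.z] + order[i + 1 :])
        states = new_states[:cap]
        if not states:
            return LinearityResult(is_linear=False, join_ops=join_ops)

    orders = sorted({_canonical(o) for o in states})
    flags = []
    if len(orders) > 1:
        flags.append(f"{len(orders)} admissible orders (terminal/copy ambiguity)")
    return LinearityResult(
        is_linear=True, orders=orders, ambiguity_flags=flags, join_ops=join_ops
    )


def colinearity_score(order_a: Sequence[str], order_b: Sequence[str]) -> float:
    """Fraction of adjacent pairs of `order_a` that are adjacent in `order_b`.

    1.0 for identical or reversed orders; ~2/n for unrelated random orders.
    Invariant under reversal of either argument.
    """
    a, b = list(order_a), list(order_b)
    if set(a) != set(b) or len(a) != len(b):
        raise ValueError("orders must be permutations of the same label set")
    if len(a) < 2:
        raise ValueError("need at least 2 labels")
    adj_b = {frozenset(p) for p in zip(b[:-1], b[1:])}
    hits = sum(1 for p in zip(a[:-1], a[1:]) if frozenset(p) in adj_b)
    return hits / (len(a) - 1)
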