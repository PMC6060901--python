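"""Direct simulation of gene-cluster distance matrices.

Gene clusters expand by unequal crossing over. When the crossover breakpoint
falls *between* genes the new gene is a faithful tandem copy of one parent;
when it falls *inside* a gene (Gehring's model) the new gene is a hybrid of
its two genomic neighbours ``x`` and ``y``, composed of fractions ``a`` and
``1 - a`` identical to each. At the distance-matrix level a recombinant child
``z`` inserted between adjacent parents satisfies

    d(z, u) = a*d(x, u) + (1 - a)*d(y, u)      for u not in {x, y}
    d(z, x) = (1 - a)*d(x, y),   d(z, y) = a*d(x, y)

and after every event each gene ``p`` diverges independently, adding
``delta_p + delta_q`` to every distance ``d(p, q)``. Simulating the matrix
directly (rather than sequences) separates the model's exact structure from
sampling noise: tandem-only histories give additive tree metrics, hybrid
histories give *linear type R* matrices, and block duplications give tree
metrics whose genomic order is discordant with the tree.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np

from .distmat import DistanceMatrix

__all__ = [
    "DuplicationEvent",
    "EventLog",
    "SimConfig",
    "duplicate_leaf",
    "recombine_leaf",
    "add_deltas",
    "block_duplicate",
    "simulate_cluster_matrix",
    "replay_events",
]


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------

def duplicate_leaf(
    D: DistanceMatrix, x: str, z: str, *, side: Literal["before", "after"] = "after"
) -> DistanceMatrix:
    """Tandem duplication: insert a faithful copy ``z`` of ``x`` next to it.

    The new row/column duplicates that of ``x`` (``d(z, y) = d(x, y)``,
    ``d(x, z) = 0``); ``z`` is placed immediately before or after ``x`` so the
    label order keeps encoding the genomic order.
    """
    if z in D:
        raise ValueError(f"duplicate label {z!r}")
    i = D.index(x)
    pos = i if side == "before" else i + 1
    row = {y: D[x, y] for y in D.labels if y != x}
    row[x] = 0.0
    return D.insert(pos, z, row)


def recombine_leaf(
    D: DistanceMatrix,
    x: str,
    y: str,
    a: float,
    z: str,
    *,
    allow_nonadjacent: bool = False,
) -> DistanceMatrix:
    """Unequal crossing over within genes: ``z`` a hybrid of neighbours x, y.

    ``a`` is the fraction of ``z`` identical to ``x``. Parents must be
    adjacent in the genomic order (that is what makes the resulting matrix
    *linear* type R); `allow_nonadjacent` lifts the restriction to construct
    non-linear counterexamples.
    """
    if not 0.0 <= a <= 1.0:
        raise ValueError("crossover fraction a must lie in [0, 1]")
    if z in D:
        raise ValueError(f"duplicate label {z!r}")
    ix, iy = D.index(x), D.index(y)
    if abs(ix - iy) != 1 and not allow_nonadjacent:
        raise ValueError(
            f"parents {x!r} and {y!r} are not adjacent in the genomic order"
        )
    row = {
        u: a * D[x, u] + (1.0 - a) * D[y, u]
        for u in D.labels
        if u not in (x, y)
    }
    row[x] = (1.0 - a) * D[x, y]
    row[y] = a * D[x, y]
    return D.insert(max(ix, iy) if abs(ix - iy) == 1 else ix + 1, z, row)


def add_deltas(D: DistanceMatrix, deltas: Mapping[str, float]) -> DistanceMatrix:
    """Independent divergence: ``d'(p, q) = d(p, q) + delta_p + delta_q``.

    Adding per-leaf increments preserves the additive-tree property (each
    increment lengthens a pendant edge), and more generally keeps a type R
    matrix type R.
    """
    dv = np.zeros(D.n)
    for lab, val in deltas.items():
        if val < 0:
            raise ValueError(f"negative delta for {lab!r}")
        dv[D.index(lab)] = float(val)
    grow = dv[:, None] + dv[None, :]
    np.fill_diagonal(grow, 0.0)
    return DistanceMatrix(D.labels, D.values + grow, _validate=False)


def block_duplicate(
    D: DistanceMatrix,
    block: Sequence[str],
    new_labels: Sequence[str],
    *,
    insert_after: int | None = None,
) -> DistanceMatrix:
    """Duplicate a contiguous block of >= 1 genes as a unit.

    The copies keep the within-block distances and sit at distance 0 from
    their originals; they are inserted contiguously, by default immediately
    after the block (a tandem block duplication). A single-gene block is the
    same as :func:`duplicate_leaf`.
    """
    block = list(block)
    idx = D.indices(block)
    if idx != list(range(idx[0], idx[0] + len(block))):
        raise ValueError("block must be a contiguous interval of the label order")
    if len(new_labels) != len(block):
        raise ValueError("need one new label per block member")
    pos = idx[-1] + 1 if insert_after is None else insert_after
    out = D
    for k, (orig, new) in enumerate(zip(block, new_labels)):
        row = {u: out[orig, u] for u in out.labels if u != orig}
        row[orig] = 0.0
        for prev_orig, prev_new in zip(block[:k], new_labels[:k]):
            row[prev_new] = out[orig, prev_orig]
        out = out.insert(pos + k, new, row)
    return out


# ---------------------------------------------------------------------------
# event bookkeeping
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DuplicationEvent:
    """One duplication event plus the divergence increments that follow it.

    ``kind`` is ``"tandem"`` (faithful copy of a single parent),
    ``"recombinant"`` (hybrid of two adjacent parents with crossover fraction
    ``a``) or ``"block"`` (a contiguous block copied as a unit; ``child`` is
    then a tuple of new labels). ``deltas`` maps every gene present *after*
    the duplication to its divergence increment for this step.
    """

    kind: Literal["tandem", "recombinant", "block"]
    parents: tuple[str, ...]
    child: str | tuple[str, ...]
    a: float | None
    deltas: dict[str, float]
    time_index: int
    side: Literal["before", "after"] | None = None  # tandem insertion side

    def children(self) -> tuple[str, ...]:
        return self.child if isinstance(self.child, tuple) else (self.child,)


@dataclass
class EventLog:
    """Full ground truth of a simulation run.

    Replaying ``events`` from the two initial labels reproduces the returned
    matrix exactly (bit-identical floats). ``total_branch_length`` is the sum
    of all divergence increments; for tandem-only histories it equals the
    total edge length of the underlying gene tree, so the shortest
    Hamiltonian path has length ``2*total_branch_length - d_max``.
    """

    initial_labels: tuple[str, str]
    events: list[DuplicationEvent]
    genomic_order: tuple[str, ...]
    total_branch_length: float
    seed: int | None
    config: "SimConfig | None" = None

    def recombination_triples(self) -> list[tuple[str, str, str, float]]:
        """(x, y, z, a) for every recombinant event, in temporal order."""
        return [
            (e.parents[0], e.parents[1], e.child, e.a)
            for e in self.events
            if e.kind == "recombinant"
        ]


@dataclass
class SimConfig:
    """Parameters of the matrix-level simulator.

    Attributes
    ----------
    n_final : int
        Number of genes in the final cluster (>= 3).
    mode : str
        ``"tandem"`` — every event a faithful copy (tree metric);
        ``"gehring"`` — every event a hybrid (linear type R);
        ``"mixed"`` — copy with probability ``psi``, hybrid otherwise;
        ``"block"`` — repeated duplication of blocks of ``block_size`` genes
        (negative control: genomic order discordant with the tree).
    psi : float
        Probability that a duplication is a pure copy (mixed mode).
    a_range : (float, float)
        Crossover fraction ``a`` is drawn uniformly from this interval.
    delta_rate_range : (float, float)
        Per-step divergence is ``delta = r * dt`` with ``dt = 1/n_final`` and
        the rate ``r`` drawn uniformly from this interval, independently per
        gene per step (a constant duplication rate makes ``dt`` the natural
        time unit).
    equal_rates : bool
        Draw one shared rate per step instead (makes hybrid histories exactly
        Robinsonian in genomic order).
    block_size : int
        Block length for ``"block"`` mode.
    seed : int
        RNG seed; runs are bit-reproducible.
    """

    n_final: int
    mode: Literal["tandem", "gehring", "mixed", "block"] = "gehring"
    psi: float = 0.0
    a_range: tuple[float, float] = (0.0, 1.0)
    delta_rate_range: tuple[float, float] = (0.0, 1.0)
    equal_rates: bool = False
    block_size: int = 2
    seed: int = 0
    label_prefix: str = "g"

    def __post_init__(self):
        if self.n_final < 3:
            raise ValueError("n_final must be >= 3")
        if self.mode not in ("tandem", "gehring", "mixed", "block"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if not 0.0 <= self.psi <= 1.0:
            raise ValueError("psi must lie in [0, 1]")
        if not 0.0 <= self.a_range[0] <= self.a_range[1] <= 1.0:
            raise ValueError("a_range must be within [0, 1]")
        if self.block_size < 1:
            raise ValueError("block_size must be >= 1")


# ---------------------------------------------------------------------------
# the simulator
# ---------------------------------------------------------------------------

def _draw_deltas(labels, rng, cfg: SimConfig) -> dict[str, float]:
    dt = 1.0 / cfg.n_final
    lo, hi = cfg.delta_rate_range
    if cfg.equal_rates:
        r = rng.uniform(lo, hi)
        return {lab: r * dt for lab in labels}
    return {lab: rng.uniform(lo, hi) * dt for lab in labels}


def simulate_cluster_matrix(cfg: SimConfig) -> tuple[DistanceMatrix, EventLog]:
    """Grow a cluster from one ancestral gene to ``cfg.n_final`` genes.

    The ancestral gene is duplicated at t=0 (two identical genes at distance
    0); every step thereafter performs one duplication according to ``mode``
    followed by a round of independent divergence of all genes. Deterministic
    given ``cfg.seed``.

    Returns
    -------
    (DistanceMatrix, EventLog)
        The final matrix, labels in genomic order, and the replayable ground
        truth.
    """
    rng = np.random.default_rng(cfg.seed)
    counter = 2
    g1, g2 = f"{cfg.label_prefix}1", f"{cfg.label_prefix}2"
    D = DistanceMatrix.zeros([g1, g2])
    events: list[DuplicationEvent] = []

    # t=0: the ancestral duplication, then the first divergence round.
    deltas = _draw_deltas(D.labels, rng, cfg)
    D = add_deltas(D, deltas)
    events.append(
        DuplicationEvent(
            kind="tandem", parents=(g1,), child=g2, a=1.0,
            deltas=deltas, time_index=0, side="after",
        )
    )

    t = 0
    while D.n < cfg.n_final:
        t += 1
        mode = cfg.mode
        if mode == "mixed":
            mode = "tandem" if rng.random() < cfg.psi else "gehring"

        if mode == "block" and not (
            D.n >= cfg.block_size and D.n + cfg.block_size <= cfg.n_final
        ):
            mode = "tandem"  # pad block histories to the target size

        if mode == "tandem":
            x = D.labels[rng.integers(D.n)]
            counter += 1
            z = f"{cfg.label_prefix}{counter}"
            side = "after" if rng.random() < 0.5 else "before"
            D = duplicate_leaf(D, x, z, side=side)
            deltas = _draw_deltas(D.labels, rng, cfg)
            D = add_deltas(D, deltas)
            events.append(
                DuplicationEvent(
                    kind="tandem", parents=(x,), child=z, a=1.0,
                    deltas=deltas, time_index=t, side=side,
                )
            )
        elif mode == "gehring":
            i = int(rng.integers(D.n - 1))
            x, y = D.labels[i], D.labels[i + 1]
            a = float(rng.uniform(*cfg.a_range))
            counter += 1
            z = f"{cfg.label_prefix}{counter}"
            D = recombine_leaf(D, x, y, a, z)
            deltas = _draw_deltas(D.labels, rng, cfg)
            D = add_deltas(D, deltas)
            events.append(
                DuplicationEvent(
                    kind="recombinant", parents=(x, y), child=z, a=a,
                    deltas=deltas, time_index=t,
                )
            )
        else:  # block
            start = int(rng.integers(D.n - cfg.block_size + 1))
            block = list(D.labels[start : start + cfg.block_size])
            new = []
            for _ in block:
                counter += 1
                new.append(f"{cfg.label_prefix}{counter}")
            D = block_duplicate(D, block, new)
            deltas = _draw_deltas(D.labels, rng, cfg)
            D = add_deltas(D, deltas)
            events.append(
                DuplicationEvent(
                    kind="block", parents=tuple(block), child=tuple(new),
                    a=None, deltas=deltas, time_index=t,
                )
            )

    total = sum(v for e in events for v in e.deltas.values())
    log = EventLog(
        initial_labels=(g1, g2),
        events=events,
        genomic_order=D.labels,
        total_branch_length=total,
        seed=cfg.seed,
        config=cfg,
    )
    return D, log


def replay_events(log: EventLog) -> DistanceMatrix:
    """Re-apply the logged events from scratch; must reproduce the matrix."""
    g1, g2 = log.initial_labels
    D = DistanceMatrix.zeros([g1, g2])
    for e in log.events:
        if e.time_index == 0:
            pass  # the ancestral duplication created the initial 2x2 matrix
        elif e.kind == "tandem":
            D = duplicate_leaf(D, e.parents[0], e.child, side=e.side or "after")
        elif e.kind == "recombinant":
            D = recombine_leaf(D, e.parents[0], e.parents[1], e.a, e.child)
        elif e.kind == "block":
            D = block_duplicate(D, list(e.parents), list(e.children()))
        else:  # pragma: no cover
            raise ValueError(f"unknown event kind {e.kind!r}")
        D = add_deltas(D, e.deltas)
    return D
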