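"""Sequence-level simulation of gene-cluster expansion.

The matrix-level simulator (:mod:`typermat.simulate`) produces *exact* type R
structure; this module adds the stochastic noise of real sequence evolution.
A random protein of length ``N`` over 21 amino acids (the 20 standard ones
plus selenocysteine) is copied once, and the cluster then grows step by step:
a crossover breakpoint ``k`` is drawn uniformly inside the gene, the child is
the concatenation of the left parent's prefix ``y[1..k]`` and the right
parent's suffix ``x[k+1..N]`` and is inserted between them (with probability
``psi`` the breakpoint falls between genes and the child is instead a
faithful copy of one parent). After every step each sequence mutates
site-wise with probability ``mu`` to a uniformly chosen *different* residue.

Mismatch fractions between the final sequences, corrected for multiple hits
by the Jukes–Cantor transformation, approximate a linear type R matrix; the
approximation sharpens as ``N`` grows. ``mu`` should satisfy
``1/N <~ mu <~ 1/n`` so each step is measurable but distances do not
saturate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .distmat import DistanceMatrix

__all__ = [
    "AMINO_ACIDS",
    "SeqEvent",
    "SequenceFamily",
    "SeqSimConfig",
    "simulate_sequences",
    "p_distances",
    "jukes_cantor",
    "jukes_cantor_matrix",
]

#: 20 standard amino acids plus selenocysteine (U)
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWYU"


@dataclass(frozen=True)
class SeqEvent:
    """One sequence-level duplication: a crossover or a faithful copy.

    For a crossover, ``child = y[:k] + x[k:]`` with ``x`` the left and ``y``
    the right parent, so the *expected* fraction of the child identical to
    ``x`` is ``a = (N - k)/N``.
    """

    kind: Literal["tandem", "recombinant"]
    parents: tuple[str, ...]
    child: str
    breakpoint: int | None
    a_expected: float
    time_index: int


@dataclass
class SequenceFamily:
    """Aligned equal-length sequences of a simulated cluster.

    ``sequences`` is an (n, N) integer array of alphabet indices; labels are
    in genomic order. Since no indels are simulated the family is its own
    alignment.
    """

    labels: tuple[str, ...]
    sequences: np.ndarray
    alphabet: str = AMINO_ACIDS
    events: list[SeqEvent] = field(default_factory=list)
    seed: int | None = None

    @property
    def n(self) -> int:
        return len(self.labels)

    @property
    def length(self) -> int:
        return int(self.sequences.shape[1])

    def as_strings(self) -> dict[str, str]:
        lut = np.array(list(self.alphabet))
        return {
            lab: "".join(lut[row]) for lab, row in zip(self.labels, self.sequences)
        }


@dataclass
class SeqSimConfig:
    """Parameters of the sequence simulator.

    ``N`` — sequence length (default 1000). ``mu`` — per-site per-step
    substitution probability; keep ``1/N <~ mu <~ 1/n_final``. ``psi`` —
    probability that a step copies a parent instead of recombining
    (``psi=1`` is the tree-like limit).
    """

    n_final: int
    N: int = 1000
    mu: float = 0.01
    psi: float = 0.0
    seed: int = 0
    alphabet: str = AMINO_ACIDS
    label_prefix: str = "g"

    def __post_init__(self):
        if self.n_final < 2:
            raise ValueError("n_final must be >= 2")
        if self.N < 2:
            raise ValueError("N must be >= 2")
        if not 0.0 <= self.mu <= 1.0:
            raise ValueError("mu must lie in [0, 1]")
        if not 0.0 <= self.psi <= 1.0:
            raise ValueError("psi must lie in [0, 1]")
        if len(set(self.alphabet)) != len(self.alphabet) or len(self.alphabet) < 2:
            raise ValueError("alphabet must have >= 2 distinct residues")


def _mutate(seqs: np.ndarray, mu: float, K: int, rng) -> None:
    """Site-wise substitution to a uniformly chosen different residue."""
    if mu == 0.0:
        return
    mask = rng.random(seqs.shape) < mu
    n_hits = int(mask.sum())
    if n_hits:
        seqs[mask] = (seqs[mask] + rng.integers(1, K, size=n_hits)) % K


def simulate_sequences(cfg: SeqSimConfig) -> SequenceFamily:
    """Grow a family of sequences under the crossover model.

    The initial sequence is copied identically; mutation applies every step,
    including this first one, which separates the two initial parents. The
    run is deterministic given ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    K = len(cfg.alphabet)
    N = cfg.N
    pfx = cfg.label_prefix

    root = rng.integers(0, K, size=N)
    seqs = [root.copy(), root.copy()]
    labels = [f"{pfx}1", f"{pfx}2"]
    events = [
        SeqEvent(
            kind="tandem", parents=(f"{pfx}1",), child=f"{pfx}2",
            breakpoint=None, a_expected=1.0, time_index=0,
        )
    ]
    arr = np.vstack(seqs)
    _mutate(arr, cfg.mu, K, rng)

    counter = 2
    t = 0
    while len(labels) < cfg.n_final:
        t += 1
        i = int(rng.integers(len(labels) - 1))
        x_lab, y_lab = labels[i], labels[i + 1]
        counter += 1
        z_lab = f"{pfx}{counter}"
        if rng.random() < cfg.psi:
            which = int(rng.integers(2))  # 0: copy x, 1: copy y
            child = arr[i + which].copy()
            events.append(
                SeqEvent(
                    kind="tandem", parents=((x_lab, y_lab)[which],), child=z_lab,
                    breakpoint=None, a_expected=1.0 - which, time_index=t,
                )
            )
        else:
            k = int(rng.integers(1, N))  # both parents contribute >= 1 site
            child = np.concatenate([arr[i + 1][:k], arr[i][k:]])
            events.append(
                SeqEvent(
                    kind="recombinant", parents=(x_lab, y_lab), child=z_lab,
                    breakpoint=k, a_expected=(N - k) / N, time_index=t,
                )
            )
        arr = np.vstack([arr[: i + 1], child[None, :], arr[i + 1 :]])
        labels.insert(i + 1, z_lab)
        _mutate(arr, cfg.mu, K, rng)

    return SequenceFamily(
        labels=tuple(labels),
        sequences=arr,
        alphabet=cfg.alphabet,
        events=events,
        seed=cfg.seed,
    )


def p_distances(F: SequenceFamily) -> DistanceMatrix:
    """Observed mismatch fractions (p-distances) between all pairs."""
    arr = F.sequences
    if arr.ndim != 2:
        raise ValueError("sequences must form an (n, N) array")
    n = arr.shape[0]
    m = np.zeros((n, n))
    for i in range(n):
        diff = (arr[i + 1 :] != arr[i]).mean(axis=1)
        m[i, i + 1 :] = diff
        m[i + 1 :, i] = diff
    return DistanceMatrix(F.labels, m, _validate=False)


def jukes_cantor(p, K: int = 21, *, inf_on_saturation: bool = False):
    """Jukes–Cantor correction of a mismatch fraction to an additive distance.

        d = -((K-1)/K) * ln(1 - K*p/(K-1)),   0 <= p < (K-1)/K

    ``K`` is the alphabet size. The correction accounts for multiple
    substitutions hitting the same site; it is strictly increasing, ``>= p``,
    and diverges at the saturation point ``p = (K-1)/K`` (error by default,
    ``+inf`` with `inf_on_saturation`). Accepts scalars or arrays.
    """
    if K < 2:
        raise ValueError("alphabet size K must be >= 2")
    p = np.asarray(p, dtype=float)
    c = (K - 1.0) / K
    if np.any(p < 0):
        raise ValueError("mismatch fraction must be nonnegative")
    saturated = p >= c
    if np.any(saturated) and not inf_on_saturation:
        raise ValueError(
            f"mismatch fraction at or beyond saturation ((K-1)/K = {c:.4g}); "
            "distances are undefined"
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        d = np.where(saturated, np.inf, -c * np.log1p(-np.minimum(p, c) / c))
    return float(d) if d.ndim == 0 else d


def jukes_cantor_matrix(
    D: DistanceMatrix, K: int = 21, *, inf_on_saturation: bool = False
) -> DistanceMatrix:
    """Apply the Jukes–Cantor correction entry-wise to a p-distance matrix."""
    vals = jukes_cantor(D.values, K, inf_on_saturation=inf_on_saturation)
    return DistanceMatrix(D.labels, np.asarray(vals), _validate=False)
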