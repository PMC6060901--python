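"""Labelled symmetric distance matrices.

:class:`DistanceMatrix` is the universal currency of the package: a square
symmetric dissimilarity matrix whose label order is interpreted as the genomic
order of the genes in a cluster unless stated otherwise.
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping, Sequence

import numpy as np

__all__ = ["DistanceMatrix"]


class DistanceMatrix:
    """A symmetric, nonnegative, zero-diagonal distance matrix with labels.

    Parameters
    ----------
    labels : sequence of str
        Unique gene identifiers. Their order encodes the genomic order.
    values : (n, n) array_like
        Symmetric matrix of pairwise distances (substitutions per site or
        arbitrary units).

    Raises
    ------
    ValueError
        If labels are not unique, fewer than 2, the matrix shape mismatches,
        or the matrix violates symmetry / nonnegativity / zero diagonal.
    """

    __slots__ = ("labels", "values", "_index")

    def __init__(self, labels: Sequence[str], values, *, _validate: bool = True):
        labels = tuple(str(x) for x in labels)
        values = np.asarray(values, dtype=float)
        if _validate:
            if len(labels) < 2:
                raise ValueError("need at least 2 labels")
            if len(set(labels)) != len(labels):
                raise ValueError("labels must be unique")
            if values.shape != (len(labels), len(labels)):
                raise ValueError(
                    f"matrix shape {values.shape} does not match {len(labels)} labels"
                )
            if not np.allclose(values, values.T, atol=0, rtol=0):
                raise ValueError("matrix must be exactly symmetric")
            if np.any(np.diag(values) != 0):
                raise ValueError("diagonal must be zero")
            if np.any(values < 0):
                raise ValueError("distances must be nonnegative")
        self.labels = labels
        self.values = values
        self._index = {lab: i for i, lab in enumerate(labels)}

    # -- construction helpers -------------------------------------------------

    @classmethod
    def from_dict(cls, labels: Sequence[str], d: Mapping) -> "DistanceMatrix":
        """Build from a mapping ``(x, y) -> distance`` (either key order)."""
        labels = tuple(labels)
        n = len(labels)
        m = np.zeros((n, n))
        idx = {lab: i for i, lab in enumerate(labels)}
        for (x, y), v in d.items():
            i, j = idx[x], idx[y]
            m[i, j] = m[j, i] = float(v)
        return cls(labels, m)

    @classmethod
    def zeros(cls, labels: Sequence[str]) -> "DistanceMatrix":
        n = len(tuple(labels))
        return cls(labels, np.zeros((n, n)))

    @classmethod
    def line_metric(cls, positions: Mapping[str, float]) -> "DistanceMatrix":
        """Metric of points on a line, ``d(x, y) = |pos[x] - pos[y]|``."""
        labels = tuple(positions)
        p = np.array([positions[x] for x in labels], dtype=float)
        return cls(labels, np.abs(p[:, None] - p[None, :]))

    # -- basic protocol --------------------------------------------------------

    @property
    def n(self) -> int:
        return len(self.labels)

    def __len__(self) -> int:
        return len(self.labels)

    def __getitem__(self, key) -> float:
        x, y = key
        return float(self.values[self._index[x], self._index[y]])

    def __contains__(self, label: str) -> bool:
        return label in self._index

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, DistanceMatrix)
            and self.labels == other.labels
            and np.array_equal(self.values, other.values)
        )

    def __repr__(self) -> str:
        return f"DistanceMatrix(n={self.n}, labels={list(self.labels)!r})"

    def index(self, label: str) -> int:
        try:
            return self._index[label]
        except KeyError:
            raise KeyError(f"unknown label {label!r}") from None

    def indices(self, labels: Iterable[str]) -> list[int]:
        return [self.index(x) for x in labels]

    def copy(self) -> "DistanceMatrix":
        return DistanceMatrix(self.labels, self.values.copy(), _validate=False)

    def allclose(self, other: "DistanceMatrix", atol: float = 1e-12) -> bool:
        return self.labels == other.labels and np.allclose(
            self.values, other.values, atol=atol, rtol=0
        )

    # -- structural edits (pure; return new matrices) --------------------------

    def permute(self, order: Sequence[str]) -> "DistanceMatrix":
        """Reorder rows/columns to `order` (a permutation of the labels)."""
        idx = self._permutation_indices(order)
        return DistanceMatrix(
            tuple(order), self.values[np.ix_(idx, idx)], _validate=False
        )

    def restrict(self, keep: Sequence[str]) -> "DistanceMatrix":
        """Submatrix on `keep`, preserving the given order."""
        idx = self.indices(keep)
        return DistanceMatrix(
            tuple(keep), self.values[np.ix_(idx, idx)], _validate=False
        )

    def insert(self, position: int, label: str, row: Mapping[str, float]) -> "DistanceMatrix":
        """Insert a new `label` at `position` with distances `row` to the others."""
        if label in self._index:
            raise ValueError(f"duplicate label {label!r}")
        n = self.n
        new_labels = self.labels[:position] + (label,) + self.labels[position:]
        m = np.zeros((n + 1, n + 1))
        old_pos = [i if i < position else i + 1 for i in range(n)]
        m[np.ix_(old_pos, old_pos)] = self.values
        for lab, v in row.items():
            j = old_pos[self._index[lab]]
            m[position, j] = m[j, position] = float(v)
        return DistanceMatrix(new_labels, m, _validate=False)

    def drop(self, label: str) -> "DistanceMatrix":
        keep = [x for x in self.labels if x != label]
        if len(keep) == self.n:
            raise KeyError(f"unknown label {label!r}")
        return self.restrict(keep)

    # -- diagnostics ----------------------------------------------------------

    @property
    def d_max(self) -> float:
        """Largest pairwise distance."""
        return float(self.values.max())

    def is_metric(self, tol: float = 1e-9) -> bool:
        """Triangle inequality on all triples, with absolute slack `tol`."""
        v = self.values
        # d(i,k) <= d(i,j) + d(j,k) for all j: check via min-plus product
        through = (v[:, :, None] + v[None, :, :]).min(axis=1)
        return bool(np.all(v <= through + tol))

    def _permutation_indices(self, order: Sequence[str]) -> list[int]:
        order = list(order)
        if len(order) != self.n or set(order) != set(self.labels):
            missing = set(order) - set(self.labels)
            if missing:
                raise KeyError(f"unknown labels {sorted(missing)}")
            raise ValueError("order must be a permutation of the labels")
        return self.indices(order)
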