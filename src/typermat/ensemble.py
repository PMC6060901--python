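"""Shortest Hamiltonian paths and Boltzmann path ensembles.

For a well-behaved gene cluster (single-gene duplications, no
rearrangements) the genetic distances are Robinsonian and the shortest
Hamiltonian path through the distance matrix is co-linear with the genomic
gene order. Beyond the single optimum, a Boltzmann ensemble

    Prob[pi] proportional to exp(-beta * L(pi))

over all undirected Hamiltonian paths (``L`` the path length, ``beta`` an
inverse temperature) yields posterior probabilities that two genes are
adjacent and that a gene is an endpoint of the cluster — soft evidence for
the reconstructed order. Both the optimum and the ensemble are computed
exactly by dynamic programming over label subsets (`O(2^n n^2)`), the
classical Held–Karp recursion and its sum-product analogue in log-space.

In every path ensemble the adjacency posteriors sum to ``n - 1`` and the
endpoint posteriors to ``2`` — each Hamiltonian path has exactly that many
adjacencies and endpoints.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations

import numpy as np
from scipy.special import logsumexp

from .distmat import DistanceMatrix
from .diagnostics import path_length

__all__ = [
    "PathEnsembleResult",
    "shortest_hamiltonian_path",
    "boltzmann_ensemble",
    "brute_force_ensemble",
]

DEFAULT_CAP = 20


@dataclass
class PathEnsembleResult:
    """Partition function and posteriors of a Boltzmann path ensemble.

    Attributes
    ----------
    labels : tuple of str
        Gene labels, fixing row/column order of the posterior arrays.
    beta : float
        Inverse temperature; 0 gives the uniform ensemble, large values
        concentrate on shortest paths.
    logZ : float
        Log partition function over *undirected* Hamiltonian paths.
    adjacency : (n, n) ndarray
        ``adjacency[i, j]`` = posterior probability that genes i and j are
        adjacent on a path; symmetric, zero diagonal, sums to ``n - 1`` over
        unordered pairs.
    endpoint : (n,) ndarray
        Posterior probability of being a path endpoint; sums to 2.
    map_order : tuple of str
        A shortest Hamiltonian path (canonical orientation).
    map_length : float
        Its length.
    """

    labels: tuple[str, ...]
    beta: float
    logZ: float
    adjacency: np.ndarray
    endpoint: np.ndarray
    map_order: tuple[str, ...]
    map_length: float

    def adjacency_of(self, x: str, y: str) -> float:
        i, j = self.labels.index(x), self.labels.index(y)
        return float(self.adjacency[i, j])

    def endpoint_of(self, x: str) -> float:
        return float(self.endpoint[self.labels.index(x)])


def _check_cap(n: int, cap: int, what: str):
    if n > cap:
        raise ValueError(
            f"{what} over {n} genes exceeds the subset-DP cap ({cap}); "
            "the 2^n state space would be infeasible"
        )


def shortest_hamiltonian_path(
    D: DistanceMatrix, cap: int = DEFAULT_CAP
) -> tuple[tuple[str, ...], float]:
    """Exact shortest Hamiltonian path by Held–Karp subset DP.

    Returns the optimal visiting order (canonical orientation: smaller
    endpoint label first) and its length.
    """
    n = D.n
    _check_cap(n, cap, "shortest Hamiltonian path")
    v = D.values
    full = (1 << n) - 1
    INF = float("inf")
    # dp[mask][q]: shortest path covering `mask`, ending at q
    dp = [[INF] * n for _ in range(full + 1)]
    parent = [[-1] * n for _ in range(full + 1)]
    for q in range(n):
        dp[1 << q][q] = 0.0
    for mask in range(1, full + 1):
        row = dp[mask]
        for q in range(n):
            if not mask & (1 << q):
                continue
            cur = row[q]
            if cur == INF:
                continue
            rest = full & ~mask
            m = rest
            while m:
                u = (m & -m).bit_length() - 1
                m &= m - 1
                nmask = mask | (1 << u)
                cand = cur + v[q, u]
                if cand < dp[nmask][u]:
                    dp[nmask][u] = cand
                    parent[nmask][u] = q
    end = int(np.argmin(dp[full]))
    best = dp[full][end]
    order_idx = [end]
    mask = full
    while parent[mask][order_idx[-1]] != -1:
        p = parent[mask][order_idx[-1]]
        mask &= ~(1 << order_idx[-1])
        order_idx.append(p)
    order = tuple(D.labels[i] for i in order_idx)
    if order[0] > order[-1]:
        order = order[::-1]
    return order, float(best)


def boltzmann_ensemble(
    D: DistanceMatrix, beta: float, cap: int = DEFAULT_CAP
) -> PathEnsembleResult:
    """Exact Boltzmann path ensemble by sum-product subset DP (log-space).

    The forward quantity ``Z(A, q)`` sums ``exp(-beta * length)`` over all
    directed Hamiltonian paths of the subset ``A`` ending at ``q``:
    ``Z({q}, q) = 1`` and ``Z(A, q) = sum_u Z(A - q, u) * exp(-beta d(u, q))``.
    Undirected quantities halve the directed totals; an adjacency
    marginalises over the split of the path at the edge ``(u, v)``:

        P[u ~ v] = 2 * sum_A Z(A, u) e^{-beta d(u,v)} Z(V - A, v) / Z_dir

    with the sum over subsets containing ``u`` but not ``v``.
    """
    if beta < 0:
        raise ValueError("beta must be nonnegative")
    n = D.n
    _check_cap(n, cap, "Boltzmann ensemble")
    w = -beta * D.values  # log edge weights
    full = (1 << n) - 1
    logZ_f = np.full((full + 1, n), -np.inf)
    members_of = [[q for q in range(n) if mask & (1 << q)] for mask in range(full + 1)]
    for q in range(n):
        logZ_f[1 << q, q] = 0.0
    for mask in range(1, full + 1):
        members = members_of[mask]
        if len(members) < 2:
            continue
        for q in members:
            prev = mask & ~(1 << q)
            pm = members_of[prev]
            logZ_f[mask, q] = logsumexp(logZ_f[prev, pm] + w[pm, q])

    log_total = float(logsumexp(logZ_f[full]))  # directed paths
    endpoint = 2.0 * np.exp(logZ_f[full] - log_total)

    adjacency = np.zeros((n, n))
    for mask in range(1, full):
        comp = full & ~mask
        for u in members_of[mask]:
            zu = logZ_f[mask, u]
            if zu == -np.inf:
                continue
            for vtx in members_of[comp]:
                zv = logZ_f[comp, vtx]
                if zv == -np.inf:
                    continue
                adjacency[u, vtx] += np.exp(zu + w[u, vtx] + zv - log_total)
    adjacency = adjacency + adjacency.T  # u->v and v->u directed contributions

    map_order, map_length = shortest_hamiltonian_path(D, cap=cap)
    return PathEnsembleResult(
        labels=D.labels,
        beta=float(beta),
        logZ=log_total - np.log(2.0),
        adjacency=adjacency,
        endpoint=endpoint,
        map_order=map_order,
        map_length=map_length,
    )


def brute_force_ensemble(D: DistanceMatrix, beta: float, cap: int = 9) -> PathEnsembleResult:
    """Oracle: enumerate all n!/2 undirected Hamiltonian paths explicitly."""
    if beta < 0:
        raise ValueError("beta must be nonnegative")
    n = D.n
    if n > cap:
        raise ValueError(f"brute force enumeration infeasible beyond n={cap}")
    idx = list(range(n))
    paths = [p for p in permutations(idx) if p[0] < p[-1]]
    lengths = np.array(
        [sum(D.values[p[i - 1], p[i]] for i in range(1, n)) for p in paths]
    )
    logw = -beta * lengths
    logZ = float(logsumexp(logw))
    prob = np.exp(logw - logZ)
    adjacency = np.zeros((n, n))
    endpoint = np.zeros(n)
    for p, pr in zip(paths, prob):
        endpoint[p[0]] += pr
        endpoint[p[-1]] += pr
        for i in range(1, n):
            adjacency[p[i - 1], p[i]] += pr
            adjacency[p[i], p[i - 1]] += pr
    best = int(np.argmin(lengths))
    order = tuple(D.labels[i] for i in paths[best])
    if order[0] > order[-1]:
        order = order[::-1]
    return PathEnsembleResult(
        labels=D.labels,
        beta=float(beta),
        logZ=logZ,
        adjacency=adjacency,
        endpoint=endpoint,
        map_order=order,
        map_length=float(lengths[best]),
    )


def shortest_hamiltonian_cycle_brute(D: DistanceMatrix, cap: int = 9):
    """Oracle: shortest Hamiltonian *cycle* by enumeration (first label fixed)."""
    n = D.n
    if n > cap:
        raise ValueError(f"cycle enumeration infeasible beyond n={cap}")
    v = D.values
    best_len, best = np.inf, None
    for rest in permutations(range(1, n)):
        cyc = (0,) + rest
        length = sum(v[cyc[i - 1], cyc[i]] for i in range(1, n)) + v[cyc[-1], cyc[0]]
        if length < best_len:
            best_len, best = length, cyc
    return tuple(D.labels[i] for i in best), float(best_len)
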