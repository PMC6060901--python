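# Methods

## The model

A gene cluster is a set of paralogous genes whose order along the genome is
meaningful. Two expansion mechanisms are modelled:

- **Tandem duplication** (crossover breakpoint between genes): a gene `x`
  acquires an identical neighbour `z`; in the distance matrix the row of
  `x` is duplicated (`d(z,·) = d(x,·)`, `d(x,z) = 0`).
- **Within-gene crossover** (Gehring's model): a new gene `z`, hybrid of
  adjacent parents `x` and `y` in proportions `a : 1−a`, is inserted
  between them: `d(z,u) = a·d(x,u) + (1−a)·d(y,u)` for outsiders,
  `d(z,x) = (1−a)·d(x,y)`, `d(z,y) = a·d(x,y)`. Note
  `d(z,x) + d(z,y) = d(x,y)`: the child is born "on the segment" between
  its parents.

After every event each gene `p` diverges independently by `δ_p ≥ 0`,
adding `δ_p + δ_q` to every `d(p,q)`. Matrices reachable by these rules are
**type R**; tandem-only histories give additive tree metrics (the special
case `a ∈ {0,1}`). Linear type R matrices (children always between adjacent
parents) satisfy the Kalmanson quadruple condition with respect to the
genomic circular order, hence decompose exactly into weighted circular
splits; if the per-event increments are shared across genes they are also
Robinsonian in genomic order, making that order a shortest Hamiltonian
path. Block duplication (two or more adjacent genes copied as a unit)
yields a tree metric whose genomic order is *discordant* with the tree, so
the genomic-order Kalmanson check fails — the negative control.

## Recognition by reverse-time peeling

For the most recent event `(x,y:z)`:

- `2δ_z = d(x,z) + d(y,z) − d(x,y)` (the child's triangle slack is pure
  post-event divergence);
- `f(a) = d(u,z) − a·d(u,x) − (1−a)·d(u,y)` is independent of the witness
  `u`; equating two witnesses gives
  `a = ((d_uz + d_vy) − (d_vz + d_uy)) / ((d_ux + d_vy) − (d_vx + d_uy))`,
  over-determined for n > 5 — the spread of these estimates is the
  candidate's residual;
- the ancestral parent distance follows from
  `2a(1−a)·d_xy = f(a) − 2δ_z + a·d(x,z) + (1−a)·d(y,z)`, and
  `δ_x = d(x,z) − (1−a)d_xy − δ_z`, `δ_y = d(y,z) − a·d_xy − δ_z`.

Divergence of non-participants cannot be attributed to a specific event
(`δ_u = 0` convention; the length is charged to earlier events). Peeling
removes `z`, rolls back `δ_x`, `δ_y`, restores `d(x,y)`, and recurses.
Copies (`a ∈ {0,1}`) show a constant row shift `d(z,u) − d(p,u)` and are
simply removed; the ancestral parent distance is then unidentifiable, as is
the second flanking gene. At n = 4 the witness formula runs out of pairs:
every 4-point metric is a "box" (four pendant edges `h` on a rectangle with
half-sides `u = (C−A)/2 ≥ v = (C−B)/2 ≥ 0`, where `A ≤ B ≤ C` are the three
pairing sums); the box fixes the circular order of the quartet, but its
four corner triples are equivalent last events. At n = 3 every metric is
type R.

### Genomic-order convention

The package's input convention is that label order encodes genomic order.
`recognize_type_r` exploits it by default (`use_genomic_order=True`):
the child of a peelable event must sit directly between its parents
(anything later inserted into the gap would descend from the child), so
only consecutive label triples are candidates. This reduces the per-level
scan from O(n⁵) to O(n³), rejects block-duplication matrices (their genomic
order admits no consistent peel, even though the matrix is a tree metric
and hence type R after reordering), and pins down the *cut* of the circular
order — see below. `use_genomic_order=False` restores the order-agnostic
O(n⁶) scan.

### Identifiability: the history is unique only up to a gauge freedom

Two exact ambiguities survive any matrix-only analysis:

1. **Terminal box**: the four corner triples of the n = 4 base case are
   equivalent; equivalently, in order-agnostic mode the linear order is
   determined only as a circular order — an end gene whose lineage runs
   through a single event can be rotated past the "cut" with an equally
   exact history.
2. **Chain re-attribution**: for a nested chain — `w` born of `(x,y)`,
   then `v` of `(x,w)` — the alternative history `v` born of `(x,y)` then
   `w` of `(v,y)`, with transformed fractions
   (`λ = a_w / (a_v + a_w(1−a_v))` pattern) and re-divided increments,
   reproduces every matrix entry exactly. Both histories satisfy every
   witness equation with zero spread and nonnegative increments.

Consequently `recognize_type_r` returns one canonical exact history
(lowest residual, deterministic scan order), and `enumerate_histories`
returns them all by backtracking over every exactly feasible peel
(deduplicated by event multiset; on 8-gene crossover simulations typically
1–6 histories). Round-trip validation therefore checks that the simulated
history — triples and crossover fractions to 1e−6 — is *among* the exact
histories, which holds in 100% of seeded runs; demanding that the single
canonical output equal the simulated gauge is not a well-posed requirement.

## Order assembly

Each crossover event is a betweenness triple `(x,y:z)`. For a complete
generic triple set the final adjacencies are exactly the parent–child pairs
`{x,z}`, `{z,y}` that no later event subdivided — an O(1) hash lookup per
triple — and the order is linear iff these pairs form a single path.
Copies only assert "adjacent to the parent at insertion time": clones of
the same parent that no later hybrid event resolves have no defined
relative order and are reported as unordered clone groups (full enumeration
behind a flag with a hard cap, default 256, rather than expanding the
potentially exponential set). Recognition output (whose oldest events are
folded into the terminal core) is assembled by forward replay from the
terminal backbone; with the genomic-order convention the backbone is exact
and the assembled order reproduces the input order or its reversal.

`colinearity_score(a, b)` is the fraction of the n−1 adjacent pairs of `a`
that are adjacent in `b`; reversal-invariant, 1 for identical paths, ≈ 2/n
for unrelated orders.

## Path ensembles

`shortest_hamiltonian_path` is the Held–Karp subset dynamic program (exact,
`O(2ⁿ n²)`, default cap n = 20 ≈ the largest real clusters of interest).
The Boltzmann ensemble weighs every undirected Hamiltonian path by
`exp(−β·L(π))`: forward quantities `Z(A,q)` (paths of subset `A` ending at
`q`) are computed in log-space; endpoint posteriors are
`2·Z(V,q)/Σ_q Z(V,q)` and adjacency posteriors marginalise over the split
of the path at an edge, `P[u∼v] = 2·Σ_A Z(A,u)·e^{−β d_uv}·Z(V∖A,v)/Z_dir`
(the factor 2 covers both edge directions; all posteriors are
convention-independent). Exact normalizations — adjacencies sum to n−1,
endpoints to 2 — are asserted in tests, and a brute-force enumeration over
all n!/2 paths serves as an independent oracle up to n = 9.

β has units of inverse distance: β = 0.01 is calibrated for distances
expressed as substitutions per 100 sites (β ≈ 0.0025 for very large
clusters); rescale β when feeding per-site distances. The MAP path itself
is β-independent.

## Simulators

**Matrix level** (`simulate_cluster_matrix`): starts from one ancestral
gene duplicated at t = 0 (two identical genes), then per step one event
(mode `tandem`, `gehring`, `mixed` with copy probability ψ, or `block`)
followed by a divergence round `δ_p = r_p·Δt` with `Δt = 1/n_final`
(constant duplication rate makes Δt the natural unit) and `r_p ~ U(0,1)`
i.i.d. per gene per step. `equal_rates=True` draws one shared rate per
step, which keeps the Robinson property exact. Crossover fractions are
uniform on a configurable interval (default [0,1]). Every run is
bit-reproducible from its seed, and the event log replays to the exact
matrix. The per-step division of divergence between events is one
admissible convention; only sums along lineages are identifiable.

**Sequence level** (`simulate_sequences`): a random protein of length
N = 1000 over 21 amino acids (including selenocysteine) is copied; each
step inserts either a crossover child `z = y[1..k] ⧺ x[k+1..N]`
(breakpoint k uniform on 1..N−1, so both parents contribute) or, with
probability ψ, a faithful copy; then every sequence mutates site-wise with
probability μ to a uniformly chosen *different* residue — including the
step that separates the two initial parents. μ defaults to 0.01, inside
the informative window 1/N ≲ μ ≲ 1/n. No indels are simulated, so the
family is its own alignment; distances are mismatch fractions with the
K = 21 Jukes–Cantor correction. What the generator does *not* emulate:
rate heterogeneity across sites or genes, gene conversion, selection, gene
loss, and alignment uncertainty — passing tests show the theory's
signature survives substitution noise, not that real alignments are this
clean.

### Noise floor of sequence-level order recovery

With the study conditions (N = 1000, n = 10, μ = 0.01, ψ = 0) the shortest
path equals the genomic order (up to reversal) in ≈ 60% of runs and the
correct circular order in ≈ 72%, versus 0% for the tree-like control; mean
adjacency preservation is ≈ 0.93 vs ≈ 0.55. The failures are of two
well-understood kinds: a rotation of the correct circular order (the cut
between the cluster ends is the most noise-fragile quantity) and single
adjacent transpositions caused by near-tree-like steps (breakpoint close
to a gene boundary). Recovery is a consistency property of the method, not
of these particular sizes: the exact-order rate rises to ≈ 84% at N = 4000
and 100% at N = 16000, and the noise-free matrix-level simulator gives
100%.

## Numerical choices

- Checks use an absolute slack `tol` (default 1e−9, suited to exact
  arithmetic; use ~1e−2·median(d) for empirical matrices). Reports carry
  the signed worst violation and a witness.
- Isolation indices in (−tol, 0) are clipped to 0 and splits with α ≤ tol
  dropped; more negative indices are reported (`min_alpha`), not raised —
  empirical input may violate the Kalmanson condition.
- Peeling clamps crossover fractions within 1e−6 of {0,1} to the copy
  case; the reduced matrix must stay a metric (strictness configurable).
- Ensemble computations are in log-sum-exp space throughout; β·d up to
  ~700 is safe.
- Ties between equally feasible peel candidates are broken by scan order
  (left-to-right in the current label order) for determinism.

## Problem sizes

Validation uses clusters of 5–12 genes, 50–500 seeded replicates per
property, brute-force oracles up to n = 9 (n!/2 = 181k paths), and
sequence families of 10 × 1000 residues — sizes at which every check is
exact or exhaustively cross-checked while the full suite runs in seconds.
Real clusters of up to ~20 genes are within the subset-DP cap.
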