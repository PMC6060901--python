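"""Shortest Hamiltonian path and Boltzmann posteriors for a simulated
cluster: the distance-based reconstruction of the genomic gene order.

With equal divergence rates a crossover-built matrix is Robinsonian, so the
shortest Hamiltonian path through the distances IS the genomic order. The
Boltzmann ensemble at inverse temperature beta turns the single optimum
into posterior probabilities for gene adjacencies and cluster ends.
"""

import numpy as np

from typermat import (
    DistanceMatrix,
    SimConfig,
    boltzmann_ensemble,
    colinearity_score,
    simulate_cluster_matrix,
)

D, log = simulate_cluster_matrix(
    SimConfig(n_final=8, mode="gehring", equal_rates=True,
              a_range=(0.1, 0.9), seed=3)
)
# beta=0.01 is calibrated for distances in substitutions per 100 sites
# (the unit of the real-cluster analyses); rescale accordingly.
D = DistanceMatrix(D.labels, 100.0 * D.values, _validate=False)
res = boltzmann_ensemble(D, beta=0.01)

print(f"genomic order : {' '.join(log.genomic_order)}")
print(f"MAP path      : {' '.join(res.map_order)}  (length {res.map_length:.4f})")
print(f"co-linearity  : {colinearity_score(res.map_order, log.genomic_order):.2f}"
      "  (1.0 = identical up to reversal)")
print(f"log partition function at beta=0.01: {res.logZ:.6f}")

print("\nendpoint posteriors (P[gene is a cluster end]):")
for lab, p in zip(res.labels, res.endpoint):
    bar = "#" * int(round(p * 40))
    print(f"  {lab:>4} {p:6.3f} {bar}")

i = np.unravel_index(np.argmax(res.adjacency), res.adjacency.shape)
print(f"\nstrongest adjacency: {res.labels[i[0]]}–{res.labels[i[1]]} "
      f"P={res.adjacency[i]:.3f}")
print("-> the true cluster ends carry the endpoint mass and the genomic")
print("   neighbours carry the adjacency mass: distance data alone recover")
print("   the gene order of a crossover-built cluster.")
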