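"""Simulate a gene cluster expanding by within-gene crossover and diagnose
the structure of its genetic distance matrix.

A cluster grown purely by within-gene unequal crossing over is NOT tree-like
(four-point condition fails) but IS circular-decomposable in its genomic
order (Kalmanson condition holds), which is the matrix signature this
toolkit is built around.
"""

from typermat import (
    SimConfig,
    check_four_point,
    check_kalmanson,
    check_robinson,
    isolation_indices,
    simulate_cluster_matrix,
)

cfg = SimConfig(n_final=9, mode="gehring", a_range=(0.1, 0.9), seed=42)
D, log = simulate_cluster_matrix(cfg)
order = list(D.labels)

print(f"simulated cluster of {D.n} genes, genomic order: {' '.join(order)}")
print(f"events: {sum(e.kind == 'recombinant' for e in log.events)} crossovers")

fp = check_four_point(D)
kal = check_kalmanson(D, order)
rob = check_robinson(D, order)
print(f"four-point (tree-like)        : holds={fp.holds}  worst slack={fp.worst_violation:.3g}")
print(f"Kalmanson (circular, genomic) : holds={kal.holds}  worst slack={kal.worst_violation:.3g}")
print(f"Robinson (seriation, genomic) : holds={rob.holds}  worst slack={rob.worst_violation:.3g}")

S = isolation_indices(D, order)
print(f"circular splits retained: {len(S)}; reconstruction residual {S.residual:.2e}")
print("-> the matrix decomposes exactly into weighted circular splits:")
print("   the cluster is circular-decomposable, as crossover theory predicts;")
print("   a positive four-point slack confirms it is not an additive tree.")
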