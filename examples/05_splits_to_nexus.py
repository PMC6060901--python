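"""Export the circular split decomposition of a simulated cluster as a
SplitsTree-compatible NEXUS file.

The retained splits with their isolation indices are exactly the input that
split-network viewers draw; for a crossover-built cluster they reconstruct
the distance matrix with zero residual.
"""

from pathlib import Path
from tempfile import mkdtemp

from typermat import SimConfig, isolation_indices, simulate_cluster_matrix
from typermat.io import write_nexus_splits

D, log = simulate_cluster_matrix(
    SimConfig(n_final=7, mode="gehring", a_range=(0.1, 0.9), seed=1)
)
S = isolation_indices(D, list(D.labels))
print(f"{len(S)} circular splits; residual {S.residual:.2e}; "
      f"smallest isolation index {min(s.alpha for s in S.splits):.4f}")

out = Path(mkdtemp()) / "cluster_splits.nex"
write_nexus_splits(S, out)
print(f"NEXUS written to {out}")
print("\nfirst lines:")
print("\n".join(out.read_text().splitlines()[:12]))
print("-> load this file in SplitsTree to draw the split network; a clean")
print("   circular arrangement of the genes mirrors the genomic order.")
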