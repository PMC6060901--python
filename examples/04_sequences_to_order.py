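"""Full sequence-level pipeline: simulate protein sequences of an expanding
cluster, compute Jukes-Cantor distances, and test co-linearity of the
shortest Hamiltonian path with the genomic order.

Contrasts the within-gene crossover model (psi=0) with tree-like tandem
duplication (psi=1): only the former carries an order signal that survives
sequence noise.
"""

from typermat import (
    SeqSimConfig,
    colinearity_score,
    jukes_cantor_matrix,
    p_distances,
    shortest_hamiltonian_path,
    simulate_sequences,
)

for psi, name in ((0.0, "crossover model"), (1.0, "tree-like control")):
    scores = []
    exact = 0
    runs = 20
    for seed in range(runs):
        fam = simulate_sequences(
            SeqSimConfig(n_final=10, N=1000, mu=0.01, psi=psi, seed=seed)
        )
        D = jukes_cantor_matrix(p_distances(fam), K=21)
        order, _ = shortest_hamiltonian_path(D)
        scores.append(colinearity_score(order, fam.labels))
        exact += order in (fam.labels, fam.labels[::-1])
    mean = sum(scores) / runs
    print(f"{name} (psi={psi}): exact order in {exact}/{runs} runs; "
          f"mean adjacency preservation {mean:.2f}")

print("\n-> crossover-built clusters keep their genes' genomic neighbourhoods")
print("   in the distance data (score near 1); tree-like clusters do not")
print("   (score near the 2/n chance level), so co-linearity of the shortest")
print("   path distinguishes the two expansion modes.")
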