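"""All-pairs ANI matrix and neighbor-joining tree for four related strains.

Simulates one ancestor and three descendants at increasing divergence,
builds the symmetrized ANI matrix, converts it to distances (100 - ANI)
and prints the Newick tree. More-diverged strains should attach with
longer branches.
"""

from anikit.ani import build_matrix
from anikit.genome_io import Genome
from anikit.phylo import ani_to_distance, neighbor_joining
from anikit.synthetic import EvolveParams, evolve, random_genome

ancestor, genes = random_genome(40_000, 25, (300, 750), seed=7,
                                genome_id="anc")
genomes = [ancestor]
for k, d in enumerate((0.01, 0.04, 0.08), start=1):
    out = evolve(ancestor, EvolveParams(substitution_rate=d, seed=100 + k),
                 planted_genes=genes)
    genomes.append(Genome(f"strain_d{int(d * 100):02d}", out.genome.contigs))

matrix = build_matrix(genomes)
print("symmetrized ANI matrix (%):")
print(matrix.to_dataframe().round(2))

tree = neighbor_joining(ani_to_distance(matrix))
print("\nneighbor-joining tree (branch lengths in 100 - ANI units):")
print(tree.newick)
# Diagonal is exactly 100; off-diagonal entries track 100*(1-d) for each
# simulated rate, and pendant branch lengths grow with divergence.
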