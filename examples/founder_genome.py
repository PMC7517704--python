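"""Build a synthetic founder panel and inspect its map, frequencies and LD.

The founders emulate a genotyped base population: 29 chromosome pairs
spanning 2927.1 cM, segregating biallelic loci, and within-chromosome
linkage disequilibrium created by a few generations of random mating.
Run:  python examples/founder_genome.py
"""

import numpy as np

from troutsim import build_genetic_map, generate_founder_population

# a trimmed panel (2 chromosomes, 400 loci, 200 fish) so the script runs in seconds
gmap = build_genetic_map(n_chromosomes=2, total_length_cM=201.9, n_loci=400, seed=1)
founders = generate_founder_population(
    200, gmap, maf_low=0.05, maf_high=0.5, n_mixing_generations=10, seed=1
)

freqs = founders.sum(axis=(0, 1)) / (2 * founders.shape[0])
alleles = founders.reshape(-1, gmap.n_loci).astype(float)
r2 = np.corrcoef(alleles.T) ** 2
dist = np.abs(gmap.pos_cM[:, None] - gmap.pos_cM[None, :])
same_chrom = gmap.chrom[:, None] == gmap.chrom[None, :]
near = same_chrom & (dist < 1) & (dist > 0)
far = same_chrom & (dist > 50)

print(f"map: {gmap.n_chromosomes} chromosomes, {gmap.n_loci} loci, {gmap.total_length_cM:.1f} cM")
print(f"allele frequencies: min {freqs.min():.3f}, mean {freqs.mean():.3f} (all segregating)")
print(f"mean r^2 between loci <1 cM apart : {r2[near].mean():.3f}")
print(f"mean r^2 between loci >50 cM apart: {r2[far].mean():.3f}")
print("-> nearby loci are in LD while distant loci are near equilibrium,")
print("   which is what the genomic relationship matrix needs to work with.")
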