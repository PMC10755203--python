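"""Build an F2 linkage map from simulated consensus genotypes.

Simulates an F2 intercross directly at the genotype level (no sequencing),
estimates pairwise recombination fractions by maximum likelihood, groups the
loci, orders each group along a minimum-spanning-tree backbone, and reports
cumulative Kosambi positions.
"""

import numpy as np
import pandas as pd

from gbsmap.genotyping import GenotypeMatrix
from gbsmap.linkmap import (
    build_genetic_map,
    group_loci,
    kosambi_cm,
    order_loci,
    pairwise_rf,
)
from gbsmap.simulate import SimConfig, simulate_f2_population, simulate_parents

cfg = SimConfig(
    n_chromosomes=2,
    chromosome_length=400_000,
    snv_rate=0.001,
    n_individuals=192,
    crossover_mean=1.2,
    seed=5,
    n_contigs=4,
)
truth = simulate_parents(cfg)
simulate_f2_population(truth, cfg)

# one locus per 14-kb window midpoint, genotypes straight from the truth
rows, codes = [], []
for chrom in truth.haplotype_a:
    pos = np.arange(7_000, cfg.chromosome_length, 14_000)
    dose = truth.genotype_dosage(chrom, pos).to_numpy().astype(np.uint8)
    for i, p in enumerate(pos):
        rows.append((chrom, i, p - 7_000, p + 7_000))
    codes.append(dose)
matrix = GenotypeMatrix(
    loci=pd.DataFrame(rows, columns=["contig", "window_index", "start", "end"]),
    individuals=truth.individuals,
    codes=np.concatenate(codes),
)

rf = pairwise_rf(matrix)
groups = group_loci(rf["r"], rf["lod"])
ordered = [order_loci(g, rf["r"], rf["n"]) for g in groups if g.size >= 2]
gmap = build_genetic_map(ordered, rf["r"])

print(f"{len(matrix.loci)} window loci, {cfg.n_individuals} F2 individuals")
print(f"linkage groups found: {len(gmap.groups)} (one per simulated chromosome)")
for g in gmap.groups:
    print(f"  {g.name}: {len(g)} loci, {g.length_cm:.1f} cM")
print(f"\nexpected genetic length per chromosome ~ {100 * cfg.crossover_mean:.0f} cM")
print(f"Kosambi distance at r = 0.25: {kosambi_cm(0.25):.3f} cM")
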