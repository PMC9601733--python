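"""Find a ROH island shared by most of a population and annotate its genes.

Plants one 4-Mb tract in 60% of 30 individuals, calls ROHs, builds the
per-SNP ROH-incidence track, selects the top-0.5% SNPs, merges them into
islands and intersects the result with a small gene annotation.
"""

import tempfile

from rohscan import (
    GeneModel,
    SimulationConfig,
    compare_candidate_sets,
    detect_roh,
    find_islands,
    gene_region_frequency_profile,
    genes_in_islands,
    simulate_dataset,
)

carriers = range(0, 18)  # 18 of 30 individuals share the tract
config = SimulationConfig(
    n_individuals=30,
    n_chromosomes=2,
    chrom_length_bp=30_000_000,
    n_snps_per_chrom=15_000,
    tract_spec=[(i, "1", 10_000_001, 14_000_000) for i in carriers],
    het_error_rate=0.0,
    missing_rate=0.0,
    seed=3,
)
snp_map, geno, _ = simulate_dataset(config)
segments = detect_roh(snp_map, geno)
track, candidates, islands = find_islands(segments, snp_map, geno.n_individuals)

genes = [
    GeneModel("g1", "FGF9", "1", 11_000_000, 11_200_000),    # inside the island
    GeneModel("g2", "BMPR1B", "1", 25_000_000, 25_300_000),  # outside
    GeneModel("g3", "MICU2", "2", 5_000_000, 5_150_000),     # other chromosome
]
islands = genes_in_islands(islands, genes)

print(f"candidate SNPs (top 0.5% of ROH frequency): {len(candidates)}")
for isl in islands:
    print(f"island chr{isl.chrom} {isl.start_bp:,}-{isl.end_bp:,}  "
          f"{isl.n_snps} SNPs  genes: {isl.genes or '-'}")

profile = gene_region_frequency_profile(track, genes)
print("\nper-gene ROH-frequency profile (n SNPs, median, max):")
for name, p in profile.items():
    print(f"  {name:8s} n={p['n']:4d}  median={p['median']:.3f}  max={p['max']:.3f}")

print(
    "\nThe island spans the shared tract: its SNPs sit in ROHs of 60% of "
    "individuals while the background is near 0, so the top-0.5% rule "
    "selects exactly the plateau. FGF9 lies inside the island and shows a "
    "high median ROH frequency; the other genes profile at background."
)
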