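import pytest

from rohscan import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """20 individuals, 2 x 30 Mb chromosomes at 1 SNP / 2 kb, two planted
    tracts, default noise."""
    config = SimulationConfig(
        n_individuals=20,
        n_chromosomes=2,
        chrom_length_bp=30_000_000,
        n_snps_per_chrom=15_000,
        tract_spec=[
            (0, "1", 5_000_001, 8_000_000),
            (1, "2", 10_000_001, 14_000_000),
        ],
        seed=42,
    )
    snp_map, geno, truths = simulate_dataset(config)
    return snp_map, geno, truths, config


@pytest.fixture(scope="session")
def clean_dataset():
    """Noise-free panel with one 3-Mb planted tract (~1500 SNPs)."""
    config = SimulationConfig(
        n_individuals=10,
        n_chromosomes=1,
        chrom_length_bp=30_000_000,
        n_snps_per_chrom=15_000,
        tract_spec=[(0, "1", 5_000_001, 8_000_000)],
        het_error_rate=0.0,
        missing_rate=0.0,
        seed=7,
    )
    snp_map, geno, truths = simulate_dataset(config)
    return snp_map, geno, truths, config


GFF_FIXTURE = """\
##gff-version 3
1\ttest\tgene\t100000\t200000\t.\t+\t.\tID=gene:G1;Name=FGF9
1\ttest\tmRNA\t100000\t200000\t.\t+\t.\tID=tx:G1.1;Parent=gene:G1
1\ttest\texon\t100000\t120000\t.\t+\t.\tID=ex:G1.1.1;Parent=tx:G1.1
1\ttest\tgene\t500000\t650000\t.\t-\t.\tID=gene:G2;Name=BMPR1B
this line is not a gff record
2\ttest\tgene\t300000\t400000\t.\t+\t.\tID=gene:G3;Name=MICU2
"""


@pytest.fixture()
def gff_file(tmp_path):
    path = tmp_path / "genes.gff3"
    path.write_text(GFF_FIXTURE)
    return str(path)
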