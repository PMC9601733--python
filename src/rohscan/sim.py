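"""Synthetic diploid genotype data with planted autozygous tracts.

The generator emulates a small livestock population genotyped on a dense SNP
panel: ~100 diploid individuals across 26 autosomes, Hardy–Weinberg
background genotypes at sites with minor allele frequency in [0.05, 0.5],
and known runs of homozygosity planted as contiguous tracts in named
individuals. Sites are independent (no linkage disequilibrium is simulated;
the false-positive run-length formula used downstream assumes independent
sites, and the generator matches that assumption).

Two corruption channels mimic genotyping artifacts: heterozygous mis-calls
inside planted tracts, and missing calls anywhere.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import yaml

from .data import MISSING, GenotypeMatrix, SNPMap

logger = logging.getLogger(__name__)

# sub-stream labels so that map/population/tracts/noise draw from
# independent deterministic streams derived from one user seed
_STREAM_MAP, _STREAM_POP, _STREAM_TRACT, _STREAM_NOISE = 0, 1, 2, 3


@dataclass
class SimulationConfig:
    """Study-scale defaults: 108 individuals, 26 autosomes, 1 SNP / 2 kb.

    ``tract_spec`` entries are ``(individual_index, chrom, start_bp, end_bp)``
    with 1-based inclusive coordinates.
    """

    n_individuals: int = 108
    n_chromosomes: int = 26
    chrom_length_bp: int = 90_000_000
    n_snps_per_chrom: int = 45_000
    maf_low: float = 0.05
    maf_high: float = 0.5
    tract_spec: list = field(default_factory=list)
    het_error_rate: float = 0.005
    missing_rate: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_individuals < 1 or self.n_chromosomes < 1:
            raise ValueError("need at least one individual and one chromosome")
        if not (0.0 <= self.maf_low <= self.maf_high <= 0.5):
            raise ValueError("require 0 <= maf_low <= maf_high <= 0.5")
        for r in (self.het_error_rate, self.missing_rate):
            if not 0.0 <= r <= 1.0:
                raise ValueError("rates must lie in [0, 1]")
        for ind, chrom, start, end in self.tract_spec:
            if not (1 <= start <= end <= self.chrom_length_bp):
                raise ValueError(
                    f"tract ({ind}, {chrom}, {start}, {end}) outside "
                    f"[1, {self.chrom_length_bp}]"
                )
            if not 0 <= ind < self.n_individuals:
                raise ValueError(f"tract individual index {ind} out of range")

    @property
    def chromosome_names(self) -> list:
        return [str(c + 1) for c in range(self.n_chromosomes)]

    @property
    def individual_ids(self) -> list:
        return [f"ind{i:03d}" for i in range(self.n_individuals)]

    def to_dict(self) -> dict:
        return {
            "n_individuals": self.n_individuals,
            "n_chromosomes": self.n_chromosomes,
            "chrom_length_bp": int(self.chrom_length_bp),
            "n_snps_per_chrom": self.n_snps_per_chrom,
            "maf_low": self.maf_low,
            "maf_high": self.maf_high,
            "tract_spec": [list(t) for t in self.tract_spec],
            "het_error_rate": self.het_error_rate,
            "missing_rate": self.missing_rate,
            "seed": self.seed,
        }


@dataclass
class TruthTract:
    """Ground-truth planted autozygous tract (1-based inclusive)."""

    individual: str
    chrom: str
    start_bp: int
    end_bp: int
    n_snps: int

    def __post_init__(self) -> None:
        if self.start_bp > self.end_bp:
            raise ValueError("start_bp must be <= end_bp")
        if self.n_snps < 0:
            raise ValueError("n_snps must be >= 0")


@dataclass
class NoiseSummary:
    n_het_flips: int
    n_set_missing: int


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(config.seed), stream])


def _sample_positions(rng: np.random.Generator, n: int, length: int) -> np.ndarray:
    """n sorted unique 1-based positions in [1, length]."""
    if n > length:
        raise ValueError(
            f"cannot place {n} distinct SNPs on a {length}-bp chromosome"
        )
    # draw with replacement in batches, deduplicate; avoids materializing
    # a permutation of a ~1e8-element range
    pool = np.empty(0, dtype=np.int64)
    while len(pool) < n:
        batch = rng.integers(1, length + 1, size=max(2 * (n - len(pool)), 16))
        pool = np.unique(np.concatenate([pool, batch]))
    if len(pool) > n:
        pool = pool[np.sort(rng.choice(len(pool), size=n, replace=False))]
    return pool


def simulate_map(config: SimulationConfig) -> SNPMap:
    """Per chromosome, n_snps_per_chrom sorted unique positions and a
    uniform[maf_low, maf_high] frequency per SNP."""
    if config.n_snps_per_chrom < 2:
        raise ValueError("need at least 2 SNPs per chromosome")
    rng = _rng(config, _STREAM_MAP)
    chroms, pos, freq = [], [], []
    for name in config.chromosome_names:
        p = _sample_positions(rng, config.n_snps_per_chrom, config.chrom_length_bp)
        chroms.extend([name] * len(p))
        pos.append(p)
        freq.append(rng.uniform(config.maf_low, config.maf_high, size=len(p)))
    return SNPMap(
        chrom=np.array(chroms, dtype=object),
        pos=np.concatenate(pos),
        freq=np.concatenate(freq),
    )


def simulate_population(snp_map: SNPMap, config: SimulationConfig) -> GenotypeMatrix:
    """Hardy–Weinberg genotypes: ALT count ~ Binomial(2, p) per site."""
    if snp_map.freq is None:
        raise ValueError("map must carry allele frequencies")
    rng = _rng(config, _STREAM_POP)
    calls = rng.binomial(
        2, snp_map.freq[None, :], size=(config.n_individuals, snp_map.n_snps)
    ).astype(np.int8)
    return GenotypeMatrix(config.individual_ids, calls)


def _merge_spans(spans: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge overlapping/abutting 1-based inclusive spans."""
    merged: list[list[int]] = []
    for s, e in sorted(spans):
        if merged and s <= merged[-1][1] + 1:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def plant_tracts(
    geno: GenotypeMatrix,
    snp_map: SNPMap,
    tract_spec: list,
    config: SimulationConfig,
) -> tuple[GenotypeMatrix, list[TruthTract]]:
    """Force homozygosity within each tract of the named individual.

    The homozygous allele is drawn per SNP from its population frequency
    (one Bernoulli(p) draw, both copies equal), mimicking identity by
    descent of a random haplotype and so preserving the allele-frequency
    spectrum inside runs. Overlapping tracts of one individual merge into a
    single truth interval.
    """
    rng = _rng(config, _STREAM_TRACT)
    out = geno.copy()
    by_ind_chrom: dict[tuple[int, str], list[tuple[int, int]]] = {}
    for ind, chrom, start, end in tract_spec:
        by_ind_chrom.setdefault((int(ind), str(chrom)), []).append((int(start), int(end)))
    truths: list[TruthTract] = []
    for (ind, chrom), spans in sorted(
        by_ind_chrom.items(), key=lambda kv: (kv[0][0], kv[0][1])
    ):
        for start, end in _merge_spans(spans):
            lo, hi = snp_map.index_range(chrom, start, end)
            if hi > lo:
                p = snp_map.freq[lo:hi]
                allele = rng.binomial(1, p).astype(np.int8)
                out.calls[ind, lo:hi] = 2 * allele
            truths.append(
                TruthTract(
                    individual=geno.individuals[ind],
                    chrom=chrom,
                    start_bp=start,
                    end_bp=end,
                    n_snps=hi - lo,
                )
            )
    return out, truths


def inject_noise(
    geno: GenotypeMatrix,
    snp_map: SNPMap,
    truths: list[TruthTract],
    het_error_rate: float,
    missing_rate: float,
    config: SimulationConfig,
) -> tuple[GenotypeMatrix, NoiseSummary]:
    """Corrupt calls: tract SNPs flip to heterozygous with ``het_error_rate``;
    any call goes missing with ``missing_rate``."""
    for r in (het_error_rate, missing_rate):
        if not 0.0 <= r <= 1.0:
            raise ValueError("rates must lie in [0, 1]")
    rng = _rng(config, _STREAM_NOISE)
    out = geno.copy()
    ind_index = {name: i for i, name in enumerate(geno.individuals)}
    n_flips = 0
    if het_error_rate > 0:
        for t in truths:
            lo, hi = snp_map.index_range(t.chrom, t.start_bp, t.end_bp)
            if hi <= lo:
                continue
            flip = rng.random(hi - lo) < het_error_rate
            row = ind_index[t.individual]
            out.calls[row, lo:hi][flip] = 1
            n_flips += int(flip.sum())
    n_missing = 0
    if missing_rate > 0:
        drop = rng.random(out.calls.shape) < missing_rate
        n_missing = int(drop.sum())
        out.calls[drop] = MISSING
    summary = NoiseSummary(n_het_flips=n_flips, n_set_missing=n_missing)
    logger.info(
        "noise injection: %d het flips inside tracts, %d calls set missing",
        summary.n_het_flips,
        summary.n_set_missing,
    )
    return out, summary


def simulate_dataset(
    config: SimulationConfig,
) -> tuple[SNPMap, GenotypeMatrix, list[TruthTract]]:
    """Full generator chain: map -> HWE population -> tracts -> noise."""
    snp_map = simulate_map(config)
    geno = simulate_population(snp_map, config)
    geno, truths = plant_tracts(geno, snp_map, config.tract_spec, config)
    geno, _ = inject_noise(
        geno, snp_map, truths, config.het_error_rate, config.missing_rate, config
    )
    return snp_map, geno, truths


_GT_STRING = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_outputs(
    geno: GenotypeMatrix,
    snp_map: SNPMap,
    truths: list[TruthTract],
    config: SimulationConfig,
    out_prefix: str,
) -> dict:
    """Emit <prefix>.vcf (GT-only VCF 4.2), <prefix>.truth.bed
    (0-based half-open, col 4 = individual), <prefix>.config.yaml."""
    vcf_path = f"{out_prefix}.vcf"
    bed_path = f"{out_prefix}.truth.bed"
    cfg_path = f"{out_prefix}.config.yaml"
    with open(vcf_path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=rohscan-simulate\n")
        for chrom in snp_map.chromosomes:
            fh.write(
                f"##contig=<ID={chrom},length={int(config.chrom_length_bp)}>\n"
            )
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(geno.individuals)
            + "\n"
        )
        for j in range(snp_map.n_snps):
            gts = "\t".join(_GT_STRING[int(g)] for g in geno.calls[:, j])
            fh.write(
                f"{snp_map.chrom[j]}\t{snp_map.pos[j]}\t{snp_map.ids[j]}"
                f"\tA\tG\t.\t.\t.\tGT\t{gts}\n"
            )
    with open(bed_path, "w") as fh:
        for t in truths:
            fh.write(f"{t.chrom}\t{t.start_bp - 1}\t{t.end_bp}\t{t.individual}\n")
    with open(cfg_path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
    return {"vcf": vcf_path, "truth_bed": bed_path, "config": cfg_path}


def read_truth_bed(path: str) -> list[TruthTract]:
    """Read a truth BED back into 1-based inclusive tracts (n_snps unknown: 0)."""
    tracts = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            chrom, start0, end, ind = line.rstrip("\n").split("\t")[:4]
            tracts.append(
                TruthTract(
                    individual=ind,
                    chrom=chrom,
                    start_bp=int(start0) + 1,
                    end_bp=int(end),
                    n_snps=0,
                )
            )
    return tracts
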