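"""Reading genotype panels, SNP quality control, and tabular output.

QC mirrors the standard PLINK filters: drop SNPs with a missing-call
fraction above ``max_missing_rate`` (``--geno``), then drop SNPs whose
minor allele frequency, recomputed from the surviving non-missing calls,
falls below ``min_maf`` (``--maf``). A SNP failing both rules is counted
once, under the missingness rule.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import MISSING, GenotypeMatrix, SNPMap

logger = logging.getLogger(__name__)


class EmptyPanelError(ValueError):
    """Raised when quality control removes every SNP."""


@dataclass
class QCParams:
    max_missing_rate: float = 0.1
    min_maf: float = 0.05

    def __post_init__(self) -> None:
        if not 0.0 <= self.max_missing_rate <= 1.0:
            raise ValueError("max_missing_rate must lie in [0, 1]")
        if not 0.0 <= self.min_maf <= 0.5:
            raise ValueError("min_maf must lie in [0, 0.5]")


@dataclass
class QCReport:
    n_input: int
    n_removed_missing: int
    n_removed_maf: int
    n_kept: int


def read_vcf_genotypes(path: str) -> tuple[SNPMap, GenotypeMatrix]:
    """Read a multi-sample VCF into (SNPMap, GenotypeMatrix).

    Only biallelic SNP records are kept; multi-allelic and non-SNP records
    are skipped with a logged count. GT coding: hom-ref 0, het 1, hom-alt 2,
    missing -1 (phase is ignored).
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    if not samples:
        raise ValueError(f"VCF {path} contains no samples")
    chroms: list = []
    pos: list[int] = []
    ids: list = []
    cols: list[np.ndarray] = []
    n_skipped = 0
    last: dict = {}
    for v in vcf:
        if not v.is_snp or len(v.ALT) != 1:
            n_skipped += 1
            continue
        if v.CHROM in last and v.POS <= last[v.CHROM]:
            raise ValueError(
                f"VCF not sorted/unique within chromosome at {v.CHROM}:{v.POS}"
            )
        last[v.CHROM] = v.POS
        chroms.append(v.CHROM)
        pos.append(v.POS)
        ids.append(v.ID if v.ID not in (None, ".") else f"{v.CHROM}:{v.POS}")
        # with gts012=True: 0/1/2 = ALT count, 3 = unknown
        g = v.gt_types.astype(np.int8)
        g[g == 3] = MISSING
        cols.append(g)
    if n_skipped:
        logger.info("skipped %d non-biallelic/non-SNP records", n_skipped)
    if not pos:
        raise ValueError(f"no biallelic SNP records in {path}")
    snp_map = SNPMap(
        chrom=np.array(chroms, dtype=object),
        pos=np.array(pos, dtype=np.int64),
        ids=np.array(ids, dtype=object),
    )
    calls = np.stack(cols, axis=1)
    return snp_map, GenotypeMatrix(samples, calls)


def minor_allele_frequencies(geno: GenotypeMatrix) -> np.ndarray:
    """Per-SNP MAF from non-missing calls; NaN where all calls are missing."""
    calls = geno.calls
    present = calls != MISSING
    n_present = present.sum(axis=0)
    alt = np.where(present, calls, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n_present > 0, alt / (2.0 * n_present), np.nan)
    return np.minimum(p, 1.0 - p)


def qc_filter(
    snp_map: SNPMap, geno: GenotypeMatrix, params: QCParams | None = None
) -> tuple[SNPMap, GenotypeMatrix, QCReport]:
    """Apply missingness then MAF filters; idempotent for fixed params."""
    params = params or QCParams()
    n_input = snp_map.n_snps
    miss_frac = (geno.calls == MISSING).mean(axis=0)
    keep_miss = miss_frac <= params.max_missing_rate
    n_removed_missing = int((~keep_miss).sum())
    snp_map2 = snp_map.subset(keep_miss)
    geno2 = geno.subset_snps(keep_miss)
    maf = minor_allele_frequencies(geno2)
    # all-missing SNPs survive only when max_missing_rate is 1; their MAF is
    # undefined and they are removed whenever a MAF floor is active
    keep_maf = np.where(np.isnan(maf), params.min_maf <= 0, maf >= params.min_maf)
    n_removed_maf = int((~keep_maf).sum())
    snp_map3 = snp_map2.subset(keep_maf)
    geno3 = geno2.subset_snps(keep_maf)
    report = QCReport(
        n_input=n_input,
        n_removed_missing=n_removed_missing,
        n_removed_maf=n_removed_maf,
        n_kept=snp_map3.n_snps,
    )
    logger.info(
        "QC: %d SNPs in, %d removed by missingness>%g, %d by MAF<%g, %d kept",
        n_input,
        n_removed_missing,
        params.max_missing_rate,
        n_removed_maf,
        params.min_maf,
        report.n_kept,
    )
    if report.n_kept == 0:
        raise EmptyPanelError("quality control removed every SNP")
    return snp_map3, geno3, report


# ---------------------------------------------------------------------------
# tabular output (TSV with headers)

ROH_TABLE_COLUMNS = [
    "individual",
    "chrom",
    "start_bp",
    "end_bp",
    "n_snps",
    "length_mb",
    "length_class",
]


def segments_to_frame(segments) -> pd.DataFrame:
    rows = [
        {
            "individual": s.individual,
            "chrom": s.chrom,
            "start_bp": s.start_bp,
            "end_bp": s.end_bp,
            "n_snps": s.n_snps,
            "length_mb": s.length_mb,
            "length_class": s.length_class,
        }
        for s in segments
    ]
    return pd.DataFrame(rows, columns=ROH_TABLE_COLUMNS)


def write_roh_table(segments, path: str) -> None:
    segments_to_frame(segments).to_csv(path, sep="\t", index=False)


def read_roh_table(path: str):
    from .roh import ROHSegment

    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "individual": str})
    return [
        ROHSegment(
            individual=r.individual,
            chrom=r.chrom,
            start_bp=int(r.start_bp),
            end_bp=int(r.end_bp),
            n_snps=int(r.n_snps),
        )
        for r in df.itertuples()
    ]


def write_inbreeding_table(records: pd.DataFrame, path: str) -> None:
    records.to_csv(path, sep="\t", index=True, index_label="individual")


def write_correlation_matrix(corr: pd.DataFrame, path: str) -> None:
    corr.to_csv(path, sep="\t", index=True, index_label="coefficient")


def write_class_summary(summary: pd.DataFrame, path: str) -> None:
    summary.to_csv(path, sep="\t", index=True, index_label="roh_length_mb")


def write_island_table(islands, path: str) -> None:
    rows = [
        {
            "chrom": isl.chrom,
            "start_bp": isl.start_bp,
            "end_bp": isl.end_bp,
            "n_snps": isl.n_snps,
            "n_genes": len(isl.genes),
            "genes": ",".join(isl.genes) if isl.genes else "-",
        }
        for isl in islands
    ]
    pd.DataFrame(
        rows, columns=["chrom", "start_bp", "end_bp", "n_snps", "n_genes", "genes"]
    ).to_csv(path, sep="\t", index=False)


def read_island_table(path: str):
    from .islands import ROHIsland

    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    out = []
    for r in df.itertuples():
        genes = [] if r.genes in ("-", "", None) else str(r.genes).split(",")
        out.append(
            ROHIsland(
                chrom=r.chrom,
                start_bp=int(r.start_bp),
                end_bp=int(r.end_bp),
                n_snps=int(r.n_snps),
                genes=genes,
            )
        )
    return out
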