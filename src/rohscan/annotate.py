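"""Gene annotation of ROH islands and two-population candidate comparison."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .islands import ROHIsland

logger = logging.getLogger(__name__)


@dataclass
class GeneModel:
    """One gene interval (1-based inclusive, per GFF3 convention)."""

    gene_id: str
    gene_name: str
    chrom: str
    start_bp: int
    end_bp: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start_bp > self.end_bp:
            raise ValueError("start_bp must be <= end_bp")


@dataclass
class BreedComparison:
    """Shared/unique candidate SNPs of two populations and the gene sets
    their merged intervals overlap."""

    shared_snps: set
    unique_snps_a: set
    unique_snps_b: set
    shared_genes: set
    unique_genes_a: set
    unique_genes_b: set


def read_gene_models(gff_path: str) -> list[GeneModel]:
    """Extract ``gene`` features from a GFF3 file.

    Lines without the nine tab-separated GFF columns are dropped (with a
    logged count) before parsing, so partially malformed annotation dumps
    still load.
    """
    import tempfile

    import gffutils

    n_malformed = 0
    clean_lines = []
    with open(gff_path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                clean_lines.append(line)
                continue
            if len(line.rstrip("\n").split("\t")) != 9:
                n_malformed += 1
                continue
            clean_lines.append(line)
    if n_malformed:
        logger.info("skipped %d malformed GFF lines", n_malformed)
    with tempfile.NamedTemporaryFile("w", suffix=".gff3", delete=False) as tmp:
        tmp.writelines(clean_lines)
        tmp_path = tmp.name
    db = gffutils.create_db(
        tmp_path,
        dbfn=":memory:",
        keep_order=True,
        merge_strategy="create_unique",
        force=True,
    )
    genes = []
    for feat in db.features_of_type("gene"):
        gene_id = feat.attributes.get("gene_id", [feat.id])[0]
        name = feat.attributes.get("Name", feat.attributes.get("gene_name", [gene_id]))[0]
        genes.append(
            GeneModel(
                gene_id=gene_id,
                gene_name=name,
                chrom=feat.seqid,
                start_bp=feat.start,
                end_bp=feat.end,
                strand=feat.strand or ".",
            )
        )
    if not genes:
        logger.warning("no gene features found in %s", gff_path)
    return genes


def _gene_trees(genes: list[GeneModel]) -> dict:
    trees: dict[str, IntervalTree] = {}
    for g in genes:
        # IntervalTree is half-open; +1 converts the inclusive end
        trees.setdefault(g.chrom, IntervalTree()).addi(g.start_bp, g.end_bp + 1, g)
    return trees


def genes_in_islands(
    islands: list[ROHIsland], genes: list[GeneModel]
) -> list[ROHIsland]:
    """Assign to each island every gene overlapping it by >= 1 bp
    (strand-ignorant); returns new islands with gene lists filled."""
    trees = _gene_trees(genes)
    out = []
    for isl in islands:
        tree = trees.get(isl.chrom)
        hits = (
            sorted({iv.data.gene_name for iv in tree.overlap(isl.start_bp, isl.end_bp + 1)})
            if tree is not None
            else []
        )
        out.append(
            ROHIsland(
                chrom=isl.chrom,
                start_bp=isl.start_bp,
                end_bp=isl.end_bp,
                n_snps=isl.n_snps,
                genes=hits,
            )
        )
    return out


def _merge_snp_intervals(snps: set, merge_gap_bp: int) -> list[tuple[str, int, int]]:
    """Collapse (chrom, pos) keys into intervals, joining neighbours within
    merge_gap_bp."""
    by_chrom: dict[str, list[int]] = {}
    for chrom, pos in snps:
        by_chrom.setdefault(chrom, []).append(pos)
    intervals = []
    for chrom, positions in sorted(by_chrom.items()):
        positions.sort()
        start = prev = positions[0]
        for p in positions[1:]:
            if p - prev > merge_gap_bp:
                intervals.append((chrom, start, prev))
                start = p
            prev = p
        intervals.append((chrom, start, prev))
    return intervals


def _genes_for_snps(
    snps: set, genes: list[GeneModel], merge_gap_bp: int
) -> set:
    trees = _gene_trees(genes)
    found: set = set()
    for chrom, start, end in _merge_snp_intervals(snps, merge_gap_bp):
        tree = trees.get(chrom)
        if tree is None:
            continue
        found |= {iv.data.gene_name for iv in tree.overlap(start, end + 1)}
    return found


def compare_candidate_sets(
    candidates_a: set,
    candidates_b: set,
    genes: list[GeneModel],
    merge_gap_bp: int = 100_000,
) -> BreedComparison:
    """Set algebra on two populations' candidate SNPs keyed by (chrom, pos),
    plus the gene sets overlapped by each subset's merged intervals.

    Both panels must use the same chromosome naming; if the two non-empty
    sets share no chromosome label at all, the comparison is refused rather
    than silently reporting zero overlap.
    """
    candidates_a = set(candidates_a)
    candidates_b = set(candidates_b)
    chroms_a = {c for c, _ in candidates_a}
    chroms_b = {c for c, _ in candidates_b}
    if chroms_a and chroms_b and not (chroms_a & chroms_b):
        raise ValueError(
            "candidate sets share no chromosome names; check that both "
            f"panels use the same reference naming ({sorted(chroms_a)[:3]} "
            f"vs {sorted(chroms_b)[:3]})"
        )
    shared = candidates_a & candidates_b
    unique_a = candidates_a - candidates_b
    unique_b = candidates_b - candidates_a
    return BreedComparison(
        shared_snps=shared,
        unique_snps_a=unique_a,
        unique_snps_b=unique_b,
        shared_genes=_genes_for_snps(shared, genes, merge_gap_bp),
        unique_genes_a=_genes_for_snps(unique_a, genes, merge_gap_bp),
        unique_genes_b=_genes_for_snps(unique_b, genes, merge_gap_bp),
    )


def gene_region_frequency_profile(
    track: pd.DataFrame, genes: list[GeneModel]
) -> dict:
    """Per-gene distribution of SNP ROH frequencies inside the gene span.

    Returns ``{gene_name: {"freqs": array, "n": int, "median": float,
    "max": float}}``; a gene covering no map SNP gets an empty distribution
    (n=0, NaN summaries) and a logged flag.
    """
    out = {}
    for g in genes:
        sub = track[
            (track["chrom"] == g.chrom)
            & (track["pos_bp"] >= g.start_bp)
            & (track["pos_bp"] <= g.end_bp)
        ]
        freqs = sub["roh_freq"].to_numpy()
        if len(freqs) == 0:
            logger.warning("gene %s covers no map SNP", g.gene_name)
        out[g.gene_name] = {
            "freqs": freqs,
            "n": len(freqs),
            "median": float(np.median(freqs)) if len(freqs) else float("nan"),
            "max": float(freqs.max()) if len(freqs) else float("nan"),
        }
    return out
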