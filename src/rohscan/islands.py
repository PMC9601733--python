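"""ROH islands: regions where many individuals' ROHs stack up.

For every map SNP the incidence track counts the distinct individuals
whose called ROHs cover it; SNPs in the top fraction (default 0.5%) of
that genome-wide frequency distribution are candidate SNPs, and maximal
map-consecutive stretches of candidates form islands.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import SNPMap
from .roh import ROHSegment

logger = logging.getLogger(__name__)


@dataclass
class ROHIsland:
    """Merged interval of adjoining candidate SNPs (1-based inclusive)."""

    chrom: str
    start_bp: int
    end_bp: int
    n_snps: int
    genes: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.start_bp > self.end_bp:
            raise ValueError("start_bp must be <= end_bp")
        if self.n_snps < 1:
            raise ValueError("an island holds at least one candidate SNP")


def snp_roh_frequency(
    segments: list[ROHSegment], snp_map: SNPMap, n_individuals: int
) -> pd.DataFrame:
    """Per-SNP count/frequency of distinct individuals whose ROHs cover it.

    Columns: chrom, pos_bp, roh_count, roh_freq (aligned to the map order).
    """
    if n_individuals < 1:
        raise ValueError("n_individuals must be >= 1")
    counts = np.zeros(snp_map.n_snps, dtype=np.int64)
    by_ind: dict[str, list[ROHSegment]] = {}
    for s in segments:
        by_ind.setdefault(s.individual, []).append(s)
    for segs in by_ind.values():
        covered = np.zeros(snp_map.n_snps, dtype=bool)
        for s in segs:
            lo, hi = snp_map.index_range(s.chrom, s.start_bp, s.end_bp)
            covered[lo:hi] = True
        counts += covered
    return pd.DataFrame(
        {
            "chrom": snp_map.chrom,
            "pos_bp": snp_map.pos,
            "roh_count": counts,
            "roh_freq": counts / n_individuals,
        }
    )


def select_candidates(track: pd.DataFrame, top_fraction: float = 0.005) -> np.ndarray:
    """Indices (map order) of SNPs at or above the (1 - top_fraction)
    genome-wide quantile of ROH frequency; ties at the threshold included.

    The quantile is taken over all SNPs including zeros. An all-zero track
    yields an empty set with a warning; a constant nonzero track degenerately
    selects everything, also with a warning.
    """
    if not 0.0 < top_fraction < 1.0:
        raise ValueError("top_fraction must lie in (0, 1)")
    freq = track["roh_freq"].to_numpy()
    if len(freq) == 0:
        return np.array([], dtype=int)
    if freq.max() == 0:
        warnings.warn("ROH frequency track is all zero; no candidate SNPs")
        return np.array([], dtype=int)
    if freq.min() == freq.max():
        warnings.warn(
            "ROH frequency track is constant; every SNP ties at the "
            "threshold and all are selected"
        )
        return np.arange(len(freq))
    threshold = np.quantile(freq, 1.0 - top_fraction)
    return np.flatnonzero(freq >= threshold)


def merge_islands(
    candidate_indices: np.ndarray,
    snp_map: SNPMap,
    island_gap_kb: float | None = None,
) -> list[ROHIsland]:
    """Group map-consecutive candidate SNPs on one chromosome into islands.

    By default "adjoining" means consecutive in the map (no intervening
    non-candidate SNP). ``island_gap_kb`` optionally also merges candidate
    groups separated by non-candidates when the bp gap between them is at
    most that tolerance. Islands never cross chromosomes.
    """
    idx = np.asarray(sorted(candidate_indices), dtype=int)
    if len(idx) == 0:
        return []
    gap_bp = None if island_gap_kb is None else island_gap_kb * 1000.0
    islands: list[ROHIsland] = []
    start = prev = idx[0]
    n = 1
    for i in idx[1:]:
        same_chrom = snp_map.chrom[i] == snp_map.chrom[prev]
        adjoining = i == prev + 1
        if not adjoining and same_chrom and gap_bp is not None:
            adjoining = snp_map.pos[i] - snp_map.pos[prev] <= gap_bp
        if same_chrom and adjoining:
            prev = i
            n += 1
        else:
            islands.append(
                ROHIsland(
                    chrom=snp_map.chrom[start],
                    start_bp=int(snp_map.pos[start]),
                    end_bp=int(snp_map.pos[prev]),
                    n_snps=n,
                )
            )
            start = prev = i
            n = 1
    islands.append(
        ROHIsland(
            chrom=snp_map.chrom[start],
            start_bp=int(snp_map.pos[start]),
            end_bp=int(snp_map.pos[prev]),
            n_snps=n,
        )
    )
    return islands


def find_islands(
    segments: list[ROHSegment],
    snp_map: SNPMap,
    n_individuals: int,
    top_fraction: float = 0.005,
    island_gap_kb: float | None = None,
) -> tuple[pd.DataFrame, np.ndarray, list[ROHIsland]]:
    """Convenience chain: track -> candidates -> islands."""
    track = snp_roh_frequency(segments, snp_map, n_individuals)
    candidates = select_candidates(track, top_fraction=top_fraction)
    islands = merge_islands(candidates, snp_map, island_gap_kb=island_gap_kb)
    return track, candidates, islands


def plot_frequency_track(
    track: pd.DataFrame, path: str, reference_line: float = 0.20
) -> None:
    """Genome-wide ROH-frequency scatter with a horizontal reference line
    (drawn at 20% by convention; it is a visual guide, not the selection
    rule, which is the top-quantile threshold)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(10, 3))
    offset = 0
    ticks, labels = [], []
    for chrom, sub in track.groupby("chrom", sort=False):
        x = sub["pos_bp"].to_numpy() + offset
        ax.scatter(x, sub["roh_freq"], s=1)
        ticks.append(offset + sub["pos_bp"].max() / 2)
        labels.append(str(chrom))
        offset += int(sub["pos_bp"].max())
    ax.axhline(reference_line, color="red", linewidth=1)
    ax.set_xticks(ticks, labels)
    ax.set_xlabel("chromosome")
    ax.set_ylabel("SNP frequency in ROH")
    ax.set_ylim(0, 1)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
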