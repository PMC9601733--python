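"""Sliding-window runs-of-homozygosity caller.

The calling scheme is the PLINK ``--homozyg`` one made explicit:

1. slide a fixed-size window of ``window_snps`` SNPs along each chromosome
   of each individual; a window *passes* when it contains at most
   ``window_het_max`` heterozygous and ``window_missing_max`` missing calls;
2. score each SNP by the fraction of windows containing it that pass; the
   SNP is in *homozygous state* when that fraction reaches ``hit_threshold``;
3. maximal stretches of homozygous-state SNPs form candidate runs, split
   wherever adjacent SNPs are more than ``max_gap_kb`` apart;
4. keep runs with at least ``max(min_snps, l)`` SNPs, length at least
   ``min_length_kb``, and density no sparser than one SNP per
   ``max_density_kb_per_snp`` kb.

The minimum run length ``l`` that controls the expected number of
chance runs across the whole panel at false-positive rate ``alpha`` is

    l = ln(alpha / (ns * ni)) / ln(1 - h_bar)

with ``ns`` SNPs per individual, ``ni`` individuals and mean
heterozygosity ``h_bar``: a stretch of l independent sites is all
homozygous with probability (1 - h_bar)^l, and there are about ns * ni
stretch starts in the panel.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

import numpy as np

from .data import MISSING, GenotypeMatrix, SNPMap

logger = logging.getLogger(__name__)

LENGTH_CLASSES = ("1-5", "5-10", ">10")


@dataclass
class CallerParams:
    """Defaults follow the common livestock ROH settings: 50-SNP windows
    allowing 1 heterozygote and 5 missing calls, 100-SNP / 1-Mb minimum
    runs, density >= 1 SNP / 50 kb, runs split at gaps > 1 Mb, and a 5%
    false-positive rate for the minimum-run-length formula."""

    window_snps: int = 50
    window_het_max: int = 1
    window_missing_max: int = 5
    hit_threshold: float = 0.05
    min_snps: int = 100
    min_length_kb: float = 1000.0
    max_density_kb_per_snp: float = 50.0
    max_gap_kb: float = 1000.0
    alpha: float | None = 0.05
    strict_segment_check: bool = False

    def __post_init__(self) -> None:
        if self.window_snps < 1 or self.min_snps < 1:
            raise ValueError("window_snps and min_snps must be >= 1")
        if not 0.0 < self.hit_threshold <= 1.0:
            raise ValueError("hit_threshold must lie in (0, 1]")
        if self.window_het_max < 0 or self.window_missing_max < 0:
            raise ValueError("window allowances must be >= 0")
        if self.min_length_kb < 0 or self.max_gap_kb <= 0:
            raise ValueError("lengths must be positive")
        if self.alpha is not None and not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")


@dataclass
class ROHSegment:
    """One called run: 1-based inclusive span of its first and last SNP."""

    individual: str
    chrom: str
    start_bp: int
    end_bp: int
    n_snps: int

    def __post_init__(self) -> None:
        if self.start_bp > self.end_bp:
            raise ValueError("start_bp must be <= end_bp")

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp + 1

    @property
    def length_mb(self) -> float:
        return self.length_bp / 1e6

    @property
    def length_class(self) -> str:
        # "<1" only arises when the 1-Mb length filter is disabled
        if self.length_mb < 1.0:
            return "<1"
        return classify_length(self.length_mb)


def min_snp_count_raw(
    alpha: float, ns: int, ni: int, het_mean: float
) -> float:
    """Real-valued minimum run length l = ln(alpha/(ns*ni)) / ln(1-h_bar)."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    if ns < 1 or ni < 1:
        raise ValueError("ns and ni must be >= 1")
    if not 0.0 < het_mean < 1.0:
        raise ValueError("het_mean must lie strictly in (0, 1)")
    return math.log(alpha / (ns * ni)) / math.log(1.0 - het_mean)


def min_snp_count(alpha: float, ns: int, ni: int, het_mean: float) -> int:
    """Smallest integer >= the real-valued minimum run length."""
    return math.ceil(min_snp_count_raw(alpha, ns, ni, het_mean))


def mean_heterozygosity(geno: GenotypeMatrix) -> float:
    """Fraction of heterozygous calls among non-missing calls."""
    present = geno.calls != MISSING
    n = int(present.sum())
    if n == 0:
        return float("nan")
    return float((geno.calls == 1).sum() / n)


def window_pass(window: np.ndarray, params: CallerParams) -> bool:
    """True iff the window holds at most the allowed het and missing counts."""
    window = np.asarray(window)
    n_het = int((window == 1).sum())
    n_mis = int((window == MISSING).sum())
    return n_het <= params.window_het_max and n_mis <= params.window_missing_max


def snp_hit_fraction(genotypes: np.ndarray, params: CallerParams) -> np.ndarray:
    """Per-SNP fraction of passing windows among windows containing the SNP.

    ``genotypes`` is one individual's calls on one chromosome, aligned to the
    map. Chromosomes shorter than one window have no windows: all fractions 0.
    """
    g = np.asarray(genotypes)
    n = len(g)
    w = params.window_snps
    if n < w:
        return np.zeros(n, dtype=float)
    het = (g == 1).astype(np.int64)
    mis = (g == MISSING).astype(np.int64)
    chet = np.concatenate([[0], np.cumsum(het)])
    cmis = np.concatenate([[0], np.cumsum(mis)])
    starts = np.arange(n - w + 1)
    passing = (
        (chet[starts + w] - chet[starts] <= params.window_het_max)
        & (cmis[starts + w] - cmis[starts] <= params.window_missing_max)
    )
    cpass = np.concatenate([[0], np.cumsum(passing)])
    idx = np.arange(n)
    lo = np.maximum(0, idx - w + 1)
    hi = np.minimum(idx, n - w)
    n_pass = cpass[hi + 1] - cpass[lo]
    n_tot = hi - lo + 1
    return n_pass / n_tot


def extract_runs(
    flags: np.ndarray,
    positions: np.ndarray,
    params: CallerParams,
) -> list[tuple[int, int]]:
    """Maximal runs of True flags as half-open index pairs, split where the
    bp gap between adjacent SNPs exceeds ``max_gap_kb``."""
    flags = np.asarray(flags, dtype=bool)
    positions = np.asarray(positions)
    max_gap_bp = params.max_gap_kb * 1000.0
    runs: list[tuple[int, int]] = []
    n = len(flags)
    i = 0
    while i < n:
        if not flags[i]:
            i += 1
            continue
        j = i
        while (
            j + 1 < n
            and flags[j + 1]
            and positions[j + 1] - positions[j] <= max_gap_bp
        ):
            j += 1
        runs.append((i, j + 1))
        i = j + 1
    return runs


def classify_length(length_mb: float) -> str:
    """Length classes [1,5) -> "1-5", [5,10) -> "5-10", [10,inf) -> ">10"."""
    if length_mb < 1.0:
        raise ValueError("length classes are defined for runs >= 1 Mb")
    if length_mb < 5.0:
        return "1-5"
    if length_mb < 10.0:
        return "5-10"
    return ">10"


def filter_segments(
    candidates: list[ROHSegment],
    params: CallerParams,
    min_snps_effective: int | None = None,
) -> list[ROHSegment]:
    """Apply SNP-count, length, and density thresholds to candidate runs."""
    floor = params.min_snps if min_snps_effective is None else min_snps_effective
    kept = []
    for seg in candidates:
        if seg.n_snps < floor:
            continue
        length_kb = seg.length_bp / 1000.0
        if length_kb < params.min_length_kb:
            continue
        if length_kb / seg.n_snps > params.max_density_kb_per_snp:
            continue
        kept.append(seg)
    return kept


def _segment_strict_ok(
    geno_row: np.ndarray, snp_map: SNPMap, seg: ROHSegment, params: CallerParams
) -> bool:
    lo, hi = snp_map.index_range(seg.chrom, seg.start_bp, seg.end_bp)
    g = geno_row[lo:hi]
    return (
        int((g == 1).sum()) <= params.window_het_max
        and int((g == MISSING).sum()) <= params.window_missing_max
    )


def effective_min_snps(
    snp_map: SNPMap, geno: GenotypeMatrix, params: CallerParams
) -> int:
    """SNP-count floor: max of the fixed rule and the false-positive formula."""
    if params.alpha is None:
        return params.min_snps
    h_bar = mean_heterozygosity(geno)
    if not 0.0 < h_bar < 1.0:
        logger.warning(
            "mean heterozygosity %.3f outside (0,1); the minimum-run-length "
            "formula is undefined, falling back to the fixed floor %d",
            h_bar,
            params.min_snps,
        )
        return params.min_snps
    l = min_snp_count(params.alpha, snp_map.n_snps, geno.n_individuals, h_bar)
    return max(params.min_snps, l)


def detect_roh(
    snp_map: SNPMap, geno: GenotypeMatrix, params: CallerParams | None = None
) -> list[ROHSegment]:
    """Run the full window -> state -> runs -> filter chain for every
    individual and chromosome; output sorted by (individual, chrom, start)."""
    params = params or CallerParams()
    floor = effective_min_snps(snp_map, geno, params)
    segments: list[ROHSegment] = []
    for i, ind in enumerate(geno.individuals):
        row = geno.calls[i]
        for chrom in snp_map.chromosomes:
            sl = snp_map.chrom_slice(chrom)
            g = row[sl]
            pos = snp_map.pos[sl]
            frac = snp_hit_fraction(g, params)
            flags = frac >= params.hit_threshold
            candidates = [
                ROHSegment(
                    individual=ind,
                    chrom=chrom,
                    start_bp=int(pos[a]),
                    end_bp=int(pos[b - 1]),
                    n_snps=b - a,
                )
                for a, b in extract_runs(flags, pos, params)
            ]
            kept = filter_segments(candidates, params, floor)
            if params.strict_segment_check:
                kept = [
                    s
                    for s in kept
                    if _segment_strict_ok(row, snp_map, s, params)
                ]
            segments.extend(kept)
    segments.sort(key=lambda s: (s.individual, s.chrom, s.start_bp))
    return segments


def relaxed_params(params: CallerParams) -> CallerParams:
    """Copy of params with length/density/gap filters disabled (used by the
    false-positive calibration study)."""
    return replace(
        params,
        min_length_kb=0.0,
        max_density_kb_per_snp=float("inf"),
        max_gap_kb=float("inf"),
    )
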