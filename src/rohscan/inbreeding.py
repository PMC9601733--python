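"""Genomic inbreeding coefficients.

Seven per-individual coefficients are computed:

* ``F_ROH`` — total ROH length divided by L_aut, the autosomal length
  covered by the SNP panel — overall and restricted to the 1-5 Mb,
  5-10 Mb and >10 Mb length classes;
* three SNP-based estimators in the GCTA ``--ibc`` family, per SNP i with
  ALT count x, frequency p and expected heterozygosity h = 2p(1-p):

      F1 = (x - 2p)^2 / h - 1        (variance-standardized, GRM diagonal - 1)
      F2 = 1 - x(2 - x) / h          (excess homozygosity)
      F3 = (x^2 - (1+2p)x + 2p^2)/h  (correlation between uniting gametes)

  each averaged over the SNPs usable for that individual (non-missing call,
  0 < p < 1). All three have expectation 0 under Hardy-Weinberg equilibrium
  when p is the true frequency; with in-sample plug-in frequencies they
  carry an O(1/n_individuals) downward finite-sample bias.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import MISSING, GenotypeMatrix, SNPMap
from .roh import LENGTH_CLASSES, ROHSegment

logger = logging.getLogger(__name__)

COEFFICIENT_COLUMNS = [
    "f_roh_all",
    "f_roh_1_5",
    "f_roh_5_10",
    "f_roh_gt10",
    "f_snp1",
    "f_snp2",
    "f_snp3",
]

_CLASS_TO_COLUMN = {"1-5": "f_roh_1_5", "5-10": "f_roh_5_10", ">10": "f_roh_gt10"}


@dataclass
class GenomeParams:
    """L_aut: total autosomal length (bp) covered by the SNP panel."""

    l_aut: int

    def __post_init__(self) -> None:
        if self.l_aut <= 0:
            raise ValueError("l_aut must be positive")


def compute_laut(snp_map: SNPMap, override: int | None = None) -> GenomeParams:
    """Sum over chromosomes of (last SNP - first SNP + 1), or a supplied
    constant (e.g. an assembly-based 2.36e9)."""
    if override is not None:
        return GenomeParams(l_aut=int(override))
    if snp_map.n_snps == 0:
        raise ValueError("cannot derive L_aut from an empty map")
    total = 0
    for chrom in snp_map.chromosomes:
        sl = snp_map.chrom_slice(chrom)
        total += int(snp_map.pos[sl][-1] - snp_map.pos[sl][0] + 1)
    return GenomeParams(l_aut=total)


def f_roh(
    segments: list[ROHSegment],
    genome: GenomeParams,
    length_class: str | None = None,
) -> float:
    """Total (class-restricted) ROH length of one individual over L_aut."""
    total = sum(
        s.length_bp
        for s in segments
        if length_class is None or s.length_class == length_class
    )
    return total / genome.l_aut


def allele_frequencies(geno: GenotypeMatrix) -> np.ndarray:
    """In-sample ALT-allele frequency per SNP from non-missing calls;
    NaN where every call is missing."""
    present = geno.calls != MISSING
    n_present = present.sum(axis=0)
    alt = np.where(present, geno.calls, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n_present > 0, alt / (2.0 * n_present), np.nan)
    n_all_missing = int((n_present == 0).sum())
    if n_all_missing:
        logger.info("%d SNPs have no non-missing calls; excluded", n_all_missing)
    return p


def f_snp_estimators(
    geno: GenotypeMatrix, freqs: np.ndarray | None = None
) -> pd.DataFrame:
    """Per-individual (f_snp1, f_snp2, f_snp3).

    ``freqs`` defaults to in-sample frequencies; external (e.g. reference
    panel or simulation-truth) frequencies may be supplied instead. SNPs
    monomorphic at the supplied frequencies, with undefined frequency, or
    missing for an individual are excluded from that individual's mean.
    """
    p = allele_frequencies(geno) if freqs is None else np.asarray(freqs, float)
    if p.shape != (geno.n_snps,):
        raise ValueError("freqs must align with the SNP axis")
    usable = np.isfinite(p) & (p > 0.0) & (p < 1.0)
    if not usable.any():
        raise ValueError("no polymorphic SNPs available for the estimators")
    p = p[usable]
    h = 2.0 * p * (1.0 - p)
    calls = geno.calls[:, usable]
    x = np.where(calls == MISSING, np.nan, calls).astype(float)
    n_usable = np.isfinite(x).sum(axis=1)
    if (n_usable == 0).any():
        bad = [geno.individuals[i] for i in np.where(n_usable == 0)[0]]
        raise ValueError(f"no usable SNPs for individual(s): {bad}")
    with np.errstate(invalid="ignore"):
        f1 = (x - 2.0 * p) ** 2 / h - 1.0
        f2 = 1.0 - x * (2.0 - x) / h
        f3 = (x**2 - (1.0 + 2.0 * p) * x + 2.0 * p**2) / h
    return pd.DataFrame(
        {
            "f_snp1": np.nanmean(f1, axis=1),
            "f_snp2": np.nanmean(f2, axis=1),
            "f_snp3": np.nanmean(f3, axis=1),
        },
        index=pd.Index(geno.individuals, name="individual"),
    )


def compute_inbreeding(
    segments: list[ROHSegment],
    geno: GenotypeMatrix,
    genome: GenomeParams,
    freqs: np.ndarray | None = None,
) -> pd.DataFrame:
    """The seven coefficients for every individual in the panel.

    Individuals with no called ROH get 0 for all F_ROH components. The
    returned frame also carries the "+1" GRM-diagonal variants of the three
    SNP-based estimators (``f_snp*_grm``), which are the same quantities on
    the uncentered scale some tools report.
    """
    by_ind: dict[str, list[ROHSegment]] = {ind: [] for ind in geno.individuals}
    for s in segments:
        if s.individual not in by_ind:
            raise ValueError(f"segment individual {s.individual!r} not in panel")
        by_ind[s.individual].append(s)
    roh_cols = {c: [] for c in ("f_roh_all", "f_roh_1_5", "f_roh_5_10", "f_roh_gt10")}
    for ind in geno.individuals:
        segs = by_ind[ind]
        roh_cols["f_roh_all"].append(f_roh(segs, genome))
        for cls in LENGTH_CLASSES:
            roh_cols[_CLASS_TO_COLUMN[cls]].append(f_roh(segs, genome, cls))
    records = pd.DataFrame(
        roh_cols, index=pd.Index(geno.individuals, name="individual")
    )
    fsnp = f_snp_estimators(geno, freqs=freqs)
    records = records.join(fsnp)
    for k in ("f_snp1", "f_snp2", "f_snp3"):
        records[f"{k}_grm"] = records[k] + 1.0
    return records


def correlation_matrix(records: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlations among the seven coefficients (symmetric,
    unit diagonal; zero-variance columns yield NaN entries)."""
    if len(records) < 3:
        raise ValueError("need at least 3 individuals for correlations")
    return records[COEFFICIENT_COLUMNS].corr(method="pearson")


def coefficient_stats(records: pd.DataFrame) -> pd.DataFrame:
    """Mean / min / max / sample SD (ddof=1) per coefficient."""
    sub = records[COEFFICIENT_COLUMNS]
    return pd.DataFrame(
        {
            "mean": sub.mean(),
            "min": sub.min(),
            "max": sub.max(),
            "sd": sub.std(ddof=1),
        }
    )


def length_class_summary(segments: list[ROHSegment]) -> pd.DataFrame:
    """Count, percent of total count, mean and sample SD of length (Mb) per
    length class, plus a total row. SD is reported as 0 when a class holds
    fewer than two segments."""
    lengths = {cls: [] for cls in LENGTH_CLASSES}
    for s in segments:
        cls = s.length_class
        if cls in lengths:
            lengths[cls].append(s.length_mb)
    total_n = sum(len(v) for v in lengths.values())
    rows = {}
    all_lengths: list[float] = []
    for cls in LENGTH_CLASSES:
        v = np.asarray(lengths[cls], dtype=float)
        all_lengths.extend(v)
        rows[cls] = {
            "count": len(v),
            "percent": 100.0 * len(v) / total_n if total_n else 0.0,
            "mean_length_mb": float(v.mean()) if len(v) else 0.0,
            "sd_length_mb": float(v.std(ddof=1)) if len(v) > 1 else 0.0,
        }
    av = np.asarray(all_lengths)
    rows["total"] = {
        "count": total_n,
        "percent": 100.0 if total_n else 0.0,
        "mean_length_mb": float(av.mean()) if total_n else 0.0,
        "sd_length_mb": float(av.std(ddof=1)) if total_n > 1 else 0.0,
    }
    return pd.DataFrame.from_dict(rows, orient="index")


def combine_class_stats(
    counts: list[int], means: list[float], sds: list[float]
) -> dict:
    """Pool per-class (count, mean, sample SD) summaries into overall totals.

    Returns the per-class percentages, the total count, the count-weighted
    overall mean, and the pooled overall sample SD obtained by recombining
    within-class and between-class variation:

        s^2 = [sum (n_k - 1) s_k^2 + sum n_k (m_k - m)^2] / (N - 1)
    """
    n = np.asarray(counts, dtype=float)
    m = np.asarray(means, dtype=float)
    s = np.asarray(sds, dtype=float)
    if not (len(n) == len(m) == len(s)):
        raise ValueError("counts, means, sds must have equal length")
    total = n.sum()
    if total < 2:
        raise ValueError("need at least two observations to pool")
    grand_mean = float((n * m).sum() / total)
    within = ((n - 1) * s**2).sum()
    between = (n * (m - grand_mean) ** 2).sum()
    pooled_sd = float(np.sqrt((within + between) / (total - 1)))
    return {
        "total_count": int(total),
        "percents": [float(100.0 * k / total) for k in n],
        "overall_mean": grand_mean,
        "overall_sd": pooled_sd,
    }
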