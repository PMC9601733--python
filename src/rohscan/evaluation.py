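"""Simulation studies that characterize the pipeline on data with known truth.

Each study builds synthetic panels with the generator, runs the detection /
estimation machinery, and measures recovery against the planted truth:

* :func:`tract_recovery_study` — sensitivity, boundary error and F_ROH
  accuracy for planted 1.5-12 Mb tracts at study scale (108 individuals);
* :func:`fp_calibration_study` — empirical false-positive rate of the
  minimum-run-length formula under a tract-free Hardy-Weinberg null;
* :func:`estimator_null_study` — null means of the three SNP-based
  inbreeding estimators;
* :func:`estimator_burden_study` — F1/F3 agreement across individuals with
  varying planted autozygosity burden;
* :func:`island_recovery_study` — island discovery for a tract shared by a
  fixed fraction of the population.

Seeds: every study derives per-replicate seeds deterministically from one
base seed.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .data import SNPMap
from .inbreeding import compute_laut, f_roh, f_snp_estimators
from .roh import (
    CallerParams,
    detect_roh,
    mean_heterozygosity,
    min_snp_count,
    relaxed_params,
)
from .sim import SimulationConfig, TruthTract, simulate_dataset
from .islands import find_islands


def _replicate_seed(base_seed: int, replicate: int, salt: int) -> int:
    """Deterministic per-replicate seed, kept below 2**31."""
    ss = np.random.SeedSequence([int(base_seed), salt, replicate])
    return int(ss.generate_state(1)[0] % (2**31))


def _random_tracts(
    rng: np.random.Generator,
    config: SimulationConfig,
    min_mb: float,
    max_mb: float,
) -> list:
    """One tract per individual, uniform length in [min_mb, max_mb], placed
    uniformly on a random chromosome away from the exact ends."""
    spec = []
    for ind in range(config.n_individuals):
        chrom = str(rng.integers(1, config.n_chromosomes + 1))
        length = int(rng.uniform(min_mb, max_mb) * 1e6)
        start = int(rng.integers(1, config.chrom_length_bp - length))
        spec.append((ind, chrom, start, start + length - 1))
    return spec


def _truth_index_span(snp_map: SNPMap, t: TruthTract) -> tuple[int, int]:
    lo, hi = snp_map.index_range(t.chrom, t.start_bp, t.end_bp)
    return lo, hi - 1


def tract_recovery_study(
    n_replicates: int = 20,
    seed: int = 0,
    n_individuals: int = 108,
    n_chromosomes: int = 3,
    chrom_length_bp: int = 30_000_000,
    n_snps_per_chrom: int = 15_000,
    min_tract_mb: float = 1.5,
    max_tract_mb: float = 12.0,
    het_error_rate: float = 0.0,
    missing_rate: float = 0.0,
    params: CallerParams | None = None,
) -> dict:
    """Plant one 1.5-12 Mb tract per individual, call ROHs with default
    parameters, and score recovery.

    Returns sensitivity (fraction of truth tracts overlapped by a called
    segment of the same individual), the maximum start/end boundary error in
    SNP positions among recovered tracts, and summary statistics of the
    per-individual relative error |F_ROH - planted fraction| / planted
    fraction.

    Boundary and F_ROH accuracy are properties of clean tracts, so the
    noise channels default to zero here; with heterozygote errors enabled,
    chance error clusters legitimately split runs and the boundary of the
    best-overlap piece is no longer comparable to the planted edge (use
    this study with nonzero rates for overlap sensitivity only).
    """
    params = params or CallerParams()
    n_truths = n_recovered = 0
    max_boundary_err = 0
    rel_errors: list[float] = []
    for rep in range(n_replicates):
        rep_seed = _replicate_seed(seed, rep, salt=1)
        rng = np.random.default_rng(rep_seed)
        base = SimulationConfig(
            n_individuals=n_individuals,
            n_chromosomes=n_chromosomes,
            chrom_length_bp=chrom_length_bp,
            n_snps_per_chrom=n_snps_per_chrom,
            het_error_rate=het_error_rate,
            missing_rate=missing_rate,
            seed=rep_seed,
        )
        config = replace(base, tract_spec=_random_tracts(rng, base, min_tract_mb, max_tract_mb))
        snp_map, geno, truths = simulate_dataset(config)
        segments = detect_roh(snp_map, geno, params)
        by_ind: dict[str, list] = {}
        for s in segments:
            by_ind.setdefault(s.individual, []).append(s)
        genome = compute_laut(snp_map)
        truth_bp: dict[str, int] = {}
        for t in truths:
            truth_bp[t.individual] = truth_bp.get(t.individual, 0) + (
                t.end_bp - t.start_bp + 1
            )
            n_truths += 1
            t_lo, t_hi = _truth_index_span(snp_map, t)
            hits = [
                s
                for s in by_ind.get(t.individual, [])
                if s.chrom == t.chrom
                and s.start_bp <= t.end_bp
                and s.end_bp >= t.start_bp
            ]
            if not hits:
                continue
            n_recovered += 1
            best = max(hits, key=lambda s: min(s.end_bp, t.end_bp) - max(s.start_bp, t.start_bp))
            s_lo, s_hi = snp_map.index_range(best.chrom, best.start_bp, best.end_bp)
            err = max(abs(s_lo - t_lo), abs((s_hi - 1) - t_hi))
            max_boundary_err = max(max_boundary_err, err)
        for ind, planted in truth_bp.items():
            q = planted / genome.l_aut
            fr = f_roh(by_ind.get(ind, []), genome)
            rel_errors.append(abs(fr - q) / q)
    rel = np.asarray(rel_errors)
    return {
        "n_replicates": n_replicates,
        "n_truth_tracts": n_truths,
        "sensitivity": n_recovered / n_truths if n_truths else float("nan"),
        "max_boundary_error_snps": max_boundary_err,
        "froh_relative_error_mean": float(rel.mean()),
        "froh_relative_error_max": float(rel.max()),
    }


def noisy_sensitivity_study(
    n_replicates: int = 20,
    seed: int = 0,
    n_individuals: int = 30,
    n_chromosomes: int = 2,
    chrom_length_bp: int = 30_000_000,
    n_snps_per_chrom: int = 15_000,
    min_tract_mb: float = 1.5,
    max_tract_mb: float = 12.0,
    het_error_rate: float = 0.02,
    missing_rate: float = 0.1,
) -> dict:
    """Overlap-only recovery under heavy corruption: up to 1 heterozygote
    error per 50 tract SNPs and 5 missing calls per 50 — the limits the
    window rule is built to tolerate. A tract counts as recovered when any
    called segment of its individual overlaps it."""
    n_truths = n_recovered = 0
    for rep in range(n_replicates):
        rep_seed = _replicate_seed(seed, rep, salt=6)
        rng = np.random.default_rng(rep_seed)
        base = SimulationConfig(
            n_individuals=n_individuals,
            n_chromosomes=n_chromosomes,
            chrom_length_bp=chrom_length_bp,
            n_snps_per_chrom=n_snps_per_chrom,
            het_error_rate=het_error_rate,
            missing_rate=missing_rate,
            seed=rep_seed,
        )
        config = replace(
            base, tract_spec=_random_tracts(rng, base, min_tract_mb, max_tract_mb)
        )
        snp_map, geno, truths = simulate_dataset(config)
        segments = detect_roh(snp_map, geno)
        by_ind: dict[str, list] = {}
        for s in segments:
            by_ind.setdefault(s.individual, []).append(s)
        for t in truths:
            n_truths += 1
            if any(
                s.chrom == t.chrom
                and s.start_bp <= t.end_bp
                and s.end_bp >= t.start_bp
                for s in by_ind.get(t.individual, [])
            ):
                n_recovered += 1
    return {
        "n_replicates": n_replicates,
        "n_truth_tracts": n_truths,
        "sensitivity": n_recovered / n_truths if n_truths else float("nan"),
    }


def fp_calibration_study(
    n_replicates: int = 200,
    seed: int = 0,
    n_individuals: int = 25,
    n_snps: int = 3000,
    chrom_length_bp: int = 6_000_000,
    alpha: float = 0.05,
) -> dict:
    """Empirical false-positive rate of the minimum-run-length formula.

    Tract-free Hardy-Weinberg panels; per replicate the caller is matched
    to the formula's assumption (a called run = l consecutive homozygous
    genotypes): window of l SNPs, zero het/missing allowance, a SNP is in
    homozygous state when any containing window passes, minimum run l,
    length/density/gap filters disabled. Reports the fraction of replicates
    with at least one called run, which the formula bounds near alpha.
    """
    n_positive = 0
    l_values = []
    for rep in range(n_replicates):
        rep_seed = _replicate_seed(seed, rep, salt=2)
        config = SimulationConfig(
            n_individuals=n_individuals,
            n_chromosomes=1,
            chrom_length_bp=chrom_length_bp,
            n_snps_per_chrom=n_snps,
            het_error_rate=0.0,
            missing_rate=0.0,
            seed=rep_seed,
        )
        snp_map, geno, _ = simulate_dataset(config)
        h_bar = mean_heterozygosity(geno)
        l = min_snp_count(alpha, snp_map.n_snps, geno.n_individuals, h_bar)
        l_values.append(l)
        params = relaxed_params(
            CallerParams(
                window_snps=l,
                window_het_max=0,
                window_missing_max=0,
                hit_threshold=1e-9,
                min_snps=l,
                alpha=None,
            )
        )
        if detect_roh(snp_map, geno, params):
            n_positive += 1
    fpr = n_positive / n_replicates
    mc_se = float(np.sqrt(alpha * (1 - alpha) / n_replicates))
    return {
        "n_replicates": n_replicates,
        "false_positive_rate": fpr,
        "alpha": alpha,
        "bound": alpha + 3 * mc_se,
        "mean_min_snp_count": float(np.mean(l_values)),
    }


def estimator_null_study(
    seed: int = 0,
    n_individuals: int = 108,
    n_snps: int = 5000,
    chrom_length_bp: int = 10_000_000,
) -> dict:
    """Means and z-scores of F1/F2/F3 on a tract-free HWE panel, evaluated
    at the generator's true allele frequencies (the estimators are exactly
    unbiased there; in-sample plug-in frequencies add an O(1/n) bias that
    this study deliberately excludes — see the methods note)."""
    config = SimulationConfig(
        n_individuals=n_individuals,
        n_chromosomes=1,
        chrom_length_bp=chrom_length_bp,
        n_snps_per_chrom=n_snps,
        het_error_rate=0.0,
        missing_rate=0.0,
        seed=_replicate_seed(seed, 0, salt=3),
    )
    snp_map, geno, _ = simulate_dataset(config)
    est = f_snp_estimators(geno, freqs=snp_map.freq)
    out: dict = {"n_individuals": n_individuals, "n_snps": n_snps}
    for k in ("f_snp1", "f_snp2", "f_snp3"):
        mean = float(est[k].mean())
        se = float(est[k].std(ddof=1) / np.sqrt(len(est)))
        out[k] = {"mean": mean, "se": se, "z": mean / se if se > 0 else float("nan")}
    return out


def estimator_burden_study(
    seed: int = 0,
    n_individuals_per_level: int = 30,
    burdens: tuple = (0.0, 0.05, 0.15),
    n_snps: int = 15_000,
    chrom_length_bp: int = 30_000_000,
) -> dict:
    """Correlation of F1 and F3 (in-sample frequencies) across individuals
    whose planted autozygous fraction varies over ``burdens``."""
    n_ind = n_individuals_per_level * len(burdens)
    rep_seed = _replicate_seed(seed, 0, salt=4)
    rng = np.random.default_rng(rep_seed)
    base = SimulationConfig(
        n_individuals=n_ind,
        n_chromosomes=1,
        chrom_length_bp=chrom_length_bp,
        n_snps_per_chrom=n_snps,
        het_error_rate=0.0,
        missing_rate=0.0,
        seed=rep_seed,
    )
    spec = []
    for level, q in enumerate(burdens):
        if q == 0:
            continue
        length = int(q * chrom_length_bp)
        for j in range(n_individuals_per_level):
            ind = level * n_individuals_per_level + j
            start = int(rng.integers(1, chrom_length_bp - length))
            spec.append((ind, "1", start, start + length - 1))
    config = replace(base, tract_spec=spec)
    _, geno, _ = simulate_dataset(config)
    est = f_snp_estimators(geno)
    corr = float(np.corrcoef(est["f_snp1"], est["f_snp3"])[0, 1])
    return {
        "n_individuals": n_ind,
        "burdens": list(burdens),
        "f1_f3_correlation": corr,
        "f1_means_by_level": [
            float(
                est["f_snp1"]
                .iloc[k * n_individuals_per_level : (k + 1) * n_individuals_per_level]
                .mean()
            )
            for k in range(len(burdens))
        ],
    }


def island_recovery_study(
    n_replicates: int = 20,
    seed: int = 0,
    n_individuals: int = 60,
    share: float = 0.6,
    n_chromosomes: int = 2,
    chrom_length_bp: int = 30_000_000,
    n_snps_per_chrom: int = 15_000,
    tract_start_bp: int = 10_000_001,
    tract_end_bp: int = 14_000_000,
    top_fraction: float = 0.005,
    het_error_rate: float = 0.0,
    missing_rate: float = 0.0,
) -> dict:
    """A single tract shared by ``share`` of the population on an otherwise
    quiet genome; success = exactly one island overlapping the truth span.

    Clean tracts by default: the island geometry test asks whether the
    candidate plateau merges into one region, which presumes every carrier's
    run covers the tract; error-induced run splits would fragment the
    plateau by construction."""
    n_carriers = int(round(share * n_individuals))
    n_success = 0
    for rep in range(n_replicates):
        rep_seed = _replicate_seed(seed, rep, salt=5)
        rng = np.random.default_rng(rep_seed)
        carriers = rng.choice(n_individuals, size=n_carriers, replace=False)
        spec = [(int(i), "1", tract_start_bp, tract_end_bp) for i in carriers]
        config = SimulationConfig(
            n_individuals=n_individuals,
            n_chromosomes=n_chromosomes,
            chrom_length_bp=chrom_length_bp,
            n_snps_per_chrom=n_snps_per_chrom,
            tract_spec=spec,
            het_error_rate=het_error_rate,
            missing_rate=missing_rate,
            seed=rep_seed,
        )
        snp_map, geno, _ = simulate_dataset(config)
        segments = detect_roh(snp_map, geno)
        _, _, islands = find_islands(
            segments, snp_map, geno.n_individuals, top_fraction=top_fraction
        )
        overlapping = [
            isl
            for isl in islands
            if isl.chrom == "1"
            and isl.start_bp <= tract_end_bp
            and isl.end_bp >= tract_start_bp
        ]
        if len(overlapping) == 1:
            n_success += 1
    return {
        "n_replicates": n_replicates,
        "recovery_rate": n_success / n_replicates,
        "share": share,
    }
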