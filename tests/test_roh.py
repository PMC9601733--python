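import math

import numpy as np
import pytest

from rohscan import (
    CallerParams,
    GenotypeMatrix,
    ROHSegment,
    SNPMap,
    classify_length,
    detect_roh,
    extract_runs,
    filter_segments,
    min_snp_count,
    min_snp_count_raw,
    snp_hit_fraction,
    window_pass,
)
from rohscan.data import MISSING

from _bruteforce import bruteforce_detect


class TestMinSnpCount:
    def test_cancellation_case(self):
        assert min_snp_count_raw(0.5, 1, 1, 0.5) == pytest.approx(1.0)
        assert min_snp_count(0.5, 1, 1, 0.5) == 1

    def test_direct_evaluation(self):
        raw = min_snp_count_raw(0.05, 10**6, 100, 0.3)
        assert raw == pytest.approx(math.log(5e-10) / math.log(0.7), rel=1e-12)
        assert raw == pytest.approx(60.05, abs=0.01)
        assert min_snp_count(0.05, 10**6, 100, 0.3) == 61

    def test_monotone_in_heterozygosity(self):
        raw = min_snp_count_raw(0.05, 10**6, 100, 0.4)
        assert raw == pytest.approx(41.93, abs=0.01)
        assert min_snp_count(0.05, 10**6, 100, 0.4) == 42
        assert min_snp_count(0.05, 10**6, 100, 0.4) < min_snp_count(
            0.05, 10**6, 100, 0.3
        )

    @pytest.mark.parametrize("het", [0.0, 1.0])
    def test_degenerate_heterozygosity_rejected(self, het):
        with pytest.raises(ValueError):
            min_snp_count(0.05, 1000, 10, het)


class TestWindowPass:
    @pytest.mark.parametrize(
        "n_het,n_missing,expected",
        [(0, 0, True), (1, 0, True), (2, 0, False), (1, 5, True), (1, 6, False)],
    )
    def test_het_and_missing_allowances(self, n_het, n_missing, expected):
        window = np.zeros(50, dtype=np.int8)
        window[:n_het] = 1
        window[n_het : n_het + n_missing] = MISSING
        assert window_pass(window, CallerParams()) is expected


class TestSnpHitFraction:
    def test_all_homozygous_gives_unit_fractions(self):
        g = np.zeros(20, dtype=np.int8)
        frac = snp_hit_fraction(g, CallerParams(window_snps=5))
        assert np.allclose(frac, 1.0)

    def test_single_het_window3_enumeration(self):
        # 10 SNPs, window 3, het at index 5, no het allowance: the 8 windows
        # starting 0..7 fail at starts 3,4,5; every window containing SNP 5
        # fails, SNPs 4 and 6 keep one passing window each.
        g = np.zeros(10, dtype=np.int8)
        g[5] = 1
        params = CallerParams(window_snps=3, window_het_max=0, hit_threshold=0.05)
        frac = snp_hit_fraction(g, params)
        assert frac[5] == 0.0
        assert 0 < frac[4] < 1 and 0 < frac[6] < 1
        assert np.allclose(frac[:3], 1.0) and np.allclose(frac[8:], 1.0)

    def test_isolated_het_recovers_homozygous_state_at_low_threshold(self):
        g = np.zeros(200, dtype=np.int8)
        g[100] = 1
        params = CallerParams(window_snps=50, window_het_max=0, hit_threshold=0.05)
        frac = snp_hit_fraction(g, params)
        # the het SNP sits in 50 windows, none pass
        assert frac[100] == 0.0
        # its direct neighbour has 1 passing window of 50: 0.02 < 0.05
        assert frac[99] < 0.05
        # 45 SNPs away most windows avoid the het
        assert frac[55] >= 0.05

    def test_chromosome_shorter_than_window_has_no_state(self):
        g = np.zeros(10, dtype=np.int8)
        assert np.all(snp_hit_fraction(g, CallerParams(window_snps=50)) == 0.0)


class TestExtractRuns:
    def test_no_flags_no_runs(self):
        pos = np.arange(1, 101) * 1000
        assert extract_runs(np.zeros(100, bool), pos, CallerParams()) == []

    def test_single_block(self):
        flags = np.zeros(300, bool)
        flags[10:251] = True
        pos = np.arange(1, 301) * 1000
        runs = extract_runs(flags, pos, CallerParams())
        assert runs == [(10, 251)]
        assert runs[0][1] - runs[0][0] == 241

    def test_large_gap_splits_run(self):
        flags = np.ones(100, bool)
        pos = np.arange(1, 101) * 1000
        pos[50:] += 1_500_000  # 1.5 Mb jump between SNP 49 and 50
        runs = extract_runs(flags, pos, CallerParams(max_gap_kb=1000))
        assert runs == [(0, 50), (50, 100)]


class TestFilterAndClassify:
    def test_snp_count_floor(self):
        seg = ROHSegment("i", "1", 1, 2_000_000, 99)
        assert filter_segments([seg], CallerParams(min_snps=100)) == []

    def test_density_rule_keeps_13kb_per_snp(self):
        seg = ROHSegment("i", "1", 1, 2_000_000, 150)  # 13.3 kb/SNP
        params = CallerParams(min_snps=100, min_length_kb=1000)
        assert filter_segments([seg], params) == [seg]

    def test_min_length_rule(self):
        seg = ROHSegment("i", "1", 1, 2_000_000, 150)
        assert filter_segments([seg], CallerParams(min_length_kb=3000)) == []

    def test_sparse_run_dropped_by_density(self):
        seg = ROHSegment("i", "1", 1, 6_000_000, 100)  # 60 kb/SNP > 50
        assert filter_segments([seg], CallerParams()) == []

    @pytest.mark.parametrize(
        "length_mb,expected",
        [(1.55, "1-5"), (4.999, "1-5"), (5.0, "5-10"), (9.999, "5-10"),
         (10.0, ">10"), (12.86, ">10"), (24.11, ">10")],
    )
    def test_length_classes(self, length_mb, expected):
        assert classify_length(length_mb) == expected

    def test_sub_megabase_is_contract_violation(self):
        with pytest.raises(ValueError):
            classify_length(0.8)


class TestDetectRoh:
    def test_planted_tract_recovered_with_tight_boundaries(self, clean_dataset):
        snp_map, geno, truths, _ = clean_dataset
        params = CallerParams()
        segments = detect_roh(snp_map, geno, params)
        assert len(segments) == 1
        seg, truth = segments[0], truths[0]
        assert seg.individual == truth.individual
        t_lo, t_hi = snp_map.index_range(truth.chrom, truth.start_bp, truth.end_bp)
        s_lo, s_hi = snp_map.index_range(seg.chrom, seg.start_bp, seg.end_bp)
        assert abs(s_lo - t_lo) <= params.window_snps
        assert abs(s_hi - t_hi) <= params.window_snps

    def test_tract_free_hwe_panel_yields_no_segments(self):
        from rohscan import SimulationConfig, simulate_dataset

        cfg = SimulationConfig(
            n_individuals=30, n_chromosomes=1, chrom_length_bp=20_000_000,
            n_snps_per_chrom=10_000, het_error_rate=0.0, missing_rate=0.0, seed=11,
        )
        snp_map, geno, _ = simulate_dataset(cfg)
        assert detect_roh(snp_map, geno) == []

    def test_all_homozygous_individual_saturates_chromosomes(self):
        rng = np.random.default_rng(3)
        n_snp = 600
        pos = np.sort(rng.choice(np.arange(1, 6_000_001), size=n_snp, replace=False))
        snp_map = SNPMap(chrom=np.array(["1"] * n_snp, dtype=object), pos=pos)
        calls = rng.binomial(2, 0.3, size=(5, n_snp)).astype(np.int8)
        calls[0] = 2 * rng.binomial(1, 0.3, size=n_snp).astype(np.int8)
        geno = GenotypeMatrix([f"s{i}" for i in range(5)], calls)
        params = CallerParams(alpha=None, min_snps=100, min_length_kb=1000)
        segments = [s for s in detect_roh(snp_map, geno, params) if s.individual == "s0"]
        assert len(segments) >= 1
        covered = sum(s.length_bp for s in segments)
        span = int(pos[-1] - pos[0] + 1)
        assert covered >= 0.95 * span

    def test_monotone_in_thresholds(self, small_dataset):
        snp_map, geno, _, _ = small_dataset
        base = CallerParams(min_snps=50, min_length_kb=500)
        n_base = len(detect_roh(snp_map, geno, base))
        for stricter in (
            CallerParams(min_snps=200, min_length_kb=500),
            CallerParams(min_snps=50, min_length_kb=2500),
        ):
            assert len(detect_roh(snp_map, geno, stricter)) <= n_base

    def test_recovery_under_within_allowance_corruption(self):
        """Tracts stay recoverable when corruption is held inside the
        per-window budget (half the allowance: 0.5 het + 2.5 missing
        expected per 50-SNP window)."""
        from rohscan.evaluation import noisy_sensitivity_study

        res = noisy_sensitivity_study(
            n_replicates=10, seed=2, het_error_rate=0.01, missing_rate=0.05
        )
        assert res["sensitivity"] >= 0.95

    def test_matches_bruteforce_on_small_panel(self):
        from rohscan import SimulationConfig, simulate_dataset

        cfg = SimulationConfig(
            n_individuals=4, n_chromosomes=2, chrom_length_bp=2_000_000,
            n_snps_per_chrom=500,
            tract_spec=[(0, "1", 200_001, 1_000_000), (1, "2", 500_001, 1_800_000)],
            het_error_rate=0.01, missing_rate=0.05, seed=5,
        )
        snp_map, geno, _ = simulate_dataset(cfg)
        params = CallerParams(
            window_snps=20, min_snps=50, min_length_kb=300,
            max_density_kb_per_snp=50, max_gap_kb=500, alpha=None,
        )
        got = [
            (s.individual, s.chrom, s.start_bp, s.end_bp, s.n_snps)
            for s in detect_roh(snp_map, geno, params)
        ]
        expected = bruteforce_detect(snp_map, geno, params, params.min_snps)
        assert sorted(got) == expected
        assert expected  # the comparison exercised real segments
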