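import numpy as np
import pandas as pd
import pytest

from rohscan import (
    CallerParams,
    GenomeParams,
    GenotypeMatrix,
    ROHSegment,
    SNPMap,
    allele_frequencies,
    coefficient_stats,
    combine_class_stats,
    compute_inbreeding,
    compute_laut,
    correlation_matrix,
    detect_roh,
    f_roh,
    f_snp_estimators,
    length_class_summary,
)
from rohscan.data import MISSING


def _map(pos_by_chrom):
    chroms, pos = [], []
    for c, ps in pos_by_chrom.items():
        chroms.extend([c] * len(ps))
        pos.extend(ps)
    return SNPMap(chrom=np.array(chroms, dtype=object), pos=np.array(pos))


class TestLaut:
    def test_single_chromosome_span(self):
        gp = compute_laut(_map({"1": [1, 500_000, 1_000_000]}))
        assert gp.l_aut == 1_000_000

    def test_additive_over_chromosomes(self):
        gp = compute_laut(_map({"1": [1, 5_000_000], "2": [1_000_000, 6_000_000 - 1]}))
        assert gp.l_aut == 5_000_000 + 5_000_000

    def test_override_constant(self):
        gp = compute_laut(_map({"1": [1, 10]}), override=2_360_000_000)
        assert gp.l_aut == 2_360_000_000

    def test_empty_map_rejected(self):
        with pytest.raises(ValueError):
            compute_laut(_map({"1": []}))


class TestFroh:
    def test_no_segments_gives_zero(self):
        assert f_roh([], GenomeParams(10**6)) == 0.0

    def test_saturation_gives_one(self):
        seg = ROHSegment("i", "1", 1, 10**6, 500)
        assert f_roh([seg], GenomeParams(10**6)) == 1.0

    def test_class_partition_arithmetic(self):
        # 2.0, 3.5 and 11.0 Mb segments against L_aut = 2360 Mb
        laut = 2_360_000_000
        segs = [
            ROHSegment("i", "1", 1, 2_000_000, 1000),
            ROHSegment("i", "2", 1, 3_500_000, 1500),
            ROHSegment("i", "3", 1, 11_000_000, 4000),
        ]
        gp = GenomeParams(laut)
        assert f_roh(segs, gp) == pytest.approx(16_500_000 / laut)
        assert f_roh(segs, gp, "1-5") == pytest.approx(5_500_000 / laut)
        assert f_roh(segs, gp, "5-10") == 0.0
        assert f_roh(segs, gp, ">10") == pytest.approx(11_000_000 / laut)


class TestAlleleFrequencies:
    def test_symmetric_counts(self):
        calls = np.array([[0]] * 25 + [[1]] * 50 + [[2]] * 25, dtype=np.int8)
        geno = GenotypeMatrix([f"s{i}" for i in range(100)], calls)
        assert allele_frequencies(geno)[0] == pytest.approx(0.5)

    def test_skewed_counts(self):
        calls = np.array([[0]] * 90 + [[1]] * 8 + [[2]] * 2, dtype=np.int8)
        geno = GenotypeMatrix([f"s{i}" for i in range(100)], calls)
        assert allele_frequencies(geno)[0] == pytest.approx(0.06)

    def test_missing_calls_excluded_from_denominator(self):
        calls = np.array([[1], [1], [MISSING], [MISSING]], dtype=np.int8)
        geno = GenotypeMatrix(list("abcd"), calls)
        assert allele_frequencies(geno)[0] == pytest.approx(0.5)


class TestFSnpEstimators:
    @pytest.mark.parametrize(
        "x,p,expected",
        [
            (1, 0.5, (-1.0, -1.0, -1.0)),
            (2, 0.5, (1.0, 1.0, 1.0)),
            (2, 0.8, (-0.5, 1.0, 0.25)),
            (0, 0.5, (1.0, 1.0, 1.0)),
        ],
    )
    def test_single_snp_substitution(self, x, p, expected):
        geno = GenotypeMatrix(["a"], np.array([[x]], dtype=np.int8))
        est = f_snp_estimators(geno, freqs=np.array([p]))
        assert est.loc["a", "f_snp1"] == pytest.approx(expected[0])
        assert est.loc["a", "f_snp2"] == pytest.approx(expected[1])
        assert est.loc["a", "f_snp3"] == pytest.approx(expected[2])

    def test_monomorphic_snps_excluded(self):
        calls = np.array([[2, 1], [2, 1], [2, 0]], dtype=np.int8)
        geno = GenotypeMatrix(list("abc"), calls)
        # SNP 0 has p=1 in-sample: excluded; only SNP 1 contributes
        est = f_snp_estimators(geno)
        single = f_snp_estimators(geno.subset_snps(np.array([1])))
        pd.testing.assert_frame_equal(est, single)

    def test_all_monomorphic_rejected(self):
        geno = GenotypeMatrix(list("ab"), np.array([[2], [2]], dtype=np.int8))
        with pytest.raises(ValueError, match="polymorphic"):
            f_snp_estimators(geno)

    def test_individual_without_usable_calls_rejected(self):
        calls = np.array([[0, 1], [MISSING, MISSING]], dtype=np.int8)
        geno = GenotypeMatrix(list("ab"), calls)
        with pytest.raises(ValueError, match="b"):
            f_snp_estimators(geno)


class TestCorrelationMatrix:
    def _records(self, n=10, seed=0):
        rng = np.random.default_rng(seed)
        base = rng.normal(size=n)
        cols = {
            "f_roh_all": base,
            "f_roh_1_5": base.copy(),          # duplicated column
            "f_roh_5_10": -base,               # negated column
            "f_roh_gt10": rng.normal(size=n),
            "f_snp1": rng.normal(size=n),
            "f_snp2": rng.normal(size=n),
            "f_snp3": rng.normal(size=n),
        }
        return pd.DataFrame(cols)

    def test_duplicate_and_negated_columns(self):
        corr = correlation_matrix(self._records())
        assert corr.loc["f_roh_all", "f_roh_1_5"] == pytest.approx(1.0)
        assert corr.loc["f_roh_all", "f_roh_5_10"] == pytest.approx(-1.0)
        assert np.allclose(np.diag(corr), 1.0)
        assert np.allclose(corr.values, corr.values.T)

    def test_zero_variance_column_reported_undefined(self):
        rec = self._records()
        rec["f_snp2"] = 0.42
        corr = correlation_matrix(rec)
        assert np.isnan(corr.loc["f_snp2", "f_roh_all"])

    def test_too_few_individuals_rejected(self):
        with pytest.raises(ValueError):
            correlation_matrix(self._records(n=2))


class TestSummaries:
    def test_pooled_table_arithmetic(self):
        out = combine_class_stats([5638, 223, 43], [1.55, 6.62, 12.86], [0.74, 1.21, 3.25])
        assert out["total_count"] == 5904
        assert [round(p, 2) for p in out["percents"]] == [95.49, 3.78, 0.73]
        assert round(out["overall_mean"], 2) == 1.82
        assert round(out["overall_sd"], 2) == 1.58

    def test_length_class_summary_counts_and_total(self):
        segs = (
            [ROHSegment("i", "1", 1, 2_000_000, 100)] * 3
            + [ROHSegment("i", "1", 1, 7_000_000, 300)] * 2
            + [ROHSegment("i", "1", 1, 12_000_000, 500)]
        )
        df = length_class_summary(segs)
        assert df.loc["1-5", "count"] == 3
        assert df.loc["5-10", "count"] == 2
        assert df.loc[">10", "count"] == 1
        assert df.loc["total", "count"] == 6
        assert df["percent"][:3].sum() == pytest.approx(100.0)

    def test_singleton_class_sd_reported_zero(self):
        df = length_class_summary([ROHSegment("i", "1", 1, 12_000_000, 500)])
        assert df.loc[">10", "sd_length_mb"] == 0.0

    def test_coefficient_stats_shape(self):
        rng = np.random.default_rng(1)
        rec = pd.DataFrame(
            rng.normal(size=(20, 7)),
            columns=["f_roh_all", "f_roh_1_5", "f_roh_5_10", "f_roh_gt10",
                     "f_snp1", "f_snp2", "f_snp3"],
        )
        stats = coefficient_stats(rec)
        assert list(stats.columns) == ["mean", "min", "max", "sd"]
        assert stats.loc["f_snp1", "sd"] == pytest.approx(rec["f_snp1"].std(ddof=1))


class TestPipelineLevel:
    def test_froh_additivity_on_called_segments(self, small_dataset):
        snp_map, geno, _, _ = small_dataset
        segments = detect_roh(snp_map, geno, CallerParams())
        genome = compute_laut(snp_map)
        records = compute_inbreeding(segments, geno, genome)
        lhs = records["f_roh_all"]
        rhs = records[["f_roh_1_5", "f_roh_5_10", "f_roh_gt10"]].sum(axis=1)
        assert np.allclose(lhs, rhs, atol=1e-12)
        assert (records["f_roh_all"] >= records["f_roh_1_5"] - 1e-12).all()

    def test_planted_burden_recovered_by_froh(self):
        from rohscan import SimulationConfig, simulate_dataset

        cfg = SimulationConfig(
            n_individuals=6, n_chromosomes=1, chrom_length_bp=30_000_000,
            n_snps_per_chrom=15_000,
            tract_spec=[(i, "1", 2_000_001 + 4_000_000 * i,
                         2_000_000 + 4_000_000 * i + 3_000_000) for i in range(3)],
            het_error_rate=0.0, missing_rate=0.0, seed=9,
        )
        snp_map, geno, truths = simulate_dataset(cfg)
        segments = detect_roh(snp_map, geno)
        genome = compute_laut(snp_map)
        records = compute_inbreeding(segments, geno, genome)
        for t in truths:
            q = (t.end_bp - t.start_bp + 1) / genome.l_aut
            got = records.loc[t.individual, "f_roh_all"]
            assert got == pytest.approx(q, rel=0.05)
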