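# Methods

## Scope and model

`rohscan` detects runs of homozygosity (ROH) in unphased diploid SNP
genotypes, summarizes them into genomic inbreeding coefficients, and finds
ROH islands shared across a population. Genotypes are ALT-allele counts
0/1/2 with a missing sentinel; coordinates are 1-based inclusive everywhere
except the BED boundary (0-based half-open). Only autosomes are expected;
chromosome labels are opaque strings and no X/Y logic exists.

## The sliding-window caller

For each individual and chromosome, every window of `window_snps`
consecutive SNPs (default 50) *passes* if it contains at most
`window_het_max` heterozygotes (1) and `window_missing_max` missing calls
(5). Each SNP is scored by the fraction of windows containing it that pass;
at chromosome ends the denominator is the number of windows that actually
exist (no padding), and a chromosome shorter than one window has no
homozygous-state SNPs at all. A SNP is in homozygous state when its
fraction reaches `hit_threshold` (0.05 — the established sliding-window
default; the hit proportion is rarely reported alongside the other
parameters, so it is exposed as a flag). Maximal stretches of
homozygous-state SNPs become candidate runs, split wherever adjacent SNPs
lie more than `max_gap_kb` (1000) apart so that a sparse region cannot
bridge two distinct runs. Runs are kept when they have at least
`max(min_snps, ⌈l⌉)` SNPs (`min_snps` = 100, "at least" semantics matching
`--homozyg-snp 100`), span at least `min_length_kb` (1000), and are no
sparser than one SNP per `max_density_kb_per_snp` (50). Whether the length
or density rule is applied first does not change the output (both are pure
per-run predicates).

The minimum run length that controls chance runs at false-positive rate
`α` is `l = ln(α/(ns·ni)) / ln(1 − h̄)` with `ns` SNPs per individual, `ni`
individuals and mean heterozygosity `h̄` computed from non-missing calls.
`l` is combined with the fixed 100-SNP floor by taking the maximum, since
both rules are stated without precedence. If `h̄` is 0 or 1 the formula is
undefined; the caller warns and falls back to the fixed floor.

Length classes are half-open: [1, 5) → "1-5", [5, 10) → "5-10",
[10, ∞) → ">10" Mb; ties at exactly 5 or 10 Mb go upward. Segment length is
`end_bp − start_bp + 1` over the first/last SNP of the run. When the 1-Mb
filter is disabled (calibration runs), sub-megabase runs are labelled "<1";
the standalone classifier treats them as a contract violation.

An optional strict per-segment post-check (`strict_segment_check`, default
off) re-applies the het/missing allowance to the whole segment rather than
per window, for users who read the allowance as a per-ROH budget.

## Inbreeding coefficients

`F_ROH = L_ROH / L_aut`, where `L_aut` defaults to the map-derived covered
length (per chromosome, last SNP − first SNP + 1, summed) and can be
overridden by an assembly constant (e.g. 2.36 Gb for sheep autosomes). The
three class-restricted components partition `F_ROH` exactly because they
share the denominator.

The SNP-based estimators are the GCTA `--ibc` family (F1: variance-
standardized deviation, the GRM diagonal minus one; F2: excess
homozygosity; F3: correlation between uniting gametes), averaged per
individual over SNPs that are polymorphic at the frequencies used and
non-missing for that individual (per-individual denominators). Frequencies
default to in-sample ALT frequencies; an external frequency vector can be
supplied. Published applications of these estimators sometimes report an
uncentered, GRM-diagonal-like scale with values near 1; the records
therefore also carry `f_snp*_grm = f_snp* + 1`, clearly labelled, and no
attempt is made to match any particular publication's absolute scale.

Plug-in bias: with in-sample frequencies, E[F1] ≈ −1/n under the null
(the standardized sample variance sums to n−1, not n). At n ≈ 100 this bias
is comparable to 3 standard errors of the population mean, so the *null
calibration* study evaluates the estimators at the generator's true
frequencies, where all three are exactly unbiased; the pipeline itself uses
in-sample frequencies, as real analyses must.

Summary tables use the sample SD (ddof = 1) throughout; a class with fewer
than two segments reports SD 0. `combine_class_stats` pools per-class
(count, mean, SD) rows into the total row via
`s² = [Σ(n_k−1)s_k² + Σ n_k(m_k − m̄)²] / (N−1)`.

## ROH islands

The incidence track counts, per map SNP, the distinct individuals with at
least one ROH covering it. Candidate SNPs are those at or above the
(1 − 0.005) quantile of the genome-wide frequency distribution, zeros
included; ties at the threshold are all kept (deterministic and
order-independent, at the cost of occasionally selecting a superset).
"Adjoining" candidates means map-consecutive on one chromosome; an optional
`island_gap_kb` tolerance can merge candidate groups across short
non-candidate stretches (off by default). A 20% horizontal line is drawn by
the plotting helper as a visual convention; it is not the selection rule.
No minimum SNP count per island is imposed. Degenerate tracks (all zero,
or constant) produce a warning and an empty/complete candidate set
respectively.

Two-population comparison: candidate sets are intersected by (chrom, pos);
each subset is collapsed into intervals by merging neighbouring SNPs within
100 kb, and genes overlapping those intervals by ≥ 1 bp (strand-ignorant)
form the subset's gene set. Disjoint chromosome naming between the two
panels is a hard error rather than a silent zero overlap.

## The synthetic-data generator

The generator emulates a ~100-animal livestock panel: 108 individuals, 26
autosomes of 90 Mb at 1 SNP / 2 kb by default, site frequencies uniform on
[0.05, 0.5], Hardy–Weinberg genotypes drawn independently per site. It does
**not** simulate linkage disequilibrium, demography or imputation artifacts
— the `l` formula assumes independent sites and the generator matches that
assumption, so passing tests demonstrate correctness of the machinery on
LD-free data, not calibration on real genomes, where LD inflates chance
homozygosity runs and `l` is conservative only through `h̄`.

Planted tracts force homozygosity over a span; the homozygous allele is
drawn once per SNP from its frequency (both copies equal), mimicking IBD of
a random haplotype and preserving the allele-frequency spectrum inside
runs. Overlapping tracts of one individual merge into a single truth
interval. Two corruption channels follow: heterozygous mis-calls inside
tracts at `het_error_rate` and missing calls anywhere at `missing_rate`.
Defaults are 0.005 and 0.01 — small rates consistent with a
post-imputation, dosage-filtered panel. Each user seed feeds four
independent deterministic sub-streams (map, population, tracts, noise), so
identical configs are byte-identical on rerun, including the emitted VCF.

## Evaluation studies and their sizes

* **Tract recovery**: 20 replicates of 108 individuals × 3 chromosomes ×
  30 Mb at 1 SNP / 2 kb, one clean tract of uniform 1.5–12 Mb per
  individual. Metrics: sensitivity (truth overlapped by a called segment of
  the same individual), maximum boundary error in SNP positions, and the
  per-individual relative error of `F_ROH` against the planted fraction.
  Clean tracts are essential here: heterozygote-error *clusters* (three or
  more within about a window) legitimately split a run — a brute-force
  re-implementation splits identically — so boundary agreement is only a
  well-posed metric without noise. The noisy regime is covered separately
  by an overlap-only sensitivity test at half the window allowance
  (het 0.01, missing 0.05), where sensitivity stays ≈ 0.99. Corruption
  *at* the full allowance (expected 1 het + 5 missing per 50-SNP window)
  makes roughly half of all windows fail and fragments runs — the window
  budget is a per-window maximum, not a sustainable average.
* **False-positive calibration**: 200 tract-free replicates of 25
  individuals × 3000 SNPs. The caller is configured to the formula's exact
  semantics (window = `l`, zero allowances, any-passing-window state,
  `min_snps = l`, other filters off); the fraction of replicates with ≥ 1
  called run must stay within α + 3·SE. The measured rate sits well below
  α because the ceiling on `l` and the heterogeneity of per-site
  heterozygosity (the product of (1 − h_i) is below (1 − h̄)^l by the
  AM–GM inequality) both act conservatively.
* **Estimator null / agreement**: one 108 × 5000 tract-free panel at true
  frequencies (each estimator's mean within 3 SE of 0), and a 90-individual
  burden panel (planted fractions 0 / 0.05 / 0.15) where corr(F1, F3)
  across individuals exceeds 0.9 — both are frequency-weighted
  homozygosity measures and track burden together.
* **Island recovery**: 20 replicates of 60 individuals × 2 chromosomes,
  one 4-Mb tract shared by 60% of individuals on a quiet genome; success is
  exactly one island overlapping the truth span. Clean tracts for the same
  fragmentation reason as above.
* **Oracle equivalence**: 50 random panels (≤ 2000 SNPs × 5 individuals,
  randomized caller parameters, noise on) where the vectorized caller must
  equal a deliberately naive enumerator of every window and run.

These sizes keep the whole suite and the acceptance script within a couple
of minutes on one CPU while leaving the Monte-Carlo error of each metric
well below its acceptance margin.

## Numerical and design choices

* Missingness QC precedes the MAF rule (PLINK order); MAF is computed from
  non-missing calls of the surviving SNPs; a SNP failing both is counted
  under missingness. The filter is idempotent. QC is applied per input
  panel (per-breed), not jointly.
* The hit fraction is an exact rational (passing/existing windows) compared
  with `hit_threshold` by `>=`; with 50-SNP windows the nearest attainable
  fractions to 0.05 are 2/50 and 3/50, so the comparison is never decided
  by float rounding.
* Pearson correlations with a zero-variance column are reported as NaN
  rather than raising.
* `min_snp_count` exposes both the raw real value and the ceiling; the
  ceiling is what the caller uses.
* Quantile thresholds use the default linear interpolation of
  `numpy.quantile`; because ties at the threshold are included, the
  candidate set is insensitive to the interpolation rule whenever the
  threshold lands on a plateau of equal frequencies.
* The pipeline is single-threaded; per-individual calling is
  embarrassingly parallel and order-independent, so a parallel variant
  would be contract-preserving.

## Known limitations

* No LD, no phasing, no X chromosome, no pedigree coefficients.
* The simulator's error model (independent per-call corruption) is an
  explicit simplification; imputation errors in real low-coverage panels
  are correlated along haplotypes.
* `read_vcf_genotypes` handles plain multi-sample VCF with GT; BCF and
  PLINK binary formats are out of scope.
* Island discovery on very small panels is degenerate by construction
  (with few distinct frequency values the top-quantile rule selects large
  tied sets); the warnings make this visible.
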