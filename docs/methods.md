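# Methods

This note documents the models, estimators and numerical choices behind
`towpath`, what the synthetic-data generator does and does not emulate, and
the known limitations.

## Phenotype model

The cohort table holds one record per individual and visit; the analysis
uses the earliest ("baseline") visit of each genotyped individual. Derived
phenotypes are exact linear maps of the two measured pressures:
MAP = (2·DBP + SBP)/3 (computed in that order for better conditioning) and
pulse gap = SBP − DBP. Rows with missing pressures or SBP < DBP are
physically implausible; they are flagged (`bp_flagged`) and excluded from
the derived columns and from association testing, never silently dropped.
Descriptive summaries use the sample SD (denominator n − 1). The
hypertension indicator (SBP ≥ 140 or DBP ≥ 90 or medication use — the
standard clinical rule) is carried as a covariate-style descriptor only; it
is not an analyzed outcome.

Antihypertensive-medication use enters the analysis solely as a covariate.
No medication-based BP imputation or correction is applied.

## Variant classification and gene mapping

Sample MAF is computed from the analysis sample itself: minor-allele count
over 2 × non-missing individuals. If the coded allele's frequency exceeds
0.5 the dosages are flipped (x → 2 − x) and the flip logged. Classes:
*monomorphic* (MAF = 0, excluded downstream), *rare* (0 < MAF < 1%, strict
inequality), *common* (MAF ≥ 1%). The 1% threshold is configurable. Missing
dosages are mean-imputed per variant immediately before association testing
so the closed-form statistics stay defined; with ≈1% missingness this has
negligible effect, and the MAF used for classification ignores imputed
values. Note a sample-size artifact: the smallest nonzero sample MAF is
1/(2n), so for n < 50 no variant can classify as rare.

Gene intervals are 1-based inclusive; BED input (0-based half-open) is
converted on read. A variant maps to a gene iff it lies on the same
chromosome (labels normalized for a "chr" prefix) within
[start − flank, end + flank]; the default flank is 0 bp. Variants inside
overlapping genes are used by every containing gene — no exclusive
assignment — and unmapped variants are counted and reported.

## Gene-level association

**TOW.** With phenotype y and dosage columns x_m, the statistic is computed
through the explicit weighted-combination form: per-variant weights
w_m = cov*(y, x_m)/ss(x_m) (cov* the centered cross-product sum, ss the
centered sum of squares), combined genotype x_0 = Σ w_m x_m, and
T = Σ_i (y_i − ȳ)(x_i0 − x̄_0). The closed form T = Σ_m cov*²/ss is used for
batch permutation evaluation; the two routes agree to 1e-10 relative and
prove T ≥ 0. Monomorphic (zero-variance) columns must be filtered upstream;
n ≥ 3 is required.

**Covariate adjustment.** y and every variant column are replaced by OLS
residuals from their own regression on (intercept, age, sex, smoking,
medication use) before any statistic is computed. Residualization is a QR
projection; a rank-deficient design raises an error naming the collinear
columns (QR with column pivoting). Permutations shuffle the phenotype
residuals with genotype residuals fixed, preserving the covariate-adjusted
null. A consequence verified in the tests: when a covariate drives both the
trait and variant frequencies, adjusted p-values stay uniform under the
null while unadjusted ones do not.

**VW-TOW.** Rare and common classes are scored separately (T_r, T_c) and
mixed as T_λ = λ·T_r/var(T_r) + (1 − λ)·T_c/var(T_c).

- λ grid: 0 to 1 in steps of 0.01 (101 values), configurable; the grid is
  the practical surrogate for the continuous minimum.
- var(T_r), var(T_c): sample variances (ddof = 1) of the statistics over
  the B permutations — the permutation distribution is already available
  and matches the test's calibration logic.
- One shared permutation set serves both classes and every λ. For each
  permutation b the per-λ p-value ranks T_λ^(b) against the *other*
  permutations (leave-one-out, denominator B), while the observed data rank
  against all B (denominator B + 1); per-λ p-values use the add-one rule.
  The observed statistic is min_λ p_λ, and its final p-value is the add-one
  fraction of permutations whose own min-λ p is at least as small. This
  avoids nested permutation at the cost of a slight exchangeability
  asymmetry; measured calibration at n = 129, B = 500 over 500 null genes
  is uniform (KS) with 5% type-I error inside ±2 binomial SE.
- Degenerate cases: if a class statistic is constant across permutations
  (zero variance), the gene falls back to single-class TOW on the class
  that still varies; if both are degenerate the gene is logged and dropped.
  Genes with only one class present go directly to single-class TOW.
- Permutation p-values are invariant under strictly increasing affine
  transforms of the phenotype (verified with shared permutation sets).

Per-gene RNG streams derive from (master seed, CRC32 of the gene id), so
results are independent of iteration order and stable across runs. The
score table records, for VW-TOW genes, the observed min-p as the statistic
(the variable-weight statistic *is* a minimum p-value); plain-TOW rows
record T. Default B = 1000 at desk scale; B ≥ 100 is enforced for random
permutations (explicitly supplied permutation sets, e.g. exhaustive
enumerations, bypass the floor).

## Pathway enrichment

Genes are ranked by ascending p, ties broken lexicographically by gene id;
the ranking score is s_g = −log₁₀(p) (nonnegative; add-one p-values make
p = 0 impossible, and its occurrence raises an error). Set filtering keeps
collections with ≥ 10 genes in total *and* ≥ 1 gene on the target chromosome
present in the ranked list; a size report summarizes kept sets by their
on-chromosome gene counts (bands 1–5, 6–20, 21+).

The reported enrichment score is the maximum positive deviation of the
weighted KS-like running sum (hit increment s^α/Σ_hits s^α with default
α = 1, miss decrement 1/(N − N_H)), floored at 0, hence ES ∈ [0, 1]; if all
hit scores are zero the increments fall back to 1/N_H. The running sum ends
at exactly 0 by construction.

**Null and normalization.** Each set's null sample draws N_H labels
uniformly without replacement from the ranked list (equivalent to permuting
gene labels) and keeps the **signed** extremum of the running sum, in
[−1, 1]. Normalization and testing are one-sided within the positive null:
NES = signed ES / mean(positive null ES), empirical
p = (1 + #{positive null ≥ ES})/(#positive null + 1). The signed null is a
deliberate design choice: flooring null excursions at zero would give every
single-member set a null mean of exactly ½ regardless of the score
distribution, capping singleton NES at 2 and compressing the NES scale so
that genuinely enriched multi-gene sets cannot separate from rank-1
singletons; within-sign normalization is also how the reference preranked
enrichment implementations behave, and it reproduces their characteristic
pattern (singleton sets with ES ≈ 0.9 but NES ≈ 1.2). For a single-member
set with uniform scores the signed null has the closed form
ES(k) = 1 − d if 1 − d ≥ d else −d, with d = (k − 1)/(N − 1) and k uniform
over ranks — used as an exact oracle in the tests.

**FDR.** Per-set null NES values (positive null divided by its mean) are
pooled across sets; q_raw(S) = [fraction of pooled null NES ≥ NES(S)] /
[fraction of observed NES ≥ NES(S)], clipped to [0, 1], followed by a
monotone pass q(S) = min{q_raw(S′) : NES(S′) ≤ NES(S)} so q is
non-increasing in NES. Enriched flag: q < 0.05 (configurable) and NES > 0.
The same permutation sample serves normalization, empirical p and the FDR
pool. Per-set RNG streams derive from (seed, CRC32 of the set name).

## Synthetic-data generator

What it emulates: a small unrelated cohort (defaults: 157 individuals, 129
genotyped — the genotyped subset is the first block of ids); age
~ N(52.9, 15.6²) clipped to [18, 95]; binary covariates with prevalences
60.5% female, 24.8% smokers, 20.2% medicated; SBP/DBP as linear models in
the covariates (age +0.5/+0.1 mm Hg per year, female −3/−1, smoking +4/+1,
medication +8/+3) with a correlated bivariate-normal residual
(SDs 20/9 mm Hg, correlation 0.5). Intercepts (101.2/66.3) put the trait
means near 128.4/71.8 mm Hg under these prevalences; the residual
correlation of 0.5 reproduces a pulse-gap SD near 19 mm Hg given the trait
SDs. Variants are biallelic, Hardy–Weinberg, and mutually independent (no
LD) with population MAF drawn from a mixture: a configurable fraction rare
(uniform on (0.001, 0.01)) and the rest common (uniform on (0.01, 0.5)).
Genes are non-overlapping intervals (5–50 kb) tiling one chromosome; each
receives an equal share of variants with one forced rare and one forced
common so both classes exist per gene. Gene sets are heterogeneous:
on-chromosome membership counts are drawn as 8% zero, 64% 1–5, 22% 6–20, 6%
21+, padded with ids from an off-chromosome universe absent from the
annotation; two sentinel sets (total size 9; zero on-chromosome genes)
guarantee material for the downstream filters. An optional causal spec
plants per-variant effects: "per_allele" adds effect·SD(trait) per minor
allele; "standardized" scales by 1/√(2p(1−p)) so each causal variant
explains effect² of residual variance regardless of frequency (beware:
for very rare variants this implies multi-SD per-allele effects and
outlier phenotypes). Effects apply to both traits, scaled by each trait's
residual SD, and the hypertension indicator is recomputed afterwards.
When enriched sets are requested, background sets draw their on-chromosome
members from non-causal genes only, so that enrichment in the experiment is
attributable to the constructed set rather than to chance inclusion of
causal genes in negative controls.

What it does **not** emulate — and hence what passing tests do not show
about real data: linkage disequilibrium (the statistics do not model LD,
and independence gives clean null calibration, but real-panel behavior
under LD is untested here); family structure and kinship; population
stratification; genotyping error and call-rate structure; longitudinal
visits (only baseline is generated); sex chromosomes; realistic
site-frequency spectra (the MAF mixture is uniform within bands).

Determinism: every operation derives its RNG from (config.seed, fixed
stream id); identical configs give bit-identical bundles, and fixture files
are written with 17-significant-digit floats and read back with round-trip
parsing so write→read is exact.

## Problem sizes used in the checks

Null calibration: 500 genes × 5 variants, n = 129, B = 500. Enrichment
recovery: 20 replicates of 60 genes / 600 variants / 60 sets at n = 129
with B = 300 and 300 set permutations, one planted set of 8 causal genes
(per-allele effects of 1 trait SD at ¾ of each gene's variants); the
matched effect-free fixtures provide the null FDR check. The TOW closed-form
identity is checked on 1000 random instances; the VW-TOW permutation
p-value is checked exactly against 24-permutation enumeration at n = 4.
These sizes keep the full suite under a minute of compute for the
deterministic parts and a few tens of seconds for each stochastic suite.

## Known limitations

- The min-p construction uses leave-one-out ranking rather than nested
  permutation; its calibration is verified empirically, not proven.
- Permutation p-values are granular (multiples of 1/(B+1)); ranked-list
  ties among top genes are resolved lexicographically, which is
  deterministic but arbitrary.
- FDR q uses the pooled-null two-fraction estimator; it is a point estimate
  without uncertainty, and with few surviving sets it is coarse.
- Gene-set enrichment here tests overrepresentation near the top of the
  list only (one-sided); depletion is not flagged.
- At n below ~50 the rare class is empty by arithmetic (see above) and
  every gene falls back to common-only TOW.
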