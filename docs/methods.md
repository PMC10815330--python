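# Methods

This note records the models, conventions and design choices behind the
package, and what the synthetic-data experiments do and do not show.

## Allelic association model

Stage 1 treats each biallelic SNP under the multiplicative (allelic)
model: every non-missing diploid call contributes two alleles to its
group's 2×2 table, so a cohort of 144 cases and 163 controls yields at
most 288 and 326 alleles per variant. The effect allele is the minor
allele in the pooled sample; because two-directional reporting is
conventional, the reciprocal OR of the other allele is also emitted. At
an exact 50/50 allele split the reference allele is designated the
effect allele (an arbitrary but deterministic tie-break).

No continuity correction is applied anywhere. This is deliberate: the
published pooled-allele tables the package validates against reproduce
their χ² p-values only without Yates correction, and the Woolf interval
is likewise computed on raw cells. Tables with a zero cell get an
undefined OR/CI (reported as NaN) rather than a corrected estimate;
degenerate margins give χ² = 0, p = 1 by convention, as does a
monomorphic variant in the Hardy–Weinberg test.

## Quality control

Filters run in a fixed order — non-autosomal, variant call rate
(default ≥ 0.99, i.e. at most 1% failed calls), sample call rate
(default ≥ 0.95), MAF (default ≥ 0.03), HWE (Pearson χ², df = 1,
default α = 0.05) — and each removed variant is charged to the first
filter it fails. This makes the ledger additive: input = Σ removals +
kept, which is the invariant the tests and the pipeline summary check.
Two defaults resolve an ambiguity between the ">1% failed genotyping"
rule for markers and the 0.95 call-rate rule for samples by keeping them
as separate thresholds, both configurable. HWE is tested in controls
only by default (testing in cases would discard true associations);
MAF and HWE are recomputed after sample removal.

## Linkage disequilibrium

Haplotype frequencies at a pair of loci are maximum-likelihood estimates
from unphased genotypes via the standard two-locus EM algorithm; only
the double heterozygote is phase-ambiguous, and the E-step splits it
between cis and trans configurations in proportion to the current
frequency products. Convergence is declared when the largest frequency
change falls below 1e-8 (cap 1000 iterations). Summaries follow the
usual definitions: D = f(AB) − pA·pB, D′ = |D|/Dmax, r² = D²/(pA·pa·pB·pb),
and significance via χ² = n_chrom · r² with df = 1 — a Wald-style test
chosen over a likelihood ratio for simplicity; the two agree closely at
the sample sizes involved. LD is computed in controls by default
(population LD, uncontaminated by case ascertainment) on the unfiltered
input matrix so that loci removed by QC can still be characterized.

Because EM preserves the observed allele frequencies, the likelihood has
a single free dimension (f(AB)); the test-suite oracle exploits this and
grids that dimension at 1e-3 steps rather than the full simplex.

## Stage-2 pair models

Polarity comes from stage 1: at each locus the negative (risk) allele is
the direction with OR > 1. It is not re-estimated per pair, because the
pairing stage is defined on variants that were individually risk-
associated. A variant with OR exactly 1 is unpolarizable and errors.

Pooled-allele counting drops only a missing locus's two alleles and
keeps the other locus's contribution; consequently pooled totals are
4 × group size only under complete data and decrease by exactly 2 per
missing single-locus call. (The published tables this package checks
against include control totals such as 650 and 616 that are not
multiples of 4, which is what forces this convention.)

The additive model stratifies individuals with complete calls at both
loci by total negative-allele count: Groups I (3–4), II (2), III (0–1),
splitting the nine two-locus genotype combinations 3/3/3. The default
contrast is Group I vs Group III; I vs II+III is available because the
choice of reference stratum is genuinely open — the published analyses
do not state theirs, and the two contrasts answer slightly different
questions (extreme-vs-extreme versus extreme-vs-rest). The stage-2
Bonferroni divisor is always the number of pairs actually tested in the
scan, never a constant, and is logged in the run summary.

## Synthetic cohort generator

The generator emulates the statistical structure the analysis assumes,
at the study scale it was designed for (144 cases / 163 controls,
biallelic autosomal SNPs, MAF spectrum uniform on [0.03, 0.5]):

- **Controls** are drawn from Hardy–Weinberg equilibrium at per-variant
  population allele frequencies.
- **Cases** are drawn by rejection sampling under a multiplicative-
  penetrance disease model: P(disease | g) = f₀ · ∏ OR^g, with baseline
  penetrance f₀ = 0.05 and g the risk-allele (ALT) dosage at each
  planted locus; pair effects act on the summed dosage across their two
  loci. Multiplicative penetrance (rather than a logistic model) is the
  choice that makes the induced case/control allelic OR equal the
  planted per-allele OR exactly — the HWE genotype distribution tilted
  by OR^g factorizes into independent Bernoulli alleles — so parameter-
  recovery experiments have an unbiased estimand. Penetrance is clipped
  at 1; configs where the clipped region carries more than 1% of
  Hardy–Weinberg mass are rejected as infeasible with the offending
  effect named, and a config whose acceptance rate cannot accrue the
  requested cases errors out of the rejection loop.
- **LD blocks** are made by founder copying: within a block every
  haplotype allele is a copy of a shared founder allele with probability
  c = (r² target)^¼, giving pairwise haplotype correlation c² and hence
  LD r² equal to the target; all sites in a block share one MAF so the
  marginals stay in HWE. c = 1 yields exact complete LD (r² = D′ = 1).
- **Missingness** is completely at random at a per-genotype rate,
  default 0.004. The default was set so that the variant call-rate
  filter removes roughly 4% of variants at n = 307 — the same order as
  the staged removal fraction reported for the real array data — whereas
  a 1% rate would fail about a third of all variants at the 0.99
  threshold. The rate is configurable, and several tests deliberately
  run at 1% or higher.
- **Fixtures**: `write_fixtures` emits VCF v4.2 (GT-only, `./.` for
  missing), phenotype/annotation/PPI TSVs. Planted pair variants are
  annotated as exonic in two dedicated genes joined by a PPI edge at
  score 0.9; decoy edges (one below the 0.700 cutoff, one between genes
  hosting no variants) exercise the edge filters. Output is
  deterministic given the seed, byte for byte.

What the generator does *not* emulate: population structure or
admixture, realistic recombination maps, array-intensity artifacts, and
informative (non-random) missingness. Passing calibration here therefore
shows the statistics are correctly implemented and calibrated under the
model's own assumptions, not that the pipeline is robust to structured
confounding in real cohorts — the original study likewise applied no
stratification correction.

## Simulation experiment sizes

Replicated experiments are sized to run quickly on one CPU while leaving
Monte-Carlo error well below the effects being measured: type-I error
uses 200 null variants at n = 144/163 (3·SE band ±0.046 around 0.05);
CI-coverage experiments use 100 replicates at n = 2000/2000 (SE of a
0.95 coverage estimate ≈ 0.022); ranking/power checks use 20–50
replicates where the expected rate is near 1. The end-to-end pipeline
recovery experiment runs 20 replicates at the study scale; its expected
recovery is noticeably below 1 (≈ 0.7) because a per-allele OR of 2 at
144/163 has imperfect single-SNP power and the HWE/call-rate filters
occasionally remove a planted locus — an honest reflection of power at
that sample size, not an implementation defect.

## Numerical conventions

- Dosages are int8 with −1 for missing; all counting excludes missing
  calls locus-wise.
- p-values come from `scipy.stats.chi2.sf` (upper tail, df = 1) and are
  kept at full precision internally; tables round for display only.
- EM initialization uses the unambiguous haplotype counts plus an even
  split of double heterozygotes; with at most three haplotypes present
  the likelihood is unimodal and the boundary optimum is reached to
  within the 1e-8 tolerance.
- Pair-scan output ordering, candidate ordering and PPI edge
  deduplication are all canonical (lexicographic/positional), so every
  table is invariant to input row order and re-runs are byte-identical.
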