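"""Synthetic case-control cohort generation.

The generator reproduces the statistical structure the downstream analysis
assumes: biallelic autosomal SNPs in Hardy–Weinberg equilibrium at
population (control) allele frequencies, a MAF spectrum with a configurable
floor, LD blocks built by founder-haplotype copying, genotype-level missing
data, and planted effects under a multiplicative-penetrance
disease model.

Controls are drawn directly from the population; cases are drawn by
rejection sampling against the disease model, in which each risk-allele
copy at a planted locus multiplies the baseline penetrance by that
effect's odds ratio (pair effects act on the total risk-allele count
across both loci).  Because the multiplicative tilt of a
Hardy–Weinberg genotype distribution factorizes over alleles, the induced
case/control allelic odds ratio equals the planted per-allele odds ratio
exactly, which makes parameter-recovery experiments clean.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import MISSING, GenotypeMatrix, Phenotypes

BASELINE_PREVALENCE = 0.05  # baseline disease probability for genotype (0,...,0)
_MAX_REJECTION_BATCHES = 2000

ALLELE_PAIRS = [("A", "G"), ("C", "T"), ("A", "C"), ("G", "T")]


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one synthetic cohort.

    ``ld_blocks`` is a list of ``(block_size, r2_target)``: consecutive
    runs of variants whose haplotype alleles are copies of a founder allele
    with copy probability ``r2_target ** 0.25``, which yields pairwise
    haplotype-allele correlation ``sqrt(r2_target)`` and hence LD r-squared
    equal to the target.  Planted effects are ``(variant_index, odds_ratio)``
    for single SNPs and ``(index_a, index_b, per_allele_odds_ratio)`` for
    pairs; the risk allele is always the ALT allele.
    """

    n_case: int = 144
    n_control: int = 163
    n_variants: int = 300
    maf_range: tuple[float, float] = (0.03, 0.5)
    missing_rate: float = 0.004
    ld_blocks: tuple[tuple[int, float], ...] = ()
    planted_snp_effects: tuple[tuple[int, float], ...] = ()
    planted_pair_effects: tuple[tuple[int, int, float], ...] = ()
    n_x_decoys: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_case <= 0 or self.n_control <= 0:
            raise ValueError("n_case and n_control must be positive")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError(f"maf_range {self.maf_range} outside (0, 0.5]")
        if not 0.0 <= self.missing_rate <= 1.0:
            raise ValueError("missing_rate outside [0, 1]")
        for idx, orr in self.planted_snp_effects:
            if not 0 <= idx < self.n_variants:
                raise ValueError(f"planted SNP index {idx} out of range")
            if orr <= 0:
                raise ValueError("planted odds ratios must be > 0")
        for ia, ib, orr in self.planted_pair_effects:
            for idx in (ia, ib):
                if not 0 <= idx < self.n_variants:
                    raise ValueError(f"planted pair index {idx} out of range")
            if orr <= 0:
                raise ValueError("planted odds ratios must be > 0")
        if sum(size for size, _ in self.ld_blocks) > self.n_variants:
            raise ValueError("ld_blocks exceed n_variants")


@dataclass
class SyntheticCohort:
    genotypes: GenotypeMatrix
    phenotypes: Phenotypes
    truth: dict = field(default_factory=dict)

    @property
    def variants(self) -> pd.DataFrame:
        return self.genotypes.variants


def _haplotypes(rng, n_hap: int, mafs, blocks) -> np.ndarray:
    """Draw ``n_hap`` haplotypes (rows) over the variants.

    ``blocks`` maps each variant to (block_id or -1, copy probability);
    within a block every site copies the founder allele with that
    probability, otherwise draws independently at the site's ALT frequency.
    """
    n_var = len(mafs)
    hap = (rng.random((n_hap, n_var)) < mafs).astype(np.int8)
    block_ids = sorted({b for b, _ in blocks.values() if b >= 0})
    for bid in block_ids:
        sites = [j for j, (b, _) in blocks.items() if b == bid]
        copy_p = blocks[sites[0]][1]
        founder = (rng.random(n_hap) < mafs[sites[0]]).astype(np.int8)
        for j in sites:
            take = rng.random(n_hap) < copy_p
            hap[take, j] = founder[take]
    return hap


def _disease_prob(genos: np.ndarray, config: SimConfig) -> np.ndarray:
    """P(disease | genotype) under multiplicative penetrance.

    Each risk-allele (ALT) copy at a planted locus multiplies the baseline
    penetrance by that effect's odds ratio, so the case genotype
    distribution is the per-allele tilt of Hardy–Weinberg and the induced
    case/control allelic odds ratio equals the planted value exactly.
    """
    log_p = np.full(genos.shape[0], np.log(BASELINE_PREVALENCE))
    for idx, orr in config.planted_snp_effects:
        log_p += genos[:, idx] * np.log(orr)
    for ia, ib, orr in config.planted_pair_effects:
        log_p += (genos[:, ia] + genos[:, ib]) * np.log(orr)
    return np.minimum(np.exp(log_p), 1.0)


#: tolerated Hardy-Weinberg mass of genotypes whose multiplicative
#: penetrance saturates at 1 (clipped); beyond this the effect-size bias
#: is no longer negligible and the config is rejected
MAX_SATURATED_MASS = 0.01


def _penetrance_audit(mafs: np.ndarray, config: SimConfig) -> None:
    """Reject configs whose planted effects drive penetrance above 1 on a
    non-negligible part of the population.

    Penetrance is clipped at 1 during sampling; clipping on a rare tail
    genotype is harmless, but if the saturated region carries more than
    ``MAX_SATURATED_MASS`` of Hardy-Weinberg probability the planted odds
    ratios would no longer be the estimands, so the config is reported as
    infeasible with the offending effect named.
    """
    from itertools import product as iproduct

    per_locus_or: dict[int, float] = {}
    for idx, orr in config.planted_snp_effects:
        per_locus_or[idx] = per_locus_or.get(idx, 1.0) * orr
    for ia, ib, orr in config.planted_pair_effects:
        for idx in (ia, ib):
            per_locus_or[idx] = per_locus_or.get(idx, 1.0) * orr
    if not per_locus_or:
        return
    loci = sorted(per_locus_or)
    saturated = 0.0
    for combo in iproduct((0, 1, 2), repeat=len(loci)):
        pen = BASELINE_PREVALENCE
        prob = 1.0
        for idx, g in zip(loci, combo):
            pen *= per_locus_or[idx] ** g
            q = mafs[idx]
            prob *= ((1 - q) ** 2, 2 * q * (1 - q), q * q)[g]
        if pen > 1.0:
            saturated += prob
    if saturated > MAX_SATURATED_MASS:
        worst = max(loci, key=lambda i: per_locus_or[i])
        raise ValueError(
            f"infeasible config: penetrance exceeds 1 on {saturated:.3g} of "
            f"the population (baseline {BASELINE_PREVALENCE}); largest "
            f"planted odds ratio product {per_locus_or[worst]:.3g} at "
            f"variant index {worst}"
        )


def _variant_table(config: SimConfig, rng) -> pd.DataFrame:
    """Deterministic variant metadata: autosomal positions plus optional
    X-labelled decoys appended at the end."""
    n = config.n_variants
    # contiguous chromosome runs so LD blocks stay within one chromosome
    chroms = [str(1 + (j * 22) // n) for j in range(n)]
    rows = []
    for j in range(n):
        ref, alt = ALLELE_PAIRS[j % len(ALLELE_PAIRS)]
        rows.append((f"snp{j:05d}", chroms[j], 10_000 + 500 * j, ref, alt))
    for k in range(config.n_x_decoys):
        ref, alt = ALLELE_PAIRS[k % len(ALLELE_PAIRS)]
        rows.append((f"snpX{k:03d}", "X", 10_000 + 500 * k, ref, alt))
    return pd.DataFrame(rows, columns=["variant_id", "chrom", "pos", "ref", "alt"])


def simulate_cohort(config: SimConfig) -> SyntheticCohort:
    """Generate one cohort; deterministic for a fixed ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    n_var = config.n_variants

    mafs = rng.uniform(*config.maf_range, size=n_var)
    _penetrance_audit(mafs, config)
    # one MAF per LD block so copied founder alleles keep HWE marginals
    blocks: dict[int, tuple[int, float]] = {j: (-1, 0.0) for j in range(n_var)}
    j0 = 0
    for bid, (size, r2_target) in enumerate(config.ld_blocks):
        if not 0.0 <= r2_target <= 1.0:
            raise ValueError("r2 target outside [0, 1]")
        copy_p = 1.0 if r2_target == 1.0 else r2_target ** 0.25
        mafs[j0:j0 + size] = mafs[j0]
        for j in range(j0, j0 + size):
            blocks[j] = (bid, copy_p)
        j0 += size

    def draw_genotypes(n_ind: int) -> np.ndarray:
        h1 = _haplotypes(rng, n_ind, mafs, blocks)
        h2 = _haplotypes(rng, n_ind, mafs, blocks)
        return (h1 + h2).astype(np.int8)

    controls = draw_genotypes(config.n_control)

    cases = np.empty((0, n_var), dtype=np.int8)
    has_effects = bool(config.planted_snp_effects or config.planted_pair_effects)
    batch = max(256, int(config.n_case / BASELINE_PREVALENCE / 8))
    for _ in range(_MAX_REJECTION_BATCHES):
        if len(cases) >= config.n_case:
            break
        g = draw_genotypes(batch)
        if has_effects:
            accept = rng.random(batch) < _disease_prob(g, config)
        else:
            # no planted effects: every genotype is equally likely in cases
            accept = np.ones(batch, dtype=bool)
        cases = np.vstack([cases, g[accept]])
    else:
        raise RuntimeError(
            f"disease model cannot produce n_case={config.n_case}: "
            f"baseline prevalence {BASELINE_PREVALENCE} with the planted "
            "effects accepts too few individuals"
        )
    cases = cases[: config.n_case]

    genos = np.vstack([cases, controls])
    if config.n_x_decoys:
        x_mafs = rng.uniform(*config.maf_range, size=config.n_x_decoys)
        x_h = (rng.random((genos.shape[0], config.n_x_decoys)) < x_mafs).astype(np.int8)
        x_h2 = (rng.random((genos.shape[0], config.n_x_decoys)) < x_mafs).astype(np.int8)
        genos = np.hstack([genos, (x_h + x_h2).astype(np.int8)])

    if config.missing_rate > 0:
        holes = rng.random(genos.shape) < config.missing_rate
        genos[holes] = MISSING

    samples = (
        [f"case{i:04d}" for i in range(config.n_case)]
        + [f"ctrl{i:04d}" for i in range(config.n_control)]
    )
    status = pd.Series(
        ["case"] * config.n_case + ["control"] * config.n_control,
        index=pd.Index(samples, name="sample_id"), name="status",
    )
    variants = _variant_table(config, rng)
    gm = GenotypeMatrix(genos, samples, variants)
    truth = {
        "mafs": mafs,
        "planted_snp_effects": list(config.planted_snp_effects),
        "planted_pair_effects": list(config.planted_pair_effects),
        "config": config,
    }
    return SyntheticCohort(gm, Phenotypes(status), truth)


def _annotation_table(cohort: SyntheticCohort) -> pd.DataFrame:
    """Gene/region assignments for fixture runs.

    Planted pair variants land in exons of dedicated, distinct genes; every
    other variant gets its own gene with a deterministic region rotation so
    exonic and non-exonic candidates both occur.
    """
    config: SimConfig = cohort.truth["config"]
    regions = ["exon", "intron", "intergenic"]
    pair_genes: dict[int, str] = {}
    for k, (ia, ib, _) in enumerate(config.planted_pair_effects):
        pair_genes[ia] = f"PAIRGENE{2 * k}"
        pair_genes[ib] = f"PAIRGENE{2 * k + 1}"
    rows = []
    for j, v in cohort.variants.iterrows():
        if j in pair_genes:
            gene, region = pair_genes[j], "exon"
        else:
            gene, region = f"GENE{j:05d}", regions[j % 3]
        rows.append((v["variant_id"], v["chrom"], v["pos"], gene, region))
    return pd.DataFrame(rows, columns=["variant_id", "chrom", "pos", "gene", "region"])


def _ppi_table(cohort: SyntheticCohort) -> pd.DataFrame:
    """STRING-dialect edge list: planted-pair gene edges at high confidence,
    plus decoy edges (below threshold, and between candidate-free genes)."""
    config: SimConfig = cohort.truth["config"]
    rows = []
    for k in range(len(config.planted_pair_effects)):
        rows.append((f"PAIRGENE{2 * k}", f"PAIRGENE{2 * k + 1}", 900))
    rows.append(("DECOY_A", "DECOY_B", 950))       # genes hosting no variant
    rows.append(("GENE00000", "GENE00001", 400))   # below the 0.700 cutoff
    return pd.DataFrame(rows, columns=["protein1", "protein2", "score"])


def write_fixtures(cohort: SyntheticCohort, out_dir) -> dict[str, Path]:
    """Write the VCF + phenotype/annotation/PPI TSVs for one cohort.

    Output is deterministic given the cohort, so a fixed seed yields
    byte-identical files.  Returns the path of each artifact.
    """
    from . import io as hio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": out / "genotypes.vcf",
        "pheno": out / "phenotypes.tsv",
        "annot": out / "annotation.tsv",
        "ppi": out / "ppi_edges.tsv",
    }
    hio.write_vcf(cohort.genotypes, paths["vcf"])
    cohort.phenotypes.status.reset_index().to_csv(
        paths["pheno"], sep="\t", index=False)
    _annotation_table(cohort).to_csv(paths["annot"], sep="\t", index=False)
    _ppi_table(cohort).to_csv(paths["ppi"], sep="\t", index=False)
    return paths
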