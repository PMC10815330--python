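"""Two-locus haplotype-group association for protein-interaction SNP pairs.

Each pair of exonic SNPs is first polarized: at every locus the *negative*
allele is the risk allele (single-SNP odds ratio above 1) and the
*positive* allele is the protective one.  Two tests follow.

Pooled-allele multiplicative test
    The up-to-four alleles an individual carries across the two loci are
    pooled into a case/control 2x2 of negative vs positive allele counts;
    odds ratio, Woolf CI and Pearson chi-square are computed exactly as in
    the single-SNP allelic model.  An individual missing one locus still
    contributes the other locus's two alleles.

Additive (group-contrast) test
    Individuals with complete genotypes at both loci are stratified by
    their total negative-allele count k into Group I (k = 3-4, negative
    alleles prevail), Group II (k = 2, balanced — the compound
    heterozygote stratum), and Group III (k = 0-1, positive alleles
    prevail); this splits the nine two-locus genotype combinations 3/3/3.
    The default contrast compares Group I against Group III as a 2x2 of
    individual counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .association import AlleleTable2x2, chi2_p, odds_ratio, woolf_ci
from .containers import MISSING, GenotypeMatrix, Phenotypes
from .ppi import SnpPair

CONTRASTS = ("I_vs_III", "I_vs_II+III")


@dataclass(frozen=True)
class PolarizedPair:
    pair: SnpPair
    negative_allele_a: str
    positive_allele_a: str
    negative_allele_b: str
    positive_allele_b: str


@dataclass(frozen=True)
class GroupCounts:
    case_I: int
    case_II: int
    case_III: int
    control_I: int
    control_II: int
    control_III: int


def polarize(pair: SnpPair, assoc_results: pd.DataFrame) -> PolarizedPair:
    """Attach the risk (negative) and protective (positive) allele at each
    locus, taken from the stage-1 single-SNP odds ratios."""

    def direction(variant_id: str) -> tuple[str, str]:
        rows = assoc_results.loc[assoc_results["variant_id"] == variant_id]
        if rows.empty:
            raise KeyError(f"variant {variant_id} absent from stage-1 results")
        row = rows.iloc[0]
        or_val = row["or_value"]
        if not np.isfinite(or_val) or or_val == 1.0:
            raise ValueError(
                f"variant {variant_id} has no risk direction (OR = {or_val})")
        if or_val > 1.0:
            return row["effect_allele"], row["other_allele"]
        return row["other_allele"], row["effect_allele"]

    neg_a, pos_a = direction(pair.variant_a)
    neg_b, pos_b = direction(pair.variant_b)
    return PolarizedPair(pair, neg_a, pos_a, neg_b, pos_b)


def _negative_dosages(
    genotypes: GenotypeMatrix, variant_id: str, negative_allele: str
) -> np.ndarray:
    """Per-sample count of the negative allele (missing stays MISSING)."""
    j = genotypes.variant_index(variant_id)
    v = genotypes.variants.iloc[j]
    g = genotypes.dosages[:, j].astype(np.int16)
    if negative_allele == v["alt"]:
        out = g.copy()
    elif negative_allele == v["ref"]:
        out = np.where(g == MISSING, MISSING, 2 - g)
    else:
        raise ValueError(
            f"allele {negative_allele!r} not one of {v['ref']}/{v['alt']} "
            f"at {variant_id}")
    return out


def pooled_allele_table(
    p: PolarizedPair, genotypes: GenotypeMatrix, phenotypes: Phenotypes
) -> AlleleTable2x2:
    """Case/control 2x2 of pooled negative vs positive allele counts.

    A locus missing in an individual drops only that locus's two alleles;
    the other locus still contributes.
    """
    case_mask = phenotypes.case_mask(genotypes.samples)
    da = _negative_dosages(genotypes, p.pair.variant_a, p.negative_allele_a)
    db = _negative_dosages(genotypes, p.pair.variant_b, p.negative_allele_b)

    def pool(mask: np.ndarray) -> tuple[int, int]:
        neg = pos = 0
        for d in (da[mask], db[mask]):
            ok = d != MISSING
            neg += int(d[ok].sum())
            pos += int(2 * ok.sum() - d[ok].sum())
        return neg, pos

    a, b = pool(case_mask)
    c, d = pool(~case_mask)
    if a + b + c + d == 0:
        raise ValueError("pair has no non-missing genotype data")
    return AlleleTable2x2(a, b, c, d)


def multiplicative_test(t: AlleleTable2x2) -> tuple[float, tuple[float, float], float]:
    """(OR, 95% CI, p) on the pooled table — same machinery as stage 1."""
    chi2, p = chi2_p(t)
    return odds_ratio(t), woolf_ci(t), p


def classify_group(dosage_a: int, dosage_b: int) -> str:
    """Group I/II/III by total negative-allele count across both loci."""
    for d in (dosage_a, dosage_b):
        if d not in (0, 1, 2):
            raise ValueError(f"dosage {d} outside 0..2 (complete calls only)")
    k = dosage_a + dosage_b
    if k >= 3:
        return "I"
    if k == 2:
        return "II"
    return "III"


def group_counts(
    p: PolarizedPair, genotypes: GenotypeMatrix, phenotypes: Phenotypes
) -> GroupCounts:
    """Stratum sizes over individuals with complete calls at both loci."""
    case_mask = phenotypes.case_mask(genotypes.samples)
    da = _negative_dosages(genotypes, p.pair.variant_a, p.negative_allele_a)
    db = _negative_dosages(genotypes, p.pair.variant_b, p.negative_allele_b)
    complete = (da != MISSING) & (db != MISSING)

    def tally(mask: np.ndarray) -> tuple[int, int, int]:
        k = da[mask] + db[mask]
        return int((k >= 3).sum()), int((k == 2).sum()), int((k <= 1).sum())

    ci, cii, ciii = tally(case_mask & complete)
    ui, uii, uiii = tally(~case_mask & complete)
    return GroupCounts(ci, cii, ciii, ui, uii, uiii)


def additive_test(
    g: GroupCounts, contrast: str = "I_vs_III"
) -> tuple[float, tuple[float, float], float]:
    """Group-contrast odds ratio on individual counts.

    ``I_vs_III`` uses (case_I, case_III, control_I, control_III);
    ``I_vs_II+III`` pools Groups II and III as the reference stratum.
    """
    if contrast == "I_vs_III":
        t = AlleleTable2x2(g.case_I, g.case_III, g.control_I, g.control_III)
    elif contrast == "I_vs_II+III":
        t = AlleleTable2x2(
            g.case_I, g.case_II + g.case_III,
            g.control_I, g.control_II + g.control_III,
        )
    else:
        raise ValueError(f"unknown contrast {contrast!r}; use one of {CONTRASTS}")
    chi2, p = chi2_p(t)
    return odds_ratio(t), woolf_ci(t), p


def pair_scan(
    pairs: list[SnpPair],
    genotypes: GenotypeMatrix,
    phenotypes: Phenotypes,
    assoc_results: pd.DataFrame,
    alpha: float = 0.05,
    contrast: str = "I_vs_III",
) -> pd.DataFrame:
    """Both models for every pair, with stage-2 Bonferroni flagging.

    The Bonferroni divisor is the number of pairs actually tested in this
    scan.  Per-pair failures are recorded in the ``error`` column and the
    scan continues.  Output is sorted by the multiplicative p-value.
    """
    if not pairs:
        raise ValueError("no SNP pairs to scan")
    rows = []
    for pair in pairs:
        rec: dict = {
            "variant_a": pair.variant_a, "variant_b": pair.variant_b,
            "gene_a": pair.gene_a, "gene_b": pair.gene_b,
            "edge_score": pair.edge_score, "error": "",
        }
        try:
            pol = polarize(pair, assoc_results)
            t = pooled_allele_table(pol, genotypes, phenotypes)
            mult_or, (mlo, mhi), mult_p = multiplicative_test(t)
            g = group_counts(pol, genotypes, phenotypes)
            add_or, (alo, ahi), add_p = additive_test(g, contrast)
            rec.update(
                negative_allele_a=pol.negative_allele_a,
                positive_allele_a=pol.positive_allele_a,
                negative_allele_b=pol.negative_allele_b,
                positive_allele_b=pol.positive_allele_b,
                case_negative=t.a, case_positive=t.b,
                control_negative=t.c, control_positive=t.d,
                mult_or=mult_or, mult_ci_low=mlo, mult_ci_high=mhi,
                mult_p=mult_p,
                case_I=g.case_I, case_II=g.case_II, case_III=g.case_III,
                control_I=g.control_I, control_II=g.control_II,
                control_III=g.control_III,
                add_or=add_or, add_ci_low=alo, add_ci_high=ahi, add_p=add_p,
            )
        except (ValueError, KeyError) as exc:
            rec["error"] = str(exc)
            rec["mult_p"] = np.nan
        rows.append(rec)
    out = pd.DataFrame(rows)
    n_tested = int(out["error"].eq("").sum())
    threshold = alpha / max(n_tested, 1)
    out["bonferroni_threshold"] = threshold
    out["passes_bonferroni"] = out["mult_p"] < threshold
    return out.sort_values("mult_p", kind="stable").reset_index(drop=True)
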