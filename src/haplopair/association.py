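"""Stage-1 single-SNP allelic association.

The allelic (multiplicative) model compares allele counts between cases and
controls: every non-missing diploid call contributes two alleles to its
group's 2x2 table.  Effect sizes are odds ratios with Woolf (log-scale)
confidence intervals; significance is the Pearson chi-square test on the
2x2 table with one degree of freedom and no continuity correction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .containers import MISSING, GenotypeMatrix, Phenotypes

Z95 = sps.norm.ppf(0.975)


@dataclass(frozen=True)
class AlleleTable2x2:
    """Allele-count contingency table.

    ``a``/``b`` are case effect/other allele counts, ``c``/``d`` the control
    counts.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("allele counts must be non-negative")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def swapped(self) -> "AlleleTable2x2":
        """Table with the effect allele and the other allele exchanged."""
        return AlleleTable2x2(self.b, self.a, self.d, self.c)


def allele_table(
    case_dosages: np.ndarray,
    control_dosages: np.ndarray,
    effect_is_alt: bool = True,
) -> AlleleTable2x2:
    """Tally the 2x2 allele table for one biallelic variant.

    Missing calls (``MISSING``) are excluded; every other diploid call adds
    two alleles to its group.  ``effect_is_alt`` selects which allele's
    dosage the matrix encodes as the effect allele.
    """
    case_dosages = np.asarray(case_dosages)
    control_dosages = np.asarray(control_dosages)
    case_ok = case_dosages != MISSING
    ctrl_ok = control_dosages != MISSING
    if not case_ok.any() and not ctrl_ok.any():
        raise ValueError("all genotypes missing at this variant")
    a = int(case_dosages[case_ok].sum())
    b = int(2 * case_ok.sum() - a)
    c = int(control_dosages[ctrl_ok].sum())
    d = int(2 * ctrl_ok.sum() - c)
    t = AlleleTable2x2(a, b, c, d)
    return t if effect_is_alt else t.swapped()


def odds_ratio(t: AlleleTable2x2) -> float:
    """(a*d)/(b*c); ``nan`` when a denominator cell is zero (no correction)."""
    if t.b * t.c == 0:
        return math.nan
    return (t.a * t.d) / (t.b * t.c)


def woolf_ci(t: AlleleTable2x2, level: float = 0.95) -> tuple[float, float]:
    """Log-scale (Woolf) confidence interval for the odds ratio.

    exp(ln OR +/- z * sqrt(1/a + 1/b + 1/c + 1/d)).  Undefined (nan, nan)
    when any cell is zero.
    """
    if min(t.a, t.b, t.c, t.d) == 0:
        return (math.nan, math.nan)
    z = sps.norm.ppf(0.5 + level / 2.0)
    log_or = math.log(odds_ratio(t))
    se = math.sqrt(1 / t.a + 1 / t.b + 1 / t.c + 1 / t.d)
    return (math.exp(log_or - z * se), math.exp(log_or + z * se))


def chi2_p(t: AlleleTable2x2) -> tuple[float, float]:
    """Pearson chi-square (df=1, no continuity correction) and its p-value.

    chi2 = N (ad - bc)^2 / ((a+b)(c+d)(a+c)(b+d)); degenerate margins give
    (0.0, 1.0).
    """
    r1, r2 = t.a + t.b, t.c + t.d
    c1, c2 = t.a + t.c, t.b + t.d
    denom = r1 * r2 * c1 * c2
    if denom == 0:
        return (0.0, 1.0)
    num = t.n * (t.a * t.d - t.b * t.c) ** 2
    chi2 = num / denom
    return (chi2, float(sps.chi2.sf(chi2, df=1)))


def bonferroni(alpha: float, m: int) -> float:
    """Per-test significance threshold alpha/m for m tests."""
    if m < 1:
        raise ValueError("number of tests must be >= 1")
    return alpha / m


def run_gwas(
    genotypes: GenotypeMatrix,
    phenotypes: Phenotypes,
) -> pd.DataFrame:
    """Allelic association scan over every variant in the matrix.

    The effect allele is the minor allele in the pooled (case + control)
    sample; at an exact 50/50 split the reference allele is designated.
    Both the effect-allele OR and its reciprocal (the other allele's OR)
    are reported, mirroring the two-directional presentation conventional
    in case-control tables.

    Returns a DataFrame sorted by (chrom, pos) with one row per variant:
    variant_id, chrom, pos, effect_allele, other_allele, a, b, c, d,
    maf_case, maf_control, or_value, or_other, ci_low, ci_high, chi2, p.
    """
    case_mask = phenotypes.case_mask(genotypes.samples)
    if case_mask.sum() == 0 or (~case_mask).sum() == 0:
        raise ValueError("need at least one case and one control")
    case = genotypes.dosages[case_mask]
    ctrl = genotypes.dosages[~case_mask]

    rows = []
    for j in range(genotypes.n_variants):
        v = genotypes.variants.iloc[j]
        case_d, ctrl_d = case[:, j], ctrl[:, j]
        pooled = genotypes.dosages[:, j]
        ok = pooled != MISSING
        if not ok.any():
            raise ValueError(f"variant {v['variant_id']} is entirely missing")
        alt_freq = pooled[ok].sum() / (2 * ok.sum())
        # minor allele is the effect allele; ties go to the reference allele
        effect_is_alt = alt_freq < 0.5
        t = allele_table(case_d, ctrl_d, effect_is_alt=effect_is_alt)
        or_val = odds_ratio(t)
        ci_low, ci_high = woolf_ci(t)
        chi2, p = chi2_p(t)
        case_ok, ctrl_ok = case_d != MISSING, ctrl_d != MISSING
        maf_case = (
            t.a / (t.a + t.b) if case_ok.any() else math.nan
        )
        maf_control = (
            t.c / (t.c + t.d) if ctrl_ok.any() else math.nan
        )
        eff, other = (
            (v["alt"], v["ref"]) if effect_is_alt else (v["ref"], v["alt"])
        )
        rows.append(
            {
                "variant_id": v["variant_id"],
                "chrom": v["chrom"],
                "pos": v["pos"],
                "effect_allele": eff,
                "other_allele": other,
                "a": t.a, "b": t.b, "c": t.c, "d": t.d,
                "maf_case": maf_case,
                "maf_control": maf_control,
                "or_value": or_val,
                "or_other": 1.0 / or_val if or_val and not math.isnan(or_val) else math.nan,
                "ci_low": ci_low,
                "ci_high": ci_high,
                "chi2": chi2,
                "p": p,
            }
        )
    out = pd.DataFrame(rows)
    return out.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)


def manhattan_export(
    results: pd.DataFrame,
    tsv_path,
    plot_path=None,
    gwas_threshold: float = 5e-8,
    bonferroni_threshold: float | None = None,
):
    """Write the (chrom, pos, -log10 p) table and, optionally, the plot.

    Horizontal reference lines mark the conventional genome-wide threshold
    and, when given, the study-internal Bonferroni threshold.
    """
    table = results[["chrom", "pos", "p"]].copy()
    table["neg_log10_p"] = -np.log10(table["p"])
    table.to_csv(tsv_path, sep="\t", index=False)
    if plot_path is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(9, 3.5))
        chroms = list(dict.fromkeys(table["chrom"]))
        offset, ticks = 0.0, []
        for i, ch in enumerate(chroms):
            sub = table[table["chrom"] == ch]
            x = offset + sub["pos"].to_numpy(dtype=float)
            ax.scatter(x, sub["neg_log10_p"], s=6,
                       color="steelblue" if i % 2 == 0 else "darkorange")
            ticks.append((offset + x.max()) / 2 if len(x) else offset)
            offset = x.max() + 1 if len(x) else offset
        ax.axhline(-math.log10(gwas_threshold), color="black", lw=1)
        if bonferroni_threshold is not None:
            ax.axhline(-math.log10(bonferroni_threshold), color="red",
                       lw=1, ls="--")
        ax.set_xticks(ticks, [str(c) for c in chroms])
        ax.set_xlabel("chromosome")
        ax.set_ylabel(r"$-\log_{10} p$")
        fig.tight_layout()
        fig.savefig(plot_path)
        plt.close(fig)
    return table
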