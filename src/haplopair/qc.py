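"""Sequential genotype quality control with a staged removal ledger.

Filters are applied in a fixed order — non-autosomal variants, variant call
rate, sample call rate, minor allele frequency, Hardy–Weinberg equilibrium —
and each removed variant is attributed to exactly one stage (the first it
fails), so the ledger counts always sum back to the input count.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .containers import MISSING, GenotypeMatrix, Phenotypes, is_autosomal


@dataclass(frozen=True)
class QCThresholds:
    """Filter settings.

    Variants need a call rate of at least ``min_variant_call_rate`` (0.99,
    i.e. at most 1% failed calls) and samples ``min_sample_call_rate``
    (0.95).  ``min_maf`` keeps common variants only (3% floor) and
    ``hwe_alpha`` removes variants whose genotype counts deviate from
    Hardy–Weinberg proportions at that significance level.  HWE is tested
    in controls only by default.
    """

    min_sample_call_rate: float = 0.95
    min_variant_call_rate: float = 0.99
    min_maf: float = 0.03
    hwe_alpha: float = 0.05
    autosomes_only: bool = True
    hwe_controls_only: bool = True

    def __post_init__(self) -> None:
        for name in ("min_sample_call_rate", "min_variant_call_rate",
                     "min_maf", "hwe_alpha"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")


@dataclass
class QCReport:
    """Staged removal ledger.

    Invariant: ``n_variants_in`` equals the sum of the four per-stage
    variant removals plus ``n_variants_kept``.  Sample removals are tracked
    separately (they do not consume variants).
    """

    n_variants_in: int
    n_removed_nonautosomal: int = 0
    n_removed_call_rate: int = 0
    n_samples_removed: int = 0
    n_removed_maf: int = 0
    n_removed_hwe: int = 0
    n_variants_kept: int = 0

    def check(self) -> None:
        total = (self.n_removed_nonautosomal + self.n_removed_call_rate
                 + self.n_removed_maf + self.n_removed_hwe
                 + self.n_variants_kept)
        if total != self.n_variants_in:
            raise ValueError(
                f"ledger does not balance: in={self.n_variants_in}, "
                f"removed+kept={total}"
            )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                ("variants_in", self.n_variants_in),
                ("removed_nonautosomal", self.n_removed_nonautosomal),
                ("removed_call_rate", self.n_removed_call_rate),
                ("samples_removed", self.n_samples_removed),
                ("removed_maf", self.n_removed_maf),
                ("removed_hwe", self.n_removed_hwe),
                ("variants_kept", self.n_variants_kept),
            ],
            columns=["stage", "count"],
        )


def call_rates(genotypes: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Fraction of non-missing calls per sample and per variant."""
    if genotypes.n_samples == 0 or genotypes.n_variants == 0:
        raise ValueError("empty genotype matrix")
    present = genotypes.dosages != MISSING
    return present.mean(axis=1), present.mean(axis=0)


def minor_allele_frequency(dosages: np.ndarray) -> float:
    """min(p, 1-p) of the allele-count fraction over non-missing calls."""
    dosages = np.asarray(dosages)
    ok = dosages != MISSING
    if not ok.any():
        raise ValueError("all calls missing at this variant")
    p = dosages[ok].sum() / (2 * ok.sum())
    return float(min(p, 1.0 - p))


def hwe_test(n_hom_ref: int, n_het: int, n_hom_alt: int) -> tuple[float, float]:
    """Pearson chi-square test (df=1) for Hardy–Weinberg proportions.

    Expected genotype counts come from the estimated allele frequency;
    monomorphic variants return (0.0, 1.0) by convention.
    """
    n = n_hom_ref + n_het + n_hom_alt
    if n <= 0:
        raise ValueError("no genotype calls")
    p = (2 * n_hom_ref + n_het) / (2 * n)
    q = 1.0 - p
    if p == 0.0 or q == 0.0:
        return (0.0, 1.0)
    expected = np.array([n * p * p, 2 * n * p * q, n * q * q])
    observed = np.array([n_hom_ref, n_het, n_hom_alt], dtype=float)
    chi2 = float(((observed - expected) ** 2 / expected).sum())
    return (chi2, float(sps.chi2.sf(chi2, df=1)))


def _hwe_pvalues(dosages: np.ndarray) -> np.ndarray:
    """Vectorized per-variant HWE p-values over a dosage block."""
    out = np.ones(dosages.shape[1])
    for j in range(dosages.shape[1]):
        col = dosages[:, j]
        col = col[col != MISSING]
        if col.size == 0:
            continue
        n0 = int((col == 0).sum())
        n1 = int((col == 1).sum())
        n2 = int((col == 2).sum())
        out[j] = hwe_test(n0, n1, n2)[1]
    return out


def apply_qc(
    genotypes: GenotypeMatrix,
    phenotypes: Phenotypes | None,
    thresholds: QCThresholds = QCThresholds(),
) -> tuple[GenotypeMatrix, QCReport]:
    """Run the sequential filters and return the surviving matrix + ledger.

    Order: non-autosomal removal, variant call rate, sample call rate
    (samples dropped; earlier variant stages are not revisited), MAF and
    HWE recomputed on the surviving samples.  ``phenotypes`` is required
    when HWE is restricted to controls.
    """
    report = QCReport(n_variants_in=genotypes.n_variants)
    gm = genotypes

    if thresholds.autosomes_only:
        auto = is_autosomal(gm.variants["chrom"])
        report.n_removed_nonautosomal = int((~auto).sum())
        gm = gm.subset_variants(auto)

    sample_rates, variant_rates = call_rates(gm) if gm.n_variants else (
        np.ones(gm.n_samples), np.empty(0))
    keep_v = variant_rates >= thresholds.min_variant_call_rate
    report.n_removed_call_rate = int((~keep_v).sum())
    gm = gm.subset_variants(keep_v)

    if gm.n_variants:
        sample_rates, _ = call_rates(gm)
    keep_s = sample_rates >= thresholds.min_sample_call_rate
    report.n_samples_removed = int((~keep_s).sum())
    gm = gm.subset_samples(keep_s)

    mafs = np.array([
        minor_allele_frequency(gm.dosages[:, j]) for j in range(gm.n_variants)
    ])
    keep_maf = mafs >= thresholds.min_maf
    report.n_removed_maf = int((~keep_maf).sum())
    gm = gm.subset_variants(keep_maf)

    if thresholds.hwe_controls_only:
        if phenotypes is None:
            raise ValueError("phenotypes required for controls-only HWE")
        case_mask = phenotypes.case_mask(gm.samples)
        hwe_block = gm.dosages[~case_mask]
    else:
        hwe_block = gm.dosages
    pvals = _hwe_pvalues(hwe_block)
    keep_hwe = pvals >= thresholds.hwe_alpha
    report.n_removed_hwe = int((~keep_hwe).sum())
    gm = gm.subset_variants(keep_hwe)

    report.n_variants_kept = gm.n_variants
    report.check()
    return gm, report
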