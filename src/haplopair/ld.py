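"""Pairwise linkage disequilibrium from unphased genotypes.

Haplotype frequencies at a pair of biallelic loci are estimated by the
standard two-locus EM algorithm (the only phase ambiguity is the double
heterozygote), then summarized as D, D' and r-squared with a chi-square
significance test (chi2 = n_chromosomes * r2, df = 1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .containers import MISSING

EM_TOL = 1e-8
EM_MAX_ITER = 1000


@dataclass(frozen=True)
class LDResult:
    variant_a: str
    variant_b: str
    hap_freqs: tuple[float, float, float, float]  # f(AB), f(Ab), f(aB), f(ab)
    d: float
    d_prime: float
    r2: float
    p: float
    n_chrom: int


def em_haplotype_freqs(
    dosages_a: np.ndarray, dosages_b: np.ndarray
) -> tuple[tuple[float, float, float, float], int]:
    """ML haplotype frequencies (f_AB, f_Ab, f_aB, f_ab) for two loci.

    ``A``/``B`` denote the reference alleles (dosage counts the ALT allele,
    lower case).  Individuals missing either genotype are excluded;
    returns the frequency 4-tuple and the number of chromosomes used.
    Monomorphic loci are allowed here; downstream LD statistics flag them.
    """
    da = np.asarray(dosages_a)
    db = np.asarray(dosages_b)
    ok = (da != MISSING) & (db != MISSING)
    da, db = da[ok].astype(int), db[ok].astype(int)
    n = da.size
    if n == 0:
        raise ValueError("no individuals with both genotypes called")
    n_chrom = 2 * n

    # 3x3 genotype cross-table; cell (i, j) = count with ALT dosages (i, j)
    counts = np.zeros((3, 3), dtype=float)
    np.add.at(counts, (da, db), 1.0)

    # unambiguous haplotype contributions; double hets split in the E-step
    # haplotype order: AB, Ab, aB, ab  (A = ref at locus 1, B = ref at locus 2)
    base = np.zeros(4)
    # per-cell contributions of known haplotypes (two per individual)
    known = {
        (0, 0): (2, 0, 0, 0), (0, 1): (1, 1, 0, 0), (0, 2): (0, 2, 0, 0),
        (1, 0): (1, 0, 1, 0), (1, 2): (0, 1, 0, 1),
        (2, 0): (0, 0, 2, 0), (2, 1): (0, 0, 1, 1), (2, 2): (0, 0, 0, 2),
    }
    for (i, j), contrib in known.items():
        base += counts[i, j] * np.asarray(contrib, dtype=float)
    n_dh = counts[1, 1]  # double heterozygotes: AB/ab or Ab/aB

    freqs = np.full(4, 0.25)
    if base.sum() > 0 or n_dh > 0:
        start = base + n_dh * np.array([0.5, 0.5, 0.5, 0.5])
        freqs = start / start.sum()
    for _ in range(EM_MAX_ITER):
        f_ab_cis = freqs[0] * freqs[3]      # AB/ab
        f_ab_trans = freqs[1] * freqs[2]    # Ab/aB
        tot = f_ab_cis + f_ab_trans
        w = 0.5 if tot == 0 else f_ab_cis / tot
        new = base + n_dh * np.array([w, 1 - w, 1 - w, w])
        new /= new.sum()
        if np.max(np.abs(new - freqs)) < EM_TOL:
            freqs = new
            break
        freqs = new
    return (float(freqs[0]), float(freqs[1]), float(freqs[2]), float(freqs[3])), n_chrom


def ld_stats(
    hap_freqs: tuple[float, float, float, float],
    n_chrom: int,
    variant_a: str = "a",
    variant_b: str = "b",
) -> LDResult:
    """D, D', r2 and chi-square p-value from haplotype frequencies.

    D = f(AB) - pA*pB; D' normalizes by the maximum attainable |D| given
    the allele frequencies; r2 = D^2 / (pA*pa*pB*pb).  Raises when either
    locus is monomorphic (LD undefined).
    """
    f_ab, f_aB_, f_bA_, f_ab_min = hap_freqs  # AB, Ab, aB, ab
    total = sum(hap_freqs)
    if not math.isclose(total, 1.0, abs_tol=1e-6):
        raise ValueError("haplotype frequencies must sum to 1")
    p_a = f_ab + f_aB_          # P(ref allele at locus 1)
    p_b = f_ab + f_bA_          # P(ref allele at locus 2)
    q_a, q_b = 1.0 - p_a, 1.0 - p_b
    if min(p_a, q_a, p_b, q_b) <= 0:
        raise ValueError("monomorphic locus: LD undefined")
    d = f_ab - p_a * p_b
    if d > 0:
        d_max = min(p_a * q_b, q_a * p_b)
    else:
        d_max = min(p_a * p_b, q_a * q_b)
    d_prime = 0.0 if d == 0 else abs(d) / d_max
    r2 = d * d / (p_a * q_a * p_b * q_b)
    chi2 = n_chrom * r2
    p = float(sps.chi2.sf(chi2, df=1)) if r2 > 0 else 1.0
    return LDResult(variant_a, variant_b, tuple(hap_freqs), d, d_prime,
                    min(r2, 1.0), p, n_chrom)


def ld_between(
    dosages_a: np.ndarray,
    dosages_b: np.ndarray,
    variant_a: str = "a",
    variant_b: str = "b",
) -> LDResult:
    """EM haplotype frequencies followed by LD statistics for one pair."""
    freqs, n_chrom = em_haplotype_freqs(dosages_a, dosages_b)
    return ld_stats(freqs, n_chrom, variant_a, variant_b)


def loglik(hap_freqs, dosages_a, dosages_b) -> float:
    """Observed-data log-likelihood of unphased genotypes given haplotype
    frequencies; used by tests as an independent check of the EM optimum."""
    f = np.asarray(hap_freqs, dtype=float)
    da = np.asarray(dosages_a)
    db = np.asarray(dosages_b)
    ok = (da != MISSING) & (db != MISSING)
    da, db = da[ok].astype(int), db[ok].astype(int)
    # genotype probability = sum over compatible ordered haplotype pairs
    probs = {
        (0, 0): f[0] ** 2, (0, 1): 2 * f[0] * f[1], (0, 2): f[1] ** 2,
        (1, 0): 2 * f[0] * f[2], (1, 2): 2 * f[1] * f[3],
        (2, 0): f[2] ** 2, (2, 1): 2 * f[2] * f[3], (2, 2): f[3] ** 2,
        (1, 1): 2 * f[0] * f[3] + 2 * f[1] * f[2],
    }
    ll = 0.0
    for i, j in zip(da, db):
        pg = probs[(int(i), int(j))]
        if pg <= 0:
            return -math.inf
        ll += math.log(pg)
    return ll
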