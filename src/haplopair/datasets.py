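"""Published summary statistics used for cross-validation.

These constants are summary-level results from an external two-stage
case-control association study of early-onset breast cancer (144 cases,
163 controls): the staged genotype-QC removal counts, a reconstructed
single-SNP allele table, and the pooled-allele 2x2 tables reported for the
seven significant protein-interaction SNP pairs.  The individual-level
genotypes behind them were never deposited, so these printed tables are
the only quantities the statistical machinery can be checked against.
"""

from __future__ import annotations

from .association import AlleleTable2x2

# staged QC ledger: autosomal markers in, removals per sequential filter
QC_LEDGER = {
    "n_variants_in": 654_027,
    "n_removed_call_rate": 25_323,
    "n_samples_removed": 3,
    "n_removed_maf": 231_362,
    "n_removed_hwe": 70_304,
}

#: markers surviving QC; the stage-1 Bonferroni divisor
N_MARKERS_TESTED = 327_038

#: pairs behind the reported stage-2 Bonferroni threshold of 9.4e-4
N_STAGE2_TESTS = 53

# pooled-allele 2x2 tables (case negative, case positive, control negative,
# control positive) for the seven significant protein-pair haplotype tests,
# keyed by the gene pair; published multiplicative ORs in PAIR_TABLE_ORS.
PAIR_TABLES: dict[str, AlleleTable2x2] = {
    "A2M/LRP1": AlleleTable2x2(103, 473, 60, 592),
    "A2ML1/LRP1": AlleleTable2x2(156, 420, 120, 532),
    "HEATR1/NOP14": AlleleTable2x2(469, 107, 479, 173),
    "NOL10/NOP14": AlleleTable2x2(418, 158, 413, 237),
    "SLX4/TOPBP1": AlleleTable2x2(507, 69, 528, 124),
    "GABRP/NSF": AlleleTable2x2(84, 492, 53, 599),
    "ACKR1/CD82": AlleleTable2x2(216, 360, 181, 435),
}

PAIR_TABLE_ORS: dict[str, float] = {
    "A2M/LRP1": 2.15,
    "A2ML1/LRP1": 1.65,
    "HEATR1/NOP14": 1.58,
    "NOL10/NOP14": 1.52,
    "SLX4/TOPBP1": 1.73,
    "GABRP/NSF": 1.93,
    "ACKR1/CD82": 1.44,
}

# single-SNP spot check: rs942694 printed case/control MAFs with the
# cohort sizes, from which integer allele counts reconstruct uniquely
RS942694 = {
    "maf_case": 0.29,
    "maf_control": 0.14,
    "n_case": 144,
    "n_control": 163,
    "or_reported": 2.51,
}


def rs942694_table() -> AlleleTable2x2:
    """Allele table reconstructed from the printed MAFs (nearest integer)."""
    a = round(RS942694["maf_case"] * 2 * RS942694["n_case"])
    c = round(RS942694["maf_control"] * 2 * RS942694["n_control"])
    return AlleleTable2x2(
        a, 2 * RS942694["n_case"] - a,
        c, 2 * RS942694["n_control"] - c,
    )
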