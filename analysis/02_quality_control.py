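"""Sequential genotype QC on the simulated cohort.

Applies the staged filters — non-autosomal variants, variant call rate
(>= 0.99), sample call rate (>= 0.95), MAF floor (0.03), Hardy-Weinberg
equilibrium in controls (alpha 0.05) — and writes the filtered VCF plus
the removal ledger, whose counts always sum back to the input count.
"""

from pathlib import Path

from haplopair import io
from haplopair.qc import QCThresholds, apply_qc

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    genotypes = io.read_vcf(ROOT / "fixtures" / "genotypes.vcf")
    phenotypes = io.read_phenotypes(ROOT / "fixtures" / "phenotypes.tsv")
    gm, report = apply_qc(genotypes, phenotypes, QCThresholds())

    out = ROOT / "qc"
    out.mkdir(parents=True, exist_ok=True)
    io.write_vcf(gm, out / "qc.vcf")
    report.to_frame().to_csv(out / "qc_report.tsv", sep="\t", index=False)

    print(report.to_frame().to_string(index=False))
    total = (report.n_removed_nonautosomal + report.n_removed_call_rate
             + report.n_removed_maf + report.n_removed_hwe
             + report.n_variants_kept)
    assert total == report.n_variants_in, "ledger does not balance"
    print(f"\nledger balances: {report.n_variants_in} in = "
          f"{report.n_variants_in - report.n_variants_kept} removed + "
          f"{report.n_variants_kept} kept")


if __name__ == "__main__":
    main()
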