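"""Stage-1 single-SNP allelic association scan on the QC-passed matrix.

For every variant: the 2x2 allele-count table (effect allele = pooled
minor allele), odds ratio with its reciprocal, Woolf 95% CI, Pearson
chi-square p-value.  Writes the association table, the Manhattan TSV/SVG
with the genome-wide (5e-8) and study-internal Bonferroni reference
lines, and prints the top hits.
"""

from pathlib import Path

from haplopair import io
from haplopair.association import bonferroni, manhattan_export, run_gwas

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    gm = io.read_vcf(ROOT / "qc" / "qc.vcf")
    phenotypes = io.read_phenotypes(ROOT / "fixtures" / "phenotypes.tsv")
    results = run_gwas(gm, phenotypes)

    out = ROOT / "gwas"
    out.mkdir(parents=True, exist_ok=True)
    results.to_csv(out / "assoc.tsv", sep="\t", index=False)
    bonf = bonferroni(0.05, len(results))
    manhattan_export(results, out / "manhattan.tsv", out / "manhattan.svg",
                     gwas_threshold=5e-8, bonferroni_threshold=bonf)

    n_sig = int((results["p"] < 0.05).sum())
    print(f"{len(results)} variants tested; {n_sig} at p < 0.05; "
          f"internal Bonferroni threshold {bonf:.2e}")
    top = results.nsmallest(5, "p")[
        ["variant_id", "chrom", "pos", "effect_allele",
         "maf_case", "maf_control", "or_value", "ci_low", "ci_high", "p"]]
    print("\ntop associations:")
    print(top.to_string(index=False, float_format=lambda v: f"{v:.3g}"))


if __name__ == "__main__":
    main()
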