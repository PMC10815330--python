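"""Calibration and parameter-recovery experiments on synthetic cohorts.

Because the study's genotypes were never deposited, the statistical
machinery is validated on its own generator instead: type-I error of the
allelic test at the study's sample sizes, Woolf-CI coverage of planted
single-SNP (OR 2.5) and two-locus (per-allele OR 2.0) effects at
n = 2000/2000 over 100 replicates, and the top-hit ranking rate of a
planted variant among null companions.
"""

from pathlib import Path

import pandas as pd

from haplopair import experiments as ex

ROOT = Path(__file__).resolve().parent.parent / "results"
SEED = 20240117


def main() -> None:
    out = ROOT / "calibration"
    out.mkdir(parents=True, exist_ok=True)

    type_i = ex.null_type_i_error(n_variants=200, seed=SEED)
    print(f"type-I error at alpha 0.05, 200 null variants, n=144/163: "
          f"{type_i:.3f} (3-SE band: 0.004..0.096)")

    snp = ex.single_snp_recovery(n_reps=100, seed=SEED)
    snp.to_csv(out / "single_snp_recovery.tsv", sep="\t", index=False)
    print(f"planted OR 2.5 @ MAF 0.15: mean estimate "
          f"{snp['or_est'].mean():.3f}, 95% CI coverage "
          f"{snp['covered'].mean():.2f} over {len(snp)} replicates")

    pair = ex.pair_recovery(n_reps=100, seed=SEED)
    pair.to_csv(out / "pair_recovery.tsv", sep="\t", index=False)
    print(f"planted pair per-allele OR 2.0 @ MAF 0.2: mean pooled estimate "
          f"{pair['or_est'].mean():.3f}, 95% CI coverage "
          f"{pair['covered'].mean():.2f} over {len(pair)} replicates")

    rate = ex.top_hit_rate(n_reps=50, seed=SEED)
    print(f"planted OR 2.5 ranks first among 20 null variants in "
          f"{rate:.2f} of 50 replicates")

    summary = pd.DataFrame([
        ("type_i_error", type_i),
        ("single_snp_ci_coverage", snp["covered"].mean()),
        ("pair_ci_coverage", pair["covered"].mean()),
        ("top_hit_rate", rate),
    ], columns=["experiment", "value"])
    summary.to_csv(out / "summary.tsv", sep="\t", index=False)


if __name__ == "__main__":
    main()
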