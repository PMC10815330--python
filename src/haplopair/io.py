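"""Readers and writers for the pipeline's file formats.

Genotypes travel as VCF v4.2 with diploid GT calls (``./.`` for missing);
phenotypes, variant annotation and protein-interaction edges as TSV.
VCF parsing is delegated to cyvcf2.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .containers import MISSING, GenotypeMatrix, Phenotypes

VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
)


def write_vcf(genotypes: GenotypeMatrix, path) -> None:
    """Write a minimal VCF v4.2 with GT-only genotype columns."""
    gt_strings = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    contigs = dict.fromkeys(str(c) for c in genotypes.variants["chrom"])
    with open(path, "w") as fh:
        fh.write(VCF_HEADER)
        for contig in contigs:
            fh.write(f"##contig=<ID={contig}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(genotypes.samples) + "\n"
        )
        for j, v in genotypes.variants.iterrows():
            calls = "\t".join(
                gt_strings[int(g)] for g in genotypes.dosages[:, j]
            )
            fh.write(
                f"{v['chrom']}\t{v['pos']}\t{v['variant_id']}\t{v['ref']}\t"
                f"{v['alt']}\t.\tPASS\t.\tGT\t{calls}\n"
            )


def read_vcf(path) -> GenotypeMatrix:
    """Load biallelic diploid GT calls into a :class:`GenotypeMatrix`."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows, columns = [], []
    for rec in vcf:
        if len(rec.ALT) != 1:
            raise ValueError(
                f"variant {rec.ID or rec.POS} is not biallelic"
            )
        # gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        g = rec.gt_types
        dos = np.where(g == 0, 0, np.where(g == 1, 1, np.where(g == 3, 2, MISSING)))
        columns.append(dos.astype(np.int8))
        rows.append((rec.ID, str(rec.CHROM), int(rec.POS), rec.REF, rec.ALT[0]))
    vcf.close()
    if not rows:
        raise ValueError(f"no variants in {path}")
    variants = pd.DataFrame(
        rows, columns=["variant_id", "chrom", "pos", "ref", "alt"]
    )
    return GenotypeMatrix(np.column_stack(columns), samples, variants)


def read_phenotypes(path) -> Phenotypes:
    """Phenotype TSV with columns sample_id, status in {case, control}."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    for col in ("sample_id", "status"):
        if col not in df.columns:
            raise ValueError(f"phenotype file lacks column {col!r}")
    return Phenotypes.from_frame(df)


def read_annotation(path) -> pd.DataFrame:
    """Annotation TSV: variant_id, chrom, pos, gene, region."""
    df = pd.read_csv(path, sep="\t", dtype={"variant_id": str, "chrom": str})
    required = {"variant_id", "gene", "region"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"annotation file lacks columns {sorted(missing)}")
    bad = set(df["region"].unique()) - {"exon", "intron", "intergenic"}
    if bad:
        raise ValueError(f"unknown region labels: {sorted(bad)}")
    return df
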