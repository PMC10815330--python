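"""End-to-end orchestration of the two-stage association analysis.

``run_pipeline`` executes QC, the single-SNP allelic scan, Manhattan
export, candidate selection, PPI pairing and the pair scan from a single
config, writing every table plus a machine-readable run summary so a run
is fully reproducible from its output directory.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import association, io, ld, pairmodels, ppi, qc


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and the cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    vcf: str
    pheno: str
    annot: str
    ppi: str
    out_dir: str
    thresholds: qc.QCThresholds = field(default_factory=qc.QCThresholds)
    gwas_alpha: float = 5e-8
    nominal_alpha: float = 0.05
    min_ppi_score: float = 0.700
    additive_contrast: str = "I_vs_III"
    ld_pairs: list[tuple[str, str]] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("gwas_alpha", "nominal_alpha"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name}={v} outside (0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        thr = qc.QCThresholds(**raw.pop("thresholds", {}))
        raw["ld_pairs"] = [tuple(p) for p in raw.pop("ld_pairs", [])]
        return cls(thresholds=thr, **raw)


def run_pipeline(config: PipelineConfig) -> Path:
    """Run every stage; returns the output directory.

    Any stage failure raises :class:`StageError` naming the stage; tables
    written before the failure are retained.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"seed": config.seed,
                     "nominal_alpha": config.nominal_alpha,
                     "gwas_alpha": config.gwas_alpha}

    def stage(name, fn):
        try:
            return fn()
        except StageError:
            raise
        except Exception as exc:  # noqa: BLE001 - report stage and cause
            _write_summary(out, summary)
            raise StageError(name, exc) from exc

    genotypes = stage("read_inputs", lambda: io.read_vcf(config.vcf))
    phenotypes = stage("read_inputs", lambda: io.read_phenotypes(config.pheno))
    annotation = stage("read_inputs", lambda: io.read_annotation(config.annot))

    def _qc():
        gm, report = qc.apply_qc(genotypes, phenotypes, config.thresholds)
        report.to_frame().to_csv(out / "qc_report.tsv", sep="\t", index=False)
        return gm, report

    gm, report = stage("qc", _qc)
    summary["qc"] = {
        "variants_in": report.n_variants_in,
        "removed_nonautosomal": report.n_removed_nonautosomal,
        "removed_call_rate": report.n_removed_call_rate,
        "samples_removed": report.n_samples_removed,
        "removed_maf": report.n_removed_maf,
        "removed_hwe": report.n_removed_hwe,
        "variants_kept": report.n_variants_kept,
    }

    def _gwas():
        res = association.run_gwas(gm, phenotypes)
        res.to_csv(out / "assoc.tsv", sep="\t", index=False)
        bonf = association.bonferroni(config.nominal_alpha, len(res))
        association.manhattan_export(
            res, out / "manhattan.tsv", out / "manhattan.svg",
            gwas_threshold=config.gwas_alpha, bonferroni_threshold=bonf)
        return res, bonf

    results, stage1_bonf = stage("gwas", _gwas)
    summary["gwas"] = {
        "variants_tested": len(results),
        "nominally_significant": int((results["p"] < config.nominal_alpha).sum()),
        "bonferroni_threshold": stage1_bonf,
        "genomewide_hits": int((results["p"] < config.gwas_alpha).sum()),
    }

    if config.ld_pairs:
        def _ld():
            import pandas as pd

            # population LD: controls only, on the unfiltered input matrix
            # so loci removed by QC can still be characterized
            ctrl = genotypes.subset_samples(
                ~phenotypes.case_mask(genotypes.samples))
            rows = []
            for va, vb in config.ld_pairs:
                r = ld.ld_between(ctrl.column(va), ctrl.column(vb), va, vb)
                rows.append({
                    "variant_a": va, "variant_b": vb, "d": r.d,
                    "d_prime": r.d_prime, "r2": r.r2, "p": r.p,
                    "n_chrom": r.n_chrom,
                })
            pd.DataFrame(rows).to_csv(out / "ld.tsv", sep="\t", index=False)
            return rows

        summary["ld_pairs"] = len(stage("ld", _ld))

    def _pairs():
        cands = ppi.select_candidates(results, annotation, config.nominal_alpha)
        cands.to_csv(out / "candidates.tsv", sep="\t", index=False)
        edges = ppi.load_ppi_edges(config.ppi, config.min_ppi_score)
        pairs = ppi.build_snp_pairs(cands, edges)
        return cands, edges, pairs

    cands, edges, pairs = stage("ppi_pairing", _pairs)
    summary["stage2"] = {
        "candidates": len(cands),
        "candidate_genes": int(cands["gene"].nunique()) if len(cands) else 0,
        "ppi_edges_retained": len(edges),
        "snp_pairs": len(pairs),
    }

    if pairs:
        def _scan():
            table = pairmodels.pair_scan(
                pairs, gm, phenotypes, results,
                alpha=config.nominal_alpha, contrast=config.additive_contrast)
            table.to_csv(out / "pairs.tsv", sep="\t", index=False)
            return table

        table = stage("pair_scan", _scan)
        summary["stage2"].update(
            pairs_tested=int(table["error"].eq("").sum()),
            bonferroni_threshold=float(table["bonferroni_threshold"].iloc[0]),
            pairs_passing=int(table["passes_bonferroni"].sum()),
            additive_contrast=config.additive_contrast,
        )
    _write_summary(out, summary)
    return out


def _write_summary(out: Path, summary: dict) -> None:
    with open(out / "run_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
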