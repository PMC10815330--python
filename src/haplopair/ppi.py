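"""Stage-2 candidate selection and protein-interaction SNP pairing.

Candidates are exonic variants with a nominally significant (p < 0.05)
single-SNP association; their risk allele is the direction whose odds
ratio exceeds 1.  Candidates are then paired across a high-confidence
physical protein-protein interaction edge table (STRING export dialect):
for every retained edge whose two genes both host candidates, all
cross-gene SNP combinations are emitted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd


@dataclass(frozen=True)
class PPIEdge:
    gene_a: str
    gene_b: str
    score: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.score <= 1.0:
            raise ValueError(f"edge score {self.score} outside [0, 1]")


@dataclass(frozen=True)
class SnpPair:
    variant_a: str
    variant_b: str
    gene_a: str
    gene_b: str
    edge_score: float


def load_ppi_edges(path, min_score: float = 0.700) -> list[PPIEdge]:
    """Read a protein1/protein2/score TSV into deduplicated undirected edges.

    Scores above 1 are taken to be on STRING's 0-999 integer scale and are
    divided by 1000; self-edges and edges below ``min_score`` are dropped.
    Malformed rows raise with their (1-based, header-inclusive) line number.
    """
    df = pd.read_csv(path, sep="\t")
    for col in ("protein1", "protein2", "score"):
        if col not in df.columns:
            raise ValueError(f"PPI file lacks column {col!r}")
    seen: dict[tuple[str, str], float] = {}
    for i, row in df.iterrows():
        line_no = i + 2
        try:
            score = float(row["score"])
        except (TypeError, ValueError) as exc:
            raise ValueError(f"PPI line {line_no}: bad score {row['score']!r}") from exc
        if score > 1.0:
            score /= 1000.0
        if not 0.0 <= score <= 1.0:
            raise ValueError(f"PPI line {line_no}: score {score} outside [0, 1]")
        ga, gb = str(row["protein1"]), str(row["protein2"])
        if ga == gb:
            continue
        if score < min_score:
            continue
        key = (ga, gb) if ga < gb else (gb, ga)
        seen[key] = max(seen.get(key, 0.0), score)
    return [PPIEdge(a, b, s) for (a, b), s in sorted(seen.items())]


def select_candidates(
    assoc_results: pd.DataFrame,
    annotation: pd.DataFrame,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Exonic, nominally associated variants with their risk allele.

    The risk allele is the effect allele when its OR exceeds 1, otherwise
    the other allele (whose OR is the reciprocal).  Variants whose OR is
    exactly 1 or undefined carry no direction and are excluded, as are
    unannotated variants (with a warning).
    """
    merged = assoc_results.merge(
        annotation[["variant_id", "gene", "region"]], on="variant_id",
        how="left", validate="one_to_one",
    )
    unannotated = merged["region"].isna()
    if unannotated.any():
        warnings.warn(
            f"{int(unannotated.sum())} variants lack annotation and were "
            "excluded from candidate selection",
            stacklevel=2,
        )
    keep = (
        ~unannotated
        & (merged["region"] == "exon")
        & (merged["p"] < alpha)
        & merged["or_value"].notna()
        & (merged["or_value"] != 1.0)
    )
    out = merged.loc[keep].copy()
    risk_is_effect = out["or_value"] > 1.0
    out["risk_allele"] = out["effect_allele"].where(
        risk_is_effect, out["other_allele"])
    out["risk_or"] = out["or_value"].where(risk_is_effect, out["or_other"])
    return out.reset_index(drop=True)


def build_snp_pairs(
    candidates: pd.DataFrame, edges: list[PPIEdge]
) -> list[SnpPair]:
    """Cartesian cross-gene SNP combinations over candidate-bearing edges.

    Output order is canonical — edge genes sorted lexicographically, then
    variant positions — so the pair list is invariant to input row order.
    """
    by_gene: dict[str, pd.DataFrame] = {
        g: sub.sort_values(["pos", "variant_id"]).reset_index(drop=True)
        for g, sub in candidates.groupby("gene")
    }
    pairs: list[SnpPair] = []
    for edge in sorted(edges, key=lambda e: (e.gene_a, e.gene_b)):
        ga, gb = sorted((edge.gene_a, edge.gene_b))
        if ga not in by_gene or gb not in by_gene:
            continue
        for _, va in by_gene[ga].iterrows():
            for _, vb in by_gene[gb].iterrows():
                pairs.append(SnpPair(
                    va["variant_id"], vb["variant_id"], ga, gb, edge.score))
    return pairs
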