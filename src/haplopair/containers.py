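"""Core in-memory containers for the case-control genotype analysis.

Genotypes are held as minor-allele-agnostic ALT-dosage calls: each diploid
call is the number of ALT alleles carried (0, 1, 2) or ``MISSING`` (-1).
Variant identity/locus metadata travels in a pandas DataFrame alongside the
dosage matrix so that positional operations (sorting, autosome filters,
region joins) use ordinary pandas idioms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = -1

#: columns every variant table must carry
VARIANT_COLUMNS = ["variant_id", "chrom", "pos", "ref", "alt"]

AUTOSOMES = {str(i) for i in range(1, 23)} | {f"chr{i}" for i in range(1, 23)}


@dataclass
class GenotypeMatrix:
    """Samples x variants table of ALT-allele dosage calls.

    Parameters
    ----------
    dosages
        ``(n_samples, n_variants)`` int8 array with entries in
        ``{0, 1, 2, MISSING}``.
    samples
        Sample identifiers, one per row.
    variants
        DataFrame with at least :data:`VARIANT_COLUMNS`, one row per column
        of ``dosages``, in matrix column order.
    """

    dosages: np.ndarray
    samples: list[str]
    variants: pd.DataFrame

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-D (samples x variants)")
        if self.dosages.shape[0] != len(self.samples):
            raise ValueError(
                f"{len(self.samples)} samples but {self.dosages.shape[0]} rows"
            )
        if self.dosages.shape[1] != len(self.variants):
            raise ValueError(
                f"{len(self.variants)} variants but {self.dosages.shape[1]} columns"
            )
        bad = ~np.isin(self.dosages, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("dosage entries must be in {0, 1, 2, -1}")
        missing_cols = [c for c in VARIANT_COLUMNS if c not in self.variants.columns]
        if missing_cols:
            raise ValueError(f"variant table lacks columns {missing_cols}")
        self.variants = self.variants.reset_index(drop=True)

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    @property
    def variant_ids(self) -> pd.Series:
        return self.variants["variant_id"]

    def variant_index(self, variant_id: str) -> int:
        idx = self.variants.index[self.variants["variant_id"] == variant_id]
        if len(idx) == 0:
            raise KeyError(f"variant {variant_id!r} not in matrix")
        return int(idx[0])

    def column(self, variant_id: str) -> np.ndarray:
        """Dosage vector for one variant."""
        return self.dosages[:, self.variant_index(variant_id)]

    def subset_variants(self, mask: np.ndarray) -> "GenotypeMatrix":
        mask = np.asarray(mask, dtype=bool)
        return GenotypeMatrix(
            self.dosages[:, mask], list(self.samples),
            self.variants.loc[mask].reset_index(drop=True),
        )

    def subset_samples(self, mask: np.ndarray) -> "GenotypeMatrix":
        mask = np.asarray(mask, dtype=bool)
        samples = [s for s, keep in zip(self.samples, mask) if keep]
        return GenotypeMatrix(self.dosages[mask, :], samples, self.variants.copy())


@dataclass
class Phenotypes:
    """Case/control labels keyed by sample id."""

    status: pd.Series  # index: sample_id, values in {"case", "control"}

    def __post_init__(self) -> None:
        bad = set(self.status.unique()) - {"case", "control"}
        if bad:
            raise ValueError(f"unknown status labels: {sorted(bad)}")

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "Phenotypes":
        return cls(df.set_index("sample_id")["status"])

    def case_mask(self, samples: list[str]) -> np.ndarray:
        missing = [s for s in samples if s not in self.status.index]
        if missing:
            raise KeyError(f"samples without phenotype: {missing[:5]}")
        return (self.status.loc[samples] == "case").to_numpy()

    @property
    def n_case(self) -> int:
        return int((self.status == "case").sum())

    @property
    def n_control(self) -> int:
        return int((self.status == "control").sum())


def is_autosomal(chrom: pd.Series) -> np.ndarray:
    """Boolean mask of autosomal chromosome labels (1-22, chr1-chr22)."""
    return chrom.astype(str).isin(AUTOSOMES).to_numpy()
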