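"""In-memory containers shared across the pipeline.

Tabular data (cohorts, annotations, score tables, enrichment tables) travel
as plain pandas DataFrames with documented columns; the two containers that
need invariants of their own get small dataclasses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Cohort table columns (one row per individual and visit).
COHORT_COLUMNS = [
    "individual_id",
    "visit",
    "SBP",
    "DBP",
    "hypertension",
    "age",
    "sex",
    "smoking",
    "medication_use",
    "genotyped",
]

#: Gene annotation columns; start/end are 1-based inclusive base pairs.
ANNOTATION_COLUMNS = ["gene_id", "chrom", "start", "end"]


@dataclass
class GenotypeMatrix:
    """n individuals x M variants of minor-allele dosages.

    dosages: float array, entries in {0, 1, 2} or NaN for missing.
    variants: DataFrame with columns variant_id, chrom, pos (1-based bp) and
        optionally maf_true (the population frequency the generator drew).
    """

    individual_ids: list[str]
    variants: pd.DataFrame
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        n, m = self.dosages.shape
        if n != len(self.individual_ids):
            raise ValueError(
                f"dosage rows ({n}) != number of individuals ({len(self.individual_ids)})"
            )
        if m != len(self.variants):
            raise ValueError(
                f"dosage columns ({m}) != number of variants ({len(self.variants)})"
            )
        vals = self.dosages[~np.isnan(self.dosages)]
        if vals.size and not np.isin(vals, (0.0, 1.0, 2.0)).all():
            bad = np.unique(vals[~np.isin(vals, (0.0, 1.0, 2.0))])
            raise ValueError(f"dosages must be in {{0,1,2}} or missing; found {bad}")
        if (self.variants["pos"] <= 0).any():
            raise ValueError("variant positions must be strictly positive (1-based)")
        if self.variants["variant_id"].duplicated().any():
            dup = self.variants.loc[self.variants["variant_id"].duplicated(), "variant_id"]
            raise ValueError(f"duplicate variant ids: {sorted(set(dup))[:5]}")

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def equals(self, other: "GenotypeMatrix") -> bool:
        return (
            self.individual_ids == other.individual_ids
            and self.variants.reset_index(drop=True).equals(
                other.variants.reset_index(drop=True)
            )
            and np.array_equal(self.dosages, other.dosages, equal_nan=True)
        )


@dataclass
class GeneSetCollection:
    """Named gene sets with a free-text provenance/description per set."""

    sets: dict[str, list[str]] = field(default_factory=dict)
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValueError(f"gene set {name!r} is empty")
        for name in self.sets:
            self.descriptions.setdefault(name, "")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def subset(self, names) -> "GeneSetCollection":
        return GeneSetCollection(
            sets={n: list(self.sets[n]) for n in names},
            descriptions={n: self.descriptions.get(n, "") for n in names},
        )


@dataclass
class GeneVariantMap:
    """gene_id -> ordered array of variant column indices in a GenotypeMatrix."""

    gene_to_variants: dict[str, np.ndarray]
    n_unmapped: int = 0
    unmapped_variant_ids: list[str] = field(default_factory=list)

    def __getitem__(self, gene_id: str) -> np.ndarray:
        return self.gene_to_variants[gene_id]

    def __iter__(self):
        return iter(self.gene_to_variants)

    def __len__(self) -> int:
        return len(self.gene_to_variants)
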