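"""Configuration objects for the synthetic cohort generator and the pipeline.

The generator emulates a small unrelated-individuals blood-pressure cohort:
two correlated quantitative traits (SBP, DBP) driven by age, sex, smoking and
antihypertensive-medication use, a single chromosome of biallelic variants
with a minor-allele-frequency spectrum straddling the 1% rare/common
threshold, non-overlapping gene intervals, and curated-style gene sets of
heterogeneous size.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence


@dataclass(frozen=True)
class CausalGene:
    """A gene whose variants carry phenotype effects.

    rule:
        "standardized": per-allele effect beta_m = effect_size * sd_trait /
            sqrt(2 p_m (1 - p_m)), so every causal variant explains
            effect_size**2 of the trait's residual variance regardless of
            its frequency.
        "per_allele": beta_m = effect_size * sd_trait per copy of the minor
            allele.
    """

    gene_id: str
    effect_size: float = 0.35
    fraction_causal: float = 0.5
    rule: str = "standardized"


@dataclass(frozen=True)
class TraitNoise:
    """Residual standard deviations (mm Hg) and residual correlation of the
    two pressure traits."""

    sd_sbp: float = 20.0
    sd_dbp: float = 9.0
    residual_correlation: float = 0.5


# Effects are (beta on SBP, beta on DBP) per unit of the covariate.
DEFAULT_COVARIATE_EFFECTS: dict[str, tuple[float, float]] = {
    "age": (0.5, 0.1),
    "sex": (-3.0, -1.0),
    "smoking": (4.0, 1.0),
    "medication_use": (8.0, 3.0),
}


@dataclass
class SimulationConfig:
    """Everything the synthetic-data module needs, in one validated object.

    Defaults reproduce the structure of the study cohort: 157 unrelated
    individuals of whom 129 are genotyped, baseline demographics matching the
    descriptive table (age 52.9 +/- 15.6, 60.5% female, 24.8% smokers, 20.2%
    on antihypertensive medication), trait means near 128.4/71.8 mm Hg, and a
    variant spectrum with half the variants rare (MAF < 1%).
    """

    seed: int = 0
    n_individuals: int = 157
    n_genotyped: int = 129
    n_variants: int = 5000
    chromosome_label: str = "3"
    fraction_rare: float = 0.5
    rare_maf_range: tuple[float, float] = (0.001, 0.01)
    common_maf_range: tuple[float, float] = (0.01, 0.5)
    n_genes: int = 200
    gene_length_range: tuple[int, int] = (5_000, 50_000)
    covariate_effects: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_COVARIATE_EFFECTS)
    )
    sbp_intercept: float = 101.2
    dbp_intercept: float = 66.3
    age_mean: float = 52.9
    age_sd: float = 15.6
    p_female: float = 0.605
    p_smoking: float = 0.248
    p_medication: float = 0.202
    trait_noise: TraitNoise = field(default_factory=TraitNoise)
    causal_spec: tuple[CausalGene, ...] = ()
    n_sets: int = 500
    set_size_range: tuple[int, int] = (3, 60)
    fraction_sets_enriched_for_causal_gene: float = 0.0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name in ("n_individuals", "n_genotyped", "n_variants", "n_genes", "n_sets"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")
        if self.n_genotyped > self.n_individuals:
            raise ValueError("n_genotyped cannot exceed n_individuals")
        if self.n_variants < self.n_genes:
            raise ValueError(
                f"n_variants ({self.n_variants}) must be >= n_genes ({self.n_genes})"
            )
        for lo, hi, label in (
            (*self.rare_maf_range, "rare_maf_range"),
            (*self.common_maf_range, "common_maf_range"),
        ):
            if not (0.0 < lo <= hi <= 0.5):
                raise ValueError(
                    f"{label} must satisfy 0 < low <= high <= 0.5, got ({lo}, {hi})"
                )
        if self.rare_maf_range[1] > 0.01:
            raise ValueError("rare_maf_range upper bound must be <= 0.01")
        if not 0.0 <= self.fraction_rare <= 1.0:
            raise ValueError("fraction_rare must lie in [0, 1]")
        if not 0.0 <= self.fraction_sets_enriched_for_causal_gene <= 1.0:
            raise ValueError("fraction_sets_enriched_for_causal_gene must lie in [0, 1]")
        rho = self.trait_noise.residual_correlation
        if not -1.0 < rho < 1.0:
            raise ValueError(f"residual correlation must lie in (-1, 1), got {rho}")
        if self.trait_noise.sd_sbp < 0 or self.trait_noise.sd_dbp < 0:
            raise ValueError("trait residual SDs must be non-negative")
        if self.gene_length_range[0] < 1 or self.gene_length_range[0] > self.gene_length_range[1]:
            raise ValueError("gene_length_range must be a positive, ordered pair")
        if self.set_size_range[0] < 1:
            raise ValueError("set_size_range lower bound must be >= 1")
        if self.set_size_range[0] > self.set_size_range[1]:
            raise ValueError("set_size_range must be ordered")
        for c in self.causal_spec:
            if not 0.0 <= c.fraction_causal <= 1.0:
                raise ValueError(f"fraction_causal out of [0,1] for {c.gene_id}")
            if c.rule not in ("standardized", "per_allele"):
                raise ValueError(f"unknown effect rule {c.rule!r} for {c.gene_id}")

    def to_dict(self) -> dict:
        return asdict(self)


PHENOTYPES: tuple[str, ...] = ("SBP", "DBP", "MAP", "SBP-DBP")

#: Column carrying each analyzable phenotype in a derived cohort table.
PHENOTYPE_COLUMNS: dict[str, str] = {
    "SBP": "SBP",
    "DBP": "DBP",
    "MAP": "MAP",
    "SBP-DBP": "pulse_gap",
}

DEFAULT_COVARIATES: tuple[str, ...] = ("age", "sex", "smoking", "medication_use")


def default_lambda_grid(step: float = 0.01) -> "tuple[float, ...]":
    """Grid of mixing weights for the variable-weight statistic: 0 to 1
    inclusive in steps of `step` (101 values at the default)."""
    import numpy as np

    if not 0 < step <= 1:
        raise ValueError("lambda step must lie in (0, 1]")
    n = int(round(1.0 / step))
    return tuple(np.linspace(0.0, 1.0, n + 1))
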