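"""Polygenic score computation and APOE haplotype calling.

Weighted scores are plain dosage-weighted sums over a coefficient table.
The LDL-C score additionally receives a fixed per-haplotype increment for
the two-SNP APOE isoform system (rs7412 / rs429358).  Scores are
stratified against an empirical reference distribution: HIGH above the
80th percentile, LOW below the 50th.

Quantile convention (fixed, documented): the percentile of a score *s*
within reference values ``r`` is ``100 * (#{r < s} + 0.5 * #{r == s}) / n``
(fraction strictly below, midpoint at ties).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "ApoeHaplotype",
    "Band",
    "PrsModel",
    "StratificationBands",
    "VariantAnnotation",
    "VariantSpec",
    "APOE_LDL_ADJUSTMENT",
    "call_apoe_haplotype",
    "compute_weighted_prs",
    "final_ldl_score",
    "oriented_dosage",
    "percentile_rank",
    "rare_variant_filter",
    "stratify",
]


class ApoeHaplotype(Enum):
    E2E2 = "e2e2"
    E2E3 = "e2e3"
    E2E4 = "e2e4"
    E3E3 = "e3e3"
    E3E4 = "e3e4"
    E4E4 = "e4e4"


class Band(Enum):
    HIGH = "HIGH"
    LOW = "LOW"
    INTERMEDIATE = "INTERMEDIATE"


#: Final LDL-C score increment per APOE haplotype.
APOE_LDL_ADJUSTMENT = {
    ApoeHaplotype.E2E2: -0.9,
    ApoeHaplotype.E2E3: -0.4,
    ApoeHaplotype.E2E4: -0.2,
    ApoeHaplotype.E3E3: 0.0,
    ApoeHaplotype.E3E4: 0.1,
    ApoeHaplotype.E4E4: 0.2,
}


@dataclass(frozen=True)
class VariantSpec:
    """One score variant: effect allele, its frequency and per-allele weight."""

    rsid: str
    effect_allele: str
    effect_allele_freq: float
    beta: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.effect_allele_freq <= 1.0):
            raise ValueError(
                f"{self.rsid}: effect_allele_freq {self.effect_allele_freq} "
                "outside [0, 1]"
            )
        if not np.isfinite(self.beta):
            raise ValueError(f"{self.rsid}: beta must be finite")
        if self.effect_allele not in ("A", "C", "G", "T"):
            raise ValueError(f"{self.rsid}: bad effect allele {self.effect_allele!r}")


@dataclass(frozen=True)
class PrsModel:
    """A weighted score definition for one trait (``LDL_C`` or ``TG``)."""

    trait: str
    variants: tuple[VariantSpec, ...]
    apoe_adjustment: Optional[dict[ApoeHaplotype, float]] = None

    def __post_init__(self) -> None:
        if self.trait not in ("LDL_C", "TG"):
            raise ValueError(f"unknown trait {self.trait!r}")
        if not self.variants:
            raise ValueError("PrsModel requires a non-empty variant list")
        if self.trait == "LDL_C":
            if self.apoe_adjustment is None:
                raise ValueError("LDL_C model requires an apoe_adjustment map")
            missing = set(ApoeHaplotype) - set(self.apoe_adjustment)
            if missing:
                raise ValueError(f"apoe_adjustment misses haplotypes: {missing}")
        elif self.apoe_adjustment is not None:
            raise ValueError("TG model must not carry an apoe_adjustment map")

    @property
    def betas(self) -> np.ndarray:
        return np.array([v.beta for v in self.variants], dtype=float)

    @property
    def rsids(self) -> tuple[str, ...]:
        return tuple(v.rsid for v in self.variants)


@dataclass
class StratificationBands:
    """Reference score distribution plus the two percentile cut points."""

    reference_scores: np.ndarray
    high_threshold_percentile: float = 80.0
    low_threshold_percentile: float = 50.0

    def __post_init__(self) -> None:
        self.reference_scores = np.asarray(self.reference_scores, dtype=float)
        if self.reference_scores.size == 0:
            raise ValueError("reference_scores must be non-empty")
        if not (0.0 < self.low_threshold_percentile < self.high_threshold_percentile < 100.0):
            raise ValueError("need 0 < low < high < 100")


@dataclass(frozen=True)
class VariantAnnotation:
    """External annotation of a candidate causal variant (consumed as input)."""

    rsid: str
    gene: str
    gnomad_af: Optional[float] = None
    synonymous: bool = False
    pathogenicity: Optional[str] = None  # P, LP, VUS, LB, B or None

    def __post_init__(self) -> None:
        if self.gnomad_af is not None and not (0.0 <= self.gnomad_af <= 1.0):
            raise ValueError(f"{self.rsid}: gnomad_af outside [0, 1]")
        if self.pathogenicity not in (None, "P", "LP", "VUS", "LB", "B"):
            raise ValueError(f"{self.rsid}: bad pathogenicity {self.pathogenicity!r}")


class HaplotypeError(ValueError):
    """APOE haplotype cannot be determined from the supplied genotypes."""


def _alt_count(gt) -> int:
    """Alternate-allele count from an int 0/1/2 or a 'a/b'-style GT string."""
    if gt is None:
        raise HaplotypeError("missing genotype: haplotype undetermined")
    if isinstance(gt, str):
        alleles = gt.replace("|", "/").split("/")
        if len(alleles) != 2 or any(a not in ("0", "1") for a in alleles):
            raise HaplotypeError(f"unsupported genotype string {gt!r}")
        return sum(int(a) for a in alleles)
    count = int(gt)
    if count not in (0, 1, 2):
        raise HaplotypeError(f"genotype must be a 0/1/2 alt count, got {gt!r}")
    return count


def call_apoe_haplotype(gt_rs7412, gt_rs429358) -> ApoeHaplotype:
    """Call the APOE epsilon haplotype from the two defining SNPs.

    The epsilon-2 allele count equals the rs7412 alternate-allele count and
    the epsilon-4 count equals the rs429358 alternate-allele count;
    epsilon-3 fills the remainder.  The double-heterozygote is genuinely
    ambiguous (e2e4 vs the essentially absent e1e3) and is resolved to
    ``E2E4`` with a warning.
    """
    e2 = _alt_count(gt_rs7412)
    e4 = _alt_count(gt_rs429358)
    if e2 + e4 > 2:
        raise HaplotypeError(
            f"inconsistent APOE genotypes: e2 count {e2} + e4 count {e4} > 2"
        )
    if e2 == 1 and e4 == 1:
        warnings.warn(
            "rs7412/rs429358 double heterozygote: assigning e2e4 "
            "(e1e3 cannot be excluded)",
            stacklevel=2,
        )
    key = "".join(sorted(["e2"] * e2 + ["e3"] * (2 - e2 - e4) + ["e4"] * e4))
    return ApoeHaplotype(key)


def compute_weighted_prs(dosages: Sequence[float], model: PrsModel) -> float:
    """Raw weighted score: sum of beta_i * dosage_i over the model variants.

    Dosages must align with ``model.variants``; missing values are a hard
    error (no silent imputation).
    """
    d = np.asarray(dosages, dtype=float)
    if d.shape != (len(model.variants),):
        raise ValueError(
            f"dosage vector length {d.size} != model size {len(model.variants)}"
        )
    if np.isnan(d).any():
        raise ValueError("missing dosage; refuse to impute by default")
    if not np.isin(d, (0.0, 1.0, 2.0)).all():
        raise ValueError("dosages must be 0, 1 or 2")
    return float(d @ model.betas)


def final_ldl_score(raw: float, hap: ApoeHaplotype, model: PrsModel) -> float:
    """Raw LDL-C score plus the haplotype-specific APOE increment."""
    if model.trait != "LDL_C":
        raise ValueError("APOE adjustment applies to the LDL_C model only")
    assert model.apoe_adjustment is not None
    return raw + model.apoe_adjustment[hap]


def percentile_rank(score: float, bands: StratificationBands) -> float:
    """Empirical percentile of ``score`` within the reference distribution."""
    r = bands.reference_scores
    below = np.count_nonzero(r < score)
    equal = np.count_nonzero(r == score)
    return 100.0 * (below + 0.5 * equal) / r.size


def stratify(percentile: float, bands: Optional[StratificationBands] = None) -> Band:
    """HIGH strictly above the 80th percentile, LOW strictly below the 50th."""
    if not (0.0 <= percentile <= 100.0):
        raise ValueError(f"percentile {percentile} outside [0, 100]")
    high = bands.high_threshold_percentile if bands else 80.0
    low = bands.low_threshold_percentile if bands else 50.0
    if percentile > high:
        return Band.HIGH
    if percentile < low:
        return Band.LOW
    return Band.INTERMEDIATE


def score_band(score: float, bands: StratificationBands) -> Band:
    """Convenience: percentile rank then band assignment."""
    return stratify(percentile_rank(score, bands), bands)


def rare_variant_filter(
    annotations: Sequence[VariantAnnotation], af_max: float = 0.0001
) -> list[VariantAnnotation]:
    """Keep non-synonymous variants with gnomAD AF < ``af_max`` or absent."""
    return [
        a
        for a in annotations
        if not a.synonymous and (a.gnomad_af is None or a.gnomad_af < af_max)
    ]


def oriented_dosage(
    gt_alt_count: int, ref: str, alt: str, effect_allele: str
) -> int:
    """Effect-allele dosage from an alt-allele count, flipping when the
    effect allele sits on the REF side (the classic strand/orientation
    pitfall of weighted scores)."""
    if effect_allele == alt:
        return gt_alt_count
    if effect_allele == ref:
        return 2 - gt_alt_count
    raise ValueError(
        f"effect allele {effect_allele!r} matches neither REF {ref!r} nor ALT {alt!r}"
    )
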