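"""Seeded synthetic reference populations and study cohorts.

Everything downstream (scoring, classification, ultrasound aggregation,
comparisons) is exercised on cohorts produced here, so each generated
participant is constructed to satisfy the defining criteria of its
intended group and lipids are drawn from log-normal distributions whose
medians match the calibration targets.

The shipped coefficient tables are SYNTHETIC placeholders with plausible
frequency/weight ranges (the original per-variant effect estimates are
not public); override them with your own CSVs for real data.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional, Sequence

import numpy as np

from . import classify as cls
from . import prs as prsmod
from . import ultrasound as us
from .prs import ApoeHaplotype, Band, PrsModel, StratificationBands, VariantSpec

__all__ = [
    "CohortSpec",
    "GroupParams",
    "LipidDist",
    "ReferencePopulation",
    "UltrasoundParams",
    "default_cohort_spec",
    "default_ldl_model",
    "default_tg_model",
    "generate_cohort",
    "generate_reference_population",
    "generate_ultrasound",
    "load_prs_model",
]

#: Typical European APOE allele frequencies (e2, e3, e4); config-overridable.
DEFAULT_APOE_ALLELE_FREQS = {"e2": 0.08, "e3": 0.78, "e4": 0.14}

_MAX_REJECTION_TRIES = 20_000


def load_prs_model(path, trait: str) -> PrsModel:
    """Read a coefficient CSV (rsid,effect_allele,effect_allele_freq,beta)."""
    variants = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            variants.append(
                VariantSpec(
                    rsid=row["rsid"],
                    effect_allele=row["effect_allele"],
                    effect_allele_freq=float(row["effect_allele_freq"]),
                    beta=float(row["beta"]),
                )
            )
    adj = dict(prsmod.APOE_LDL_ADJUSTMENT) if trait == "LDL_C" else None
    return PrsModel(trait=trait, variants=tuple(variants), apoe_adjustment=adj)


def _data_path(name: str):
    return resources.files("lipidstrat") / "data" / name


def default_ldl_model() -> PrsModel:
    return load_prs_model(_data_path("ldl_prs_coefficients.csv"), "LDL_C")


def default_tg_model() -> PrsModel:
    return load_prs_model(_data_path("tg_prs_coefficients.csv"), "TG")


# ---------------------------------------------------------------------------
# specs


@dataclass
class LipidDist:
    """Log-normal draw: exp(N(log(median), sigma^2)), optionally truncated."""

    median: float
    sigma: float
    minimum: Optional[float] = None
    maximum: Optional[float] = None

    def __post_init__(self) -> None:
        if self.median <= 0 or self.sigma <= 0:
            raise ValueError("median and sigma must be positive")

    def draw(self, rng: np.random.Generator) -> float:
        for _ in range(_MAX_REJECTION_TRIES):
            v = float(rng.lognormal(np.log(self.median), self.sigma))
            if (self.minimum is None or v >= self.minimum) and (
                self.maximum is None or v <= self.maximum
            ):
                return v
        raise RuntimeError("truncated lipid draw failed; bounds too tight")


@dataclass
class UltrasoundParams:
    """Per-territory severity: Poisson plaque count, log-normal heights,
    normal stenosis percentages."""

    plaque_rate: float  # Poisson mean over the whole territory
    stenosis_mean: float  # %
    stenosis_sd: float = 12.0
    height_median: float = 1.4  # mm
    height_sigma: float = 0.30

    def __post_init__(self) -> None:
        if self.plaque_rate < 0:
            raise ValueError("plaque_rate must be >= 0")


@dataclass
class GroupParams:
    n: int
    ldl: LipidDist
    hdl: LipidDist
    tg: LipidDist
    lpa: LipidDist
    age_median: float
    age_sd: float
    male_frac: float
    bmi_median: float
    current_smoker_frac: float
    ex_smoker_frac: float
    hypertension_frac: float
    diabetes_frac: float
    statin_frac: float
    chd_frequency: float
    chd_onset_median: float
    carotid: UltrasoundParams
    femoral: UltrasoundParams

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ValueError("group size must be >= 0")
        for name in ("male_frac", "current_smoker_frac", "ex_smoker_frac",
                     "hypertension_frac", "diabetes_frac", "statin_frac",
                     "chd_frequency"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.chd_onset_median <= 0:
            raise ValueError("chd_onset_median must be positive")


@dataclass
class CohortSpec:
    groups: dict[str, GroupParams]
    seed: int = 0
    apoe_allele_freqs: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_APOE_ALLELE_FREQS)
    )


def default_cohort_spec(
    n_per_group: Optional[dict[str, int]] = None, seed: int = 0
) -> CohortSpec:
    """Calibrated defaults: group sizes, lipid medians, CHD frequencies and
    plaque burden chosen to reproduce the published per-group summaries."""
    n = {"FD": 29, "FH": 61, "POLY_HCL": 49, "SEVERE_HCL": 41, "CONTROL": 144}
    if n_per_group:
        n.update(n_per_group)
    groups = {
        "FD": GroupParams(
            n=n["FD"],
            ldl=LipidDist(3.57, 0.30),
            hdl=LipidDist(1.03, 0.22),
            tg=LipidDist(4.10, 0.40, minimum=1.54, maximum=13.12),
            lpa=LipidDist(14.0, 0.9),
            age_median=50, age_sd=8, male_frac=0.483, bmi_median=29.0,
            current_smoker_frac=0.310, ex_smoker_frac=0.207,
            hypertension_frac=0.690, diabetes_frac=0.069, statin_frac=0.448,
            chd_frequency=0.310, chd_onset_median=40,
            carotid=UltrasoundParams(2.0, 22.0),
            femoral=UltrasoundParams(2.2, 24.0),
        ),
        "FH": GroupParams(
            n=n["FH"],
            ldl=LipidDist(8.03, 0.28),
            hdl=LipidDist(1.20, 0.20),
            tg=LipidDist(1.30, 0.35),
            lpa=LipidDist(18.0, 1.0),
            age_median=50, age_sd=10, male_frac=0.459, bmi_median=26.3,
            current_smoker_frac=0.148, ex_smoker_frac=0.197,
            hypertension_frac=0.459, diabetes_frac=0.066, statin_frac=0.836,
            chd_frequency=0.295, chd_onset_median=44,
            carotid=UltrasoundParams(4.2, 33.0, height_median=1.72),
            femoral=UltrasoundParams(2.6, 25.0),
        ),
        "POLY_HCL": GroupParams(
            n=n["POLY_HCL"],
            ldl=LipidDist(5.60, 0.18, minimum=4.95),
            hdl=LipidDist(1.35, 0.20),
            tg=LipidDist(1.40, 0.30),
            lpa=LipidDist(13.0, 0.9),
            age_median=56, age_sd=6, male_frac=0.327, bmi_median=29.5,
            current_smoker_frac=0.143, ex_smoker_frac=0.122,
            hypertension_frac=0.796, diabetes_frac=0.102, statin_frac=0.224,
            chd_frequency=0.061, chd_onset_median=56,
            carotid=UltrasoundParams(2.0, 22.0),
            femoral=UltrasoundParams(2.0, 22.0),
        ),
        "SEVERE_HCL": GroupParams(
            n=n["SEVERE_HCL"],
            ldl=LipidDist(5.40, 0.16, minimum=4.95),
            hdl=LipidDist(1.35, 0.20),
            tg=LipidDist(1.40, 0.30),
            lpa=LipidDist(11.6, 0.9),
            age_median=58, age_sd=6, male_frac=0.341, bmi_median=29.6,
            current_smoker_frac=0.098, ex_smoker_frac=0.098,
            hypertension_frac=1.0, diabetes_frac=0.098, statin_frac=0.244,
            chd_frequency=0.073, chd_onset_median=58,
            carotid=UltrasoundParams(2.0, 22.0),
            femoral=UltrasoundParams(2.0, 22.0),
        ),
        "CONTROL": GroupParams(
            n=n["CONTROL"],
            ldl=LipidDist(2.40, 0.18, maximum=2.95),
            hdl=LipidDist(1.50, 0.18),
            tg=LipidDist(1.00, 0.22, maximum=1.45),
            lpa=LipidDist(10.0, 0.9),
            age_median=52, age_sd=8, male_frac=0.271, bmi_median=27.3,
            current_smoker_frac=0.132, ex_smoker_frac=0.153,
            hypertension_frac=0.715, diabetes_frac=0.063, statin_frac=0.042,
            chd_frequency=0.028, chd_onset_median=60,
            carotid=UltrasoundParams(0.25, 12.0),
            femoral=UltrasoundParams(0.25, 12.0),
        ),
    }
    return CohortSpec(groups=groups, seed=seed)


# ---------------------------------------------------------------------------
# reference population


@dataclass
class ReferencePopulation:
    """Hardy-Weinberg genotype matrix with per-subject haplotypes and scores."""

    rsids: tuple[str, ...]
    dosages: np.ndarray  # subjects x variants, values 0/1/2
    haplotypes: list[ApoeHaplotype]
    ldl_scores: np.ndarray  # APOE-adjusted
    tg_scores: np.ndarray
    ldl_model: PrsModel
    tg_model: PrsModel

    @property
    def ldl_bands(self) -> StratificationBands:
        return StratificationBands(self.ldl_scores)

    @property
    def tg_bands(self) -> StratificationBands:
        return StratificationBands(self.tg_scores)


def _draw_haplotype(rng: np.random.Generator, freqs: dict[str, float]) -> ApoeHaplotype:
    alleles = list(freqs)
    p = np.array([freqs[a] for a in alleles], dtype=float)
    p = p / p.sum()
    pair = sorted(rng.choice(alleles, size=2, p=p))
    return ApoeHaplotype("".join(pair))


def _model_scores(dosage_row, haplotype, ldl_model, tg_model, n_ldl):
    raw_ldl = prsmod.compute_weighted_prs(dosage_row[:n_ldl], ldl_model)
    ldl = prsmod.final_ldl_score(raw_ldl, haplotype, ldl_model)
    tg = prsmod.compute_weighted_prs(dosage_row[n_ldl:], tg_model)
    return ldl, tg


def generate_reference_population(
    n: int,
    ldl_model: Optional[PrsModel] = None,
    tg_model: Optional[PrsModel] = None,
    seed: int = 0,
    apoe_allele_freqs: Optional[dict[str, float]] = None,
) -> ReferencePopulation:
    """Binomial(2, freq) genotypes per variant (Hardy-Weinberg), random
    APOE haplotypes, and the two per-subject scores."""
    if n < 2:
        raise ValueError("reference population needs n >= 2")
    ldl_model = ldl_model or default_ldl_model()
    tg_model = tg_model or default_tg_model()
    freqs = apoe_allele_freqs or DEFAULT_APOE_ALLELE_FREQS
    rng = np.random.default_rng(seed)

    variants = list(ldl_model.variants) + list(tg_model.variants)
    p = np.array([v.effect_allele_freq for v in variants])
    dosages = rng.binomial(2, p, size=(n, len(variants))).astype(np.int8)
    haplotypes = [_draw_haplotype(rng, freqs) for _ in range(n)]

    n_ldl = len(ldl_model.variants)
    betas_ldl = ldl_model.betas
    betas_tg = tg_model.betas
    adj = np.array([ldl_model.apoe_adjustment[h] for h in haplotypes])
    ldl_scores = dosages[:, :n_ldl] @ betas_ldl + adj
    tg_scores = dosages[:, n_ldl:] @ betas_tg

    return ReferencePopulation(
        rsids=tuple(v.rsid for v in variants),
        dosages=dosages,
        haplotypes=haplotypes,
        ldl_scores=np.asarray(ldl_scores, dtype=float),
        tg_scores=np.asarray(tg_scores, dtype=float),
        ldl_model=ldl_model,
        tg_model=tg_model,
    )


# ---------------------------------------------------------------------------
# cohort


def _draw_genotype_with_band(
    rng, ldl_model, tg_model, haplotype, bands, want: Optional[Band]
):
    """Rejection-sample a genotype vector until the final LDL-C score falls
    in the requested stratification band (any band when ``want`` is None)."""
    variants = list(ldl_model.variants) + list(tg_model.variants)
    p = np.array([v.effect_allele_freq for v in variants])
    n_ldl = len(ldl_model.variants)
    for _ in range(_MAX_REJECTION_TRIES):
        d = rng.binomial(2, p).astype(np.int8)
        ldl_score, tg_score = _model_scores(d, haplotype, ldl_model, tg_model, n_ldl)
        band = prsmod.score_band(ldl_score, bands)
        if want is None or band is want:
            return d, ldl_score, tg_score, band
    raise RuntimeError(
        f"could not draw a genotype in band {want}: infeasible specification"
    )


_GROUP_HAPLOTYPE = {
    "FD": ApoeHaplotype.E2E2,
    "FH": ApoeHaplotype.E3E3,
    "POLY_HCL": ApoeHaplotype.E3E3,
    "SEVERE_HCL": ApoeHaplotype.E3E3,
    "CONTROL": ApoeHaplotype.E3E3,
}

_GROUP_LDL_BAND = {
    "FD": None,
    "FH": None,
    "POLY_HCL": Band.HIGH,
    "SEVERE_HCL": Band.LOW,
    "CONTROL": Band.LOW,
}


def _draw_statin(rng, gp: GroupParams, equivalence) -> Optional[cls.StatinTherapy]:
    if rng.random() >= gp.statin_frac:
        return None
    drugs = sorted(equivalence)
    drug = drugs[rng.integers(len(drugs))]
    dose = equivalence[drug][rng.integers(len(equivalence[drug]))][0]
    return cls.StatinTherapy(
        drug=drug, dose=dose,
        months_before_ultrasound=float(rng.integers(2, 24)),
        months_historical=float(rng.integers(3, 60)),
    )


def generate_cohort(
    spec: CohortSpec, reference: ReferencePopulation
) -> list[cls.Participant]:
    """Emit participants whose genotypes, lipids and annotations satisfy the
    defining predicates of their intended groups (label-recoverable).

    Lipids are drawn on the pretreatment scale; statin users get a measured
    LDL-C reduced by the shipped dose-response table, so back-correction in
    the classifier recovers the generated value exactly.
    """
    rng = np.random.default_rng(spec.seed + 1)
    equivalence = cls.load_equivalence_table()
    reduction = cls.load_reduction_table()
    ldl_bands = reference.ldl_bands
    tg_bands = reference.tg_bands
    participants: list[cls.Participant] = []
    counter = 0

    for group in ("FD", "FH", "POLY_HCL", "SEVERE_HCL", "CONTROL"):
        if group not in spec.groups:
            continue
        gp = spec.groups[group]
        hap = _GROUP_HAPLOTYPE[group]
        for _ in range(gp.n):
            counter += 1
            pid = f"P{counter:05d}"
            dosage, ldl_score, tg_score, band = _draw_genotype_with_band(
                rng, reference.ldl_model, reference.tg_model, hap,
                ldl_bands, _GROUP_LDL_BAND[group],
            )
            tg_band = prsmod.score_band(tg_score, tg_bands)

            ldl_pre = gp.ldl.draw(rng)
            hdl = gp.hdl.draw(rng)
            tg = gp.tg.draw(rng)
            lpa = gp.lpa.draw(rng)

            statin = _draw_statin(rng, gp, equivalence)
            ldl_measured = ldl_pre
            if cls.statin_user(statin):
                atorva = cls.atorvastatin_equivalent(
                    statin.drug, statin.dose, equivalence
                )
                ldl_measured = ldl_pre * (1.0 - cls.statin_reduction(atorva, reduction))

            ldl_direct = tg > cls.DEFAULT_THRESHOLDS.friedewald_tg_max
            tc = ldl_measured + hdl + tg / 2.2
            lipids = cls.LipidPanel(
                tc=tc, ldl_c=ldl_measured, hdl_c=hdl, tg=tg,
                ldl_direct=ldl_direct, lpa=lpa,
            )

            age = max(25.0, float(rng.normal(gp.age_median, gp.age_sd)))
            chd = bool(rng.random() < gp.chd_frequency)
            onset = None
            if chd:
                onset = float(
                    np.clip(rng.normal(gp.chd_onset_median, 6.0), 25.0, age)
                )
                age = max(age, onset)

            smoke_u = rng.random()
            if smoke_u < gp.current_smoker_frac:
                smoking = "current"
            elif smoke_u < gp.current_smoker_frac + gp.ex_smoker_frac:
                smoking = "ex"
            else:
                smoking = "never"

            causal = []
            xanthomas = False
            if group == "FH":
                causal = [
                    prsmod.VariantAnnotation(
                        rsid=f"fhvar{counter}", gene="LDLR",
                        gnomad_af=None, synonymous=False, pathogenicity="P",
                    )
                ]
                xanthomas = True  # with the causal variant this forces DLCN >= 9

            participants.append(
                cls.Participant(
                    id=pid,
                    sex="M" if rng.random() < gp.male_frac else "F",
                    age=age,
                    lipids=lipids,
                    bmi=float(rng.lognormal(np.log(gp.bmi_median), 0.12)),
                    smoking=smoking,
                    hypertension=bool(rng.random() < gp.hypertension_frac),
                    diabetes=bool(rng.random() < gp.diabetes_frac),
                    tendon_xanthomas=xanthomas,
                    statin=statin,
                    causal_variants=causal,
                    apoe_haplotype=hap,
                    prs_ldl_band=band,
                    prs_tg_band=tg_band,
                    chd=chd,
                    chd_onset_age=onset,
                    panel="GENES_24",
                    intended_group=group,
                )
            )
            # stash the genotype for fixture writing
            participants[-1].__dict__["_dosages"] = dosage
    return participants


# ---------------------------------------------------------------------------
# ultrasound


_SITES = [
    (us.Side.LEFT, us.Site.MAIN),
    (us.Side.LEFT, us.Site.BIFURCATION),
    (us.Side.LEFT, us.Site.BRANCH),
    (us.Side.RIGHT, us.Site.MAIN),
    (us.Side.RIGHT, us.Site.BIFURCATION),
    (us.Side.RIGHT, us.Site.BRANCH),
]


def _site_segment(rng, site: us.Site) -> us.Segment:
    if site is us.Site.BRANCH:
        return us.Segment.BRANCH_PROXIMAL
    if site is us.Site.BIFURCATION:
        return us.Segment.BULB
    return (us.Segment.MAIN_DISTAL_1, us.Segment.MAIN_DISTAL_2)[rng.integers(2)]


def generate_ultrasound(
    participants: Sequence[cls.Participant],
    spec: CohortSpec,
    seed: int = 0,
) -> list[us.UltrasoundSiteRecord]:
    """Per-site plaque records with group-dependent burden.

    Each territory draws a Poisson plaque count scattered uniformly over
    the six sites; heights are log-normal and every generated plaque
    satisfies the plaque predicate (encroachment >= 0.5 mm).
    """
    rng = np.random.default_rng(seed + 2)
    records: list[us.UltrasoundSiteRecord] = []
    for p in participants:
        group = p.intended_group
        if group is None or group not in spec.groups:
            raise ValueError(f"participant {p.id}: unknown group label {group!r}")
        gp = spec.groups[group]
        for territory, params in (
            (us.Territory.CAROTID, gp.carotid),
            (us.Territory.FEMORAL, gp.femoral),
        ):
            site_records: dict[tuple, us.UltrasoundSiteRecord] = {}
            imt = {sk: float(np.clip(rng.normal(0.75, 0.08), 0.4, 1.4)) for sk in _SITES}
            k = int(rng.poisson(params.plaque_rate))
            for _ in range(k):
                side, site = _SITES[rng.integers(6)]
                segment = _site_segment(rng, site)
                height = float(
                    rng.lognormal(np.log(params.height_median), params.height_sigma)
                )
                stenosis = float(
                    np.clip(rng.normal(params.stenosis_mean, params.stenosis_sd), 3.0, 90.0)
                )
                original = 50.0
                plaque = us.PlaqueMeasurement(
                    height=height,
                    encroachment=max(0.55, 0.5 * height),
                    residual_lumen_area=original * (1.0 - stenosis / 100.0),
                    original_lumen_area=original,
                )
                key = (side, site, segment)
                if key not in site_records:
                    site_records[key] = us.UltrasoundSiteRecord(
                        participant_id=p.id, territory=territory, side=side,
                        site=site, segment=segment,
                        surrounding_imt=imt[(side, site)],
                    )
                site_records[key].plaques.append(plaque)
            # plaque-free sites still get one (empty) record each
            for side, site in _SITES:
                if not any(k[:2] == (side, site) for k in site_records):
                    seg = (us.Segment.MAIN_DISTAL_1 if site is us.Site.MAIN
                           else us.Segment.BULB if site is us.Site.BIFURCATION
                           else us.Segment.BRANCH_PROXIMAL)
                    site_records[(side, site, seg)] = us.UltrasoundSiteRecord(
                        participant_id=p.id, territory=territory, side=side,
                        site=site, segment=seg, surrounding_imt=imt[(side, site)],
                    )
            records.extend(site_records.values())
    return records
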