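"""Lipid harmonization and rule-based hyperlipidemia group assignment.

Implements the study-group decision cascade: exclusions first, then
familial dysbetalipoproteinemia (FD), familial hypercholesterolemia (FH),
polygenic hypercholesterolemia, severe hypercholesterolemia, control.
Participants failing every rule are UNCLASSIFIED with explicit reasons.

LDL-C for classification is the estimated pretreatment value for statin
users; HDL-C and TG are never back-corrected.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from enum import Enum
from importlib import resources
from typing import Optional, Sequence

import numpy as np

from .prs import ApoeHaplotype, Band, VariantAnnotation

__all__ = [
    "FH_GENES",
    "PANEL_24_GENES",
    "PANEL_6_GENES",
    "ClassificationThresholds",
    "Group",
    "GroupAssignment",
    "LipidPanel",
    "LpaBand",
    "Participant",
    "StatinTherapy",
    "assign_group",
    "atorvastatin_equivalent",
    "dlcn_score",
    "friedewald_ldl",
    "harmonize",
    "load_dlcn_table",
    "load_equivalence_table",
    "load_reduction_table",
    "lpa_band",
    "pretreatment_ldl",
    "statin_user",
]

FH_GENES = frozenset({"LDLR", "APOB", "PCSK9"})

PANEL_24_GENES = (
    "ABCA1", "ABCG5", "ABCG8", "ANGPTL3", "APOA1", "APOA5", "APOB", "APOC2",
    "APOC3", "APOE", "CETP", "GPD1", "GPIHBP1", "LCAT", "LDLR", "LDLRAP1",
    "LIPC", "LIPI", "LMF1", "LPL", "PCSK9", "SAR1B", "STAP1", "USF1",
)
PANEL_6_GENES = ("ANGPTL3", "APOB", "APOC3", "LDLR", "LPL", "PCSK9")


class Group(Enum):
    FD = "FD"
    FH = "FH"
    POLY_HCL = "POLY_HCL"
    SEVERE_HCL = "SEVERE_HCL"
    CONTROL = "CONTROL"
    EXCLUDED = "EXCLUDED"
    UNCLASSIFIED = "UNCLASSIFIED"


class LpaBand(Enum):
    NORMAL = "NORMAL"          # < 30 mg/dL
    BORDERLINE = "BORDERLINE"  # 30 to < 50
    ELEVATED = "ELEVATED"      # >= 50
    VERY_HIGH = "VERY_HIGH"    # > 180


@dataclass(frozen=True)
class ClassificationThresholds:
    fd_tg_min: float = 1.5           # mmol/L
    hcl_ldl_min: float = 4.9         # mmol/L, strictly above
    control_ldl_max: float = 3.0     # mmol/L, strictly below
    control_tg_max: float = 1.5      # mmol/L, strictly below
    dlcn_definite_min: int = 9       # points
    friedewald_tg_max: float = 4.5   # mmol/L
    lpa_borderline: float = 30.0     # mg/dL
    lpa_elevated: float = 50.0
    lpa_very_high: float = 180.0

    def __post_init__(self) -> None:
        vals = (self.fd_tg_min, self.hcl_ldl_min, self.control_ldl_max,
                self.control_tg_max, self.dlcn_definite_min,
                self.friedewald_tg_max)
        if any(v <= 0 for v in vals):
            raise ValueError("thresholds must be positive")
        if not (self.lpa_borderline < self.lpa_elevated < self.lpa_very_high):
            raise ValueError("Lp(a) bands must be strictly increasing")


DEFAULT_THRESHOLDS = ClassificationThresholds()


@dataclass
class LipidPanel:
    """Lipid concentrations in mmol/L; Lp(a) in mg/dL."""

    tc: Optional[float] = None
    ldl_c: Optional[float] = None
    hdl_c: Optional[float] = None
    tg: Optional[float] = None
    ldl_direct: bool = False
    lpa: Optional[float] = None

    def __post_init__(self) -> None:
        for name in ("tc", "ldl_c", "hdl_c", "tg", "lpa"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be >= 0, got {v}")


@dataclass
class StatinTherapy:
    drug: str
    dose: float  # mg/day
    months_before_ultrasound: float = 0.0
    months_historical: float = 0.0

    def __post_init__(self) -> None:
        if self.dose <= 0:
            raise ValueError("statin dose must be positive")
        if self.months_before_ultrasound < 0 or self.months_historical < 0:
            raise ValueError("therapy durations must be >= 0")


@dataclass
class Participant:
    id: str
    sex: str  # "M" / "F"
    age: float
    lipids: LipidPanel
    bmi: Optional[float] = None
    smoking: str = "never"  # current / ex / never
    hypertension: bool = False
    diabetes: bool = False
    tendon_xanthomas: bool = False
    arcus_under_45: bool = False
    family_premature_cvd: bool = False
    family_high_ldl: bool = False
    family_xanthoma_or_arcus: bool = False
    family_child_high_ldl: bool = False
    statin: Optional[StatinTherapy] = None
    causal_variants: list[VariantAnnotation] = field(default_factory=list)
    apoe_haplotype: Optional[ApoeHaplotype] = None
    prs_ldl_band: Optional[Band] = None
    prs_tg_band: Optional[Band] = None
    chd: bool = False
    chd_onset_age: Optional[float] = None
    panel: str = "GENES_24"
    intended_group: Optional[str] = None  # generator bookkeeping only

    def __post_init__(self) -> None:
        if self.age <= 0:
            raise ValueError("age must be positive")
        if self.bmi is not None and self.bmi <= 0:
            raise ValueError("bmi must be positive")
        if self.chd_onset_age is not None and not self.chd:
            raise ValueError("chd_onset_age present but chd flag is false")
        if self.panel not in ("GENES_24", "GENES_6"):
            raise ValueError(f"unknown panel {self.panel!r}")


@dataclass
class GroupAssignment:
    label: Group
    reasons: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.label in (Group.EXCLUDED, Group.UNCLASSIFIED) and not self.reasons:
            raise ValueError(f"{self.label.value} requires at least one reason")


# ---------------------------------------------------------------------------
# lipid harmonization


def friedewald_ldl(
    tc: float, hdl: float, tg: float,
    thresholds: ClassificationThresholds = DEFAULT_THRESHOLDS,
) -> float:
    """LDL-C (mmol/L) as TC - HDL-C - TG/2.2; invalid above TG 4.5 mmol/L."""
    if min(tc, hdl, tg) < 0:
        raise ValueError("lipid concentrations must be >= 0")
    if tg > thresholds.friedewald_tg_max:
        raise ValueError(
            f"TG {tg} > {thresholds.friedewald_tg_max} mmol/L: "
            "direct measurement required"
        )
    return tc - hdl - tg / 2.2


def load_equivalence_table(path=None) -> dict[str, list[tuple[float, float]]]:
    """drug -> sorted (dose, atorvastatin-equivalent dose) support points."""
    table: dict[str, list[tuple[float, float]]] = {}
    with _open_data(path, "statin_equivalence.csv") as fh:
        for row in csv.DictReader(fh):
            table.setdefault(row["drug"], []).append(
                (float(row["dose_mg"]), float(row["atorvastatin_equivalent_mg"]))
            )
    for pts in table.values():
        pts.sort()
    return table


def load_reduction_table(path=None) -> list[tuple[float, float]]:
    """Sorted (atorvastatin dose, LDL-C reduction fraction) support points."""
    with _open_data(path, "statin_ldl_reduction.csv") as fh:
        pts = [
            (float(r["atorvastatin_dose_mg"]), float(r["ldl_reduction_fraction"]))
            for r in csv.DictReader(fh)
        ]
    pts.sort()
    return pts


def _open_data(path, default_name):
    if path is not None:
        return open(path, newline="")
    return (resources.files("lipidstrat") / "data" / default_name).open(newline="")


def atorvastatin_equivalent(
    drug: str, dose: float, equivalence_table=None
) -> float:
    """Atorvastatin-equivalent daily dose, interpolating between table points.

    Doses outside the tabulated range are clamped to the nearest endpoint.
    """
    table = equivalence_table or load_equivalence_table()
    if drug not in table:
        raise KeyError(f"no equivalence entry for drug {drug!r}")
    pts = table[drug]
    doses = np.array([p[0] for p in pts])
    equiv = np.array([p[1] for p in pts])
    return float(np.interp(dose, doses, equiv))


def statin_reduction(atorva_dose: float, reduction_table=None) -> float:
    """Expected fractional LDL-C reduction at an atorvastatin-equivalent dose."""
    pts = reduction_table or load_reduction_table()
    doses = np.array([p[0] for p in pts])
    red = np.array([p[1] for p in pts])
    r = float(np.interp(atorva_dose, doses, red))
    if not (0.0 <= r < 1.0):
        raise ValueError(f"reduction fraction {r} outside [0, 1)")
    return r


def pretreatment_ldl(
    measured_ldl: float, atorva_dose: float, reduction_table=None
) -> float:
    """Back-correct an on-statin LDL-C to its estimated untreated value."""
    if measured_ldl < 0:
        raise ValueError("measured LDL-C must be >= 0")
    r = statin_reduction(atorva_dose, reduction_table)
    return measured_ldl / (1.0 - r)


def statin_user(therapy: Optional[StatinTherapy]) -> bool:
    """True when on statins > 1 month pre-ultrasound or >= 3 months ever."""
    if therapy is None:
        return False
    return therapy.months_before_ultrasound > 1.0 or therapy.months_historical >= 3.0


def harmonize(
    participant: Participant,
    equivalence_table=None,
    reduction_table=None,
) -> Participant:
    """Return a copy whose LDL-C is the estimated pretreatment value.

    Identity for non-users.  HDL-C and TG are left untouched.
    """
    p = participant
    if not statin_user(p.statin) or p.lipids.ldl_c is None:
        return p
    assert p.statin is not None
    atorva = atorvastatin_equivalent(p.statin.drug, p.statin.dose, equivalence_table)
    corrected = pretreatment_ldl(p.lipids.ldl_c, atorva, reduction_table)
    lipids = replace(p.lipids, ldl_c=corrected)
    return replace(p, lipids=lipids)


def lpa_band(
    lpa: float, thresholds: ClassificationThresholds = DEFAULT_THRESHOLDS
) -> LpaBand:
    if lpa < 0:
        raise ValueError("Lp(a) must be >= 0")
    if lpa > thresholds.lpa_very_high:
        return LpaBand.VERY_HIGH
    if lpa >= thresholds.lpa_elevated:
        return LpaBand.ELEVATED
    if lpa >= thresholds.lpa_borderline:
        return LpaBand.BORDERLINE
    return LpaBand.NORMAL


# ---------------------------------------------------------------------------
# DLCN score


def load_dlcn_table(path=None) -> dict[str, dict[str, int]]:
    """category -> {item: points} from the editable criteria CSV."""
    table: dict[str, dict[str, int]] = {}
    with _open_data(path, "dlcn_criteria.csv") as fh:
        for row in csv.DictReader(fh):
            table.setdefault(row["category"], {})[row["item"]] = int(row["points"])
    if not table:
        raise ValueError("empty DLCN criteria table")
    return table


def _premature_chd(p: Participant) -> bool:
    if not p.chd or p.chd_onset_age is None:
        return False
    return p.chd_onset_age < (55.0 if p.sex == "M" else 60.0)


def _dlcn_items(p: Participant, ldl: Optional[float]) -> dict[str, bool]:
    has_mutation = any(
        v.gene in FH_GENES and v.pathogenicity in ("P", "LP")
        for v in p.causal_variants
    )
    items = {
        "first_degree_premature_cvd": p.family_premature_cvd,
        "first_degree_high_ldl": p.family_high_ldl,
        "first_degree_xanthoma_or_arcus": p.family_xanthoma_or_arcus,
        "child_high_ldl": p.family_child_high_ldl,
        "premature_chd": _premature_chd(p),
        "premature_cerebral_peripheral": False,
        "tendon_xanthomas": p.tendon_xanthomas,
        "arcus_cornealis_under_45": p.arcus_under_45,
        "causal_mutation": has_mutation,
        "ldl_ge_8_5": False,
        "ldl_6_5_to_8_4": False,
        "ldl_5_0_to_6_4": False,
        "ldl_4_0_to_4_9": False,
    }
    if ldl is not None:
        items["ldl_ge_8_5"] = ldl >= 8.5
        items["ldl_6_5_to_8_4"] = 6.5 <= ldl < 8.5
        items["ldl_5_0_to_6_4"] = 5.0 <= ldl < 6.5
        items["ldl_4_0_to_4_9"] = 4.0 <= ldl < 5.0
    return items


def dlcn_score(participant: Participant, criteria_table=None) -> int:
    """Dutch Lipid Clinic Network points: best item per category, summed.

    LDL-C bands are evaluated on the participant's (harmonized) LDL-C.
    """
    table = criteria_table or load_dlcn_table()
    items = _dlcn_items(participant, participant.lipids.ldl_c)
    total = 0
    for category, entries in table.items():
        best = 0
        for item, points in entries.items():
            if item not in items:
                raise ValueError(f"DLCN table references unknown item {item!r}")
            if items[item]:
                best = max(best, points)
        total += best
    return total


# ---------------------------------------------------------------------------
# group assignment


def _plp(variants: Sequence[VariantAnnotation]) -> list[VariantAnnotation]:
    return [v for v in variants if v.pathogenicity in ("P", "LP")]


def assign_group(
    participant: Participant,
    thresholds: ClassificationThresholds = DEFAULT_THRESHOLDS,
    criteria_table=None,
) -> GroupAssignment:
    """Apply the classification cascade to a harmonized participant.

    Order: exclusions, FD, FH, polygenic HCL, severe HCL, control,
    UNCLASSIFIED.  The reasons list records the predicates of the winning
    rule (or the failure reasons for UNCLASSIFIED).
    """
    p = participant
    t = thresholds
    plp = _plp(p.causal_variants)
    fh_plp = [v for v in plp if v.gene in FH_GENES]
    other_plp = [v for v in plp if v.gene not in FH_GENES and v.gene != "APOE"]

    # 1. exclusions
    if other_plp:
        genes = sorted({v.gene for v in other_plp})
        return GroupAssignment(
            Group.EXCLUDED, [f"plp_outside_fh_apoe_genes:{','.join(genes)}"]
        )
    if fh_plp and p.apoe_haplotype is ApoeHaplotype.E2E2:
        return GroupAssignment(Group.EXCLUDED, ["fh_plp_with_e2e2"])
    if len({(v.gene, v.rsid) for v in fh_plp}) > 1:
        return GroupAssignment(Group.EXCLUDED, ["multiple_fh_plp_variants"])

    missing = []
    if p.apoe_haplotype is None:
        missing.append("apoe_haplotype")
    if p.lipids.tg is None:
        missing.append("tg")
    if p.lipids.ldl_c is None:
        missing.append("ldl_c")
    if missing:
        return GroupAssignment(
            Group.UNCLASSIFIED, ["insufficient data: " + ", ".join(missing)]
        )

    tg = p.lipids.tg
    ldl = p.lipids.ldl_c

    # 2. FD: e2e2 plus TG >= 1.5 mmol/L
    if p.apoe_haplotype is ApoeHaplotype.E2E2 and tg >= t.fd_tg_min:
        return GroupAssignment(Group.FD, ["apoe=e2e2", f"tg>={t.fd_tg_min}"])

    # 3. FH: P/LP in LDLR/APOB/PCSK9 and definite DLCN
    if fh_plp:
        score = dlcn_score(p, criteria_table)
        if score >= t.dlcn_definite_min:
            return GroupAssignment(
                Group.FH,
                [f"plp:{fh_plp[0].gene}", f"dlcn={score}>={t.dlcn_definite_min}"],
            )

    if p.prs_ldl_band is None:
        return GroupAssignment(
            Group.UNCLASSIFIED, ["insufficient data: prs_ldl_band"]
        )

    # 4/5. polygenic vs severe HCL (disjoint by PRS band)
    if ldl > t.hcl_ldl_min and not p.tendon_xanthomas:
        if p.prs_ldl_band is Band.HIGH:
            return GroupAssignment(
                Group.POLY_HCL,
                [f"ldl>{t.hcl_ldl_min}", "prs_ldl=HIGH", "no_xanthomas"],
            )
        if p.prs_ldl_band is Band.LOW:
            return GroupAssignment(
                Group.SEVERE_HCL,
                [f"ldl>{t.hcl_ldl_min}", "prs_ldl=LOW", "no_xanthomas"],
            )

    # 6. control: no causal panel variant, low PRS, normal lipids
    if (
        not plp
        and p.prs_ldl_band is Band.LOW
        and ldl < t.control_ldl_max
        and tg < t.control_tg_max
    ):
        reasons = [
            "no_causal_variant",
            "prs_ldl=LOW",
            f"ldl<{t.control_ldl_max}",
            f"tg<{t.control_tg_max}",
        ]
        if p.panel == "GENES_6":
            reasons.append("reduced_panel_control")
        return GroupAssignment(Group.CONTROL, reasons)

    return GroupAssignment(Group.UNCLASSIFIED, ["no rule matched"])
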