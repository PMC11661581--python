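"""Carotid / femoral atherosclerosis quantification.

Measurements arrive per arterial site (six per territory: left and right
main vessel, bifurcation, and distal branch).  A focal lesion counts as a
plaque when it encroaches >= 0.5 mm into the lumen, or >= 50% of the
surrounding intima-media thickness, or is >= 1.5 mm thick.  Percent
stenosis follows the area-based ECST convention.  Five aggregates are
reported per territory: plaque number, maximum stenosis, total stenosis
(sum of per-artery maxima, may exceed 100%), maximum plaque height, and
plaque score (sum over the eight scoring segments of the per-segment
maximum plaque thickness).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence

__all__ = [
    "Territory",
    "Side",
    "Site",
    "Segment",
    "PlaqueMeasurement",
    "PlaqueRule",
    "PlaqueMetrics",
    "UltrasoundSiteRecord",
    "aggregate_territory",
    "ecst_stenosis",
    "is_plaque",
    "plaque_score",
]


class Territory(Enum):
    CAROTID = "CAROTID"
    FEMORAL = "FEMORAL"


class Side(Enum):
    LEFT = "LEFT"
    RIGHT = "RIGHT"


class Site(Enum):
    """Arterial site; MAIN is the CCA (carotid) or CFA (femoral), BRANCH the
    proximal ICA (carotid) or SFA (femoral)."""

    MAIN = "MAIN"
    BIFURCATION = "BIFURCATION"
    BRANCH = "BRANCH"


class Segment(Enum):
    """Four scoring segments per side: proximal branch, bulb, and two
    distal main-vessel segments (15 mm each by convention)."""

    BRANCH_PROXIMAL = "BRANCH_PROXIMAL"
    BULB = "BULB"
    MAIN_DISTAL_1 = "MAIN_DISTAL_1"
    MAIN_DISTAL_2 = "MAIN_DISTAL_2"


_SITE_SEGMENTS = {
    Site.BRANCH: (Segment.BRANCH_PROXIMAL,),
    Site.BIFURCATION: (Segment.BULB,),
    Site.MAIN: (Segment.MAIN_DISTAL_1, Segment.MAIN_DISTAL_2),
}


@dataclass(frozen=True)
class PlaqueRule:
    encroachment_min: float = 0.5  # mm
    imt_ratio_min: float = 0.5
    thickness_min: float = 1.5  # mm

    def __post_init__(self) -> None:
        if min(self.encroachment_min, self.imt_ratio_min, self.thickness_min) <= 0:
            raise ValueError("plaque rule thresholds must be positive")


DEFAULT_RULE = PlaqueRule()


@dataclass(frozen=True)
class PlaqueMeasurement:
    height: float  # mm, media-adventitia to intima-lumen
    encroachment: float  # mm into the lumen
    residual_lumen_area: Optional[float] = None  # mm^2
    original_lumen_area: Optional[float] = None  # mm^2

    def __post_init__(self) -> None:
        if self.height < 0 or self.encroachment < 0:
            raise ValueError("height and encroachment must be >= 0")
        if self.residual_lumen_area is not None and self.original_lumen_area is not None:
            if not (0 <= self.residual_lumen_area <= self.original_lumen_area):
                raise ValueError("need 0 <= residual <= original lumen area")


@dataclass
class UltrasoundSiteRecord:
    participant_id: str
    territory: Territory
    side: Side
    site: Site
    segment: Segment
    surrounding_imt: float  # mm
    plaques: list[PlaqueMeasurement] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.surrounding_imt <= 0:
            raise ValueError("IMT must be positive")
        if self.segment not in _SITE_SEGMENTS[self.site]:
            raise ValueError(
                f"segment {self.segment.value} invalid for site {self.site.value}"
            )


@dataclass
class PlaqueMetrics:
    plaque_number: int
    max_stenosis: float  # %
    total_stenosis: float  # %
    max_plaque_height: float  # mm
    plaque_score: float  # mm

    def __post_init__(self) -> None:
        if self.total_stenosis < self.max_stenosis:
            raise ValueError("total stenosis must be >= max stenosis")
        if self.plaque_number == 0 and any(
            (self.max_stenosis, self.total_stenosis,
             self.max_plaque_height, self.plaque_score)
        ):
            raise ValueError("zero plaques implies zero metrics")


def is_plaque(
    m: PlaqueMeasurement, surrounding_imt: float, rule: PlaqueRule = DEFAULT_RULE
) -> bool:
    """Plaque predicate: any of the three criteria suffices."""
    return (
        m.encroachment >= rule.encroachment_min
        or m.encroachment >= rule.imt_ratio_min * surrounding_imt
        or m.height >= rule.thickness_min
    )


def ecst_stenosis(residual_lumen_area: float, original_lumen_area: float) -> float:
    """Percent stenosis = (1 - residual/original) * 100 (area-based)."""
    if original_lumen_area <= 0:
        raise ValueError("original lumen area must be positive")
    if not (0 <= residual_lumen_area <= original_lumen_area):
        raise ValueError("need 0 <= residual <= original lumen area")
    return (1.0 - residual_lumen_area / original_lumen_area) * 100.0


def _plaque_stenosis(m: PlaqueMeasurement) -> Optional[float]:
    if m.residual_lumen_area is None or m.original_lumen_area is None:
        return None  # partial-protocol record: no stenosis contribution
    return ecst_stenosis(m.residual_lumen_area, m.original_lumen_area)


def _check_one(records: Sequence[UltrasoundSiteRecord]) -> None:
    if len({r.participant_id for r in records}) > 1:
        raise ValueError("records span multiple participants")
    if len({r.territory for r in records}) > 1:
        raise ValueError("records span multiple territories")


def plaque_score(
    records: Sequence[UltrasoundSiteRecord], rule: PlaqueRule = DEFAULT_RULE
) -> float:
    """Sum over the 8 per-territory segments of the max qualifying plaque
    thickness in that segment (plaque-free segments contribute 0)."""
    _check_one(records)
    best: dict[tuple[Side, Segment], float] = {}
    for rec in records:
        for m in rec.plaques:
            if not is_plaque(m, rec.surrounding_imt, rule):
                continue
            key = (rec.side, rec.segment)
            best[key] = max(best.get(key, 0.0), m.height)
    return sum(best.values())


def aggregate_territory(
    records: Sequence[UltrasoundSiteRecord], rule: PlaqueRule = DEFAULT_RULE
) -> PlaqueMetrics:
    """Five per-territory aggregates over qualifying plaques only.

    An "artery" is one (side, site) pair; its stenosis is the maximum over
    its plaques, total stenosis sums those per-artery maxima.
    """
    _check_one(records)
    n = 0
    max_height = 0.0
    artery_max: dict[tuple[Side, Site], float] = {}
    for rec in records:
        for m in rec.plaques:
            if not is_plaque(m, rec.surrounding_imt, rule):
                continue
            n += 1
            max_height = max(max_height, m.height)
            st = _plaque_stenosis(m)
            if st is not None:
                key = (rec.side, rec.site)
                artery_max[key] = max(artery_max.get(key, 0.0), st)
    total = sum(artery_max.values())
    mx = max(artery_max.values(), default=0.0)
    return PlaqueMetrics(
        plaque_number=n,
        max_stenosis=mx,
        total_stenosis=total,
        max_plaque_height=max_height,
        plaque_score=plaque_score(records, rule),
    )
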