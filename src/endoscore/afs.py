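"""Revised American Fertility Society (1985) endometriosis scoring.

Implements the point form for endometriotic implants (by site, depth and
largest diameter), cul-de-sac obliteration, and adnexal adhesions (by
organ, type and degree of enclosure), and maps the total point score to
stages I-IV.

The point values are stored as literal lookup tables
(:data:`IMPLANT_POINTS`, :data:`CULDESAC_POINTS`, :data:`ADHESION_POINTS`)
so the form itself is reviewable; no arithmetic shortcuts are used.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Any, Optional

__all__ = [
    "ValidationError",
    "Site",
    "Depth",
    "Organ",
    "Side",
    "AdhesionKind",
    "Enclosure",
    "Culdesac",
    "Stage",
    "Lesion",
    "Adhesion",
    "SurgicalFindings",
    "AFSResult",
    "IMPLANT_POINTS",
    "CULDESAC_POINTS",
    "ADHESION_POINTS",
    "FIMBRIA_ENCLOSED_POINTS",
    "size_band",
    "implant_points",
    "adhesion_points",
    "score_lesions",
    "score_adhesions",
    "afs_total_and_stage",
    "stage_from_total",
    "validate_findings",
]


class ValidationError(ValueError):
    """A record violates the scoring form's constraints."""


class Site(str, Enum):
    PERITONEUM = "peritoneum"
    OVARY_LEFT = "ovary_left"
    OVARY_RIGHT = "ovary_right"


class Depth(str, Enum):
    SUPERFICIAL = "superficial"
    DEEP = "deep"


class Organ(str, Enum):
    OVARY = "ovary"
    TUBE = "tube"


class Side(str, Enum):
    LEFT = "left"
    RIGHT = "right"


class AdhesionKind(str, Enum):
    FILMY = "filmy"
    DENSE = "dense"


class Enclosure(str, Enum):
    LT_ONE_THIRD = "lt_one_third"
    ONE_TO_TWO_THIRDS = "one_to_two_thirds"
    GT_TWO_THIRDS = "gt_two_thirds"


class Culdesac(str, Enum):
    NONE = "none"
    PARTIAL = "partial"
    COMPLETE = "complete"


class Stage(str, Enum):
    I = "I"
    II = "II"
    III = "III"
    IV = "IV"

    @property
    def numeric(self) -> int:
        return {"I": 1, "II": 2, "III": 3, "IV": 4}[self.value]


# --- literal point tables (revised AFS form, 1985) -----------------------

# size bands for the largest diameter of an implant, in cm
_BAND_LT_1 = "lt_1cm"
_BAND_1_TO_3 = "1_to_3cm"
_BAND_GT_3 = "gt_3cm"

#: implant points keyed by (tissue, depth, size band); "ovary" applies
#: per side.
IMPLANT_POINTS: dict[tuple[str, Depth, str], int] = {
    ("peritoneum", Depth.SUPERFICIAL, _BAND_LT_1): 1,
    ("peritoneum", Depth.SUPERFICIAL, _BAND_1_TO_3): 2,
    ("peritoneum", Depth.SUPERFICIAL, _BAND_GT_3): 4,
    ("peritoneum", Depth.DEEP, _BAND_LT_1): 2,
    ("peritoneum", Depth.DEEP, _BAND_1_TO_3): 4,
    ("peritoneum", Depth.DEEP, _BAND_GT_3): 6,
    ("ovary", Depth.SUPERFICIAL, _BAND_LT_1): 1,
    ("ovary", Depth.SUPERFICIAL, _BAND_1_TO_3): 2,
    ("ovary", Depth.SUPERFICIAL, _BAND_GT_3): 4,
    ("ovary", Depth.DEEP, _BAND_LT_1): 4,
    ("ovary", Depth.DEEP, _BAND_1_TO_3): 16,
    ("ovary", Depth.DEEP, _BAND_GT_3): 20,
}

#: cul-de-sac obliteration points
CULDESAC_POINTS: dict[Culdesac, int] = {
    Culdesac.NONE: 0,
    Culdesac.PARTIAL: 4,
    Culdesac.COMPLETE: 40,
}

#: adhesion points keyed by (organ, kind, enclosure); applied per side.
ADHESION_POINTS: dict[tuple[Organ, AdhesionKind, Enclosure], int] = {
    (Organ.OVARY, AdhesionKind.FILMY, Enclosure.LT_ONE_THIRD): 1,
    (Organ.OVARY, AdhesionKind.FILMY, Enclosure.ONE_TO_TWO_THIRDS): 2,
    (Organ.OVARY, AdhesionKind.FILMY, Enclosure.GT_TWO_THIRDS): 4,
    (Organ.OVARY, AdhesionKind.DENSE, Enclosure.LT_ONE_THIRD): 4,
    (Organ.OVARY, AdhesionKind.DENSE, Enclosure.ONE_TO_TWO_THIRDS): 8,
    (Organ.OVARY, AdhesionKind.DENSE, Enclosure.GT_TWO_THIRDS): 16,
    (Organ.TUBE, AdhesionKind.FILMY, Enclosure.LT_ONE_THIRD): 1,
    (Organ.TUBE, AdhesionKind.FILMY, Enclosure.ONE_TO_TWO_THIRDS): 2,
    (Organ.TUBE, AdhesionKind.FILMY, Enclosure.GT_TWO_THIRDS): 4,
    (Organ.TUBE, AdhesionKind.DENSE, Enclosure.LT_ONE_THIRD): 4,
    (Organ.TUBE, AdhesionKind.DENSE, Enclosure.ONE_TO_TWO_THIRDS): 8,
    (Organ.TUBE, AdhesionKind.DENSE, Enclosure.GT_TWO_THIRDS): 16,
}

#: a tube whose fimbriated end is completely enclosed scores this many
#: points regardless of the enclosure band (form footnote).
FIMBRIA_ENCLOSED_POINTS = 16


def size_band(size_cm: float) -> str:
    """Classify the largest implant diameter into the form's size bands.

    Band edges are inclusive on the middle band: 1.0 cm and 3.0 cm both
    fall in the 1-3 cm band.
    """
    if not size_cm > 0:
        raise ValidationError(f"lesion size must be positive, got {size_cm}")
    if size_cm < 1.0:
        return _BAND_LT_1
    if size_cm <= 3.0:
        return _BAND_1_TO_3
    return _BAND_GT_3


# --- domain records ------------------------------------------------------


@dataclass(frozen=True)
class Lesion:
    """One endometriotic implant."""

    site: Site
    depth: Depth
    size_cm: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "site", Site(self.site))
        object.__setattr__(self, "depth", Depth(self.depth))
        if not self.size_cm > 0:
            raise ValidationError(
                f"lesion size must be positive, got {self.size_cm}"
            )


@dataclass(frozen=True)
class Adhesion:
    """One adnexal adhesion (per organ and side)."""

    organ: Organ
    side: Side
    kind: AdhesionKind
    enclosure: Enclosure
    fimbria_completely_enclosed: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "organ", Organ(self.organ))
        object.__setattr__(self, "side", Side(self.side))
        object.__setattr__(self, "kind", AdhesionKind(self.kind))
        object.__setattr__(self, "enclosure", Enclosure(self.enclosure))
        if self.fimbria_completely_enclosed and self.organ is not Organ.TUBE:
            raise ValidationError(
                "fimbria_completely_enclosed is only meaningful for tubes"
            )


def _default_ovaries() -> dict[Side, bool]:
    return {Side.LEFT: True, Side.RIGHT: True}


@dataclass
class SurgicalFindings:
    """One patient's laparoscopic record.

    ``function_ratings`` (a :class:`~endoscore.efi.FunctionScores`) is
    optional here; it is only needed downstream by the EFI calculation.
    """

    lesions: list[Lesion] = field(default_factory=list)
    adhesions: list[Adhesion] = field(default_factory=list)
    culdesac: Culdesac = Culdesac.NONE
    ovary_present: dict[Side, bool] = field(default_factory=_default_ovaries)
    function_ratings: Optional[Any] = None

    def __post_init__(self) -> None:
        self.culdesac = Culdesac(self.culdesac)
        self.ovary_present = {
            Side(k): bool(v) for k, v in self.ovary_present.items()
        }
        for s in (Side.LEFT, Side.RIGHT):
            self.ovary_present.setdefault(s, True)


_OVARY_SITE = {Side.LEFT: Site.OVARY_LEFT, Side.RIGHT: Site.OVARY_RIGHT}


def validate_findings(findings: SurgicalFindings) -> SurgicalFindings:
    """Validate a surgical record and canonicalize its adhesion list.

    Raises :class:`ValidationError` for lesions or adhesions recorded on
    an absent ovary.  When several adhesions share (organ, side, kind),
    only the worst-scoring one is kept (the form rates extent per organ,
    not per adhesion event).
    """
    for side, present in findings.ovary_present.items():
        if present:
            continue
        ovary_site = _OVARY_SITE[side]
        for lesion in findings.lesions:
            if lesion.site is ovary_site:
                raise ValidationError(
                    f"lesion recorded on absent {side.value} ovary"
                )
        for adh in findings.adhesions:
            if adh.organ is Organ.OVARY and adh.side is side:
                raise ValidationError(
                    f"adhesion recorded on absent {side.value} ovary"
                )
    canonical: dict[tuple[Organ, Side, AdhesionKind], Adhesion] = {}
    for adh in findings.adhesions:
        key = (adh.organ, adh.side, adh.kind)
        prev = canonical.get(key)
        if prev is None or adhesion_points(adh) > adhesion_points(prev):
            canonical[key] = adh
    return replace(findings, adhesions=list(canonical.values()))


# --- scoring -------------------------------------------------------------


def implant_points(lesion: Lesion) -> int:
    """Points for a single implant, from the literal form table."""
    tissue = "peritoneum" if lesion.site is Site.PERITONEUM else "ovary"
    return IMPLANT_POINTS[(tissue, lesion.depth, size_band(lesion.size_cm))]


def adhesion_points(adhesion: Adhesion) -> int:
    """Points for a single adhesion entry.

    A tube whose fimbriated end is completely enclosed is scored
    :data:`FIMBRIA_ENCLOSED_POINTS` regardless of the enclosure band.
    """
    if adhesion.fimbria_completely_enclosed:
        return FIMBRIA_ENCLOSED_POINTS
    return ADHESION_POINTS[(adhesion.organ, adhesion.kind, adhesion.enclosure)]


def score_lesions(
    findings: SurgicalFindings, include_culdesac: bool = True
) -> int:
    """Implant points (plus cul-de-sac points unless disabled).

    For each (site, depth) category only the single worst implant is
    scored: the form rates extent of disease per category, not per
    lesion.
    """
    findings = validate_findings(findings)
    worst: dict[tuple[Site, Depth], int] = {}
    for lesion in findings.lesions:
        key = (lesion.site, lesion.depth)
        pts = implant_points(lesion)
        if pts > worst.get(key, 0):
            worst[key] = pts
    total = sum(worst.values())
    if include_culdesac:
        total += CULDESAC_POINTS[findings.culdesac]
    return total


def score_adhesions(findings: SurgicalFindings) -> int:
    """Sum of adhesion points over organs and sides."""
    findings = validate_findings(findings)
    return sum(adhesion_points(a) for a in findings.adhesions)


def stage_from_total(total_score: int) -> Optional[Stage]:
    """Map a total point score to stage I-IV.

    A total of 0 means no endometriosis was scored and the stage is
    undefined (``None``).
    """
    if total_score < 0:
        raise ValidationError("total score cannot be negative")
    if total_score == 0:
        return None
    if total_score <= 5:
        return Stage.I
    if total_score <= 15:
        return Stage.II
    if total_score <= 40:
        return Stage.III
    return Stage.IV


@dataclass(frozen=True)
class AFSResult:
    """r-AFS scores and stage for one patient.

    ``lesion_score`` is the implant score, including cul-de-sac points
    when computed with ``lesion_score_includes_culdesac=True`` (the
    default convention); ``total_score`` always includes implants,
    cul-de-sac and adhesions.
    """

    lesion_score: int
    adhesion_score: int
    total_score: int
    stage: Optional[Stage]
    culdesac_points: int = 0

    @property
    def scored(self) -> bool:
        """False when no endometriosis points were recorded at all."""
        return self.total_score > 0

    @property
    def severe(self) -> bool:
        """Dichotomized grouping: stage III-IV vs I-II."""
        return self.stage in (Stage.III, Stage.IV)

    @property
    def stage_numeric(self) -> int:
        """Stage as 1-4 (0 when undefined), usable as a ROC index."""
        return self.stage.numeric if self.stage is not None else 0


def afs_total_and_stage(
    findings: SurgicalFindings,
    lesion_score_includes_culdesac: bool = True,
) -> AFSResult:
    """Full r-AFS result: lesion score, adhesion score, total, stage.

    The cul-de-sac convention for the *reported* lesion score is
    configurable because published usage varies; the total score is
    unaffected by the switch.
    """
    findings = validate_findings(findings)
    implants = score_lesions(findings, include_culdesac=False)
    culdesac = CULDESAC_POINTS[findings.culdesac]
    adhesions = score_adhesions(findings)
    total = implants + culdesac + adhesions
    lesion = implants + culdesac if lesion_score_includes_culdesac else implants
    return AFSResult(
        lesion_score=lesion,
        adhesion_score=adhesions,
        total_score=total,
        stage=stage_from_total(total),
        culdesac_points=culdesac,
    )
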