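"""Endometriosis Fertility Index (EFI).

Combines historical factors (age, duration of infertility, prior
pregnancy) with surgical factors (least-function score, r-AFS lesion
score band, r-AFS total score band) into a 0-10 prognostic score.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

from .afs import (
    AFSResult,
    Organ,
    Side,
    SurgicalFindings,
    ValidationError,
    adhesion_points,
    validate_findings,
)

__all__ = [
    "SideRatings",
    "FunctionScores",
    "ClinicalHistory",
    "EFIResult",
    "lf_side",
    "lf_total",
    "age_points",
    "infertility_points",
    "prior_pregnancy_points",
    "lf_points",
    "lesion_band_points",
    "total_band_points",
    "efi_total",
    "compute_efi",
    "suggest_ratings",
]

_RATING_RANGE = range(0, 5)


def _check_rating(value: int, label: str) -> int:
    if not isinstance(value, (int,)) or isinstance(value, bool):
        # ratings are ordinal 0..4; reject floats to catch unit mistakes
        if not (isinstance(value, float) and value.is_integer()):
            raise ValidationError(f"{label} rating must be an integer 0-4")
        value = int(value)
    if value not in _RATING_RANGE:
        raise ValidationError(f"{label} rating must be in 0-4, got {value}")
    return int(value)


@dataclass(frozen=True)
class SideRatings:
    """Function ratings for one side: tube, fimbria, ovary, each 0-4.

    4 = normal, 3 = mild dysfunction, 2 = moderate, 1 = severe,
    0 = absent or nonfunctional.
    """

    tube: int
    fimbria: int
    ovary: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "tube", _check_rating(self.tube, "tube"))
        object.__setattr__(
            self, "fimbria", _check_rating(self.fimbria, "fimbria")
        )
        object.__setattr__(self, "ovary", _check_rating(self.ovary, "ovary"))


@dataclass(frozen=True)
class FunctionScores:
    """Per-side function ratings plus ovary-presence flags."""

    left: SideRatings
    right: SideRatings
    ovary_present_left: bool = True
    ovary_present_right: bool = True


@dataclass(frozen=True)
class ClinicalHistory:
    age_years: float
    infertility_duration_years: float
    prior_pregnancy: bool

    def __post_init__(self) -> None:
        if not self.age_years > 0:
            raise ValidationError("age must be positive")
        if self.infertility_duration_years < 0:
            raise ValidationError("infertility duration cannot be negative")
        if not 15.0 <= self.age_years <= 55.0:
            warnings.warn(
                f"age {self.age_years} outside plausible reproductive "
                "range 15-55",
                stacklevel=2,
            )


@dataclass(frozen=True)
class EFIResult:
    lf_total: int
    historical_points: int
    surgical_points: int
    total: int
    lf_left: Optional[int] = None
    lf_right: Optional[int] = None

    @property
    def low_group(self) -> bool:
        """Dichotomized grouping: EFI <= 5 vs >= 6."""
        return self.total <= 5


def lf_side(tube: int, fimbria: int, ovary: int) -> int:
    """Least-function score of one side: minimum of the three ratings."""
    return min(
        _check_rating(tube, "tube"),
        _check_rating(fimbria, "fimbria"),
        _check_rating(ovary, "ovary"),
    )


def lf_total(scores: FunctionScores) -> int:
    """Least-function total (0-8).

    Left + right side scores; if one ovary is absent, the contralateral
    side score is doubled instead.  Undefined when both ovaries are
    absent.
    """
    left = lf_side(scores.left.tube, scores.left.fimbria, scores.left.ovary)
    right = lf_side(
        scores.right.tube, scores.right.fimbria, scores.right.ovary
    )
    if scores.ovary_present_left and scores.ovary_present_right:
        return left + right
    if scores.ovary_present_left:
        return 2 * left
    if scores.ovary_present_right:
        return 2 * right
    raise ValidationError("LF score undefined: both ovaries absent")


# --- rubric bands --------------------------------------------------------
# Band edges are inclusive toward the higher-scoring band: age exactly
# 35.0 scores 2, duration exactly 3.0 y scores 2.


def age_points(age_years: float) -> int:
    if age_years <= 35.0:
        return 2
    if age_years < 40.0:
        return 1
    return 0


def infertility_points(duration_years: float) -> int:
    return 2 if duration_years <= 3.0 else 0


def prior_pregnancy_points(prior_pregnancy: bool) -> int:
    return 1 if prior_pregnancy else 0


def lf_points(lf: int) -> int:
    if not 0 <= lf <= 8:
        raise ValidationError(f"LF total must be in 0-8, got {lf}")
    if lf >= 7:
        return 3
    if lf >= 4:
        return 2
    return 0


def lesion_band_points(afs_lesion_score: int) -> int:
    return 1 if afs_lesion_score < 16 else 0


def total_band_points(afs_total_score: int) -> int:
    return 1 if afs_total_score < 71 else 0


def efi_total(
    history: ClinicalHistory,
    lf: int,
    afs: AFSResult,
    lf_left: Optional[int] = None,
    lf_right: Optional[int] = None,
) -> EFIResult:
    """Apply the EFI rubric to pre-computed inputs.

    Historical points: age band (2/1/0) + infertility band (2/0) +
    prior pregnancy (1/0).  Surgical points: LF band (3/2/0) + lesion
    score band (1/0 at 16) + total score band (1/0 at 71).
    """
    historical = (
        age_points(history.age_years)
        + infertility_points(history.infertility_duration_years)
        + prior_pregnancy_points(history.prior_pregnancy)
    )
    surgical = (
        lf_points(lf)
        + lesion_band_points(afs.lesion_score)
        + total_band_points(afs.total_score)
    )
    return EFIResult(
        lf_total=lf,
        historical_points=historical,
        surgical_points=surgical,
        total=historical + surgical,
        lf_left=lf_left,
        lf_right=lf_right,
    )


def compute_efi(
    history: ClinicalHistory, scores: FunctionScores, afs: AFSResult
) -> EFIResult:
    """EFI from raw inputs: derives the LF score then applies the rubric."""
    left = lf_side(scores.left.tube, scores.left.fimbria, scores.left.ovary)
    right = lf_side(
        scores.right.tube, scores.right.fimbria, scores.right.ovary
    )
    return efi_total(
        history, lf_total(scores), afs, lf_left=left, lf_right=right
    )


# advisory rating heuristic — never used implicitly by the pipeline
_ADHESION_TO_RATING = ((16, 1), (8, 2), (4, 3), (1, 3))


def suggest_ratings(findings: SurgicalFindings) -> FunctionScores:
    """Suggest function ratings from adhesion severity.

    Purely advisory: surgeons rate function directly, and the pipeline
    never substitutes this heuristic for recorded ratings.  An organ
    with no adhesions is rated 4; worsening adhesion points lower the
    rating; an absent ovary is rated 0.
    """
    findings = validate_findings(findings)
    pts: dict[tuple[Organ, Side], int] = {}
    for adh in findings.adhesions:
        key = (adh.organ, adh.side)
        pts[key] = pts.get(key, 0) + adhesion_points(adh)

    def rating(organ: Organ, side: Side) -> int:
        p = pts.get((organ, side), 0)
        for threshold, rated in _ADHESION_TO_RATING:
            if p >= threshold:
                return rated
        return 4

    def side_ratings(side: Side) -> SideRatings:
        tube = rating(Organ.TUBE, side)
        fimbria = tube  # fimbrial function is not rated separately here
        if any(
            a.organ is Organ.TUBE
            and a.side is side
            and a.fimbria_completely_enclosed
            for a in findings.adhesions
        ):
            fimbria = 0
        ovary = (
            rating(Organ.OVARY, side) if findings.ovary_present[side] else 0
        )
        return SideRatings(tube=tube, fimbria=fimbria, ovary=ovary)

    return FunctionScores(
        left=side_ratings(Side.LEFT),
        right=side_ratings(Side.RIGHT),
        ovary_present_left=findings.ovary_present[Side.LEFT],
        ovary_present_right=findings.ovary_present[Side.RIGHT],
    )
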