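"""r-AFS scoring: worked examples, independent table oracle, properties."""
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from endoscore.afs import (
    Adhesion,
    Lesion,
    Side,
    Stage,
    SurgicalFindings,
    ValidationError,
    afs_total_and_stage,
    score_adhesions,
    score_lesions,
    stage_from_total,
)

# --- independent oracle: a flat literal point table, coded separately ----

ORACLE_IMPLANTS = {
    # (tissue, depth, band): points
    ("peritoneum", "superficial", "small"): 1,
    ("peritoneum", "superficial", "mid"): 2,
    ("peritoneum", "superficial", "large"): 4,
    ("peritoneum", "deep", "small"): 2,
    ("peritoneum", "deep", "mid"): 4,
    ("peritoneum", "deep", "large"): 6,
    ("ovary", "superficial", "small"): 1,
    ("ovary", "superficial", "mid"): 2,
    ("ovary", "superficial", "large"): 4,
    ("ovary", "deep", "small"): 4,
    ("ovary", "deep", "mid"): 16,
    ("ovary", "deep", "large"): 20,
}
ORACLE_ADHESIONS = {
    ("ovary", "filmy", "lt"): 1,
    ("ovary", "filmy", "mid"): 2,
    ("ovary", "filmy", "gt"): 4,
    ("ovary", "dense", "lt"): 4,
    ("ovary", "dense", "mid"): 8,
    ("ovary", "dense", "gt"): 16,
    ("tube", "filmy", "lt"): 1,
    ("tube", "filmy", "mid"): 2,
    ("tube", "filmy", "gt"): 4,
    ("tube", "dense", "lt"): 4,
    ("tube", "dense", "mid"): 8,
    ("tube", "dense", "gt"): 16,
}
ORACLE_CULDESAC = {"none": 0, "partial": 4, "complete": 40}
_ENC_SHORT = {
    "lt_one_third": "lt",
    "one_to_two_thirds": "mid",
    "gt_two_thirds": "gt",
}


def oracle_total(lesions, adhesions, culdesac):
    """Brute-force scorer over the literal tables.

    lesions: (site, depth, size_cm) tuples; adhesions: (organ, side,
    kind, enclosure, fimbria) tuples.
    """
    worst = {}
    for site, depth, size in lesions:
        tissue = "peritoneum" if site == "peritoneum" else "ovary"
        if size < 1.0:
            band = "small"
        elif size <= 3.0:
            band = "mid"
        else:
            band = "large"
        pts = ORACLE_IMPLANTS[(tissue, depth, band)]
        worst[(site, depth)] = max(worst.get((site, depth), 0), pts)
    total = sum(worst.values()) + ORACLE_CULDESAC[culdesac]
    worst_adh = {}
    for organ, side, kind, enclosure, fimbria in adhesions:
        if organ == "tube" and fimbria:
            pts = 16
        else:
            pts = ORACLE_ADHESIONS[(organ, kind, _ENC_SHORT[enclosure])]
        key = (organ, side, kind)
        worst_adh[key] = max(worst_adh.get(key, 0), pts)
    return total + sum(worst_adh.values())


def oracle_stage(total):
    if total == 0:
        return None
    if 1 <= total <= 5:
        return "I"
    if 6 <= total <= 15:
        return "II"
    if 16 <= total <= 40:
        return "III"
    return "IV"


# --- worked examples -----------------------------------------------------


def test_empty_record_scores_zero():
    f = SurgicalFindings()
    assert score_lesions(f) == 0
    assert score_adhesions(f) == 0
    res = afs_total_and_stage(f)
    assert res.total_score == 0
    assert res.stage is None
    assert not res.scored


def test_deep_left_ovarian_lesion_with_partial_culdesac():
    f = SurgicalFindings(
        lesions=[Lesion("ovary_left", "deep", 2.5)],
        culdesac="partial",
    )
    assert score_lesions(f) == 16 + 4


def test_peritoneal_superficial_plus_deep():
    f = SurgicalFindings(
        lesions=[
            Lesion("peritoneum", "superficial", 0.5),
            Lesion("peritoneum", "deep", 4.0),
        ]
    )
    assert score_lesions(f) == 1 + 6


def test_adhesion_examples():
    f = SurgicalFindings(
        adhesions=[
            Adhesion("ovary", "right", "dense", "gt_two_thirds"),
            Adhesion("tube", "right", "filmy", "lt_one_third"),
        ]
    )
    assert score_adhesions(f) == 16 + 1


def test_fimbria_override_scores_16():
    f = SurgicalFindings(
        adhesions=[
            Adhesion(
                "tube", "left", "dense", "one_to_two_thirds",
                fimbria_completely_enclosed=True,
            )
        ]
    )
    assert score_adhesions(f) == 16


def test_fimbria_flag_invalid_on_ovary():
    with pytest.raises(ValidationError):
        Adhesion("ovary", "left", "dense", "lt_one_third",
                 fimbria_completely_enclosed=True)


@pytest.mark.parametrize(
    "total,stage",
    [(1, "I"), (5, "I"), (6, "II"), (15, "II"), (16, "III"), (40, "III"),
     (41, "IV"), (100, "IV")],
)
def test_stage_boundaries(total, stage):
    assert stage_from_total(total) == Stage(stage)


def test_stage_step_function_matches_oracle():
    for total in range(0, 130):
        got = stage_from_total(total)
        assert (got.value if got else None) == oracle_stage(total)


def test_combined_example_stage_iii():
    f = SurgicalFindings(
        lesions=[Lesion("ovary_left", "deep", 2.5)],
        adhesions=[
            Adhesion("ovary", "right", "dense", "gt_two_thirds"),
            Adhesion("tube", "right", "filmy", "lt_one_third"),
        ],
        culdesac="partial",
    )
    res = afs_total_and_stage(f)
    assert res.lesion_score == 20
    assert res.adhesion_score == 17
    assert res.total_score == 37
    assert res.stage == Stage.III
    assert res.severe


def test_worst_lesion_per_category_only():
    f = SurgicalFindings(
        lesions=[
            Lesion("peritoneum", "superficial", 0.5),
            Lesion("peritoneum", "superficial", 2.0),
        ]
    )
    assert score_lesions(f) == 2  # largest lesion only, not 1 + 2


def test_duplicate_adhesions_canonicalized_to_worst():
    f = SurgicalFindings(
        adhesions=[
            Adhesion("ovary", "left", "dense", "lt_one_third"),
            Adhesion("ovary", "left", "dense", "gt_two_thirds"),
        ]
    )
    assert score_adhesions(f) == 16


def test_lesion_on_absent_ovary_rejected():
    f = SurgicalFindings(
        lesions=[Lesion("ovary_left", "deep", 2.0)],
        ovary_present={Side.LEFT: False, Side.RIGHT: True},
    )
    with pytest.raises(ValidationError):
        score_lesions(f)


def test_adhesion_on_absent_ovary_rejected():
    f = SurgicalFindings(
        adhesions=[Adhesion("ovary", "right", "filmy", "lt_one_third")],
        ovary_present={Side.LEFT: True, Side.RIGHT: False},
    )
    with pytest.raises(ValidationError):
        score_adhesions(f)


def test_culdesac_convention_switch():
    f = SurgicalFindings(
        lesions=[Lesion("peritoneum", "deep", 4.0)], culdesac="complete"
    )
    with_cds = afs_total_and_stage(f, lesion_score_includes_culdesac=True)
    without = afs_total_and_stage(f, lesion_score_includes_culdesac=False)
    assert with_cds.lesion_score == 46
    assert without.lesion_score == 6
    assert with_cds.total_score == without.total_score == 46


def test_invalid_lesion_size():
    with pytest.raises(ValidationError):
        Lesion("peritoneum", "deep", 0.0)


# --- property tests ------------------------------------------------------

lesion_tuples = hst.tuples(
    hst.sampled_from(["peritoneum", "ovary_left", "ovary_right"]),
    hst.sampled_from(["superficial", "deep"]),
    hst.floats(min_value=0.1, max_value=12.0, allow_nan=False),
)
adhesion_tuples = hst.tuples(
    hst.sampled_from(["ovary", "tube"]),
    hst.sampled_from(["left", "right"]),
    hst.sampled_from(["filmy", "dense"]),
    hst.sampled_from(
        ["lt_one_third", "one_to_two_thirds", "gt_two_thirds"]
    ),
    hst.booleans(),
).map(lambda t: t if t[0] == "tube" else (*t[:4], False))
findings_raw = hst.tuples(
    hst.lists(lesion_tuples, max_size=6),
    hst.lists(adhesion_tuples, max_size=6),
    hst.sampled_from(["none", "partial", "complete"]),
)


def _build(raw):
    lesions, adhesions, culdesac = raw
    return SurgicalFindings(
        lesions=[Lesion(*t) for t in lesions],
        adhesions=[Adhesion(*t) for t in adhesions],
        culdesac=culdesac,
    )


@settings(max_examples=200, deadline=None)
@given(findings_raw)
def test_total_matches_independent_oracle(raw):
    f = _build(raw)
    res = afs_total_and_stage(f)
    assert res.total_score == oracle_total(*raw)
    assert (res.stage.value if res.stage else None) == oracle_stage(
        res.total_score
    )


@settings(max_examples=100, deadline=None)
@given(findings_raw, lesion_tuples, adhesion_tuples)
def test_adding_findings_never_decreases_scores(raw, lesion, adhesion):
    base = _build(raw)
    base_res = afs_total_and_stage(base)
    more = _build(
        (raw[0] + [lesion], raw[1] + [adhesion], raw[2])
    )
    more_res = afs_total_and_stage(more)
    assert more_res.lesion_score >= base_res.lesion_score
    assert more_res.adhesion_score >= base_res.adhesion_score
    assert more_res.total_score >= base_res.total_score
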