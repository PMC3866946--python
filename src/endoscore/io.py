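"""Schema-validated CSV readers and writers for the patient tables.

All tables are plain CSV with documented headers.  Malformed rows are
rejected with line-numbered messages collected into a single
:class:`SchemaError`.
"""
from __future__ import annotations

from pathlib import Path
from typing import Union

import pandas as pd

from .afs import (
    Adhesion,
    Culdesac,
    Lesion,
    Side,
    Site,
    SurgicalFindings,
    ValidationError,
    validate_findings,
)
from .efi import ClinicalHistory, FunctionScores, SideRatings

__all__ = [
    "SchemaError",
    "CLINICAL_COLUMNS",
    "SURGICAL_COLUMNS",
    "RATINGS_COLUMNS",
    "SCORES_COLUMNS",
    "read_clinical",
    "read_surgical",
    "read_ratings",
    "read_scores",
    "read_outcomes",
    "write_table",
    "findings_from_frame",
    "ratings_from_frame",
    "history_from_frame",
]

PathLike = Union[str, Path]

CLINICAL_COLUMNS = [
    "patient_id",
    "age_years",
    "infertility_years",
    "prior_pregnancy",
]
SURGICAL_COLUMNS = [
    "patient_id",
    "record_type",
    "site_or_organ",
    "side",
    "depth_or_kind",
    "size_cm",
    "enclosure",
    "fimbria_enclosed",
]
RATINGS_COLUMNS = ["patient_id", "side", "tube", "fimbria", "ovary",
                   "ovary_present"]
SCORES_COLUMNS = ["patient_id", "index_value", "outcome"]
OUTCOMES_REQUIRED = ["patient_id", "clinical_pregnancy"]

_TRUE = {"1", "true", "yes", "t"}
_FALSE = {"0", "false", "no", "f", ""}


class SchemaError(ValidationError):
    """One or more rows or columns failed validation."""

    def __init__(self, path: PathLike, problems: list[str]):
        self.problems = problems
        shown = "\n  ".join(problems[:20])
        extra = "" if len(problems) <= 20 else f"\n  ... {len(problems) - 20} more"
        super().__init__(f"{path}: {len(problems)} problem(s):\n  {shown}{extra}")


def _parse_bool(value, row: int, column: str, problems: list[str]) -> bool:
    s = str(value).strip().lower()
    if s in _TRUE:
        return True
    if s in _FALSE:
        return False
    problems.append(f"row {row}: {column} must be boolean, got {value!r}")
    return False


def _require_columns(
    df: pd.DataFrame, required: list[str], path: PathLike
) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(path, [f"missing column(s): {missing}"])


def _check_unique_ids(df: pd.DataFrame, path: PathLike) -> None:
    dupes = df["patient_id"][df["patient_id"].duplicated()].unique().tolist()
    if dupes:
        raise SchemaError(path, [f"duplicate patient_id(s): {dupes}"])


def read_clinical(path: PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"patient_id": str})
    _require_columns(df, CLINICAL_COLUMNS, path)
    _check_unique_ids(df, path)
    problems: list[str] = []
    for idx, row in df.iterrows():
        line = idx + 2  # header is line 1
        if not row["age_years"] > 0:
            problems.append(f"row {line}: age_years must be positive")
        if row["infertility_years"] < 0:
            problems.append(f"row {line}: infertility_years negative")
        _parse_bool(row["prior_pregnancy"], line, "prior_pregnancy", problems)
    if problems:
        raise SchemaError(path, problems)
    df["prior_pregnancy"] = df["prior_pregnancy"].astype(bool).astype(int)
    return df


def read_surgical(path: PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    _require_columns(df, SURGICAL_COLUMNS, path)
    problems: list[str] = []
    for idx, row in df.iterrows():
        line = idx + 2
        rtype = row["record_type"]
        if rtype not in ("lesion", "adhesion", "culdesac"):
            problems.append(f"row {line}: unknown record_type {rtype!r}")
            continue
        if rtype == "lesion":
            try:
                size = float(row["size_cm"])
                if size <= 0:
                    raise ValueError
            except ValueError:
                problems.append(
                    f"row {line}: lesion size_cm must be positive, "
                    f"got {row['size_cm']!r}"
                )
            if row["depth_or_kind"] not in ("superficial", "deep"):
                problems.append(
                    f"row {line}: lesion depth must be superficial/deep"
                )
        elif rtype == "adhesion":
            if row["depth_or_kind"] not in ("filmy", "dense"):
                problems.append(
                    f"row {line}: adhesion kind must be filmy/dense"
                )
            if row["enclosure"] not in (
                "lt_one_third",
                "one_to_two_thirds",
                "gt_two_thirds",
            ):
                problems.append(f"row {line}: bad enclosure {row['enclosure']!r}")
        else:
            if row["depth_or_kind"] not in ("none", "partial", "complete"):
                problems.append(
                    f"row {line}: culdesac state must be none/partial/complete"
                )
    if problems:
        raise SchemaError(path, problems)
    return df


def read_ratings(path: PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"patient_id": str})
    _require_columns(df, RATINGS_COLUMNS, path)
    problems: list[str] = []
    for idx, row in df.iterrows():
        line = idx + 2
        if row["side"] not in ("left", "right"):
            problems.append(f"row {line}: side must be left/right")
        for col in ("tube", "fimbria", "ovary"):
            v = row[col]
            if not (float(v).is_integer() and 0 <= v <= 4):
                problems.append(
                    f"row {line}: {col} rating must be an integer 0-4, got {v}"
                )
        _parse_bool(row["ovary_present"], line, "ovary_present", problems)
    if problems:
        raise SchemaError(path, problems)
    return df


def read_scores(path: PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"patient_id": str})
    _require_columns(df, SCORES_COLUMNS, path)
    _check_unique_ids(df, path)
    problems: list[str] = []
    for idx, row in df.iterrows():
        line = idx + 2
        _parse_bool(row["outcome"], line, "outcome", problems)
    if problems:
        raise SchemaError(path, problems)
    df["outcome"] = df["outcome"].astype(bool).astype(int)
    return df


def read_outcomes(path: PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"patient_id": str})
    _require_columns(df, OUTCOMES_REQUIRED, path)
    _check_unique_ids(df, path)
    return df


def write_table(df: pd.DataFrame, path: PathLike) -> None:
    """Write a table as plain CSV (the round-trip partner of the readers)."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


# --- frame -> domain-object conversion -----------------------------------


def findings_from_frame(df: pd.DataFrame) -> dict[str, SurgicalFindings]:
    """Group a long-format surgical table into per-patient findings.

    Ovary presence is inferred from the ratings table when merged later;
    here an ovary is assumed present unless declared otherwise via
    :func:`apply_ovary_presence`.
    """
    out: dict[str, SurgicalFindings] = {}
    for pid, sub in df.groupby("patient_id", sort=True):
        lesions: list[Lesion] = []
        adhesions: list[Adhesion] = []
        culdesac = Culdesac.NONE
        for _, row in sub.iterrows():
            if row["record_type"] == "lesion":
                site = row["site_or_organ"]
                if site == "ovary":
                    site = f"ovary_{row['side']}"
                lesions.append(
                    Lesion(
                        Site(site),
                        row["depth_or_kind"],
                        float(row["size_cm"]),
                    )
                )
            elif row["record_type"] == "adhesion":
                fimbria = str(row["fimbria_enclosed"]).strip().lower() in _TRUE
                adhesions.append(
                    Adhesion(
                        row["site_or_organ"],
                        row["side"],
                        row["depth_or_kind"],
                        row["enclosure"],
                        fimbria,
                    )
                )
            else:
                culdesac = Culdesac(row["depth_or_kind"])
        out[str(pid)] = SurgicalFindings(
            lesions=lesions, adhesions=adhesions, culdesac=culdesac
        )
    return out


def ratings_from_frame(df: pd.DataFrame) -> dict[str, FunctionScores]:
    out: dict[str, FunctionScores] = {}
    for pid, sub in df.groupby("patient_id", sort=True):
        sides: dict[str, SideRatings] = {}
        present: dict[str, bool] = {}
        for _, row in sub.iterrows():
            sides[row["side"]] = SideRatings(
                tube=int(row["tube"]),
                fimbria=int(row["fimbria"]),
                ovary=int(row["ovary"]),
            )
            present[row["side"]] = str(
                row["ovary_present"]
            ).strip().lower() in _TRUE
        if set(sides) != {"left", "right"}:
            raise SchemaError(
                "ratings", [f"patient {pid}: need exactly one row per side"]
            )
        out[str(pid)] = FunctionScores(
            left=sides["left"],
            right=sides["right"],
            ovary_present_left=present["left"],
            ovary_present_right=present["right"],
        )
    return out


def history_from_frame(df: pd.DataFrame) -> dict[str, ClinicalHistory]:
    return {
        str(row["patient_id"]): ClinicalHistory(
            age_years=float(row["age_years"]),
            infertility_duration_years=float(row["infertility_years"]),
            prior_pregnancy=bool(row["prior_pregnancy"]),
        )
        for _, row in df.iterrows()
    }


def apply_ovary_presence(
    findings: dict[str, SurgicalFindings],
    ratings: dict[str, FunctionScores],
) -> dict[str, SurgicalFindings]:
    """Copy ovary-presence flags from ratings onto findings and validate."""
    for pid, f in findings.items():
        r = ratings.get(pid)
        if r is None:
            continue
        f.ovary_present = {
            Side.LEFT: r.ovary_present_left,
            Side.RIGHT: r.ovary_present_right,
        }
        f.function_ratings = r
        validate_findings(f)
    return findings
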