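"""End-to-end pipeline: score a cohort, run ROC analyses for both
indices, and build the two-group comparison tables."""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import pandas as pd

from . import __version__
from .afs import ValidationError, afs_total_and_stage
from .efi import compute_efi
from .io import (
    apply_ovary_presence,
    findings_from_frame,
    history_from_frame,
    ratings_from_frame,
    write_table,
)
from .roc import analyze
from .simulate import SimulationConfig, generate
from .stats import VariableSpec, build_report

__all__ = [
    "PipelineConfig",
    "score_cohort",
    "run_report",
    "TABLE2_VARIABLES",
    "TABLE3_VARIABLES",
]

logger = logging.getLogger(__name__)

#: baseline/cycle characteristics (mirrors the declared normal vs
#: non-normal routing of the baseline table)
TABLE2_VARIABLES = [
    VariableSpec("age", "normal", column="age_years", label="Average age (y)"),
    VariableSpec("infertility", "nonnormal", column="infertility_years",
                 label="Duration of infertility (y)"),
    VariableSpec("bmi", "nonnormal", column="bmi", label="BMI (kg/m2)"),
    VariableSpec("bfsh", "nonnormal", column="bfsh", label="bFSH (iu/L)"),
    VariableSpec("blh", "nonnormal", column="blh", label="bLH (iu/L)"),
    VariableSpec("e2", "nonnormal", column="e2", label="E2 (ng/L)"),
    VariableSpec("afc", "nonnormal", column="afc",
                 label="Antral follicle count"),
    VariableSpec("e2_hcg", "nonnormal", column="e2_hcg",
                 label="E2 on day of hCG (ng/L)"),
    VariableSpec("gn_start", "nonnormal", column="gn_start",
                 label="Start dose of Gn (iu/day)"),
    VariableSpec("stim_days", "nonnormal", column="stim_days",
                 label="Duration of stimulation (d)"),
    VariableSpec("gn_total", "normal", column="gn_total",
                 label="Total dose of Gn (iu)"),
]

#: embryo quality and IVF outcome rows
TABLE3_VARIABLES = [
    VariableSpec("oocytes", "nonnormal", column="oocytes",
                 label="No. of oocytes retrieved"),
    VariableSpec("two_pn", "nonnormal", column="two_pn",
                 label="No. of 2PN fertilisations"),
    VariableSpec("two_pn_rate", "rate", numerator="two_pn",
                 denominator="oocytes", label="Rate of 2PN fertilisation"),
    VariableSpec("poly_rate", "rate", numerator="polypronucleate",
                 denominator="oocytes",
                 label="Rate of polypronucleate zygote"),
    VariableSpec("cleaved", "nonnormal", column="cleaved",
                 label="No. of cleavage from 2PN"),
    VariableSpec("cleavage_rate", "rate", numerator="cleaved",
                 denominator="two_pn", label="Cleavage rate from 2PN"),
    VariableSpec("available_rate", "rate", numerator="available_embryos",
                 denominator="cleaved", label="Availability of embryos"),
    VariableSpec("top_rate", "rate", numerator="top_quality_embryos",
                 denominator="available_embryos",
                 label="Top quality embryos"),
    VariableSpec("transferred", "nonnormal", column="embryos_transferred",
                 label="No. of embryos transferred"),
    VariableSpec("implantation_rate", "rate", numerator="implantations",
                 denominator="embryos_transferred",
                 label="Implantation rate"),
    VariableSpec("clinical_pregnancy", "rate",
                 numerator="clinical_pregnancy",
                 label="Clinical pregnancy rate"),
    VariableSpec("cumulative_pregnancy", "rate",
                 numerator="cumulative_pregnancy",
                 label="Cumulative pregnancy rate"),
]


def score_cohort(
    clinical: pd.DataFrame,
    surgical: pd.DataFrame,
    ratings: pd.DataFrame,
    lesion_score_includes_culdesac: bool = True,
) -> pd.DataFrame:
    """Per-patient r-AFS and EFI scores from the three input tables."""
    findings = findings_from_frame(surgical)
    fscores = ratings_from_frame(ratings)
    history = history_from_frame(clinical)
    findings = apply_ovary_presence(findings, fscores)
    rows = []
    for pid in clinical["patient_id"].astype(str):
        if pid not in findings or pid not in fscores:
            raise ValidationError(
                f"patient {pid} missing surgical or ratings records"
            )
        afs_res = afs_total_and_stage(
            findings[pid],
            lesion_score_includes_culdesac=lesion_score_includes_culdesac,
        )
        efi_res = compute_efi(history[pid], fscores[pid], afs_res)
        rows.append(
            {
                "patient_id": pid,
                "lesion_score": afs_res.lesion_score,
                "adhesion_score": afs_res.adhesion_score,
                "total_score": afs_res.total_score,
                "stage": afs_res.stage.value if afs_res.stage else "",
                "stage_numeric": afs_res.stage_numeric,
                "severe": int(afs_res.severe),
                "lf_left": efi_res.lf_left,
                "lf_right": efi_res.lf_right,
                "lf_total": efi_res.lf_total,
                "historical_points": efi_res.historical_points,
                "surgical_points": efi_res.surgical_points,
                "efi": efi_res.total,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class PipelineConfig:
    """Configuration for one end-to-end report run."""

    out_dir: Path
    seed: int = 0
    n_patients: int = 199
    simulation: Optional[SimulationConfig] = None
    efi_cutoff: Optional[int] = None  # None -> Youden-derived
    se_method: str = "hanley"
    bootstrap_reps: int = 2000
    lesion_score_includes_culdesac: bool = True
    input_dir: Optional[Path] = None  # read cohort CSVs instead of simulating


def _grouped_frame(scored: pd.DataFrame, outcomes: pd.DataFrame,
                   clinical: pd.DataFrame) -> pd.DataFrame:
    df = scored.merge(outcomes, on="patient_id").merge(
        clinical, on="patient_id"
    )
    return df


def run_report(config: PipelineConfig) -> dict:
    """Simulate (or load), score, analyse and write the report bundle.

    Emits per-patient scores, ROC JSON for both indices, Table-2- and
    Table-3-style comparison CSVs for both groupings, and a run log.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if config.input_dir is not None:
        from . import io as _io

        base = Path(config.input_dir)
        clinical = _io.read_clinical(base / "clinical.csv")
        surgical = _io.read_surgical(base / "surgical.csv")
        ratings = _io.read_ratings(base / "ratings.csv")
        outcomes = _io.read_outcomes(base / "outcomes.csv")
    else:
        sim_cfg = config.simulation or SimulationConfig(
            n_patients=config.n_patients, seed=config.seed
        )
        cohort = generate(sim_cfg)
        clinical, surgical, ratings, outcomes = (
            cohort.clinical,
            cohort.surgical,
            cohort.ratings,
            cohort.outcomes,
        )
        for name, df in (
            ("clinical", clinical),
            ("surgical", surgical),
            ("ratings", ratings),
            ("outcomes", outcomes),
            ("truth", cohort.truth),
        ):
            write_table(df, out / f"{name}.csv")
        with open(out / "truth_params.json", "w") as fh:
            json.dump(cohort.params, fh, indent=2, default=str)

    scored = score_cohort(
        clinical,
        surgical,
        ratings,
        lesion_score_includes_culdesac=config.lesion_score_includes_culdesac,
    )
    write_table(scored, out / "scores.csv")

    merged = _grouped_frame(scored, outcomes, clinical)
    outcome = merged["clinical_pregnancy"].astype(bool).to_numpy()

    roc_results = {}
    for index_name, column in (("efi", "efi"), ("rafs", "stage_numeric")):
        res = analyze(
            merged[column].to_numpy(dtype=float),
            outcome,
            se_method=config.se_method,
            bootstrap_reps=config.bootstrap_reps,
            seed=config.seed,
        )
        roc_results[index_name] = res
        with open(out / f"roc_{index_name}.json", "w") as fh:
            json.dump(res.to_dict(), fh, indent=2)

    cutoff = (
        config.efi_cutoff
        if config.efi_cutoff is not None
        else int(roc_results["efi"].youden_cutoff)
    )
    if cutoff not in set(merged["efi"].tolist()):
        raise ValidationError(
            f"cutoff override {cutoff} is not an attainable EFI value"
        )
    merged["efi_group"] = (merged["efi"] >= cutoff).map(
        {True: f"efi>={cutoff}", False: f"efi<={cutoff - 1}"}
    )
    merged["rafs_group"] = (merged["severe"] == 1).map(
        {True: "stage III-IV", False: "stage I-II"}
    )

    comparisons = {}
    for grouping, col, order in (
        ("efi", "efi_group", [f"efi<={cutoff - 1}", f"efi>={cutoff}"]),
        ("rafs", "rafs_group", ["stage I-II", "stage III-IV"]),
    ):
        table2 = build_report(merged, col, TABLE2_VARIABLES, group_order=order)
        table3 = build_report(merged, col, TABLE3_VARIABLES, group_order=order)
        write_table(table2, out / f"baseline_comparison_{grouping}.csv")
        write_table(table3, out / f"outcome_comparison_{grouping}.csv")
        comparisons[grouping] = {"baseline": table2, "outcomes": table3}

    log_lines = [
        f"endoscore {__version__}",
        f"seed {config.seed}",
        f"n_patients {len(merged)}",
        f"efi_cutoff {cutoff}",
        f"se_method {config.se_method}",
    ]
    (out / "run_log.txt").write_text("\n".join(log_lines) + "\n")
    logger.info("report bundle written to %s", out)
    return {
        "scores": scored,
        "roc": roc_results,
        "cutoff": cutoff,
        "comparisons": comparisons,
        "merged": merged,
    }
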