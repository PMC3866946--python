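"""Synthetic patient cohort generator.

Emits clinical history, surgical findings, function ratings and IVF
cycle outcomes with the marginal structure the analysis assumes:
age ~ Normal(32.0, 4.2), infertility duration log-normal fitted to
median 5.0 with IQR 3.0-7.0, and clinical pregnancy drawn from
logit P = beta0 + beta1 * EFI with (beta0, beta1) calibrated so that
the expected pregnancy rates of the EFI <= 5 and >= 6 groups hit the
configured targets (defaults 28.6% / 53.0%).

A single master seed drives independent substreams per output table, so
adding a column to one table never perturbs draws in another.  Every
generated patient round-trips through the r-AFS and EFI scorers.
"""
from __future__ import annotations

import math
from dataclasses import asdict, dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize as _opt
from scipy.special import expit, logit

from . import afs as _afs
from . import efi as _efi
from .afs import (
    Adhesion,
    AdhesionKind,
    Culdesac,
    Depth,
    Lesion,
    Organ,
    Side,
    Site,
    SurgicalFindings,
    ValidationError,
)
from .efi import ClinicalHistory, FunctionScores, SideRatings

__all__ = [
    "SimulationConfig",
    "SimulatedCohort",
    "generate",
    "calibrate_outcome_model",
]

_ENCLOSURES = (
    _afs.Enclosure.LT_ONE_THIRD,
    _afs.Enclosure.ONE_TO_TWO_THIRDS,
    _afs.Enclosure.GT_TWO_THIRDS,
)
_CULDESAC = (Culdesac.NONE, Culdesac.PARTIAL, Culdesac.COMPLETE)


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the synthetic cohort.

    Probabilities are per patient (or per side where noted).  ``beta0``
    and ``beta1`` may be fixed to bypass calibration, e.g. ``beta1=0``
    for a no-signal cohort.
    """

    n_patients: int = 199
    seed: int = 0
    # clinical history
    age_mean: float = 32.0
    age_sd: float = 4.2
    age_range: tuple[float, float] = (20.0, 45.0)
    infertility_median: float = 5.0
    infertility_iqr: tuple[float, float] = (3.0, 7.0)
    prior_pregnancy_prob: float = 0.32
    # surgical findings
    p_peritoneal_lesion: float = 0.85
    p_peritoneal_deep: float = 0.35
    peritoneal_size_log_mean: float = math.log(1.2)
    peritoneal_size_log_sd: float = 0.7
    p_ovarian_lesion: float = 0.40  # per side
    p_ovarian_deep: float = 0.75
    ovarian_size_log_mean: float = math.log(2.5)
    ovarian_size_log_sd: float = 0.6
    culdesac_probs: tuple[float, float, float] = (0.60, 0.25, 0.15)
    p_ovary_absent: float = 0.02  # per side; never both
    p_adhesion_ovary: float = 0.45  # per side
    p_adhesion_tube: float = 0.40  # per side
    p_dense: float = 0.50
    enclosure_probs: tuple[float, float, float] = (0.50, 0.30, 0.20)
    p_fimbria_enclosed: float = 0.25  # given a dense tubal adhesion
    # function ratings
    base_degrade_prob: float = 0.10
    rating_coupling: float = 0.55  # scales adhesion load into degradation
    # outcome model
    target_rate_low: float = 0.286
    target_rate_high: float = 0.530
    efi_cutoff: int = 6
    beta0: Optional[float] = None
    beta1: Optional[float] = None
    thaw_pregnancy_prob: float = 0.21
    lesion_score_includes_culdesac: bool = True

    def __post_init__(self) -> None:
        if self.n_patients < 2:
            raise ValidationError("need at least 2 patients")
        probs = {
            "prior_pregnancy_prob": self.prior_pregnancy_prob,
            "p_peritoneal_lesion": self.p_peritoneal_lesion,
            "p_peritoneal_deep": self.p_peritoneal_deep,
            "p_ovarian_lesion": self.p_ovarian_lesion,
            "p_ovarian_deep": self.p_ovarian_deep,
            "p_ovary_absent": self.p_ovary_absent,
            "p_adhesion_ovary": self.p_adhesion_ovary,
            "p_adhesion_tube": self.p_adhesion_tube,
            "p_dense": self.p_dense,
            "p_fimbria_enclosed": self.p_fimbria_enclosed,
            "base_degrade_prob": self.base_degrade_prob,
            "thaw_pregnancy_prob": self.thaw_pregnancy_prob,
            "target_rate_low": self.target_rate_low,
            "target_rate_high": self.target_rate_high,
        }
        for name, value in probs.items():
            if not 0.0 <= value <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1], got {value}")
        for name in ("culdesac_probs", "enclosure_probs"):
            v = getattr(self, name)
            if abs(sum(v) - 1.0) > 1e-9 or any(p < 0 for p in v):
                raise ValidationError(f"{name} must be a probability vector")
        if self.p_ovary_absent >= 0.5:
            raise ValidationError(
                "p_ovary_absent >= 0.5 would routinely remove both ovaries"
            )
        if (self.beta0 is None) != (self.beta1 is None):
            raise ValidationError("set both beta0 and beta1, or neither")

    @classmethod
    def from_mapping(cls, mapping: dict) -> "SimulationConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(mapping) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        coerced = {
            k: tuple(v) if isinstance(v, list) else v
            for k, v in mapping.items()
        }
        return cls(**coerced)


@dataclass
class SimulatedCohort:
    """Output tables plus the ground truth used to generate them."""

    clinical: pd.DataFrame
    surgical: pd.DataFrame
    ratings: pd.DataFrame
    outcomes: pd.DataFrame
    truth: pd.DataFrame
    params: dict


def _lognormal_fit_median_iqr(
    median: float, iqr: tuple[float, float]
) -> tuple[float, float]:
    """Least-squares fit of (mu, sigma) to three quantiles in log space.

    A log-normal cannot in general match an asymmetric (q1, median, q3)
    triple exactly; the fit spreads the discrepancy across all three.
    """
    z75 = 0.6744897501960817  # Phi^-1(0.75)
    lq1, lmed, lq3 = math.log(iqr[0]), math.log(median), math.log(iqr[1])
    mu = (lq1 + lmed + lq3) / 3.0
    sigma = (lq3 - lq1) / (2.0 * z75)
    return mu, sigma


def calibrate_outcome_model(
    target_rates: tuple[float, float],
    efi_values: Sequence[float],
    cutoff: int = 6,
    require_positive_effect: bool = False,
) -> tuple[float, float]:
    """Solve for (beta0, beta1) of logit P = beta0 + beta1 * EFI.

    Finds coefficients such that the *expected* pregnancy rate in the
    EFI < cutoff group equals ``target_rates[0]`` and in the >= cutoff
    group equals ``target_rates[1]``, on the supplied EFI distribution.
    Deterministic root finding; residuals are verified below 1e-6.
    """
    r_low, r_high = target_rates
    for r in (r_low, r_high):
        if not 0.0 < r < 1.0:
            raise ValidationError(f"target rate must be in (0, 1), got {r}")
    e = np.asarray(efi_values, dtype=float)
    low = e < cutoff
    if not low.any() or low.all():
        raise ValidationError("both EFI groups must be non-empty")
    if abs(r_low - r_high) < 1e-12:
        return float(logit(r_low)), 0.0

    def resid(beta: np.ndarray) -> list[float]:
        p = expit(beta[0] + beta[1] * e)
        return [p[low].mean() - r_low, p[~low].mean() - r_high]

    x0 = np.array([float(logit((r_low + r_high) / 2.0)), 0.0])
    sol = _opt.root(resid, x0, method="hybr")
    if max(abs(r) for r in resid(sol.x)) > 1e-8:
        raise ValidationError(
            "outcome-model calibration failed to converge for these targets"
        )
    beta0, beta1 = float(sol.x[0]), float(sol.x[1])
    if require_positive_effect and r_high != r_low and beta1 <= 0:
        raise ValidationError(
            "targets are non-monotone in EFI with beta1 constrained positive"
        )
    return beta0, beta1


def _draw_patient_surgery(
    cfg: SimulationConfig, rng: np.random.Generator
) -> SurgicalFindings:
    present = {Side.LEFT: True, Side.RIGHT: True}
    absent_l = rng.random() < cfg.p_ovary_absent
    absent_r = rng.random() < cfg.p_ovary_absent
    if absent_l and absent_r:
        absent_l = False  # never remove both ovaries
    present[Side.LEFT] = not absent_l
    present[Side.RIGHT] = not absent_r

    lesions: list[Lesion] = []
    if rng.random() < cfg.p_peritoneal_lesion:
        depth = (
            Depth.DEEP
            if rng.random() < cfg.p_peritoneal_deep
            else Depth.SUPERFICIAL
        )
        size = float(
            rng.lognormal(cfg.peritoneal_size_log_mean, cfg.peritoneal_size_log_sd)
        )
        lesions.append(Lesion(Site.PERITONEUM, depth, max(size, 0.1)))
    for side, site in (
        (Side.LEFT, Site.OVARY_LEFT),
        (Side.RIGHT, Site.OVARY_RIGHT),
    ):
        if not present[side]:
            rng.random(3)  # keep stream aligned across presence patterns
            continue
        if rng.random() < cfg.p_ovarian_lesion:
            depth = (
                Depth.DEEP
                if rng.random() < cfg.p_ovarian_deep
                else Depth.SUPERFICIAL
            )
            size = float(
                rng.lognormal(cfg.ovarian_size_log_mean, cfg.ovarian_size_log_sd)
            )
            lesions.append(Lesion(site, depth, max(size, 0.1)))
        else:
            rng.random(2)

    culdesac = _CULDESAC[rng.choice(3, p=cfg.culdesac_probs)]

    adhesions: list[Adhesion] = []
    for organ, p_organ in ((Organ.OVARY, cfg.p_adhesion_ovary),
                           (Organ.TUBE, cfg.p_adhesion_tube)):
        for side in (Side.LEFT, Side.RIGHT):
            if organ is Organ.OVARY and not present[side]:
                rng.random(4)
                continue
            if rng.random() < p_organ:
                dense = rng.random() < cfg.p_dense
                kind = AdhesionKind.DENSE if dense else AdhesionKind.FILMY
                enclosure = _ENCLOSURES[rng.choice(3, p=cfg.enclosure_probs)]
                fimbria = bool(
                    organ is Organ.TUBE
                    and dense
                    and rng.random() < cfg.p_fimbria_enclosed
                )
                adhesions.append(
                    Adhesion(organ, side, kind, enclosure, fimbria)
                )
            else:
                rng.random(3)

    return SurgicalFindings(
        lesions=lesions,
        adhesions=adhesions,
        culdesac=culdesac,
        ovary_present=present,
    )


def _adhesion_load(findings: SurgicalFindings) -> dict[tuple[Organ, Side], float]:
    load: dict[tuple[Organ, Side], float] = {}
    for adh in findings.adhesions:
        key = (adh.organ, adh.side)
        load[key] = load.get(key, 0.0) + _afs.adhesion_points(adh) / 16.0
    return load


def _draw_ratings(
    cfg: SimulationConfig,
    findings: SurgicalFindings,
    rng: np.random.Generator,
) -> FunctionScores:
    load = _adhesion_load(findings)
    fimbria_enclosed = {
        adh.side
        for adh in findings.adhesions
        if adh.organ is Organ.TUBE and adh.fimbria_completely_enclosed
    }

    def rating(organ_load: float, extra: float = 0.0) -> int:
        p = min(
            cfg.base_degrade_prob + cfg.rating_coupling * organ_load + extra,
            0.95,
        )
        return int(4 - rng.binomial(4, p))

    def one_side(side: Side) -> SideRatings:
        tube_load = load.get((Organ.TUBE, side), 0.0)
        ovary_load = load.get((Organ.OVARY, side), 0.0)
        tube = rating(tube_load)
        fimbria = rating(
            tube_load, extra=0.5 if side in fimbria_enclosed else 0.0
        )
        if findings.ovary_present[side]:
            ovary = rating(ovary_load)
        else:
            rng.binomial(4, 0.5)  # burn the draw to keep streams aligned
            ovary = 0
        return SideRatings(tube=tube, fimbria=fimbria, ovary=ovary)

    return FunctionScores(
        left=one_side(Side.LEFT),
        right=one_side(Side.RIGHT),
        ovary_present_left=findings.ovary_present[Side.LEFT],
        ovary_present_right=findings.ovary_present[Side.RIGHT],
    )


def _surgical_rows(patient_id: str, f: SurgicalFindings) -> list[dict]:
    rows = []
    for les in f.lesions:
        side = ""
        site = les.site.value
        if les.site is Site.OVARY_LEFT:
            site, side = "ovary", "left"
        elif les.site is Site.OVARY_RIGHT:
            site, side = "ovary", "right"
        rows.append(
            {
                "patient_id": patient_id,
                "record_type": "lesion",
                "site_or_organ": site,
                "side": side,
                "depth_or_kind": les.depth.value,
                "size_cm": round(les.size_cm, 3),
                "enclosure": "",
                "fimbria_enclosed": "",
            }
        )
    for adh in f.adhesions:
        rows.append(
            {
                "patient_id": patient_id,
                "record_type": "adhesion",
                "site_or_organ": adh.organ.value,
                "side": adh.side.value,
                "depth_or_kind": adh.kind.value,
                "size_cm": "",
                "enclosure": adh.enclosure.value,
                "fimbria_enclosed": int(adh.fimbria_completely_enclosed),
            }
        )
    rows.append(
        {
            "patient_id": patient_id,
            "record_type": "culdesac",
            "site_or_organ": "",
            "side": "",
            "depth_or_kind": f.culdesac.value,
            "size_cm": "",
            "enclosure": "",
            "fimbria_enclosed": "",
        }
    )
    return rows


def generate(config: SimulationConfig) -> SimulatedCohort:
    """Generate a full synthetic cohort, deterministically from the seed."""
    cfg = config
    master = np.random.SeedSequence(cfg.seed)
    rng_clin, rng_surg, rng_rate, rng_out = (
        np.random.default_rng(s) for s in master.spawn(4)
    )
    n = cfg.n_patients
    ids = [f"P{i + 1:05d}" for i in range(n)]

    # clinical history; rounded to the emitted CSV precision up front so
    # the persisted tables and the internal truth scores agree exactly
    ages = np.round(
        np.clip(
            rng_clin.normal(cfg.age_mean, cfg.age_sd, size=n), *cfg.age_range
        ),
        1,
    )
    mu, sigma = _lognormal_fit_median_iqr(
        cfg.infertility_median, cfg.infertility_iqr
    )
    infertility = np.round(rng_clin.lognormal(mu, sigma, size=n), 1)
    prior_preg = rng_clin.random(n) < cfg.prior_pregnancy_prob

    # surgery + ratings, scored through the real pipeline
    surgical_rows: list[dict] = []
    ratings_rows: list[dict] = []
    efi_vals = np.empty(n, dtype=int)
    afs_totals = np.empty(n, dtype=int)
    afs_lesions = np.empty(n, dtype=int)
    stages = np.empty(n, dtype=int)
    lf_totals = np.empty(n, dtype=int)
    for i, pid in enumerate(ids):
        findings = _draw_patient_surgery(cfg, rng_surg)
        ratings = _draw_ratings(cfg, findings, rng_rate)
        findings.function_ratings = ratings
        result = _afs.afs_total_and_stage(
            findings,
            lesion_score_includes_culdesac=cfg.lesion_score_includes_culdesac,
        )
        history = ClinicalHistory(
            age_years=float(ages[i]),
            infertility_duration_years=float(infertility[i]),
            prior_pregnancy=bool(prior_preg[i]),
        )
        efi_res = _efi.compute_efi(history, ratings, result)
        efi_vals[i] = efi_res.total
        afs_totals[i] = result.total_score
        afs_lesions[i] = result.lesion_score
        stages[i] = result.stage_numeric
        lf_totals[i] = efi_res.lf_total
        surgical_rows.extend(_surgical_rows(pid, findings))
        for side_name, side_r, present in (
            ("left", ratings.left, ratings.ovary_present_left),
            ("right", ratings.right, ratings.ovary_present_right),
        ):
            ratings_rows.append(
                {
                    "patient_id": pid,
                    "side": side_name,
                    "tube": side_r.tube,
                    "fimbria": side_r.fimbria,
                    "ovary": side_r.ovary,
                    "ovary_present": int(present),
                }
            )

    # outcome model
    if cfg.beta0 is not None and cfg.beta1 is not None:
        beta0, beta1 = float(cfg.beta0), float(cfg.beta1)
    elif cfg.beta0 is None and cfg.beta1 is None:
        beta0, beta1 = calibrate_outcome_model(
            (cfg.target_rate_low, cfg.target_rate_high),
            efi_vals,
            cutoff=cfg.efi_cutoff,
        )
    else:
        raise ValidationError("set both beta0 and beta1, or neither")
    p_preg = expit(beta0 + beta1 * efi_vals)
    pregnant = rng_out.random(n) < p_preg
    cumulative = pregnant | (rng_out.random(n) < cfg.thaw_pregnancy_prob)

    # IVF cycle counts (statistical stand-ins, weakly coupled to EFI)
    afc = np.maximum(
        1, rng_out.poisson(np.clip(8.5 + 0.5 * (efi_vals - 5), 2.0, None))
    )
    mean_oo = 0.85 * afc
    oocytes = rng_out.negative_binomial(8, 8.0 / (8.0 + mean_oo))
    two_pn = rng_out.binomial(oocytes, 0.59)
    poly = rng_out.binomial(oocytes - two_pn, 0.084 / 0.41)
    cleaved = rng_out.binomial(two_pn, 0.845)
    available = rng_out.binomial(cleaved, 0.71)
    top_quality = rng_out.binomial(available, 0.15)
    transferred = np.minimum(cleaved, np.where(ages >= 35.0, 3, 2))
    # a pregnancy implies at least one transferred embryo
    fix = pregnant & (transferred == 0)
    two_pn[fix] = np.maximum(two_pn[fix], 1)
    cleaved[fix] = np.maximum(cleaved[fix], 1)
    oocytes[fix] = np.maximum(oocytes[fix], two_pn[fix] + poly[fix])
    transferred[fix] = 1
    implantations = np.where(
        pregnant,
        1 + rng_out.binomial(np.maximum(transferred - 1, 0), 0.20),
        0,
    )

    bmi = rng_out.lognormal(math.log(20.2), 0.07, size=n)
    bfsh = rng_out.lognormal(math.log(8.1), 0.25, size=n)
    blh = rng_out.lognormal(math.log(3.8), 0.35, size=n)
    e2 = rng_out.lognormal(math.log(42.0), 0.45, size=n)
    e2_hcg = rng_out.lognormal(
        math.log(1900.0) + 0.04 * (efi_vals - 5.5), 0.55, size=n
    )
    gn_start = rng_out.choice([150.0, 187.5, 225.0, 300.0], size=n,
                              p=[0.25, 0.15, 0.40, 0.20])
    stim_days = 9 + rng_out.poisson(1.3, size=n)
    gn_total = np.clip(
        rng_out.normal(2280.0 - 45.0 * (efi_vals - 5.5), 900.0, size=n),
        600.0,
        None,
    )

    clinical = pd.DataFrame(
        {
            "patient_id": ids,
            "age_years": np.round(ages, 1),
            "infertility_years": np.round(infertility, 1),
            "prior_pregnancy": prior_preg.astype(int),
        }
    )
    surgical = pd.DataFrame(surgical_rows)
    ratings_df = pd.DataFrame(ratings_rows)
    outcomes = pd.DataFrame(
        {
            "patient_id": ids,
            "afc": afc,
            "oocytes": oocytes,
            "two_pn": two_pn,
            "polypronucleate": poly,
            "cleaved": cleaved,
            "available_embryos": available,
            "top_quality_embryos": top_quality,
            "embryos_transferred": transferred,
            "implantations": implantations,
            "clinical_pregnancy": pregnant.astype(int),
            "cumulative_pregnancy": cumulative.astype(int),
            "bmi": np.round(bmi, 1),
            "bfsh": np.round(bfsh, 1),
            "blh": np.round(blh, 1),
            "e2": np.round(e2, 1),
            "e2_hcg": np.round(e2_hcg, 1),
            "gn_start": gn_start,
            "gn_total": np.round(gn_total, 1),
            "stim_days": stim_days,
        }
    )
    truth = pd.DataFrame(
        {
            "patient_id": ids,
            "efi": efi_vals,
            "afs_total": afs_totals,
            "afs_lesion": afs_lesions,
            "stage_numeric": stages,
            "lf_total": lf_totals,
            "p_pregnancy": p_preg,
        }
    )
    params = {
        "beta0": beta0,
        "beta1": beta1,
        "seed": cfg.seed,
        "config": asdict(cfg),
    }
    return SimulatedCohort(
        clinical=clinical,
        surgical=surgical,
        ratings=ratings_df,
        outcomes=outcomes,
        truth=truth,
        params=params,
    )
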