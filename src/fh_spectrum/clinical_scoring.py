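"""Lipid-derived quantities, study eligibility and Dutch Lipid Clinic Network scoring.

The DLCN score is the sum over five evidence groups (family history, clinical
history, physical examination, LDL-C band and DNA confirmation) of the single
highest-scoring item within each group.  Score bands map to the four clinical
categories: unlikely (<3), possible (3-5), probable (6-8) and definite (>8);
"potential FH" pools probable and definite.

The point table and the category cut-offs live in a versioned JSON data file
(``data/dlcn_points.json``) so that criterion revisions are swappable without
code changes.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass
from importlib import resources
from typing import Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

FRIEDEWALD_TG_MAX = 4.5
"""Upper triglyceride bound (mmol/L) for validity of the Friedewald equation."""


class InvalidLipidError(ValueError):
    """Raised when lipid inputs fall outside the validity of a formula."""


def _load_points() -> dict:
    with resources.files("fh_spectrum.data").joinpath("dlcn_points.json").open() as fh:
        return json.load(fh)


DLCN_POINTS: dict = _load_points()


def friedewald_ldl(tc: float, hdl: float, tg: float) -> float:
    """Estimate LDL-C (mmol/L) as TC - HDL-C - TG/2.2.

    Valid only for TG <= 4.5 mmol/L; above that the TG/2.2 proxy for VLDL
    cholesterol breaks down and an :class:`InvalidLipidError` is raised.
    TG may be 0 as a limiting case.
    """
    if tc <= 0 or hdl <= 0 or tg < 0:
        raise InvalidLipidError(
            f"lipid inputs must be positive (tc={tc}, hdl={hdl}, tg={tg})"
        )
    if tg > FRIEDEWALD_TG_MAX:
        raise InvalidLipidError(
            f"Friedewald equation invalid for tg={tg} > {FRIEDEWALD_TG_MAX} mmol/L"
        )
    return tc - hdl - tg / 2.2


class Sex(str, enum.Enum):
    M = "M"
    F = "F"


class SubjectRecord(BaseModel):
    """One screened individual: demographics, lipid panel and history flags.

    Lipids are mmol/L.  ``ldl_baseline`` is the pre-treatment LDL-C; when
    absent it is derived from TC/HDL/TG by the Friedewald equation.
    """

    subject_id: str
    age: float = Field(ge=0)
    sex: Sex = Sex.F
    tc: Optional[float] = Field(default=None, gt=0)
    tg: Optional[float] = Field(default=None, ge=0)
    hdl: Optional[float] = Field(default=None, gt=0)
    ldl_baseline: Optional[float] = Field(default=None, gt=0)
    tendon_xanthomata: bool = False
    corneal_arcus: bool = False
    corneal_arcus_age: Optional[float] = Field(default=None, ge=0)
    personal_pcad: bool = False
    personal_premature_cerebral_or_peripheral: bool = False
    family_first_degree_premature_cad_or_high_ldl: bool = False
    family_first_degree_xanthoma_arcus_or_child_high_ldl: bool = False
    secondary_cause: bool = False
    pregnant: bool = False
    dna_pv_confirmed: bool = False

    @model_validator(mode="after")
    def _check_arcus_age(self) -> "SubjectRecord":
        if self.corneal_arcus_age is not None and not self.corneal_arcus:
            raise ValueError(
                "corneal_arcus_age given for a subject without corneal arcus"
            )
        return self

    def ldl(self) -> float:
        """Baseline LDL-C, derived via Friedewald when not measured directly."""
        if self.ldl_baseline is not None:
            return self.ldl_baseline
        if self.tc is None or self.hdl is None or self.tg is None:
            raise InvalidLipidError(
                f"subject {self.subject_id}: LDL-C missing and not derivable "
                "(needs tc, hdl and tg)"
            )
        return friedewald_ldl(self.tc, self.hdl, self.tg)


class DlcnCategory(str, enum.Enum):
    UNLIKELY = "unlikely"
    POSSIBLE = "possible"
    PROBABLE = "probable"
    DEFINITE = "definite"


@dataclass(frozen=True)
class EligibilityResult:
    included: bool
    reason: Optional[str] = None  # first failing rule when excluded


@dataclass(frozen=True)
class DlcnResult:
    score: int
    group_points: dict[str, int]
    category: DlcnCategory
    potential: bool


# Exclusion rules in the order their reasons are reported.
_MIN_AGE = 18.0
_LDL_CUTOFF_WITH_PCAD = 4.0
_LDL_CUTOFF_WITHOUT_PCAD = 4.9


def eligibility(record: SubjectRecord) -> EligibilityResult:
    """Apply the screening inclusion rules.

    Adults (>=18 y) are included unless they have a secondary cause of
    hypercholesterolaemia or are pregnant, and only when baseline LDL-C meets
    the PCAD-conditional cut-off: >=4.0 mmol/L with personal premature CAD,
    >=4.9 mmol/L without.  The reported reason is the first failing rule in
    that order.
    """
    if record.age < _MIN_AGE:
        return EligibilityResult(False, "age")
    if record.secondary_cause:
        return EligibilityResult(False, "secondary_cause")
    if record.pregnant:
        return EligibilityResult(False, "pregnant")
    cutoff = _LDL_CUTOFF_WITH_PCAD if record.personal_pcad else _LDL_CUTOFF_WITHOUT_PCAD
    if record.ldl() < cutoff:
        return EligibilityResult(False, "ldl_cutoff")
    return EligibilityResult(True)


def _ldl_band_points(ldl: float, points: dict = DLCN_POINTS) -> int:
    for band in points["groups"]["ldl_bands"]:
        upper = band["upper"]
        if ldl >= band["lower"] and (upper is None or ldl < upper):
            return band["points"]
    return 0


def dlcn_score(
    record: SubjectRecord,
    *,
    dna_points_enabled: bool = False,
    points: dict = DLCN_POINTS,
) -> DlcnResult:
    """Score a subject on the DLCN point table (maximum item per group).

    The DNA group is disabled by default so that subjects are scored on
    clinical grounds before any sequencing result exists; enabling it adds
    8 points for a confirmed pathogenic variant.  Corneal arcus counts only
    when premature (< 45 y at onset/observation); when no onset age was
    recorded the subject's current age is used.
    """
    g = points["groups"]
    fam = g["family_history"]
    family = (
        fam["first_degree_xanthoma_arcus_or_child_high_ldl"]
        if record.family_first_degree_xanthoma_arcus_or_child_high_ldl
        else fam["first_degree_premature_cad_or_high_ldl"]
        if record.family_first_degree_premature_cad_or_high_ldl
        else 0
    )
    clin = g["clinical_history"]
    clinical = (
        clin["personal_premature_cad"]
        if record.personal_pcad
        else clin["personal_premature_cerebral_or_peripheral"]
        if record.personal_premature_cerebral_or_peripheral
        else 0
    )
    arcus_age = (
        record.corneal_arcus_age if record.corneal_arcus_age is not None else record.age
    )
    phys = g["physical_exam"]
    physical = (
        phys["tendon_xanthomata"]
        if record.tendon_xanthomata
        else phys["premature_corneal_arcus"]
        if record.corneal_arcus and arcus_age < points["premature_corneal_arcus_age_max"]
        else 0
    )
    ldl_points = _ldl_band_points(record.ldl(), points)
    dna = (
        g["dna"]["pathogenic_variant"]
        if dna_points_enabled and record.dna_pv_confirmed
        else 0
    )
    group_points = {
        "family_history": family,
        "clinical_history": clinical,
        "physical_exam": physical,
        "ldl": ldl_points,
        "dna": dna,
    }
    score = sum(group_points.values())
    category, potential = dlcn_category(score, cutoffs=points["categories"])
    return DlcnResult(score, group_points, category, potential)


def dlcn_category(
    score: int, cutoffs: dict | None = None
) -> tuple[DlcnCategory, bool]:
    """Map a DLCN score to its category and the pooled "potential FH" flag.

    Definite >8, probable 6-8, possible 3-5, unlikely <3; potential pools
    probable and definite.
    """
    if score < 0:
        raise ValueError(f"DLCN score must be non-negative, got {score}")
    c = cutoffs or DLCN_POINTS["categories"]
    if score >= c["definite_min"]:
        cat = DlcnCategory.DEFINITE
    elif score >= c["probable_min"]:
        cat = DlcnCategory.PROBABLE
    elif score >= c["possible_min"]:
        cat = DlcnCategory.POSSIBLE
    else:
        cat = DlcnCategory.UNLIKELY
    return cat, cat in (DlcnCategory.PROBABLE, DlcnCategory.DEFINITE)


# ---------------------------------------------------------------------------
# Vectorised cohort-level scoring used by the pipeline.

def score_cohort(
    subjects: pd.DataFrame,
    *,
    dna_points_enabled: bool = False,
    points: dict = DLCN_POINTS,
) -> pd.DataFrame:
    """Eligibility + DLCN scoring over a subject table.

    Expects the documented subject-table columns
    (``synthetic_cohort.SUBJECT_COLUMNS``).
    Returns a copy with ``ldl``, ``eligible``, ``exclusion_reason``,
    ``dlcn_score``, ``dlcn_category`` and ``potential`` columns.  Rows that
    fail eligibility are still scored (score reported for audit) but flagged.
    """
    df = subjects.copy()
    n = len(df)
    tg = df["tg"].to_numpy(float)
    if "ldl_baseline" in df.columns:
        ldl = df["ldl_baseline"].to_numpy(float)
    else:
        ldl = np.full(n, np.nan)
    derived = df["tc"].to_numpy(float) - df["hdl"].to_numpy(float) - tg / 2.2
    ldl = np.where(np.isnan(ldl), derived, ldl)
    if np.isnan(ldl).any():
        bad = df.loc[np.isnan(ldl), "subject_id"].tolist()[:5]
        raise InvalidLipidError(f"LDL-C missing and not derivable for subjects {bad}")
    df["ldl"] = ldl

    cutoff = np.where(
        df["personal_pcad"].to_numpy(bool), _LDL_CUTOFF_WITH_PCAD, _LDL_CUTOFF_WITHOUT_PCAD
    )
    reason = np.select(
        [
            df["age"].to_numpy(float) < _MIN_AGE,
            df["secondary_cause"].to_numpy(bool),
            df["pregnant"].to_numpy(bool),
            ldl < cutoff,
        ],
        ["age", "secondary_cause", "pregnant", "ldl_cutoff"],
        default="",
    )
    df["eligible"] = reason == ""
    df["exclusion_reason"] = reason

    g = points["groups"]
    family = np.select(
        [
            df["family_first_degree_xanthoma_arcus_or_child_high_ldl"].to_numpy(bool),
            df["family_first_degree_premature_cad_or_high_ldl"].to_numpy(bool),
        ],
        [
            g["family_history"]["first_degree_xanthoma_arcus_or_child_high_ldl"],
            g["family_history"]["first_degree_premature_cad_or_high_ldl"],
        ],
        default=0,
    )
    clinical = np.select(
        [
            df["personal_pcad"].to_numpy(bool),
            df["personal_premature_cerebral_or_peripheral"].to_numpy(bool),
        ],
        [
            g["clinical_history"]["personal_premature_cad"],
            g["clinical_history"]["personal_premature_cerebral_or_peripheral"],
        ],
        default=0,
    )
    if "corneal_arcus_age" in df.columns:
        arcus_age = df["corneal_arcus_age"].to_numpy(float)
        arcus_age = np.where(np.isnan(arcus_age), df["age"].to_numpy(float), arcus_age)
    else:
        arcus_age = df["age"].to_numpy(float)
    premature_arcus = df["corneal_arcus"].to_numpy(bool) & (
        arcus_age < points["premature_corneal_arcus_age_max"]
    )
    physical = np.select(
        [df["tendon_xanthomata"].to_numpy(bool), premature_arcus],
        [g["physical_exam"]["tendon_xanthomata"], g["physical_exam"]["premature_corneal_arcus"]],
        default=0,
    )
    bands = g["ldl_bands"]
    conds = [
        (ldl >= b["lower"]) & (ldl < (np.inf if b["upper"] is None else b["upper"]))
        for b in bands
    ]
    ldl_points = np.select(conds, [b["points"] for b in bands], default=0)
    if dna_points_enabled and "dna_pv_confirmed" in df.columns:
        dna = np.where(
            df["dna_pv_confirmed"].to_numpy(bool), g["dna"]["pathogenic_variant"], 0
        )
    else:
        dna = np.zeros(n, dtype=int)

    score = family + clinical + physical + ldl_points + dna
    c = points["categories"]
    category = np.select(
        [score >= c["definite_min"], score >= c["probable_min"], score >= c["possible_min"]],
        [DlcnCategory.DEFINITE.value, DlcnCategory.PROBABLE.value, DlcnCategory.POSSIBLE.value],
        default=DlcnCategory.UNLIKELY.value,
    )
    df["dlcn_score"] = score.astype(int)
    df["dlcn_category"] = category
    df["potential"] = np.isin(
        category, [DlcnCategory.PROBABLE.value, DlcnCategory.DEFINITE.value]
    )
    return df
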