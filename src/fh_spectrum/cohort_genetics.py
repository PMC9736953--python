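"""Genotype profiles, detection rates, prevalence and the variant spectrum.

Conventions fixed here and used for every reported number:

* Percentages are rounded half-up to one decimal.
* "1:N" prevalence ratios round N to the nearest integer with exact halves
  rounded down (e.g. 5130/12 = 427.5 reports 1:427).
* A subject is PV-positive when carrying at least one pathogenic or
  likely-pathogenic variant in a counted gene.  By default the counted genes
  are the dominant ones (LDLR, APOB, PCSK9): LDLRAP1 is autosomal recessive,
  so its heterozygotes are labelled ``LDLRAP1_het`` but not counted as
  genetically confirmed; ``count_recessive_het=True`` includes them.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from fractions import Fraction
from typing import Iterable, Optional

import pandas as pd

from .acmg_engine import Tier
from .clinical_scoring import DlcnCategory

log = logging.getLogger(__name__)

DOMINANT_GENES = ("LDLR", "APOB", "PCSK9")
RECESSIVE_GENES = ("LDLRAP1",)

DOUBLE_LABELS = {
    frozenset({"LDLR", "APOB"}): "LDLR+APOB_double",
    frozenset({"LDLR", "PCSK9"}): "LDLR+PCSK9_double",
    frozenset({"APOB", "PCSK9"}): "APOB+PCSK9_double",
}

GENOTYPE_LABELS = (
    "LDLR_het",
    "APOB_het",
    "PCSK9_het",
    "LDLRAP1_het",
    "LDLR+APOB_double",
    "LDLR+PCSK9_double",
    "APOB+PCSK9_double",
    "other_combination",
    "none",
)


def percent(numerator: int, denominator: int) -> float:
    """100*num/den rounded half-up to one decimal (exact rational arithmetic)."""
    if denominator == 0:
        raise ZeroDivisionError("percent undefined for zero denominator")
    value = Decimal(100 * numerator) / Decimal(denominator)
    return float(value.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def ratio_string(numerator: int, denominator: int) -> str:
    """"1:N" with N = den/num rounded to nearest, exact halves down.

    Halves-down is the only rounding consistent with reporting 5130/12
    (=427.5) as 1:427 while 5130/82 (=62.6) is 1:63.  A zero numerator has
    no finite ratio and reports the sentinel "1:inf".
    """
    if numerator == 0:
        return "1:inf"
    n = math.ceil(Fraction(denominator, numerator) - Fraction(1, 2))
    return f"1:{n}"


@dataclass(frozen=True)
class PrevalenceResult:
    numerator: int
    denominator: int
    percent: float
    ratio: str

    def __str__(self) -> str:
        return f"{self.percent}% ({self.numerator}/{self.denominator}, {self.ratio})"


def prevalence(numerator: int, n_screened: int) -> PrevalenceResult:
    """Prevalence of a condition among ``n_screened`` individuals."""
    if n_screened <= 0:
        raise ValueError("n_screened must be positive")
    if not 0 <= numerator <= n_screened:
        raise ValueError(f"numerator {numerator} outside [0, {n_screened}]")
    return PrevalenceResult(
        numerator, n_screened, percent(numerator, n_screened), ratio_string(numerator, n_screened)
    )


@dataclass(frozen=True)
class GenotypeProfile:
    subject_id: str
    label: str  # one of GENOTYPE_LABELS
    pv_positive: bool


def genotype_profile(
    subject_id: str,
    classified_calls: pd.DataFrame,
    *,
    count_recessive_het: bool = False,
) -> GenotypeProfile:
    """Label one subject from their classified, retained calls.

    ``classified_calls`` needs ``gene`` and ``is_pv`` columns (rows for this
    subject only).  Subjects with two PV in the same gene keep that gene's
    heterozygote label (logged; the underlying study reported none).
    """
    pv = classified_calls.loc[classified_calls["is_pv"].astype(bool)]
    counted = set(DOMINANT_GENES) | (set(RECESSIVE_GENES) if count_recessive_het else set())
    pv_genes = frozenset(pv["gene"]) & counted
    if not pv_genes:
        if set(pv["gene"]) & set(RECESSIVE_GENES):
            return GenotypeProfile(subject_id, "LDLRAP1_het", count_recessive_het)
        return GenotypeProfile(subject_id, "none", False)
    if len(pv_genes) == 1:
        gene = next(iter(pv_genes))
        if (pv["gene"] == gene).sum() > 1:
            log.info("subject %s carries >1 PV in %s; labelled %s_het", subject_id, gene, gene)
        return GenotypeProfile(subject_id, f"{gene}_het", True)
    label = DOUBLE_LABELS.get(pv_genes, "other_combination")
    return GenotypeProfile(subject_id, label, True)


def genotype_profiles(
    classified_calls: pd.DataFrame,
    subject_ids: Optional[Iterable[str]] = None,
    *,
    count_recessive_het: bool = False,
) -> pd.DataFrame:
    """Per-subject genotype profiles over a classified call table.

    When ``subject_ids`` is given, subjects with no calls appear with label
    ``none``; otherwise only subjects present in the call table are profiled.
    """
    profiles = {
        sid: genotype_profile(sid, grp, count_recessive_het=count_recessive_het)
        for sid, grp in classified_calls.groupby("subject_id", sort=True)
    }
    if subject_ids is not None:
        for sid in subject_ids:
            profiles.setdefault(sid, GenotypeProfile(sid, "none", False))
    return pd.DataFrame(
        [
            {"subject_id": p.subject_id, "label": p.label, "pv_positive": p.pv_positive}
            for p in sorted(profiles.values(), key=lambda p: p.subject_id)
        ],
        columns=["subject_id", "label", "pv_positive"],
    )


_DETECTION_GROUPS = {
    "all_fh": (DlcnCategory.POSSIBLE, DlcnCategory.PROBABLE, DlcnCategory.DEFINITE),
    "potential": (DlcnCategory.PROBABLE, DlcnCategory.DEFINITE),
    "possible": (DlcnCategory.POSSIBLE,),
}


def detection_rates(profiles: pd.DataFrame, categories: pd.DataFrame) -> pd.DataFrame:
    """Genetic-confirmation rate per clinical group.

    ``categories`` maps subject_id to dlcn_category; every profiled subject
    must have one.  Rows: all clinically diagnosed FH, potential only
    (probable + definite) and possible only.  An empty group reports NaN
    percent, never 0.
    """
    merged = profiles.merge(categories[["subject_id", "dlcn_category"]], on="subject_id")
    if len(merged) < len(profiles):
        missing = set(profiles["subject_id"]) - set(categories["subject_id"])
        raise ValueError(f"profiled subjects without a DLCN category: {sorted(missing)[:5]}")
    rows = []
    for group, cats in _DETECTION_GROUPS.items():
        values = [c.value for c in cats]
        sub = merged.loc[merged["dlcn_category"].isin(values)]
        num = int(sub["pv_positive"].sum())
        den = int(len(sub))
        rows.append(
            {
                "group": group,
                "numerator": num,
                "denominator": den,
                "percent": percent(num, den) if den else float("nan"),
            }
        )
    return pd.DataFrame(rows)


def spectrum(classified_catalogue: pd.DataFrame, tier_col: str = "tier") -> pd.DataFrame:
    """Per-gene distribution of distinct PV and VUS variants.

    Variants are distinct (gene, hgvs_c) pairs; duplicated rows collapse.
    PV pools pathogenic and likely-pathogenic; percents are of the column
    totals.
    """
    distinct = classified_catalogue.drop_duplicates(subset=["gene", "hgvs_c"])
    pv_mask = distinct[tier_col].isin([Tier.PATHOGENIC.value, Tier.LIKELY_PATHOGENIC.value])
    vus_mask = distinct[tier_col] == Tier.VUS.value
    total_pv = int(pv_mask.sum())
    total_vus = int(vus_mask.sum())
    rows = []
    for gene in sorted(set(distinct["gene"]), key=list(distinct["gene"]).index):
        n_pv = int((pv_mask & (distinct["gene"] == gene)).sum())
        n_vus = int((vus_mask & (distinct["gene"] == gene)).sum())
        rows.append(
            {
                "gene": gene,
                "n_pv": n_pv,
                "pv_percent": percent(n_pv, total_pv) if total_pv else float("nan"),
                "n_vus": n_vus,
                "vus_percent": percent(n_vus, total_vus) if total_vus else float("nan"),
            }
        )
    return pd.DataFrame(rows)


def genotype_frequencies(profiles: pd.DataFrame) -> pd.DataFrame:
    """Counts and percents per genotype label among PV-positive subjects."""
    positive = profiles.loc[profiles["pv_positive"].astype(bool)]
    total = len(positive)
    if total == 0:
        log.warning("no PV-positive subjects; genotype-frequency table is empty")
        return pd.DataFrame(columns=["label", "n", "percent"])
    rows = []
    counts = positive["label"].value_counts()
    for label in GENOTYPE_LABELS:
        n = int(counts.get(label, 0))
        if n:
            rows.append({"label": label, "n": n, "percent": percent(n, total)})
    return pd.DataFrame(rows)


@dataclass
class CohortSummary:
    """Cohort-level outputs of one pipeline run."""

    n_screened: int
    n_by_category: dict[str, int]
    detection: pd.DataFrame
    prevalence: pd.DataFrame  # per clinical group: clinical + genetic prevalence
    genotype_freq: pd.DataFrame
    spectrum: pd.DataFrame
    carrier_prevalence: PrevalenceResult = None  # PV carriers among all screened
    stage_counts: dict[str, int] = field(default_factory=dict)


def prevalence_table(
    detection: pd.DataFrame, n_screened: int
) -> pd.DataFrame:
    """Clinical and genetically confirmed prevalence per clinical group,
    with numerators taken from the detection table."""
    rows = []
    for _, row in detection.iterrows():
        clin = prevalence(int(row["denominator"]), n_screened)
        gen = prevalence(int(row["numerator"]), n_screened)
        rows.append(
            {
                "group": row["group"],
                "n_clinical": clin.numerator,
                "clinical_percent": clin.percent,
                "clinical_ratio": clin.ratio,
                "n_genetic": gen.numerator,
                "genetic_percent": gen.percent,
                "genetic_ratio": gen.ratio,
            }
        )
    return pd.DataFrame(rows)
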