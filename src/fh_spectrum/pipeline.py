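"""End-to-end orchestration: eligibility -> DLCN -> filter -> classify -> report.

The pipeline starts from called variants (VCF or TSV) plus a subject table;
sequencing and variant calling are upstream of it.  Stage counts are logged
and returned so that conservation (subjects in = excluded + scored; calls in
= retained + common-excluded) is auditable.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml
from pydantic import BaseModel, Field, model_validator

from . import cohort_genetics
from .acmg_engine import classify_catalogue
from .clinical_scoring import DLCN_POINTS, DlcnCategory, score_cohort
from .cohort_genetics import (
    CohortSummary,
    genotype_frequencies,
    genotype_profiles,
    prevalence,
    prevalence_table,
    spectrum,
)
from .variant_filtering import maf_filter, read_variants

log = logging.getLogger(__name__)


class RunConfig(BaseModel):
    """Configuration of one pipeline run (loadable from YAML or JSON)."""

    subject_table: Optional[Path] = None
    variant_source: Optional[Path] = None
    variant_format: str = "tsv"  # 'tsv' or 'vcf'
    output_dir: Optional[Path] = None
    maf_threshold: float = Field(gt=0.0, lt=1.0, default=0.05)
    possible_min: int = 3
    probable_min: int = 6
    definite_min: int = 9
    count_recessive_het: bool = False
    dna_points_enabled: bool = False
    seed: int = 0  # simulation runs only

    @model_validator(mode="after")
    def _check(self) -> "RunConfig":
        if not self.possible_min < self.probable_min < self.definite_min:
            raise ValueError(
                "DLCN cut-offs must be strictly increasing "
                f"(got {self.possible_min}, {self.probable_min}, {self.definite_min})"
            )
        return self

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text) if str(path).endswith((".yml", ".yaml")) else json.loads(text)
        return cls(**data)

    def dlcn_points(self) -> dict:
        points = json.loads(json.dumps(DLCN_POINTS))  # deep copy
        points["categories"] = {
            "possible_min": self.possible_min,
            "probable_min": self.probable_min,
            "definite_min": self.definite_min,
        }
        return points


def read_subjects(path) -> pd.DataFrame:
    """Read the documented subject TSV (booleans as 0/1)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"subject_id": str})
    from .synthetic_cohort import SUBJECT_COLUMNS, _BOOL_COLUMNS

    missing = set(SUBJECT_COLUMNS[:2]) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required column(s) {sorted(missing)}")
    for col in _BOOL_COLUMNS:
        if col in df.columns:
            df[col] = df[col].astype(bool)
        else:
            df[col] = False
    return df


def write_subjects(df: pd.DataFrame, path) -> None:
    from .synthetic_cohort import _BOOL_COLUMNS

    out = df.copy()
    for col in _BOOL_COLUMNS:
        if col in out.columns:
            out[col] = out[col].astype(int)
    out.to_csv(path, sep="\t", index=False)


def summarise_cohort(
    subjects: pd.DataFrame, calls: pd.DataFrame, config: RunConfig | None = None
) -> tuple[CohortSummary, pd.DataFrame, pd.DataFrame]:
    """Run all analysis stages on in-memory tables.

    Returns (summary, scored subject table, classified retained calls).
    Detection and per-group prevalence follow the study design: only
    eligible, clinically diagnosed subjects (DLCN category at least
    possible) enter the detection denominators, while the overall carrier
    prevalence counts PV carriers among everyone screened.
    """
    config = config or RunConfig()
    n_screened = len(subjects)

    scored = score_cohort(
        subjects, dna_points_enabled=config.dna_points_enabled, points=config.dlcn_points()
    )
    diagnosed = scored.loc[
        scored["eligible"] & (scored["dlcn_category"] != DlcnCategory.UNLIKELY.value)
    ]
    log.info(
        "stage eligibility+dlcn: %d subjects in, %d excluded, %d clinically diagnosed",
        n_screened, int((~scored["eligible"]).sum()), len(diagnosed),
    )

    retained, excluded = maf_filter(calls, config.maf_threshold)
    log.info(
        "stage maf_filter: %d calls in, %d retained, %d common-excluded",
        len(calls), len(retained), len(excluded),
    )

    classified = classify_catalogue(retained)
    log.info("stage classify: %d calls, %d PV", len(classified), int(classified["is_pv"].sum()))

    all_profiles = genotype_profiles(
        classified, count_recessive_het=config.count_recessive_het
    )
    diagnosed_ids = set(diagnosed["subject_id"])
    diag_calls = classified.loc[classified["subject_id"].isin(diagnosed_ids)]
    diag_profiles = genotype_profiles(
        diag_calls, subject_ids=diagnosed_ids, count_recessive_het=config.count_recessive_het
    )

    detection = cohort_genetics.detection_rates(diag_profiles, scored)
    prev = prevalence_table(detection, n_screened)
    geno = genotype_frequencies(diag_profiles)
    spec = spectrum(classified)
    carrier_prev = prevalence(int(all_profiles["pv_positive"].sum()), n_screened)

    n_by_category = scored.loc[scored["eligible"], "dlcn_category"].value_counts().to_dict()
    summary = CohortSummary(
        n_screened=n_screened,
        n_by_category=n_by_category,
        detection=detection,
        prevalence=prev,
        genotype_freq=geno,
        spectrum=spec,
        carrier_prevalence=carrier_prev,
        stage_counts={
            "subjects_in": n_screened,
            "subjects_excluded": int((~scored["eligible"]).sum()),
            "subjects_scored": int(scored["eligible"].sum()),
            "clinically_diagnosed": len(diagnosed),
            "calls_in": len(calls),
            "calls_retained": len(retained),
            "calls_common_excluded": len(excluded),
            "pv_positive_diagnosed": int(diag_profiles["pv_positive"].sum()),
            "pv_positive_all": int(all_profiles["pv_positive"].sum()),
        },
    )
    return summary, scored, classified


def render_report(summary: CohortSummary) -> str:
    """Plain-text cohort report."""
    lines = [
        "FH screening cohort report",
        "=" * 26,
        f"Subjects screened: {summary.n_screened}",
        "Eligible subjects by DLCN category: "
        + ", ".join(f"{k}={v}" for k, v in sorted(summary.n_by_category.items())),
        "",
        "Detection of pathogenic variants among clinically diagnosed FH:",
    ]
    for _, row in summary.detection.iterrows():
        lines.append(
            f"  {row['group']:<10} {row['numerator']}/{row['denominator']}"
            f" ({row['percent']}%)"
        )
    lines.append("")
    lines.append("Prevalence in the screened community:")
    for _, row in summary.prevalence.iterrows():
        lines.append(
            f"  {row['group']:<10} clinical {row['n_clinical']}/{summary.n_screened}"
            f" ({row['clinical_percent']}%, {row['clinical_ratio']});"
            f" genetically confirmed {row['n_genetic']}/{summary.n_screened}"
            f" ({row['genetic_percent']}%, {row['genetic_ratio']})"
        )
    if summary.carrier_prevalence is not None:
        lines.append(
            f"  carriers among all screened: {summary.carrier_prevalence}"
        )
    lines.append("")
    lines.append("Genotype classes among PV-positive subjects:")
    for _, row in summary.genotype_freq.iterrows():
        lines.append(f"  {row['label']:<22} {row['n']:>4}  {row['percent']}%")
    lines.append("")
    lines.append("Variant spectrum (distinct variants per gene):")
    for _, row in summary.spectrum.iterrows():
        lines.append(
            f"  {row['gene']:<8} PV {row['n_pv']:>3} ({row['pv_percent']}%)"
            f"  VUS {row['n_vus']:>3}"
        )
    return "\n".join(lines) + "\n"


def run_pipeline(config: RunConfig) -> CohortSummary:
    """File-to-file pipeline run; writes all intermediate and report tables."""
    if config.subject_table is None or config.variant_source is None:
        raise ValueError("run_pipeline needs subject_table and variant_source paths")
    subjects = read_subjects(config.subject_table)
    calls = read_variants(config.variant_source, format=config.variant_format)
    summary, scored, classified = summarise_cohort(subjects, calls, config)

    outdir = Path(config.output_dir or ".")
    outdir.mkdir(parents=True, exist_ok=True)
    write_subjects(scored, outdir / "subjects_scored.tsv")
    classified.to_csv(outdir / "variants_classified.tsv", sep="\t", index=False)
    summary.detection.to_csv(outdir / "detection.tsv", sep="\t", index=False)
    summary.prevalence.to_csv(outdir / "prevalence.tsv", sep="\t", index=False)
    summary.genotype_freq.to_csv(outdir / "genotype_frequencies.tsv", sep="\t", index=False)
    summary.spectrum.to_csv(outdir / "spectrum.tsv", sep="\t", index=False)
    (outdir / "report.txt").write_text(render_report(summary))
    log.info("pipeline complete; outputs in %s", outdir)
    return summary
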