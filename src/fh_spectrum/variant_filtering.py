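"""Variant-call ingestion, the common-variant MAF filter and in-silico summaries.

Calls arrive either as VCF v4.2 (one sample column per subject, annotation
carried in INFO keys) or as a flat TSV.  The pipeline is annotation-level:
HGVS strings are opaque identifiers, the uniqueness key of a variant is
(gene, hgvs_c), and no transcript normalisation or liftover is attempted.

The MAF filter implements the rare-variant screen: a call is excluded iff a
reference-panel minor allele frequency is recorded AND it is strictly above
the threshold (default 5%).  Absent MAF means retained — novel variants have
no panel record and must not be excluded by missingness.
"""

from __future__ import annotations

import enum
import logging
from typing import Optional
from urllib.parse import unquote

import pandas as pd
import pysam
from pydantic import BaseModel, Field

from .acmg_engine import EvidenceSet

log = logging.getLogger(__name__)

GENE_PANEL = ("LDLR", "APOB", "PCSK9", "LDLRAP1")
"""The four-gene FH sequencing panel."""

# Reference chromosome per panel gene; used only as VCF CHROM passthrough.
GENE_CHROM = {"LDLR": "chr19", "APOB": "chr2", "PCSK9": "chr1", "LDLRAP1": "chr1"}

DEFAULT_MAF_THRESHOLD = 0.05

CALL_COLUMNS = [
    "subject_id",
    "gene",
    "hgvs_c",
    "protein_change",
    "exon_or_intron",
    "zygosity",
    "rsid",
    "panel_maf",
    "polyphen",
    "sift",
    "revel",
    "evidence",
]

# INFO keys the VCF writer emits and the reader understands.
_KNOWN_INFO = {
    "GENE", "HGVSC", "PANEL_MAF", "EVIDENCE", "PROTEIN", "EXON", "RSID",
    "POLYPHEN", "SIFT", "REVEL",
}


class VariantParseError(ValueError):
    """Raised when a variant source fails to parse or violates the schema."""


class PolyphenCall(str, enum.Enum):
    PROBABLY_DAMAGING = "probably_damaging"
    POSSIBLY_DAMAGING = "possibly_damaging"
    BENIGN = "benign"
    NA = "NA"


class SiftCall(str, enum.Enum):
    DELETERIOUS = "deleterious"
    TOLERATED = "tolerated"
    NA = "NA"


class RevelCall(str, enum.Enum):
    LIKELY_DISEASE_CAUSING = "likely_disease_causing"
    LIKELY_BENIGN = "likely_benign"
    NA = "NA"


class InsilicoProfile(BaseModel):
    """Categorical calls of the three in-silico predictors."""

    polyphen: PolyphenCall = PolyphenCall.NA
    sift: SiftCall = SiftCall.NA
    revel: RevelCall = RevelCall.NA


class Zygosity(str, enum.Enum):
    HET = "het"
    HOM = "hom"


class VariantCall(BaseModel):
    """One called variant in one subject, with annotations as supplied."""

    subject_id: str
    gene: str
    hgvs_c: str
    protein_change: Optional[str] = None
    exon_or_intron: Optional[str] = None
    zygosity: Zygosity = Zygosity.HET
    rsid: Optional[str] = None
    panel_maf: Optional[float] = Field(default=None, ge=0.0, le=1.0)
    insilico: Optional[InsilicoProfile] = None
    evidence: Optional[EvidenceSet] = None

    model_config = {"arbitrary_types_allowed": True}


def _validate_genes(df: pd.DataFrame, source: str) -> None:
    bad = sorted(set(df["gene"]) - set(GENE_PANEL))
    if bad:
        raise VariantParseError(
            f"{source}: gene(s) {bad} outside the panel {GENE_PANEL}"
        )


def _read_tsv(path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", comment="#", dtype={"subject_id": str})
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise VariantParseError(f"{path}: {exc}") from exc
    required = {"subject_id", "gene", "hgvs_c"}
    missing = required - set(df.columns)
    if missing:
        raise VariantParseError(f"{path}: missing required column(s) {sorted(missing)}")
    for col in CALL_COLUMNS:
        if col not in df.columns:
            df[col] = None
    df = df.replace({".": None})
    if df["zygosity"].isna().all():
        df["zygosity"] = Zygosity.HET.value
    df["panel_maf"] = pd.to_numeric(df["panel_maf"], errors="coerce")
    return df[CALL_COLUMNS]


def _info_str(value) -> Optional[str]:
    """Decode a string INFO value (tuples re-joined, percent-escapes undone)."""
    if value is None:
        return None
    if isinstance(value, (tuple, list)):
        value = ",".join(str(v) for v in value)
    return unquote(str(value))


def _read_vcf(path) -> pd.DataFrame:
    try:
        vcf = pysam.VariantFile(str(path))
    except Exception as exc:
        raise VariantParseError(f"{path}: {exc}") from exc
    rows = []
    warned: set[str] = set()
    with vcf:
        samples = list(vcf.header.samples)
        for i, rec in enumerate(vcf.fetch() if vcf.index else vcf, start=1):
            info = dict(rec.info)
            for key in info:
                if key not in _KNOWN_INFO and key not in warned:
                    warned.add(key)
                    log.warning("%s: ignoring unknown INFO key %r", path, key)
            if "GENE" not in info or "HGVSC" not in info:
                raise VariantParseError(
                    f"{path}: record {i} (POS {rec.pos}) lacks GENE/HGVSC INFO"
                )
            base = {
                "gene": _info_str(info["GENE"]),
                "hgvs_c": _info_str(info["HGVSC"]),
                "protein_change": _info_str(info.get("PROTEIN")),
                "exon_or_intron": _info_str(info.get("EXON")),
                "rsid": _info_str(info.get("RSID")),
                "panel_maf": float(info["PANEL_MAF"]) if "PANEL_MAF" in info else None,
                "polyphen": _info_str(info.get("POLYPHEN")),
                "sift": _info_str(info.get("SIFT")),
                "revel": _info_str(info.get("REVEL")),
                "evidence": _info_str(info.get("EVIDENCE")),
            }
            for sample in samples:
                gt = rec.samples[sample].get("GT")
                if gt is None:
                    continue
                alts = sum(1 for a in gt if a not in (None, 0))
                if alts == 0:
                    continue
                zyg = Zygosity.HOM.value if alts >= 2 else Zygosity.HET.value
                rows.append({"subject_id": sample, "zygosity": zyg, **base})
    df = pd.DataFrame(rows, columns=CALL_COLUMNS)
    return df


def read_variants(path, format: str = "tsv") -> pd.DataFrame:
    """Read variant calls from a VCF v4.2 or TSV file into the call table.

    One row per (subject, variant); GT 0/1 maps to ``het`` and 1/1 to
    ``hom``.  Evidence-code strings are validated against the closed ACMG
    vocabulary; genes against the four-gene panel.
    """
    if format == "tsv":
        df = _read_tsv(path)
    elif format == "vcf":
        df = _read_vcf(path)
    else:
        raise ValueError(f"unknown variant format {format!r} (expected 'vcf' or 'tsv')")
    _validate_genes(df, str(path))
    # Validate evidence strings eagerly so a bad code fails at ingest.
    for raw in df["evidence"].dropna().unique():
        EvidenceSet.parse(raw)
    return df


def maf_filter(
    calls: pd.DataFrame, threshold: float = DEFAULT_MAF_THRESHOLD
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition calls into (retained, excluded) by reference-panel MAF.

    Excluded iff ``panel_maf`` is present and strictly greater than the
    threshold; a MAF exactly at the threshold, or absent, is retained.
    """
    if not (0 < threshold < 1):
        raise ValueError(f"MAF threshold must be in (0, 1), got {threshold}")
    maf = pd.to_numeric(calls["panel_maf"], errors="coerce")
    common = maf.notna() & (maf > threshold)
    return calls.loc[~common].copy(), calls.loc[common].copy()


_DAMAGING = {
    "polyphen": {PolyphenCall.PROBABLY_DAMAGING.value, PolyphenCall.POSSIBLY_DAMAGING.value},
    "sift": {SiftCall.DELETERIOUS.value},
    "revel": {RevelCall.LIKELY_DISEASE_CAUSING.value},
}


def insilico_summary(profile: InsilicoProfile) -> int:
    """Count predictors (0-3) calling the variant damaging; NA never counts."""
    return (
        int(profile.polyphen.value in _DAMAGING["polyphen"])
        + int(profile.sift.value in _DAMAGING["sift"])
        + int(profile.revel.value in _DAMAGING["revel"])
    )


def damaging_counts(calls: pd.DataFrame) -> pd.Series:
    """Vectorised :func:`insilico_summary` over a call table."""
    total = pd.Series(0, index=calls.index)
    for col, damaging in _DAMAGING.items():
        if col in calls.columns:
            total += calls[col].isin(damaging).astype(int)
    return total


def apply_insilico_evidence(
    calls: pd.DataFrame, *, pp3_min_damaging: int = 2, enabled: bool = False
) -> pd.DataFrame:
    """Optionally derive PP3/BP4 from the in-silico profile (off by default).

    The mapping from predictor consensus to ACMG computational evidence is a
    curation policy, not a fact of the data, so it is informational unless
    explicitly enabled: PP3 when at least ``pp3_min_damaging`` tools call
    damaging, BP4 when all three tools reported and none did.
    """
    if not enabled:
        return calls
    df = calls.copy()
    n_damaging = damaging_counts(df)
    reported = pd.Series(True, index=df.index)
    for col in ("polyphen", "sift", "revel"):
        reported &= df[col].notna() & (df[col] != "NA")
    for idx in df.index:
        ev = EvidenceSet.parse(df.at[idx, "evidence"])
        if n_damaging[idx] >= pp3_min_damaging:
            ev = EvidenceSet(set(ev) | {"PP3"})
        elif reported[idx] and n_damaging[idx] == 0:
            ev = EvidenceSet(set(ev) | {"BP4"})
        df.at[idx, "evidence"] = str(ev)
    return df
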