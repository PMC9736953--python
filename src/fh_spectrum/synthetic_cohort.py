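"""Synthetic community-screening cohorts with planted heterozygous carriers.

The generator emulates the sampling structure the downstream analysis
assumes: a community screen of adults in which each subject independently
carries each catalogue variant with a small per-variant frequency, LDL-C is
shifted upward in carriers by a per-gene effect, clinical signs occur with
probabilities conditional on carrier status, and total cholesterol is
reconstructed as TC = LDL + HDL + TG/2.2 so the Friedewald equation
round-trips exactly.  Carriers are heterozygous; because per-variant draws
are independent, double heterozygotes arise at product frequencies (they can
be disabled with ``allow_double_heterozygotes=False``, which keeps only the
first carried variant per subject).

Reproducibility: one root seed; every random quantity is drawn from its own
named substream (``[seed, 0, field]`` for clinical fields, ``[seed, 1, j]``
for catalogue variant ``j``), so appending a variant to the catalogue or
growing the cohort never perturbs draws already made for earlier variants or
subjects.
"""

from __future__ import annotations

from typing import Optional
from urllib.parse import quote

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator
from scipy import stats

from .acmg_engine import EvidenceSet
from .variant_filtering import CALL_COLUMNS, GENE_CHROM, GENE_PANEL

SUBJECT_COLUMNS = [
    "subject_id",
    "age",
    "sex",
    "tc",
    "tg",
    "hdl",
    "ldl_baseline",
    "tendon_xanthomata",
    "corneal_arcus",
    "personal_pcad",
    "personal_premature_cerebral_or_peripheral",
    "family_first_degree_premature_cad_or_high_ldl",
    "family_first_degree_xanthoma_arcus_or_child_high_ldl",
    "secondary_cause",
    "pregnant",
]

_BOOL_COLUMNS = SUBJECT_COLUMNS[7:]


class PlantedVariant(BaseModel):
    """A catalogue variant planted into the simulated cohort.

    ``carrier_freq`` is the simulation frequency of heterozygous carriers;
    ``panel_maf`` is only an annotation (the reference-panel frequency the
    MAF filter will see) and is deliberately not tied to it.
    """

    gene: str
    hgvs_c: str
    evidence: str = ""
    carrier_freq: float = Field(ge=0.0, le=0.5)
    panel_maf: Optional[float] = Field(default=None, ge=0.0, le=1.0)
    protein_change: Optional[str] = None
    exon_or_intron: Optional[str] = None
    rsid: Optional[str] = None
    polyphen: str = "NA"
    sift: str = "NA"
    revel: str = "NA"

    @model_validator(mode="after")
    def _check(self) -> "PlantedVariant":
        if self.gene not in GENE_PANEL:
            raise ValueError(f"gene {self.gene!r} outside the panel {GENE_PANEL}")
        EvidenceSet.parse(self.evidence)  # vocabulary check at config time
        return self


class ConditionalProb(BaseModel):
    """P(flag) conditional on carrying at least one planted variant."""

    carrier: float = Field(ge=0.0, le=1.0)
    noncarrier: float = Field(ge=0.0, le=1.0)


def _default_sign_probs() -> dict[str, ConditionalProb]:
    # Carrier-conditional clinical sign frequencies on the scale reported for
    # clinically diagnosed community FH (signs enriched in carriers; rare
    # background rates otherwise).
    return {
        "tendon_xanthomata": ConditionalProb(carrier=0.08, noncarrier=0.001),
        "corneal_arcus": ConditionalProb(carrier=0.35, noncarrier=0.02),
        "personal_pcad": ConditionalProb(carrier=0.12, noncarrier=0.04),
        "personal_premature_cerebral_or_peripheral": ConditionalProb(
            carrier=0.03, noncarrier=0.01
        ),
        "family_first_degree_premature_cad_or_high_ldl": ConditionalProb(
            carrier=0.30, noncarrier=0.12
        ),
        "family_first_degree_xanthoma_arcus_or_child_high_ldl": ConditionalProb(
            carrier=0.05, noncarrier=0.002
        ),
    }


def _default_shifts() -> dict[str, float]:
    # Additive LDL-C shift (mmol/L) in carriers, by gene: dominant FH genes
    # push carriers into the 5.5-6.5 range against a ~3.4 community mean;
    # the recessive-gene heterozygotes are only mildly hypercholesterolaemic.
    return {"LDLR": 2.5, "APOB": 2.0, "PCSK9": 2.3, "LDLRAP1": 1.0}


class SimConfig(BaseModel):
    """Parameters of one simulated community screen."""

    n_subjects: int = Field(ge=1, default=5130)
    seed: int = Field(ge=0, default=0)
    variant_catalogue: list[PlantedVariant] = Field(default_factory=list)
    ldl_noncarrier: tuple[float, float] = (3.4, 1.0)  # (mean, sd) mmol/L
    ldl_carrier_shift: dict[str, float] = Field(default_factory=_default_shifts)
    sign_probs: dict[str, ConditionalProb] = Field(default_factory=_default_sign_probs)
    age_dist: tuple[float, float] = (46.0, 15.0)  # (mean, sd) years, min 18
    tg_dist: tuple[float, float] = (1.85, 0.7)  # truncated to (0.2, 4.5)
    hdl_dist: tuple[float, float] = (1.35, 0.35)  # truncated below 0.4
    prop_male: float = Field(ge=0.0, le=1.0, default=0.46)
    exclusion_probs: dict[str, float] = Field(
        default_factory=lambda: {"secondary_cause": 0.02, "pregnant": 0.005}
    )
    allow_double_heterozygotes: bool = True

    @model_validator(mode="after")
    def _check(self) -> "SimConfig":
        for name, (label, sd) in {
            "ldl_noncarrier": self.ldl_noncarrier,
            "age_dist": self.age_dist,
            "tg_dist": self.tg_dist,
            "hdl_dist": self.hdl_dist,
        }.items():
            if sd <= 0:
                raise ValueError(f"{name}: sd must be > 0, got {sd}")
        for key, p in self.exclusion_probs.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"exclusion_probs[{key!r}] must be in [0,1], got {p}")
        for gene, shift in self.ldl_carrier_shift.items():
            if gene not in GENE_PANEL:
                raise ValueError(f"ldl_carrier_shift: unknown gene {gene!r}")
        return self


def _stream(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng([seed, *key])


def _truncnorm(
    rng: np.random.Generator, n: int, mean: float, sd: float, lower: float, upper: float
) -> np.ndarray:
    a, b = (lower - mean) / sd, (upper - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=n, random_state=rng)


def simulate_cohort(config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate one screen; returns (subject table, variant-call table).

    Identical configs (including seed) produce identical tables.  For every
    subject, TC - HDL - TG/2.2 equals the stored baseline LDL-C exactly.
    """
    n = config.n_subjects
    width = max(4, len(str(n)))
    ids = np.array([f"S{i:0{width}d}" for i in range(1, n + 1)])
    seed = config.seed

    # Clinical substreams, keyed by field index.
    age = np.round(_truncnorm(_stream(seed, 0, 0), n, *config.age_dist, 18.0, 95.0), 1)
    sex = np.where(_stream(seed, 0, 1).random(n) < config.prop_male, "M", "F")
    tg = np.round(_truncnorm(_stream(seed, 0, 2), n, *config.tg_dist, 0.2, 4.5), 2)
    hdl = np.round(_truncnorm(_stream(seed, 0, 3), n, *config.hdl_dist, 0.4, 4.0), 2)
    ldl_base = _truncnorm(_stream(seed, 0, 4), n, *config.ldl_noncarrier, 0.5, 15.0)

    # Carrier substreams, keyed by catalogue position: one uniform per
    # (variant, subject); masks are independent across variants.
    carrier_masks = []
    for j, variant in enumerate(config.variant_catalogue):
        u = _stream(seed, 1, j).random(n)
        carrier_masks.append(u < variant.carrier_freq)
    if carrier_masks and not config.allow_double_heterozygotes:
        taken = np.zeros(n, dtype=bool)
        for mask in carrier_masks:
            mask &= ~taken
            taken |= mask

    shift = np.zeros(n)
    any_carrier = np.zeros(n, dtype=bool)
    for variant, mask in zip(config.variant_catalogue, carrier_masks):
        shift += np.where(mask, config.ldl_carrier_shift.get(variant.gene, 0.0), 0.0)
        any_carrier |= mask
    ldl = np.round(ldl_base + shift, 2)

    flags = {}
    for k, (field, probs) in enumerate(config.sign_probs.items()):
        u = _stream(seed, 0, 10 + k).random(n)
        flags[field] = u < np.where(any_carrier, probs.carrier, probs.noncarrier)
    for k, (field, p) in enumerate(config.exclusion_probs.items()):
        flags[field] = _stream(seed, 0, 30 + k).random(n) < p
    if "pregnant" in flags:
        flags["pregnant"] &= sex == "F"

    subjects = pd.DataFrame(
        {
            "subject_id": ids,
            "age": age,
            "sex": sex,
            "tc": ldl + hdl + tg / 2.2,
            "tg": tg,
            "hdl": hdl,
            "ldl_baseline": ldl,
        }
    )
    for col in _BOOL_COLUMNS:
        subjects[col] = flags.get(col, np.zeros(n, dtype=bool))

    rows = []
    for variant, mask in zip(config.variant_catalogue, carrier_masks):
        for sid in ids[mask]:
            rows.append(
                {
                    "subject_id": sid,
                    "gene": variant.gene,
                    "hgvs_c": variant.hgvs_c,
                    "protein_change": variant.protein_change,
                    "exon_or_intron": variant.exon_or_intron,
                    "zygosity": "het",
                    "rsid": variant.rsid,
                    "panel_maf": variant.panel_maf,
                    "polyphen": variant.polyphen,
                    "sift": variant.sift,
                    "revel": variant.revel,
                    "evidence": variant.evidence,
                }
            )
    calls = pd.DataFrame(rows, columns=CALL_COLUMNS)
    calls = calls.sort_values(["subject_id", "gene", "hgvs_c"], kind="stable").reset_index(
        drop=True
    )
    return subjects, calls


# ---------------------------------------------------------------------------
# VCF output

_INFO_HEADER = [
    ('GENE', '1', 'String', 'Panel gene symbol'),
    ('HGVSC', '1', 'String', 'Coding HGVS description'),
    ('PANEL_MAF', '1', 'Float', 'Reference-panel minor allele frequency'),
    ('EVIDENCE', '.', 'String', 'ACMG evidence codes'),
    ('PROTEIN', '1', 'String', 'Protein change'),
    ('EXON', '1', 'String', 'Exon or intron'),
    ('RSID', '1', 'String', 'dbSNP identifier'),
    ('POLYPHEN', '1', 'String', 'PolyPhen2 categorical call'),
    ('SIFT', '1', 'String', 'SIFT categorical call'),
    ('REVEL', '1', 'String', 'REVEL categorical call'),
]

_QUOTE_SAFE = "._->:+()"


def _vcf_escape(value) -> Optional[str]:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    text = str(value)
    if not text:
        return None
    return quote(text, safe=_QUOTE_SAFE)


def write_vcf(calls: pd.DataFrame, subject_ids, path) -> None:
    """Write the call table as VCF v4.2 with one sample column per subject.

    Annotation-level passthrough: CHROM is the gene's chromosome, POS a
    running per-chromosome index and REF/ALT placeholders; the biological
    content travels in the INFO keys.  Round-trips losslessly through
    :func:`fh_spectrum.variant_filtering.read_variants`.
    """
    subject_ids = list(subject_ids)
    unknown = sorted(set(calls["subject_id"]) - set(subject_ids))
    if unknown:
        raise ValueError(f"calls reference unknown subject id(s): {unknown[:5]}")

    lines = ["##fileformat=VCFv4.2", "##source=fh-spectrum synthetic cohort"]
    for chrom in sorted(set(GENE_CHROM.values())):
        lines.append(f"##contig=<ID={chrom}>")
    for key, num, typ, desc in _INFO_HEADER:
        lines.append(f'##INFO=<ID={key},Number={num},Type={typ},Description="{desc}">')
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(subject_ids)
    )

    sample_pos = {sid: i for i, sid in enumerate(subject_ids)}
    pos_counter: dict[str, int] = {}
    grouped = calls.groupby(["gene", "hgvs_c"], sort=True)
    for (gene, hgvs_c), group in grouped:
        chrom = GENE_CHROM[gene]
        pos_counter[chrom] = pos_counter.get(chrom, 0) + 1
        first = group.iloc[0]
        info_values = {
            "GENE": gene,
            "HGVSC": _vcf_escape(hgvs_c),
            "PANEL_MAF": None
            if pd.isna(first.get("panel_maf"))
            else f"{float(first['panel_maf']):g}",
            "EVIDENCE": _vcf_escape(first.get("evidence")),
            "PROTEIN": _vcf_escape(first.get("protein_change")),
            "EXON": _vcf_escape(first.get("exon_or_intron")),
            "RSID": _vcf_escape(first.get("rsid")),
            "POLYPHEN": _vcf_escape(first.get("polyphen")),
            "SIFT": _vcf_escape(first.get("sift")),
            "REVEL": _vcf_escape(first.get("revel")),
        }
        info = ";".join(f"{k}={v}" for k, v in info_values.items() if v is not None)
        gts = ["0/0"] * len(subject_ids)
        for _, row in group.iterrows():
            gts[sample_pos[row["subject_id"]]] = (
                "1/1" if row["zygosity"] == "hom" else "0/1"
            )
        rsid = first.get("rsid")
        vid = "." if rsid is None or pd.isna(rsid) else str(rsid)
        lines.append(
            f"{chrom}\t{pos_counter[chrom]}\t{vid}\tN\tA\t.\tPASS\t{info}\tGT\t"
            + "\t".join(gts)
        )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def catalogue_to_planted(
    catalogue: pd.DataFrame, n_screened: int = 5130
) -> list[PlantedVariant]:
    """Turn a variant catalogue table into planted variants whose carrier
    frequencies are per-variant carrier counts over the screened total."""
    def opt(value):
        return None if value is None or pd.isna(value) else str(value)

    planted = []
    for _, row in catalogue.iterrows():
        planted.append(
            PlantedVariant(
                gene=row["gene"],
                hgvs_c=row["hgvs_c"],
                evidence=row.get("evidence") or "",
                carrier_freq=float(row["n_individuals"]) / n_screened,
                panel_maf=None,
                protein_change=opt(row.get("protein_change")),
                exon_or_intron=opt(row.get("exon_or_intron")),
                rsid=opt(row.get("rsid")),
                polyphen=opt(row.get("polyphen")) or "NA",
                sift=opt(row.get("sift")) or "NA",
                revel=opt(row.get("revel")) or "NA",
            )
        )
    return planted
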