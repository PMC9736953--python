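"""ACMG/AMP evidence combination into the five-tier variant classification.

Evidence codes are inputs (assigned upstream by curators); this module only
combines them.  Strength is fixed by the code prefix — PVS very strong, PS
strong, PM moderate, PP supporting on the pathogenic side; BA stand-alone,
BS strong, BP supporting on the benign side.  Strength-modified usage (for
example a PM invoked at PS strength) is unsupported.

The combining clauses live in ``data/acmg_rules.json`` as minimum-count
conjunctions and are evaluated in a documented order: pathogenic clauses
before likely-pathogenic, benign before likely-benign, first match wins and
is reported as ``fired_rule``.  Evidence matching both sides is conflicting
and yields VUS.  Pathogenic and likely-pathogenic are pooled as "PV"
(pathogenic variant), the study's unit of genetic confirmation.
"""

from __future__ import annotations

import enum
import json
import re
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Optional

import pandas as pd

_VALID_CODES = frozenset(
    ["PVS1"]
    + [f"PS{i}" for i in range(1, 5)]
    + [f"PM{i}" for i in range(1, 7)]
    + [f"PP{i}" for i in range(1, 6)]
    + ["BA1"]
    + [f"BS{i}" for i in range(1, 5)]
    + [f"BP{i}" for i in range(1, 8)]
)

_STRENGTH_RE = re.compile(r"^(PVS|PS|PM|PP|BA|BS|BP)\d+$")


class EvidenceError(ValueError):
    """Raised for evidence codes outside the closed ACMG vocabulary."""


class EvidenceSet(frozenset):
    """A set of ACMG evidence codes with vocabulary validation.

    Set semantics: duplicates collapse, order is irrelevant, and the
    classification depends only on code multiplicity per strength class.
    """

    def __new__(cls, codes: Iterable[str] = ()):
        codes = [c.strip() for c in codes if str(c).strip()]
        bad = [c for c in codes if c not in _VALID_CODES]
        if bad:
            raise EvidenceError(f"unknown ACMG evidence code(s): {sorted(bad)}")
        return super().__new__(cls, codes)

    @classmethod
    def parse(cls, text: Optional[str]) -> "EvidenceSet":
        """Parse a comma-separated code string, e.g. ``"PVS1,PM1,PM2"``."""
        if text is None or not str(text).strip() or str(text).strip() == ".":
            return cls()
        return cls(str(text).split(","))

    def counts(self) -> dict[str, int]:
        """Code count per strength class (PVS/PS/PM/PP/BA/BS/BP)."""
        out = {k: 0 for k in ("PVS", "PS", "PM", "PP", "BA", "BS", "BP")}
        for code in self:
            out[_STRENGTH_RE.match(code).group(1)] += 1
        return out

    def __str__(self) -> str:  # stable serialisation for TSV round trips
        return ",".join(sorted(self))


class Tier(str, enum.Enum):
    PATHOGENIC = "pathogenic"
    LIKELY_PATHOGENIC = "likely_pathogenic"
    VUS = "vus"
    LIKELY_BENIGN = "likely_benign"
    BENIGN = "benign"


PV_TIERS = frozenset({Tier.PATHOGENIC, Tier.LIKELY_PATHOGENIC})


@dataclass(frozen=True)
class AcmgClassification:
    tier: Tier
    is_pv: bool
    fired_rule: str  # clause id, "none", or "conflicting_evidence"


def _load_rules() -> dict:
    with resources.files("fh_spectrum.data").joinpath("acmg_rules.json").open() as fh:
        return json.load(fh)


ACMG_RULES: dict = _load_rules()


def _first_match(counts: dict[str, int], clauses: list[dict]) -> Optional[str]:
    for clause in clauses:
        if all(counts[k] >= v for k, v in clause["min"].items()):
            return clause["rule"]
    return None


def combine(evidence: EvidenceSet | Iterable[str], rules: dict = ACMG_RULES) -> AcmgClassification:
    """Combine an evidence set into a tier, pooled-PV flag and fired rule."""
    if not isinstance(evidence, EvidenceSet):
        evidence = EvidenceSet(evidence)
    counts = evidence.counts()

    patho = _first_match(counts, rules["pathogenic"])
    if patho is None:
        patho = _first_match(counts, rules["likely_pathogenic"])
        patho_tier = Tier.LIKELY_PATHOGENIC if patho else None
    else:
        patho_tier = Tier.PATHOGENIC
    benign = _first_match(counts, rules["benign"])
    if benign is None:
        benign = _first_match(counts, rules["likely_benign"])
        benign_tier = Tier.LIKELY_BENIGN if benign else None
    else:
        benign_tier = Tier.BENIGN

    if patho_tier and benign_tier:
        return AcmgClassification(Tier.VUS, False, "conflicting_evidence")
    if patho_tier:
        return AcmgClassification(patho_tier, True, patho)
    if benign_tier:
        return AcmgClassification(benign_tier, False, benign)
    return AcmgClassification(Tier.VUS, False, "none")


def classify_catalogue(variants: pd.DataFrame, rules: dict = ACMG_RULES) -> pd.DataFrame:
    """Classify every row of a variant table by its ``evidence`` column.

    Returns a copy with ``tier``, ``is_pv`` and ``fired_rule`` columns.  Rows
    with a missing evidence set are flagged ``unclassifiable`` (tier left
    empty, is_pv False) rather than aborting the run.
    """
    df = variants.copy()
    tiers, is_pv, fired = [], [], []
    for raw in df["evidence"]:
        if raw is None or (isinstance(raw, float) and pd.isna(raw)):
            tiers.append("unclassifiable")
            is_pv.append(False)
            fired.append("unclassifiable")
            continue
        ev = raw if isinstance(raw, EvidenceSet) else EvidenceSet.parse(raw)
        cls = combine(ev, rules)
        tiers.append(cls.tier.value)
        is_pv.append(cls.is_pv)
        fired.append(cls.fired_rule)
    df["tier"] = tiers
    df["is_pv"] = is_pv
    df["fired_rule"] = fired
    return df
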