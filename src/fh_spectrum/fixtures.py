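"""Packaged reference tables and helpers to reconstruct subject-level inputs.

The underlying screening study deposited no raw data; what it published are
aggregate tables — the 40-variant pathogenic catalogue with ACMG evidence,
per-category subject counts, and genotype-class counts.  Those tables ship
with the package as TSV/JSON and the helpers below expand the count tables
back into minimal subject-level inputs so the cohort statistics can be
exercised end to end.
"""

from __future__ import annotations

import json
from importlib import resources

import pandas as pd

_TSV_FIXTURES = {
    "pv_catalogue": "table6_catalogue.tsv",
    "detection_counts": "table2_counts.tsv",
    "genotype_counts": "table4_genotypes.tsv",
}
_JSON_FIXTURES = {
    "dlcn_points": "dlcn_points.json",
    "acmg_rules": "acmg_rules.json",
}
_ALIASES = {
    "table6_catalogue": "pv_catalogue",
    "table2_counts": "detection_counts",
    "table4_genotypes": "genotype_counts",
}

N_SCREENED = 5130  # community adults screened in the source study


def load_fixture(name: str):
    """Load a packaged fixture by name.

    Names: ``pv_catalogue`` (40-variant catalogue), ``detection_counts``
    (per-category subject and carrier counts), ``genotype_counts``
    (genotype-class counts of the 82 carriers), ``dlcn_points`` and
    ``acmg_rules`` (the versioned scoring/combination tables).
    """
    name = _ALIASES.get(name, name)
    data = resources.files("fh_spectrum.data")
    if name in _TSV_FIXTURES:
        with data.joinpath(_TSV_FIXTURES[name]).open() as fh:
            # "NA" is a meaningful predictor level, not missing; "." is missing.
            return pd.read_csv(
                fh, sep="\t", comment="#", keep_default_na=False, na_values=["."]
            )
    if name in _JSON_FIXTURES:
        with data.joinpath(_JSON_FIXTURES[name]).open() as fh:
            return json.load(fh)
    known = sorted(set(_TSV_FIXTURES) | set(_JSON_FIXTURES) | set(_ALIASES))
    raise KeyError(f"unknown fixture {name!r}; known: {known}")


def subjects_from_detection_counts(counts: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Expand per-category counts into (profiles, categories) subject tables.

    Each clinical category contributes ``n_subjects`` pseudo-subjects of
    which the first ``n_pv_positive`` are PV carriers.  "potential" subjects
    are assigned the probable DLCN category (any category in the pooled
    probable/definite group gives identical statistics).
    """
    category_map = {"potential": "probable", "possible": "possible"}
    prof_rows, cat_rows = [], []
    i = 0
    for _, row in counts.iterrows():
        n, k = int(row["n_subjects"]), int(row["n_pv_positive"])
        if not 0 <= k <= n:
            raise ValueError(f"{row['category']}: n_pv_positive {k} outside [0, {n}]")
        for j in range(n):
            i += 1
            sid = f"C{i:04d}"
            prof_rows.append(
                {
                    "subject_id": sid,
                    "label": "LDLR_het" if j < k else "none",
                    "pv_positive": j < k,
                }
            )
            cat_rows.append(
                {"subject_id": sid, "dlcn_category": category_map[row["category"]]}
            )
    return pd.DataFrame(prof_rows), pd.DataFrame(cat_rows)


def profiles_from_genotype_counts(counts: pd.DataFrame) -> pd.DataFrame:
    """Expand genotype-class counts into one profile row per carrier."""
    rows = []
    i = 0
    for _, row in counts.iterrows():
        for _ in range(int(row["n_individuals"])):
            i += 1
            rows.append(
                {"subject_id": f"G{i:04d}", "label": row["label"], "pv_positive": True}
            )
    return pd.DataFrame(rows)
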