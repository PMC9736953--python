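"""Genotype labels, detection rates, prevalence formatting and the spectrum."""

import math

import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fh_spectrum.acmg_engine import classify_catalogue
from fh_spectrum.cohort_genetics import (
    detection_rates,
    genotype_frequencies,
    genotype_profile,
    genotype_profiles,
    percent,
    prevalence,
    ratio_string,
    spectrum,
)
from fh_spectrum.fixtures import (
    load_fixture,
    profiles_from_genotype_counts,
    subjects_from_detection_counts,
)


def calls(rows):
    return pd.DataFrame(rows, columns=["subject_id", "gene", "is_pv"])


class TestGenotypeProfile:
    def test_single_het(self):
        p = genotype_profile("S1", calls([("S1", "LDLR", True)]))
        assert p.label == "LDLR_het" and p.pv_positive

    def test_double_heterozygote(self):
        p = genotype_profile("S1", calls([("S1", "LDLR", True), ("S1", "APOB", True)]))
        assert p.label == "LDLR+APOB_double" and p.pv_positive

    def test_recessive_het_not_counted_by_default(self):
        p = genotype_profile("S1", calls([("S1", "LDLRAP1", True)]))
        assert p.label == "LDLRAP1_het" and not p.pv_positive
        q = genotype_profile(
            "S1", calls([("S1", "LDLRAP1", True)]), count_recessive_het=True
        )
        assert q.label == "LDLRAP1_het" and q.pv_positive

    def test_non_pv_calls_ignored(self):
        p = genotype_profile("S1", calls([("S1", "APOB", False)]))
        assert p.label == "none" and not p.pv_positive

    def test_triple_is_other_combination(self):
        p = genotype_profile(
            "S1",
            calls([("S1", "LDLR", True), ("S1", "APOB", True), ("S1", "PCSK9", True)]),
        )
        assert p.label == "other_combination" and p.pv_positive

    def test_profiles_fill_missing_subjects(self):
        df = genotype_profiles(calls([("S1", "LDLR", True)]), subject_ids=["S1", "S2"])
        assert dict(zip(df["subject_id"], df["label"])) == {
            "S1": "LDLR_het",
            "S2": "none",
        }


class TestDetectionRates:
    def test_published_counts_reproduced(self):
        profiles, categories = subjects_from_detection_counts(
            load_fixture("detection_counts")
        )
        table = detection_rates(profiles, categories).set_index("group")
        assert table.loc["all_fh", ["numerator", "denominator", "percent"]].tolist() == [
            82, 372, 22.0,
        ]
        assert table.loc["potential", "percent"] == 20.7
        assert table.loc["possible", "percent"] == 22.3

    def test_partition_of_numerators_and_denominators(self):
        profiles, categories = subjects_from_detection_counts(
            load_fixture("detection_counts")
        )
        t = detection_rates(profiles, categories).set_index("group")
        for col in ("numerator", "denominator"):
            assert t.loc["potential", col] + t.loc["possible", col] == t.loc["all_fh", col]

    def test_zero_of_hundred(self):
        profiles = pd.DataFrame(
            {"subject_id": [f"S{i}" for i in range(100)], "label": "none", "pv_positive": False}
        )
        categories = profiles.assign(dlcn_category="possible")
        t = detection_rates(profiles, categories).set_index("group")
        assert t.loc["all_fh", "percent"] == 0.0

    def test_empty_group_undefined_not_zero(self):
        profiles = pd.DataFrame(
            {"subject_id": ["S1"], "label": ["LDLR_het"], "pv_positive": [True]}
        )
        categories = pd.DataFrame({"subject_id": ["S1"], "dlcn_category": ["possible"]})
        t = detection_rates(profiles, categories).set_index("group")
        assert math.isnan(t.loc["potential", "percent"])


class TestPrevalence:
    @pytest.mark.parametrize(
        "num,den,pct,ratio",
        [
            (12, 5130, 0.2, "1:427"),  # 427.5 rounds half down
            (82, 5130, 1.6, "1:63"),
            (70, 5130, 1.4, "1:73"),
            (372, 5130, 7.3, "1:14"),
            (58, 5130, 1.1, "1:88"),
            (314, 5130, 6.1, "1:16"),
            (1, 2, 50.0, "1:2"),
        ],
    )
    def test_published_pairs(self, num, den, pct, ratio):
        res = prevalence(num, den)
        assert res.percent == pct and res.ratio == ratio

    def test_zero_numerator_sentinel(self):
        res = prevalence(0, 100)
        assert res.percent == 0.0 and res.ratio == "1:inf"

    def test_bounds_checked(self):
        with pytest.raises(ValueError):
            prevalence(5, 4)

    @given(k=st.integers(1, 10_000), n=st.integers(1, 10_000))
    @settings(max_examples=300, derandomize=True)
    def test_ratio_round_trip(self, k, n):
        """Parsing "1:N" back recovers n/k to within 0.5, halves rounded down."""
        if k > n:
            k, n = n, k
        N = int(ratio_string(k, n).split(":")[1])
        err = n / k - N
        assert -0.5 <= err <= 0.5
        if err == -0.5:  # exact half must have been rounded down, not up
            pytest.fail("half was rounded up")

    def test_percent_half_up(self):
        assert percent(1, 8) == 12.5
        assert percent(5, 4000) == 0.1  # 0.125 -> 0.1
        assert percent(15, 10000) == 0.2  # 0.15 rounds half UP even in binary float


class TestSpectrum:
    def test_published_catalogue_distribution(self):
        catalogue = classify_catalogue(load_fixture("pv_catalogue"))
        # reported pooled classes: use the published classification column
        catalogue["tier"] = catalogue["reported_class"].map(
            {"P": "pathogenic", "LP": "likely_pathogenic"}
        )
        table = spectrum(catalogue).set_index("gene")
        assert table.loc["LDLR", ["n_pv", "pv_percent"]].tolist() == [18, 45.0]
        assert table.loc["APOB", ["n_pv", "pv_percent"]].tolist() == [15, 37.5]
        assert table.loc["PCSK9", ["n_pv", "pv_percent"]].tolist() == [5, 12.5]
        assert table.loc["LDLRAP1", ["n_pv", "pv_percent"]].tolist() == [2, 5.0]

    def test_single_variant(self):
        df = pd.DataFrame(
            {"gene": ["LDLR"], "hgvs_c": ["c.1G>A"], "tier": ["pathogenic"]}
        )
        t = spectrum(df)
        assert t.loc[0, "n_pv"] == 1 and t.loc[0, "pv_percent"] == 100.0

    def test_duplicates_collapse_to_distinct_variants(self):
        df = pd.DataFrame(
            {
                "gene": ["LDLR", "LDLR", "APOB"],
                "hgvs_c": ["c.1G>A", "c.1G>A", "c.2G>A"],
                "tier": ["pathogenic"] * 3,
            }
        )
        t = spectrum(df).set_index("gene")
        assert t.loc["LDLR", "n_pv"] == 1 and t.loc["APOB", "n_pv"] == 1


class TestGenotypeFrequencies:
    def test_published_counts(self):
        freq = genotype_frequencies(
            profiles_from_genotype_counts(load_fixture("genotype_counts"))
        ).set_index("label")
        assert freq.loc["LDLR_het", "percent"] == 31.7
        assert freq.loc["APOB_het", "percent"] == 22.0
        assert freq.loc["PCSK9_het", "percent"] == 39.0
        assert freq.loc["LDLR+APOB_double", "percent"] == 3.7
        assert freq.loc["LDLR+PCSK9_double", "percent"] == 1.2
        assert freq.loc["APOB+PCSK9_double", "percent"] == 2.4
        assert int(freq["n"].sum()) == 82
        assert freq["percent"].sum() == pytest.approx(100.0, abs=0.2)

    def test_single_subject(self):
        p = pd.DataFrame(
            {"subject_id": ["S1"], "label": ["PCSK9_het"], "pv_positive": [True]}
        )
        freq = genotype_frequencies(p)
        assert freq.loc[0, "percent"] == 100.0

    def test_no_positive_subjects_empty_table(self):
        p = pd.DataFrame({"subject_id": ["S1"], "label": ["none"], "pv_positive": [False]})
        assert len(genotype_frequencies(p)) == 0
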