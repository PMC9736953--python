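"""Friedewald LDL-C, eligibility rules and DLCN scoring."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fh_spectrum.clinical_scoring import (
    DlcnCategory,
    InvalidLipidError,
    dlcn_category,
    dlcn_score,
    eligibility,
    friedewald_ldl,
)

from .conftest import make_subject


class TestFriedewald:
    @pytest.mark.parametrize(
        "tc,hdl,tg,expected",
        [
            (5.0, 1.0, 0.0, 4.0),  # zero-TG limiting case
            (5.0, 1.0, 2.2, 3.0),  # tg/2.2 contributes exactly 1
            (7.4, 1.4, 1.8, 7.4 - 1.4 - 1.8 / 2.2),
        ],
    )
    def test_values(self, tc, hdl, tg, expected):
        assert friedewald_ldl(tc, hdl, tg) == pytest.approx(expected, abs=1e-12)

    def test_invalid_above_tg_bound(self):
        with pytest.raises(InvalidLipidError):
            friedewald_ldl(7.0, 1.2, 4.6)

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(InvalidLipidError):
            friedewald_ldl(-1.0, 1.0, 1.0)

    @given(
        ldl=st.floats(0.5, 12.0),
        hdl=st.floats(0.5, 3.0),
        tg=st.floats(0.0, 4.5),
    )
    @settings(max_examples=200, derandomize=True)
    def test_conservation(self, ldl, hdl, tg):
        """ldl + hdl + tg/2.2 reconstructs tc to within 1e-9."""
        tc = ldl + hdl + tg / 2.2
        assert abs(friedewald_ldl(tc, hdl, tg) - ldl) < 1e-9


class TestEligibility:
    def test_minor_excluded_first(self):
        r = make_subject(age=17.0, secondary_cause=True)
        res = eligibility(r)
        assert not res.included and res.reason == "age"

    @pytest.mark.parametrize(
        "flags,reason",
        [
            ({"secondary_cause": True}, "secondary_cause"),
            ({"pregnant": True}, "pregnant"),
        ],
    )
    def test_exclusion_order(self, flags, reason):
        assert eligibility(make_subject(ldl_baseline=6.0, **flags)).reason == reason

    def test_ldl_cutoff_without_pcad(self):
        assert eligibility(make_subject(ldl_baseline=4.5)).reason == "ldl_cutoff"
        assert eligibility(make_subject(ldl_baseline=4.9)).included

    def test_ldl_cutoff_with_pcad_inclusive_boundary(self):
        assert eligibility(make_subject(ldl_baseline=4.0, personal_pcad=True)).included
        assert not eligibility(make_subject(ldl_baseline=3.9, personal_pcad=True)).included

    def test_missing_ldl_underivable(self):
        with pytest.raises(InvalidLipidError):
            eligibility(make_subject(tc=None, ldl_baseline=None))


class TestDlcnScore:
    def test_all_false_low_ldl(self):
        r = make_subject(ldl_baseline=3.0)
        res = dlcn_score(r)
        assert res.score == 0 and res.category is DlcnCategory.UNLIKELY

    def test_xanthomata_plus_top_ldl_band(self):
        r = make_subject(ldl_baseline=9.0, tendon_xanthomata=True)
        res = dlcn_score(r)
        assert res.score == 14
        assert res.group_points == {
            "family_history": 0,
            "clinical_history": 0,
            "physical_exam": 6,
            "ldl": 8,
            "dna": 0,
        }
        assert res.category is DlcnCategory.DEFINITE

    def test_family_history_plus_mid_band(self):
        r = make_subject(
            ldl_baseline=5.5, family_first_degree_premature_cad_or_high_ldl=True
        )
        res = dlcn_score(r)
        assert res.score == 4 and res.category is DlcnCategory.POSSIBLE

    def test_max_within_group_not_sum(self):
        r = make_subject(
            ldl_baseline=3.0,
            family_first_degree_premature_cad_or_high_ldl=True,
            family_first_degree_xanthoma_arcus_or_child_high_ldl=True,
        )
        assert dlcn_score(r).group_points["family_history"] == 2

    def test_corneal_arcus_only_when_premature(self):
        young = make_subject(age=40.0, ldl_baseline=3.0, corneal_arcus=True)
        old = make_subject(age=60.0, ldl_baseline=3.0, corneal_arcus=True)
        onset = make_subject(
            age=60.0, ldl_baseline=3.0, corneal_arcus=True, corneal_arcus_age=42.0
        )
        assert dlcn_score(young).group_points["physical_exam"] == 4
        assert dlcn_score(old).group_points["physical_exam"] == 0
        assert dlcn_score(onset).group_points["physical_exam"] == 4

    def test_dna_group_disabled_by_default(self):
        r = make_subject(ldl_baseline=3.0, dna_pv_confirmed=True)
        assert dlcn_score(r).score == 0
        assert dlcn_score(r, dna_points_enabled=True).score == 8

    @pytest.mark.parametrize(
        "ldl,points", [(3.9, 0), (4.0, 1), (4.9, 1), (5.0, 3), (6.5, 5), (8.4, 5), (8.5, 8)]
    )
    def test_ldl_band_boundaries(self, ldl, points):
        assert dlcn_score(make_subject(ldl_baseline=ldl)).group_points["ldl"] == points

    _FLAGS = [
        "tendon_xanthomata",
        "corneal_arcus",
        "personal_pcad",
        "personal_premature_cerebral_or_peripheral",
        "family_first_degree_premature_cad_or_high_ldl",
        "family_first_degree_xanthoma_arcus_or_child_high_ldl",
    ]

    @given(
        flags=st.lists(st.booleans(), min_size=6, max_size=6),
        ldl=st.floats(1.0, 12.0),
        extra=st.integers(0, 5),
        raise_ldl=st.floats(0.0, 4.0),
        age=st.floats(18.0, 80.0),
    )
    @settings(max_examples=200, derandomize=True)
    def test_monotonicity(self, flags, ldl, extra, raise_ldl, age):
        """Setting any additional flag or raising LDL-C never lowers the score."""
        kwargs = dict(zip(self._FLAGS, flags))
        base = dlcn_score(make_subject(age=age, ldl_baseline=ldl, **kwargs)).score
        more = dict(kwargs)
        more[self._FLAGS[extra]] = True
        assert dlcn_score(make_subject(age=age, ldl_baseline=ldl, **more)).score >= base
        higher = dlcn_score(
            make_subject(age=age, ldl_baseline=ldl + raise_ldl, **kwargs)
        ).score
        assert higher >= base


class TestDlcnCategory:
    @pytest.mark.parametrize(
        "score,category,potential",
        [
            (0, DlcnCategory.UNLIKELY, False),
            (2, DlcnCategory.UNLIKELY, False),
            (3, DlcnCategory.POSSIBLE, False),
            (5, DlcnCategory.POSSIBLE, False),
            (6, DlcnCategory.PROBABLE, True),
            (8, DlcnCategory.PROBABLE, True),
            (9, DlcnCategory.DEFINITE, True),
            (14, DlcnCategory.DEFINITE, True),
        ],
    )
    def test_bands(self, score, category, potential):
        cat, pot = dlcn_category(score)
        assert cat is category and pot is potential

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            dlcn_category(-1)

    @given(score=st.integers(0, 40))
    @settings(max_examples=41, derandomize=True)
    def test_partition(self, score):
        """Every non-negative score maps to exactly one category."""
        cat, pot = dlcn_category(score)
        expected = (
            DlcnCategory.DEFINITE
            if score > 8
            else DlcnCategory.PROBABLE
            if score >= 6
            else DlcnCategory.POSSIBLE
            if score >= 3
            else DlcnCategory.UNLIKELY
        )
        assert cat is expected
        assert pot == (cat in (DlcnCategory.PROBABLE, DlcnCategory.DEFINITE))
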