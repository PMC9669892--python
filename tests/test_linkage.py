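from __future__ import annotations

from datetime import datetime, timedelta

import pytest

from feverdq.linkage import (
    LinkageError,
    compare_demographics,
    demographic_dqi,
    detect_synonymous_profiles,
    link_profiles,
)
from feverdq.model import (
    APP_ONLY_ADULT,
    APP_ONLY_SIBLING,
    MATCHED,
    OFFICE_ONLY,
    SYNONYMOUS_DUPLICATE,
    Profile,
    ProfileLink,
)

T0 = datetime(2020, 1, 1, 9, 0)


def child(pid, gender="female", bmy=(3, 2015), fam="abcdefgh", hours=0, **kw):
    return Profile(family_code=fam, profile_id=pid, gender=gender,
                   birth_month_year=bmy, created_at=T0 + timedelta(hours=hours), **kw)


def patient(pid, gender="female", bmy=(3, 2015), fam="abcdefgh"):
    return Profile(family_code=fam, profile_id=pid, gender=gender, birth_month_year=bmy)


class TestSynonymousProfiles:
    def test_distinct_demographics_form_no_groups(self):
        assert detect_synonymous_profiles([child("a"), child("b", bmy=(4, 2015))]) == []

    def test_two_identical_tuples_form_one_group(self):
        groups = detect_synonymous_profiles([child("a"), child("b", hours=1)])
        assert len(groups) == 1 and len(groups[0]) == 2
        assert groups[0][0].profile_id == "a"  # earliest-created is canonical

    def test_three_identical_tuples_one_group_one_canonical(self):
        groups = detect_synonymous_profiles(
            [child("c", hours=2), child("a"), child("b", hours=1)]
        )
        assert len(groups) == 1 and len(groups[0]) == 3
        assert groups[0][0].profile_id == "a"


class TestLinkProfiles:
    def test_exact_match_single_child_family(self):
        links = link_profiles([child("a")], [patient("p1")])
        assert len(links) == 1
        assert links[0].status == MATCHED and links[0].mismatches == frozenset()

    def test_duplicate_profiles_collapse_to_one_link(self):
        links = link_profiles([child("a"), child("b", hours=1)], [patient("p1")])
        by_status = {l.status for l in links}
        assert by_status == {MATCHED, SYNONYMOUS_DUPLICATE}
        dup = next(l for l in links if l.status == SYNONYMOUS_DUPLICATE)
        assert dup.canonical_profile_id == "a"

    def test_adults_and_unmatched_children_classified(self):
        links = link_profiles(
            [child("a"), child("sib", bmy=(1, 2010)), child("mum", bmy=(5, 1985), is_adult=True)],
            [patient("p1")],
        )
        statuses = sorted(l.status for l in links)
        assert statuses == sorted([MATCHED, APP_ONLY_SIBLING, APP_ONLY_ADULT])

    def test_office_only_patients_reported(self):
        links = link_profiles([child("a")], [patient("p1"), patient("p2", bmy=(9, 2018))])
        assert sorted(l.status for l in links) == sorted([MATCHED, OFFICE_ONLY])

    def test_strict_mode_rejects_family_absent_from_office(self):
        with pytest.raises(LinkageError, match="not office"):
            link_profiles([child("a")], [], strict=True)

    def test_every_profile_lands_in_exactly_one_link(self):
        from feverdq.simulate import GeneratorConfig, generate

        app, office, _ = generate(GeneratorConfig(seed=21, n_families=40))
        links = link_profiles(app.profiles, office.patients)
        app_ids = sorted(l.app_profile.profile_id for l in links if l.app_profile)
        office_ids = sorted(l.office_patient.profile_id for l in links if l.office_patient)
        assert app_ids == sorted(p.profile_id for p in app.profiles)
        assert office_ids == sorted(p.profile_id for p in office.patients)

    def test_matched_pairs_bounded_by_smaller_side_per_family(self):
        kids = [child(f"a{i}", bmy=(i + 1, 2015)) for i in range(4)]
        links = link_profiles(kids, [patient("p1"), patient("p2", bmy=(2, 2015))])
        assert sum(1 for l in links if l.status == MATCHED) == 2

    def test_relinking_matched_output_is_a_fixed_point(self):
        app = [child("a"), child("b", gender="male", bmy=(7, 2012))]
        office = [patient("p1"), patient("p2", gender="male", bmy=(7, 2012))]
        links1 = link_profiles(app, office)
        pairs1 = {(l.app_profile.profile_id, l.office_patient.profile_id)
                  for l in links1 if l.status == MATCHED}
        links2 = link_profiles(
            [l.app_profile for l in links1 if l.status == MATCHED],
            [l.office_patient for l in links1 if l.status == MATCHED],
        )
        pairs2 = {(l.app_profile.profile_id, l.office_patient.profile_id)
                  for l in links2 if l.status == MATCHED}
        assert pairs1 == pairs2


class TestCompareDemographics:
    def make_link(self, app_kw=None, office_kw=None):
        a = child("a", **(app_kw or {}))
        o = patient("p1", **(office_kw or {}))
        return ProfileLink(a, o, MATCHED)

    def test_identical_demographics_no_mismatch(self):
        assert compare_demographics(self.make_link()) == frozenset()

    def test_gender_and_dob_mismatches_combine(self):
        link = self.make_link(app_kw={"gender": "male", "bmy": (4, 2015)})
        assert compare_demographics(link) == {"gender", "date_of_birth"}

    def test_diverse_gender_never_auto_matches(self):
        link = self.make_link(app_kw={"gender": "diverse"})
        assert compare_demographics(link) == {"gender"}

    def test_missing_dob_counts_as_incomplete_not_discordant(self):
        link = self.make_link(app_kw={"bmy": None})
        assert compare_demographics(link) == {"dob_missing"}

    def test_unmatched_link_rejected(self):
        with pytest.raises(LinkageError):
            compare_demographics(ProfileLink(child("a"), None, APP_ONLY_SIBLING))


class TestCohortAccounting:
    """The published profile arithmetic: 1047 app profiles reduce to 1012
    comparable children after removing 6 profiles of unidentifiable
    families, 22 siblings, 2 adults, and 5 synonymous duplicates."""

    def test_profile_exclusion_arithmetic(self, reference_report):
        acc = reference_report.payload["accounting"]
        assert acc["app_profiles"] == 1047
        assert acc["unidentifiable_family_profiles"] == 6
        assert acc["unidentifiable_families"] == 5
        assert acc["siblings"] == 22
        assert acc["adults"] == 2
        assert acc["synonymous_duplicates"] == 5
        assert acc["comparable_profiles"] == 1012
        assert acc["app_profiles"] - acc["unidentifiable_family_profiles"] == 1041
        assert 1041 - 22 - 2 - 5 == acc["comparable_profiles"]

    def test_demographic_mismatch_counts(self, reference_report):
        demo = reference_report.payload["demographic"]
        assert demo["gender"]["mismatches"] == 7
        assert demo["date_of_birth"]["mismatches"] == 12

    def test_demographic_rates(self, reference_report):
        demo = reference_report.payload["demographic"]
        assert demo["gender"]["concordance"]["rate_pct"] == pytest.approx(99.31, abs=0.005)
        assert demo["date_of_birth"]["concordance"]["rate_pct"] == pytest.approx(98.81, abs=0.005)
        assert demo["date_of_birth"]["completeness"]["rate_pct"] == pytest.approx(99.2, abs=0.05)
        assert demo["gender"]["completeness"]["rate_pct"] == 100.0


def test_demographic_dqi_requires_matched_links():
    with pytest.raises(LinkageError):
        demographic_dqi([ProfileLink(child("a"), None, APP_ONLY_SIBLING)])
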