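from __future__ import annotations


from datetime import datetime, timedelta


import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from feverdq.matching import (
    MatchingConfig,
    _pair_weight,
    grade_agreement,
    match_episodes,
    temperature_difference,
    venn_partition,
)
from feverdq.model import MATCHED, EpisodeMatch, FeverEpisode, Profile, ProfileLink


def app_ep(start_day, end_day, temp=None, **kw):
    return FeverEpisode(
        profile_id="child1", source="app",
        start=datetime(2020, 1, 1, 8) + timedelta(days=start_day),
        end=datetime(2020, 1, 1, 8) + timedelta(days=end_day),
        max_temperature=temp, **kw,
    )


def office_ep(visit_day, kind="acute", temp=None, **kw):
    ts = datetime(2020, 1, 1, 12) + timedelta(days=visit_day)
    return FeverEpisode(
        profile_id="pat1", source="office", start=ts, end=ts,
        max_temperature=temp, office_kind=kind, **kw,
    )


class TestPairing:
    def test_acute_visit_inside_app_interval_pairs(self):
        matches = match_episodes([app_ep(2, 5)], [office_ep(3)])
        assert len(matches) == 1 and matches[0].is_paired

    def test_no_app_episodes_leaves_office_exclusive(self):
        matches = match_episodes([], [office_ep(3), office_ep(40, "past")])
        assert len(matches) == 2
        assert all(m.office_episode is not None and m.app_episode is None for m in matches)

    def test_acute_outside_window_stays_unpaired(self):
        matches = match_episodes([app_ep(0, 2)], [office_ep(20)])
        assert not any(m.is_paired for m in matches)

    def test_past_report_pairs_with_most_recent_preceding_episode(self):
        earlier, recent = app_ep(0, 2), app_ep(20, 22)
        matches = match_episodes([earlier, recent], [office_ep(30, "past")])
        paired = [m for m in matches if m.is_paired]
        assert len(paired) == 1
        assert paired[0].app_episode.start == recent.start

    def test_past_report_beyond_window_stays_unpaired(self):
        matches = match_episodes([app_ep(0, 2)], [office_ep(70, "past")])
        assert not any(m.is_paired for m in matches)

    def test_no_episode_pairs_twice(self):
        matches = match_episodes([app_ep(0, 4)], [office_ep(1), office_ep(2)])
        assert sum(m.is_paired for m in matches) == 1

    def _exhaustive_max_pairs(self, apps, offices, config):
        """Oracle: maximum one-to-one pairing by exhaustive recursion."""
        admissible = [
            [i for i, a in enumerate(apps) if _pair_weight(a, o, config) > 0]
            for o in offices
        ]

        def best(j: int, used: frozenset) -> int:
            if j == len(offices):
                return 0
            out = best(j + 1, used)  # office episode j stays unpaired
            for i in admissible[j]:
                if i not in used:
                    out = max(out, 1 + best(j + 1, used | {i}))
            return out

        return best(0, frozenset())

    @settings(max_examples=60, deadline=None)
    @given(
        st.lists(st.integers(min_value=0, max_value=40), min_size=0, max_size=6),
        st.lists(
            st.tuples(st.integers(min_value=0, max_value=45), st.booleans()),
            min_size=0, max_size=6,
        ),
    )
    def test_pairs_attain_exhaustive_maximum_on_small_instances(self, app_starts, visits):
        apps = [app_ep(s, s + 1) for s in sorted(set(app_starts))]
        offices = [office_ep(d, "acute" if ac else "past") for d, ac in visits]
        config = MatchingConfig()
        matches = match_episodes(apps, offices, config)
        got = sum(m.is_paired for m in matches)
        assert got == self._exhaustive_max_pairs(apps, offices, config)

    @settings(max_examples=40, deadline=None)
    @given(st.randoms(use_true_random=False))
    def test_pairing_stable_under_input_permutation(self, rnd):
        apps = [app_ep(s, s + 2) for s in (0, 10, 20, 30)]
        offices = [office_ep(d, k) for d, k in ((1, "acute"), (24, "past"), (31, "acute"))]
        base = {
            (m.app_episode.start, m.office_episode.start)
            for m in match_episodes(apps, offices)
            if m.is_paired
        }
        rnd.shuffle(apps)
        rnd.shuffle(offices)
        shuffled = {
            (m.app_episode.start, m.office_episode.start)
            for m in match_episodes(apps, offices)
            if m.is_paired
        }
        assert base == shuffled


class TestGradeAgreement:
    def test_matching_binary_flags_agree(self):
        m = match_episodes(
            [app_ep(0, 2, physician_visit=True)], [office_ep(1, physician_visit=True)]
        )[0]
        assert m.agreement["physician_visit"] == "agree"

    def test_temperature_equal_at_resolution_agrees(self):
        m = match_episodes([app_ep(0, 2, temp=39.4)], [office_ep(1, temp=39.4)])[0]
        assert m.agreement["max_temperature"] == "agree"
        assert temperature_difference(m) == 0.0

    def test_temperature_differing_by_04_disagrees(self):
        m = match_episodes([app_ep(0, 2, temp=39.4)], [office_ep(1, temp=39.0)])[0]
        assert m.agreement["max_temperature"] == "disagree"
        assert temperature_difference(m) == pytest.approx(0.4)

    def test_missing_temperature_not_comparable(self):
        m = match_episodes([app_ep(0, 2)], [office_ep(1, temp=39.0)])[0]
        assert m.agreement["max_temperature"] == "not_comparable"
        assert temperature_difference(m) is None

    def test_unpaired_match_rejected(self):
        with pytest.raises(ValueError):
            grade_agreement(EpisodeMatch(app_ep(0, 1), None))


class TestVenn:
    def test_single_paired_episode_leaves_other_cells_zero(self):
        a = Profile("abcdefgh", "child1", "female", (3, 2015))
        o = Profile("abcdefgh", "pat1", "female", (3, 2015))
        link = ProfileLink(a, o, MATCHED)
        apps, offices = [app_ep(0, 2)], [office_ep(1)]
        matches = {"child1": match_episodes(apps, offices)}
        v = venn_partition([link], matches, {"child1": apps}, {"pat1": offices})
        assert v.office_paired == v.app_paired == 1
        assert v.office_total == v.app_total == 1
        assert v.app_only == v.office_only == 0
        assert v.office_family_no_app == v.office_child_no_profile == 0

    def test_reference_partition_reproduces_published_cells(self, reference_report):
        v = reference_report.payload["venn"]
        assert v["office_total"] == 1171
        assert v["office_family_no_app"] == 133
        assert v["office_child_no_profile"] == 85
        assert v["office_profiled"] == 953
        assert v["office_acute"] == 681 and v["office_past"] == 272
        assert v["office_paired"] == 686 and v["office_only"] == 267
        assert v["app_total"] == 1481
        assert v["app_identifiable"] == 1452
        assert v["app_only"] == 766 and v["app_unidentifiable"] == 29

    def test_synthetic_cells_match_generator_ground_truth(self):
        from feverdq.report import run_pipeline
        from feverdq.simulate import GeneratorConfig, generate

        # no structural anomalies: the pipeline's cells must equal the
        # generator's own bookkeeping exactly
        cfg = GeneratorConfig(
            seed=13, n_families=60, p_office_report_past_noapp=0.0,
            p_sibling_not_patient=0.0, p_child_unregistered=0.0,
            p_duplicate_profile=0.0, p_gender_error=0.0, p_dob_error=0.0,
            p_dob_missing=0.0,
        )
        app, office, truth = generate(cfg)
        v = run_pipeline(app, office).payload["venn"]
        df = truth.episodes
        recording = df.groupby("family_code")["app_recorded"].any()
        active_fams = set(recording[recording].index)
        in_active = df.family_code.isin(active_fams)
        assert v["office_paired"] == int((df.app_recorded & (df.office_kind != "none")).sum())
        assert v["app_identifiable"] == int(df.app_recorded.sum())
        assert v["office_profiled"] == int(((df.office_kind != "none") & in_active).sum())
        assert v["office_family_no_app"] == int(((df.office_kind != "none") & ~in_active).sum())

    def test_conservation_paired_plus_exclusive_equals_totals(self, reference_report):
        v = reference_report.payload["venn"]
        assert v["office_paired"] + v["app_only"] == v["app_identifiable"]
        assert v["office_paired"] + v["office_only"] == v["office_profiled"]
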