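"""Pair app episodes with office episodes per linked child.

The registry never records which office visit belongs to which diary
episode, so correspondence is a declared convention with explicit
windows:

* an office *acute* episode pairs with the app episode whose interval
  contains the visit date; failing that, with the nearest app episode
  starting within +/- ``acute_window_days`` (default 7);
* an office *past* episode (reported retrospectively at a later visit)
  pairs with the most recent app episode ending before the visit date,
  at most ``past_window_days`` (default 60) earlier;
* every episode pairs at most once; leftovers become source-exclusive
  matches.

Pairing is solved as a maximum-cardinality assignment with containment
preferred over windowed proximity and nearer episodes over farther
ones, so on small instances it provably attains the maximum number of
pairs and is invariant to input order.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

import numpy as np

from .assignment import BASE_WEIGHT, max_weight_pairs
from .model import (
    AGREE,
    DISAGREE,
    MATCHED,
    NOT_COMPARABLE,
    EpisodeMatch,
    FeverEpisode,
    ProfileLink,
)

#: Two submitted maximum temperatures agree only exactly at the sources'
#: shared 0.1 degC resolution.
TEMP_AGREE_TOL = 0.05


@dataclass(frozen=True, slots=True)
class MatchingConfig:
    acute_window_days: float = 7.0
    past_window_days: float = 60.0


def _pair_weight(app: FeverEpisode, office: FeverEpisode, config: MatchingConfig) -> float:
    visit = office.visit_date
    if office.office_kind == "acute":
        if app.start.date() <= visit <= app.end.date():
            return BASE_WEIGHT + 100_000.0
        dist = abs((app.start.date() - visit).days)
        if dist <= config.acute_window_days:
            return BASE_WEIGHT + 10_000.0 - 10.0 * dist
        return 0.0
    # past: reported after the episode ended
    delay = (visit - app.end.date()).days
    if 0 <= delay <= config.past_window_days:
        return BASE_WEIGHT + 10_000.0 - 10.0 * delay
    return 0.0


def match_episodes(
    app_episodes: list[FeverEpisode],
    office_episodes: list[FeverEpisode],
    config: MatchingConfig = MatchingConfig(),
) -> list[EpisodeMatch]:
    """One-to-one pairing of one child's episodes across the two sources.

    Returns paired matches first (by office visit date), then app-only,
    then office-only matches. Degenerate inputs yield all-exclusive
    matches.
    """
    apps = sorted(app_episodes, key=lambda e: (e.start, e.end))
    offices = sorted(office_episodes, key=lambda e: (e.start, e.office_kind))
    w = np.zeros((len(apps), len(offices)))
    for i, a in enumerate(apps):
        for j, o in enumerate(offices):
            w[i, j] = _pair_weight(a, o, config)
    pairs = max_weight_pairs(w)
    matches = [
        EpisodeMatch(apps[i], offices[j], agreement=grade_agreement_pair(apps[i], offices[j]))
        for i, j in sorted(pairs, key=lambda ij: ij[1])
    ]
    used_a = {i for i, _ in pairs}
    used_o = {j for _, j in pairs}
    matches.extend(EpisodeMatch(a, None) for i, a in enumerate(apps) if i not in used_a)
    matches.extend(EpisodeMatch(None, o) for j, o in enumerate(offices) if j not in used_o)
    return matches


def grade_agreement_pair(app: FeverEpisode, office: FeverEpisode) -> dict[str, str]:
    """Per-variable agreement verdicts for a paired episode.

    Binary flags compare after the negation coercion; temperatures
    agree iff |delta| < 0.05 degC (exact at 0.1 degC resolution) and are
    not comparable when either side did not submit a value.
    """
    out: dict[str, str] = {}
    for var in ("physician_visit", "antipyretic", "antibiotic"):
        out[var] = AGREE if getattr(app, var) == getattr(office, var) else DISAGREE
    if app.max_temperature is None or office.max_temperature is None:
        out["max_temperature"] = NOT_COMPARABLE
    else:
        delta = app.max_temperature - office.max_temperature
        out["max_temperature"] = AGREE if abs(delta) < TEMP_AGREE_TOL else DISAGREE
    return out


def grade_agreement(match: EpisodeMatch) -> dict[str, str]:
    if not match.is_paired:
        raise ValueError("grade_agreement requires a paired match")
    assert match.app_episode is not None and match.office_episode is not None
    return grade_agreement_pair(match.app_episode, match.office_episode)


def temperature_difference(match: EpisodeMatch) -> float | None:
    """App minus office; positive means the app temperature was higher."""
    if not match.is_paired:
        return None
    a, o = match.app_episode, match.office_episode
    assert a is not None and o is not None
    if a.max_temperature is None or o.max_temperature is None:
        return None
    return round(a.max_temperature - o.max_temperature, 10)


@dataclass(slots=True)
class VennPartition:
    """The cross-registry partition of episode sets.

    Office side: episodes from families with no app episodes at all,
    episodes from children without app profiles, and episodes from
    profiled children split paired / office-only and acute / past.
    App side: episodes from identifiable children split paired /
    app-only, plus episodes from children not identifiable in the
    office (siblings, adults, families unknown to the office).
    """

    office_family_no_app: int = 0
    office_child_no_profile: int = 0
    office_profiled: int = 0
    office_paired: int = 0
    office_only: int = 0
    office_acute: int = 0
    office_past: int = 0
    office_paired_acute: int = 0
    office_paired_past: int = 0
    app_identifiable: int = 0
    app_paired: int = 0
    app_only: int = 0
    app_unidentifiable: int = 0

    @property
    def office_total(self) -> int:
        return self.office_family_no_app + self.office_child_no_profile + self.office_profiled

    @property
    def app_total(self) -> int:
        return self.app_identifiable + self.app_unidentifiable

    def to_dict(self) -> dict[str, int]:
        return {
            "office_total": self.office_total,
            "office_family_no_app": self.office_family_no_app,
            "office_child_no_profile": self.office_child_no_profile,
            "office_profiled": self.office_profiled,
            "office_paired": self.office_paired,
            "office_only": self.office_only,
            "office_acute": self.office_acute,
            "office_past": self.office_past,
            "office_paired_acute": self.office_paired_acute,
            "office_paired_past": self.office_paired_past,
            "app_total": self.app_total,
            "app_identifiable": self.app_identifiable,
            "app_paired": self.app_paired,
            "app_only": self.app_only,
            "app_unidentifiable": self.app_unidentifiable,
        }


def venn_partition(
    links: list[ProfileLink],
    matches_by_profile: dict[str, list[EpisodeMatch]],
    app_episodes_by_profile: dict[str, list[FeverEpisode]],
    office_episodes_by_patient: dict[str, list[FeverEpisode]],
) -> VennPartition:
    """Partition both sources' episodes into the cross-registry cells.

    ``matches_by_profile`` is keyed by canonical app profile id for
    matched children; the episode dicts cover *all* profiles/patients.
    Cells sum to the source totals by construction.
    """
    app_family = {l.app_profile.profile_id: l.app_profile.family_code
                  for l in links if l.app_profile is not None}
    office_family = {l.office_patient.profile_id: l.office_patient.family_code
                     for l in links if l.office_patient is not None}
    matched_patient_ids = {l.office_patient.profile_id for l in links
                           if l.status == MATCHED and l.office_patient is not None}
    matched_profile_ids = {l.app_profile.profile_id for l in links
                           if l.status == MATCHED and l.app_profile is not None}

    families_with_app_entries = {
        app_family[pid] for pid, eps in app_episodes_by_profile.items()
        if eps and pid in app_family
    }

    v = VennPartition()
    for pid, eps in sorted(office_episodes_by_patient.items()):
        fam = office_family.get(pid)
        for ep in eps:
            if fam not in families_with_app_entries:
                v.office_family_no_app += 1
            elif pid not in matched_patient_ids:
                v.office_child_no_profile += 1
            else:
                v.office_profiled += 1
                if ep.office_kind == "acute":
                    v.office_acute += 1
                else:
                    v.office_past += 1
    for pid, mts in sorted(matches_by_profile.items()):
        for m in mts:
            if m.is_paired:
                v.office_paired += 1
                v.app_paired += 1
                assert m.office_episode is not None
                if m.office_episode.office_kind == "acute":
                    v.office_paired_acute += 1
                else:
                    v.office_paired_past += 1
            elif m.app_episode is not None:
                v.app_only += 1
    v.office_only = v.office_profiled - v.office_paired
    for pid, eps in sorted(app_episodes_by_profile.items()):
        if pid in matched_profile_ids:
            v.app_identifiable += len(eps)
        else:
            v.app_unidentifiable += len(eps)
    return v


def group_episodes_by_profile(episodes: list[FeverEpisode]) -> dict[str, list[FeverEpisode]]:
    out: dict[str, list[FeverEpisode]] = defaultdict(list)
    for e in episodes:
        out[e.profile_id].append(e)
    for eps in out.values():
        eps.sort(key=lambda e: e.start)
    return dict(out)
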