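"""Segment a profile's diary entries into fever episodes.

An episode is a maximal run of entries in which no inter-entry gap
exceeds the configured threshold: if no entry was made for more than 48
hours, the next entry opens a new episode. The comparison is strict —
a gap of exactly 48 hours stays within the episode.

The "child healthy" button would naturally end an episode, but users
often forget to press it, which is why the registry redefines episodes
by the gap rule. Here the gap rule is authoritative; healthy markers
are advisory and only counted (see :func:`healthy_marker_conflicts`).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

from .model import DiaryEntry, FeverEpisode


@dataclass(frozen=True, slots=True)
class SegmentationConfig:
    gap_hours: float = 48.0

    def __post_init__(self) -> None:
        if self.gap_hours <= 0:
            raise ValueError("gap_hours must be positive")


def segment_groups(
    entries: list[DiaryEntry], config: SegmentationConfig = SegmentationConfig()
) -> list[list[DiaryEntry]]:
    """Group one profile's entries into episode runs by the gap rule.

    Entries with no fever-relevant content still count for timing: the
    rule operates on entry timestamps, not content.
    """
    if not entries:
        return []
    profiles = {e.profile_id for e in entries}
    if len(profiles) > 1:
        raise ValueError(f"entries from multiple profiles: {sorted(profiles)}")
    ordered = sorted(entries, key=lambda e: e.occurred_at)
    gap_seconds = config.gap_hours * 3600.0
    groups: list[list[DiaryEntry]] = [[ordered[0]]]
    for prev, cur in zip(ordered, ordered[1:]):
        delta = (cur.occurred_at - prev.occurred_at).total_seconds()
        if delta > gap_seconds:
            groups.append([cur])
        else:
            groups[-1].append(cur)
    return groups


def summarize_episode(entries: list[DiaryEntry]) -> FeverEpisode:
    """Aggregate one episode's entries.

    The maximum temperature is the maximum of the submitted values
    (missing if none was submitted). Each binary flag is true iff any
    entry answered "yes"; all-missing answers coerce to "no" — in the
    analysis, missing answers concerning physician visits and
    medication are equal to negation.
    """
    if not entries:
        raise ValueError("cannot summarize an empty episode")
    ordered = sorted(entries, key=lambda e: e.occurred_at)
    temps = [e.temperature for e in ordered if e.temperature is not None]
    return FeverEpisode(
        profile_id=ordered[0].profile_id,
        source="app",
        start=ordered[0].occurred_at,
        end=ordered[-1].occurred_at,
        max_temperature=max(temps) if temps else None,
        physician_visit=any(e.physician_visit is True for e in ordered),
        antipyretic=any(e.antipyretic is True for e in ordered),
        antibiotic=any(e.antibiotic is True for e in ordered),
        n_entries=len(ordered),
    )


def segment_entries(
    entries: list[DiaryEntry], config: SegmentationConfig = SegmentationConfig()
) -> list[FeverEpisode]:
    """Convert one profile's diary entries into ordered fever episodes."""
    return [summarize_episode(g) for g in segment_groups(entries, config)]


def healthy_marker_conflicts(
    entries: list[DiaryEntry], config: SegmentationConfig = SegmentationConfig()
) -> int:
    """Count healthy-marked entries followed within the gap by more entries.

    These are cases where the advisory "child healthy" signal would have
    split an episode that the authoritative gap rule keeps together;
    they are surfaced in the report but do not affect segmentation.
    """
    n = 0
    for group in segment_groups(entries, config):
        n += sum(1 for e in group[:-1] if e.healthy_marker)
    return n


def episode_count_difference(
    app_episodes: dict[str, int], office_episodes: dict[str, int]
) -> dict[str, int]:
    """Signed per-unit episode-count difference (app minus office).

    Keys are unit identifiers (family codes or profile ids); positive
    means the app recorded more episodes than the office for that unit.
    """
    units = set(app_episodes) | set(office_episodes)
    return {u: app_episodes.get(u, 0) - office_episodes.get(u, 0) for u in sorted(units)}


def count_differences_summary(diffs: dict[str, int]) -> dict[int, int]:
    """Histogram of signed differences, for the per-unit comparison figure."""
    return dict(sorted(Counter(diffs.values()).items()))
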