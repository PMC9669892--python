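"""Domain types for the two-source fever-registry comparison.

The study design compares two independently kept records of the same
children's fever episodes:

* an *app registry*: parents document fever in real time (ecological
  momentary assessment), producing timestamped diary entries grouped
  under child profiles, which in turn belong to a family identified by a
  shared 8-character lowercase family code;
* *office reference records*: a pediatric practice documents, per visit,
  acute fever episodes (child presented with fever) and past episodes
  (reported retrospectively when the physician asks about fever since
  the last visit).

Everything downstream — segmentation, linkage, episode matching and the
data-quality indicators (DQIs) — operates on the types defined here.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from datetime import date, datetime
from typing import Optional

FAMILY_CODE_RE = re.compile(r"^[a-z]{8}$")

#: Plausible bounds for a submitted body temperature in degrees Celsius.
#: The app's own entry bounds are not documented; these defaults bracket
#: the observed range (36.2-42.4 C) generously and are configurable via
#: ``validate_dataset``.
TEMP_MIN = 34.0
TEMP_MAX = 43.5

GENDERS_APP = ("female", "male", "diverse")
GENDERS_OFFICE = ("female", "male")

EPISODE_VARIABLES = ("physician_visit", "antipyretic", "antibiotic", "max_temperature")


@dataclass(frozen=True, slots=True)
class DiaryEntry:
    """One timestamped parental observation for one child profile.

    Ternary flags use ``True`` / ``False`` / ``None`` where ``None`` means
    the question was left unanswered (distinct from an explicit "no"
    until the negation coercion is applied at episode level).
    """

    profile_id: str
    occurred_at: datetime
    temperature: Optional[float] = None
    physician_visit: Optional[bool] = None
    antipyretic: Optional[bool] = None
    antibiotic: Optional[bool] = None
    healthy_marker: bool = False


@dataclass(frozen=True, slots=True)
class Profile:
    """A person record in either source.

    App profiles carry month/year of birth only (``birth_month_year``)
    and may omit it; office patients carry a full date of birth, exposed
    both as ``birth_date`` and through the same month/year tuple used
    for comparisons.
    """

    family_code: str
    profile_id: str
    gender: str
    birth_month_year: Optional[tuple[int, int]] = None  # (month, year)
    is_adult: bool = False
    created_at: Optional[datetime] = None
    birth_date: Optional[date] = None  # office only


@dataclass(slots=True)
class FeverEpisode:
    """An aggregated fever episode from either source.

    For app episodes ``start``/``end`` are the first/last diary entry
    timestamps. Office records are already episode-grained: one visit
    row becomes one episode with ``start == end`` at the visit date and
    ``office_kind`` distinguishing acute from past episodes.

    Binary flags are stored post-coercion: a question never answered
    "yes" counts as "no" (missing answers about physician visits and
    medication are treated as negation).
    """

    profile_id: str
    source: str  # "app" | "office"
    start: datetime
    end: datetime
    max_temperature: Optional[float] = None
    physician_visit: bool = False
    antipyretic: bool = False
    antibiotic: bool = False
    office_kind: str = "not_applicable"  # "acute" | "past" | "not_applicable"
    n_entries: int = 0

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("episode start after end")
        if self.source == "office" and self.office_kind not in ("acute", "past"):
            raise ValueError("office episodes must be acute or past")

    @property
    def visit_date(self) -> date:
        """Date anchoring an office episode (the visit date)."""
        return self.start.date()


# ProfileLink statuses
MATCHED = "matched"
APP_ONLY_SIBLING = "app_only_sibling"
APP_ONLY_ADULT = "app_only_adult"
SYNONYMOUS_DUPLICATE = "synonymous_duplicate"
OFFICE_ONLY = "office_only"

LINK_STATUSES = (MATCHED, APP_ONLY_SIBLING, APP_ONLY_ADULT, SYNONYMOUS_DUPLICATE, OFFICE_ONLY)


@dataclass(slots=True)
class ProfileLink:
    """A resolved correspondence between an app profile and an office patient."""

    app_profile: Optional[Profile]
    office_patient: Optional[Profile]
    status: str
    mismatches: frozenset[str] = frozenset()  # subset of {gender, date_of_birth, dob_missing}
    canonical_profile_id: Optional[str] = None  # for synonymous duplicates

    def __post_init__(self) -> None:
        if self.status not in LINK_STATUSES:
            raise ValueError(f"unknown link status {self.status!r}")
        if (self.status == MATCHED) != (
            self.office_patient is not None and self.app_profile is not None
        ):
            raise ValueError("status=matched iff both sides present")
        if self.mismatches and self.status != MATCHED:
            raise ValueError("mismatches only meaningful on matched links")


AGREE = "agree"
DISAGREE = "disagree"
NOT_COMPARABLE = "not_comparable"


@dataclass(slots=True)
class EpisodeMatch:
    """A paired (app, office) episode, or a source-exclusive episode."""

    app_episode: Optional[FeverEpisode]
    office_episode: Optional[FeverEpisode]
    agreement: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.app_episode is None and self.office_episode is None:
            raise ValueError("at least one episode must be present")
        if self.agreement and not self.is_paired:
            raise ValueError("agreement populated only for paired matches")

    @property
    def is_paired(self) -> bool:
        return self.app_episode is not None and self.office_episode is not None


@dataclass(frozen=True, slots=True)
class DQIResult:
    """A completeness or concordance rate with its exact 95% CI."""

    indicator: str  # "completeness" | "concordance"
    variable: str
    k: int
    n: int
    rate: float
    ci_low: float
    ci_high: float
    level: str  # "family" | "profile" | "episode"

    def __post_init__(self) -> None:
        if not 0 <= self.k <= self.n:
            raise ValueError("need 0 <= k <= n")
        if not (self.ci_low - 1e-12 <= self.rate <= self.ci_high + 1e-12):
            raise ValueError("rate outside its own CI")


@dataclass(frozen=True, slots=True)
class Violation:
    """One validation finding; ``kind`` is machine-readable."""

    kind: str
    source: str
    detail: str

    def to_dict(self) -> dict[str, str]:
        return {"kind": self.kind, "source": self.source, "detail": self.detail}


def validate_profiles(
    profiles: list[Profile], source: str, current_year: int = 2026
) -> list[Violation]:
    out: list[Violation] = []
    seen: set[str] = set()
    for p in profiles:
        if p.profile_id in seen:
            raise ValueError(f"duplicate ({source}, {p.profile_id}) primary key")
        seen.add(p.profile_id)
        if not FAMILY_CODE_RE.match(p.family_code):
            out.append(Violation("bad_family_code", source, f"{p.profile_id}: {p.family_code!r}"))
        if p.birth_month_year is not None:
            month, year = p.birth_month_year
            if not (1 <= month <= 12 and 1900 <= year <= current_year):
                out.append(
                    Violation("bad_birth_month_year", source, f"{p.profile_id}: {p.birth_month_year}")
                )
        genders = GENDERS_APP if source == "app" else GENDERS_OFFICE
        if p.gender not in genders:
            out.append(Violation("bad_gender", source, f"{p.profile_id}: {p.gender!r}"))
    return out


def validate_dataset(
    profiles: list[Profile],
    entries_or_visits: list,
    source: str = "app",
    temp_bounds: tuple[float, float] = (TEMP_MIN, TEMP_MAX),
) -> list[Violation]:
    """Check one source's tables; returns violations, never mutates input.

    Raises ``ValueError`` on duplicate ``(source, profile_id)`` primary
    keys; everything else is reported, not raised.
    """
    out = validate_profiles(profiles, source)
    known = {p.profile_id for p in profiles}
    lo, hi = temp_bounds
    for item in entries_or_visits:
        pid = item.profile_id
        temp = item.temperature if isinstance(item, DiaryEntry) else item.max_temperature
        if pid not in known:
            out.append(Violation("orphan_entry", source, f"unknown profile {pid}"))
        if temp is not None and not (lo <= temp <= hi):
            out.append(Violation("temperature_out_of_range", source, f"{pid}: {temp}"))
    return out
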