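"""CSV serialization for the app export and the office reference export.

All files are UTF-8 CSV with a header row. Timestamps are ISO-8601 at
minute resolution and timezone-naive (local time); dates are
``YYYY-MM-DD``. Ternary flags serialize as ``yes`` / ``no`` / empty
string, where empty means the question was not answered. Temperatures
are written at 0.1 degC resolution.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date, datetime
from pathlib import Path
from typing import Optional, Union

import pandas as pd

from .model import DiaryEntry, FeverEpisode, Profile

APP_PROFILE_COLS = [
    "family_code", "profile_id", "gender", "birth_month", "birth_year", "is_adult", "created_at",
]
APP_ENTRY_COLS = [
    "profile_id", "occurred_at", "temperature", "physician_visit",
    "antipyretic", "antibiotic", "healthy_marker",
]
OFFICE_PATIENT_COLS = ["family_code", "patient_id", "gender", "birth_date"]
OFFICE_VISIT_COLS = [
    "patient_id", "visit_date", "kind", "max_temperature",
    "physician_visit", "antipyretic", "antibiotic",
]

PathLike = Union[str, Path]


@dataclass(slots=True)
class AppData:
    """The app-registry export: profiles plus raw diary entries."""

    profiles: list[Profile]
    entries: list[DiaryEntry]


@dataclass(slots=True)
class OfficeData:
    """The reference-records export: patients plus per-visit fever reports.

    ``visits`` are already episode-grained, so each row is materialized
    directly as an office :class:`~feverdq.model.FeverEpisode`.
    """

    patients: list[Profile]
    visits: list[FeverEpisode]


def _ternary_to_str(v: Optional[bool]) -> str:
    return "" if v is None else ("yes" if v else "no")


def _str_to_ternary(s: str) -> Optional[bool]:
    s = s.strip().lower()
    if s == "":
        return None
    if s in ("yes", "true", "1"):
        return True
    if s in ("no", "false", "0"):
        return False
    raise ValueError(f"bad ternary value {s!r}")


def _temp_to_str(t: Optional[float]) -> str:
    return "" if t is None else f"{t:.1f}"


def _read_csv(path: PathLike, cols: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return df


def write_app_data(data: AppData, profiles_path: PathLike, entries_path: PathLike) -> None:
    prof_rows = []
    for p in data.profiles:
        m, y = p.birth_month_year if p.birth_month_year is not None else ("", "")
        prof_rows.append({
            "family_code": p.family_code,
            "profile_id": p.profile_id,
            "gender": p.gender,
            "birth_month": m,
            "birth_year": y,
            "is_adult": "true" if p.is_adult else "false",
            "created_at": p.created_at.isoformat(timespec="minutes") if p.created_at else "",
        })
    pd.DataFrame(prof_rows, columns=APP_PROFILE_COLS).to_csv(profiles_path, index=False)

    entry_rows = []
    for e in data.entries:
        entry_rows.append({
            "profile_id": e.profile_id,
            "occurred_at": e.occurred_at.isoformat(timespec="minutes"),
            "temperature": _temp_to_str(e.temperature),
            "physician_visit": _ternary_to_str(e.physician_visit),
            "antipyretic": _ternary_to_str(e.antipyretic),
            "antibiotic": _ternary_to_str(e.antibiotic),
            "healthy_marker": "true" if e.healthy_marker else "false",
        })
    pd.DataFrame(entry_rows, columns=APP_ENTRY_COLS).to_csv(entries_path, index=False)


def read_app_data(profiles_path: PathLike, entries_path: PathLike) -> AppData:
    pdf = _read_csv(profiles_path, APP_PROFILE_COLS)
    profiles = []
    for r in pdf.itertuples(index=False):
        bmy = None
        if r.birth_month != "" and r.birth_year != "":
            bmy = (int(r.birth_month), int(r.birth_year))
        profiles.append(Profile(
            family_code=r.family_code,
            profile_id=r.profile_id,
            gender=r.gender,
            birth_month_year=bmy,
            is_adult=r.is_adult == "true",
            created_at=datetime.fromisoformat(r.created_at) if r.created_at else None,
        ))
    edf = _read_csv(entries_path, APP_ENTRY_COLS)
    entries = []
    for r in edf.itertuples(index=False):
        entries.append(DiaryEntry(
            profile_id=r.profile_id,
            occurred_at=datetime.fromisoformat(r.occurred_at),
            temperature=float(r.temperature) if r.temperature != "" else None,
            physician_visit=_str_to_ternary(r.physician_visit),
            antipyretic=_str_to_ternary(r.antipyretic),
            antibiotic=_str_to_ternary(r.antibiotic),
            healthy_marker=r.healthy_marker == "true",
        ))
    return AppData(profiles, entries)


def write_office_data(data: OfficeData, patients_path: PathLike, visits_path: PathLike) -> None:
    pat_rows = []
    for p in data.patients:
        pat_rows.append({
            "family_code": p.family_code,
            "patient_id": p.profile_id,
            "gender": p.gender,
            "birth_date": p.birth_date.isoformat() if p.birth_date else "",
        })
    pd.DataFrame(pat_rows, columns=OFFICE_PATIENT_COLS).to_csv(patients_path, index=False)

    visit_rows = []
    for v in data.visits:
        visit_rows.append({
            "patient_id": v.profile_id,
            "visit_date": v.visit_date.isoformat(),
            "kind": v.office_kind,
            "max_temperature": _temp_to_str(v.max_temperature),
            "physician_visit": _ternary_to_str(v.physician_visit),
            "antipyretic": _ternary_to_str(v.antipyretic),
            "antibiotic": _ternary_to_str(v.antibiotic),
        })
    pd.DataFrame(visit_rows, columns=OFFICE_VISIT_COLS).to_csv(visits_path, index=False)


def read_office_data(patients_path: PathLike, visits_path: PathLike) -> OfficeData:
    pdf = _read_csv(patients_path, OFFICE_PATIENT_COLS)
    patients = []
    for r in pdf.itertuples(index=False):
        bd = date.fromisoformat(r.birth_date) if r.birth_date else None
        patients.append(Profile(
            family_code=r.family_code,
            profile_id=r.patient_id,
            gender=r.gender,
            birth_month_year=(bd.month, bd.year) if bd else None,
            birth_date=bd,
        ))
    vdf = _read_csv(visits_path, OFFICE_VISIT_COLS)
    visits = []
    for r in vdf.itertuples(index=False):
        visits.append(office_visit_to_episode(
            patient_id=r.patient_id,
            visit_date=date.fromisoformat(r.visit_date),
            kind=r.kind,
            max_temperature=float(r.max_temperature) if r.max_temperature != "" else None,
            physician_visit=_str_to_ternary(r.physician_visit),
            antipyretic=_str_to_ternary(r.antipyretic),
            antibiotic=_str_to_ternary(r.antibiotic),
        ))
    return OfficeData(patients, visits)


def office_visit_to_episode(
    patient_id: str,
    visit_date: date,
    kind: str,
    max_temperature: Optional[float],
    physician_visit: Optional[bool],
    antipyretic: Optional[bool],
    antibiotic: Optional[bool],
) -> FeverEpisode:
    """Materialize one office visit row as an episode.

    Missing binary answers coerce to negation, except the visit flag of
    an *acute* record, which is by definition a physician visit and
    defaults to yes.
    """
    if kind not in ("acute", "past"):
        raise ValueError(f"bad office episode kind {kind!r}")
    if physician_visit is None:
        physician_visit = kind == "acute"
    ts = datetime.combine(visit_date, datetime.min.time()).replace(hour=12)
    return FeverEpisode(
        profile_id=patient_id,
        source="office",
        start=ts,
        end=ts,
        max_temperature=max_temperature,
        physician_visit=physician_visit,
        antipyretic=bool(antipyretic),
        antibiotic=bool(antibiotic),
        office_kind=kind,
        n_entries=1,
    )
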