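"""Deterministic synthetic reconstruction of the published study cohort.

The registry deposits no raw data; what survives in print is the exact
accounting of the cohort — profile exclusions, the cross-registry Venn
partition of episodes, per-variable agreement tables and demographic
error counts. This module rebuilds a synthetic cohort to those printed
marginal counts, so that running the full pipeline on it reproduces the
published rates and intervals *by computation*:

* 1047 app profiles: 6 in 5 families unknown to the office, 22
  non-patient siblings, 2 adults, 5 synonymous duplicates, leaving 1012
  comparable children in 676 families (plus 3 families that installed
  the app without creating profiles);
* demographic errors among the 1012: 6 gender-only, 11 date-of-birth
  only, 1 both, 8 missing dates of birth;
* episodes: 1171 office (133 from families without app entries, 85 from
  children without profiles, 953 = 681 acute + 272 past from profiled
  children) against 1481 app (29 from unidentifiable siblings, 1452
  identifiable = 686 paired + 766 app-only); office-only = 257 acute
  + 10 past;
* per-variable agreement on the 686 paired episodes: physician visits
  245 yes / 178 no, antipyretics 234 / 223, antibiotics 13 / 606,
  temperature 110 exact agreements (90 of 424 acute, 20 of 262 past),
  with 110 office and 11 app episodes lacking a temperature.

Every child's diary entries are laid out so the >48 h gap rule recovers
exactly the intended episodes, and office visit dates are placed so the
windowed pairing recovers exactly the intended correspondence. All
content is synthetic; identifiers, timestamps and temperatures carry no
information beyond the counts above.
"""

from __future__ import annotations

from datetime import date, datetime, timedelta

from .io import AppData, OfficeData, office_visit_to_episode
from .model import DiaryEntry, FeverEpisode, Profile

BASE = datetime(2020, 1, 1)

# slot grid: one potential episode per 55-day slot, far beyond every
# segmentation gap and matching window
SLOT_DAYS = 55
SLOT_OFFSET = 15


def _code(i: int) -> str:
    letters = []
    for _ in range(8):
        letters.append(chr(97 + i % 26))
        i //= 26
    return "".join(reversed(letters))


def _child_demo(fam_idx: int, child_idx: int) -> tuple[str, int, int]:
    """Distinct (gender, birth month, birth year) for children of one family."""
    gender = "female" if (fam_idx + child_idx) % 2 == 0 else "male"
    year = 2007 + (fam_idx + 5 * child_idx) % 13
    month = 1 + (fam_idx * 3 + child_idx * 5) % 12
    return gender, month, year


class _Queue:
    """Deterministic pattern dispenser: [(count, label), ...]."""

    def __init__(self, spec: list[tuple[int, str]]):
        self.items: list[str] = []
        for count, label in spec:
            self.items.extend([label] * count)
        self.pos = 0

    def take(self) -> str:
        v = self.items[self.pos]
        self.pos += 1
        return v

    def exhausted(self) -> bool:
        return self.pos == len(self.items)


def reference_cohort() -> tuple[AppData, OfficeData]:
    """Build the reconstructed study cohort (synthetic; see module docstring)."""
    app_profiles: list[Profile] = []
    entries: list[DiaryEntry] = []
    patients: list[Profile] = []
    visits: list[FeverEpisode] = []
    patient_counter = 0

    # per-variable agreement patterns over the 686 paired episodes:
    # app value x office value after negation coercion
    visits_q = _Queue([(245, "yy"), (34, "yn"), (229, "ny"), (178, "nn")])
    anti_q = _Queue([(234, "yy"), (40, "yn"), (189, "ny"), (223, "nn")])
    abx_q = _Queue([(13, "yy"), (19, "yn"), (48, "ny"), (606, "nn")])
    # temperature patterns keyed by office episode kind:
    # eq = exact agreement, om/am = office/app missing, diff = differ
    temp_acute_q = _Queue([(90, "eq"), (70, "om"), (8, "am"), (256, "diff")])
    temp_past_q = _Queue([(20, "eq"), (40, "om"), (3, "am"), (199, "diff")])
    # app-only episode margins (diary totals beyond the paired subset)
    ao_visit_q = _Queue([(121, "y"), (645, "n")])
    ao_anti_q = _Queue([(176, "y"), (590, "n")])
    ao_abx_q = _Queue([(14, "y"), (752, "n")])
    ao_temp_q = _Queue([(26, "missing"), (740, "present")])

    acute_diffs = [-0.3, -0.2, -0.1, 0.1, 0.2, 0.3, 0.4]
    past_diffs = [-0.1, 0.1, 0.3, 0.4, 0.5, 0.7, 0.9]

    paired_counter = 0
    diff_counter = {"acute": 0, "past": 0}

    def next_patient_id() -> str:
        nonlocal patient_counter
        patient_counter += 1
        return f"p{patient_counter:05d}"

    def add_app_episode(pid: str, slot: int, temp: float | None,
                        visit: bool, anti: bool, abx: bool) -> None:
        """Three diary entries with gaps of 26 h and 23 h (< 48 h)."""
        b = BASE + timedelta(days=SLOT_OFFSET + SLOT_DAYS * slot)
        t0 = b.replace(hour=8)
        t1 = b.replace(hour=10) + timedelta(days=1)
        t2 = b.replace(hour=9) + timedelta(days=2)
        entries.append(DiaryEntry(pid, t0, temperature=temp))
        entries.append(DiaryEntry(
            pid, t1, physician_visit=visit or None,
            antipyretic=anti or None, antibiotic=abx or None,
        ))
        entries.append(DiaryEntry(pid, t2, healthy_marker=True))

    def add_office_visit(patient_id: str, slot: int, kind: str,
                         temp: float | None, visit: bool, anti: bool, abx: bool,
                         day_in_slot: int) -> None:
        d = (BASE + timedelta(days=SLOT_OFFSET + SLOT_DAYS * slot + day_in_slot)).date()
        visits.append(office_visit_to_episode(
            patient_id=patient_id, visit_date=d, kind=kind,
            max_temperature=temp, physician_visit=visit,
            antipyretic=anti, antibiotic=abx,
        ))

    def realize_paired(pid: str, patient_id: str, slot: int, kind: str) -> None:
        nonlocal paired_counter
        v, a, x = visits_q.take(), anti_q.take(), abx_q.take()
        tq = temp_acute_q if kind == "acute" else temp_past_q
        tpat = tq.take()
        app_temp: float | None = round(38.5 + 0.1 * (paired_counter % 25), 1)
        if tpat == "eq":
            office_temp: float | None = app_temp
        elif tpat == "om":
            office_temp = None
        elif tpat == "am":
            office_temp, app_temp = round(39.0 + 0.1 * (paired_counter % 9), 1), None
        else:
            diffs = acute_diffs if kind == "acute" else past_diffs
            delta = diffs[diff_counter[kind] % len(diffs)]
            diff_counter[kind] += 1
            office_temp = round(app_temp - delta, 1)
        paired_counter += 1
        add_app_episode(pid, slot, app_temp, v[0] == "y", a[0] == "y", x[0] == "y")
        add_office_visit(
            patient_id, slot, kind, office_temp, v[1] == "y", a[1] == "y", x[1] == "y",
            day_in_slot=1 if kind == "acute" else 5,
        )

    def realize_app_only(pid: str, slot: int) -> None:
        temp = round(38.4 + 0.1 * (len(entries) % 20), 1) if ao_temp_q.take() == "present" else None
        add_app_episode(
            pid, slot, temp,
            ao_visit_q.take() == "y", ao_anti_q.take() == "y", ao_abx_q.take() == "y",
        )

    # ---- active-children token plan (668 children, see module docstring) ----
    # child j: paired kind PA (acute) if j < 424 else PP (past);
    # children 0..17 additionally carry a PP; app-only once for all,
    # twice for j in 18..115; office-only acute for j < 257.
    def child_tokens(j: int) -> list[str]:
        tokens = ["PA" if j < 424 else "PP"]
        if j < 18:
            tokens.append("PP")
        tokens.append("AO")
        if 18 <= j < 116:
            tokens.append("AO")
        if j < 257:
            tokens.append("OA")
        return tokens

    active_child = 0

    def add_comparable_child(fam_idx: int, fam: str, child_idx: int, *,
                             tokens: list[str] | None = None,
                             gender_error: bool = False,
                             dob_error: bool = False,
                             dob_missing: bool = False,
                             duplicate: bool = False) -> tuple[str, str]:
        """One child present in both sources; returns (app id, patient id)."""
        gender, month, year = _child_demo(fam_idx, child_idx)
        pid = f"f{fam_idx:03d}c{child_idx}"
        patient_id = next_patient_id()
        app_bmy: tuple[int, int] | None = (month, year)
        if dob_error:
            app_bmy = (month % 12 + 1, year)
        if dob_missing:
            app_bmy = None
        office_gender = gender
        if gender_error:
            office_gender = "male" if gender == "female" else "female"
        created = BASE - timedelta(days=10) + timedelta(minutes=fam_idx * 10 + child_idx)
        app_profiles.append(Profile(fam, pid, gender, app_bmy, created_at=created))
        patients.append(Profile(
            fam, patient_id, office_gender, (month, year),
            birth_date=date(year, month, 15),
        ))
        if duplicate:
            app_profiles.append(Profile(
                fam, pid + "d", gender, app_bmy,
                created_at=created + timedelta(hours=1),
            ))
        for slot, token in enumerate(tokens or []):
            if token == "PA":
                realize_paired(pid, patient_id, slot, "acute")
            elif token == "PP":
                realize_paired(pid, patient_id, slot, "past")
            elif token == "AO":
                realize_app_only(pid, slot)
            elif token == "OA":
                add_office_visit(patient_id, slot, "acute",
                                 round(39.0 + 0.1 * (patient_counter % 15), 1),
                                 True, False, False, day_in_slot=1)
            elif token == "OP":
                add_office_visit(patient_id, slot, "past",
                                 round(39.2 + 0.1 * (patient_counter % 9), 1),
                                 False, False, False, day_in_slot=5)
        return pid, patient_id

    def add_sibling(fam_idx: int, fam: str, n_episodes: int) -> None:
        pid = f"f{fam_idx:03d}s"
        app_profiles.append(Profile(
            fam, pid, "female" if fam_idx % 2 else "male",
            (1 + fam_idx % 12, 2006),
            created_at=BASE - timedelta(days=10) + timedelta(minutes=fam_idx * 10 + 7),
        ))
        for slot in range(n_episodes):
            add_app_episode(pid, slot, round(38.6 + 0.1 * (fam_idx % 10), 1),
                            False, False, False)

    # ---- group A: 534 families whose profiled children use the app ----
    for fam_idx in range(534):
        fam = _code(fam_idx)
        n_active = 2 if fam_idx < 134 else 1
        for child_idx in range(n_active):
            add_comparable_child(
                fam_idx, fam, child_idx,
                tokens=child_tokens(active_child),
                duplicate=300 <= fam_idx <= 304 and child_idx == 0 and fam_idx >= 134,
            )
            active_child += 1
        if 134 <= fam_idx < 144:  # a profiled child seen only at the office (past report)
            add_comparable_child(fam_idx, fam, 5, tokens=["OP"])
        if 144 <= fam_idx < 336:  # an episode-free second child
            add_comparable_child(
                fam_idx, fam, 6,
                gender_error=190 <= fam_idx < 196 or fam_idx == 207,
                dob_error=196 <= fam_idx < 207 or fam_idx == 207,
                dob_missing=208 <= fam_idx < 216,
            )
        if fam_idx < 50:  # a child never registered in the app
            n_eps = 1 if fam_idx < 35 else (2 if fam_idx < 45 else 6)
            gender, month, year = _child_demo(fam_idx, 9)
            patient_id = next_patient_id()
            patients.append(Profile(fam, patient_id, gender, (month, year),
                                    birth_date=date(year, month, 15)))
            for slot in range(n_eps):
                add_office_visit(patient_id, slot, "acute",
                                 round(38.9 + 0.1 * (fam_idx % 12), 1),
                                 True, False, False, day_in_slot=1)
        if 150 <= fam_idx < 169:  # non-patient sibling with app entries
            add_sibling(fam_idx, fam, 1 if fam_idx < 165 else 2)
        if fam_idx in (400, 401):  # adult (parent) profile
            app_profiles.append(Profile(
                fam, f"f{fam_idx:03d}a", "female", (6, 1985), is_adult=True,
                created_at=BASE - timedelta(days=10) + timedelta(minutes=fam_idx * 10 + 8),
            ))

    # ---- group B: 3 families with entries only for non-patient siblings ----
    for b in range(3):
        fam_idx = 534 + b
        fam = _code(fam_idx)
        add_comparable_child(fam_idx, fam, 0)  # episode-free profiled child
        add_sibling(fam_idx, fam, 2)

    # ---- group C: 139 profile-holding families without any app entry ----
    for c in range(139):
        fam_idx = 537 + c
        fam = _code(fam_idx)
        n_eps = 1 if c < 97 else (2 if c < 112 else (3 if c == 112 else 0))
        _, patient_id = add_comparable_child(fam_idx, fam, 0)
        for slot in range(n_eps):
            add_office_visit(patient_id, slot, "acute",
                             round(39.1 + 0.1 * (c % 10), 1),
                             True, False, False, day_in_slot=1)

    # ---- 3 families that installed the app but created no profiles ----
    for k in range(3):
        fam_idx = 676 + k
        fam = _code(fam_idx)
        gender, month, year = _child_demo(fam_idx, 0)
        patient_id = next_patient_id()
        patients.append(Profile(fam, patient_id, gender, (month, year),
                                birth_date=date(year, month, 15)))
        add_office_visit(patient_id, 0, "acute", 39.0, True, False, False, day_in_slot=1)

    # ---- 5 app families the office export could not identify (6 profiles) ----
    for k in range(5):
        fam_idx = 679 + k
        fam = _code(fam_idx)
        for child_idx in range(2 if k == 0 else 1):
            gender, month, year = _child_demo(fam_idx, child_idx)
            app_profiles.append(Profile(
                fam, f"f{fam_idx:03d}c{child_idx}", gender, (month, year),
                created_at=BASE - timedelta(days=10) + timedelta(minutes=fam_idx * 10),
            ))

    for q in (visits_q, anti_q, abx_q, temp_acute_q, temp_past_q,
              ao_visit_q, ao_anti_q, ao_abx_q, ao_temp_q):
        assert q.exhausted(), "pattern queue not fully consumed"
    assert len(app_profiles) == 1047, len(app_profiles)
    assert len(visits) == 1171, len(visits)
    assert paired_counter == 686

    return AppData(app_profiles, entries), OfficeData(patients, visits)
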