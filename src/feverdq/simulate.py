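"""Synthetic paired app/office cohorts with known ground truth.

The generator emulates the study's two data sources jointly. A cohort of
families with children experiences *true* fever episodes; each episode
is then observed — imperfectly and independently — by the two recording
channels:

* the app channel records an episode (with probability depending on
  whether the child was brought to the office acutely) as a cluster of
  2-6 diary entries with inter-entry gaps well below 48 h, and submits
  each variable with a per-variable probability;
* the office channel records an episode either as an *acute* visit
  during the episode or, with some probability, as a *past* report at a
  follow-up visit a few days after the episode ends.

Measurement noise and recall bias affect temperatures (past reports are
recalled from memory and biased upward), and demographic errors (gender
flips, month/year-of-birth errors, missing dates) plus structural
anomalies (synonymous duplicate profiles, non-patient siblings, adult
profiles, children never registered in the app) corrupt the linkage
surface exactly where the real pipeline has to cope with them.

Default parameter values emulate the study conditions: 676 families
observed for 16 months, an episode rate and acute/past/app-recording
probabilities back-solved from the cohort's episode accounting, and
per-variable submission probabilities approximating the observed
marginal response rates (the real per-variable probabilities are
unknown; these defaults are documented approximations).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, datetime, timedelta

import numpy as np
import pandas as pd

from .io import AppData, OfficeData, office_visit_to_episode
from .model import DiaryEntry, Profile

BASE_DATE = datetime(2020, 1, 1)

BINARY_VARS = ("physician_visit", "antipyretic", "antibiotic")


def _default_children_dist() -> dict[int, float]:
    return {1: 0.58, 2: 0.33, 3: 0.08, 4: 0.01}


def _default_p_submit() -> dict[tuple[str, str], float]:
    return {
        ("physician_visit", "app"): 0.60,
        ("physician_visit", "office"): 0.90,
        ("antipyretic", "app"): 0.65,
        ("antipyretic", "office"): 0.75,
        ("antibiotic", "app"): 0.55,
        ("antibiotic", "office"): 0.90,
        ("max_temperature", "app"): 0.97,
        ("max_temperature", "office_acute"): 0.85,
        ("max_temperature", "office_past"): 0.80,
    }


@dataclass(slots=True)
class GeneratorConfig:
    """Study conditions for one synthetic cohort. Same seed, same bytes."""

    seed: int = 0
    n_families: int = 676
    children_per_family: dict[int, float] = field(default_factory=_default_children_dist)
    observation_days: int = 487  # 16 months
    episode_rate: float = 2.0  # true episodes per child-year
    min_spacing_days: float = 9.0  # end-to-start gap keeping episodes separable

    # channel recording probabilities
    p_family_never_records: float = 0.21  # family installs the app, never enters
    p_office_visit_acute: float = 0.34  # episode leads to an acute office visit
    p_app_record_acute: float = 0.623  # app records an episode, given acute
    p_app_record: float = 0.777  # app records an episode, given not acute
    p_office_report_past: float = 0.253  # past report, given app-recorded & not acute
    p_office_report_past_noapp: float = 0.04  # past report, given unrecorded & not acute
    p_visit_other: float = 0.10  # non-acute episode still saw some physician

    # per-episode true state
    p_antipyretic: float = 0.55
    p_antibiotic: float = 0.08
    p_submit: dict[tuple[str, str], float] = field(default_factory=_default_p_submit)

    # temperatures (degC)
    true_temp_mode: float = 39.2
    true_temp_sd: float = 0.6
    true_temp_min: float = 38.0
    true_temp_max: float = 42.4
    app_temp_noise_sd: float = 0.3
    office_temp_noise_sd_acute: float = 0.2
    office_temp_noise_sd_past: float = 0.3
    office_past_recall_bias: float = 0.4  # past reports recalled upward

    # demographic error rates
    p_gender_error: float = 0.007
    p_dob_error: float = 0.012
    p_dob_missing: float = 0.008

    # structural anomaly rates
    p_duplicate_profile: float = 0.005  # per child
    p_sibling_not_patient: float = 0.03  # per family
    p_adult_profile: float = 0.003  # per family
    p_child_unregistered: float = 0.07  # per family with >= 2 children

    def validate(self) -> None:
        probs = [
            self.p_family_never_records,
            self.p_office_visit_acute, self.p_app_record_acute, self.p_app_record,
            self.p_office_report_past, self.p_office_report_past_noapp, self.p_visit_other,
            self.p_antipyretic, self.p_antibiotic, self.p_gender_error, self.p_dob_error,
            self.p_dob_missing, self.p_duplicate_profile, self.p_sibling_not_patient,
            self.p_adult_profile, self.p_child_unregistered,
            *self.p_submit.values(), *self.children_per_family.values(),
        ]
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("all probabilities must lie in [0, 1]")
        if abs(sum(self.children_per_family.values()) - 1.0) > 1e-9:
            raise ValueError("children_per_family must sum to 1")
        if self.episode_rate <= 0 or self.observation_days <= 0:
            raise ValueError("episode_rate and observation_days must be positive")


@dataclass(slots=True)
class GroundTruth:
    """What actually happened, for validating every pipeline stage."""

    profile_map: dict[str, str]  # app profile id -> office patient id
    episodes: pd.DataFrame  # one row per true episode

    @property
    def n_app_episodes(self) -> int:
        return int(self.episodes["app_recorded"].sum())

    @property
    def n_office_episodes(self) -> int:
        return int((self.episodes["office_kind"] != "none").sum())

    @property
    def n_paired(self) -> int:
        return int(
            (self.episodes["app_recorded"] & (self.episodes["office_kind"] != "none")).sum()
        )


def _truncnorm(rng: np.random.Generator, mode: float, sd: float, lo: float, hi: float) -> float:
    for _ in range(100):
        v = rng.normal(mode, sd)
        if lo <= v <= hi:
            return v
    return mode


def _round01(v: float) -> float:
    return round(max(34.1, min(43.4, v)), 1)


def _family_code(rng: np.random.Generator, taken: set[str]) -> str:
    while True:
        code = "".join(chr(97 + int(x)) for x in rng.integers(0, 26, 8))
        if code not in taken:
            taken.add(code)
            return code


def _submit_flag(rng, true_value: bool, q: float) -> bool | None:
    """Ternary channel: true -> yes w.p. q else missing; false -> explicit
    no w.p. q else missing. Either way negation coercion yields the truth
    for false values."""
    if true_value:
        return True if rng.random() < q else None
    return False if rng.random() < q else None


def generate(config: GeneratorConfig) -> tuple[AppData, OfficeData, GroundTruth]:
    """Generate one synthetic cohort: (app export, office export, ground truth)."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    taken_codes: set[str] = set()

    app_profiles: list[Profile] = []
    entries: list[DiaryEntry] = []
    office_patients: list[Profile] = []
    visits = []
    profile_map: dict[str, str] = {}
    truth_rows: list[dict] = []
    patient_counter = 0

    kid_counts = np.array(sorted(config.children_per_family))
    kid_probs = np.array([config.children_per_family[k] for k in kid_counts])

    for fam_idx in range(config.n_families):
        fam = _family_code(rng, taken_codes)
        registered_at = BASE_DATE - timedelta(days=1) + timedelta(minutes=fam_idx)
        family_records = rng.random() >= config.p_family_never_records
        n_children = int(rng.choice(kid_counts, p=kid_probs))
        unregistered_child = (
            n_children >= 2 and rng.random() < config.p_child_unregistered
        )

        used_demo: set[tuple] = set()
        for child_idx in range(n_children):
            # distinct (gender, month, year) within a family: otherwise the
            # children are genuinely indistinguishable to the linkage rule
            # and would collapse as synonymous duplicates
            while True:
                gender = "female" if rng.random() < 0.5 else "male"
                birth_year = int(rng.integers(2006, 2021))
                birth_month = int(rng.integers(1, 13))
                if (gender, birth_month, birth_year) not in used_demo:
                    used_demo.add((gender, birth_month, birth_year))
                    break
            birth_day = int(rng.integers(1, 29))
            patient_counter += 1
            patient_id = f"p{patient_counter:05d}"
            office_gender = gender
            if rng.random() < config.p_gender_error:
                office_gender = "male" if gender == "female" else "female"
            office_patients.append(Profile(
                family_code=fam, profile_id=patient_id, gender=office_gender,
                birth_month_year=(birth_month, birth_year),
                birth_date=date(birth_year, birth_month, birth_day),
            ))

            in_app = not (unregistered_child and child_idx == n_children - 1)
            app_pid = None
            if in_app:
                app_pid = f"a{fam_idx:04d}c{child_idx}"
                u = rng.random()
                if u < config.p_dob_missing:
                    bmy = None
                elif u < config.p_dob_missing + config.p_dob_error:
                    shift = 1 if birth_month < 12 else -1
                    bmy = (birth_month + shift, birth_year)
                else:
                    bmy = (birth_month, birth_year)
                app_profiles.append(Profile(
                    family_code=fam, profile_id=app_pid, gender=gender,
                    birth_month_year=bmy, created_at=registered_at,
                ))
                profile_map[app_pid] = patient_id
                if bmy is not None and rng.random() < config.p_duplicate_profile:
                    app_profiles.append(Profile(
                        family_code=fam, profile_id=app_pid + "d", gender=gender,
                        birth_month_year=bmy,
                        created_at=registered_at + timedelta(hours=2),
                    ))

            _simulate_child_episodes(
                rng, config, fam, app_pid, patient_id, entries, visits, truth_rows,
                family_records=family_records,
            )

        if rng.random() < config.p_sibling_not_patient:
            sib_pid = f"a{fam_idx:04d}s"
            app_profiles.append(Profile(
                family_code=fam, profile_id=sib_pid,
                gender="female" if rng.random() < 0.5 else "male",
                birth_month_year=(int(rng.integers(1, 13)), int(rng.integers(2006, 2021))),
                created_at=registered_at,
            ))
            # sibling episodes exist only on the app side
            _simulate_child_episodes(
                rng, config, fam, sib_pid, None, entries, visits, truth_rows,
                family_records=family_records,
            )
        if rng.random() < config.p_adult_profile:
            app_profiles.append(Profile(
                family_code=fam, profile_id=f"a{fam_idx:04d}x",
                gender="female" if rng.random() < 0.5 else "male",
                birth_month_year=(int(rng.integers(1, 13)), int(rng.integers(1975, 1996))),
                is_adult=True, created_at=registered_at,
            ))

    truth = GroundTruth(
        profile_map=profile_map,
        episodes=pd.DataFrame(
            truth_rows,
            columns=[
                "family_code", "app_profile_id", "patient_id", "episode_index",
                "start_day", "end_day", "app_recorded", "office_kind",
                "visit_true", "antipyretic_true", "antibiotic_true", "true_temp",
                "app_visit", "app_antipyretic", "app_antibiotic", "app_temp",
                "office_visit", "office_antipyretic", "office_antibiotic", "office_temp",
            ],
        ),
    )
    return AppData(app_profiles, entries), OfficeData(office_patients, visits), truth


def _simulate_child_episodes(
    rng: np.random.Generator,
    config: GeneratorConfig,
    fam: str,
    app_pid: str | None,
    patient_id: str | None,
    entries: list[DiaryEntry],
    visits: list,
    truth_rows: list[dict],
    family_records: bool = True,
) -> None:
    mean_gap = max(1.0, 365.0 / config.episode_rate - config.min_spacing_days)
    t = config.min_spacing_days + rng.exponential(mean_gap)
    ep_index = 0
    while True:
        n_entries = 2 + min(4, int(rng.poisson(1.5)))
        gaps_h = rng.uniform(4.0, 28.0, n_entries - 1)
        span_days = float(gaps_h.sum()) / 24.0
        if t + span_days > config.observation_days - 6:
            break

        acute = rng.random() < config.p_office_visit_acute
        if acute:
            app_recorded = rng.random() < config.p_app_record_acute
        else:
            app_recorded = rng.random() < config.p_app_record
        app_recorded = app_recorded and app_pid is not None and family_records

        if patient_id is None:
            office_kind = "none"
        elif acute:
            office_kind = "acute"
        else:
            p_past = (
                config.p_office_report_past if app_recorded
                else config.p_office_report_past_noapp
            )
            office_kind = "past" if rng.random() < p_past else "none"

        visit_true = acute or rng.random() < config.p_visit_other
        antipyretic_true = rng.random() < config.p_antipyretic
        antibiotic_true = rng.random() < config.p_antibiotic
        true_temp = _round01(_truncnorm(
            rng, config.true_temp_mode, config.true_temp_sd,
            config.true_temp_min, config.true_temp_max,
        ))

        row: dict = {
            "family_code": fam, "app_profile_id": app_pid, "patient_id": patient_id,
            "episode_index": ep_index, "start_day": t, "end_day": t + span_days,
            "app_recorded": app_recorded, "office_kind": office_kind,
            "visit_true": visit_true, "antipyretic_true": antipyretic_true,
            "antibiotic_true": antibiotic_true, "true_temp": true_temp,
            "app_visit": None, "app_antipyretic": None, "app_antibiotic": None,
            "app_temp": None, "office_visit": None, "office_antipyretic": None,
            "office_antibiotic": None, "office_temp": None,
        }

        start_dt = BASE_DATE + timedelta(days=t, hours=float(rng.uniform(7, 11)))
        times = [start_dt]
        for g in gaps_h:
            times.append(times[-1] + timedelta(hours=float(g)))

        if app_recorded:
            flags = {
                var: _submit_flag(
                    rng,
                    {"physician_visit": visit_true,
                     "antipyretic": antipyretic_true,
                     "antibiotic": antibiotic_true}[var],
                    config.p_submit[(var, "app")],
                )
                for var in BINARY_VARS
            }
            temp = None
            if rng.random() < config.p_submit[("max_temperature", "app")]:
                temp = _round01(true_temp + rng.normal(0.0, config.app_temp_noise_sd))
            carrier = {var: int(rng.integers(0, n_entries)) for var in BINARY_VARS}
            temp_carrier = int(rng.integers(0, n_entries))
            for i, ts in enumerate(times):
                entries.append(DiaryEntry(
                    profile_id=app_pid,  # type: ignore[arg-type]
                    occurred_at=ts.replace(second=0, microsecond=0),
                    temperature=temp if i == temp_carrier else None,
                    physician_visit=flags["physician_visit"] if i == carrier["physician_visit"] else None,
                    antipyretic=flags["antipyretic"] if i == carrier["antipyretic"] else None,
                    antibiotic=flags["antibiotic"] if i == carrier["antibiotic"] else None,
                    healthy_marker=i == n_entries - 1 and rng.random() < 0.4,
                ))
            row["app_visit"] = flags["physician_visit"]
            row["app_antipyretic"] = flags["antipyretic"]
            row["app_antibiotic"] = flags["antibiotic"]
            row["app_temp"] = temp

        if office_kind != "none":
            if office_kind == "acute":
                visit_day = t + rng.uniform(0.0, span_days)
                office_visit_flag: bool | None = True
                q_temp = config.p_submit[("max_temperature", "office_acute")]
                bias, sd = 0.0, config.office_temp_noise_sd_acute
            else:
                visit_day = t + span_days + rng.uniform(2.0, 5.0)
                office_visit_flag = _submit_flag(
                    rng, visit_true, config.p_submit[("physician_visit", "office")]
                )
                q_temp = config.p_submit[("max_temperature", "office_past")]
                bias, sd = config.office_past_recall_bias, config.office_temp_noise_sd_past
            office_temp = None
            if rng.random() < q_temp:
                office_temp = _round01(true_temp + bias + rng.normal(0.0, sd))
            office_anti = _submit_flag(
                rng, antipyretic_true, config.p_submit[("antipyretic", "office")]
            )
            office_abx = _submit_flag(
                rng, antibiotic_true, config.p_submit[("antibiotic", "office")]
            )
            visits.append(office_visit_to_episode(
                patient_id=patient_id,  # type: ignore[arg-type]
                visit_date=(BASE_DATE + timedelta(days=visit_day)).date(),
                kind=office_kind,
                max_temperature=office_temp,
                physician_visit=office_visit_flag,
                antipyretic=office_anti,
                antibiotic=office_abx,
            ))
            row["office_visit"] = office_visit_flag
            row["office_antipyretic"] = office_anti
            row["office_antibiotic"] = office_abx
            row["office_temp"] = office_temp

        truth_rows.append(row)
        ep_index += 1
        t = t + span_days + config.min_spacing_days + rng.exponential(mean_gap)


def _prob_rounded_equal(sd_a: float, sd_b: float, bias: float) -> float:
    """P(round(T+ea, 0.1) == round(T+b+eb, 0.1)) for grid-valued T."""
    from scipy.stats import norm

    grid = np.arange(-5.0, 5.0 + 1e-9, 0.1)
    if sd_a == 0.0:
        pa = (np.abs(grid) < 0.05).astype(float)
    else:
        pa = norm.cdf((grid + 0.05) / sd_a) - norm.cdf((grid - 0.05) / sd_a)
    if sd_b == 0.0:
        pb = (np.abs(grid - bias) < 0.05).astype(float)
    else:
        pb = norm.cdf((grid + 0.05 - bias) / sd_b) - norm.cdf((grid - 0.05 - bias) / sd_b)
    return float(np.sum(pa * pb))


def binary_agreement_probability(prevalence: float, q_app: float, q_office: float) -> float:
    """Coercion algebra for one binary flag.

    A true "yes" is submitted independently by each channel; anything
    not submitted "yes" coerces to "no", and false flags are never
    submitted as "yes". Agreement therefore fails only when exactly one
    channel submits a true "yes"."""
    return 1.0 - prevalence * (q_app * (1.0 - q_office) + q_office * (1.0 - q_app))


def expected_dqi(config: GeneratorConfig) -> dict[str, float]:
    """Analytic expected concordance per variable among paired episodes.

    Also carries expected demographic concordance/completeness. Ignores
    the (rare, default ~0.1%) mispairings possible when an unrecorded
    episode's past report falls inside another episode's window.
    """
    config.validate()
    f_acute = config.p_office_visit_acute * config.p_app_record_acute
    f_past = (
        (1.0 - config.p_office_visit_acute)
        * config.p_app_record
        * config.p_office_report_past
    )
    total = f_acute + f_past
    if total == 0:
        raise ValueError("configuration admits no paired episodes")
    f_acute, f_past = f_acute / total, f_past / total

    qa_v = config.p_submit[("physician_visit", "app")]
    qo_v = config.p_submit[("physician_visit", "office")]
    e_visit = f_acute * qa_v + f_past * (
        (1.0 - config.p_visit_other)
        + config.p_visit_other * (qa_v * qo_v + (1.0 - qa_v) * (1.0 - qo_v))
    )

    e_anti = binary_agreement_probability(
        config.p_antipyretic,
        config.p_submit[("antipyretic", "app")],
        config.p_submit[("antipyretic", "office")],
    )
    e_abx = binary_agreement_probability(
        config.p_antibiotic,
        config.p_submit[("antibiotic", "app")],
        config.p_submit[("antibiotic", "office")],
    )

    qa_t = config.p_submit[("max_temperature", "app")]
    e_temp = qa_t * (
        f_acute
        * config.p_submit[("max_temperature", "office_acute")]
        * _prob_rounded_equal(
            config.app_temp_noise_sd, config.office_temp_noise_sd_acute, 0.0
        )
        + f_past
        * config.p_submit[("max_temperature", "office_past")]
        * _prob_rounded_equal(
            config.app_temp_noise_sd,
            config.office_temp_noise_sd_past,
            config.office_past_recall_bias,
        )
    )

    return {
        "physician_visit": e_visit,
        "antipyretic": e_anti,
        "antibiotic": e_abx,
        "max_temperature": e_temp,
        "gender": 1.0 - config.p_gender_error,
        "date_of_birth": 1.0 - config.p_dob_error,
        "date_of_birth_completeness": 1.0 - config.p_dob_missing,
    }
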