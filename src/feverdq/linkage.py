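"""Deterministic linkage of app profiles to office patients.

Identifiers differ between the sources (random strings in the app,
sequential numbers in the office), so profiles are linked within each
shared family code using the children's gender and date of birth. The
app stores only month and year of birth, so dates are compared at
month/year granularity.

Linkage proceeds per family:

1. adult app profiles are set aside (the registry compares children);
2. synonymous duplicate profiles — identical (gender, month/year of
   birth) within one family, created when two caregivers register the
   same child on two devices before synchronization — collapse to the
   earliest-created canonical profile;
3. remaining app children are matched one-to-one to office patients,
   maximizing the number of matched pairs, preferring full
   (gender AND date-of-birth) agreement over partial (gender OR
   date-of-birth) agreement, then earlier office registration;
4. if exactly one app child and one office patient remain unmatched in
   a family, they are linked regardless of demographic agreement (the
   study adjudicated such cases by name, which is unavailable here;
   this fallback is what allows a matched pair to disagree on both
   fields);
5. leftovers become app-only siblings (children the office never saw)
   or office-only patients (children never registered in the app).

Which source is *correct* on a mismatch is deliberately not decided;
mismatches are reported symmetrically.
"""

from __future__ import annotations

from collections import defaultdict

import numpy as np

from .assignment import BASE_WEIGHT, max_weight_pairs
from .model import (
    APP_ONLY_ADULT,
    APP_ONLY_SIBLING,
    MATCHED,
    OFFICE_ONLY,
    SYNONYMOUS_DUPLICATE,
    Profile,
    ProfileLink,
)


class LinkageError(ValueError):
    pass


def detect_synonymous_profiles(profiles: list[Profile]) -> list[list[Profile]]:
    """Duplicate groups within one family: identical (gender, month/year).

    Each returned group has >= 2 profiles; the earliest-created profile
    is first and canonical. Profiles without a date of birth never group.
    """
    families = {p.family_code for p in profiles}
    if len(families) > 1:
        raise LinkageError("synonymous detection operates on one family")
    by_key: dict[tuple, list[Profile]] = defaultdict(list)
    for p in profiles:
        if p.is_adult or p.birth_month_year is None:
            continue
        by_key[(p.gender, p.birth_month_year)].append(p)
    groups = []
    for key in sorted(by_key, key=str):
        members = by_key[key]
        if len(members) > 1:
            members.sort(key=lambda p: (p.created_at or p.profile_id, p.profile_id))
            groups.append(members)
    return groups


def _gender_agrees(app: Profile, office: Profile) -> bool:
    # App offers three answer options, the office two; "diverse" can
    # never auto-match an office value.
    return app.gender == office.gender


def _dob_agrees(app: Profile, office: Profile) -> bool:
    return (
        app.birth_month_year is not None
        and office.birth_month_year is not None
        and app.birth_month_year == office.birth_month_year
    )


def _match_family(
    app_children: list[Profile], office_patients: list[Profile]
) -> tuple[list[tuple[Profile, Profile]], list[Profile], list[Profile]]:
    """One family's one-to-one matching; returns (pairs, app_rest, office_rest)."""
    app_children = sorted(app_children, key=lambda p: p.profile_id)
    office_patients = sorted(office_patients, key=lambda p: p.profile_id)
    n_a, n_o = len(app_children), len(office_patients)
    w = np.zeros((n_a, n_o))
    for i, a in enumerate(app_children):
        for j, o in enumerate(office_patients):
            g, d = _gender_agrees(a, o), _dob_agrees(a, o)
            if g or d:
                # full agreement outranks partial; earlier office
                # registration (list order) breaks remaining ties
                w[i, j] = BASE_WEIGHT + (1000.0 if g and d else 100.0) - j * 0.001
    pairs_idx = max_weight_pairs(w)
    pairs = [(app_children[i], office_patients[j]) for i, j in pairs_idx]
    used_a = {i for i, _ in pairs_idx}
    used_o = {j for _, j in pairs_idx}
    rest_a = [p for i, p in enumerate(app_children) if i not in used_a]
    rest_o = [p for j, p in enumerate(office_patients) if j not in used_o]
    if len(rest_a) == 1 and len(rest_o) == 1:
        # sole-remaining fallback: one child on each side can only be
        # each other, even if both demographic fields disagree
        pairs.append((rest_a[0], rest_o[0]))
        rest_a, rest_o = [], []
    return pairs, rest_a, rest_o


def compare_demographics(link: ProfileLink) -> frozenset[str]:
    """Classify demographic agreement of a matched link.

    Returns a subset of {"gender", "date_of_birth", "dob_missing"}.
    A missing app date of birth is counted as incomplete
    (``dob_missing``), not discordant.
    """
    if link.status != MATCHED:
        raise LinkageError("compare_demographics requires a matched link")
    app, office = link.app_profile, link.office_patient
    assert app is not None and office is not None
    out = set()
    if app.gender != office.gender:
        out.add("gender")
    if app.birth_month_year is None:
        out.add("dob_missing")
    elif app.birth_month_year != office.birth_month_year:
        out.add("date_of_birth")
    return frozenset(out)


def link_profiles(
    app_profiles: list[Profile], office_patients: list[Profile], strict: bool = False
) -> list[ProfileLink]:
    """Link the two sources; every input profile lands in exactly one link."""
    app_by_family: dict[str, list[Profile]] = defaultdict(list)
    for p in app_profiles:
        app_by_family[p.family_code].append(p)
    office_by_family: dict[str, list[Profile]] = defaultdict(list)
    for p in office_patients:
        office_by_family[p.family_code].append(p)

    links: list[ProfileLink] = []
    for fam in sorted(set(app_by_family) | set(office_by_family)):
        fam_app = app_by_family.get(fam, [])
        fam_office = office_by_family.get(fam, [])
        if fam_app and not fam_office and strict:
            raise LinkageError(f"family {fam} present in app but not office")

        adults = [p for p in fam_app if p.is_adult]
        children = [p for p in fam_app if not p.is_adult]
        for a in adults:
            links.append(ProfileLink(a, None, APP_ONLY_ADULT))

        canonical = list(children)
        for group in detect_synonymous_profiles(children):
            head = group[0]
            for dup in group[1:]:
                links.append(ProfileLink(
                    dup, None, SYNONYMOUS_DUPLICATE, canonical_profile_id=head.profile_id,
                ))
                canonical.remove(dup)

        pairs, rest_a, rest_o = _match_family(canonical, fam_office)
        for a, o in pairs:
            link = ProfileLink(a, o, MATCHED)
            link.mismatches = compare_demographics(link)
            links.append(link)
        for a in rest_a:
            links.append(ProfileLink(a, None, APP_ONLY_SIBLING))
        for o in rest_o:
            links.append(ProfileLink(None, o, OFFICE_ONLY))
    return links


def demographic_dqi(links: list[ProfileLink]) -> dict[str, dict]:
    """Profile-level completeness and concordance for gender and date of birth.

    Completeness = submitted / matched; concordance = (matched -
    mismatched) / matched, with missing dates counted as incomplete
    rather than discordant.
    """
    from .stats import completeness_rate, concordance_rate

    matched = [l for l in links if l.status == MATCHED]
    if not matched:
        raise LinkageError("no matched links")
    n = len(matched)
    gender_mismatch = sum(1 for l in matched if "gender" in l.mismatches)
    dob_mismatch = sum(1 for l in matched if "date_of_birth" in l.mismatches)
    dob_missing = sum(1 for l in matched if "dob_missing" in l.mismatches)
    return {
        "gender": {
            "completeness": completeness_rate(n, n, "gender", level="profile"),
            "concordance": concordance_rate(n - gender_mismatch, n, "gender", level="profile"),
            "mismatches": gender_mismatch,
        },
        "date_of_birth": {
            "completeness": completeness_rate(n - dob_missing, n, "date_of_birth", level="profile"),
            "concordance": concordance_rate(n - dob_mismatch, n, "date_of_birth", level="profile"),
            "mismatches": dob_mismatch,
        },
    }
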