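"""End-to-end pipeline orchestration and report rendering.

``run_pipeline`` wires the stages together — validation, duplicate
collapsing, segmentation, linkage, episode matching — and computes every
reported quantity: the three-level accounting (families, profiles,
episodes), demographic DQIs, the per-variable response/agreement
matrix, completeness and concordance tables with exact CIs, the
cross-registry Venn partition, the acute-versus-past temperature
agreement chi-square, temperature-difference summaries with the
Mann-Whitney test, per-unit episode-count differences, and
duration-of-use statistics.

The report is a plain nested dict rendered either as JSON (fixed key
order, no timestamps: byte-identical across runs on the same inputs)
or as human-readable text tables.
"""

from __future__ import annotations

import dataclasses
import json
import re
from collections import defaultdict
from dataclasses import dataclass, field

from .io import AppData, OfficeData
from .linkage import demographic_dqi, link_profiles
from .matching import (
    MatchingConfig,
    group_episodes_by_profile,
    match_episodes,
    temperature_difference,
    venn_partition,
)
from .model import (
    AGREE,
    MATCHED,
    OFFICE_ONLY,
    SYNONYMOUS_DUPLICATE,
    APP_ONLY_ADULT,
    APP_ONLY_SIBLING,
    DiaryEntry,
    DQIResult,
    EpisodeMatch,
    validate_dataset,
)
from .segmentation import (
    SegmentationConfig,
    count_differences_summary,
    episode_count_difference,
    healthy_marker_conflicts,
    segment_entries,
)
from .stats import (
    ContingencyTable2x2,
    chi_square_yates,
    completeness_rate,
    concordance_rate,
    format_p,
    mann_whitney,
    median_iqr,
    threshold_check,
)

BINARY_VARS = ("physician_visit", "antipyretic", "antibiotic")
ALL_VARS = BINARY_VARS + ("max_temperature",)


@dataclass(slots=True)
class PipelineConfig:
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    matching: MatchingConfig = field(default_factory=MatchingConfig)
    threshold: float = 0.95
    strict: bool = False


@dataclass(slots=True)
class AnalysisReport:
    payload: dict
    links: list = field(default_factory=list, repr=False)
    matches_by_profile: dict = field(default_factory=dict, repr=False)
    warnings: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return self.payload

    def to_json(self) -> str:
        return json.dumps(self.payload, indent=2)


def _dqi_dict(d: DQIResult) -> dict:
    return {
        "variable": d.variable, "indicator": d.indicator, "k": d.k, "n": d.n,
        "rate": d.rate, "rate_pct": round(100 * d.rate, 2),
        "ci_low": d.ci_low, "ci_high": d.ci_high,
        "ci_low_pct": round(100 * d.ci_low, 1), "ci_high_pct": round(100 * d.ci_high, 1),
        "level": d.level,
    }


def run_pipeline(
    app: AppData, office: OfficeData, config: PipelineConfig = PipelineConfig()
) -> AnalysisReport:
    """Run every stage on one paired export and assemble the report."""
    warnings: list[str] = []
    violations = validate_dataset(app.profiles, app.entries, source="app")
    violations += validate_dataset(office.patients, office.visits, source="office")

    links = link_profiles(app.profiles, office.patients, strict=config.strict)

    # synonymous duplicates are the same child twice: fold their diary
    # entries onto the canonical profile before segmentation
    canonical_of = {
        l.app_profile.profile_id: l.canonical_profile_id
        for l in links
        if l.status == SYNONYMOUS_DUPLICATE and l.app_profile is not None
    }
    entries = [
        dataclasses.replace(e, profile_id=canonical_of[e.profile_id])
        if e.profile_id in canonical_of else e
        for e in app.entries
    ]

    entries_by_profile: dict[str, list[DiaryEntry]] = defaultdict(list)
    for e in entries:
        entries_by_profile[e.profile_id].append(e)
    app_eps_by_profile = {
        pid: segment_entries(es, config.segmentation)
        for pid, es in sorted(entries_by_profile.items())
    }
    office_eps_by_patient = group_episodes_by_profile(office.visits)

    matched_links = [l for l in links if l.status == MATCHED]
    matches_by_profile: dict[str, list[EpisodeMatch]] = {}
    for link in matched_links:
        assert link.app_profile is not None and link.office_patient is not None
        matches_by_profile[link.app_profile.profile_id] = match_episodes(
            app_eps_by_profile.get(link.app_profile.profile_id, []),
            office_eps_by_patient.get(link.office_patient.profile_id, []),
            config.matching,
        )

    venn = venn_partition(links, matches_by_profile, app_eps_by_profile, office_eps_by_patient)

    paired = [m for ms in matches_by_profile.values() for m in ms if m.is_paired]
    if not paired:
        warnings.append("no comparable episodes between the sources")

    # --- response/agreement matrix over the paired subset ---
    agreement: dict[str, dict] = {}
    for var in BINARY_VARS:
        app_yes = sum(1 for m in paired if getattr(m.app_episode, var))
        office_yes = sum(1 for m in paired if getattr(m.office_episode, var))
        agree_yes = sum(
            1 for m in paired if m.agreement[var] == AGREE and getattr(m.app_episode, var)
        )
        agree_no = sum(
            1 for m in paired if m.agreement[var] == AGREE and not getattr(m.app_episode, var)
        )
        agreement[var] = {
            "app_yes": app_yes, "office_yes": office_yes,
            "agree_yes": agree_yes, "agree_no": agree_no,
            "agreements": agree_yes + agree_no,
        }
    temp_agree = sum(1 for m in paired if m.agreement["max_temperature"] == AGREE)
    agreement["max_temperature"] = {
        "app_answered": sum(1 for m in paired if m.app_episode.max_temperature is not None),
        "office_answered": sum(1 for m in paired if m.office_episode.max_temperature is not None),
        "agreements": temp_agree,
    }

    n_paired = len(paired)
    n_office = venn.office_profiled
    n_app = venn.app_identifiable

    concordance = {}
    completeness_vs_office = {}
    completeness_vs_app = {}
    if n_paired and n_office and n_app:
        for var in ALL_VARS:
            k = agreement[var]["agreements"]
            concordance[var] = _dqi_dict(concordance_rate(k, n_paired, var))
            completeness_vs_office[var] = _dqi_dict(completeness_rate(k, n_office, var))
            completeness_vs_app[var] = _dqi_dict(completeness_rate(k, n_app, var))

    # --- acute vs past temperature agreement ---
    acute = [m for m in paired if m.office_episode.office_kind == "acute"]
    past = [m for m in paired if m.office_episode.office_kind == "past"]
    acute_agree = sum(1 for m in acute if m.agreement["max_temperature"] == AGREE)
    past_agree = sum(1 for m in past if m.agreement["max_temperature"] == AGREE)
    acute_vs_past: dict = {
        "acute_paired": len(acute), "acute_temp_agreements": acute_agree,
        "past_paired": len(past), "past_temp_agreements": past_agree,
    }
    if acute and past and acute_agree + past_agree > 0:
        table = ContingencyTable2x2(
            acute_agree, len(acute) - acute_agree, past_agree, len(past) - past_agree
        )
        try:
            stat, df, p = chi_square_yates(table)
            acute_vs_past.update({"chi_square": stat, "df": df, "p": p, "p_text": format_p(p)})
        except ValueError:
            warnings.append("degenerate acute/past agreement table; chi-square skipped")

    # --- temperature differences (app minus office) ---
    temp_diff: dict = {}
    diffs = {"acute": [], "past": []}
    for m in paired:
        d = temperature_difference(m)
        if d is not None:
            diffs[m.office_episode.office_kind].append(d)
    for kind, vals in diffs.items():
        if vals:
            med, q1, q3, lo, hi = median_iqr(vals)
            temp_diff[kind] = {
                "n": len(vals), "median": med, "q1": q1, "q3": q3, "min": lo, "max": hi,
            }
    if diffs["acute"] and diffs["past"]:
        u, p = mann_whitney(diffs["acute"], diffs["past"])
        temp_diff["mann_whitney_u"] = u
        temp_diff["mann_whitney_p"] = p
        temp_diff["mann_whitney_p_text"] = format_p(p)

    # --- per-episode temperature summaries per source ---
    temp_summary = {}
    app_temps = [
        e.max_temperature
        for eps in app_eps_by_profile.values() for e in eps
        if e.max_temperature is not None
    ]
    if app_temps:
        med, q1, q3, lo, hi = median_iqr(app_temps)
        temp_summary["app"] = {"median": med, "q1": q1, "q3": q3, "min": lo, "max": hi}
    for kind in ("acute", "past"):
        temps = [
            e.max_temperature
            for eps in office_eps_by_patient.values() for e in eps
            if e.office_kind == kind and e.max_temperature is not None
        ]
        if temps:
            med, q1, q3, lo, hi = median_iqr(temps)
            temp_summary[f"office_{kind}"] = {
                "median": med, "q1": q1, "q3": q3, "min": lo, "max": hi,
            }

    # --- accounting at the three levels ---
    office_families = {p.family_code for p in office.patients}
    app_families = {p.family_code for p in app.profiles}
    unident_profiles = [p for p in app.profiles if p.family_code not in office_families]
    fam_of_profile = {p.profile_id: p.family_code for p in app.profiles}
    families_with_entries = {
        fam_of_profile[pid] for pid, eps in app_eps_by_profile.items() if eps
    }
    accounting = {
        "app_families": len(app_families),
        "app_profiles": len(app.profiles),
        "unidentifiable_families": len({p.family_code for p in unident_profiles}),
        "unidentifiable_family_profiles": len(unident_profiles),
        "siblings": sum(
            1 for l in links
            if l.status == APP_ONLY_SIBLING and l.app_profile.family_code in office_families
        ),
        "adults": sum(1 for l in links if l.status == APP_ONLY_ADULT),
        "synonymous_duplicates": sum(1 for l in links if l.status == SYNONYMOUS_DUPLICATE),
        "comparable_profiles": len(matched_links),
        "office_only_children": sum(1 for l in links if l.status == OFFICE_ONLY),
        "families_with_app_entries": len(families_with_entries),
        "healthy_marker_conflicts": sum(
            healthy_marker_conflicts(es, config.segmentation)
            for es in entries_by_profile.values()
        ),
    }

    # --- demographic DQIs ---
    demographic: dict = {}
    if matched_links:
        raw = demographic_dqi(links)
        for var, block in raw.items():
            demographic[var] = {
                "completeness": _dqi_dict(block["completeness"]),
                "concordance": _dqi_dict(block["concordance"]),
                "mismatches": block["mismatches"],
            }
    else:
        warnings.append("no matched profiles; demographic DQIs skipped")

    # --- episode-count differences per family and per profile ---
    app_counts_profile = {
        l.app_profile.profile_id: len(app_eps_by_profile.get(l.app_profile.profile_id, []))
        for l in matched_links
    }
    office_counts_profile = {
        l.app_profile.profile_id: len(office_eps_by_patient.get(l.office_patient.profile_id, []))
        for l in matched_links
    }
    profile_diffs = episode_count_difference(app_counts_profile, office_counts_profile)
    fam_app: dict[str, int] = defaultdict(int)
    fam_office: dict[str, int] = defaultdict(int)
    for l in matched_links:
        fam = l.app_profile.family_code
        fam_app[fam] += app_counts_profile[l.app_profile.profile_id]
        fam_office[fam] += office_counts_profile[l.app_profile.profile_id]
    family_diffs = episode_count_difference(dict(fam_app), dict(fam_office))
    episode_counts = {
        "profile_difference_histogram": {
            str(k): v for k, v in count_differences_summary(profile_diffs).items()
        },
        "family_difference_histogram": {
            str(k): v for k, v in count_differences_summary(family_diffs).items()
        },
    }

    # --- duration of app use per family (days between first and last entry) ---
    fam_span: dict[str, list] = defaultdict(list)
    for pid, es in entries_by_profile.items():
        if pid in fam_of_profile:
            fam_span[fam_of_profile[pid]].extend(e.occurred_at for e in es)
    durations = [
        (max(ts) - min(ts)).total_seconds() / 86400.0 for ts in fam_span.values() if ts
    ]
    duration_of_use = {}
    if durations:
        med, q1, q3, lo, hi = median_iqr(durations)
        duration_of_use = {
            "n_families": len(durations), "median_days": med, "q1_days": q1, "q3_days": q3,
        }

    coverage = {}
    if venn.office_past:
        coverage["past_in_app"] = {
            "k": venn.office_paired_past, "n": venn.office_past,
            "rate": venn.office_paired_past / venn.office_past,
        }
    if venn.office_acute:
        coverage["acute_in_app"] = {
            "k": venn.office_paired_acute, "n": venn.office_acute,
            "rate": venn.office_paired_acute / venn.office_acute,
        }

    thresholds = {
        f"{block}:{var}": threshold_check(
            DQIResult(**{k: v for k, v in d.items()
                         if k in ("indicator", "variable", "k", "n", "rate",
                                  "ci_low", "ci_high", "level")}),
            config.threshold,
        )
        for block, table in (
            ("concordance", concordance),
            ("completeness_vs_office", completeness_vs_office),
        )
        for var, d in table.items()
    }

    payload = {
        "validation": [v.to_dict() for v in violations],
        "accounting": accounting,
        "demographic": demographic,
        "venn": venn.to_dict(),
        "agreement": agreement,
        "concordance": concordance,
        "completeness_vs_office": completeness_vs_office,
        "completeness_vs_app": completeness_vs_app,
        "coverage": coverage,
        "acute_vs_past": acute_vs_past,
        "temperature_differences": temp_diff,
        "temperature_summary": temp_summary,
        "episode_counts": episode_counts,
        "duration_of_use": duration_of_use,
        "threshold_pass": thresholds,
        "warnings": warnings,
    }
    return AnalysisReport(payload, links, matches_by_profile, warnings)


def format_rate_cell(k: int, n: int, pct_decimals: int = 1) -> str:
    """Render one DQI cell, e.g. ``423/953 (44.4; 41.2-47.6)``."""
    from .stats import clopper_pearson

    low, high = clopper_pearson(k, n)
    pct = f"{100 * k / n:.{pct_decimals}f}"
    return f"{k}/{n} ({pct}; {100 * low:.1f}-{100 * high:.1f})"


_CELL_RE = re.compile(r"^(\d+)/(\d+) \(")


def parse_rate_cell(cell: str) -> tuple[int, int]:
    """Inverse of :func:`format_rate_cell` for the n/N part."""
    m = _CELL_RE.match(cell)
    if not m:
        raise ValueError(f"not a rate cell: {cell!r}")
    return int(m.group(1)), int(m.group(2))


def render_tables(report: AnalysisReport) -> str:
    """Human-readable text tables; every rate appears with its n/N."""
    p = report.payload
    lines: list[str] = []

    lines.append("== Accounting ==")
    for k, v in p["accounting"].items():
        lines.append(f"  {k:<32s} {v}")

    if p["demographic"]:
        lines.append("== Demographic DQIs (profile level) ==")
        for var, block in p["demographic"].items():
            for ind in ("completeness", "concordance"):
                d = block[ind]
                lines.append(
                    f"  {var:<16s} {ind:<14s} {format_rate_cell(d['k'], d['n'], 2)}"
                )

    lines.append("== Episode Venn partition ==")
    for k, v in p["venn"].items():
        lines.append(f"  {k:<28s} {v}")

    for title, key, decimals in (
        ("Concordance (episode level)", "concordance", 1),
        ("Completeness vs office total", "completeness_vs_office", 1),
        ("Completeness vs app total", "completeness_vs_app", 2),
    ):
        table = p[key]
        if table:
            lines.append(f"== {title} ==")
            for var, d in table.items():
                lines.append(f"  {var:<18s} {format_rate_cell(d['k'], d['n'], decimals)}")

    avp = p["acute_vs_past"]
    if "chi_square" in avp:
        lines.append("== Acute vs past temperature agreement ==")
        lines.append(
            f"  acute {avp['acute_temp_agreements']}/{avp['acute_paired']}, "
            f"past {avp['past_temp_agreements']}/{avp['past_paired']}, "
            f"chi2_1={avp['chi_square']:.3f} (P{avp['p_text']})"
        )

    td = p["temperature_differences"]
    if "mann_whitney_u" in td:
        lines.append("== Temperature differences (app - office) ==")
        for kind in ("acute", "past"):
            if kind in td:
                d = td[kind]
                lines.append(
                    f"  {kind}: n={d['n']} median {d['median']:+.1f} "
                    f"IQR ({d['q1']:+.1f} to {d['q3']:+.1f})"
                )
        lines.append(
            f"  Mann-Whitney U={td['mann_whitney_u']:.0f} (P{td['mann_whitney_p_text']})"
        )
    return "\n".join(lines) + "\n"
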