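"""Pre-merge discrepancy checks and field harmonization.

Before a confirmed match is merged, the pair is screened for discrepancies
that would be implausible for one woman: conflicting country of birth or
ethnicity, a clinic-recorded death before the estimated conception of a
reported pregnancy, an ART-naive report postdating an antenatal ART start,
or a UK-arrival date postdating a UK lab result.  Flagged pairs are kept only
when enough other fields corroborate the match; otherwise they are un-matched.

Kept matches are merged into CombinedRecords, harmonizing the fields both
studies collect:

* HIV-diagnosis date — earliest of the two, unless the earlier is a proxy
  date (1 Jan / 30 Jun) and the later falls in the same year; an earlier
  CD4/viral-load/ART date overrides, and stands in when no diagnosis date
  exists at all.
* Region of birth — the WHO region of the country of birth; a European vs
  non-European conflict resolves to the non-European region, two different
  non-European regions resolve to Not Known.
* Ethnicity — agreement stands; a somewhat-discrepant pair defers to the
  clinic cohort (re-reported yearly); a strong black-vs-white conflict
  resolves to not-known.

Every harmonized field carries a provenance entry naming the source and rule.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from datetime import date

from .records import (
    ARTEpisode,
    AuditEvent,
    ClinicRecord,
    LinkageConfig,
    MatchDecision,
    Pregnancy,
    PregnancyRecord,
)
from .regions import ETHNICITY_GROUPS, STRONG_CONFLICTS, WHO_REGIONS
from .linkage import corroboration_score
from .simulate import UndefinedWindowError, pregnancy_window

__all__ = [
    "DiscrepancyFlag",
    "CombinedRecord",
    "check_discrepancies",
    "adjudicate_flags",
    "harmonize_diagnosis_date",
    "resolve_region_of_birth",
    "resolve_ethnicity",
    "merge_matches",
]

DISCREPANCY_KINDS = (
    "cob-conflict",
    "ethnicity-conflict",
    "death-before-conception",
    "naive-after-art",
    "arrival-after-lab",
)


@dataclass
class DiscrepancyFlag:
    clinic_id: str
    pregnancy_id: str
    kind: str
    details: str = ""


@dataclass
class CombinedRecord:
    """The merged record for one matched woman, with per-field provenance.

    ``provenance`` maps each harmonized field name to a ``(source, rule)``
    pair, e.g. ``("pregnancy", "proxy-replaced")`` for a diagnosis date where
    the clinic's 1-January proxy was superseded by the surveillance study's
    same-year date.
    """

    clinic_id: str
    pregnancy_id: str
    dob: date
    hiv_diagnosis_date: date | None
    region_of_birth: str
    ethnicity: str
    pregnancies: list[Pregnancy]
    cd4_series: list[tuple[date, int]]
    vl_series: list[tuple[date, int]]
    art_episodes: list[ARTEpisode]
    provenance: dict[str, tuple[str, str]] = field(default_factory=dict)


# --------------------------------------------------------------------------
# discrepancy screening

def check_discrepancies(matches: list[MatchDecision],
                        clinic_by_id: dict[str, ClinicRecord],
                        preg_by_id: dict[str, PregnancyRecord],
                        config: LinkageConfig) -> list[DiscrepancyFlag]:
    """Screen each confirmed match for implausible cross-study conflicts."""
    flags = []
    for m in matches:
        clinic = clinic_by_id[m.pair.clinic_id]
        preg = preg_by_id[m.pair.pregnancy_id]

        if (clinic.country_of_birth is not None
                and preg.country_of_birth is not None
                and clinic.country_of_birth != preg.country_of_birth):
            flags.append(DiscrepancyFlag(
                clinic.record_id, preg.record_id, "cob-conflict",
                f"{clinic.country_of_birth} vs {preg.country_of_birth}"))

        if (clinic.ethnicity != "not-known" and preg.ethnicity != "not-known"
                and clinic.ethnicity != preg.ethnicity):
            flags.append(DiscrepancyFlag(
                clinic.record_id, preg.record_id, "ethnicity-conflict",
                f"{clinic.ethnicity} vs {preg.ethnicity}"))

        if clinic.death_date is not None:
            for p in preg.pregnancies:
                try:
                    conception, _ = pregnancy_window(p, config)
                except UndefinedWindowError:
                    continue
                if clinic.death_date < conception:
                    flags.append(DiscrepancyFlag(
                        clinic.record_id, preg.record_id,
                        "death-before-conception",
                        f"death {clinic.death_date} < conception {conception}"))
                    break

        if clinic.naive_until is not None:
            starts = [ep.start for p in preg.pregnancies
                      for ep in p.antenatal_art]
            early = [s for s in starts if s < clinic.naive_until]
            if early:
                flags.append(DiscrepancyFlag(
                    clinic.record_id, preg.record_id, "naive-after-art",
                    f"naive until {clinic.naive_until}, antenatal ART start "
                    f"{min(early)}"))

        if preg.uk_arrival_date is not None:
            lab_dates = [d for d, _ in clinic.cd4_series]
            lab_dates += [d for d, _ in clinic.vl_series]
            early = [d for d in lab_dates if d < preg.uk_arrival_date]
            if early:
                flags.append(DiscrepancyFlag(
                    clinic.record_id, preg.record_id, "arrival-after-lab",
                    f"UK arrival {preg.uk_arrival_date} after lab {min(early)}"))
    return flags


def adjudicate_flags(flags: list[DiscrepancyFlag],
                     matches: list[MatchDecision],
                     clinic_by_id: dict[str, ClinicRecord],
                     preg_by_id: dict[str, PregnancyRecord],
                     config: LinkageConfig
                     ) -> tuple[list[MatchDecision], list[MatchDecision],
                                list[AuditEvent]]:
    """Keep flagged matches with sufficient corroboration; un-match the rest.

    Returns (kept matches, un-matched pairs, audit events).  A flagged pair
    is kept when its corroboration score (the same rule the manual stage
    uses) meets the configured threshold.
    """
    flagged_keys = {(f.clinic_id, f.pregnancy_id) for f in flags}
    kept, unmatched, events = [], [], []
    for m in matches:
        if m.pair.key not in flagged_keys:
            kept.append(m)
            continue
        clinic = clinic_by_id[m.pair.clinic_id]
        preg = preg_by_id[m.pair.pregnancy_id]
        score, nondemo, evidence = corroboration_score(clinic, preg, config)
        if score >= config.corroboration_threshold and nondemo >= 1:
            kept.append(m)
        else:
            unmatched.append(m)
            events.append(AuditEvent(
                m.pair.clinic_id, m.pair.pregnancy_id,
                "unmatched-after-discrepancy", stage=m.stage,
                criterion=m.criterion,
                evidence=[(f.kind, "", f.details) for f in flags
                          if (f.clinic_id, f.pregnancy_id) == m.pair.key]))
    return kept, unmatched, events


# --------------------------------------------------------------------------
# field harmonization

def harmonize_diagnosis_date(
    d_clinic: date | None, d_pregnancy: date | None,
    earliest_lab_or_art: date | None, config: LinkageConfig
) -> tuple[date, tuple[str, str]]:
    """Harmonized HIV-diagnosis date with (source, rule) provenance.

    The earliest of the two reported dates wins, unless the earlier one is a
    proxy date (month/day in ``config.proxy_diagnosis_dates``) and the later
    falls in the same calendar year — proxies stand for "some time that
    year", so the more specific date is preferred.  With no diagnosis date
    at all, the earliest CD4/viral-load/ART date stands in; and whenever that
    earliest lab date precedes the harmonized diagnosis date, it replaces it
    (care cannot precede diagnosis).
    """
    if d_clinic is None and d_pregnancy is None and earliest_lab_or_art is None:
        raise ValueError("no diagnosis date and no lab/ART date available")

    if d_clinic is not None and d_pregnancy is not None:
        if d_clinic <= d_pregnancy:
            earlier, later = d_clinic, d_pregnancy
            earlier_src, later_src = "clinic", "pregnancy"
        else:
            earlier, later = d_pregnancy, d_clinic
            earlier_src, later_src = "pregnancy", "clinic"
        if ((earlier.month, earlier.day) in config.proxy_diagnosis_dates
                and later.year == earlier.year and later != earlier):
            chosen, prov = later, (later_src, "proxy-replaced")
        else:
            chosen, prov = earlier, (earlier_src, "earliest")
    elif d_clinic is not None:
        chosen, prov = d_clinic, ("clinic", "single-source")
    elif d_pregnancy is not None:
        chosen, prov = d_pregnancy, ("pregnancy", "single-source")
    else:
        return earliest_lab_or_art, ("clinical-series", "lab-fallback")

    if earliest_lab_or_art is not None and earliest_lab_or_art < chosen:
        return earliest_lab_or_art, ("clinical-series", "lab-precedes")
    return chosen, prov


def resolve_region_of_birth(
    cob_clinic: str | None, cob_pregnancy: str | None,
    region_table: dict[str, str] | None = None
) -> str:
    """WHO region of birth harmonized from the two countries of birth.

    Symmetric in its inputs: equal regions stand; European vs non-European
    resolves to the non-European region (the UK is a frequent default entry);
    two different non-European regions resolve to "Not Known".
    """
    table = region_table if region_table is not None else WHO_REGIONS

    def lookup(cob):
        if cob is None:
            return None
        region = table.get(cob)
        if region is None:
            warnings.warn(f"unknown country of birth {cob!r}; treating as Not Known")
        return region

    r1, r2 = lookup(cob_clinic), lookup(cob_pregnancy)
    if r1 is None and r2 is None:
        return "Not Known"
    if r1 is None or r2 is None:
        return r1 if r1 is not None else r2
    if r1 == r2:
        return r1
    if r1 == "European":
        return r2
    if r2 == "European":
        return r1
    return "Not Known"


def resolve_ethnicity(e_clinic: str, e_pregnancy: str,
                      conflict_table: frozenset | None = None) -> str:
    """Harmonized ethnicity: agreement stands; one-sided data stands; a
    strong (black vs white) conflict resolves to not-known; any other
    disagreement defers to the clinic cohort's value."""
    conflicts = conflict_table if conflict_table is not None else STRONG_CONFLICTS
    c_missing = e_clinic in (None, "not-known")
    p_missing = e_pregnancy in (None, "not-known")
    if c_missing and p_missing:
        return "not-known"
    if c_missing:
        return e_pregnancy
    if p_missing:
        return e_clinic
    if e_clinic == e_pregnancy:
        return e_clinic
    g1, g2 = ETHNICITY_GROUPS[e_clinic], ETHNICITY_GROUPS[e_pregnancy]
    if frozenset({g1, g2}) in conflicts:
        return "not-known"
    return e_clinic


def _earliest_lab_or_art(clinic: ClinicRecord, preg: PregnancyRecord) -> date | None:
    dates = [d for d, _ in clinic.cd4_series]
    dates += [d for d, _ in clinic.vl_series]
    dates += [ep.start for ep in clinic.art_episodes]
    for p in preg.pregnancies:
        dates += [pt[0] for pt in (p.first_cd4, p.last_cd4, p.first_vl, p.last_vl)
                  if pt is not None]
        dates += [ep.start for ep in p.antenatal_art]
    return min(dates) if dates else None


def merge_matches(kept: list[MatchDecision],
                  clinic_by_id: dict[str, ClinicRecord],
                  preg_by_id: dict[str, PregnancyRecord],
                  config: LinkageConfig,
                  region_table: dict[str, str] | None = None
                  ) -> list[CombinedRecord]:
    """Merge each kept match into a CombinedRecord, applying every
    harmonization rule and recording per-field provenance."""
    combined = []
    for m in kept:
        clinic = clinic_by_id[m.pair.clinic_id]
        preg = preg_by_id[m.pair.pregnancy_id]
        provenance: dict[str, tuple[str, str]] = {
            "dob": ("both", "blocking-key"),
        }

        earliest = _earliest_lab_or_art(clinic, preg)
        if (clinic.hiv_diagnosis_date is None
                and preg.hiv_diagnosis_date is None and earliest is None):
            diagnosis, provenance["hiv_diagnosis_date"] = None, ("none", "missing")
        else:
            diagnosis, prov = harmonize_diagnosis_date(
                clinic.hiv_diagnosis_date, preg.hiv_diagnosis_date,
                earliest, config)
            provenance["hiv_diagnosis_date"] = prov

        region = resolve_region_of_birth(clinic.country_of_birth,
                                         preg.country_of_birth, region_table)
        if clinic.country_of_birth == preg.country_of_birth:
            provenance["region_of_birth"] = ("both", "agreement")
        elif clinic.country_of_birth is None or preg.country_of_birth is None:
            provenance["region_of_birth"] = (
                "clinic" if preg.country_of_birth is None else "pregnancy",
                "single-source")
        else:
            provenance["region_of_birth"] = ("both", "region-conflict-rule")

        ethnicity = resolve_ethnicity(clinic.ethnicity, preg.ethnicity)
        if clinic.ethnicity == preg.ethnicity:
            provenance["ethnicity"] = ("both", "agreement")
        elif ethnicity == clinic.ethnicity:
            provenance["ethnicity"] = ("clinic", "clinic-precedence")
        elif ethnicity == preg.ethnicity:
            provenance["ethnicity"] = ("pregnancy", "single-source")
        else:
            provenance["ethnicity"] = ("both", "strong-conflict")

        combined.append(CombinedRecord(
            clinic_id=clinic.record_id,
            pregnancy_id=preg.record_id,
            dob=clinic.dob,
            hiv_diagnosis_date=diagnosis,
            region_of_birth=region,
            ethnicity=ethnicity,
            pregnancies=list(preg.pregnancies),
            cd4_series=list(clinic.cd4_series),
            vl_series=list(clinic.vl_series),
            art_episodes=list(clinic.art_episodes),
            provenance=provenance,
        ))
    return combined
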