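"""The staged deterministic matching cascade.

Candidate pairs are generated by *blocking* on exact date of birth, then
confirmed by a fixed sequence of criteria applied in order:

1. ``CD4-exact``  — an exactly matching CD4 date with counts within 10
   cells/mm^3; failing that, an exactly matching CD4 date plus an identical
   HIV-diagnosis date or care at equivalent sites (with a manual-review flag
   when the counts differ by more than 100 cells/mm^3).
2. ``CD4-window`` — the same two criteria with CD4 dates within 30 days.
3. ``ART-exact``  — five ART-episode criteria in order: drug + start + stop
   all matching; drug plus one date; start + stop with drug missing or
   different; one date plus equivalent site; one date plus identical
   diagnosis date.
4. ``ART-window`` — the same five criteria with ART dates within 7 days.
5. ``manual``     — remaining pairs are flagged for review (same site,
   diagnosis dates within 30 days, any ART date equality, matching soundex,
   or a pregnancy-indicating ART profile) and confirmed by a deterministic
   corroboration rule over the fields a human reviewer would inspect.

After each stage, confirmed pairs leave the pool together with every other
candidate pair containing either member; when a record matches several
counterparts within a stage, the strongest match wins under a deterministic
scoring rule.  The final confirmed set is one-to-one.
"""
from __future__ import annotations

from datetime import date, timedelta

from .records import (
    AuditEvent,
    CandidatePair,
    ClinicRecord,
    LinkageConfig,
    MatchDecision,
    PregnancyRecord,
)
from .simulate import ZDV_MONO, UndefinedWindowError, pregnancy_window

__all__ = [
    "block_by_dob",
    "cd4_stage",
    "art_stage",
    "flag_manual_candidates",
    "resolve_manual",
    "run_linkage",
    "corroboration_score",
]

ART_CRITERIA = (
    "drug+start+stop",
    "drug+start|stop",
    "start+stop",
    "start|stop+site",
    "start|stop+diagnosis-date",
)


# --------------------------------------------------------------------------
# field helpers

def _pregnancy_cd4s(rec: PregnancyRecord) -> list[tuple[date, int]]:
    """The CD4 values the surveillance study collects: first and last of
    each pregnancy."""
    out = []
    for p in rec.pregnancies:
        for pt in (p.first_cd4, p.last_cd4):
            if pt is not None:
                out.append(pt)
    return out


def _pregnancy_vls(rec: PregnancyRecord) -> list[tuple[date, int]]:
    out = []
    for p in rec.pregnancies:
        for pt in (p.first_vl, p.last_vl):
            if pt is not None:
                out.append(pt)
    return out


def _antenatal_episodes(rec: PregnancyRecord):
    for p in rec.pregnancies:
        yield from p.antenatal_art


def _sites_equivalent(config: LinkageConfig, clinic: ClinicRecord,
                      preg: PregnancyRecord) -> bool:
    clinic_sites = [s for s, _ in clinic.sites]
    for p in preg.pregnancies:
        for cs in clinic_sites:
            if config.sites_equivalent(p.site, cs):
                return True
    return False


def _diagnosis_equal(clinic: ClinicRecord, preg: PregnancyRecord) -> bool:
    return (clinic.hiv_diagnosis_date is not None
            and clinic.hiv_diagnosis_date == preg.hiv_diagnosis_date)


def _days(a: date, b: date) -> int:
    return abs((a - b).days)


def _sorted_pairs(pairs) -> list[CandidatePair]:
    return sorted(pairs, key=lambda q: (q.pregnancy_id, q.clinic_id))


# --------------------------------------------------------------------------
# blocking

def block_by_dob(clinic: list[ClinicRecord],
                 pregnancy: list[PregnancyRecord]) -> list[CandidatePair]:
    """All clinic x pregnancy pairs with identical date of birth.

    A record may appear in several pairs; the cascade resolves multiplicity
    later.  Records whose DOB matches nothing simply produce no pairs.
    """
    by_dob: dict[date, list[str]] = {}
    for rec in clinic:
        by_dob.setdefault(rec.dob, []).append(rec.record_id)
    pairs = [
        CandidatePair(clinic_id=cid, pregnancy_id=rec.record_id, dob=rec.dob)
        for rec in pregnancy
        for cid in by_dob.get(rec.dob, ())
    ]
    return _sorted_pairs(pairs)


# --------------------------------------------------------------------------
# CD4 stages

def cd4_stage(pairs, clinic_by_id: dict[str, ClinicRecord],
              preg_by_id: dict[str, PregnancyRecord],
              config: LinkageConfig, window_days: int) -> list[MatchDecision]:
    """CD4-based criteria at the given date window (0 = exact dates).

    Criterion 1: some (clinic CD4, pregnancy first/last CD4) pair has dates
    within the window and counts within ``cd4_count_tolerance``.  Criterion 2:
    some date-compatible CD4 pair exists and the records share an HIV-diagnosis
    date or equivalent sites; the decision carries ``manual_flag`` when the
    smallest count difference on compatible dates exceeds
    ``cd4_manual_check_threshold``.
    """
    stage = "CD4-exact" if window_days == 0 else "CD4-window"
    decisions = []
    for pair in _sorted_pairs(pairs):
        clinic = clinic_by_id[pair.clinic_id]
        preg = preg_by_id[pair.pregnancy_id]
        compatible = [
            (cd, cc, pd, pc)
            for cd, cc in clinic.cd4_series
            for pd, pc in _pregnancy_cd4s(preg)
            if _days(cd, pd) <= window_days
        ]
        if not compatible:
            continue
        within = [t for t in compatible
                  if abs(t[1] - t[3]) <= config.cd4_count_tolerance]
        if within:
            cd, cc, pd, pc = min(within, key=lambda t: (_days(t[0], t[2]),
                                                        abs(t[1] - t[3]), t[0]))
            decisions.append(MatchDecision(
                pair=pair, stage=stage, criterion="cd4±10",
                evidence=[("cd4", f"{cd}:{cc}", f"{pd}:{pc}")]))
            continue
        if _diagnosis_equal(clinic, preg):
            criterion = "diagnosis-date"
            evidence = [("hiv_diagnosis_date", str(clinic.hiv_diagnosis_date),
                         str(preg.hiv_diagnosis_date))]
        elif _sites_equivalent(config, clinic, preg):
            criterion = "site"
            evidence = [("site", ";".join(s for s, _ in clinic.sites),
                         ";".join(str(p.site) for p in preg.pregnancies))]
        else:
            continue
        min_diff = min(abs(t[1] - t[3]) for t in compatible)
        decisions.append(MatchDecision(
            pair=pair, stage=stage, criterion=criterion,
            manual_flag=min_diff > config.cd4_manual_check_threshold,
            evidence=evidence + [("cd4_min_count_diff", str(min_diff), "")]))
    return decisions


# --------------------------------------------------------------------------
# ART stages

def art_stage(pairs, clinic_by_id: dict[str, ClinicRecord],
              preg_by_id: dict[str, PregnancyRecord],
              config: LinkageConfig, window_days: int) -> list[MatchDecision]:
    """ART-episode criteria at the given date window (0 = exact dates).

    The five sub-criteria are evaluated in their published order over every
    (clinic episode, antenatal episode) pair; the first satisfied criterion
    labels the decision.
    """
    stage = "ART-exact" if window_days == 0 else "ART-window"
    decisions = []
    for pair in _sorted_pairs(pairs):
        clinic = clinic_by_id[pair.clinic_id]
        preg = preg_by_id[pair.pregnancy_id]
        site_eq = _sites_equivalent(config, clinic, preg)
        diag_eq = _diagnosis_equal(clinic, preg)
        best: tuple[int, list] | None = None
        for ec in clinic.art_episodes:
            for ep in _antenatal_episodes(preg):
                start_ok = _days(ec.start, ep.start) <= window_days
                stop_ok = (ec.stop is not None and ep.stop is not None
                           and _days(ec.stop, ep.stop) <= window_days)
                drug_eq = (ec.drug is not None and ep.drug is not None
                           and ec.drug == ep.drug)
                if drug_eq and start_ok and stop_ok:
                    idx = 0
                elif drug_eq and (start_ok or stop_ok):
                    idx = 1
                elif not drug_eq and start_ok and stop_ok:
                    idx = 2
                elif (start_ok or stop_ok) and site_eq:
                    idx = 3
                elif (start_ok or stop_ok) and diag_eq:
                    idx = 4
                else:
                    continue
                if best is None or idx < best[0]:
                    best = (idx, [("art",
                                   f"{ec.drug}:{ec.start}:{ec.stop}",
                                   f"{ep.drug}:{ep.start}:{ep.stop}")])
        if best is not None:
            decisions.append(MatchDecision(
                pair=pair, stage=stage, criterion=ART_CRITERIA[best[0]],
                evidence=best[1]))
    return decisions


# --------------------------------------------------------------------------
# manual stage

def _cd4_at(clinic: ClinicRecord, when: date) -> int | None:
    """Most recent CD4 count on or before a date."""
    before = [(d, c) for d, c in clinic.cd4_series if d <= when]
    return max(before, key=lambda pt: pt[0])[1] if before else None


def _art_profile(clinic: ClinicRecord, preg: PregnancyRecord,
                 config: LinkageConfig) -> bool:
    """A clinic ART record that suggests the woman was pregnant: a start
    after the first trimester of a reported pregnancy on zidovudine
    monotherapy or on combination ART despite a high CD4 count, or an episode
    with "pregnant" as the recorded reason."""
    if any(ep.reason == "pregnant" for ep in clinic.art_episodes):
        return True
    windows = []
    for p in preg.pregnancies:
        try:
            windows.append(pregnancy_window(p, config))
        except UndefinedWindowError:
            continue
    for ep in clinic.art_episodes:
        for conception, end in windows:
            if not conception + timedelta(days=config.first_trimester_days) < ep.start <= end:
                continue
            if ep.drug == ZDV_MONO:
                return True
            cd4 = _cd4_at(clinic, ep.start)
            if cd4 is not None and cd4 > config.cd4_threshold_art_profile:
                return True
    return False


def flag_manual_candidates(pairs, clinic_by_id: dict[str, ClinicRecord],
                           preg_by_id: dict[str, PregnancyRecord],
                           config: LinkageConfig) -> list[MatchDecision]:
    """Select unmatched pairs worth manual review (unconfirmed decisions)."""
    flags = []
    for pair in _sorted_pairs(pairs):
        clinic = clinic_by_id[pair.clinic_id]
        preg = preg_by_id[pair.pregnancy_id]
        criterion = None
        if _sites_equivalent(config, clinic, preg):
            criterion = "site"
        elif (clinic.hiv_diagnosis_date is not None
              and preg.hiv_diagnosis_date is not None
              and _days(clinic.hiv_diagnosis_date, preg.hiv_diagnosis_date)
              <= config.diagnosis_date_window_days):
            criterion = "diagnosis-date"
        elif any(
            d1 is not None and d1 == d2
            for ec in clinic.art_episodes for d1 in (ec.start, ec.stop)
            for ep in _antenatal_episodes(preg) for d2 in (ep.start, ep.stop)
        ):
            criterion = "art-date"
        elif (clinic.soundex is not None and clinic.soundex == preg.soundex):
            criterion = "soundex"
        elif _art_profile(clinic, preg, config):
            criterion = "art-profile"
        if criterion is not None:
            flags.append(MatchDecision(pair=pair, stage="manual",
                                       criterion=criterion, manual_flag=True))
    return flags


def corroboration_score(clinic: ClinicRecord, preg: PregnancyRecord,
                        config: LinkageConfig) -> tuple[int, int, list]:
    """Deterministic stand-in for a human reviewer's judgement.

    Counts agreements among country of birth, ethnicity, HIV-diagnosis date
    (exact), any viral-load value+date (exact), and soundex.  Returns
    (total agreements, of which non-demographic, evidence); diagnosis date
    and viral load count as non-demographic evidence.
    """
    score = nondemo = 0
    evidence = []
    if (clinic.country_of_birth is not None
            and clinic.country_of_birth == preg.country_of_birth):
        score += 1
        evidence.append(("country_of_birth", clinic.country_of_birth,
                         preg.country_of_birth))
    if (clinic.ethnicity == preg.ethnicity and clinic.ethnicity != "not-known"):
        score += 1
        evidence.append(("ethnicity", clinic.ethnicity, preg.ethnicity))
    if _diagnosis_equal(clinic, preg):
        score += 1
        nondemo += 1
        evidence.append(("hiv_diagnosis_date", str(clinic.hiv_diagnosis_date),
                         str(preg.hiv_diagnosis_date)))
    clinic_vl = set(clinic.vl_series)
    vl_hits = [pt for pt in _pregnancy_vls(preg) if pt in clinic_vl]
    if vl_hits:
        score += 1
        nondemo += 1
        d, v = vl_hits[0]
        evidence.append(("viral_load", f"{d}:{v}", f"{d}:{v}"))
    if clinic.soundex is not None and clinic.soundex == preg.soundex:
        score += 1
        evidence.append(("soundex", clinic.soundex, preg.soundex))
    return score, nondemo, evidence


def resolve_manual(flags: list[MatchDecision],
                   clinic_by_id: dict[str, ClinicRecord],
                   preg_by_id: dict[str, PregnancyRecord],
                   config: LinkageConfig) -> list[MatchDecision]:
    """Confirm flagged pairs whose corroboration score meets the threshold
    (with at least one non-demographic agreement); when several flagged pairs
    compete for a record, only the strongest is confirmed."""
    candidates = []
    for d in flags:
        clinic = clinic_by_id[d.pair.clinic_id]
        preg = preg_by_id[d.pair.pregnancy_id]
        score, nondemo, evidence = corroboration_score(clinic, preg, config)
        if score >= config.corroboration_threshold and nondemo >= 1:
            candidates.append((score,
                               MatchDecision(pair=d.pair, stage="manual",
                                             criterion=d.criterion,
                                             manual_flag=True,
                                             evidence=list(evidence))))
    order = sorted(
        candidates,
        key=lambda sd: (-sd[0],) + _tiebreak(sd[1].pair, clinic_by_id,
                                             preg_by_id, config))
    return _greedy_one_to_one([d for _, d in order])


# --------------------------------------------------------------------------
# one-to-one resolution

def _strength(pair: CandidatePair, clinic_by_id, preg_by_id,
              config: LinkageConfig) -> tuple:
    """Strongest-match score: (CD4 date+count agreements, diagnosis-date
    equality, ART-date agreements, site equivalence, soundex equality),
    compared lexicographically (larger = stronger)."""
    clinic = clinic_by_id[pair.clinic_id]
    preg = preg_by_id[pair.pregnancy_id]
    cd4_hits = sum(
        1 for cd, cc in clinic.cd4_series for pd, pc in _pregnancy_cd4s(preg)
        if cd == pd and abs(cc - pc) <= config.cd4_count_tolerance)
    art_hits = sum(
        1 for ec in clinic.art_episodes for d1 in (ec.start, ec.stop)
        for ep in _antenatal_episodes(preg) for d2 in (ep.start, ep.stop)
        if d1 is not None and d1 == d2)
    return (cd4_hits,
            int(_diagnosis_equal(clinic, preg)),
            art_hits,
            int(_sites_equivalent(config, clinic, preg)),
            int(clinic.soundex is not None and clinic.soundex == preg.soundex))


def _date_discrepancy(pair: CandidatePair, clinic_by_id, preg_by_id) -> int:
    """Summed distance from each pregnancy-side CD4 date to the nearest
    clinic CD4 date (ties among equally strong pairs go to the closer one)."""
    clinic = clinic_by_id[pair.clinic_id]
    preg = preg_by_id[pair.pregnancy_id]
    total = 0
    for pd, _ in _pregnancy_cd4s(preg):
        if clinic.cd4_series:
            total += min(_days(cd, pd) for cd, _ in clinic.cd4_series)
        else:
            total += 10_000
    return total


def _tiebreak(pair, clinic_by_id, preg_by_id, config) -> tuple:
    return (_date_discrepancy(pair, clinic_by_id, preg_by_id),
            pair.pregnancy_id, pair.clinic_id)


def _greedy_one_to_one(ordered: list[MatchDecision]) -> list[MatchDecision]:
    used_clinic: set[str] = set()
    used_preg: set[str] = set()
    accepted = []
    for d in ordered:
        if d.pair.clinic_id in used_clinic or d.pair.pregnancy_id in used_preg:
            continue
        used_clinic.add(d.pair.clinic_id)
        used_preg.add(d.pair.pregnancy_id)
        accepted.append(d)
    return accepted


def _resolve_one_to_one(decisions: list[MatchDecision], clinic_by_id,
                        preg_by_id, config: LinkageConfig) -> list[MatchDecision]:
    order = sorted(
        decisions,
        key=lambda d: tuple(-x for x in _strength(d.pair, clinic_by_id,
                                                  preg_by_id, config))
        + _tiebreak(d.pair, clinic_by_id, preg_by_id, config))
    return _greedy_one_to_one(order)


# --------------------------------------------------------------------------
# the full cascade

def run_linkage(clinic: list[ClinicRecord], pregnancy: list[PregnancyRecord],
                config: LinkageConfig
                ) -> tuple[list[MatchDecision], list[AuditEvent]]:
    """Execute the full cascade and return (confirmed matches, audit trail).

    Stages run in order CD4-exact, CD4-window, ART-exact, ART-window, manual.
    After each stage confirmed pairs and every other pair containing either
    member leave the pool.  The confirmed set is one-to-one and every decision
    is traceable through the audit events.
    """
    config.validate()
    clinic_by_id = {r.record_id: r for r in clinic}
    preg_by_id = {r.record_id: r for r in pregnancy}

    pairs = block_by_dob(clinic, pregnancy)
    events = [AuditEvent(q.clinic_id, q.pregnancy_id, "linked",
                         evidence=[("dob", str(q.dob), str(q.dob))])
              for q in pairs]
    pool: dict[tuple[str, str], CandidatePair] = {q.key: q for q in pairs}
    confirmed: list[MatchDecision] = []

    def apply_stage(accepted: list[MatchDecision]) -> None:
        matched_c = {d.pair.clinic_id for d in accepted}
        matched_p = {d.pair.pregnancy_id for d in accepted}
        accepted_keys = {d.pair.key for d in accepted}
        for d in accepted:
            confirmed.append(d)
            events.append(AuditEvent(d.pair.clinic_id, d.pair.pregnancy_id,
                                     "matched", stage=d.stage,
                                     criterion=d.criterion,
                                     evidence=list(d.evidence)))
        for key, q in list(pool.items()):
            if q.clinic_id in matched_c or q.pregnancy_id in matched_p:
                del pool[key]
                if key not in accepted_keys:
                    events.append(AuditEvent(q.clinic_id, q.pregnancy_id,
                                             "removed-as-side-effect"))

    stages = [
        lambda ps: cd4_stage(ps, clinic_by_id, preg_by_id, config, 0),
        lambda ps: cd4_stage(ps, clinic_by_id, preg_by_id, config,
                             config.cd4_date_window_days),
        lambda ps: art_stage(ps, clinic_by_id, preg_by_id, config, 0),
        lambda ps: art_stage(ps, clinic_by_id, preg_by_id, config,
                             config.art_date_window_days),
    ]
    for stage_fn in stages:
        decisions = stage_fn(pool.values())
        # decisions carrying a manual-review flag (CD4 counts differing by
        # more than the manual-check threshold) are confirmed only when the
        # corroboration rule supports them; otherwise the pair stays pooled
        vetted = []
        for d in decisions:
            if d.manual_flag:
                events.append(AuditEvent(d.pair.clinic_id, d.pair.pregnancy_id,
                                         "flagged-manual", stage=d.stage,
                                         criterion=d.criterion,
                                         evidence=list(d.evidence)))
                score, nondemo, _ = corroboration_score(
                    clinic_by_id[d.pair.clinic_id],
                    preg_by_id[d.pair.pregnancy_id], config)
                if score < config.corroboration_threshold or nondemo < 1:
                    continue
            vetted.append(d)
        apply_stage(_resolve_one_to_one(vetted, clinic_by_id, preg_by_id,
                                        config))

    flags = flag_manual_candidates(pool.values(), clinic_by_id, preg_by_id,
                                   config)
    for d in flags:
        events.append(AuditEvent(d.pair.clinic_id, d.pair.pregnancy_id,
                                 "flagged-manual", stage="manual",
                                 criterion=d.criterion))
    apply_stage(resolve_manual(flags, clinic_by_id, preg_by_id, config))

    for q in pool.values():
        events.append(AuditEvent(q.clinic_id, q.pregnancy_id, "rejected"))
    return confirmed, events
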