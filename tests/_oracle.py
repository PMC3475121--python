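"""Independent brute-force reference for the matching cascade.

Written as plain nested loops over records and their clinical events, with no
code shared with the package's engine: every criterion, the stage order, the
manual-review vetting and the strongest-match tie-break are re-derived here
directly from their definitions.  Used to check the cascade on small
instances, where exhaustive enumeration is cheap.
"""
from __future__ import annotations

from datetime import timedelta


def _preg_cd4s(p):
    out = []
    for preg in p.pregnancies:
        if preg.first_cd4:
            out.append(preg.first_cd4)
        if preg.last_cd4:
            out.append(preg.last_cd4)
    return out


def _preg_vls(p):
    out = []
    for preg in p.pregnancies:
        if preg.first_vl:
            out.append(preg.first_vl)
        if preg.last_vl:
            out.append(preg.last_vl)
    return out


def _preg_art(p):
    return [ep for preg in p.pregnancies for ep in preg.antenatal_art]


def _same_site(c, p, cfg):
    for preg in p.pregnancies:
        for s, _ in c.sites:
            if preg.site is not None and (
                    preg.site == s or s in cfg.site_equivalence.get(preg.site, ())):
                return True
    return False


def _diag_eq(c, p):
    return (c.hiv_diagnosis_date is not None
            and c.hiv_diagnosis_date == p.hiv_diagnosis_date)


def _cd4_check(c, p, cfg, w):
    compat = []
    for cd, cc in c.cd4_series:
        for pd, pc in _preg_cd4s(p):
            if abs((cd - pd).days) <= w:
                compat.append(abs(cc - pc))
    if not compat:
        return None
    if min(compat) <= cfg.cd4_count_tolerance:
        return ("cd4±10", False)
    if _diag_eq(c, p):
        return ("diagnosis-date", min(compat) > cfg.cd4_manual_check_threshold)
    if _same_site(c, p, cfg):
        return ("site", min(compat) > cfg.cd4_manual_check_threshold)
    return None


def _art_check(c, p, cfg, w):
    names = ["drug+start+stop", "drug+start|stop", "start+stop",
             "start|stop+site", "start|stop+diagnosis-date"]
    best = None
    for ec in c.art_episodes:
        for ep in _preg_art(p):
            start_ok = abs((ec.start - ep.start).days) <= w
            stop_ok = (ec.stop is not None and ep.stop is not None
                       and abs((ec.stop - ep.stop).days) <= w)
            drug_ok = ec.drug is not None and ec.drug == ep.drug
            idx = None
            if drug_ok and start_ok and stop_ok:
                idx = 0
            elif drug_ok and (start_ok or stop_ok):
                idx = 1
            elif (not drug_ok) and start_ok and stop_ok:
                idx = 2
            elif (start_ok or stop_ok) and _same_site(c, p, cfg):
                idx = 3
            elif (start_ok or stop_ok) and _diag_eq(c, p):
                idx = 4
            if idx is not None and (best is None or idx < best):
                best = idx
    return None if best is None else (names[best], False)


def _windows(p, cfg):
    out = []
    for preg in p.pregnancies:
        anchor = preg.delivery_date or preg.expected_delivery_date
        if anchor is not None:
            out.append((anchor - timedelta(days=cfg.gestation_days - 1), anchor))
    return out


def _manual_flag_check(c, p, cfg):
    if _same_site(c, p, cfg):
        return "site"
    if (c.hiv_diagnosis_date and p.hiv_diagnosis_date and
            abs((c.hiv_diagnosis_date - p.hiv_diagnosis_date).days)
            <= cfg.diagnosis_date_window_days):
        return "diagnosis-date"
    for ec in c.art_episodes:
        for ep in _preg_art(p):
            for d1 in (ec.start, ec.stop):
                for d2 in (ep.start, ep.stop):
                    if d1 is not None and d1 == d2:
                        return "art-date"
    if c.soundex is not None and c.soundex == p.soundex:
        return "soundex"
    # pregnancy-indicating ART profile
    if any(ep.reason == "pregnant" for ep in c.art_episodes):
        return "art-profile"
    for ec in c.art_episodes:
        for conception, end in _windows(p, cfg):
            if conception + timedelta(days=cfg.first_trimester_days) < ec.start <= end:
                if ec.drug == "ZDVm":
                    return "art-profile"
                before = [cc for cd, cc in c.cd4_series if cd <= ec.start]
                at = [cc for cd, cc in c.cd4_series if cd <= ec.start
                      and cd == max(cd2 for cd2, _ in c.cd4_series if cd2 <= ec.start)]
                if before and at and at[0] > cfg.cd4_threshold_art_profile:
                    return "art-profile"
    return None


def _corroborate(c, p, cfg):
    score = nondemo = 0
    if c.country_of_birth is not None and c.country_of_birth == p.country_of_birth:
        score += 1
    if c.ethnicity == p.ethnicity and c.ethnicity != "not-known":
        score += 1
    if _diag_eq(c, p):
        score += 1
        nondemo += 1
    if any(pt in c.vl_series for pt in _preg_vls(p)):
        score += 1
        nondemo += 1
    if c.soundex is not None and c.soundex == p.soundex:
        score += 1
    return score, nondemo


def _strength(c, p, cfg):
    cd4_hits = sum(1 for cd, cc in c.cd4_series for pd, pc in _preg_cd4s(p)
                   if cd == pd and abs(cc - pc) <= cfg.cd4_count_tolerance)
    art_hits = 0
    for ec in c.art_episodes:
        for ep in _preg_art(p):
            for d1 in (ec.start, ec.stop):
                for d2 in (ep.start, ep.stop):
                    if d1 is not None and d1 == d2:
                        art_hits += 1
    return (cd4_hits, int(_diag_eq(c, p)), art_hits,
            int(_same_site(c, p, cfg)),
            int(c.soundex is not None and c.soundex == p.soundex))


def _date_disc(c, p):
    total = 0
    for pd, _ in _preg_cd4s(p):
        if c.cd4_series:
            total += min(abs((cd - pd).days) for cd, _ in c.cd4_series)
        else:
            total += 10_000
    return total


def oracle_linkage(clinic_records, pregnancy_records, cfg):
    """Exhaustive reference cascade.

    Returns {(clinic_id, pregnancy_id): (stage, criterion)} for every
    confirmed pair.
    """
    pool = {}
    for c in clinic_records:
        for p in pregnancy_records:
            if c.dob == p.dob:
                pool[(c.record_id, p.record_id)] = (c, p)

    stage_checks = [
        ("CD4-exact", lambda c, p: _cd4_check(c, p, cfg, 0)),
        ("CD4-window", lambda c, p: _cd4_check(c, p, cfg, cfg.cd4_date_window_days)),
        ("ART-exact", lambda c, p: _art_check(c, p, cfg, 0)),
        ("ART-window", lambda c, p: _art_check(c, p, cfg, cfg.art_date_window_days)),
    ]

    confirmed = {}

    def take(ordered, stage, labels):
        used_c, used_p = set(), set()
        for key in ordered:
            cid, pid = key
            if cid in used_c or pid in used_p:
                continue
            used_c.add(cid)
            used_p.add(pid)
            confirmed[key] = (stage, labels[key])
        for key in list(pool):
            if key[0] in used_c or key[1] in used_p:
                del pool[key]

    for stage, check in stage_checks:
        sat = {}
        for key, (c, p) in pool.items():
            res = check(c, p)
            if res is None:
                continue
            criterion, flagged = res
            if flagged:
                score, nondemo = _corroborate(c, p, cfg)
                if score < cfg.corroboration_threshold or nondemo < 1:
                    continue
            sat[key] = criterion
        ordered = sorted(
            sat,
            key=lambda k: tuple(-x for x in _strength(*pool[k], cfg))
            + (_date_disc(*pool[k]), k[1], k[0]))
        take(ordered, stage, sat)

    # manual stage: flag, corroborate, strongest first by corroboration score
    sat, scores = {}, {}
    for key, (c, p) in pool.items():
        criterion = _manual_flag_check(c, p, cfg)
        if criterion is None:
            continue
        score, nondemo = _corroborate(c, p, cfg)
        if score >= cfg.corroboration_threshold and nondemo >= 1:
            sat[key] = criterion
            scores[key] = score
    ordered = sorted(
        sat, key=lambda k: (-scores[k], _date_disc(*pool[k]), k[1], k[0]))
    take(ordered, "manual", sat)
    return confirmed
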