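"""Ground-truthed synthetic twin cohorts.

The generator draws a latent population of HIV-positive women (date of birth,
demographics, CD4/viral-load trajectories, ART episodes, sites, pregnancies)
and then *reports* each woman into one or both cohorts: the clinic cohort sees
the full longitudinal record, the pregnancy-surveillance cohort sees one row
per pregnancy with only first/last CD4 and viral load.  A configurable noise
model reproduces the error modes the matching cascade must tolerate:

* CD4 counts on surveillance forms rounded to the nearest 10 cells/mm^3;
* CD4 test dates mis-reported by a bounded number of days;
* proxy dates of birth (1 Jan, 2 Feb, ... — day equals month) for women who
  do not know their DOB, used consistently by both studies;
* DOB typos, where the two studies disagree (these records are lost to exact
  DOB blocking — the method's stated limitation);
* discrepant ethnicity / country of birth between studies;
* proxy HIV-diagnosis dates (1 Jan / 30 Jun) when only the year is known;
* per-field missingness (soundex in particular is rarely supplied to the
  surveillance study).

Because the true identity of every generated woman is known, the generator
returns a :class:`~cohortlink.records.GroundTruth` map — the gold standard the
real studies lack — so linkage sensitivity and PPV can be measured exactly.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from datetime import date, timedelta

import numpy as np

from .records import (
    ARTEpisode,
    ClinicRecord,
    GroundTruth,
    LinkageConfig,
    Pregnancy,
    PregnancyRecord,
    ValidationError,
)

__all__ = [
    "SimulationParams",
    "generate_twin_cohorts",
    "pregnancy_window",
    "site_equivalence_map",
    "default_linkage_config",
    "UndefinedWindowError",
]

STUDY_START = date(1996, 1, 1)
STUDY_END = date(2009, 12, 31)

ZDV_MONO = "ZDVm"
COMBO_DRUGS = ("AZT+3TC+NVP", "AZT+3TC+LPV", "TDF+FTC+EFV", "ABC+3TC+EFV", "d4T+3TC+NVP")

ETHNICITY_P = {
    "black-African": 0.70,
    "black-Caribbean": 0.05,
    "black-other": 0.03,
    "white": 0.12,
    "other": 0.08,
    "not-known": 0.02,
}

COUNTRY_POOLS = {
    "black-African": ("Nigeria", "Ghana", "Uganda", "Zimbabwe", "Kenya", "Zambia",
                      "Malawi", "South Africa", "Cameroon", "Ivory Coast"),
    "black-Caribbean": ("Jamaica", "Barbados", "Trinidad and Tobago", "United Kingdom"),
    "black-other": ("United Kingdom", "Somalia", "Brazil"),
    "white": ("United Kingdom", "Ireland", "France", "Portugal", "Poland", "Spain"),
    "other": ("India", "Thailand", "Pakistan", "China", "Philippines", "United Kingdom"),
    "not-known": ("United Kingdom", "Nigeria"),
}

# default per-field missingness; pregnancy-side soundex reflects the ~3.4%
# completeness of soundex reporting to the surveillance study
DEFAULT_MISSINGNESS = {
    "soundex_clinic": 0.30,
    "soundex_pregnancy": 0.966,
    "country_of_birth": 0.05,
    "uk_arrival_date": 0.35,
    "hiv_diagnosis_date_clinic": 0.05,
    "hiv_diagnosis_date_pregnancy": 0.10,
    "expected_delivery_date": 0.10,
    "first_cd4": 0.15,
    "last_cd4": 0.30,
    "first_vl": 0.25,
    "last_vl": 0.40,
    "antenatal_art": 0.05,
}


@dataclass
class SimulationParams:
    """Study conditions for one simulated pair of cohorts.

    Discrepancy rates default to the frequencies observed in the real merged
    dataset where published (same-site attendance 92.1%, ethnicity discrepancy
    ~8.6%, country-of-birth discrepancy ~4.7%, proxy diagnosis dates ~5.6%);
    the remaining reporting-error rates are plausible defaults, stated here
    as configuration rather than asserted as estimates of the real studies.
    """

    n_clinic: int = 500
    n_pregnancy: int = 400
    overlap_fraction: float = 0.25
    p_repeat_pregnancy: float = 0.30
    p_proxy_dob: float = 0.03
    p_dob_typo: float = 0.02
    cd4_rounding: bool = True
    p_cd4_date_jitter: float = 0.10
    jitter_max_days: int = 14
    p_field_missing: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MISSINGNESS))
    p_ethnicity_discrepant: float = 0.086
    p_cob_discrepant: float = 0.047
    p_same_site: float = 0.921
    p_diag_proxy_date: float = 0.056
    n_maternity_sites: int = 40
    n_hiv_sites: int = 13
    seed: int = 0

    def validate(self) -> None:
        if self.n_clinic <= 0 or self.n_pregnancy <= 0:
            raise ValidationError("cohort sizes must be positive")
        probs = [self.overlap_fraction, self.p_repeat_pregnancy, self.p_proxy_dob,
                 self.p_dob_typo, self.p_cd4_date_jitter, self.p_ethnicity_discrepant,
                 self.p_cob_discrepant, self.p_same_site, self.p_diag_proxy_date,
                 *self.p_field_missing.values()]
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValidationError("probabilities must lie in [0, 1]")
        if round(self.overlap_fraction * self.n_pregnancy) > self.n_clinic:
            raise ValidationError("overlap exceeds clinic cohort size")

    @classmethod
    def noiseless(cls, **overrides) -> "SimulationParams":
        """All noise off: shared women are reported identically to both
        studies (and always attend equivalent sites)."""
        params = cls(
            p_proxy_dob=0.0, p_dob_typo=0.0, cd4_rounding=False,
            p_cd4_date_jitter=0.0, p_ethnicity_discrepant=0.0,
            p_cob_discrepant=0.0, p_same_site=1.0, p_diag_proxy_date=0.0,
            p_field_missing={k: 0.0 for k in DEFAULT_MISSINGNESS},
        )
        return dataclasses.replace(params, **overrides)


class UndefinedWindowError(ValueError):
    """A pregnancy has neither a delivery date nor an expected delivery date."""


def pregnancy_window(p: Pregnancy, config: LinkageConfig) -> tuple[date, date]:
    """Estimated (conception, end) window of a pregnancy.

    Conception is estimated by counting ``config.gestation_days`` back from
    the actual delivery date, or from the expected delivery date when the
    pregnancy has not (yet) ended.
    """
    anchor = p.delivery_date if p.delivery_date is not None else p.expected_delivery_date
    if anchor is None:
        raise UndefinedWindowError(
            "pregnancy has neither delivery nor expected delivery date")
    # inclusive day count: conception day and delivery day both belong to the
    # gestation_days-long pregnancy
    return anchor - timedelta(days=config.gestation_days - 1), anchor


def site_equivalence_map(params: SimulationParams) -> dict[str, tuple[str, ...]]:
    """Maternity site -> HIV site mapping used by the simulator.

    Maternity unit M{i} is co-located with HIV clinic H{i} for i below
    ``n_hiv_sites``; the remaining maternity units pair with HIV clinics
    outside the clinic cohort (X{i}), mirroring the partial coverage of a
    cohort drawn from a subset of a country's clinics.
    """
    return {
        f"M{i:02d}": ((f"H{i:02d}",) if i < params.n_hiv_sites else (f"X{i:02d}",))
        for i in range(params.n_maternity_sites)
    }


def default_linkage_config(params: SimulationParams, **overrides) -> LinkageConfig:
    """Linkage configuration whose site-equivalence table matches the
    simulated site universe."""
    return LinkageConfig(site_equivalence=site_equivalence_map(params),
                         seed=params.seed, **overrides)


# --------------------------------------------------------------------------
# latent truth


@dataclass
class _Latent:
    dob: date
    ethnicity: str
    cob: str
    soundex: str
    diagnosis: date
    uk_arrival: date | None
    care_start: date
    mat_site: str
    hiv_site: str
    cd4: list[tuple[date, int]]
    vl: list[tuple[date, int]]
    art: list[ARTEpisode]
    naive_until: date | None
    # (conception, end, delivery_or_None, edd, outcome)
    pregnancies: list[tuple[date, date, date | None, date, str]]


def _rand_date(rng: np.random.Generator, lo: date, hi: date) -> date:
    return date.fromordinal(int(rng.integers(lo.toordinal(), hi.toordinal() + 1)))


def _soundex_code(rng: np.random.Generator) -> str:
    letter = chr(ord("A") + int(rng.integers(0, 26)))
    return letter + "".join(str(int(rng.integers(0, 7))) for _ in range(3))


def _choice(rng: np.random.Generator, items, p=None):
    return items[int(rng.choice(len(items), p=p))]


def _latent_pregnancies(rng, care_start: date, gestation: int,
                        p_repeat: float) -> list[tuple[date, date, date | None, date, str]]:
    outcomes = ("live-birth", "miscarriage", "termination", "stillbirth",
                "ectopic", "continuing-to-term")
    outcome_p = (0.875, 0.055, 0.035, 0.010, 0.005, 0.020)
    n_preg = 1
    if rng.random() < p_repeat:
        n_preg += int(rng.integers(1, 3))
    latest_end = STUDY_END - timedelta(days=30)
    pregnancies = []
    end = min(care_start + timedelta(days=int(rng.integers(180, 1500))), latest_end)
    for k in range(n_preg):
        if k > 0:
            end = end + timedelta(days=int(rng.integers(550, 1200)))
            if end > latest_end:
                break
        outcome = _choice(rng, outcomes, p=outcome_p)
        conception = end - timedelta(days=gestation)
        edd = conception + timedelta(days=280)
        if outcome in ("miscarriage", "termination", "ectopic"):
            # pregnancy ended early: same conception, earlier end
            early_end = conception + timedelta(days=int(rng.integers(49, 150)))
            pregnancies.append((conception, early_end, early_end, edd, outcome))
        elif outcome == "continuing-to-term":
            pregnancies.append((conception, edd, None, edd, outcome))
        else:
            pregnancies.append((conception, end, end, edd, outcome))
    return pregnancies


def _latent_woman(rng: np.random.Generator, params: SimulationParams,
                  gestation: int, has_pregnancy: bool, in_clinic: bool) -> _Latent:
    care_start = _rand_date(rng, date(1997, 1, 1), date(2008, 6, 30))
    age_days = int(rng.integers(16 * 365, 49 * 365))
    dob = care_start - timedelta(days=age_days)
    if rng.random() < params.p_proxy_dob:
        m = int(rng.integers(1, 13))
        dob = date(dob.year, m, m)  # day-equals-month proxy, used by both studies

    ethnicity = _choice(rng, list(ETHNICITY_P), p=list(ETHNICITY_P.values()))
    cob = _choice(rng, COUNTRY_POOLS[ethnicity])
    soundex = _soundex_code(rng)
    diagnosis = care_start - timedelta(days=int(rng.integers(0, 90)))
    uk_arrival = None
    if cob != "United Kingdom":
        uk_arrival = diagnosis - timedelta(days=int(rng.integers(30, 1500)))

    # Only the first n_hiv_sites maternity units pair with a clinic-cohort
    # HIV site; women outside the clinic cohort receive HIV care elsewhere.
    if in_clinic:
        hiv_idx = int(rng.integers(0, params.n_hiv_sites))
        hiv_site = f"H{hiv_idx:02d}"
        if has_pregnancy and rng.random() < params.p_same_site:
            mat_site = f"M{hiv_idx:02d}"
        else:
            others = [i for i in range(params.n_maternity_sites) if i != hiv_idx]
            mat_site = f"M{others[int(rng.integers(0, len(others)))]:02d}"
    else:
        mat_idx = int(rng.integers(0, params.n_maternity_sites))
        mat_site = f"M{mat_idx:02d}"
        hiv_site = f"H{mat_idx:02d}" if mat_idx < params.n_hiv_sites else f"X{mat_idx:02d}"

    pregnancies = (
        _latent_pregnancies(rng, care_start, gestation, params.p_repeat_pregnancy)
        if has_pregnancy else []
    )

    # finite follow-up (2-8 years), extended to cover any pregnancy for
    # women under clinic care while pregnant
    care_end = min(care_start + timedelta(days=int(rng.integers(730, 2921))),
                   STUDY_END)
    if pregnancies:
        last_end = max(end for _, end, _, _, _ in pregnancies)
        care_end = min(STUDY_END,
                       max(care_end, last_end + timedelta(days=int(rng.integers(90, 721)))))

    # CD4 random walk at 2-6 month intervals over the care period
    cd4: list[tuple[date, int]] = []
    t = care_start
    v = float(np.clip(rng.normal(500.0, 150.0), 10.0, 1400.0))
    while t <= care_end:
        cd4.append((t, int(max(0, round(v)))))
        v = float(np.clip(v + rng.normal(0.0, 30.0), 10.0, 1400.0))
        t = t + timedelta(days=int(rng.integers(60, 181)))
    # antenatal CD4 monitoring: every pregnancy has at least one in-window test
    for conception, end, _, _, _ in pregnancies:
        if not any(conception < d <= end for d, _ in cd4):
            dur = (end - conception).days
            offset = int(rng.integers(60, max(61, min(201, dur)))) if dur > 61 else max(1, dur // 2)
            when = conception + timedelta(days=offset)
            nearest = min(cd4, key=lambda pt: abs((pt[0] - when).days))[1]
            cd4.append((when, int(max(0, round(nearest + rng.normal(0.0, 15.0))))))
    cd4.sort(key=lambda pt: pt[0])
    vl = [(d, int(10 ** rng.uniform(1.3, 5.3))) for d, _ in cd4]

    art: list[ARTEpisode] = []
    if rng.random() < 0.5:
        start = care_start + timedelta(days=int(rng.integers(0, 2000)))
        if start <= care_end:
            art.append(ARTEpisode(_choice(rng, COMBO_DRUGS), start, None, None))
    for conception, end, _, _, _ in pregnancies:
        if rng.random() >= 0.9:
            continue
        covered = any(ep.start <= end and (ep.stop is None or ep.stop >= conception)
                      for ep in art)
        dur = (end - conception).days
        if covered or dur <= 130:
            continue
        start = conception + timedelta(days=int(rng.integers(98, min(183, dur - 10))))
        stop = end + timedelta(days=int(rng.integers(0, 29)))
        drug = ZDV_MONO if rng.random() < 0.35 else _choice(rng, COMBO_DRUGS)
        reason = "pregnant" if rng.random() < 0.4 else None
        art.append(ARTEpisode(drug, start, stop, reason))
    art.sort(key=lambda ep: ep.start)
    naive_until = None if art else cd4[-1][0]

    return _Latent(dob=dob, ethnicity=ethnicity, cob=cob, soundex=soundex,
                   diagnosis=diagnosis, uk_arrival=uk_arrival,
                   care_start=care_start, mat_site=mat_site, hiv_site=hiv_site,
                   cd4=cd4, vl=vl, art=art, naive_until=naive_until,
                   pregnancies=pregnancies)


# --------------------------------------------------------------------------
# reporting a latent woman into each cohort


def _clinic_record(rng, params: SimulationParams, record_id: str,
                   w: _Latent) -> ClinicRecord:
    miss = params.p_field_missing
    return ClinicRecord(
        record_id=record_id,
        dob=w.dob,
        soundex=None if rng.random() < miss.get("soundex_clinic", 0.0) else w.soundex,
        ethnicity=w.ethnicity,
        country_of_birth=None if rng.random() < miss.get("country_of_birth", 0.0) else w.cob,
        hiv_diagnosis_date=(None if rng.random() < miss.get("hiv_diagnosis_date_clinic", 0.0)
                            else w.diagnosis),
        death_date=None,
        cd4_series=list(w.cd4),
        vl_series=list(w.vl),
        art_episodes=list(w.art),
        sites=[(w.hiv_site, w.care_start)],
        naive_until=w.naive_until,
    )


def _typo_dob(rng, dob: date) -> date:
    """A DOB the other study disagrees on: day/month transposition when it
    changes the date, otherwise a small day shift."""
    if rng.random() < 0.5 and dob.month != dob.day and dob.day <= 12:
        return date(dob.year, dob.day, dob.month)
    delta = int(rng.integers(1, 6)) * (1 if rng.random() < 0.5 else -1)
    return dob + timedelta(days=delta)


def _pregnancy_record(rng, params: SimulationParams, record_id: str,
                      w: _Latent, shared: bool) -> PregnancyRecord:
    miss = params.p_field_missing
    dob = w.dob
    if shared and rng.random() < params.p_dob_typo:
        dob = _typo_dob(rng, dob)
    ethnicity = w.ethnicity
    if shared and rng.random() < params.p_ethnicity_discrepant:
        others = [e for e in ETHNICITY_P if e not in (ethnicity, "not-known")]
        ethnicity = _choice(rng, others)
    cob = w.cob
    if shared and rng.random() < params.p_cob_discrepant:
        cob = "United Kingdom" if cob != "United Kingdom" else _choice(
            rng, COUNTRY_POOLS["black-African"])
    diagnosis = w.diagnosis
    if rng.random() < params.p_diag_proxy_date:
        month, day = (1, 1) if rng.random() < 0.5 else (6, 30)
        diagnosis = date(diagnosis.year, month, day)

    pregnancies = []
    for conception, end, delivery, edd, outcome in w.pregnancies:
        in_window_cd4 = [pt for pt in w.cd4 if conception < pt[0] <= end]
        in_window_vl = [pt for pt in w.vl if conception < pt[0] <= end]

        def report_cd4(pt, direction: int):
            d, c = pt
            if params.cd4_rounding:
                c = int(round(c / 10.0)) * 10
            if rng.random() < params.p_cd4_date_jitter:
                # jitter first dates backward and last dates forward so the
                # reported first/last ordering is preserved
                d = d + timedelta(days=direction * int(rng.integers(1, params.jitter_max_days + 1)))
            return (d, c)

        first_cd4 = report_cd4(in_window_cd4[0], -1) if in_window_cd4 else None
        last_cd4 = report_cd4(in_window_cd4[-1], +1) if in_window_cd4 else None
        if rng.random() < miss.get("first_cd4", 0.0):
            first_cd4 = None
        if rng.random() < miss.get("last_cd4", 0.0):
            last_cd4 = None
        first_vl = in_window_vl[0] if in_window_vl else None
        last_vl = in_window_vl[-1] if in_window_vl else None
        if rng.random() < miss.get("first_vl", 0.0):
            first_vl = None
        if rng.random() < miss.get("last_vl", 0.0):
            last_vl = None

        antenatal = [ARTEpisode(ep.drug, ep.start, ep.stop)
                     for ep in w.art
                     if ep.start <= end and (ep.stop is None or ep.stop >= conception)]
        if rng.random() < miss.get("antenatal_art", 0.0):
            antenatal = []

        pregnancies.append(Pregnancy(
            expected_delivery_date=(None if rng.random() < miss.get("expected_delivery_date", 0.0)
                                    else edd),
            delivery_date=delivery,
            outcome=outcome,
            antenatal_art=antenatal,
            first_cd4=first_cd4,
            last_cd4=last_cd4,
            first_vl=first_vl,
            last_vl=last_vl,
            site=w.mat_site,
        ))

    return PregnancyRecord(
        record_id=record_id,
        dob=dob,
        soundex=None if rng.random() < miss.get("soundex_pregnancy", 0.0) else w.soundex,
        ethnicity=ethnicity,
        country_of_birth=None if rng.random() < miss.get("country_of_birth", 0.0) else cob,
        uk_arrival_date=(None if rng.random() < miss.get("uk_arrival_date", 0.0)
                         else w.uk_arrival),
        hiv_diagnosis_date=(None if rng.random() < miss.get("hiv_diagnosis_date_pregnancy", 0.0)
                            else diagnosis),
        pregnancies=pregnancies,
    )


def generate_twin_cohorts(
    params: SimulationParams,
    config: LinkageConfig | None = None,
) -> tuple[list[ClinicRecord], list[PregnancyRecord], GroundTruth]:
    """Generate a clinic cohort, a pregnancy cohort, and the true identity map.

    Exactly ``round(overlap_fraction * n_pregnancy)`` women appear in both
    cohorts.  Identical ``params`` (including ``seed``) give byte-identical
    cohorts.
    """
    params.validate()
    gestation = (config or LinkageConfig()).gestation_days
    rng = np.random.default_rng(params.seed)

    n_shared = round(params.overlap_fraction * params.n_pregnancy)
    n_total = params.n_clinic + params.n_pregnancy - n_shared
    # women [0, n_shared) are shared; [n_shared, n_clinic) clinic-only;
    # [n_clinic, n_total) pregnancy-only
    women = [
        _latent_woman(rng, params, gestation,
                      has_pregnancy=(i < n_shared or i >= params.n_clinic),
                      in_clinic=(i < params.n_clinic))
        for i in range(n_total)
    ]

    clinic_order = [int(i) for i in rng.permutation(params.n_clinic)]
    preg_members = list(range(n_shared)) + list(range(params.n_clinic, n_total))
    preg_order = [preg_members[int(i)] for i in rng.permutation(params.n_pregnancy)]

    clinic_ids = {w_idx: f"C{pos:04d}" for pos, w_idx in enumerate(clinic_order)}
    preg_ids = {w_idx: f"P{pos:04d}" for pos, w_idx in enumerate(preg_order)}

    clinic = [_clinic_record(rng, params, clinic_ids[i], women[i])
              for i in clinic_order]
    pregnancy = [_pregnancy_record(rng, params, preg_ids[i], women[i],
                                   shared=i < n_shared)
                 for i in preg_order]

    truth = GroundTruth({preg_ids[i]: clinic_ids[i] for i in range(n_shared)})
    truth.validate()
    return clinic, pregnancy, truth
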