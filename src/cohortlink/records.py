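"""Domain types shared by every stage of the linkage pipeline.

Two cohorts are represented: a longitudinal HIV *clinic* cohort (full CD4 and
viral-load series, antiretroviral-therapy episodes, sites attended) and a
per-pregnancy *surveillance* cohort (one record per woman, one entry per
pregnancy, with only the first and last CD4/viral-load of each pregnancy).
Neither cohort carries a unique shared identifier; date of birth and clinical
dates act as quasi-identifiers.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date

__all__ = [
    "ETHNICITY_VOCAB",
    "OUTCOME_VOCAB",
    "ValidationError",
    "SchemaError",
    "ARTEpisode",
    "Pregnancy",
    "ClinicRecord",
    "PregnancyRecord",
    "LinkageConfig",
    "AuditEvent",
    "CandidatePair",
    "MatchDecision",
    "GroundTruth",
]

ETHNICITY_VOCAB = (
    "black-African",
    "black-Caribbean",
    "black-other",
    "white",
    "other",
    "not-known",
)

OUTCOME_VOCAB = (
    "live-birth",
    "miscarriage",
    "termination",
    "stillbirth",
    "ectopic",
    "continuing-to-term",
    "other-missing",
)


class ValidationError(ValueError):
    """A record violates a domain invariant (bad vocabulary, bad dates...)."""


class SchemaError(ValueError):
    """An input file does not follow the documented column contract."""


@dataclass(frozen=True)
class ARTEpisode:
    """One antiretroviral-therapy episode: drug code with start/stop dates.

    ``drug`` may be None when the reporting study did not record it.  ``reason``
    is a free-text code for starting/stopping (the value "pregnant" is
    meaningful to the manual-review stage).
    """

    drug: str | None
    start: date
    stop: date | None = None
    reason: str | None = None

    def validate(self) -> None:
        if self.stop is not None and self.stop < self.start:
            raise ValidationError(
                f"ART episode stop {self.stop} precedes start {self.start}"
            )


@dataclass
class Pregnancy:
    """One reported pregnancy in the surveillance cohort."""

    expected_delivery_date: date | None = None
    delivery_date: date | None = None
    outcome: str = "other-missing"
    antenatal_art: list[ARTEpisode] = field(default_factory=list)
    first_cd4: tuple[date, int] | None = None
    last_cd4: tuple[date, int] | None = None
    first_vl: tuple[date, int] | None = None
    last_vl: tuple[date, int] | None = None
    site: str | None = None

    def validate(self) -> None:
        if self.outcome not in OUTCOME_VOCAB:
            raise ValidationError(f"unknown pregnancy outcome {self.outcome!r}")
        if self.first_cd4 is not None and self.last_cd4 is not None:
            if self.first_cd4[0] > self.last_cd4[0]:
                raise ValidationError(
                    "first_cd4 date after last_cd4 date "
                    f"({self.first_cd4[0]} > {self.last_cd4[0]})"
                )
        for ep in self.antenatal_art:
            ep.validate()


@dataclass
class ClinicRecord:
    """One woman's longitudinal record in the HIV clinical cohort."""

    record_id: str
    dob: date
    soundex: str | None = None
    ethnicity: str = "not-known"
    country_of_birth: str | None = None
    hiv_diagnosis_date: date | None = None
    death_date: date | None = None
    cd4_series: list[tuple[date, int]] = field(default_factory=list)
    vl_series: list[tuple[date, int]] = field(default_factory=list)
    art_episodes: list[ARTEpisode] = field(default_factory=list)
    sites: list[tuple[str, date]] = field(default_factory=list)
    naive_until: date | None = None

    def validate(self) -> None:
        if self.ethnicity not in ETHNICITY_VOCAB:
            raise ValidationError(
                f"{self.record_id}: unknown ethnicity {self.ethnicity!r}"
            )
        for d, count in self.cd4_series:
            if count < 0:
                raise ValidationError(
                    f"{self.record_id}: negative CD4 count {count} on {d}"
                )
        for ep in self.art_episodes:
            ep.validate()


@dataclass
class PregnancyRecord:
    """One woman's record in the pregnancy-surveillance cohort."""

    record_id: str
    dob: date
    soundex: str | None = None
    ethnicity: str = "not-known"
    country_of_birth: str | None = None
    uk_arrival_date: date | None = None
    hiv_diagnosis_date: date | None = None
    pregnancies: list[Pregnancy] = field(default_factory=list)

    def validate(self) -> None:
        if self.ethnicity not in ETHNICITY_VOCAB:
            raise ValidationError(
                f"{self.record_id}: unknown ethnicity {self.ethnicity!r}"
            )
        if not self.pregnancies:
            raise ValidationError(f"{self.record_id}: no pregnancies recorded")
        for p in self.pregnancies:
            p.validate()


@dataclass
class LinkageConfig:
    """Tunable thresholds and windows of the matching cascade.

    Defaults follow the published criteria: CD4 counts agree within 10
    cells/mm^3 (surveillance forms round to the nearest 10), CD4 dates within
    30 days, ART dates within 7 days, manual review of CD4 differences above
    100 cells/mm^3, and 1 January / 30 June as proxy dates standing in for a
    year-only HIV-diagnosis date.
    """

    cd4_count_tolerance: int = 10
    cd4_manual_check_threshold: int = 100
    cd4_date_window_days: int = 30
    art_date_window_days: int = 7
    diagnosis_date_window_days: int = 30
    proxy_diagnosis_dates: tuple[tuple[int, int], ...] = ((1, 1), (6, 30))
    # day-equals-month convention (1 Jan, 2 Feb, ...) used by the simulator
    proxy_dob_dates: tuple[tuple[int, int], ...] = tuple((m, m) for m in range(1, 13))
    site_equivalence: dict[str, tuple[str, ...]] = field(default_factory=dict)
    gestation_days: int = 266
    cd4_threshold_art_profile: int = 350
    first_trimester_days: int = 91
    corroboration_threshold: int = 2
    seed: int = 0

    def validate(self) -> None:
        for name in (
            "cd4_count_tolerance",
            "cd4_manual_check_threshold",
            "cd4_date_window_days",
            "art_date_window_days",
            "diagnosis_date_window_days",
            "gestation_days",
            "first_trimester_days",
        ):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")

    def sites_equivalent(self, maternity_site: str | None, hiv_site: str | None) -> bool:
        """True when a maternity site and an HIV-care site count as the same
        site (identical code, or paired in the equivalence mapping)."""
        if maternity_site is None or hiv_site is None:
            return False
        if maternity_site == hiv_site:
            return True
        return hiv_site in self.site_equivalence.get(maternity_site, ())


AUDIT_ACTIONS = (
    "linked",
    "matched",
    "rejected",
    "removed-as-side-effect",
    "flagged-manual",
    "unmatched-after-discrepancy",
)


@dataclass
class AuditEvent:
    """One step of the execution trace: what happened to one candidate pair."""

    clinic_id: str
    pregnancy_id: str
    action: str
    stage: str | None = None
    criterion: str | None = None
    evidence: list[tuple[str, str, str]] = field(default_factory=list)

    def validate(self) -> None:
        if self.action not in AUDIT_ACTIONS:
            raise ValidationError(f"unknown audit action {self.action!r}")


@dataclass(frozen=True)
class CandidatePair:
    """A clinic/pregnancy record pair sharing the blocking key (identical DOB)."""

    clinic_id: str
    pregnancy_id: str
    dob: date

    @property
    def key(self) -> tuple[str, str]:
        return (self.clinic_id, self.pregnancy_id)


STAGES = ("CD4-exact", "CD4-window", "ART-exact", "ART-window", "manual")

CRITERIA = (
    "cd4±10",
    "diagnosis-date",
    "site",
    "drug+start+stop",
    "drug+start|stop",
    "start+stop",
    "start|stop+site",
    "start|stop+diagnosis-date",
    "art-date",
    "soundex",
    "art-profile",
)


@dataclass
class MatchDecision:
    """A confirmed (or, for manual flags, provisional) match with its evidence."""

    pair: CandidatePair
    stage: str
    criterion: str
    manual_flag: bool = False
    evidence: list[tuple[str, str, str]] = field(default_factory=list)

    def validate(self) -> None:
        if self.stage not in STAGES:
            raise ValidationError(f"unknown stage {self.stage!r}")
        if self.criterion not in CRITERIA:
            raise ValidationError(f"unknown criterion {self.criterion!r}")


@dataclass
class GroundTruth:
    """Injective map pregnancy record_id -> clinic record_id for truly shared
    women; supplied by the simulator (no gold standard exists for real data)."""

    mapping: dict[str, str] = field(default_factory=dict)

    def validate(self) -> None:
        clinic_ids = list(self.mapping.values())
        if len(set(clinic_ids)) != len(clinic_ids):
            raise ValidationError("ground truth is not one-to-one")

    def pairs(self) -> set[tuple[str, str]]:
        """Set of (clinic_id, pregnancy_id) true pairs."""
        return {(c, p) for p, c in self.mapping.items()}

    def __len__(self) -> int:
        return len(self.mapping)
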