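"""Reading, validating and writing the cohort CSV files, the linkage
configuration (YAML) and the audit trail (JSON lines).

File layout
-----------
Clinic cohort (one directory):
    clinic_demographics.csv  record_id,dob,soundex,ethnicity,country_of_birth,
                             hiv_diagnosis_date,death_date,naive_until
    clinic_cd4.csv           record_id,date,count
    clinic_vl.csv            record_id,date,copies
    clinic_art.csv           record_id,drug,start,stop,reason
    clinic_sites.csv         record_id,site,first_seen

Pregnancy cohort (one directory):
    pregnancy_demographics.csv  record_id,dob,soundex,ethnicity,
                                country_of_birth,uk_arrival_date,
                                hiv_diagnosis_date
    pregnancy_events.csv        record_id,pregnancy_index,expected_delivery_date,
                                delivery_date,outcome,first_cd4_date,
                                first_cd4_count,last_cd4_date,last_cd4_count,
                                first_vl_date,first_vl_copies,last_vl_date,
                                last_vl_copies,site
    pregnancy_art.csv           record_id,pregnancy_index,drug,start,stop

Dates are ISO-8601; missing values are empty strings.  Partially-known dates
are not accepted: upstream systems emit proxy dates (1 Jan / 30 Jun), which
the harmonizer understands.  Every input row is either parsed into exactly one
record or named in exactly one rejection report.
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from datetime import date
from pathlib import Path

import pandas as pd
import yaml

from .records import (
    ARTEpisode,
    AuditEvent,
    ClinicRecord,
    GroundTruth,
    LinkageConfig,
    OUTCOME_VOCAB,
    Pregnancy,
    PregnancyRecord,
    SchemaError,
    ValidationError,
)

__all__ = [
    "Rejection",
    "read_clinic_cohort",
    "write_clinic_cohort",
    "read_pregnancy_cohort",
    "write_pregnancy_cohort",
    "read_audit_trail",
    "write_audit_trail",
    "read_config",
    "write_config",
    "read_ground_truth",
    "write_ground_truth",
]

CLINIC_FILES = {
    "demographics": "clinic_demographics.csv",
    "cd4": "clinic_cd4.csv",
    "vl": "clinic_vl.csv",
    "art": "clinic_art.csv",
    "sites": "clinic_sites.csv",
}
PREGNANCY_FILES = {
    "demographics": "pregnancy_demographics.csv",
    "events": "pregnancy_events.csv",
    "art": "pregnancy_art.csv",
}

CLINIC_SCHEMA = {
    "demographics": [
        "record_id", "dob", "soundex", "ethnicity", "country_of_birth",
        "hiv_diagnosis_date", "death_date", "naive_until",
    ],
    "cd4": ["record_id", "date", "count"],
    "vl": ["record_id", "date", "copies"],
    "art": ["record_id", "drug", "start", "stop", "reason"],
    "sites": ["record_id", "site", "first_seen"],
}
PREGNANCY_SCHEMA = {
    "demographics": [
        "record_id", "dob", "soundex", "ethnicity", "country_of_birth",
        "uk_arrival_date", "hiv_diagnosis_date",
    ],
    "events": [
        "record_id", "pregnancy_index", "expected_delivery_date",
        "delivery_date", "outcome", "first_cd4_date", "first_cd4_count",
        "last_cd4_date", "last_cd4_count", "first_vl_date", "first_vl_copies",
        "last_vl_date", "last_vl_copies", "site",
    ],
    "art": ["record_id", "pregnancy_index", "drug", "start", "stop"],
}


@dataclass
class Rejection:
    """One input row that could not enter the pipeline, and why."""

    table: str
    row: int  # 0-based data-row index within the table
    record_id: str | None
    reason: str


def _read_table(path: Path, columns: list[str], table: str) -> pd.DataFrame:
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in columns:
        if col not in df.columns:
            raise SchemaError(f"{table}: missing mandatory column {col!r}")
    return df


def _opt(value: str) -> str | None:
    return value if value != "" else None


def _opt_date(value: str) -> date | None:
    return date.fromisoformat(value) if value != "" else None


def _opt_int(value: str) -> int | None:
    return int(value) if value != "" else None


def _fmt(value: object) -> str:
    return "" if value is None else str(value)


def read_clinic_cohort(
    path: str | Path, schema: dict[str, list[str]] | None = None
) -> tuple[list[ClinicRecord], list[Rejection]]:
    """Read a clinic-cohort directory into validated records.

    Rows with an unparseable DOB (they could never enter DOB blocking) and
    event rows referencing an unknown record_id are reported as rejections
    rather than aborting the read.  Structural problems — missing columns,
    duplicate record_ids — raise.
    """
    path = Path(path)
    schema = schema or CLINIC_SCHEMA
    rejections: list[Rejection] = []

    demo = _read_table(path / CLINIC_FILES["demographics"], schema["demographics"], "clinic_demographics")
    if demo["record_id"].duplicated().any():
        dup = demo.loc[demo["record_id"].duplicated(), "record_id"].iloc[0]
        raise ValidationError(f"clinic_demographics: duplicate record_id {dup!r}")

    records: dict[str, ClinicRecord] = {}
    for i, row in enumerate(demo.itertuples(index=False)):
        try:
            dob = date.fromisoformat(row.dob)
        except ValueError:
            rejections.append(
                Rejection("clinic_demographics", i, row.record_id,
                          f"invalid DOB {row.dob!r}")
            )
            continue
        rec = ClinicRecord(
            record_id=row.record_id,
            dob=dob,
            soundex=_opt(row.soundex),
            ethnicity=row.ethnicity or "not-known",
            country_of_birth=_opt(row.country_of_birth),
            hiv_diagnosis_date=_opt_date(row.hiv_diagnosis_date),
            death_date=_opt_date(row.death_date),
            naive_until=_opt_date(row.naive_until),
        )
        records[rec.record_id] = rec

    def attach(table: str, fn) -> None:
        df = _read_table(path / CLINIC_FILES[table], schema[table], f"clinic_{table}")
        for i, row in enumerate(df.itertuples(index=False)):
            rec = records.get(row.record_id)
            if rec is None:
                rejections.append(
                    Rejection(f"clinic_{table}", i, row.record_id,
                              "unknown or rejected record_id")
                )
                continue
            try:
                fn(rec, row)
            except (ValueError, ValidationError) as exc:
                rejections.append(Rejection(f"clinic_{table}", i, row.record_id, str(exc)))

    attach("cd4", lambda r, x: r.cd4_series.append((date.fromisoformat(x.date), int(x.count))))
    attach("vl", lambda r, x: r.vl_series.append((date.fromisoformat(x.date), int(x.copies))))
    attach("art", lambda r, x: r.art_episodes.append(
        ARTEpisode(drug=_opt(x.drug), start=date.fromisoformat(x.start),
                   stop=_opt_date(x.stop), reason=_opt(x.reason))))
    attach("sites", lambda r, x: r.sites.append((x.site, date.fromisoformat(x.first_seen))))

    out = list(records.values())
    for rec in out:
        rec.validate()
    return out, rejections


def write_clinic_cohort(records: list[ClinicRecord], path: str | Path) -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    demo, cd4, vl, art, sites = [], [], [], [], []
    for r in records:
        demo.append({
            "record_id": r.record_id, "dob": r.dob.isoformat(),
            "soundex": _fmt(r.soundex), "ethnicity": r.ethnicity,
            "country_of_birth": _fmt(r.country_of_birth),
            "hiv_diagnosis_date": _fmt(r.hiv_diagnosis_date),
            "death_date": _fmt(r.death_date),
            "naive_until": _fmt(r.naive_until),
        })
        cd4.extend({"record_id": r.record_id, "date": d.isoformat(), "count": c}
                   for d, c in r.cd4_series)
        vl.extend({"record_id": r.record_id, "date": d.isoformat(), "copies": c}
                  for d, c in r.vl_series)
        art.extend({"record_id": r.record_id, "drug": _fmt(ep.drug),
                    "start": ep.start.isoformat(), "stop": _fmt(ep.stop),
                    "reason": _fmt(ep.reason)}
                   for ep in r.art_episodes)
        sites.extend({"record_id": r.record_id, "site": s,
                      "first_seen": d.isoformat()} for s, d in r.sites)
    for name, rows in [("demographics", demo), ("cd4", cd4), ("vl", vl),
                       ("art", art), ("sites", sites)]:
        pd.DataFrame(rows, columns=CLINIC_SCHEMA[name]).to_csv(
            path / CLINIC_FILES[name], index=False)


def read_pregnancy_cohort(
    path: str | Path, schema: dict[str, list[str]] | None = None
) -> tuple[list[PregnancyRecord], list[Rejection]]:
    """Read a pregnancy-cohort directory; event rows sharing a record_id are
    grouped into one PregnancyRecord per woman."""
    path = Path(path)
    schema = schema or PREGNANCY_SCHEMA
    rejections: list[Rejection] = []

    demo = _read_table(path / PREGNANCY_FILES["demographics"], schema["demographics"], "pregnancy_demographics")
    if demo["record_id"].duplicated().any():
        dup = demo.loc[demo["record_id"].duplicated(), "record_id"].iloc[0]
        raise ValidationError(f"pregnancy_demographics: duplicate record_id {dup!r}")

    records: dict[str, PregnancyRecord] = {}
    for i, row in enumerate(demo.itertuples(index=False)):
        try:
            dob = date.fromisoformat(row.dob)
        except ValueError:
            rejections.append(
                Rejection("pregnancy_demographics", i, row.record_id,
                          f"invalid DOB {row.dob!r}")
            )
            continue
        records[row.record_id] = PregnancyRecord(
            record_id=row.record_id,
            dob=dob,
            soundex=_opt(row.soundex),
            ethnicity=row.ethnicity or "not-known",
            country_of_birth=_opt(row.country_of_birth),
            uk_arrival_date=_opt_date(row.uk_arrival_date),
            hiv_diagnosis_date=_opt_date(row.hiv_diagnosis_date),
        )

    events = _read_table(path / PREGNANCY_FILES["events"], schema["events"], "pregnancy_events")
    pregnancy_by_key: dict[tuple[str, int], Pregnancy] = {}
    for i, row in enumerate(events.itertuples(index=False)):
        rec = records.get(row.record_id)
        if rec is None:
            rejections.append(Rejection("pregnancy_events", i, row.record_id,
                                        "unknown or rejected record_id"))
            continue
        if row.outcome not in OUTCOME_VOCAB:
            raise ValidationError(
                f"pregnancy_events row {i}: outcome {row.outcome!r} "
                f"not in vocabulary {OUTCOME_VOCAB}")
        try:
            def pair(dcol, vcol):
                d, v = getattr(row, dcol), getattr(row, vcol)
                return (date.fromisoformat(d), int(v)) if d != "" else None
            preg = Pregnancy(
                expected_delivery_date=_opt_date(row.expected_delivery_date),
                delivery_date=_opt_date(row.delivery_date),
                outcome=row.outcome,
                first_cd4=pair("first_cd4_date", "first_cd4_count"),
                last_cd4=pair("last_cd4_date", "last_cd4_count"),
                first_vl=pair("first_vl_date", "first_vl_copies"),
                last_vl=pair("last_vl_date", "last_vl_copies"),
                site=_opt(row.site),
            )
        except ValueError as exc:
            rejections.append(Rejection("pregnancy_events", i, row.record_id, str(exc)))
            continue
        rec.pregnancies.append(preg)
        pregnancy_by_key[(row.record_id, int(row.pregnancy_index))] = preg

    art = _read_table(path / PREGNANCY_FILES["art"], schema["art"], "pregnancy_art")
    for i, row in enumerate(art.itertuples(index=False)):
        preg = pregnancy_by_key.get((row.record_id, int(row.pregnancy_index)))
        if preg is None:
            rejections.append(Rejection("pregnancy_art", i, row.record_id,
                                        "unknown record_id/pregnancy_index"))
            continue
        try:
            preg.antenatal_art.append(
                ARTEpisode(drug=_opt(row.drug), start=date.fromisoformat(row.start),
                           stop=_opt_date(row.stop)))
        except ValueError as exc:
            rejections.append(Rejection("pregnancy_art", i, row.record_id, str(exc)))

    # a demographics row with no surviving pregnancy rows cannot be validated
    out = []
    for rec in records.values():
        if not rec.pregnancies:
            rejections.append(Rejection("pregnancy_demographics", -1, rec.record_id,
                                        "no pregnancies recorded"))
            continue
        rec.validate()
        out.append(rec)
    return out, rejections


def write_pregnancy_cohort(records: list[PregnancyRecord], path: str | Path) -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    demo, events, art = [], [], []
    for r in records:
        demo.append({
            "record_id": r.record_id, "dob": r.dob.isoformat(),
            "soundex": _fmt(r.soundex), "ethnicity": r.ethnicity,
            "country_of_birth": _fmt(r.country_of_birth),
            "uk_arrival_date": _fmt(r.uk_arrival_date),
            "hiv_diagnosis_date": _fmt(r.hiv_diagnosis_date),
        })
        for k, p in enumerate(r.pregnancies):
            events.append({
                "record_id": r.record_id, "pregnancy_index": k,
                "expected_delivery_date": _fmt(p.expected_delivery_date),
                "delivery_date": _fmt(p.delivery_date),
                "outcome": p.outcome,
                "first_cd4_date": _fmt(p.first_cd4 and p.first_cd4[0]),
                "first_cd4_count": _fmt(p.first_cd4 and p.first_cd4[1]),
                "last_cd4_date": _fmt(p.last_cd4 and p.last_cd4[0]),
                "last_cd4_count": _fmt(p.last_cd4 and p.last_cd4[1]),
                "first_vl_date": _fmt(p.first_vl and p.first_vl[0]),
                "first_vl_copies": _fmt(p.first_vl and p.first_vl[1]),
                "last_vl_date": _fmt(p.last_vl and p.last_vl[0]),
                "last_vl_copies": _fmt(p.last_vl and p.last_vl[1]),
                "site": _fmt(p.site),
            })
            art.extend({"record_id": r.record_id, "pregnancy_index": k,
                        "drug": _fmt(ep.drug), "start": ep.start.isoformat(),
                        "stop": _fmt(ep.stop)} for ep in p.antenatal_art)
    for name, rows in [("demographics", demo), ("events", events), ("art", art)]:
        pd.DataFrame(rows, columns=PREGNANCY_SCHEMA[name]).to_csv(
            path / PREGNANCY_FILES[name], index=False)


def write_audit_trail(events: list[AuditEvent], path: str | Path) -> None:
    """Write the audit trail as JSON lines, one event per line, replayable."""
    with open(path, "w", encoding="utf-8") as fh:
        for ev in events:
            fh.write(json.dumps({
                "clinic_id": ev.clinic_id,
                "pregnancy_id": ev.pregnancy_id,
                "action": ev.action,
                "stage": ev.stage,
                "criterion": ev.criterion,
                "evidence": [list(e) for e in ev.evidence],
            }, ensure_ascii=False) + "\n")


def read_audit_trail(path: str | Path) -> list[AuditEvent]:
    events = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.strip():
                continue
            d = json.loads(line)
            events.append(AuditEvent(
                clinic_id=d["clinic_id"], pregnancy_id=d["pregnancy_id"],
                action=d["action"], stage=d["stage"], criterion=d["criterion"],
                evidence=[tuple(e) for e in d["evidence"]],
            ))
    return events


def write_config(config: LinkageConfig, path: str | Path) -> None:
    d = dataclasses.asdict(config)
    d["proxy_diagnosis_dates"] = [list(x) for x in config.proxy_diagnosis_dates]
    d["proxy_dob_dates"] = [list(x) for x in config.proxy_dob_dates]
    d["site_equivalence"] = {k: list(v) for k, v in config.site_equivalence.items()}
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(d, fh, sort_keys=False)


def read_config(path: str | Path) -> LinkageConfig:
    with open(path, encoding="utf-8") as fh:
        d = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(LinkageConfig)}
    unknown = set(d) - known
    if unknown:
        raise SchemaError(f"unknown configuration keys: {sorted(unknown)}")
    if "proxy_diagnosis_dates" in d:
        d["proxy_diagnosis_dates"] = tuple(tuple(x) for x in d["proxy_diagnosis_dates"])
    if "proxy_dob_dates" in d:
        d["proxy_dob_dates"] = tuple(tuple(x) for x in d["proxy_dob_dates"])
    if "site_equivalence" in d:
        d["site_equivalence"] = {k: tuple(v) for k, v in d["site_equivalence"].items()}
    config = LinkageConfig(**d)
    config.validate()
    return config


def write_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    rows = [{"pregnancy_id": p, "clinic_id": c} for p, c in sorted(truth.mapping.items())]
    pd.DataFrame(rows, columns=["pregnancy_id", "clinic_id"]).to_csv(path, index=False)


def read_ground_truth(path: str | Path) -> GroundTruth:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    truth = GroundTruth(dict(zip(df["pregnancy_id"], df["clinic_id"])))
    truth.validate()
    return truth
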