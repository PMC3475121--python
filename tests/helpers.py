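"""Builders for small hand-crafted records used across the test suite."""
from __future__ import annotations

from datetime import date

from cohortlink import (
    ARTEpisode,
    ClinicRecord,
    LinkageConfig,
    Pregnancy,
    PregnancyRecord,
)

D = date.fromisoformat


def clinic(record_id="C1", dob="1975-03-14", **kw) -> ClinicRecord:
    rec = ClinicRecord(record_id=record_id, dob=D(dob), **kw)
    rec.validate()
    return rec


def pregnancy(**kw) -> Pregnancy:
    for key in ("expected_delivery_date", "delivery_date"):
        if isinstance(kw.get(key), str):
            kw[key] = D(kw[key])
    p = Pregnancy(**kw)
    p.validate()
    return p


def preg_record(record_id="P1", dob="1975-03-14", pregnancies=None, **kw) -> PregnancyRecord:
    rec = PregnancyRecord(
        record_id=record_id, dob=D(dob),
        pregnancies=pregnancies if pregnancies is not None
        else [pregnancy(delivery_date="2005-09-23", outcome="live-birth")],
        **kw)
    rec.validate()
    return rec


def art(drug, start, stop=None, reason=None) -> ARTEpisode:
    return ARTEpisode(drug=drug, start=D(start),
                      stop=D(stop) if stop else None, reason=reason)


def config(**kw) -> LinkageConfig:
    return LinkageConfig(**kw)
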