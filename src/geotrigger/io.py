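"""Flat-file formats: CSV fix streams and consent logs, GeoJSON
gazetteers, JSON-lines alerts/surveys/reports, CSV gold-event logs.

All timestamps are ISO-8601 UTC (naive, seconds resolution); dates are
ISO calendar dates.
"""

from __future__ import annotations

import json
from datetime import date, datetime
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .dwell import ConsentInterval, GeoFix, GeofenceAlert
from .evaluate import ChannelReport, GoldEvent
from .gazetteer import Gazetteer, gazetteer_to_geojson
from .surveys import SurveyInstance

__all__ = [
    "read_traces", "write_traces",
    "read_consent", "write_consent",
    "read_gold", "write_gold",
    "read_reports", "write_reports",
    "write_alerts", "write_surveys", "write_gazetteer",
]

_TS = "%Y-%m-%dT%H:%M:%S"


def _parse_ts(s: str) -> datetime:
    return datetime.strptime(s, _TS)


def write_traces(path: str | Path, traces: Mapping[str, Sequence[GeoFix]] | Iterable[GeoFix]) -> None:
    if isinstance(traces, Mapping):
        fixes = [f for pid in sorted(traces) for f in traces[pid]]
    else:
        fixes = list(traces)
    df = pd.DataFrame(
        {
            "participant_id": [f.participant_id for f in fixes],
            "timestamp": [f.timestamp.strftime(_TS) for f in fixes],
            "lat": [f.lat for f in fixes],
            "lon": [f.lon for f in fixes],
        }
    )
    df.to_csv(path, index=False)


def read_traces(path: str | Path) -> dict[str, list[GeoFix]]:
    # round_trip: the default float parser is not exact, and fix
    # coordinates must survive a write/read cycle bit-identically
    df = pd.read_csv(path, dtype={"participant_id": str}, float_precision="round_trip")
    out: dict[str, list[GeoFix]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(row.participant_id, []).append(
            GeoFix(row.participant_id, _parse_ts(row.timestamp), float(row.lat), float(row.lon))
        )
    return out


def write_consent(path: str | Path, consent: Sequence[ConsentInterval]) -> None:
    df = pd.DataFrame(
        {
            "participant_id": [c.participant_id for c in consent],
            "start": [c.start.strftime(_TS) for c in consent],
            "end": ["" if c.end is None else c.end.strftime(_TS) for c in consent],
        }
    )
    df.to_csv(path, index=False)


def read_consent(path: str | Path) -> list[ConsentInterval]:
    df = pd.read_csv(path, dtype={"participant_id": str}, keep_default_na=False)
    return [
        ConsentInterval(
            row.participant_id,
            _parse_ts(row.start),
            None if row.end == "" else _parse_ts(row.end),
        )
        for row in df.itertuples(index=False)
    ]


def write_gold(path: str | Path, gold: Sequence[GoldEvent]) -> None:
    df = pd.DataFrame(
        {
            "event_id": [g.event_id for g in gold],
            "participant_id": [g.participant_id for g in gold],
            "admit_date": [g.admit_date.isoformat() for g in gold],
            "discharge_date": [g.discharge_date.isoformat() for g in gold],
            "is_cv": [int(g.is_cv) for g in gold],
            "is_overnight": [int(g.is_overnight) for g in gold],
            "coordinator_ascertained_on": [
                "" if g.coordinator_ascertained_on is None else g.coordinator_ascertained_on.isoformat()
                for g in gold
            ],
        }
    )
    df.to_csv(path, index=False)


def read_gold(path: str | Path) -> list[GoldEvent]:
    df = pd.read_csv(path, dtype={"participant_id": str, "event_id": str}, keep_default_na=False)
    return [
        GoldEvent(
            event_id=row.event_id,
            participant_id=row.participant_id,
            admit_date=date.fromisoformat(row.admit_date),
            discharge_date=date.fromisoformat(row.discharge_date),
            is_cv=bool(int(row.is_cv)),
            is_overnight=bool(int(row.is_overnight)),
            coordinator_ascertained_on=(
                None if row.coordinator_ascertained_on == "" else date.fromisoformat(row.coordinator_ascertained_on)
            ),
        )
        for row in df.itertuples(index=False)
    ]


def write_reports(path: str | Path, reports: Sequence[ChannelReport]) -> None:
    with open(path, "w") as fh:
        for r in reports:
            fh.write(json.dumps({
                "report_id": r.report_id,
                "participant_id": r.participant_id,
                "channel": r.channel,
                "report_date": r.report_date.isoformat(),
                "claimed_admit_date": r.claimed_admit_date.isoformat(),
            }) + "\n")


def read_reports(path: str | Path) -> list[ChannelReport]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            d = json.loads(line)
            out.append(
                ChannelReport(
                    report_id=d["report_id"],
                    participant_id=d["participant_id"],
                    channel=d["channel"],
                    report_date=date.fromisoformat(d["report_date"]),
                    claimed_admit_date=date.fromisoformat(d["claimed_admit_date"]),
                )
            )
    return out


def write_alerts(path: str | Path, alerts: Sequence[GeofenceAlert]) -> None:
    with open(path, "w") as fh:
        for a in alerts:
            ep = a.episode
            fh.write(json.dumps({
                "participant_id": a.participant_id,
                "trigger_time": a.trigger_time.strftime(_TS),
                "survey_deadline": a.survey_deadline.strftime(_TS),
                "episode_start": ep.start.strftime(_TS),
                "episode_end": ep.end.strftime(_TS),
                "anchor_lat": ep.anchor.lat,
                "anchor_lon": ep.anchor.lon,
                "classification": None if ep.classification is None else ep.classification.value,
                "matched_place": None if ep.matched_place is None else ep.matched_place.place_id,
            }) + "\n")


def write_surveys(path: str | Path, instances: Sequence[SurveyInstance]) -> None:
    with open(path, "w") as fh:
        for s in instances:
            r = s.response
            fh.write(json.dumps({
                "survey_id": s.survey_id,
                "participant_id": s.participant_id,
                "kind": s.kind.value,
                "available_from": s.available_from.strftime(_TS),
                "available_until": s.available_until.strftime(_TS),
                "status": s.status.value,
                "reminders_sent": [t.strftime(_TS) for t in s.reminders_sent],
                "response": None if r is None else {
                    "completed_at": r.completed_at.strftime(_TS),
                    "hospitalized": r.hospitalized,
                    "overnight": r.overnight,
                    "admit_date": None if r.admit_date is None else r.admit_date.isoformat(),
                    "discharge_date": None if r.discharge_date is None else r.discharge_date.isoformat(),
                    "reason": r.reason.value,
                },
            }) + "\n")


def read_surveys(path: str | Path) -> list[SurveyInstance]:
    from .surveys import ReportReason, SurveyKind, SurveyResponse, SurveyStatus

    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            d = json.loads(line)
            inst = SurveyInstance(
                survey_id=d["survey_id"],
                participant_id=d["participant_id"],
                kind=SurveyKind(d["kind"]),
                available_from=_parse_ts(d["available_from"]),
                available_until=_parse_ts(d["available_until"]),
                status=SurveyStatus(d["status"]),
                reminders_sent=[_parse_ts(t) for t in d["reminders_sent"]],
            )
            r = d.get("response")
            if r is not None:
                inst.response = SurveyResponse(
                    survey_id=d["survey_id"],
                    completed_at=_parse_ts(r["completed_at"]),
                    hospitalized=r["hospitalized"],
                    overnight=r["overnight"],
                    admit_date=None if r["admit_date"] is None else date.fromisoformat(r["admit_date"]),
                    discharge_date=None if r["discharge_date"] is None else date.fromisoformat(r["discharge_date"]),
                    reason=ReportReason(r["reason"]),
                )
            out.append(inst)
    return out


def write_gazetteer(path: str | Path, gaz: Gazetteer) -> None:
    with open(path, "w") as fh:
        json.dump(gazetteer_to_geojson(gaz), fh, indent=1)
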