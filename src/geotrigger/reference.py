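"""A compact tabulated reference scenario for the event matcher.

Nine cardiovascular hospitalizations among five participants with known
per-channel detectability:

* events 1-3 (participants 1 and 2) were detected by geofencing and
  reported in both the triggered and the monthly survey;
* events 4-9 occurred while geofencing was off (one participant never
  opted in; two others had opted out before their first event), so only
  the monthly survey could report them;
* events 6 and 7 belong to the same participant fourteen days apart —
  inside one monthly cycle — and a survey response can carry a single
  hospitalization, so event 7 is structurally unreportable: the monthly
  channel captures 8 of 9.

The coordinator channel ascertains every event at the next scheduled
contact (study day 180 here). Dates are synthetic; the detectability
pattern is the object under test.
"""

from __future__ import annotations

from datetime import timedelta

from .evaluate import ChannelReport, GoldEvent
from .simulate import STUDY_START

__all__ = ["nine_event_scenario"]

# (event_id, participant, admit_day, discharge_day, geofence_detected)
_EVENTS = (
    ("ev1", "p1", 20, 22, True),
    ("ev2", "p2", 40, 42, True),
    ("ev3", "p2", 70, 71, True),
    ("ev4", "p3", 50, 52, False),   # never consented to geofencing
    ("ev5", "p4", 80, 81, False),   # opted out before the event
    ("ev6", "p5", 100, 102, False),  # opted out before the event
    ("ev7", "p5", 114, 115, False),  # 14 d after ev6: same monthly cycle
    ("ev8", "p5", 140, 141, False),
    ("ev9", "p5", 170, 172, False),
)

_COORDINATOR_CONTACT_DAY = 180
_CYCLE_DAYS = 30
_GEOFENCE_LATENCY = {"ev1": 1, "ev2": 2, "ev3": 3}


def nine_event_scenario() -> tuple[list[GoldEvent], list[ChannelReport]]:
    """Gold events plus the channel reports each method produced.

    Monthly reports: one per cycle containing a discharge, completed two
    days after the cycle's survey opens; when two events share a cycle
    only the first is encoded (so ev7 yields no report). Geofence reports
    exist for ev1-ev3 with completion latencies of 1-3 days.
    """
    t0 = STUDY_START.date()
    gold = [
        GoldEvent(
            event_id=eid,
            participant_id=pid,
            admit_date=t0 + timedelta(days=admit),
            discharge_date=t0 + timedelta(days=disch),
            is_cv=True,
            is_overnight=True,
            coordinator_ascertained_on=t0 + timedelta(days=_COORDINATOR_CONTACT_DAY),
        )
        for eid, pid, admit, disch, _ in _EVENTS
    ]

    reports: list[ChannelReport] = []
    # monthly channel: group events by (participant, cycle of discharge);
    # the single-report constraint keeps only the first event per cycle
    seen_cycles: set[tuple[str, int]] = set()
    for g in gold:
        cycle = (g.discharge_date - t0).days // _CYCLE_DAYS + 1  # cycle whose survey reports it
        key = (g.participant_id, cycle)
        if key in seen_cycles:
            continue  # ev7: unreportable, its cycle's survey already carries ev6
        seen_cycles.add(key)
        survey_opens = t0 + timedelta(days=cycle * _CYCLE_DAYS)
        reports.append(
            ChannelReport(
                report_id=f"monthly-{g.event_id}",
                participant_id=g.participant_id,
                channel="monthly",
                report_date=survey_opens + timedelta(days=2),
                claimed_admit_date=g.admit_date,
            )
        )
    for (eid, pid, admit, _, detected) in _EVENTS:
        if not detected:
            continue
        reports.append(
            ChannelReport(
                report_id=f"geofence-{eid}",
                participant_id=pid,
                channel="geofence",
                report_date=t0 + timedelta(days=admit + _GEOFENCE_LATENCY[eid]),
                claimed_admit_date=t0 + timedelta(days=admit),
            )
        )
    reports.extend(
        ChannelReport(
            report_id=f"coord-{g.event_id}",
            participant_id=g.participant_id,
            channel="coordinator",
            report_date=g.coordinator_ascertained_on,
            claimed_admit_date=g.admit_date,
        )
        for g in gold
    )
    return gold, reports
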