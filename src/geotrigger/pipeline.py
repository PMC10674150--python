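"""End-to-end study pipeline over a simulated cohort.

Chains the pieces the way the live system did: simulate (or load) a
cohort, run the geofence engine over the traces, open triggered surveys
from alerts, schedule monthly surveys, replay participant response
behavior, and feed the resulting channel reports into the evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import timedelta
from typing import Sequence

import numpy as np

from .dwell import DwellEpisode, GeofenceAlert, run_engine
from .evaluate import (
    BinomialCI,
    ChannelReport,
    EvalReport,
    GoldEvent,
    MatchResult,
    agresti_coull_interval,
    alert_table,
    coordinator_reports,
    detection_summary,
    latency_summary,
    match_events,
    yield_summary,
)
from .gazetteer import KeywordDictionary, default_dictionaries
from .simulate import Cohort, SimConfig, simulate_cohort
from .surveys import (
    ReportReason,
    SurveyInstance,
    SurveyKind,
    SurveyResponse,
    SurveyStatus,
    expire_pending,
    open_triggered_survey,
    record_response,
    schedule_monthly,
)

__all__ = ["StudyResult", "run_study", "respond_monthly", "respond_triggered", "false_alert_counts"]


@dataclass
class StudyResult:
    cohort: Cohort
    alerts: list[GeofenceAlert]
    stored_episodes: list[DwellEpisode]
    monthly: list[SurveyInstance]
    triggered: list[SurveyInstance]
    reports: list[ChannelReport]
    matches: list[MatchResult]
    surplus: list[ChannelReport]
    report: EvalReport


def _latency_days(rng: np.random.Generator, p: float) -> int:
    return int(rng.geometric(p)) - 1 if p < 1.0 else 0


def respond_monthly(
    cohort: Cohort,
    instances: Sequence[SurveyInstance],
    rng: np.random.Generator,
    pick: str = "last",
) -> None:
    """Replay monthly-survey behavior against scheduled instances.

    A compliant participant answers ``response_latency`` days after the
    survey opens and reports the hospitalization discharged within the
    just-elapsed cycle — with two events in one cycle only one is
    encodable (``pick``: the earlier or the more recent one).
    """
    cfg = cohort.config
    cycle = timedelta(days=cfg.cycle_days)
    by_pid: dict[str, list[GoldEvent]] = {}
    for g in cohort.gold:
        by_pid.setdefault(g.participant_id, []).append(g)
    for inst in instances:
        if rng.random() >= cfg.survey_compliance_p:
            continue
        delay = _latency_days(rng, cfg.response_latency_p)
        completed = inst.available_from + timedelta(days=delay, hours=10)
        if not inst.in_window(completed):
            continue
        lo, hi = (inst.available_from - cycle).date(), inst.available_from.date()
        window_events = [g for g in by_pid.get(inst.participant_id, []) if lo < g.discharge_date <= hi]
        if window_events:
            key = (lambda g: (g.discharge_date, g.admit_date))
            g = min(window_events, key=key) if pick == "first" else max(window_events, key=key)
            resp = SurveyResponse(
                survey_id=inst.survey_id,
                completed_at=completed,
                hospitalized=True,
                overnight=g.is_overnight,
                admit_date=g.admit_date,
                discharge_date=g.discharge_date,
                reason=ReportReason.CV_HOSPITALIZATION if g.is_cv else ReportReason.NONCV_HOSPITALIZATION,
            )
        else:
            resp = SurveyResponse(inst.survey_id, completed, hospitalized=False)
        record_response(inst, resp)


def respond_triggered(
    cohort: Cohort,
    alerts: Sequence[GeofenceAlert],
    rng: np.random.Generator,
) -> list[SurveyInstance]:
    """Open a triggered survey per alert and replay completion behavior.

    Honest responders: the survey reports a hospitalization only when the
    alert's dwell episode overlaps a gold hospital stay; a false alert
    (gym, pharmacy) is answered "not hospitalized".
    """
    cfg = cohort.config
    by_pid: dict[str, list[GoldEvent]] = {}
    for g in cohort.gold:
        by_pid.setdefault(g.participant_id, []).append(g)
    instances = []
    for alert in alerts:
        inst = open_triggered_survey(alert)
        instances.append(inst)
        if rng.random() >= cfg.survey_compliance_p:
            continue
        delay = _latency_days(rng, cfg.response_latency_p)
        completed = alert.trigger_time + timedelta(days=delay, hours=2)
        if not inst.in_window(completed):
            continue
        ep = alert.episode
        overlapping = [
            g for g in by_pid.get(alert.participant_id, [])
            if g.admit_date <= alert.trigger_time.date() <= g.discharge_date
        ]
        if overlapping:
            g = overlapping[0]
            resp = SurveyResponse(
                survey_id=inst.survey_id,
                completed_at=completed,
                hospitalized=True,
                overnight=g.is_overnight,
                admit_date=g.admit_date,
                discharge_date=g.discharge_date,
                reason=ReportReason.CV_HOSPITALIZATION if g.is_cv else ReportReason.NONCV_HOSPITALIZATION,
            )
        else:
            resp = SurveyResponse(inst.survey_id, completed, hospitalized=False)
        record_response(inst, resp)
    return instances


def _survey_reports(instances: Sequence[SurveyInstance], channel: str) -> list[ChannelReport]:
    out = []
    for inst in instances:
        r = inst.response
        if r is not None and r.hospitalized:
            out.append(
                ChannelReport(
                    report_id=f"{channel}-{inst.survey_id}",
                    participant_id=inst.participant_id,
                    channel=channel,
                    report_date=r.completed_at.date(),
                    claimed_admit_date=r.admit_date,
                )
            )
    return out


def false_alert_counts(alerts: Sequence[GeofenceAlert], cohort: Cohort) -> tuple[int, int]:
    """(n_true, n_false): alerts at an actual hospital vs elsewhere."""
    n_true = sum(
        1 for a in alerts
        if cohort.world.is_hospital_coord(a.episode.anchor.lat, a.episode.anchor.lon)
    )
    return n_true, len(alerts) - n_true


def _completion_ci(instances: Sequence[SurveyInstance]) -> BinomialCI | None:
    done = sum(1 for i in instances if i.status is SurveyStatus.COMPLETED)
    closed = sum(1 for i in instances if i.status in (SurveyStatus.COMPLETED, SurveyStatus.EXPIRED))
    return agresti_coull_interval(done, closed) if closed else None


def run_study(
    config: SimConfig,
    dicts: Sequence[KeywordDictionary] | None = None,
    exclusion_scope: str = "array",
    respond_pick: str = "last",
) -> StudyResult:
    """Simulate a cohort and push it through detection, surveys, and evaluation."""
    dicts = list(default_dictionaries()) if dicts is None else list(dicts)
    cohort = simulate_cohort(config)
    t0 = cohort.study_start

    alerts, stored = run_engine(
        cohort.traces, cohort.consent, cohort.world.gazetteer, dicts, t0,
        exclusion_scope=exclusion_scope,
    ) if config.with_traces else ([], [])

    monthly: list[SurveyInstance] = []
    for pid in cohort.participant_ids:
        fup = cohort.behaviors[pid].followup_days
        monthly.extend(schedule_monthly(pid, t0, t0 + timedelta(days=fup), config.cycle_days))

    rng = np.random.default_rng(config.seed + 3)
    respond_monthly(cohort, monthly, rng, pick=respond_pick)
    triggered = respond_triggered(cohort, alerts, rng)
    horizon = t0 + timedelta(days=max(cohort.behaviors[p].followup_days for p in cohort.behaviors) + 60)
    expire_pending(monthly, horizon)
    expire_pending(triggered, horizon)

    reports = (
        _survey_reports(monthly, "monthly")
        + _survey_reports(triggered, "geofence")
        + coordinator_reports(cohort.gold)
    )
    cv_gold = [g for g in cohort.gold if g.is_cv]
    matches_all, surplus = match_events(cohort.gold, reports)
    cv_ids = {g.event_id for g in cv_gold}
    matches = [m for m in matches_all if m.gold_event_id in cv_ids]

    detection, latency = {}, {}
    if matches:
        for ch in ("geofence", "monthly", "coordinator"):
            detection[ch] = detection_summary(matches, ch)
            try:
                latency[ch] = latency_summary(matches, ch)
            except ValueError:
                pass
        detection["digital_union"] = detection_summary(matches, ("geofence", "monthly"))

    completion = {}
    for name, insts in (("monthly", monthly), ("geofence", triggered)):
        ci = _completion_ci(insts)
        if ci is not None:
            completion[name] = ci

    yields = {}
    monthly_done = sum(1 for i in monthly if i.status is SurveyStatus.COMPLETED)
    if monthly_done:
        n_cv = sum(
            1 for i in monthly
            if i.response is not None and i.response.hospitalized
            and i.response.reason is ReportReason.CV_HOSPITALIZATION
        )
        yields["monthly"] = yield_summary(monthly_done, n_cv)
    trig_done = sum(1 for i in triggered if i.status is SurveyStatus.COMPLETED)
    if trig_done:
        n_cv = sum(
            1 for i in triggered
            if i.response is not None and i.response.hospitalized
            and i.response.reason is ReportReason.CV_HOSPITALIZATION
        )
        yields["geofence"] = yield_summary(trig_done, n_cv)
    n_contacts = sum(
        sum(1 for d in config.coordinator_contact_days if d <= cohort.behaviors[p].followup_days)
        + 1  # closing visit
        for p in cohort.behaviors
    )
    if n_contacts:
        yields["coordinator"] = yield_summary(n_contacts, len(cv_gold))

    bins = None
    if alerts:
        labelled = [
            ((a.trigger_time - t0).total_seconds() / 86400.0,
             cohort.world.is_hospital_coord(a.episode.anchor.lat, a.episode.anchor.lon))
            for a in alerts
        ]
        max_day = max(d for d, _ in labelled)
        edges = [e for e in (0.0, 210.0, 365.0) if e < max_day + 1] + [max_day + 1]
        bins = alert_table(labelled, edges)

    report = EvalReport(
        n_gold=len(matches),
        detection=detection,
        latency=latency,
        completion=completion,
        yields=yields,
        alert_bins=bins,
        surplus_reports=len(surplus),
    )
    return StudyResult(cohort, alerts, stored, monthly, triggered, reports, matches, surplus, report)
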