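"""Survey scheduling, windows, reminders, and response recording.

Two survey channels exist: a *monthly* hospitalization survey scheduled on
a fixed cycle from enrollment, and a *geofence-triggered* survey opened by
a hospital dwell alert with a hard seven-day completion window. Reminders
escalate: one at 24 hours after the survey opens, then weekly until
completion or window close.

A response can encode at most one hospitalization — the constraint that
makes a second hospitalization inside the same monthly cycle unreportable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, datetime, timedelta
from enum import Enum

from .dwell import SURVEY_WINDOW, GeofenceAlert

__all__ = [
    "SurveyKind",
    "SurveyStatus",
    "ReportReason",
    "SurveyInstance",
    "SurveyResponse",
    "SurveyValidationError",
    "DEFAULT_CYCLE_DAYS",
    "schedule_monthly",
    "open_triggered_survey",
    "reminder_times",
    "record_response",
]

DEFAULT_CYCLE_DAYS = 30
FIRST_REMINDER = timedelta(hours=24)
REMINDER_CADENCE = timedelta(days=7)


class SurveyKind(str, Enum):
    MONTHLY = "MONTHLY"
    GEOFENCE_TRIGGERED = "GEOFENCE_TRIGGERED"


class SurveyStatus(str, Enum):
    PENDING = "PENDING"
    COMPLETED = "COMPLETED"
    EXPIRED = "EXPIRED"


class ReportReason(str, Enum):
    CV_HOSPITALIZATION = "CV_HOSPITALIZATION"
    CV_VISIT = "CV_VISIT"
    NONCV_HOSPITALIZATION = "NONCV_HOSPITALIZATION"
    NONCV_VISIT = "NONCV_VISIT"
    NONE = "NONE"


class SurveyValidationError(ValueError):
    pass


@dataclass(frozen=True)
class SurveyResponse:
    """One completed survey form; carries at most one hospitalization."""

    survey_id: str
    completed_at: datetime
    hospitalized: bool
    overnight: bool | None = None
    admit_date: date | None = None
    discharge_date: date | None = None
    reason: ReportReason = ReportReason.NONE

    def __post_init__(self) -> None:
        if self.hospitalized:
            if self.admit_date is None or self.discharge_date is None:
                raise SurveyValidationError(f"{self.survey_id}: hospitalized response requires admit and discharge dates")
            if self.discharge_date < self.admit_date:
                raise SurveyValidationError(f"{self.survey_id}: discharge_date precedes admit_date")
            if self.reason is ReportReason.NONE:
                raise SurveyValidationError(f"{self.survey_id}: hospitalized response requires a reason")
        else:
            if self.admit_date is not None or self.discharge_date is not None:
                raise SurveyValidationError(f"{self.survey_id}: dates set on a non-hospitalized response")
            if self.reason not in (ReportReason.NONE, ReportReason.CV_VISIT, ReportReason.NONCV_VISIT):
                raise SurveyValidationError(f"{self.survey_id}: hospitalization reason on a non-hospitalized response")


@dataclass
class SurveyInstance:
    survey_id: str
    participant_id: str
    kind: SurveyKind
    available_from: datetime
    available_until: datetime
    status: SurveyStatus = SurveyStatus.PENDING
    reminders_sent: list[datetime] = field(default_factory=list)
    response: SurveyResponse | None = None

    def __post_init__(self) -> None:
        if self.available_until <= self.available_from:
            raise SurveyValidationError(f"{self.survey_id}: empty availability window")

    def in_window(self, t: datetime) -> bool:
        return self.available_from <= t <= self.available_until


def schedule_monthly(
    participant_id: str,
    enrollment: datetime,
    followup_end: datetime,
    cycle_days: int = DEFAULT_CYCLE_DAYS,
) -> list[SurveyInstance]:
    """Monthly survey instances for one participant.

    Instance k opens at ``enrollment + k*cycle_days`` (k = 1, 2, ...) for
    every opening at or before ``followup_end``; each stays available for a
    full cycle (until the next one opens).
    """
    if cycle_days <= 0:
        raise ValueError("cycle_days must be positive")
    if followup_end <= enrollment:
        raise ValueError("followup_end must be after enrollment")
    cycle = timedelta(days=cycle_days)
    out = []
    k = 1
    while enrollment + k * cycle <= followup_end:
        opens = enrollment + k * cycle
        out.append(
            SurveyInstance(
                survey_id=f"{participant_id}-monthly-{k:03d}",
                participant_id=participant_id,
                kind=SurveyKind.MONTHLY,
                available_from=opens,
                available_until=opens + cycle,
            )
        )
        k += 1
    return out


def open_triggered_survey(alert: GeofenceAlert) -> SurveyInstance:
    """The seven-day survey opened by a geofence alert."""
    return SurveyInstance(
        survey_id=f"{alert.participant_id}-geofence-{alert.trigger_time.strftime('%Y%m%dT%H%M%S')}",
        participant_id=alert.participant_id,
        kind=SurveyKind.GEOFENCE_TRIGGERED,
        available_from=alert.trigger_time,
        available_until=alert.trigger_time + SURVEY_WINDOW,
    )


def reminder_times(instance: SurveyInstance, completed_at: datetime | None = None) -> list[datetime]:
    """Reminder schedule: +24 h after opening, then weekly.

    Reminders stop at completion (no reminder at or after ``completed_at``)
    and at window close (no reminder at or after ``available_until``).
    """
    stop = instance.available_until
    if completed_at is not None:
        stop = min(stop, completed_at)
    out = []
    t = instance.available_from + FIRST_REMINDER
    while t < stop:
        out.append(t)
        t += REMINDER_CADENCE
    return out


def record_response(instance: SurveyInstance, response: SurveyResponse) -> SurveyInstance:
    """Record a response against a pending survey.

    A response inside the availability window completes the survey; an
    attempt after the window closes marks the survey EXPIRED and discards
    the response. Single-hospitalization and date-consistency constraints
    are enforced by :class:`SurveyResponse` itself.
    """
    if instance.status is not SurveyStatus.PENDING:
        raise SurveyValidationError(f"{instance.survey_id}: survey is {instance.status.value}, not PENDING")
    if response.survey_id != instance.survey_id:
        raise SurveyValidationError(f"response {response.survey_id} does not belong to {instance.survey_id}")
    if not instance.in_window(response.completed_at):
        instance.status = SurveyStatus.EXPIRED
        return instance
    instance.status = SurveyStatus.COMPLETED
    instance.response = response
    instance.reminders_sent = reminder_times(instance, response.completed_at)
    return instance


def expire_pending(instances: list[SurveyInstance], now: datetime) -> None:
    """Mark every pending survey whose window has closed as EXPIRED."""
    for inst in instances:
        if inst.status is SurveyStatus.PENDING and now > inst.available_until:
            inst.status = SurveyStatus.EXPIRED
            inst.reminders_sent = reminder_times(inst)
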