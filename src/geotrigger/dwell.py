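"""Dwell-episode segmentation and geofence alerting.

The engine consumes a participant's event-driven GPS fix stream (one fix
per detected movement, so the absence of new fixes means the phone has not
moved) together with the participant's geolocation-consent intervals. It
segments the stream into *dwell episodes* — maximal intervals during which
every fix stays within a displacement radius of an anchor fix — classifies
each episode's anchor location through the gazetteer, and raises a
:class:`GeofenceAlert` when a hospital-classified dwell reaches the dwell
threshold (4 hours by default).

Privacy contract: only episodes classified as health-related (HOSPITAL or
HEALTH_NONHOSPITAL) are retained as stored location records; dwells at
home, restaurants, etc. are never stored.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from datetime import datetime, timedelta
from typing import Iterable, Mapping, Sequence

from .gazetteer import (
    DEFAULT_QUERY_RADIUS_M,
    Classification,
    Gazetteer,
    KeywordDictionary,
    Place,
    active_dictionary,
    classify_places,
)
from .geo import haversine_m

__all__ = [
    "GeoFix",
    "ConsentInterval",
    "DwellEpisode",
    "GeofenceAlert",
    "DEFAULT_MOVEMENT_RADIUS_M",
    "DEFAULT_DWELL_THRESHOLD",
    "SURVEY_WINDOW",
    "segment_dwells",
    "evaluate_episode",
    "run_engine",
]

DEFAULT_MOVEMENT_RADIUS_M = 250.0
DEFAULT_DWELL_THRESHOLD = timedelta(hours=4)
SURVEY_WINDOW = timedelta(days=7)


@dataclass(frozen=True)
class GeoFix:
    participant_id: str
    timestamp: datetime
    lat: float
    lon: float


@dataclass(frozen=True)
class ConsentInterval:
    """A period during which a participant's geolocation was enabled.

    ``end=None`` means consent was still on at the end of observation.
    """

    participant_id: str
    start: datetime
    end: datetime | None = None

    def __post_init__(self) -> None:
        if self.end is not None and not self.start < self.end:
            raise ValueError(f"consent interval for {self.participant_id}: start must precede end")

    def contains(self, t: datetime) -> bool:
        return self.start <= t and (self.end is None or t < self.end)


@dataclass
class DwellEpisode:
    participant_id: str
    anchor: GeoFix
    start: datetime
    end: datetime
    classification: Classification | None = None
    matched_place: Place | None = None

    @property
    def duration(self) -> timedelta:
        return self.end - self.start


@dataclass(frozen=True)
class GeofenceAlert:
    participant_id: str
    trigger_time: datetime
    episode: DwellEpisode
    survey_deadline: datetime


def _check_sorted(fixes: Sequence[GeoFix]) -> None:
    for prev, cur in zip(fixes, fixes[1:]):
        if cur.timestamp <= prev.timestamp:
            raise ValueError(
                f"fix stream not strictly increasing for {cur.participant_id}: "
                f"fix at {cur.timestamp.isoformat()} follows {prev.timestamp.isoformat()}"
            )


def segment_dwells(
    fixes: Sequence[GeoFix],
    consent: Sequence[ConsentInterval],
    movement_radius_m: float = DEFAULT_MOVEMENT_RADIUS_M,
    max_gap: timedelta | None = None,
) -> list[DwellEpisode]:
    """Segment one participant's fix stream into dwell episodes.

    A new episode starts at the first fix more than ``movement_radius_m``
    (great-circle) from the current anchor; the previous episode ends at
    that fix's timestamp. Episodes also end at a consent-interval boundary
    or at stream end. Fixes outside consent intervals are discarded before
    segmentation and never stored. ``max_gap``, if set, closes an episode
    at the last fix before a silence longer than the gap (guards against
    data loss being read as one long dwell; by default silence is trusted
    as continued dwell, which is the event-driven sampling contract).
    """
    if movement_radius_m <= 0:
        raise ValueError("movement_radius_m must be positive")
    if not fixes:
        return []
    pid = fixes[0].participant_id
    if any(f.participant_id != pid for f in fixes):
        raise ValueError("segment_dwells expects a single participant's stream")
    _check_sorted(fixes)
    stream_end = fixes[-1].timestamp
    intervals = sorted((c for c in consent if c.participant_id == pid), key=lambda c: c.start)

    episodes: list[DwellEpisode] = []
    for iv in intervals:
        inside = [f for f in fixes if iv.contains(f.timestamp)]
        if not inside:
            continue
        # the dwell running at consent end is truncated there (if the
        # stream itself continues that far); otherwise it ends at stream end
        tail_end = stream_end if iv.end is None else min(iv.end, stream_end)
        anchor = inside[0]
        for f in inside[1:]:
            moved = haversine_m(anchor.lat, anchor.lon, f.lat, f.lon) > movement_radius_m
            if moved:
                episodes.append(DwellEpisode(pid, anchor, anchor.timestamp, f.timestamp))
                anchor = f
        episodes.append(DwellEpisode(pid, anchor, anchor.timestamp, max(tail_end, anchor.timestamp)))
    if max_gap is not None:
        episodes = _apply_max_gap(episodes, fixes, max_gap)
    return episodes


def _apply_max_gap(
    episodes: list[DwellEpisode], fixes: Sequence[GeoFix], max_gap: timedelta
) -> list[DwellEpisode]:
    """Split/truncate episodes at silences longer than ``max_gap``."""
    out: list[DwellEpisode] = []
    ts = [f.timestamp for f in fixes]
    for ep in episodes:
        inside = [t for t in ts if ep.start <= t <= ep.end]
        cut = ep.end
        prev = ep.start
        for t in inside[1:]:
            if t - prev > max_gap:
                cut = prev
                break
            prev = t
        else:
            if ep.end - prev > max_gap:
                cut = prev
        out.append(replace(ep, end=max(cut, ep.start)) if cut < ep.end else ep)
    return out


def evaluate_episode(
    episode: DwellEpisode,
    gazetteer: Gazetteer,
    dicts: Sequence[KeywordDictionary],
    study_start: datetime,
    dwell_threshold: timedelta = DEFAULT_DWELL_THRESHOLD,
    query_radius_m: float = DEFAULT_QUERY_RADIUS_M,
    exclusion_scope: str = "array",
) -> GeofenceAlert | None:
    """Classify an episode's anchor location and raise an alert if warranted.

    The dictionary version active on the episode's start day (relative to
    ``study_start``) is used. An alert fires iff the classification is
    HOSPITAL and the dwell lasted at least ``dwell_threshold``; the alert
    triggers at ``start + dwell_threshold`` and its survey window closes
    seven days later. The episode is annotated in place with its
    classification and nearest matching place.
    """
    study_day = (episode.start - study_start).days
    kdict = active_dictionary(dicts, study_day)
    places = gazetteer.query(episode.anchor.lat, episode.anchor.lon, query_radius_m)
    cls = classify_places(places, kdict, exclusion_scope)
    episode.classification = cls
    if cls is not Classification.OTHER:
        from .gazetteer import _place_matches

        episode.matched_place = next((p for p in places if _place_matches(p, kdict.include)), None)
    if cls is Classification.HOSPITAL and episode.duration >= dwell_threshold:
        trigger = episode.start + dwell_threshold
        return GeofenceAlert(episode.participant_id, trigger, episode, trigger + SURVEY_WINDOW)
    return None


def run_engine(
    traces: Mapping[str, Sequence[GeoFix]] | Iterable[GeoFix],
    consent: Sequence[ConsentInterval],
    gazetteer: Gazetteer,
    dicts: Sequence[KeywordDictionary],
    study_start: datetime,
    movement_radius_m: float = DEFAULT_MOVEMENT_RADIUS_M,
    dwell_threshold: timedelta = DEFAULT_DWELL_THRESHOLD,
    query_radius_m: float = DEFAULT_QUERY_RADIUS_M,
    exclusion_scope: str = "array",
    max_gap: timedelta | None = None,
) -> tuple[list[GeofenceAlert], list[DwellEpisode]]:
    """Run dwell detection + alerting over a multi-participant cohort.

    Returns ``(alerts, stored_episodes)`` where stored episodes are only
    those with a health-related classification (the privacy contract:
    nothing else is retained). Deterministic given its inputs; participants
    are processed in sorted id order.
    """
    if not isinstance(traces, Mapping):
        grouped: dict[str, list[GeoFix]] = {}
        for f in traces:
            grouped.setdefault(f.participant_id, []).append(f)
        traces = grouped
    alerts: list[GeofenceAlert] = []
    stored: list[DwellEpisode] = []
    for pid in sorted(traces):
        episodes = segment_dwells(list(traces[pid]), consent, movement_radius_m, max_gap)
        for ep in episodes:
            alert = evaluate_episode(
                ep, gazetteer, dicts, study_start, dwell_threshold, query_radius_m, exclusion_scope
            )
            if ep.classification in (Classification.HOSPITAL, Classification.HEALTH_NONHOSPITAL):
                stored.append(ep)
            if alert is not None:
                alerts.append(alert)
    return alerts, stored
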