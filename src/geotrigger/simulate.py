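"""Seeded synthetic worlds, cohorts, and behavior for end-to-end testing.

Nothing here is fitted to any real cohort: the simulator generates a
synthetic city (hospitals, gyms, pharmacies, dentists, restaurants, and
participant homes on a kilometer-scale grid), per-participant daily
trajectories with event-driven GPS fixes and Gaussian position noise,
gold-standard hospitalization logs, geolocation consent/opt-out behavior,
and partial survey compliance — the statistical structure the detection
and evaluation machinery assumes, with every piece controllable and
reproducible under a fixed seed.

Key structural guarantees:

* every gold hospitalization is placed at a gazetteer hospital, so a
  missed detection is attributable to the detector, consent, or stay
  duration — never to the world;
* stay durations are log-normal with an explicit probability mass forced
  below the 4-hour dwell threshold, so the threshold's sensitivity cost
  is exercisable;
* nonhospital health-facility visits (the false-alert mechanism) have
  their own duration distribution with mass above 4 hours.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from datetime import date, datetime, timedelta
from typing import Sequence

import numpy as np

from .dwell import ConsentInterval, GeoFix
from .evaluate import GoldEvent
from .gazetteer import Gazetteer, Place
from .geo import haversine_m, offset_point

__all__ = [
    "SimConfig",
    "World",
    "Cohort",
    "simulate_world",
    "simulate_cohort",
    "preset",
    "PILOT_FOLLOWUP_DAYS",
    "STUDY_START",
]

STUDY_START = datetime(2019, 3, 1, 0, 0, 0)

# Frozen per-participant follow-up durations (days) for the "pilot" preset:
# 85 participants, generated once from a log-normal month count (median
# ~7.4 months) and adjusted so the cohort accrues exactly 647 monthly
# survey instances under 30-day cycles (sum of floor(days/30) = 647).
PILOT_FOLLOWUP_DAYS: tuple[int, ...] = (
    645, 495, 495, 495, 495, 435, 435, 405, 375, 375, 375, 345, 345, 345,
    345, 345, 315, 315, 315, 315, 285, 285, 285, 285, 255, 255, 255, 255,
    255, 255, 255, 255, 255, 255, 255, 255, 225, 225, 225, 225, 225, 225,
    225, 225, 225, 225, 225, 225, 195, 195, 195, 195, 195, 195, 195, 195,
    195, 195, 195, 195, 165, 165, 165, 165, 165, 165, 165, 165, 165, 165,
    165, 165, 135, 135, 135, 135, 135, 135, 105, 105, 105, 105, 75, 75, 75,
)


@dataclass(frozen=True)
class SimConfig:
    """All the knobs of the synthetic study.

    Rates are per participant-month (30 days) unless noted. Defaults are
    the study-scale conditions the package is designed around: sparse CV
    hospitalizations, ~86% geofencing opt-in with substantial later
    opt-out, ~69% survey compliance, 15 m GPS noise.
    """

    seed: int = 0
    n_participants: int = 85
    followup_days: int | tuple[int, ...] = 365
    cv_hosp_rate: float = 0.014  # events / participant-month
    noncv_hosp_rate: float = 0.005
    stay_median_hours: float = 48.0
    stay_sigma_log: float = 0.6
    p_stay_lt_4h: float = 0.10
    healthfacility_visit_rate: float = 0.5  # visits / week
    confounder_median_hours: float = 1.5
    confounder_sigma_log: float = 1.0
    outing_p: float = 0.6  # daily probability of a nonhealth outing
    geofence_consent_p: float = 0.858
    optout_hazard: float = 0.5  # per-month probability of disabling geofencing
    survey_compliance_p: float = 0.69
    response_latency_p: float = 0.5  # geometric; mean delay (1-p)/p days
    gps_noise_sd_m: float = 15.0
    coordinator_contact_days: tuple[int, ...] = (180, 360)
    cycle_days: int = 30
    n_hospitals: int = 3
    n_gyms: int = 3
    n_pharmacies: int = 3
    n_dentists: int = 2
    n_restaurants: int = 6
    colocated_confounder: bool = False  # place one gym within the query radius of a hospital
    ensure_close_pair: bool = False  # force two CV events 14 days apart for one participant
    with_traces: bool = True

    def __post_init__(self) -> None:
        for name in ("p_stay_lt_4h", "geofence_consent_p", "optout_hazard", "survey_compliance_p",
                     "response_latency_p", "outing_p"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("cv_hosp_rate", "noncv_hosp_rate", "healthfacility_visit_rate", "gps_noise_sd_m"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")

    def followup_for(self, i: int) -> int:
        if isinstance(self.followup_days, int):
            return self.followup_days
        return self.followup_days[i % len(self.followup_days)]


@dataclass
class World:
    gazetteer: Gazetteer
    hospitals: list[Place]
    confounders: list[Place]  # gyms / pharmacies / dentists
    homes: dict[str, tuple[float, float]]

    def is_hospital_coord(self, lat: float, lon: float, radius_m: float = 300.0) -> bool:
        return any(haversine_m(lat, lon, h.lat, h.lon) <= radius_m for h in self.hospitals)


@dataclass
class ParticipantBehavior:
    """Pre-drawn behavioral randomness for one participant."""

    participant_id: str
    followup_days: int
    consented: bool
    optout_day: float | None  # None: never opts out within follow-up
    survey_compliance: float


@dataclass
class Cohort:
    config: SimConfig
    world: World
    study_start: datetime
    traces: dict[str, list[GeoFix]]
    consent: list[ConsentInterval]
    gold: list[GoldEvent]
    behaviors: dict[str, ParticipantBehavior]

    @property
    def participant_ids(self) -> list[str]:
        return sorted(self.behaviors)


_CITY_CENTER = (44.95, -93.10)


def simulate_world(config: SimConfig, rng: np.random.Generator | None = None) -> World:
    """Lay out the synthetic city.

    Health facilities sit on a coarse grid with >= 1 km spacing (unless
    ``colocated_confounder`` plants one gym 150 m from the first hospital,
    to probe array-level exclusion). Homes are scattered over a ~10 km box
    and rejected if within 700 m of any health facility, so residential
    dwells never fall inside a facility's query radius.
    """
    rng = np.random.default_rng(config.seed + 1) if rng is None else rng
    lat0, lon0 = _CITY_CENTER
    places: list[Place] = []

    def grid_pos(k: int) -> tuple[float, float]:
        row, col = divmod(k, 5)
        return offset_point(lat0, lon0, 1500.0 * row, 1500.0 * col)

    k = 0
    hospitals, confounders = [], []
    for i in range(config.n_hospitals):
        lat, lon = grid_pos(k); k += 1
        p = Place(f"hosp-{i}", f"General Hospital {i}", frozenset({"hospital", "health"}), lat, lon)
        hospitals.append(p)
    specs = (
        [("gym", "FitLife Gym", {"gym", "health"})] * config.n_gyms
        + [("pharm", "CityCare Pharmacy", {"pharmacy", "health"})] * config.n_pharmacies
        + [("dent", "BrightSmile Dentist", {"dentist", "health"})] * config.n_dentists
    )
    for i, (tag, name, cats) in enumerate(specs):
        if config.colocated_confounder and i == 0:
            lat, lon = offset_point(hospitals[0].lat, hospitals[0].lon, 150.0, 0.0)
        else:
            lat, lon = grid_pos(k); k += 1
        confounders.append(Place(f"{tag}-{i}", f"{name} {i}", frozenset(cats), lat, lon))
    restaurants = []
    for i in range(config.n_restaurants):
        lat, lon = grid_pos(k); k += 1
        restaurants.append(Place(f"rest-{i}", f"Corner Restaurant {i}", frozenset({"restaurant"}), lat, lon))
    places = hospitals + confounders + restaurants

    facilities = hospitals + confounders
    homes: dict[str, tuple[float, float]] = {}
    home_places = []
    for i in range(config.n_participants):
        pid = f"P{i:04d}"
        while True:
            north = float(rng.uniform(-2000.0, 9000.0))
            east = float(rng.uniform(-2000.0, 9000.0))
            lat, lon = offset_point(lat0, lon0, north, east)
            if all(haversine_m(lat, lon, f.lat, f.lon) > 700.0 for f in facilities):
                break
        homes[pid] = (lat, lon)
        home_places.append(Place(f"home-{pid}", f"Residence {pid}", frozenset({"residence"}), lat, lon))
    return World(Gazetteer(places + home_places), hospitals, confounders, homes)


def _lognormal_hours(rng: np.random.Generator, median: float, sigma: float) -> float:
    return float(np.exp(rng.normal(math.log(median), sigma)))


def _sample_stay_hours(rng: np.random.Generator, config: SimConfig) -> float:
    """Hospital stay duration: log-normal, with explicit sub-4 h mass."""
    if rng.random() < config.p_stay_lt_4h:
        return float(rng.uniform(0.5, 3.9))
    return max(4.0, _lognormal_hours(rng, config.stay_median_hours, config.stay_sigma_log))


def simulate_cohort(config: SimConfig, world: World | None = None) -> Cohort:
    """Generate the full synthetic cohort under ``config``.

    Deterministic: the same config (seed included) yields byte-identical
    traces, consent intervals, gold events and behavior draws.
    """
    if world is None:
        world = simulate_world(config)
    rng = np.random.default_rng(config.seed + 2)
    traces: dict[str, list[GeoFix]] = {}
    consent: list[ConsentInterval] = []
    gold: list[GoldEvent] = []
    behaviors: dict[str, ParticipantBehavior] = {}
    t0 = STUDY_START

    for i in range(config.n_participants):
        pid = f"P{i:04d}"
        fup = config.followup_for(i)
        end_of_followup = t0 + timedelta(days=fup)

        # --- geolocation consent / opt-out ---
        consented = bool(rng.random() < config.geofence_consent_p)
        optout_day: float | None = None
        if consented:
            if config.optout_hazard > 0:
                month = int(rng.geometric(config.optout_hazard))  # 1-based month of opt-out
                day = (month - 1) * 30 + float(rng.uniform(0.0, 30.0))
                if day < fup:
                    optout_day = day
            if optout_day is None:
                consent.append(ConsentInterval(pid, t0, None))
            else:
                # whole seconds: timestamps survive CSV round-trips losslessly
                consent.append(ConsentInterval(pid, t0, t0 + timedelta(seconds=int(optout_day * 86400))))
        behaviors[pid] = ParticipantBehavior(pid, fup, consented, optout_day, config.survey_compliance_p)

        # --- gold hospitalization events ---
        months = fup / 30.0
        admits_h: list[tuple[float, bool]] = []  # (admit day, is_cv)
        for rate, is_cv in ((config.cv_hosp_rate, True), (config.noncv_hosp_rate, False)):
            n_ev = int(rng.poisson(rate * months))
            for _ in range(n_ev):
                admits_h.append((float(rng.uniform(0.0, fup - 1)), is_cv))
        if config.ensure_close_pair and i == 0:
            first = float(rng.uniform(30.0, max(31.0, fup - 45)))
            admits_h += [(first, True), (first + 14.0, True)]
        admits_h.sort()

        stays: list[tuple[datetime, datetime, bool]] = []
        prev_end = t0
        for admit_day, is_cv in admits_h:
            admit = t0 + timedelta(days=admit_day, hours=float(rng.uniform(7.0, 19.0)))
            if admit < prev_end + timedelta(hours=12):  # overlapping/adjacent stays: push apart
                admit = prev_end + timedelta(hours=12)
            dur = _sample_stay_hours(rng, config)
            discharge = admit + timedelta(hours=dur)
            if discharge > end_of_followup:
                continue
            stays.append((admit, discharge, is_cv))
            prev_end = discharge
        hosp_idx = int(rng.integers(len(world.hospitals)))
        hospital = world.hospitals[hosp_idx]
        for j, (admit, discharge, is_cv) in enumerate(stays):
            asc = _next_contact(admit, discharge, config.coordinator_contact_days, t0, end_of_followup)
            gold.append(
                GoldEvent(
                    event_id=f"{pid}-ev{j}",
                    participant_id=pid,
                    admit_date=admit.date(),
                    discharge_date=discharge.date(),
                    is_cv=is_cv,
                    is_overnight=discharge.date() > admit.date(),
                    coordinator_ascertained_on=asc,
                )
            )

        # --- trajectory ---
        if config.with_traces:
            traces[pid] = _simulate_trace(rng, config, world, pid, fup, stays, hospital, t0)
    return Cohort(config, world, t0, traces, consent, gold, behaviors)


def _next_contact(
    admit: datetime, discharge: datetime, contact_days: Sequence[int], t0: datetime, end: datetime
) -> date:
    """Coordinator learns of the event at the next scheduled contact >= discharge,
    or at the participant's closing visit if none remains."""
    for d in sorted(contact_days):
        c = t0 + timedelta(days=int(d))
        if c >= discharge:
            return c.date()
    return max(end, discharge).date()


def _simulate_trace(
    rng: np.random.Generator,
    config: SimConfig,
    world: World,
    pid: str,
    fup: int,
    stays: list[tuple[datetime, datetime, bool]],
    hospital: Place,
    t0: datetime,
) -> list[GeoFix]:
    """Event-driven fix stream: one fix per arrival at a new location."""
    home = world.homes[pid]
    noise = config.gps_noise_sd_m
    visits: list[tuple[datetime, datetime, float, float]] = []  # (arrive, depart, lat, lon)
    for admit, discharge, _ in stays:
        visits.append((admit, discharge, hospital.lat, hospital.lon))

    def overlaps_stay(arr: datetime, dep: datetime) -> bool:
        return any(arr < d and dep > a for a, d, _ in stays)

    rest_places = [p for p in world.gazetteer.places if p.place_id.startswith("rest-")]
    p_conf_daily = config.healthfacility_visit_rate / 7.0
    for d in range(fup):
        day0 = t0 + timedelta(days=d)
        if config.outing_p > 0 and rng.random() < config.outing_p and rest_places:
            arr = day0 + timedelta(hours=float(rng.uniform(9.0, 13.0)))
            dep = arr + timedelta(hours=float(rng.uniform(0.5, 2.0)))
            if not overlaps_stay(arr, dep):
                p = rest_places[int(rng.integers(len(rest_places)))]
                visits.append((arr, dep, p.lat, p.lon))
        if world.confounders and rng.random() < p_conf_daily:
            arr = day0 + timedelta(hours=float(rng.uniform(14.0, 18.0)))
            dur = _lognormal_hours(rng, config.confounder_median_hours, config.confounder_sigma_log)
            dep = arr + timedelta(hours=min(dur, 12.0))
            if not overlaps_stay(arr, dep):
                p = world.confounders[int(rng.integers(len(world.confounders)))]
                visits.append((arr, dep, p.lat, p.lon))
    visits.sort(key=lambda v: v[0])

    fixes: list[GeoFix] = []
    last_ts: datetime | None = None

    def emit(ts: datetime, lat: float, lon: float) -> None:
        nonlocal last_ts
        ts = ts.replace(microsecond=0)
        if last_ts is not None and ts <= last_ts:
            ts = last_ts + timedelta(seconds=1)
        dn, de = rng.normal(0.0, noise, size=2)
        nlat, nlon = offset_point(lat, lon, float(dn), float(de))
        fixes.append(GeoFix(pid, ts, nlat, nlon))
        last_ts = ts

    emit(t0, *home)
    prev_depart: datetime | None = None
    for arr, dep, lat, lon in visits:
        if prev_depart is not None and arr < prev_depart:
            continue  # overlapping casual visits: drop the later one
        emit(arr, lat, lon)
        emit(dep, *home)
        prev_depart = dep
    return fixes


def preset(name: str, seed: int = 0, **overrides) -> SimConfig:
    """Named study scenarios.

    ``pilot`` — study-scale conditions: 85 participants with the frozen
    follow-up table (647 monthly surveys in total), 85.8% geofencing
    opt-in, heavy early opt-out, 69% survey compliance, sparse CV events,
    and a forced pair of CV hospitalizations 14 days apart to exercise the
    single-report-per-survey miss.

    ``ideal`` — every detection precondition holds: geofencing always on,
    full compliance, immediate responses, every stay >= 4 h. Geofence
    sensitivity should be 100% here by construction.

    ``adversarial`` — short stays, rampant confounder visits, a gym
    co-located with a hospital, aggressive opt-out.
    """
    base = dict(seed=seed)
    if name == "pilot":
        base.update(
            n_participants=85,
            followup_days=PILOT_FOLLOWUP_DAYS,
            ensure_close_pair=True,
        )
    elif name == "ideal":
        base.update(
            n_participants=200,
            followup_days=365,
            p_stay_lt_4h=0.0,
            geofence_consent_p=1.0,
            optout_hazard=0.0,
            survey_compliance_p=1.0,
            response_latency_p=1.0,
        )
    elif name == "adversarial":
        base.update(
            n_participants=85,
            followup_days=365,
            p_stay_lt_4h=0.5,
            healthfacility_visit_rate=2.0,
            confounder_median_hours=3.0,
            colocated_confounder=True,
            optout_hazard=0.7,
            survey_compliance_p=0.4,
        )
    else:
        raise ValueError(f"unknown preset {name!r} (expected pilot | ideal | adversarial)")
    base.update(overrides)
    return SimConfig(**base)
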