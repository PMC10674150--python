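"""Cross-channel ascertainment evaluation.

Given gold-standard hospitalization events (the site-coordinator channel,
treated as reference) and the digitally reported events from the geofence
and monthly-survey channels, this module matches reports to gold events
and computes the performance metrics of interest: per-channel detection
rates with Agresti-Coull 95% confidence intervals, channel yields
(confirmed CV hospitalizations per contact), survey completion rates,
detection latency medians with IQRs, and true/false alert tables per
study-time bin.

The Agresti-Coull interval adds z²/2 pseudo-successes and z² pseudo-trials
before applying the Wald formula and clips the result to [0, 1]; it is the
standard recommendation for binomial proportions at small-to-moderate n.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import date, timedelta
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.stats import norm

__all__ = [
    "BinomialCI",
    "GoldEvent",
    "ChannelReport",
    "MatchResult",
    "EvalReport",
    "agresti_coull_interval",
    "match_events",
    "detection_summary",
    "latency_summary",
    "alert_table",
    "yield_summary",
    "coordinator_reports",
]

CHANNELS = ("geofence", "monthly", "coordinator")
DEFAULT_DATE_TOLERANCE_DAYS = 7


@dataclass(frozen=True)
class BinomialCI:
    """A binomial proportion with its Agresti-Coull interval."""

    successes: int
    trials: int
    confidence: float
    point: float
    lower: float
    upper: float

    def __str__(self) -> str:  # "88.9% (8/9; 95% CI 54.3%-100.0%)"
        return (
            f"{100 * self.point:.1f}% ({self.successes}/{self.trials}; "
            f"{100 * self.confidence:.0f}% CI {100 * self.lower:.1f}%-{100 * self.upper:.1f}%)"
        )


def agresti_coull_interval(x: int, n: int, confidence: float = 0.95) -> BinomialCI:
    """Agresti-Coull confidence interval for a binomial proportion.

    With z the standard-normal quantile at (1+confidence)/2:
    ñ = n + z², p̃ = (x + z²/2)/ñ, half-width = z·sqrt(p̃(1−p̃)/ñ);
    bounds are clipped to [0, 1].
    """
    if n < 1:
        raise ValueError("trials must be >= 1")
    if not 0 <= x <= n:
        raise ValueError(f"successes {x} outside [0, {n}]")
    if not 0 < confidence < 1:
        raise ValueError("confidence must be in (0, 1)")
    z = norm.ppf((1 + confidence) / 2)
    n_tilde = n + z * z
    p_tilde = (x + z * z / 2) / n_tilde
    half = z * math.sqrt(p_tilde * (1 - p_tilde) / n_tilde)
    return BinomialCI(
        successes=x,
        trials=n,
        confidence=confidence,
        point=x / n,
        lower=max(0.0, p_tilde - half),
        upper=min(1.0, p_tilde + half),
    )


@dataclass(frozen=True)
class GoldEvent:
    """A reference (coordinator-ascertained) hospitalization."""

    event_id: str
    participant_id: str
    admit_date: date
    discharge_date: date
    is_cv: bool = True
    is_overnight: bool = True
    coordinator_ascertained_on: date | None = None

    def __post_init__(self) -> None:
        if self.discharge_date < self.admit_date:
            raise ValueError(f"gold event {self.event_id}: discharge precedes admit")
        if self.coordinator_ascertained_on is not None and self.coordinator_ascertained_on < self.discharge_date:
            raise ValueError(f"gold event {self.event_id}: ascertained before discharge")


@dataclass(frozen=True)
class ChannelReport:
    """A hospitalization report arriving through one ascertainment channel."""

    report_id: str
    participant_id: str
    channel: str  # geofence | monthly | coordinator
    report_date: date  # when the report was completed/recorded
    claimed_admit_date: date  # the admission date the report describes


def coordinator_reports(gold: Sequence[GoldEvent]) -> list[ChannelReport]:
    """Synthesize coordinator-channel reports from gold events.

    The coordinator learns of each event at its next scheduled contact
    (``coordinator_ascertained_on``); events lacking that date are skipped.
    """
    return [
        ChannelReport(
            report_id=f"coord-{g.event_id}",
            participant_id=g.participant_id,
            channel="coordinator",
            report_date=g.coordinator_ascertained_on,
            claimed_admit_date=g.admit_date,
        )
        for g in gold
        if g.coordinator_ascertained_on is not None
    ]


@dataclass
class MatchResult:
    gold_event_id: str
    matched: dict[str, bool] = field(default_factory=lambda: {c: False for c in CHANNELS})
    report_dates: dict[str, date | None] = field(default_factory=lambda: {c: None for c in CHANNELS})
    latency_days: dict[str, int | None] = field(default_factory=lambda: {c: None for c in CHANNELS})


def match_events(
    gold: Sequence[GoldEvent],
    reports: Sequence[ChannelReport],
    date_tolerance_days: int = DEFAULT_DATE_TOLERANCE_DAYS,
) -> tuple[list[MatchResult], list[ChannelReport]]:
    """Greedy one-to-one matching of channel reports to gold events.

    Per channel and participant, each report (processed in canonical
    (report_date, claimed_admit_date, report_id) order, so the outcome is
    independent of input ordering) is matched to the still-unmatched gold
    event whose admit date is nearest the claimed admit date and within
    tolerance; ties go to the earliest gold admit date. Latency is report
    completion date minus gold admit date. Unmatched reports are returned
    as surplus (digitally reported events with no reference counterpart).
    """
    results = {g.event_id: MatchResult(g.event_id) for g in gold}
    by_id = {g.event_id: g for g in gold}
    surplus: list[ChannelReport] = []
    canonical = sorted(reports, key=lambda r: (r.report_date, r.claimed_admit_date, r.report_id))
    taken: set[tuple[str, str]] = set()  # (channel, gold_event_id)
    tol = timedelta(days=date_tolerance_days)
    for rep in canonical:
        candidates = [
            g
            for g in gold
            if g.participant_id == rep.participant_id
            and (rep.channel, g.event_id) not in taken
            and abs(g.admit_date - rep.claimed_admit_date) <= tol
        ]
        if not candidates:
            surplus.append(rep)
            continue
        best = min(candidates, key=lambda g: (abs(g.admit_date - rep.claimed_admit_date), g.admit_date))
        taken.add((rep.channel, best.event_id))
        res = results[best.event_id]
        res.matched[rep.channel] = True
        res.report_dates[rep.channel] = rep.report_date
        res.latency_days[rep.channel] = (rep.report_date - by_id[best.event_id].admit_date).days
    return [results[g.event_id] for g in gold], surplus


def detection_summary(
    matches: Sequence[MatchResult],
    channel: str | Sequence[str],
    confidence: float = 0.95,
) -> BinomialCI:
    """Detection rate of one channel (or a channel union) against gold.

    ``channel`` may be a single channel name or a collection, in which case
    an event counts as detected if any listed channel matched it.
    """
    if not matches:
        raise ValueError("no gold events to summarize")
    channels = [channel] if isinstance(channel, str) else list(channel)
    hit = sum(1 for m in matches if any(m.matched[c] for c in channels))
    return agresti_coull_interval(hit, len(matches), confidence)


def latency_summary(matches: Sequence[MatchResult], channel: str) -> dict[str, float]:
    """Median and IQR of detection latency, in days.

    Quartiles use the averaged-inverted-CDF convention (order statistics,
    averaging the two straddling values when n·q is an integer): the
    median of an even-sized sample is the usual midpoint average, and the
    quartiles of a 3-element sample are its extremes.
    """
    lat = [m.latency_days[channel] for m in matches if m.matched[channel]]
    if not lat:
        raise ValueError(f"no matched events in channel {channel!r}")
    q1, med, q3 = np.percentile(lat, [25, 50, 75], method="averaged_inverted_cdf")
    return {"n": len(lat), "median": float(med), "q1": float(q1), "q3": float(q3)}


def alert_table(
    alerts: Sequence[tuple[float, bool]],
    bin_edges: Sequence[float],
) -> list[dict[str, float | None]]:
    """True/false alert counts per study-time bin.

    ``alerts`` are ``(study_day, is_true)`` pairs — is_true meaning the
    alert fired at an actual hospital rather than a nonhospital health
    facility. Bins are half-open ``[edge[i], edge[i+1])`` except the last,
    which is closed. Every alert must fall inside the bins. An empty bin's
    percentage is None (0/0 is undefined, not zero).
    """
    edges = list(bin_edges)
    if len(edges) < 2 or any(a >= b for a, b in zip(edges, edges[1:])):
        raise ValueError("bin_edges must be strictly increasing with >= 2 edges")
    rows = [
        {"bin_start": lo, "bin_end": hi, "n_true": 0, "n_false": 0}
        for lo, hi in zip(edges, edges[1:])
    ]
    for day, is_true in alerts:
        if day < edges[0] or day > edges[-1]:
            raise ValueError(f"alert at study day {day} outside bins [{edges[0]}, {edges[-1]}]")
        i = min(int(np.searchsorted(edges, day, side="right")) - 1, len(rows) - 1)
        rows[i]["n_true" if is_true else "n_false"] += 1
    for r in rows:
        total = r["n_true"] + r["n_false"]
        r["n_total"] = total
        r["true_alert_pct"] = 100.0 * r["n_true"] / total if total else None
    return rows


def yield_summary(channel_contacts: int, confirmed_cv: int) -> float:
    """Channel yield: confirmed CV hospitalizations per contact, as a proportion."""
    if channel_contacts <= 0:
        raise ValueError("channel_contacts must be positive")
    if confirmed_cv > channel_contacts:
        raise ValueError("confirmed events cannot exceed contacts")
    return confirmed_cv / channel_contacts


@dataclass
class EvalReport:
    """Bundle of everything the evaluation computes, serializable to JSON."""

    n_gold: int
    detection: dict[str, BinomialCI]
    latency: dict[str, dict[str, float]]
    completion: dict[str, BinomialCI]
    yields: dict[str, float]
    alert_bins: list[dict[str, float | None]] | None = None
    surplus_reports: int = 0

    def to_dict(self) -> dict:
        def ci(b: BinomialCI) -> dict:
            return {
                "successes": b.successes, "trials": b.trials, "point": b.point,
                "lower": b.lower, "upper": b.upper, "confidence": b.confidence,
            }

        return {
            "n_gold": self.n_gold,
            "detection": {k: ci(v) for k, v in self.detection.items()},
            "latency": self.latency,
            "completion": {k: ci(v) for k, v in self.completion.items()},
            "yields": self.yields,
            "alert_bins": self.alert_bins,
            "surplus_reports": self.surplus_reports,
        }

    def render_text(self) -> str:
        lines = [f"Gold-standard hospitalizations: {self.n_gold}", "", "Detection by channel:"]
        for ch, ci in self.detection.items():
            lines.append(f"  {ch:22s} {ci}")
        lines.append("")
        lines.append("Detection latency (days):")
        for ch, s in self.latency.items():
            lines.append(f"  {ch:22s} median {s['median']:.1f} (IQR {s['q1']:.1f}-{s['q3']:.1f}), n={s['n']:.0f}")
        if self.completion:
            lines.append("")
            lines.append("Survey completion:")
            for ch, ci in self.completion.items():
                lines.append(f"  {ch:22s} {ci}")
        if self.yields:
            lines.append("")
            lines.append("CV yield per contact:")
            for ch, y in self.yields.items():
                lines.append(f"  {ch:22s} {100 * y:.1f}%")
        if self.alert_bins is not None:
            lines.append("")
            lines.append("Geofence alerts per period (true/false, % true):")
            for r in self.alert_bins:
                pct = "n/a" if r["true_alert_pct"] is None else f"{r['true_alert_pct']:.1f}%"
                lines.append(
                    f"  days {r['bin_start']:.0f}-{r['bin_end']:.0f}: "
                    f"{r['n_true']}/{r['n_total']} true ({pct})"
                )
        if self.surplus_reports:
            lines.append("")
            lines.append(f"Surplus digital reports with no gold counterpart: {self.surplus_reports}")
        return "\n".join(lines)
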