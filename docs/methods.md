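# Methods

## Dwell detection

The fix stream is event-driven: the phone emits one fix per detected
movement, so between fixes the device is assumed stationary at its last
anchor. Segmentation is single-pass: the first retained fix anchors an
episode; the first subsequent fix farther than `movement_radius_m`
(default **250 m**, great-circle) starts a new episode and closes the old
one at its own timestamp. Episodes also close at a consent-interval end
(the running dwell is truncated there when the stream continues past it)
and at stream end. Fixes outside consent intervals are dropped before
segmentation and are never stored anywhere.

The displacement threshold of 250 m reflects urban GPS/cell-triangulation
accuracy: it is large relative to the simulator's 15 m position noise
(no spurious episode splits) and small relative to the ≥1 km spacing of
health facilities (no merged visits). An optional `max_gap` closes an
episode at the last fix before a silence longer than the gap, for feeds
where silence may mean data loss rather than stillness; by default
silence is trusted, which is the event-driven contract.

Classification uses only the episode's anchor coordinate, queried against
the gazetteer at `query_radius_m` (default **300 m**, roughly a hospital
campus); re-classification on later fixes within an episode is not
performed. The dwell clock starts at the anchor fix; an alert fires at
`start + dwell_threshold` (default **4 h**) when the classification is
HOSPITAL, at most once per episode — a multi-day continuous stay alerts
once, while separate visits (split by a movement fix) alert once each.

## Keyword classification

Matching is case-insensitive substring matching of dictionary terms
against each place's lowercased name and category tags. "Keyword" admits
several readings; substring is the most permissive that still keys on the
curated lists ("medical center" matches "St. Mary Medical Center West").
Dictionary versions are data: each has an `effective_from_day`, and an
episode uses the version active on its start day, so iterative refinement
of the exclusion list is replayable without code changes. The shipped
default set (v0: includes {hospital, medical center, health}, no
exclusions; v1 from day 210 and v2 from day 365 adding gym / fitness /
pharmacy / dentist / aesthetic / spa / veterinar) is an illustrative
synthetic reconstruction of that pattern, not a transcription of any
production dictionary.

Exclusion scope is configurable. `array` (default): one excluded place
anywhere in the returned array suppresses HOSPITAL — the literal reading
of "not containing any of the excluded places", at the cost of possibly
suppressing a true hospital co-located with a gym. `place`: only the
include-matching places are tested against the exclusion list. The
simulator's `colocated_confounder` flag builds exactly the world where
the two diverge.

## Surveys

Monthly instances open at `enrollment + k·cycle_days` (k ≥ 1, default
30-day cycles anchored to enrollment, not calendar months) and stay
available for one full cycle; triggered instances open at the alert and
close after 7 days, hard. Reminders: one at +24 h, then every 7 days,
stopping at completion or window close. A response form has a single
admit/discharge slot; the schema itself enforces one reportable
hospitalization per survey, which caps monthly-channel capacity at one
event per cycle.

## Evaluation

Reports are matched to gold events greedily, one-to-one per channel,
within a participant, on nearest admit date within ±7 days (ties to the
earlier gold event); processing order is canonicalized so the outcome is
independent of input ordering. Latency is report-completion date minus
gold **admit** date (configurable in principle to discharge; admission is
the clinically relevant onset). The Agresti–Coull interval uses
`z = Φ⁻¹((1+c)/2)` from scipy and clips to [0, 1]. Latency quartiles use
the averaged-inverted-CDF convention (order statistics, averaging when
n·q is an integer): it yields midpoint medians at even n and returns
sample extremes as quartiles of 3-element samples, matching the summary
convention of the clinical literature this package serves. Displayed
percentages are rounded half-up to one decimal; where a source prints a
truncated value instead, tests accept either reading rather than silently
adopting truncation.

An alert is labelled *true* when it fired at an actual hospital
coordinate, *false* when at a nonhospital health facility; per-bin tables
leave an empty bin's percentage undefined (None) rather than zero.

## Simulator

The synthetic city places hospitals, gyms, pharmacies, dentists and
restaurants on a 1.5 km grid (health facilities ≥ 1 km apart) and homes
uniformly over a ~10 km box, rejected within 700 m of any health facility
so residential dwells never intersect a facility's query radius. Each
participant's day: an optional restaurant outing (p = 0.6), confounder
visits at `healthfacility_visit_rate` (default 0.5/week, log-normal
duration median 1.5 h, σ = 1.0 — about 16% exceed the 4-h threshold,
which is what makes false alerts possible at all), and hospital stays
sampled per event. One fix per arrival, Gaussian noise σ = 15 m, whole
seconds.

Event model: CV and non-CV admissions are Poisson with per-participant-
month rates (defaults 0.014 and 0.005 — sparse, as in a post-PCI cohort);
stay durations are log-normal (median 48 h, σ_log = 0.6) with an explicit
probability mass `p_stay_lt_4h` (default 0.10) forced below 4 h. Every
stay is placed at a gazetteer hospital, so a missed detection is always
attributable to the detector, consent, or stay duration — never to the
world. Consent: opt-in with probability 0.858; among consenters the
opt-out month is geometric with per-month hazard 0.5, reproducing the
short transmission windows characteristic of background location tracking
(median on-time ≈ 1 month). Survey behavior: per-survey completion is
Bernoulli (default 0.69) with a geometric response delay (p = 0.5, mean
1 day); a compliant monthly response reports the event with the most
recent discharge in the just-elapsed cycle (the single-slot constraint
drops the other of a close pair); triggered surveys are answered
honestly — "not hospitalized" for false alerts. The coordinator channel
ascertains each event at the next scheduled contact (defaults: study days
180 and 360, else the participant's closing visit).

Presets: **pilot** (85 participants with a frozen follow-up table — 85
durations, median 7.4 months, chosen once so the cohort accrues exactly
647 monthly instances — plus a forced pair of CV events 14 days apart),
**ideal** (200 participants, every detection precondition satisfied;
geofence sensitivity is 100% by construction and latency ordering
geofence < monthly < coordinator emerges), **adversarial** (short stays,
heavy confounding, a gym inside a hospital's query radius, aggressive
opt-out). The follow-up table is approximate — real per-participant
exposure is known only through medians — and all enrollments are
synchronized at study day 0, which real cohorts are not.

What the simulator does **not** model: within-dwell fix chatter beyond
the arrival fix, cell-tower fallback error structure, phones left at
home, staggered enrollment, demographic covariates, recall error in
reported dates, and participants who work at hospitals. Passing tests
therefore demonstrate the pipeline's contracts and the direction of its
trade-offs under the stated generative assumptions, not field performance.

## Numerical and scale choices

All randomness flows through `numpy.random.default_rng(seed + k)` with
small fixed offsets k per stage, so every artifact is byte-reproducible
under a fixed seed. Gazetteer queries sort by (distance, place_id);
matching sorts reports by (report date, claimed admit, id) — all ties are
deterministic. Cohort-level checks run at 200 participants × 12 months
(a few hundred thousand fixes, tens of seconds end-to-end), and
parameter-recovery checks at n = 1000 without trace generation; these
sizes give 3-σ sampling bands comfortably tighter than the effects being
asserted.
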