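# geotrigger

Digital ascertainment of hospitalizations for clinical-trial follow-up:
geofence dwell detection with keyword-based hospital classification,
monthly and alert-triggered hospitalization surveys, a seeded cohort
simulator, and an evaluation harness that scores the digital channels
against gold-standard (site-coordinator) event logs.

## The problem

Trials that use hospitalization as an end point traditionally ascertain
events by coordinator phone calls and chart review — slow, expensive, and
mostly spent contacting participants who were never hospitalized. A
smartphone alternative runs two passive/low-touch channels in parallel:

* **Geofencing.** The phone reports a GPS fix on each detected movement.
  Consecutive fixes within a displacement radius *r* of an anchor fix form
  a *dwell episode*; the anchor coordinate is mapped to the array of
  nearby named places, and the array is classified with versioned
  include/exclude keyword dictionaries (HOSPITAL if some place's name or
  category contains an include term and no place matches an exclude term;
  HEALTH_NONHOSPITAL if an exclude term also matched; OTHER else). A
  hospital-classified dwell of duration ≥ T (default 4 h) raises an alert
  at `start + T` and opens a survey that expires 7 days later.
* **Monthly surveys.** Scheduled every 30 days from enrollment, each
  available for a full cycle, with reminders at +24 h then weekly. A
  response carries at most **one** hospitalization (admit/discharge dates,
  overnight flag, CV/non-CV reason) — so two events in one cycle cannot
  both be reported.

The evaluation matches each channel's reports to gold events (greedy
one-to-one on nearest admit date within ±7 days), then computes per-channel
detection rates with **Agresti–Coull** 95% intervals

> ñ = n + z², p̃ = (x + z²/2)/ñ, p̃ ± z·√(p̃(1−p̃)/ñ), clipped to [0, 1],

detection-latency medians/IQRs, survey completion rates, channel yields
(confirmed CV hospitalizations per contact), and true/false alert counts
per dictionary era.

Because no cohort data ship with the package, a simulator generates the
whole study: a synthetic city gazetteer, event-driven GPS trajectories
with Gaussian noise, hospital stays (log-normal durations with an explicit
sub-4-h mass), gym/pharmacy/dentist confounder visits, geofencing consent
and opt-out, and partial survey compliance. See `docs/methods.md`.

## Worked example

```bash
geotrigger run --preset pilot --seed 1 --report report.json
```

simulates a study-scale cohort (85 participants, 647 monthly surveys,
85.8% geofencing opt-in with heavy early opt-out, 69% compliance) and
prints:

```
Gold-standard hospitalizations: 15

Detection by channel:
  geofence               13.3% (2/15; 95% CI 2.5%-39.1%)
  monthly                66.7% (10/15; 95% CI 41.5%-85.0%)
  coordinator            100.0% (15/15; 95% CI 76.1%-100.0%)
  digital_union          66.7% (10/15; 95% CI 41.5%-85.0%)

Detection latency (days):
  geofence               median 1.0 (IQR 0.0-2.0), n=2
  monthly                median 23.0 (IQR 12.0-30.0), n=10
  coordinator            median 110.0 (IQR 55.0-157.0), n=15

Survey completion:
  monthly                68.9% (446/647; 95% CI 65.3%-72.4%)
  geofence               69.8% (30/43; 95% CI 54.8%-81.5%)

CV yield per contact:
  monthly                2.2%
  geofence               6.7%
  coordinator            9.6%

Geofence alerts per period (true/false, % true):
  days 0-139: 2/43 true (4.7%)
```

Reading it: the coordinator channel sees every event but a median 110
days late; the monthly survey catches two thirds of events (losses come
from partial compliance and the one-report-per-cycle constraint) within a
few weeks; geofencing reports within a day or two but misses events whose
participants opted out of location tracking — the qualitative trade-off
the system is designed to expose. Most early alerts are false (gyms and
pharmacies tagged "health"); switching to a dictionary version with
exclusion terms removes them.

Other entry points: `geotrigger simulate` (write a synthetic world/cohort
as CSV/GeoJSON), `detect` (dwell detection over fix streams), `schedule` /
`respond` (survey scheduling and simulated response replay), `evaluate`
(match reports to gold events and emit the metric report). Each command is
a thin wrapper over the library (`geotrigger.gazetteer`, `.dwell`,
`.surveys`, `.simulate`, `.evaluate`, `.pipeline`).

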