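# Methods

This note documents the models and procedures implemented in `ewsval`, the
choices made where the design was genuinely open, and what the synthetic
data can and cannot show.

## Scoring model

An early-warning score maps each vital parameter of an observation set to a
subscore in {0, 1, 2, 3} and sums them.  Two systems are bundled as data
files (`src/ewsval/data/*.yaml`):

* **NEWS** — the standard six-parameter score plus a binary
  oxygen-therapy flag (any flow above room air scores 2).  Maximum total
  20.  Agitated patients score as alert, as in routine practice with the
  original scale.
* **GEWS** — a frailty-adapted variant: narrower normal bands (e.g.
  tachycardia already at HR 96-120, hypotension below SBP 100), graded
  oxygen therapy by flow (0 / 1 / 2-4 / >=5 L/min), a graded consciousness
  scale with agitation assigned the highest score, and pain (NRS or
  PAINAD, 0-10) as an eighth scored item.  Maximum total 24.

Band semantics: printed ranges "a-b" are closed; bands per parameter are
validated to be disjoint and to cover a dense grid over the physiologic
domain at a stated resolution (1 unit for counts and pressures, 0.1 °C for
temperature).  Off-grid values that fall in a printed gap (e.g. a
respiration rate recorded as 23.5) resolve to the band below; a strict
mode raises instead.  Two table cells required a decision:

* the standard tachycardia rows print "111-130" (score 2) and ">= 130"
  (score 3), which overlap at 130; the score-3 band starts at 131 here,
  matching the published scale;
* the column placement of the frailty-adapted HR 76-95 / 96-120 and
  SBP 190-220 bands is a positional reading of the printed rows; since
  tables are data, a correction is a one-line YAML edit.

Forehead temperature measurements are corrected by +0.2 °C before
scoring; a missing measurement site leaves the value unchanged (logged).

Trigger rules combine a total threshold with an optional "S3" clause
(alert on any single subscore of 3).  The bundled defaults are the
escalation thresholds evaluated in validation practice: NEWS >= 5 (with and
without S3), NEWS >= 7, GEWS >= 4 + S3, GEWS >= 5 (with and without S3),
GEWS >= 8.

## Episodes and observation labeling

Hospitalizations are segmented so that post-intervention observations do
not contaminate the negative class (treatment bias):

* Episode 1 starts at admission (ED arrival when recorded).  If urgent
  interventions (Type 4 events) occur early, episode 1 ends 72 h after the
  last of them and episode 2 runs to discharge.  "Last Type 4 of the first
  episode" is self-referential, so the end is computed as a fixed point:
  the episode keeps extending while further Type 4 events fall before its
  current end.  With no early intervention the whole stay is one episode.
* A life-threatening event (Type 1-3) within 12 h after a Type 4 absorbs
  it into a single Type 1-3 event at the later timestamp; only the first
  Type 1-3 event per patient is retained, and events recorded after it are
  dropped with a warning.  Simultaneous events keep the most severe type.
* Labels use half-open windows so every instant gets exactly one label:
  `event` in [t-12 h, t) before an event; `neutralized` in [t-24 h,
  t-12 h), at/after a Type 1-3 event, at/after a Type 4 event until the
  end of its episode, or outside every episode; `non_event` otherwise.
  Membership in a *later* event's window overrides neutralization from a
  past event.  An observation at exactly t-12 h takes the more severe
  (event) label.

Neutralized sets are imputed but excluded from every metric.  For the
life-threatening-events analysis (Type 1-3 subset) the labels are
unchanged, but event-window observations anchored to a Type 4 event are
excluded, and their windows are removed from the patient-day denominator.

## Imputation

Missing values are imputed on the subscore scale (0 is a valid score, not
a valid vital value), in two stages per patient in time order: a missing
subscore becomes 0 if the set is the patient's first, the parameter was
never measured before, the set follows the previous one by more than 12 h,
or the set is neutralized; otherwise the previous observation set's final
subscore is carried forward.  Carrying the *post-imputation* value means a
stage-1 zero becomes the carried value, so LOCF can never reach back across
a >12 h gap, and every imputed subscore is either 0 or an earlier measured
subscore of the same parameter.  The 12 h gap is measured to the previous
observation set of the patient (any parameters); measuring it per
parameter is available as configuration.

## Metrics and inference

Threshold metrics come from the 2x2 table of alert x event over analyzed
observation sets.  Clinical burden: NNE = 1/PPV (alerts evaluated per true
alert), ROA = alerts per 100 patient-days, AOER = true-positive alerts per
100 patient-days; the identities AOER = PPV x ROA and NNE = ROA/AOER are
asserted to 1e-12 on every computed report.  Undefined metrics (zero
denominators) are reported as NaN, never silently 0.

The patient-day denominator defaults to *analyzed time*: length of stay
minus neutralized time (with event windows overriding, exactly as in
labeling), summed over patients contributing observations; the full stay
is available as configuration.  Ward-level burden re-expresses a
per-100-patient-day rate as events per 24 h on a fully occupied b-bed ward
by multiplying with b/100.

AUROC uses the rank (Mann-Whitney) formulation with half credit for ties,
which equals the trapezoidal area under the threshold-swept ROC curve and
the pairwise concordance probability (tested against brute-force
enumeration).  PR-AUC is non-interpolated average precision over
descending observed score thresholds (linear PR interpolation is biased);
with all-equal scores it equals prevalence exactly.

Uncertainty: 95% percentile intervals from a clustered bootstrap that
resamples patients with replacement, all of a patient's observation sets
travelling together (default 10,000 resamples; statistics undefined in a
resample are dropped, and an interval undefined in more than half of them
is reported as a failure).  Paired comparisons between scores use a Monte
Carlo permutation test whose exchange unit is the patient cluster: the
(GEWS, NEWS) assignment is swapped per patient, two-sided
p = (1 + #{|d*| >= |d|}) / (B + 1) with 9,999 permutations by default
(per-observation swapping available as configuration).  One run seed
drives independent named streams for bootstrap and permutation, so adding
one procedure never perturbs another, and fixed seed implies bit-identical
output.

## Synthetic cohorts

The generator emulates the statistical structure of an acute geriatric
ward study; defaults are the study conditions:

| quantity | default | basis |
|---|---|---|
| patients | 511 | cohort size |
| length of stay | log-normal, median 11 d, sigma 0.55 | median 11 (IQR 7-15); sigma chosen so the simulated IQR (~7.6-15.9) matches within 10% |
| life-threatening events | 0.005 / patient-day, first kept | planning rate |
| urgent interventions | Poisson(0.6)/patient, exponential times (mean 36 h from admission) | ~0.6/patient, admission-proximal with declining hazard |
| schedule | ED arrival + q3h in ED + ward admission + 2 jittered shifts/day | routine ward observation |
| demographics | age N(85,5), 60% female, CFS 27/31/30/12% | cohort summaries |
| pain missingness | 10%, but 40% in one of three centers | center effect on pain recording |

Baselines are drawn per patient from normal ranges centred in both scores'
0-bands with AR(1) within-patient noise (phi = 0.7).  Realism additions,
chosen once: 4% of observation sets carry a transient single-parameter
abnormality (isolated band crossings produce false alerts), 1.5% a
transient voice-level consciousness, and 8% of patients are on home
oxygen.  Deterioration is a linear ramp over the final 12 h before each
event; per event, severity is drawn uniformly from 0.3-1.0 and 15% of
events have no vital-sign prodrome at all (treated deterioration the
vitals never showed).  Shift profiles:

* `mixed` (default) — bands both scores penalise plus the GEWS-only items;
* `gews_sensitive` — confined to bands the frailty-adapted score marks >= 2
  but the standard score marks 0-1: pain >= 7, agitation, temperature
  37.5-38.0, HR 96-120, SBP 100-109.  (A low-normal SpO2 shift would *not*
  qualify: the standard scale scores SpO2 <= 91 as 3.)
* `news_sensitive` — SpO2 92-93, temperature 35.1-36.0, respiration 21-24;
* `symmetric` — extreme bands both scores call 3.

An effect multiplier scales every shift; 0 removes the signal.  Random
draws use independent named streams (cohort, per-patient observations,
per-patient severities), so changing the effect multiplier alters only
ramped observations.

What passing tests show — and do not.  The generator reproduces the
marginal structure the analysis relies on (stay lengths, event rates and
timing, observation cadence, missingness, a pre-event signal confined to
known bands).  It does not model treatment effects on post-event vitals
(those observations are neutralized anyway), physiologic coupling between
parameters, informative missingness, or inter-center case-mix differences
beyond pain recording.  Recovery of a GEWS-confined signal on synthetic
cohorts therefore demonstrates that the pipeline estimates what it claims
to estimate, not that either score performs at any particular level on
real patients.  Under the `symmetric` profile the AUROC difference is near
zero but slightly negative (~-0.04): the frailty-adapted bands are
narrower, so off-signal noise crosses them more often — a property of the
scores, not an artifact.

## Problem sizes

Statistical checks run at sizes chosen for stable Monte Carlo error:
bootstrap coverage with 200 replicates of 150 patients x 20 sets at
B = 1,000; permutation type-I error with 200 replicates at 999
permutations; signal recovery over 50 replicate 500-patient cohorts.  The
acceptance script validates one 511-patient cohort with B = 500 and 999
permutations; estimates are unaffected by the reduced resampling depth,
only interval/permutation resolution is.

## Known limitations

* The two GEWS table cells noted above rest on a positional reading of the
  printed rows; the data-file design makes corrections trivial.
* The analyzed-time patient-day denominator is a reconstruction; the
  full-stay alternative is one configuration switch.
* LOCF may carry an ED-measured subscore into the ward stay; no rule
  forbids it, and the gap condition bounds the reach to 12 h.
* The permutation scheme (cluster-level score swap) is one of several
  defensible choices; per-observation swapping is exposed for sensitivity
  analysis.
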