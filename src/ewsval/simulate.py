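"""Synthetic acute-geriatric-ward cohorts for exercising the validation
pipeline end to end without patient data.

The generator emulates the statistical structure the analysis assumes:

* a cohort of ~511 frail older inpatients, length of stay log-normal with
  median 11 days (IQR ~7-15);
* life-threatening (Type 1-3) outcome events as a Poisson process at
  0.005 per patient-day, at most one retained per patient;
* frequent Type 4 events (urgent unexpected interventions) concentrated
  near admission with a declining hazard, ~0.6 expected per patient;
* an observation schedule of ED arrival / in-ED / ward-admission sets plus
  two jittered ward shifts per day;
* a linear pre-event deterioration ramp over the final 12 h before each
  event, shifting selected parameters into scoring bands.  Shift profiles
  are named: ``mixed`` (default; hits bands both scores penalise plus the
  GEWS-only items), ``gews_sensitive`` (bands GEWS scores >= 2 but NEWS
  scores 0-1: pain >= 7, agitation, temperature 37.5-38.0, HR 96-120,
  SBP 100-109), ``news_sensitive`` (SpO2 92-93, temperature 35.1-36.0,
  respiration 21-24: NEWS-scored, GEWS-normal) and ``symmetric`` (extreme
  bands both scores call 3).  An effect-size multiplier scales every shift;
  0 removes the signal entirely.
* per-parameter missing-completely-at-random missingness, with pain
  missingness elevated in one simulated center.

Within-patient vital-sign noise is AR(1) around per-patient baselines drawn
from normal ranges centred in both scores' 0-bands.  Fixed seed implies
byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .scoring import OBS_COLUMNS

__all__ = ["CohortSpec", "SHIFT_PROFILES", "generate_cohort",
           "generate_worked_fixture", "draw_patients", "draw_events"]

#: Deterioration target values at full ramp (effect multiplier 1, event time).
SHIFT_PROFILES: dict[str, dict[str, float]] = {
    "mixed": {"resp_rate": 26, "spo2": 90, "temp": 38.4, "sbp": 96,
              "hr": 118, "o2_flow": 2, "pain": 7, "agitation": 0.3},
    "gews_sensitive": {"pain": 8, "temp": 37.8, "hr": 108, "sbp": 105,
                       "agitation": 0.8},
    "news_sensitive": {"spo2": 92, "temp": 35.6, "resp_rate": 22},
    "symmetric": {"resp_rate": 30, "spo2": 84, "hr": 135, "sbp": 85},
}

_BASELINES = {  # (mean, between-patient sd, within-patient AR sd)
    "resp_rate": (17.0, 1.5, 1.5),
    "spo2": (96.5, 1.0, 1.0),
    "temp": (36.6, 0.18, 0.15),
    "sbp": (141.0, 11.0, 8.0),
    "hr": (66.0, 5.0, 4.0),
}

_MISSINGNESS = {
    "resp_rate": 0.08, "spo2": 0.03, "o2_flow": 0.02, "temp": 0.05,
    "sbp": 0.03, "hr": 0.03, "consciousness": 0.05, "pain": 0.10,
}


@dataclass(frozen=True)
class CohortSpec:
    """Study conditions for one synthetic cohort."""

    n_patients: int = 511
    los_median_days: float = 11.0
    los_sigma: float = 0.55          # log-normal shape giving IQR ~7.6-15.9
    type13_rate: float = 0.005       # life-threatening events per patient-day
    type4_mean_per_patient: float = 0.6
    type4_decay_hours: float = 36.0  # declining admission-proximal hazard
    ed_stay_hours: tuple[float, float] = (3.0, 10.0)
    ed_obs_interval_hours: float = 3.0
    ward_shift_hours: tuple[float, ...] = (8.0, 16.0)
    shift_jitter_hours: float = 0.5
    effect_profile: str = "mixed"
    effect_multiplier: float = 1.0
    ramp_hours: float = 12.0
    pain_missing_center: str = "B"   # center with elevated pain missingness
    pain_missing_elevated: float = 0.40
    home_oxygen_prob: float = 0.08
    #: transient single-parameter abnormalities (frail baselines are noisy;
    #: isolated band crossings generate realistic false alerts)
    transient_spike_prob: float = 0.04
    consciousness_fluct_prob: float = 0.015  # transient 'voice' response
    #: per-event severity heterogeneity: fraction of events with no vital-sign
    #: prodrome at all, and the severity range of the rest (scales the ramp)
    silent_event_prob: float = 0.15
    severity_range: tuple[float, float] = (0.3, 1.0)
    start: str = "2022-09-01"

    def __post_init__(self) -> None:
        if self.n_patients < 1 or self.los_median_days <= 0:
            raise ValueError("infeasible cohort spec")
        if self.type13_rate < 0 or self.type4_mean_per_patient < 0:
            raise ValueError("rates must be non-negative")
        if self.effect_profile not in SHIFT_PROFILES:
            raise ValueError(
                f"unknown effect profile {self.effect_profile!r}; "
                f"have {sorted(SHIFT_PROFILES)}")


def draw_patients(spec: CohortSpec, rng: np.random.Generator) -> pd.DataFrame:
    """Admissions table: ids, admission/discharge times, demographics."""
    n = spec.n_patients
    start = pd.Timestamp(spec.start)
    adm_offset_days = rng.uniform(0, 180, size=n)
    adm_hour = rng.uniform(0, 24, size=n)
    admission = start + pd.to_timedelta(
        np.round((adm_offset_days * 24 + adm_hour) * 60), unit="m")
    los = np.exp(np.log(spec.los_median_days)
                 + spec.los_sigma * rng.standard_normal(n))
    los = np.maximum(los, 1.0)
    discharge = admission + pd.to_timedelta(np.round(los * 24 * 60), unit="m")
    ed_stay = rng.uniform(*spec.ed_stay_hours, size=n)
    ward_admission = admission + pd.to_timedelta(
        np.round(ed_stay * 60), unit="m")
    age = np.clip(np.round(rng.normal(85, 5, size=n)), 70, 101).astype(int)
    sex = np.where(rng.random(n) < 0.60, "F", "M")
    cfs_cat = rng.choice(4, size=n, p=[0.27, 0.31, 0.30, 0.12])
    cfs = np.select(
        [cfs_cat == 0, cfs_cat == 1, cfs_cat == 2],
        [rng.integers(3, 6, size=n), np.full(n, 6), rng.integers(7, 10, size=n)],
        default=-1,
    )
    dnr = rng.choice([0, 1, 2], size=n, p=[0.45, 0.17, 0.38])
    center = rng.choice(["A", "B", "C"], size=n, p=[0.40, 0.30, 0.30])
    return pd.DataFrame({
        "patient_id": [f"P{i:04d}" for i in range(n)],
        "admission": admission,
        "ward_admission": ward_admission,
        "discharge": discharge,
        "age": age,
        "sex": sex,
        "cfs": cfs,
        "dnr": dnr,
        "delirium_flag": (rng.random(n) < 0.082).astype(int),
        "center": center,
    })


def draw_events(patients: pd.DataFrame, spec: CohortSpec,
                rng: np.random.Generator) -> pd.DataFrame:
    """Clinical events: Type 1-3 Poisson at the per-patient-day rate (first
    occurrence kept), Type 4 counts Poisson with admission-proximal times."""
    rows = []
    for r in patients.itertuples():
        los_days = (r.discharge - r.admission) / pd.Timedelta(days=1)
        # Type 1-3: exponential waiting time; at most one per patient
        if spec.type13_rate > 0:
            wait = rng.exponential(1.0 / spec.type13_rate)
            if wait < los_days:
                ts = min(r.admission + pd.Timedelta(minutes=round(wait * 24 * 60)),
                         r.discharge)
                etype = int(rng.choice([1, 2, 3], p=[7 / 31, 12 / 31, 12 / 31]))
                rows.append((r.patient_id, ts, etype, "life-threatening"))
        # Type 4: declining hazard from admission
        n4 = rng.poisson(spec.type4_mean_per_patient)
        for _ in range(n4):
            h = rng.exponential(spec.type4_decay_hours)
            if h < los_days * 24:
                ts = min(r.admission + pd.Timedelta(minutes=round(h * 60)),
                         r.discharge)
                rows.append((r.patient_id, ts, 4, "urgent intervention"))
    df = pd.DataFrame(rows, columns=["patient_id", "timestamp", "event_type",
                                     "detail"])
    df = df.sort_values(["patient_id", "timestamp"], kind="stable",
                        ignore_index=True)
    df["event_id"] = [f"E{i:05d}" for i in range(len(df))]
    return df


def _obs_times(r, spec: CohortSpec, rng: np.random.Generator) -> np.ndarray:
    """Observation schedule for one patient row (minute resolution)."""
    times = [r.admission]
    t = r.admission + pd.Timedelta(hours=spec.ed_obs_interval_hours)
    while t < r.ward_admission:
        times.append(t)
        t += pd.Timedelta(hours=spec.ed_obs_interval_hours)
    times.append(r.ward_admission)
    day = r.ward_admission.normalize() + pd.Timedelta(days=1)
    while day < r.discharge:
        for h in spec.ward_shift_hours:
            t = day + pd.Timedelta(
                minutes=round((h + rng.normal(0, spec.shift_jitter_hours)) * 60))
            if r.ward_admission < t < r.discharge:
                times.append(t)
        day += pd.Timedelta(days=1)
    arr = pd.DatetimeIndex(times).round("min").unique().sort_values()
    return arr


def generate_cohort(
    spec: CohortSpec = CohortSpec(), seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate (patients, observations, events) frames for one cohort.

    Independent named random streams (admissions/events, one per patient's
    observations, one per patient's event severities) keep changes to one
    component — e.g. setting the effect multiplier to 0 — from perturbing
    draws elsewhere.
    """
    rng = np.random.default_rng([seed, 0])
    patients = draw_patients(spec, rng)
    events = draw_events(patients, spec, rng)
    ev_by_pid: dict[str, np.ndarray] = {
        pid: grp["timestamp"].to_numpy()
        for pid, grp in events.groupby("patient_id", sort=False)
    }
    profile = SHIFT_PROFILES[spec.effect_profile]
    mult = spec.effect_multiplier
    ramp = pd.Timedelta(hours=spec.ramp_hours)

    obs_rows = []
    for i, r in enumerate(patients.itertuples()):
        prng = np.random.default_rng([seed, 1, i])      # observation stream
        sev_rng = np.random.default_rng([seed, 2, i])   # event-severity stream
        times = _obs_times(r, spec, prng)
        k = len(times)
        vals = {}
        for p, (mu, sd_b, sd_w) in _BASELINES.items():
            base = prng.normal(mu, sd_b)
            dev = np.empty(k)
            dev[0] = prng.normal(0, sd_w)
            for j in range(1, k):
                dev[j] = 0.7 * dev[j - 1] + prng.normal(0, sd_w * 0.7)
            vals[p] = base + dev
        o2 = np.full(k, 1.0 if prng.random() < spec.home_oxygen_prob else 0.0)
        pain = np.where(prng.random(k) < 0.20,
                        prng.integers(1, 3, size=k), 0).astype(float)
        cons = np.full(k, "alert", dtype=object)
        cons[prng.random(k) < spec.consciousness_fluct_prob] = "voice"

        # transient single-parameter abnormalities (isolated band crossings)
        spike = np.flatnonzero(prng.random(k) < spec.transient_spike_prob)
        for j in spike:
            p = prng.choice(["resp_rate", "spo2", "temp", "sbp", "hr", "pain"])
            if p == "resp_rate":
                vals[p][j] += prng.uniform(4, 12)
            elif p == "spo2":
                vals[p][j] -= prng.uniform(3, 10)
            elif p == "temp":
                vals[p][j] += prng.choice([-1, 1]) * prng.uniform(0.6, 2.0)
            elif p == "sbp":
                vals[p][j] += prng.choice([-1, 1]) * prng.uniform(25, 60)
            elif p == "hr":
                vals[p][j] += prng.uniform(-35, 60)
            else:
                pain[j] = max(pain[j], prng.integers(3, 9))

        # pre-event deterioration ramp (fraction of full effect per obs)
        ev = ev_by_pid.get(r.patient_id)
        frac = np.zeros(k)
        if ev is not None and mult != 0:
            tn = times.to_numpy()
            for et in ev:
                if sev_rng.random() < spec.silent_event_prob:
                    continue  # no vital-sign prodrome for this event
                sev = sev_rng.uniform(*spec.severity_range)
                dt = (et - tn) / ramp  # in ramp units; (0, 1] inside window
                in_win = (dt > 0) & (dt <= 1)
                frac[in_win] = np.maximum(frac[in_win], sev * (1 - dt[in_win]))
        if frac.any():
            for p, target in profile.items():
                if p == "agitation":
                    hit = sev_rng.random(k) < mult * frac * target
                    cons[hit] = "agitated"
                elif p == "o2_flow":
                    o2 = np.maximum(o2, np.round(mult * frac * target))
                elif p == "pain":
                    pain = np.maximum(pain, np.round(mult * frac * target))
                else:
                    vals[p] = vals[p] + mult * frac * (target - vals[p])

        resp = np.clip(np.round(vals["resp_rate"]), 4, 60)
        spo2 = np.clip(np.round(vals["spo2"]), 50, 100)
        temp = np.clip(np.round(vals["temp"], 1), 30.0, 43.0)
        sbp = np.clip(np.round(vals["sbp"]), 40, 260)
        hr = np.clip(np.round(vals["hr"]), 20, 220)
        pain = np.clip(pain, 0, 10)
        site = prng.choice(["tympanic", "axilla", "temporal", "forehead"],
                          size=k, p=[0.70, 0.10, 0.10, 0.10])

        # MCAR missingness; pain elevated in one center
        pm = (spec.pain_missing_elevated if r.center == spec.pain_missing_center
              else _MISSINGNESS["pain"])
        arrs = {"resp_rate": resp, "spo2": spo2, "o2_flow": o2, "temp": temp,
                "sbp": sbp, "hr": hr, "pain": pain}
        miss = {p: prng.random(k) < (_MISSINGNESS[p] if p != "pain" else pm)
                for p in arrs}
        cons_miss = prng.random(k) < _MISSINGNESS["consciousness"]
        for j in range(k):
            row = {"patient_id": r.patient_id, "timestamp": times[j]}
            for p, a in arrs.items():
                row[p] = np.nan if miss[p][j] else float(a[j])
            row["temp_site"] = None if miss["temp"][j] else site[j]
            row["consciousness"] = None if cons_miss[j] else cons[j]
            obs_rows.append(row)

    obs = pd.DataFrame(obs_rows)[OBS_COLUMNS]
    return patients, obs, events


# ---------------------------------------------------------------------------
# hand-constructed worked fixture

def _zero_band_row(pid, ts, **over):
    row = dict(patient_id=pid, timestamp=ts, resp_rate=16.0, spo2=97.0,
               o2_flow=0.0, temp=36.8, temp_site="tympanic", sbp=130.0,
               hr=70.0, consciousness="alert", pain=0.0)
    row.update(over)
    return row


def generate_worked_fixture() -> tuple[pd.DataFrame, pd.DataFrame,
                                       pd.DataFrame, pd.DataFrame]:
    """Tiny deterministic 5-patient dataset exercising every labeling and
    imputation rule, with hand-enumerated expected labels.

    Returns (patients, observations, events, expected) where ``expected``
    has one row per observation: obs index, hand-derived label, anchoring
    event id and episode index.

    * F1: two early Type 4 events (10 h, 40 h) -> episode 2 starts at 112 h.
    * F2: Type 4 at 50 h absorbed by a Type 2 event at 58 h (single merged
      life-threatening event).
    * F3: Type 4 at 50 h and Type 1 at 70 h kept distinct (> 12 h apart);
      the later event window overrides post-intervention neutralization.
    * F4: no events, complete vitals in both scores' 0-bands.
    * F5: no events; missing respiration exercising every imputation rule.
    """
    t0 = pd.Timestamp("2022-09-01 00:00")
    H = pd.Timedelta(hours=1)

    patients = pd.DataFrame({
        "patient_id": ["F1", "F2", "F3", "F4", "F5"],
        "admission": [t0] * 5,
        "ward_admission": [t0 + 6 * H] * 5,
        "discharge": [t0 + 300 * H, t0 + 200 * H, t0 + 250 * H,
                      t0 + 96 * H, t0 + 120 * H],
        "age": [84, 88, 79, 91, 85],
        "sex": ["F", "M", "F", "F", "M"],
        "cfs": [6, 7, 5, 6, 8],
        "dnr": [0, 2, 1, 0, 2],
        "delirium_flag": [0, 0, 1, 0, 0],
        "center": ["A", "A", "B", "B", "C"],
    })

    events = pd.DataFrame({
        "patient_id": ["F1", "F1", "F2", "F2", "F3", "F3"],
        "timestamp": [t0 + 10 * H, t0 + 40 * H, t0 + 50 * H, t0 + 58 * H,
                      t0 + 50 * H, t0 + 70 * H],
        "event_type": [4, 4, 4, 2, 4, 1],
        "detail": ["iv fluids", "iv antibiotics", "iv diuretics",
                   "ICU transfer", "transfusion", "unexpected death"],
        "event_id": ["EV1", "EV2", "EV3", "EV4", "EV5", "EV6"],
    })

    rows, exp = [], []

    def add(pid, hours, label, anchor, episode, **over):
        rows.append(_zero_band_row(pid, t0 + hours * H, **over))
        exp.append((pid, hours, label, anchor, episode))

    add("F1", 2, "event", "EV1", 1)
    add("F1", 9, "event", "EV1", 1)
    add("F1", 12, "neutralized", "EV1", 1)
    add("F1", 30, "event", "EV2", 1)
    add("F1", 50, "neutralized", "EV2", 1)
    add("F1", 120, "non_event", None, 2)
    add("F1", 299, "non_event", None, 2)

    add("F2", 20, "non_event", None, 1)
    add("F2", 45, "neutralized", "EV4", 1)   # 24-12 h pre-window of merged event
    add("F2", 47, "event", "EV4", 1, hr=110.0, pain=7.0)
    add("F2", 100, "neutralized", "EV4", 1)

    add("F3", 10, "non_event", None, 1)
    add("F3", 40, "event", "EV5", 1, resp_rate=26.0, temp=37.8)
    add("F3", 52, "neutralized", "EV5", 1)
    add("F3", 60, "event", "EV6", 1, spo2=85.0, consciousness="agitated")
    add("F3", 130, "neutralized", "EV6", 2)

    for h in (1, 30):
        add("F4", h, "non_event", None, 1)
    # SpO2 95 sits in the frailty-adapted 0-band (91-100) but scores 1 on
    # the standard 94-95 band: GEWS total stays 0 while NEWS totals 1
    add("F4", 60, "non_event", None, 1, spo2=95.0)

    add("F5", 0, "non_event", None, 1, resp_rate=np.nan, pain=np.nan)
    add("F5", 6, "non_event", None, 1, resp_rate=25.0, pain=np.nan)
    add("F5", 12, "non_event", None, 1, resp_rate=np.nan, pain=np.nan)
    add("F5", 28, "non_event", None, 1, resp_rate=np.nan, pain=np.nan)
    add("F5", 34, "non_event", None, 1, resp_rate=np.nan, pain=np.nan)

    obs = pd.DataFrame(rows)[OBS_COLUMNS]
    expected = pd.DataFrame(
        exp, columns=["patient_id", "hours", "label", "anchor_event_id",
                      "episode_index"])
    return patients, obs, events, expected
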