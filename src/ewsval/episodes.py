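"""Episode construction and event/non-event labeling of observation sets.

A hospitalization is split into at most two analysis episodes.  Episode 1
starts at admission (ED arrival when recorded).  If one or more Type 4
events (urgent unexpected interventions) occur early in the stay, episode 1
ends 72 h after the last such event and episode 2 runs from there to
discharge — re-admitting the patient's observations to the analysis after
the post-intervention washout.  Because "the last Type 4 event of the first
episode" refers to the episode being built, the end is computed as a fixed
point: episode 1 keeps extending while further Type 4 events fall before
its current end.

Event types: 1 unexpected death, 2 unanticipated intensive-care transfer,
3 unexpected transition to palliative care, 4 urgent unexpected
medical/surgical intervention.  A Type 1-3 event within 12 h after a Type 4
absorbs it (single Type 1-3 event at the later timestamp); only one
Type 1-3 event per patient is retained.

Observation labels (half-open windows, every instant gets exactly one):

* ``event``        - within [t_e - 12 h, t_e) of a retained event t_e;
                     wins over any neutralization from a *past* event.
* ``neutralized``  - in [t_e - 24 h, t_e - 12 h); or at/after a Type 1-3
                     event; or at/after a Type 4 event until the end of its
                     episode; or outside every episode.  Excluded from the
                     analysis downstream (treatment bias).
* ``non_event``    - everything else (more than 24 h before any event, or
                     no upcoming event).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ClinicalEvent",
    "Episode",
    "WindowConfig",
    "ObservationLabel",
    "merge_events",
    "build_episodes",
    "classify_observation",
    "label_frame",
    "analysis_patient_days",
    "events_from_frame",
]

log = logging.getLogger(__name__)

TYPE13 = (1, 2, 3)


@dataclass(frozen=True)
class ClinicalEvent:
    patient_id: str
    timestamp: pd.Timestamp
    event_type: int  # 1-4
    detail: str = ""
    event_id: str | None = None

    def __post_init__(self) -> None:
        if self.event_type not in (1, 2, 3, 4):
            raise ValueError(f"event_type must be 1-4, got {self.event_type}")


@dataclass(frozen=True)
class Episode:
    patient_id: str
    index: int  # 1 or 2
    start: pd.Timestamp
    end: pd.Timestamp

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError("episode start must precede end")


@dataclass(frozen=True)
class WindowConfig:
    """Time windows (hours) for labeling and episode construction."""

    event_window: float = 12.0    # pre-event horizon labeled as event
    neutral_window: float = 24.0  # pre-event horizon neutralized beyond event_window
    episode_gap: float = 72.0     # washout after the last early Type 4 event
    merge_window: float = 12.0    # Type 4 absorbed by a Type 1-3 within this

    def __post_init__(self) -> None:
        if not (0 < self.event_window < self.neutral_window):
            raise ValueError("need 0 < event_window < neutral_window")
        if self.episode_gap <= 0 or self.merge_window <= 0:
            raise ValueError("episode_gap and merge_window must be positive")

    @property
    def event_td(self) -> pd.Timedelta:
        return pd.Timedelta(hours=self.event_window)

    @property
    def neutral_td(self) -> pd.Timedelta:
        return pd.Timedelta(hours=self.neutral_window)

    @property
    def gap_td(self) -> pd.Timedelta:
        return pd.Timedelta(hours=self.episode_gap)

    @property
    def merge_td(self) -> pd.Timedelta:
        return pd.Timedelta(hours=self.merge_window)


@dataclass(frozen=True)
class ObservationLabel:
    label: str  # event | non_event | neutralized
    anchor: ClinicalEvent | None = None


def _check_sorted(events: Sequence[ClinicalEvent]) -> None:
    for a, b in zip(events, events[1:]):
        if b.timestamp < a.timestamp:
            raise ValueError("events must be sorted by timestamp")


def merge_events(
    events: Sequence[ClinicalEvent], cfg: WindowConfig = WindowConfig()
) -> list[ClinicalEvent]:
    """Merge and de-duplicate one patient's sorted event list.

    Simultaneous events keep the most severe (Type 1-3 over Type 4, lowest
    type number among 1-3).  A Type 1-3 event absorbs any Type 4 within the
    preceding 12 h (single Type 1-3 event at the Type 1-3 timestamp).  Only
    the first Type 1-3 event is retained; later events are dropped with a
    warning.
    """
    events = list(events)
    _check_sorted(events)
    # de-duplicate identical timestamps, keeping the most severe
    by_ts: dict[pd.Timestamp, ClinicalEvent] = {}
    for e in events:
        cur = by_ts.get(e.timestamp)
        if cur is None:
            by_ts[e.timestamp] = e
        else:
            sev = (0 if e.event_type in TYPE13 else 1, e.event_type)
            cur_sev = (0 if cur.event_type in TYPE13 else 1, cur.event_type)
            if sev < cur_sev:
                by_ts[e.timestamp] = e
            log.warning("%s: simultaneous events at %s de-duplicated",
                        e.patient_id, e.timestamp)
    events = [by_ts[t] for t in sorted(by_ts)]

    first13 = next((e for e in events if e.event_type in TYPE13), None)
    if first13 is None:
        return events
    kept: list[ClinicalEvent] = []
    for e in events:
        if e.timestamp > first13.timestamp:
            log.warning("%s: event at %s after first Type 1-3 event dropped",
                        e.patient_id, e.timestamp)
            continue
        if e is first13:
            kept.append(e)
        elif (e.event_type == 4
              and first13.timestamp - e.timestamp <= cfg.merge_td):
            # absorbed into the single Type 1-3 event
            continue
        else:
            kept.append(e)
    return kept


def build_episodes(
    admission: pd.Timestamp,
    discharge: pd.Timestamp,
    events: Sequence[ClinicalEvent],
    cfg: WindowConfig = WindowConfig(),
    patient_id: str = "",
) -> list[Episode]:
    """Split [admission, discharge] into one or two analysis episodes."""
    if not admission < discharge:
        raise ValueError("admission must precede discharge")
    for e in events:
        if not (admission <= e.timestamp <= discharge):
            raise ValueError(
                f"event at {e.timestamp} outside hospitalization "
                f"[{admission}, {discharge}]"
            )
    t4 = sorted(e.timestamp for e in events if e.event_type == 4)
    end = admission + cfg.gap_td
    t_last = None
    # fixed point: extend episode 1 while Type 4 events fall before its end
    while True:
        in_window = [t for t in t4 if t < end and (t_last is None or t > t_last)]
        if not in_window:
            break
        t_last = max(in_window)
        end = t_last + cfg.gap_td
    if t_last is None:
        return [Episode(patient_id, 1, admission, discharge)]
    if end >= discharge:
        return [Episode(patient_id, 1, admission, discharge)]
    return [
        Episode(patient_id, 1, admission, end),
        Episode(patient_id, 2, end, discharge),
    ]


def _episode_end_for(ts: pd.Timestamp, episodes: Sequence[Episode]) -> pd.Timestamp:
    for ep in episodes:
        if ep.start <= ts < ep.end or (ep is episodes[-1] and ts == ep.end):
            return ep.end
    # ts at an episode boundary belongs to the later episode by construction
    return episodes[-1].end


def classify_observation(
    obs_time: pd.Timestamp,
    events: Sequence[ClinicalEvent],
    episodes: Sequence[Episode],
    cfg: WindowConfig = WindowConfig(),
) -> ObservationLabel:
    """Label one observation time against merged events and episodes."""
    adm, dis = episodes[0].start, episodes[-1].end
    if not (adm <= obs_time <= dis):
        raise ValueError(f"observation at {obs_time} outside hospitalization")
    # (1) event window of any retained event, nearest upcoming first
    for e in events:
        if e.timestamp - cfg.event_td <= obs_time < e.timestamp:
            return ObservationLabel("event", e)
    # (2) neutralization
    for e in events:
        if e.event_type in TYPE13 and obs_time >= e.timestamp:
            return ObservationLabel("neutralized", e)
    for e in reversed(events):  # most recent past intervention anchors
        if e.event_type == 4 and obs_time >= e.timestamp:
            if obs_time < _episode_end_for(e.timestamp, episodes):
                return ObservationLabel("neutralized", e)
    if not any(ep.start <= obs_time <= ep.end for ep in episodes):
        return ObservationLabel("neutralized", None)
    for e in events:
        if e.timestamp - cfg.neutral_td <= obs_time < e.timestamp - cfg.event_td:
            return ObservationLabel("neutralized", e)
    # (3) otherwise
    return ObservationLabel("non_event", None)


def events_from_frame(events_df: pd.DataFrame) -> dict[str, list[ClinicalEvent]]:
    """Events CSV frame -> per-patient sorted ClinicalEvent lists."""
    out: dict[str, list[ClinicalEvent]] = {}
    if len(events_df) == 0:
        return out
    df = events_df.copy()
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    if "event_id" not in df.columns:
        df["event_id"] = [f"E{i}" for i in range(len(df))]
    if "detail" not in df.columns:
        df["detail"] = ""
    df = df.sort_values(["patient_id", "timestamp"], kind="stable")
    for pid, grp in df.groupby("patient_id", sort=False):
        out[str(pid)] = [
            ClinicalEvent(str(pid), r.timestamp, int(r.event_type),
                          str(r.detail), str(r.event_id))
            for r in grp.itertuples()
        ]
    return out


def label_frame(
    obs_df: pd.DataFrame,
    events_df: pd.DataFrame,
    patients_df: pd.DataFrame,
    cfg: WindowConfig = WindowConfig(),
) -> pd.DataFrame:
    """Label every observation set; returns obs_df plus
    ``episode_index``, ``label``, ``anchor_event_id`` columns.

    Admission for episode purposes is the ED arrival time (``admission``
    column); ward-only admissions use the same column.
    """
    obs = obs_df.copy()
    obs["timestamp"] = pd.to_datetime(obs["timestamp"])
    patients = patients_df.set_index(patients_df["patient_id"].astype(str))
    per_patient_events = events_from_frame(events_df)

    labels = np.empty(len(obs), dtype=object)
    anchors = np.empty(len(obs), dtype=object)
    ep_idx = np.zeros(len(obs), dtype=int)

    for pid, grp in obs.groupby(obs["patient_id"].astype(str), sort=False):
        try:
            prow = patients.loc[pid]
        except KeyError:
            raise ValueError(f"observations for unknown patient {pid}") from None
        adm = pd.Timestamp(prow["admission"])
        dis = pd.Timestamp(prow["discharge"])
        raw = per_patient_events.get(pid, [])
        merged = merge_events(raw, cfg)
        episodes = build_episodes(adm, dis, merged, cfg, patient_id=pid)
        pos = obs.index.get_indexer(grp.index)
        for i, t in zip(pos, grp["timestamp"]):
            lab = classify_observation(t, merged, episodes, cfg)
            labels[i] = lab.label
            anchors[i] = lab.anchor.event_id if lab.anchor is not None else None
            ep_idx[i] = 2 if (len(episodes) == 2 and t >= episodes[1].start) else 1
    obs["episode_index"] = ep_idx
    obs["label"] = labels
    obs["anchor_event_id"] = anchors
    return obs


# ---------------------------------------------------------------------------
# analyzed patient-time (denominator for rate-of-alerts / AOER)

def _union(intervals: list[tuple]) -> list[tuple]:
    ivs = sorted((s, e) for s, e in intervals if s < e)
    out: list[tuple] = []
    for s, e in ivs:
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def _subtract(a: list[tuple], b: list[tuple]) -> list[tuple]:
    out = []
    for s, e in a:
        pieces = [(s, e)]
        for bs, be in b:
            nxt = []
            for ps, pe in pieces:
                if be <= ps or bs >= pe:
                    nxt.append((ps, pe))
                else:
                    if ps < bs:
                        nxt.append((ps, bs))
                    if be < pe:
                        nxt.append((be, pe))
            pieces = nxt
        out.extend(pieces)
    return out


def _length_days(intervals: list[tuple]) -> float:
    return float(sum((e - s) / pd.Timedelta(days=1) for s, e in intervals))


def analysis_patient_days(
    admission: pd.Timestamp,
    discharge: pd.Timestamp,
    events: Sequence[ClinicalEvent],
    episodes: Sequence[Episode],
    cfg: WindowConfig = WindowConfig(),
    event_subset: Iterable[int] = (1, 2, 3, 4),
    denominator: str = "analyzed",
) -> float:
    """Patient-days entering the burden denominators for one patient.

    ``denominator="analyzed"`` (default) counts only time whose observations
    would enter the analysis, i.e. the stay minus neutralized time (with
    event windows overriding neutralization, as in labeling) and, when
    Type 4 outcomes are filtered out, minus Type-4 event windows.
    ``denominator="full_stay"`` returns the whole length of stay.
    """
    stay = [(admission, discharge)]
    if denominator == "full_stay":
        return _length_days(stay)
    if denominator != "analyzed":
        raise ValueError("denominator must be 'analyzed' or 'full_stay'")

    windows = [(e.timestamp - cfg.event_td, e.timestamp) for e in events]
    neutral: list[tuple] = []
    for e in events:
        neutral.append((e.timestamp - cfg.neutral_td, e.timestamp - cfg.event_td))
        if e.event_type in TYPE13:
            neutral.append((e.timestamp, discharge))
        else:
            neutral.append((e.timestamp, _episode_end_for(e.timestamp, episodes)))
    covered = _union([(ep.start, ep.end) for ep in episodes])
    neutral.extend(_subtract(stay, covered))

    excluded = _subtract(_union(neutral), _union(windows))
    subset = set(event_subset)
    if 4 not in subset:
        t4_windows = [(e.timestamp - cfg.event_td, e.timestamp)
                      for e in events if e.event_type == 4]
        keep_windows = [(e.timestamp - cfg.event_td, e.timestamp)
                        for e in events if e.event_type in subset]
        excluded = _union(excluded + _subtract(_union(t4_windows),
                                               _union(keep_windows)))
    excluded = [(max(s, admission), min(e, discharge)) for s, e in excluded]
    return _length_days(stay) - _length_days(_union(excluded))
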