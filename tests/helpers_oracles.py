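"""Independent brute-force oracles used by the test suite.

These deliberately re-derive expected results from first principles —
exhaustive pairwise enumeration for the AUROC, explicit interval lists for
observation labeling — and share no code paths with the package
implementations they check.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

H = pd.Timedelta(hours=1)


def brute_force_auroc(scores, labels) -> float:
    """Concordance probability by enumerating every event/non-event pair."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    if y.dtype.kind in "USO":
        y = y == "event"
    pos = scores[y.astype(bool)]
    neg = scores[~y.astype(bool)]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))


def oracle_merge(raw, merge_h=12.0):
    """raw: list of (timestamp, type) sorted. Returns merged list of
    (timestamp, type) applying de-duplication, Type-4 absorption and the
    one-Type-1-3-per-patient rule."""
    sev = {1: 0, 2: 1, 3: 2, 4: 3}
    by_ts: dict = {}
    for ts, ty in raw:
        if ts not in by_ts or sev[ty] < sev[by_ts[ts]]:
            by_ts[ts] = ty
    events = sorted(by_ts.items())
    t13s = [ts for ts, ty in events if ty in (1, 2, 3)]
    if not t13s:
        return events
    first13 = t13s[0]
    out = []
    for ts, ty in events:
        if ts > first13:
            continue
        if ty == 4 and (first13 - ts) <= merge_h * H:
            continue
        out.append((ts, ty))
    return out


def oracle_episodes(adm, dis, merged, gap_h=72.0):
    """Episode interval list [(start, end), ...] by fixed-point extension."""
    t4 = sorted(ts for ts, ty in merged if ty == 4)
    end = adm + gap_h * H
    last = None
    while True:
        cand = [t for t in t4 if t < end and (last is None or t > last)]
        if not cand:
            break
        last = max(cand)
        end = last + gap_h * H
    if last is None or end >= dis:
        return [(adm, dis)]
    return [(adm, end), (end, dis)]


def oracle_label(t, merged, episodes, event_h=12.0, neutral_h=24.0):
    """Explicit interval-membership labeling with precedence
    event > neutralized > non_event."""
    event_ivs = [(ts - event_h * H, ts) for ts, _ in merged]
    for lo, hi in event_ivs:
        if lo <= t < hi:
            return "event"
    neutral_ivs = []
    for ts, ty in merged:
        neutral_ivs.append((ts - neutral_h * H, ts - event_h * H))
        if ty in (1, 2, 3):
            neutral_ivs.append((ts, episodes[-1][1] + H))  # to end of stay
        else:
            ep_end = next(e for s, e in episodes if s <= ts < e or e == episodes[-1][1])
            neutral_ivs.append((ts, ep_end))
    in_episode = any(s <= t <= e for s, e in episodes)
    if not in_episode:
        return "neutralized"
    for lo, hi in neutral_ivs:
        if lo <= t < hi:
            return "neutralized"
    return "non_event"


def oracle_labels_for_patient(adm, dis, raw_events, obs_times):
    merged = oracle_merge(sorted(raw_events))
    episodes = oracle_episodes(adm, dis, merged)
    return [oracle_label(t, merged, episodes) for t in obs_times]
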