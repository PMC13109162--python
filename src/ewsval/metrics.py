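"""Discrimination, clinical-burden and resampling inference for EWS validation.

The unit of analysis is a labeled observation set (event vs non-event;
neutralized sets were excluded upstream).  Threshold metrics come from the
standard 2x2 confusion table; the clinical-burden measures are

* NNE  - number-needed-to-evaluate, alerts per true-positive alert = 1/PPV,
* ROA  - rate-of-alerts, alerts per 100 patient-days,
* AOER - alerted-outcome-event-rate, true-positive alerts per 100
  patient-days,

which satisfy the identities AOER = PPV x ROA and NNE = ROA / AOER.

Discrimination uses the rank (Mann-Whitney) formulation of the AUROC with
half credit for ties, and non-interpolated average precision for the area
under the precision-recall curve.  Uncertainty is quantified with a
patient-clustered bootstrap percentile interval and paired Monte Carlo
permutation tests whose exchange unit is the patient cluster: the (A, B)
score assignment is swapped for all of a patient's observation sets at
once.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .scoring import TriggerRule, trigger_alerts

__all__ = [
    "ConfusionCounts",
    "ResamplingConfig",
    "confusion_counts",
    "threshold_metrics",
    "burden_metrics",
    "ward_rate",
    "alarms_per_additional_event",
    "roc_curve",
    "auroc",
    "pr_curve",
    "pr_auc",
    "clustered_bootstrap_ci",
    "paired_permutation_test",
    "expected_event_count",
    "check_burden_identities",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def alerts(self) -> int:
        return self.tp + self.fp

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class ResamplingConfig:
    """Bootstrap / permutation settings; the patient is the cluster unit."""

    bootstrap_samples: int = 10_000
    permutations: int = 9_999
    significance: float = 0.00051  # Bonferroni-corrected level
    seed: int = 0

    def __post_init__(self) -> None:
        if self.bootstrap_samples < 1 or self.permutations < 1:
            raise ValueError("resample counts must be >= 1")


def confusion_counts(
    labels: Sequence[str] | np.ndarray,
    total: np.ndarray,
    max_single: np.ndarray,
    rule: TriggerRule,
) -> ConfusionCounts:
    """2x2 counts of alert vs event over observation sets."""
    labels = np.asarray(labels)
    if labels.size == 0:
        raise ValueError("empty input")
    bad = set(np.unique(labels)) - {"event", "non_event"}
    if bad:
        raise ValueError(f"unexpected labels {bad}; neutralized must be excluded")
    event = labels == "event"
    alert = trigger_alerts(total, max_single, rule)
    return ConfusionCounts(
        tp=int((alert & event).sum()),
        fp=int((alert & ~event).sum()),
        tn=int((~alert & ~event).sum()),
        fn=int((~alert & event).sum()),
    )


def _safe_div(a: float, b: float) -> float:
    return a / b if b > 0 else float("nan")


def threshold_metrics(c: ConfusionCounts) -> dict[str, float]:
    """Accuracy, sensitivity, specificity, PPV, NPV, NNE (NaN if undefined)."""
    ppv = _safe_div(c.tp, c.tp + c.fp)
    return {
        "alerts": float(c.alerts),
        "accuracy": _safe_div(c.tp + c.tn, c.n),
        "sensitivity": _safe_div(c.tp, c.tp + c.fn),
        "specificity": _safe_div(c.tn, c.tn + c.fp),
        "ppv": ppv,
        "npv": _safe_div(c.tn, c.tn + c.fn),
        "nne": _safe_div(c.tp + c.fp, c.tp),
    }


def burden_metrics(c: ConfusionCounts, patient_days: float) -> dict[str, float]:
    """ROA and AOER per 100 patient-days."""
    if not patient_days > 0:
        raise ValueError("patient_days must be positive")
    return {
        "roa": 100.0 * c.alerts / patient_days,
        "aoer": 100.0 * c.tp / patient_days,
    }


def ward_rate(per_100_patient_days: float, beds: int = 24,
              hours: float = 24.0) -> float:
    """Convert a per-100-patient-day rate to events per ``hours`` on a
    fully occupied ``beds``-bed ward (beds x hours/24 patient-days)."""
    return per_100_patient_days * beds * (hours / 24.0) / 100.0


def alarms_per_additional_event(
    roa_increment: float, aoer_increment: float
) -> tuple[int, int]:
    """Alarm cost of a threshold change, from its ROA and AOER increments.

    Both increments must be on the same time basis (e.g. per 24 h on a ward).
    One additional detected event takes 1/aoer_increment time units, during
    which roa_increment/aoer_increment additional alarms fire; all but the
    one true alert are false positives.  Returns (alarms, false_positives),
    rounded to whole alarms.
    """
    if aoer_increment <= 0:
        raise ValueError("aoer_increment must be positive")
    alarms = roa_increment / aoer_increment
    return int(round(alarms)), int(round(alarms)) - 1


def check_burden_identities(m: dict[str, float], tol: float = 1e-12) -> None:
    """Assert NNE x PPV = 1, AOER = PPV x ROA, NNE = ROA/AOER on a report row."""
    if not math.isnan(m["nne"]):
        assert abs(m["nne"] * m["ppv"] - 1.0) < tol
    if "roa" in m and m.get("aoer", 0) > 0 and not math.isnan(m["ppv"]):
        assert abs(m["aoer"] - m["ppv"] * m["roa"]) < tol * max(1.0, m["roa"])
        if not math.isnan(m["nne"]):
            assert abs(m["nne"] - m["roa"] / m["aoer"]) < tol * max(1.0, m["nne"])


# ---------------------------------------------------------------------------
# discrimination

def _check_two_class(y: np.ndarray) -> np.ndarray:
    y = np.asarray(y)
    if y.dtype.kind in "USO":
        y = (y == "event")
    y = y.astype(bool)
    if y.all() or not y.any():
        raise ValueError("both classes must be present")
    return y


def roc_curve(scores: np.ndarray, labels) -> pd.DataFrame:
    """ROC points (fpr, tpr, threshold) sweeping all observed score values."""
    y = _check_two_class(labels)
    s = np.asarray(scores, dtype=float)
    thresholds = np.concatenate(([np.inf], np.unique(s)[::-1]))
    pos, neg = y.sum(), (~y).sum()
    rows = []
    for t in thresholds:
        alert = s >= t
        rows.append((float((alert & ~y).sum() / neg),
                     float((alert & y).sum() / pos), t))
    return pd.DataFrame(rows, columns=["fpr", "tpr", "threshold"])


def auroc(scores: np.ndarray, labels) -> float:
    """AUROC by the rank formulation (ties get half credit).

    Equals the probability that a random event observation outscores a
    random non-event observation, and the trapezoidal area under the ROC
    curve swept over all observed thresholds.
    """
    y = _check_two_class(labels)
    s = np.asarray(scores, dtype=float)
    r = rankdata(s)
    n_pos = int(y.sum())
    n_neg = y.size - n_pos
    u = r[y].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def pr_curve(scores: np.ndarray, labels) -> pd.DataFrame:
    """Precision-recall points over descending observed score thresholds."""
    y = np.asarray(labels)
    if y.dtype.kind in "USO":
        y = (y == "event")
    y = y.astype(bool)
    if not y.any():
        raise ValueError("at least one event required")
    s = np.asarray(scores, dtype=float)
    thresholds = np.unique(s)[::-1]
    pos = y.sum()
    rows = []
    for t in thresholds:
        alert = s >= t
        tp = int((alert & y).sum())
        rows.append((tp / alert.sum(), tp / pos, t))
    return pd.DataFrame(rows, columns=["precision", "recall", "threshold"])


def pr_auc(scores: np.ndarray, labels) -> float:
    """Area under the PR curve as non-interpolated average precision:
    AP = sum_k (R_k - R_{k-1}) P_k over descending score thresholds."""
    pts = pr_curve(scores, labels)
    recall = pts["recall"].to_numpy()
    precision = pts["precision"].to_numpy()
    prev = np.concatenate(([0.0], recall[:-1]))
    return float(np.sum((recall - prev) * precision))


# ---------------------------------------------------------------------------
# resampling inference

def clustered_bootstrap_ci(
    stat_fn: Callable[[np.ndarray], float],
    clusters: np.ndarray,
    cfg: ResamplingConfig | None = None,
    rng: np.random.Generator | None = None,
    level: float = 0.95,
) -> tuple[float, float]:
    """Percentile CI resampling whole patient clusters with replacement.

    ``stat_fn`` receives an integer index array selecting observation rows
    (a patient's observation sets always travel together) and returns the
    statistic.  NaN statistics (undefined metrics in a resample) are
    dropped; if more than half the resamples are undefined a ValueError is
    raised.
    """
    cfg = cfg or ResamplingConfig()
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    clusters = np.asarray(clusters)
    uniq, inv = np.unique(clusters, return_inverse=True)
    if uniq.size < 2:
        raise ValueError("need at least 2 patient clusters")
    members = [np.flatnonzero(inv == k) for k in range(uniq.size)]
    stats = np.empty(cfg.bootstrap_samples)
    for b in range(cfg.bootstrap_samples):
        pick = rng.integers(0, uniq.size, size=uniq.size)
        idx = np.concatenate([members[k] for k in pick])
        try:
            stats[b] = stat_fn(idx)
        except ValueError:  # metric undefined in this resample
            stats[b] = np.nan
    ok = ~np.isnan(stats)
    if ok.sum() < cfg.bootstrap_samples / 2:
        raise ValueError("statistic undefined in more than half the resamples")
    alpha = (1.0 - level) / 2.0
    lo, hi = np.percentile(stats[ok], [100 * alpha, 100 * (1 - alpha)])
    return float(lo), float(hi)


def paired_permutation_test(
    stat_a: Callable[[np.ndarray], float],
    stat_b: Callable[[np.ndarray], float],
    a: np.ndarray,
    b: np.ndarray,
    clusters: np.ndarray,
    cfg: ResamplingConfig | None = None,
    rng: np.random.Generator | None = None,
    unit: str = "patient",
) -> tuple[float, float]:
    """Two-sided paired Monte Carlo permutation test.

    ``a`` and ``b`` are score vectors aligned on identical observation sets
    (e.g. GEWS and NEWS totals).  The observed statistic is
    ``stat_a(a) - stat_b(b)``; the null swaps the (a, b) assignment per
    patient cluster (or per observation with ``unit="observation"``) and
    p = (1 + #{|d*| >= |d|}) / (permutations + 1).  Returns (delta, p).
    """
    cfg = cfg or ResamplingConfig()
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    clusters = np.asarray(clusters)
    if a.shape != b.shape or a.shape[0] != clusters.shape[0]:
        raise ValueError("a, b and clusters must be aligned on observations")
    delta = stat_a(a) - stat_b(b)
    uniq, inv = np.unique(clusters, return_inverse=True)
    count = 0
    for _ in range(cfg.permutations):
        if unit == "patient":
            flip = rng.random(uniq.size) < 0.5
            swap = flip[inv]
        elif unit == "observation":
            swap = rng.random(a.shape[0]) < 0.5
        else:
            raise ValueError("unit must be 'patient' or 'observation'")
        if a.ndim > 1:
            swap = swap[:, None]
        a_star = np.where(swap, b, a)
        b_star = np.where(swap, a, b)
        d = stat_a(a_star) - stat_b(b_star)
        if abs(d) >= abs(delta) - 1e-15:
            count += 1
    p = (1 + count) / (cfg.permutations + 1)
    return float(delta), float(p)


def expected_event_count(n_patients: float, mean_stay_days: float,
                         rate_per_patient_day: float) -> float:
    """Expected outcome events for a cohort: n x mean stay x daily rate."""
    return n_patients * mean_stay_days * rate_per_patient_day
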