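"""Scoring of vital-sign observation sets and alert-trigger rules.

The unit of analysis is a single *observation set*: one timestamped row of
raw vital parameters for one patient (respiration rate, SpO2, oxygen flow,
temperature + measurement site, systolic blood pressure, heart rate, AVPU
consciousness, pain).  Each parameter present in the selected
:class:`~ewsval.tables.BandTable` contributes one subscore 0-3; the total is
their sum and ``max_single`` their maximum.

Trigger rules combine a total-score threshold with an optional "S3" clause:
alert also when any single parameter scores 3.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .tables import BandTable, ValidationError

__all__ = [
    "PARAM_COLUMNS",
    "OBS_COLUMNS",
    "TEMP_SITES",
    "CONSCIOUSNESS_LEVELS",
    "ScoreResult",
    "TriggerRule",
    "DEFAULT_RULES",
    "adjust_temperature",
    "score_parameter",
    "score_observation",
    "score_frame",
    "evaluate_trigger",
    "trigger_alerts",
    "validate_observations",
]

log = logging.getLogger(__name__)

#: Raw vital-parameter columns, in table order.
PARAM_COLUMNS = [
    "resp_rate", "spo2", "o2_flow", "temp", "sbp", "hr", "consciousness", "pain",
]
#: Full observations-CSV schema.
OBS_COLUMNS = ["patient_id", "timestamp"] + PARAM_COLUMNS[:4] + [
    "temp_site"] + PARAM_COLUMNS[4:]

TEMP_SITES = frozenset({"axilla", "temporal", "tympanic", "forehead"})
CONSCIOUSNESS_LEVELS = frozenset(
    {"alert", "voice", "pain", "unresponsive", "agitated"}
)

#: Forehead thermometers under-read; the recorded value is corrected upward.
FOREHEAD_CORRECTION_C = 0.2


def adjust_temperature(raw_temp: float, site: str | None) -> float:
    """Site-correct a recorded temperature.

    Forehead measurements get +0.2 degC; axilla/temporal/tympanic are taken
    as recorded.  A missing site leaves the value unchanged (logged), an
    unknown site raises :class:`ValidationError`.
    """
    if site is None or (isinstance(site, float) and np.isnan(site)):
        log.warning("temperature with missing measurement site: no correction")
        return raw_temp
    if site not in TEMP_SITES:
        raise ValidationError(
            f"unknown temperature site {site!r}; expected one of {sorted(TEMP_SITES)}"
        )
    if site == "forehead":
        return round(raw_temp + FOREHEAD_CORRECTION_C, 10)
    return raw_temp


def score_parameter(value, bands) -> int:
    """Subscore of ``value`` under one parameter's bands (numeric or categorical)."""
    return bands.score(value)


@dataclass
class ScoreResult:
    """Per-parameter subscores for one observation set.

    ``provenance`` flags each subscore as measured / imputed_zero /
    carried_forward (the latter set by the imputation stage).
    """

    subscores: dict[str, int]
    provenance: dict[str, str] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return int(sum(self.subscores.values()))

    @property
    def max_single(self) -> int:
        return int(max(self.subscores.values()))


def score_observation(
    obs: Mapping, table: BandTable, missing: str = "zero", strict: bool = False
) -> ScoreResult:
    """Score one observation set against ``table``.

    Missing parameters yield subscore 0 flagged ``imputed_zero`` by default
    (``missing="zero"``); the pipeline instead scores with ``missing="nan"``
    at frame level and delegates to :mod:`ewsval.imputation`.
    """
    if missing not in ("zero", "error"):
        raise ValueError("missing must be 'zero' or 'error' for scalar scoring")
    subs: dict[str, int] = {}
    prov: dict[str, str] = {}
    for p in table.parameters:
        v = obs.get(p)
        if v is None or (isinstance(v, float) and np.isnan(v)):
            if missing == "error":
                raise ValidationError(f"missing parameter {p}")
            subs[p] = 0
            prov[p] = "imputed_zero"
            continue
        if p == "temp":
            v = adjust_temperature(float(v), obs.get("temp_site"))
        subs[p] = table.score_value(p, v, strict=strict)
        prov[p] = "measured"
    return ScoreResult(subscores=subs, provenance=prov)


def score_frame(
    df: pd.DataFrame, table: BandTable, strict_sites: bool = True
) -> pd.DataFrame:
    """Vectorised scoring of an observations frame.

    Returns a frame aligned with ``df`` holding one ``<param>_score`` column
    per table parameter (float; NaN where the raw value is missing).  Totals
    are *not* formed here: missing subscores are resolved by the imputation
    stage first.
    """
    out = pd.DataFrame(index=df.index)
    temp = df["temp"].astype(float).to_numpy(copy=True)
    site = df.get("temp_site")
    if site is not None:
        site = site.astype(object)
        known = site.isna() | site.isin(list(TEMP_SITES))
        if strict_sites and not known.all():
            bad = sorted(set(site[~known]))
            raise ValidationError(f"unknown temperature site(s) {bad}")
        temp = temp + np.where(site.to_numpy() == "forehead",
                               FOREHEAD_CORRECTION_C, 0.0)
        temp = np.round(temp, 10)
    for p, bands in table.numeric.items():
        vals = temp if p == "temp" else df[p].astype(float).to_numpy()
        out[f"{p}_score"] = bands.score_array(vals)
    for p, cmap in table.categorical.items():
        out[f"{p}_score"] = cmap.score_array(df[p])
    return out


@dataclass(frozen=True)
class TriggerRule:
    """Alert rule: total >= threshold, optionally OR any single subscore of 3."""

    name: str
    score: str  # which band table the rule applies to, e.g. "news"
    total_threshold: int
    s3: bool

    def __post_init__(self) -> None:
        if self.total_threshold < 1:
            raise ValueError("total_threshold must be >= 1")


#: The predefined escalation thresholds evaluated in the validation study.
DEFAULT_RULES = [
    TriggerRule("NEWS>=5+S3", "news", 5, True),
    TriggerRule("NEWS>=5", "news", 5, False),
    TriggerRule("NEWS>=7", "news", 7, False),
    TriggerRule("GEWS>=4+S3", "gews", 4, True),
    TriggerRule("GEWS>=5+S3", "gews", 5, True),
    TriggerRule("GEWS>=5", "gews", 5, False),
    TriggerRule("GEWS>=8", "gews", 8, False),
]


def evaluate_trigger(result: ScoreResult | tuple, rule: TriggerRule) -> bool:
    """Whether one score result raises an alert under ``rule``."""
    if isinstance(result, ScoreResult):
        total, max_single = result.total, result.max_single
    else:
        total, max_single = result
    return bool(total >= rule.total_threshold or (rule.s3 and max_single == 3))


def trigger_alerts(
    total: np.ndarray | pd.Series, max_single: np.ndarray | pd.Series,
    rule: TriggerRule,
) -> np.ndarray:
    """Vectorised :func:`evaluate_trigger`."""
    total = np.asarray(total)
    alerts = total >= rule.total_threshold
    if rule.s3:
        alerts = alerts | (np.asarray(max_single) == 3)
    return alerts


def validate_observations(df: pd.DataFrame) -> None:
    """Schema checks for an observations frame; raises ValidationError."""
    missing_cols = [c for c in OBS_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValidationError(f"observations missing columns {missing_cols}")
    ts = pd.to_datetime(df["timestamp"], errors="coerce")
    if ts.isna().any():
        raise ValidationError("unparseable timestamps in observations")
    checks = {
        "spo2": (0, 100),
        "pain": (0, 10),
        "resp_rate": (0, np.inf),
        "hr": (0, np.inf),
        "o2_flow": (0, np.inf),
    }
    for col, (lo, hi) in checks.items():
        v = df[col].astype(float)
        bad = v.notna() & ((v < lo) | (v > hi))
        if bad.any():
            raise ValidationError(f"{col} outside [{lo}, {hi}]: rows {list(df.index[bad])[:5]}")
    v = df["sbp"].astype(float)
    if (v.notna() & (v <= 0)).any():
        raise ValidationError("non-positive systolic blood pressure")
    cons = df["consciousness"]
    bad = cons.notna() & ~cons.isin(list(CONSCIOUSNESS_LEVELS))
    if bad.any():
        raise ValidationError(
            f"unknown consciousness levels {sorted(set(cons[bad]))}"
        )
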