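"""Two-stage imputation of missing per-parameter subscores.

Imputation operates on subscores, not raw vital values: 0 is a valid score
(the normal band) but not a valid vital value.  For each missing subscore,
stage 1 imputes 0 when the observation set is (a) the patient's first,
(b) the parameter has never been measured for the patient, (c) recorded
more than 12 h after the previous observation set, or (d) neutralized.
Stage 2 fills the rest by last observation carried forward.

LOCF carries the previous observation set's *post-imputation* subscore, so
a stage-1 zero becomes the value carried into subsequent observations: a
carried value therefore never reaches back across a > 12 h gap, and every
imputed subscore is either 0 or some earlier measured subscore of the same
parameter.  Neutralized observation sets are imputed too (they are excluded
from the analysis later, but LOCF chains passing through them stay
well-defined).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["ImputationRuleSet", "impute_scores", "finalize_totals"]


@dataclass(frozen=True)
class ImputationRuleSet:
    gap_hours: float = 12.0
    locf_enabled: bool = True
    #: "observation_set": the 12 h gap is measured to the previous observation
    #: set of the patient (any parameters); "parameter": to the previous
    #: measurement of the specific parameter.
    gap_reference: str = "observation_set"

    def __post_init__(self) -> None:
        if self.gap_hours <= 0:
            raise ValueError("gap_hours must be positive")
        if self.gap_reference not in ("observation_set", "parameter"):
            raise ValueError("gap_reference must be 'observation_set' or 'parameter'")


def impute_scores(
    df: pd.DataFrame,
    params: list[str],
    rules: ImputationRuleSet = ImputationRuleSet(),
    patient_col: str = "patient_id",
    time_col: str = "timestamp",
    label_col: str = "label",
) -> pd.DataFrame:
    """Fill missing ``<param>_score`` columns; add ``<param>_prov`` flags.

    ``df`` must be sorted by time within patient and carry an observation
    label column (condition (d) references neutralized sets).  Returns a new
    frame with integer subscores and provenance in
    {measured, imputed_zero, carried_forward}.
    """
    out = df.copy()
    times = pd.to_datetime(out[time_col])
    pids = out[patient_col].astype(str)
    # sortedness check within patient
    for pid, grp in times.groupby(pids.values, sort=False):
        if not grp.is_monotonic_increasing:
            raise ValueError(f"observations for patient {pid} not time-sorted")

    gap = pd.Timedelta(hours=rules.gap_hours)
    neutral = (out[label_col] == "neutralized").to_numpy()
    tvals = times.to_numpy()
    pvals = pids.to_numpy()

    for p in params:
        col = f"{p}_score"
        vals = out[col].to_numpy(dtype=float, copy=True)
        prov = np.where(np.isnan(vals), "", "measured").astype(object)
        # per-patient sequential scan
        start = 0
        n = len(out)
        while start < n:
            stop = start
            while stop < n and pvals[stop] == pvals[start]:
                stop += 1
            last_final = np.nan
            last_meas_time = None
            ever_measured = False
            for i in range(start, stop):
                measured = not np.isnan(vals[i])
                if rules.gap_reference == "observation_set":
                    prev_t = tvals[i - 1] if i > start else None
                else:
                    prev_t = last_meas_time
                if measured:
                    ever_measured = True
                    last_meas_time = tvals[i]
                else:
                    stale = prev_t is None or (tvals[i] - prev_t) > gap
                    if (i == start or not ever_measured or stale or neutral[i]):
                        vals[i] = 0.0
                        prov[i] = "imputed_zero"
                    elif rules.locf_enabled:
                        vals[i] = last_final
                        prov[i] = "carried_forward"
                    else:
                        vals[i] = 0.0
                        prov[i] = "imputed_zero"
                last_final = vals[i]
            start = stop
        out[col] = vals.astype(int)
        out[f"{p}_prov"] = prov
    return out


def finalize_totals(df: pd.DataFrame, params: list[str],
                    prefix: str = "") -> pd.DataFrame:
    """Add ``total`` and ``max_single`` columns from completed subscores."""
    cols = [f"{p}_score" for p in params]
    sub = df[cols]
    if sub.isna().any().any():
        raise ValueError("subscores still missing; run impute_scores first")
    out = df.copy()
    out[f"{prefix}total"] = sub.sum(axis=1).astype(int)
    out[f"{prefix}max_single"] = sub.max(axis=1).astype(int)
    return out
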