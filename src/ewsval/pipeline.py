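"""End-to-end validation runs: score -> label -> impute -> exclude
neutralized -> metrics, with reproducible seeding and tabular reports.

A run takes the three input tables (patients, observations, events),
produces per-rule threshold/burden metrics and per-score discrimination
for each configured event-type subset (all events Type 1-4 and the
life-threatening Type 1-3 subset), with patient-clustered bootstrap CIs and
paired permutation p-values comparing the two scores.  One global seed
drives independent named random streams for bootstrap and permutation so
adding one procedure never perturbs another.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .episodes import (WindowConfig, analysis_patient_days, build_episodes,
                       events_from_frame, label_frame, merge_events)
from .imputation import ImputationRuleSet, finalize_totals, impute_scores
from .metrics import (ResamplingConfig, auroc, burden_metrics,
                      check_burden_identities, clustered_bootstrap_ci,
                      confusion_counts, paired_permutation_test, pr_auc,
                      pr_curve, roc_curve, threshold_metrics, ward_rate)
from .scoring import (DEFAULT_RULES, TriggerRule, score_frame,
                      validate_observations)
from .tables import load_band_table

__all__ = ["RunConfig", "prepare_analysis", "run_validation", "render_report"]

log = logging.getLogger(__name__)

_DEFAULT_PAIRS = (
    ("NEWS>=5+S3", "GEWS>=4+S3"),
    ("NEWS>=5+S3", "GEWS>=5+S3"),
    ("NEWS>=5", "GEWS>=5"),
    ("NEWS>=7", "GEWS>=8"),
)


@dataclass
class RunConfig:
    """Everything that determines a validation run besides the data."""

    tables: tuple[str, ...] = ("news", "gews")
    #: optional alias -> band-table source overrides (name or YAML path);
    #: lets e.g. the "gews" slot point at a custom or swapped table file
    table_sources: tuple[tuple[str, str], ...] = ()
    window: WindowConfig = field(default_factory=WindowConfig)
    imputation: ImputationRuleSet = field(default_factory=ImputationRuleSet)
    rules: tuple[TriggerRule, ...] = tuple(DEFAULT_RULES)
    rule_pairs: tuple[tuple[str, str], ...] = _DEFAULT_PAIRS
    event_subsets: tuple[tuple[str, tuple[int, ...]], ...] = (
        ("type1_4", (1, 2, 3, 4)),
        ("type1_3", (1, 2, 3)),
    )
    resampling: ResamplingConfig = field(default_factory=ResamplingConfig)
    denominator: str = "analyzed"  # see episodes.analysis_patient_days
    ci_metrics: tuple[str, ...] = ("ppv", "sensitivity", "specificity")
    pvalue_metrics: tuple[str, ...] = (
        "accuracy", "npv", "ppv", "sensitivity", "specificity",
        "roa", "nne", "aoer",
    )
    compute_cis: bool = True
    compute_pvalues: bool = True

    def rule_by_name(self, name: str) -> TriggerRule:
        for r in self.rules:
            if r.name == name:
                return r
        raise KeyError(f"unresolvable trigger rule {name!r}")


def _config_hash(cfg: RunConfig) -> str:
    blob = json.dumps(dataclasses.asdict(cfg), default=str, sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def prepare_analysis(
    patients: pd.DataFrame,
    observations: pd.DataFrame,
    events: pd.DataFrame,
    cfg: RunConfig = RunConfig(),
) -> tuple[pd.DataFrame, dict]:
    """Score, label and impute every observation set.

    Returns (frame, stage_counts).  The frame carries, per bundled table
    ``t``, completed ``<param>_score`` columns prefixed ``t_``, plus
    ``t_total`` / ``t_max_single``, the observation label, anchoring event
    id and type, and episode index.  No rows are dropped here; neutralized
    exclusion happens per analysis subset.
    """
    validate_observations(observations)
    obs = observations.copy()
    obs["timestamp"] = pd.to_datetime(obs["timestamp"])
    obs = obs.sort_values(["patient_id", "timestamp"], kind="stable",
                          ignore_index=True)
    counts = {"observations_in": len(obs)}

    labeled = label_frame(obs, events, patients, cfg.window)
    counts["labeled"] = len(labeled)
    counts["label_breakdown"] = labeled["label"].value_counts().to_dict()

    etype = {}
    if len(events):
        ev = events.copy()
        if "event_id" not in ev.columns:
            ev["event_id"] = [f"E{i}" for i in range(len(ev))]
        etype = dict(zip(ev["event_id"].astype(str), ev["event_type"]))
    labeled["anchor_event_type"] = labeled["anchor_event_id"].map(
        lambda e: etype.get(e) if e is not None else None)

    sources = dict(cfg.table_sources)
    for tname in cfg.tables:
        table = load_band_table(sources.get(tname, tname))
        scored = score_frame(obs, table)
        counts[f"scored_{tname}"] = len(scored)
        work = pd.concat(
            [obs[["patient_id", "timestamp"]], labeled[["label"]], scored],
            axis=1)
        imputed = impute_scores(work, table.parameters, cfg.imputation)
        imputed = finalize_totals(imputed, table.parameters)
        counts[f"imputed_{tname}"] = len(imputed)
        counts[f"provenance_{tname}"] = {
            p: imputed[f"{p}_prov"].value_counts().to_dict()
            for p in table.parameters
        }
        ren = {c: f"{tname}_{c}" for c in imputed.columns
               if c.endswith(("_score", "_prov")) or c in ("total", "max_single")}
        labeled = pd.concat([labeled, imputed.rename(columns=ren)[list(ren.values())]],
                            axis=1)
    return labeled, counts


def _subset_frame(frame: pd.DataFrame, subset: Sequence[int]) -> pd.DataFrame:
    """Analysis rows for one event-type subset: neutralized excluded, and
    event-window rows anchored outside the subset dropped as well."""
    keep = frame["label"] == "non_event"
    is_event = frame["label"] == "event"
    in_subset = frame["anchor_event_type"].isin(list(subset))
    return frame[keep | (is_event & in_subset)].reset_index(drop=True)


def _patient_days(
    patients: pd.DataFrame, events: pd.DataFrame, cfg: RunConfig,
    subset: Sequence[int], include_pids: set[str],
) -> float:
    per_patient_events = events_from_frame(events)
    total = 0.0
    for r in patients.itertuples():
        pid = str(r.patient_id)
        if pid not in include_pids:
            continue
        adm, dis = pd.Timestamp(r.admission), pd.Timestamp(r.discharge)
        merged = merge_events(per_patient_events.get(pid, []), cfg.window)
        eps = build_episodes(adm, dis, merged, cfg.window, patient_id=pid)
        total += analysis_patient_days(
            adm, dis, merged, eps, cfg.window,
            event_subset=subset, denominator=cfg.denominator)
    return total


def _rule_stat(metric: str, rule: TriggerRule, labels: np.ndarray,
               patient_days: float):
    """Statistic over rows of (total, max_single) for one rule and metric."""

    def stat(arr: np.ndarray, idx: np.ndarray | None = None) -> float:
        lab = labels if idx is None else labels[idx]
        a = arr if idx is None else arr[idx]
        c = confusion_counts(lab, a[:, 0], a[:, 1], rule)
        if metric in ("roa", "aoer"):
            return burden_metrics(c, patient_days)[metric]
        return threshold_metrics(c)[metric]

    return stat


def run_validation(
    patients: pd.DataFrame,
    observations: pd.DataFrame,
    events: pd.DataFrame,
    cfg: RunConfig = RunConfig(),
    seed: int = 0,
    out_dir: str | Path | None = None,
) -> dict:
    """Execute the full validation chain; optionally write report files.

    Returns a dict with per-subset metric tables (``metrics``),
    discrimination tables (``discrimination``), ROC/PR points, the prepared
    analysis frame, and a run manifest.
    """
    frame, counts = prepare_analysis(patients, observations, events, cfg)
    ss = np.random.SeedSequence(seed)
    boot_rng, perm_rng = [np.random.default_rng(s) for s in ss.spawn(2)]

    metric_rows, disc_rows = [], []
    roc_points, pr_points = [], []
    analyses = {}
    for subset_name, subset in cfg.event_subsets:
        sub = _subset_frame(frame, subset)
        analyses[subset_name] = sub
        counts[f"analyzed_{subset_name}"] = len(sub)
        if (sub["label"] == "event").sum() == 0:
            raise ValueError(f"no event observation sets in subset {subset_name}")
        labels = sub["label"].to_numpy()
        pids = sub["patient_id"].astype(str).to_numpy()
        pdays = _patient_days(patients, events, cfg, subset, set(pids))
        counts[f"patient_days_{subset_name}"] = round(pdays, 3)

        arrays = {
            t: np.column_stack([sub[f"{t}_total"].to_numpy(),
                                sub[f"{t}_max_single"].to_numpy()])
            for t in cfg.tables
        }

        for rule in cfg.rules:
            arr = arrays[rule.score]
            c = confusion_counts(labels, arr[:, 0], arr[:, 1], rule)
            m = threshold_metrics(c) | burden_metrics(c, pdays)
            check_burden_identities(m)
            row = {"subset": subset_name, "rule": rule.name,
                   "score": rule.score, "tp": c.tp, "fp": c.fp,
                   "tn": c.tn, "fn": c.fn, "patient_days": pdays} | m
            if cfg.compute_cis:
                for metric in cfg.ci_metrics:
                    stat = _rule_stat(metric, rule, labels, pdays)
                    try:
                        lo, hi = clustered_bootstrap_ci(
                            lambda idx, _s=stat, _a=arr: _s(_a, idx),
                            pids, cfg.resampling, rng=boot_rng)
                    except ValueError:  # undefined in most resamples
                        lo = hi = float("nan")
                    row[f"{metric}_lo"], row[f"{metric}_hi"] = lo, hi
            metric_rows.append(row)

        if cfg.compute_pvalues:
            for name_a, name_b in cfg.rule_pairs:
                rule_a, rule_b = cfg.rule_by_name(name_a), cfg.rule_by_name(name_b)
                for metric in cfg.pvalue_metrics:
                    stat_a = _rule_stat(metric, rule_a, labels, pdays)
                    stat_b = _rule_stat(metric, rule_b, labels, pdays)
                    delta, p = paired_permutation_test(
                        stat_a, stat_b,
                        arrays[rule_a.score], arrays[rule_b.score],
                        pids, cfg.resampling, rng=perm_rng)
                    metric_rows.append({
                        "subset": subset_name,
                        "rule": f"{name_a} vs {name_b}",
                        "score": "difference", "metric": metric,
                        "delta": delta, "p_value": p})

        for t in cfg.tables:
            tot = sub[f"{t}_total"].to_numpy()
            d = {"subset": subset_name, "score": t,
                 "auroc": auroc(tot, labels), "pr_auc": pr_auc(tot, labels)}
            if cfg.compute_cis:
                for mname, fn in (("auroc", auroc), ("pr_auc", pr_auc)):
                    try:
                        lo, hi = clustered_bootstrap_ci(
                            lambda idx, _f=fn, _t=tot: _f(_t[idx], labels[idx]),
                            pids, cfg.resampling, rng=boot_rng)
                    except ValueError:
                        lo = hi = float("nan")
                    d[f"{mname}_lo"], d[f"{mname}_hi"] = lo, hi
            disc_rows.append(d)
            roc_points.append(roc_curve(tot, labels).assign(subset=subset_name,
                                                            score=t))
            pr_points.append(pr_curve(tot, labels).assign(subset=subset_name,
                                                          score=t))
        if cfg.compute_pvalues and len(cfg.tables) == 2:
            ta, tb = cfg.tables  # convention: (news, gews)
            for mname, fn in (("auroc", auroc), ("pr_auc", pr_auc)):
                stat = lambda s, _f=fn: _f(s, labels)
                delta, p = paired_permutation_test(
                    stat, stat, sub[f"{tb}_total"].to_numpy(),
                    sub[f"{ta}_total"].to_numpy(), pids,
                    cfg.resampling, rng=perm_rng)
                disc_rows.append({
                    "subset": subset_name, "score": f"{tb} - {ta}",
                    "metric": mname, "delta": delta, "p_value": p})

    result = {
        "metrics": pd.DataFrame(metric_rows),
        "discrimination": pd.DataFrame(disc_rows),
        "roc_points": pd.concat(roc_points, ignore_index=True),
        "pr_points": pd.concat(pr_points, ignore_index=True),
        "analysis": analyses,
        "frame": frame,
        "manifest": {
            "seed": seed,
            "config_hash": _config_hash(cfg),
            "config": dataclasses.asdict(cfg),
            "counts": counts,
        },
    }
    if out_dir is not None:
        _write_outputs(result, Path(out_dir))
    return result


def _write_outputs(result: dict, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    result["metrics"].to_csv(out_dir / "metrics_by_rule.csv", index=False)
    result["discrimination"].to_csv(out_dir / "discrimination.csv", index=False)
    result["roc_points"].to_csv(out_dir / "roc_points.csv", index=False)
    result["pr_points"].to_csv(out_dir / "pr_points.csv", index=False)
    (out_dir / "manifest.json").write_text(
        json.dumps(result["manifest"], indent=2, default=str))
    (out_dir / "report.md").write_text(render_report(result))


def render_report(result: dict, beds: int = 24) -> str:
    """Human-readable tables mirroring the per-rule metric layout, plus a
    ward-burden appendix re-expressing ROA/AOER as alerts and alerted
    events per 24 h on a fully occupied ``beds``-bed ward."""
    md = result["metrics"]
    lines = ["# EWS validation report", ""]
    rule_rows = md[md["score"] != "difference"] if len(md) else md
    for subset in rule_rows["subset"].unique() if len(rule_rows) else []:
        sel = rule_rows[rule_rows["subset"] == subset]
        lines.append(f"## Event subset: {subset}")
        lines.append("")
        cols = ["rule", "alerts", "accuracy", "npv", "ppv", "sensitivity",
                "specificity", "roa", "nne", "aoer"]
        lines.append("| " + " | ".join(cols) + " |")
        lines.append("|" + "---|" * len(cols))
        for _, r in sel.iterrows():
            vals = [r["rule"]] + [
                f"{r[c]:.3f}" if isinstance(r[c], float) else str(r[c])
                for c in cols[1:]]
            lines.append("| " + " | ".join(vals) + " |")
        lines.append("")
        lines.append(f"### Burden per 24 h on a {beds}-bed ward")
        lines.append("")
        lines.append("| rule | alerts/24h | alerted events/24h |")
        lines.append("|---|---|---|")
        for _, r in sel.iterrows():
            lines.append(
                f"| {r['rule']} | {ward_rate(r['roa'], beds):.3f} "
                f"| {ward_rate(r['aoer'], beds):.3f} |")
        lines.append("")
    dd = result["discrimination"]
    if len(dd):
        lines.append("## Discrimination")
        lines.append("")
        lines.append(dd.to_string(index=False))
        lines.append("")
    return "\n".join(lines)
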