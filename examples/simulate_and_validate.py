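"""End-to-end validation on a synthetic geriatric-ward cohort.

Generates a cohort with the default study conditions (scaled down to 150
patients for a quick run), pushes it through scoring, labeling, imputation
and metrics, and prints the per-rule report and discrimination summary.
"""

import logging

from ewsval import CohortSpec, RunConfig, generate_cohort, run_validation
from ewsval.metrics import ResamplingConfig

logging.basicConfig(level=logging.ERROR)

spec = CohortSpec(n_patients=150)
patients, obs, events = generate_cohort(spec, seed=7)
print(f"cohort: {len(patients)} patients, {len(obs)} observation sets, "
      f"{len(events)} events "
      f"({(events.event_type < 4).sum()} life-threatening)")

cfg = RunConfig(
    resampling=ResamplingConfig(bootstrap_samples=300, permutations=499,
                                seed=7),
    ci_metrics=("ppv",),
    pvalue_metrics=("ppv",),
)
res = run_validation(patients, obs, events, cfg, seed=7)

m = res["metrics"]
rules = m[(m["score"] != "difference") & (m["subset"] == "type1_4")]
cols = ["rule", "alerts", "accuracy", "ppv", "sensitivity", "specificity",
        "roa", "nne", "aoer"]
print("\nall clinical events (Type 1-4):")
print(rules[cols].round(3).to_string(index=False))

d = res["discrimination"]
print("\ndiscrimination:")
print(d[d["score"].isin(["news", "gews"])][
    ["subset", "score", "auroc", "pr_auc"]].round(3).to_string(index=False))
print("\npaired score-swap permutation tests (gews - news):")
print(d[~d["score"].isin(["news", "gews"])][
    ["subset", "metric", "delta", "p_value"]].round(4).to_string(index=False))
print("""
The frailty-adapted score separates deteriorating from stable observation
sets better (higher AUROC/PR-AUC) under the default mixed deterioration
profile, at lower alert burden for matched thresholds — the pattern the
pipeline is built to quantify.""")
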