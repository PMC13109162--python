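"""Alert-burden arithmetic: NNE, ROA, AOER and what they mean on a ward.

Reconstructs the burden measures from alert counts and precision, converts
per-100-patient-day rates to a 24-bed ward, and prices a threshold change
in alarms per additional detected event.
"""

from ewsval.metrics import (ConfusionCounts, alarms_per_additional_event,
                            burden_metrics, threshold_metrics, ward_rate)

# Validation-study scale inputs: the >=5 thresholds without the
# single-score-3 clause fired 459 (GEWS) and 523 (NEWS) alarms at
# precisions 0.497 and 0.365, over roughly 5,154 patient-days.
for name, alerts, ppv in [("GEWS>=5", 459, 0.497), ("NEWS>=5", 523, 0.365)]:
    tp = round(ppv * alerts)
    c = ConfusionCounts(tp=tp, fp=alerts - tp, tn=0, fn=0)
    m = threshold_metrics(c) | burden_metrics(c, patient_days=5154)
    print(f"{name}: {alerts} alerts, PPV {m['ppv']:.3f} -> "
          f"NNE {m['nne']:.3f} (alerts to evaluate per true alert), "
          f"ROA {m['roa']:.3f} and AOER {m['aoer']:.3f} per 100 patient-days")
    print(f"   on a full 24-bed ward that is {ward_rate(m['roa']):.2f} "
          f"alarms per 24 h, {ward_rate(m['aoer']):.2f} of them true")

# Price of adding the single-score-3 clause to GEWS>=5: the increments per
# 24 h on a 24-bed ward are +1.463 alarms against +0.102 detected events.
alarms, false_pos = alarms_per_additional_event(1.463, 0.102)
print(f"\nadding the S3 clause: ~{alarms} extra alarms per additional "
      f"detected event, {false_pos} of them false positives")
print("""
NNE = 1/PPV is the evaluations a responder performs per true alert; ROA
and AOER put the same trade-off on a staffing-relevant time base.  The
identities NNE = ROA/AOER and AOER = PPV x ROA tie the three together.""")
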