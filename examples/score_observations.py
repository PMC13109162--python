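"""Score vital-sign observation sets with NEWS and the frailty-adapted GEWS.

Builds two observation sets — a stable patient and a deteriorating one —
scores them with both band tables and shows where the scores disagree.
"""

from ewsval import DEFAULT_RULES, evaluate_trigger, load_band_table, \
    score_observation

news = load_band_table("news")
gews = load_band_table("gews")

stable = dict(resp_rate=16, spo2=96, o2_flow=0, temp=36.8,
              temp_site="tympanic", sbp=135, hr=72,
              consciousness="alert", pain=0)

# agitation + pain + low-grade fever + mild tachycardia: the pattern of an
# incipient deterioration in a frail older patient.  The standard bands
# score almost none of it; the frailty-adapted bands score all of it.
deteriorating = dict(resp_rate=20, spo2=94, o2_flow=0, temp=37.8,
                     temp_site="forehead", sbp=105, hr=108,
                     consciousness="agitated", pain=8)

for name, obs in [("stable", stable), ("deteriorating", deteriorating)]:
    rn = score_observation(obs, news)
    rg = score_observation(obs, gews)
    print(f"\n{name} patient:")
    print(f"  NEWS total {rn.total:2d} (max single {rn.max_single})  "
          f"subscores {rn.subscores}")
    print(f"  GEWS total {rg.total:2d} (max single {rg.max_single})  "
          f"subscores {rg.subscores}")
    for rule in DEFAULT_RULES:
        r = rg if rule.score == "gews" else rn
        if evaluate_trigger(r, rule):
            print(f"  -> alert under {rule.name}")

print("""
The deteriorating pattern (pain 8, agitation, temperature 37.8 + 0.2
forehead correction = 38.0, HR 108, SBP 105) lands in bands the geriatric
score penalises but the standard score largely ignores — the reason a
frailty-adapted score can flag deterioration earlier in this population.""")
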