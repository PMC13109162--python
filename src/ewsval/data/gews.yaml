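# Geriatric Early Warning Score band table.
#
# Frailty-adapted bands: narrower normal ranges than NEWS, graded oxygen
# therapy (L/min) instead of a yes/no flag, a graded AVPU scale with agitation
# assigned the highest score, and pain (NRS / PAINAD, 0-10) as an eighth
# scored item.  Column placement of a few printed bands (HR 76-95 / 96-120,
# SBP 190-220) is a positional reading of the published row against the
# 3-2-1-0-1-2-3 header; corrections are a one-line edit here, not a code
# change.
name: GEWS
max_total: 24
parameters:
  resp_rate:
    kind: numeric
    unit: breaths/min
    domain: [0, 60]
    resolution: 1
    bands:
      - {max: 12, max_closed: false, score: 3}
      - {min: 12, max: 23, score: 0}
      - {min: 24, max: 27, score: 2}
      - {min: 28, score: 3}
  spo2:
    kind: numeric
    unit: "%"
    domain: [50, 100]
    resolution: 1
    bands:
      - {max: 86, max_closed: false, score: 3}
      - {min: 86, max: 88, score: 2}
      - {min: 89, max: 90, score: 1}
      - {min: 91, score: 0}
  o2_flow:
    kind: numeric
    unit: L/min
    domain: [0, 15]
    resolution: 1
    bands:
      - {min: 0, max: 0, score: 0}
      - {min: 1, max: 1, score: 1}
      - {min: 2, max: 4, score: 2}
      - {min: 5, score: 3}
  temp:
    kind: numeric
    unit: degC
    domain: [30.0, 43.0]
    resolution: 0.1
    bands:
      - {max: 35.0, max_closed: false, score: 3}
      - {min: 35.0, max: 37.1, score: 0}
      - {min: 37.2, max: 37.4, score: 1}
      - {min: 37.5, max: 38.0, score: 2}
      - {min: 38.0, min_closed: false, score: 3}
  sbp:
    kind: numeric
    unit: mmHg
    domain: [40, 260]
    resolution: 1
    bands:
      - {max: 100, max_closed: false, score: 3}
      - {min: 100, max: 109, score: 2}
      - {min: 110, max: 119, score: 1}
      - {min: 120, max: 189, score: 0}
      - {min: 190, max: 220, score: 2}
      - {min: 220, min_closed: false, score: 3}
  hr:
    kind: numeric
    unit: beats/min
    domain: [20, 220]
    resolution: 1
    bands:
      - {max: 50, max_closed: false, score: 3}
      - {min: 50, max: 75, score: 0}
      - {min: 76, max: 95, score: 1}
      - {min: 96, max: 120, score: 2}
      - {min: 120, min_closed: false, score: 3}
  consciousness:
    kind: categorical
    map:
      alert: 0
      voice: 1
      pain: 2
      unresponsive: 3
      agitated: 3
  pain:
    kind: numeric
    unit: NRS/PAINAD
    domain: [0, 10]
    resolution: 1
    bands:
      - {min: 0, max: 0, score: 0}
      - {min: 1, max: 3, score: 1}
      - {min: 4, max: 6, score: 2}
      - {min: 7, score: 3}
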