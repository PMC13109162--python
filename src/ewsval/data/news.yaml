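# National Early Warning Score (Royal College of Physicians) band table.
#
# Ranges printed "a-b" are closed [a, b]; min/max omitted means unbounded on
# that side; *_closed flags default to true.  The published score-3 tachycardia
# band starts at 131 so that it stays disjoint from the 111-130 band.
# Oxygen therapy is binary here: any flow above room air scores 2.
# Agitation is not a NEWS category; agitated patients score as alert (0).
name: NEWS
max_total: 20
parameters:
  resp_rate:
    kind: numeric
    unit: breaths/min
    domain: [0, 60]
    resolution: 1
    bands:
      - {max: 8, score: 3}
      - {min: 9, max: 11, score: 1}
      - {min: 12, max: 20, score: 0}
      - {min: 21, max: 24, score: 2}
      - {min: 25, score: 3}
  spo2:
    kind: numeric
    unit: "%"
    domain: [50, 100]
    resolution: 1
    bands:
      - {max: 91, score: 3}
      - {min: 92, max: 93, score: 2}
      - {min: 94, max: 95, score: 1}
      - {min: 96, score: 0}
  o2_flow:
    kind: numeric
    unit: L/min
    domain: [0, 15]
    resolution: 1
    bands:
      - {min: 0, max: 0, score: 0}
      - {min: 0, min_closed: false, score: 2}
  temp:
    kind: numeric
    unit: degC
    domain: [30.0, 43.0]
    resolution: 0.1
    bands:
      - {max: 35.0, score: 3}
      - {min: 35.1, max: 36.0, score: 1}
      - {min: 36.1, max: 38.0, score: 0}
      - {min: 38.1, max: 39.0, score: 1}
      - {min: 39.1, score: 2}
  sbp:
    kind: numeric
    unit: mmHg
    domain: [40, 260]
    resolution: 1
    bands:
      - {max: 90, score: 3}
      - {min: 91, max: 100, score: 2}
      - {min: 101, max: 110, score: 1}
      - {min: 111, max: 219, score: 0}
      - {min: 220, score: 3}
  hr:
    kind: numeric
    unit: beats/min
    domain: [20, 220]
    resolution: 1
    bands:
      - {max: 40, score: 3}
      - {min: 41, max: 50, score: 1}
      - {min: 51, max: 90, score: 0}
      - {min: 91, max: 110, score: 1}
      - {min: 111, max: 130, score: 2}
      - {min: 131, score: 3}
  consciousness:
    kind: categorical
    map:
      alert: 0
      voice: 3
      pain: 3
      unresponsive: 3
      agitated: 0
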