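bands:
  e_over_eprime:
  - hi: 14.0
    hi_closed: true
    lo: 0.0
    lo_closed: false
    points: 0
  - hi: .inf
    hi_closed: false
    lo: 14.0
    lo_closed: false
    points: 2
  lasct:
  - hi: 6.0
    hi_closed: true
    lo: 0.0
    lo_closed: false
    points: 2
  - hi: .inf
    hi_closed: false
    lo: 6.0
    lo_closed: false
    points: 0
  lasr:
  - hi: 15.0
    hi_closed: false
    lo: 0.0
    lo_closed: false
    points: 2
  - hi: 23.0
    hi_closed: true
    lo: 15.0
    lo_closed: true
    points: 1
  - hi: .inf
    hi_closed: false
    lo: 23.0
    lo_closed: false
    points: 0
  lavi:
  - hi: 34.0
    hi_closed: false
    lo: 0.0
    lo_closed: false
    points: 0
  - hi: 48.0
    hi_closed: true
    lo: 34.0
    lo_closed: true
    points: 1
  - hi: .inf
    hi_closed: false
    lo: 48.0
    lo_closed: false
    points: 2
  pa_tdi:
  - hi: 120.0
    hi_closed: false
    lo: 0.0
    lo_closed: false
    points: 0
  - hi: 150.0
    hi_closed: true
    lo: 120.0
    lo_closed: true
    points: 1
  - hi: .inf
    hi_closed: false
    lo: 150.0
    lo_closed: false
    points: 2
  stiffness:
  - hi: 0.5
    hi_closed: true
    lo: 0.0
    lo_closed: false
    points: 0
  - hi: .inf
    hi_closed: false
    lo: 0.5
    lo_closed: false
    points: 2
category_boundaries:
- 3
- 7
higher_is_worse:
  e_over_eprime: true
  lasct: false
  lasr: false
  lavi: true
  pa_tdi: true
  stiffness: true
missing_lasct_policy: refuse
name: ease_fig6
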