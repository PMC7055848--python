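# Instrument definitions for the cardiac-rehabilitation needs-assessment battery.
#
# Schema (one record per instrument):
#   id:            short instrument name
#   n_items:       number of items
#   min_code:      lowest integer response code per item
#   max_code:      highest integer response code per item
#   scoring_mode:  "sum" (integer total) or "mean" (arithmetic mean of codes)
#   construct:     latent construct the instrument measures
#   risk_direction: "symptom" (higher score = more symptoms) or
#                   "resource" (higher score = more of a protective resource)
#   bands:         ordered score bands, low score first.  Each band:
#     label:        class label (unique within the instrument)
#     lower:        lower score edge (inclusive)
#     upper:        upper score edge (exclusive unless upper_closed)
#     upper_closed: include the upper edge in this band (default: false;
#                   the last band is always closed at the theoretical maximum)
#     risk:         the clinical risk wording attached to this score band
#
# Bands must be contiguous and jointly cover the theoretical score range.

- id: QLMI-P
  n_items: 10
  min_code: 1
  max_code: 7
  scoring_mode: mean
  construct: exercise_capacity
  risk_direction: resource
  bands:
    - {label: low, lower: 1.0, upper: 4.0, upper_closed: true, risk: low exercise capacity}
    - {label: high, lower: 4.0, upper: 7.0, risk: high exercise capacity}

- id: QLMI-S
  n_items: 7
  min_code: 1
  max_code: 7
  scoring_mode: mean
  construct: social_functioning
  risk_direction: resource
  bands:
    - {label: low, lower: 1.0, upper: 4.5, risk: high risk of social dysfunctioning}
    - {label: moderate, lower: 4.5, upper: 6.0, risk: moderate risk of social dysfunctioning}
    - {label: high, lower: 6.0, upper: 7.0, risk: low risk of social dysfunctioning}

- id: PHQ-9
  n_items: 9
  min_code: 0
  max_code: 3
  scoring_mode: sum
  construct: depression
  risk_direction: symptom
  bands:
    - {label: low, lower: 0, upper: 5, risk: low risk of depression}
    - {label: moderate, lower: 5, upper: 10, risk: moderate risk of depression}
    - {label: high, lower: 10, upper: 27, risk: serious risk of depression}

- id: GAD-7
  n_items: 7
  min_code: 0
  max_code: 3
  scoring_mode: sum
  construct: anxiety
  risk_direction: symptom
  bands:
    - {label: low, lower: 0, upper: 5, risk: low risk of anxiety}
    - {label: moderate, lower: 5, upper: 10, risk: moderate risk of anxiety}
    - {label: high, lower: 10, upper: 21, risk: serious risk of anxiety}

- id: HADS-A
  n_items: 7
  min_code: 0
  max_code: 3
  scoring_mode: sum
  construct: anxiety
  risk_direction: symptom
  bands:
    - {label: low, lower: 0, upper: 5, risk: low risk of anxiety}
    - {label: moderate, lower: 5, upper: 8, risk: moderate risk of anxiety}
    - {label: high, lower: 8, upper: 21, risk: serious risk of anxiety}

- id: HADS-D
  n_items: 7
  min_code: 0
  max_code: 3
  scoring_mode: sum
  construct: depression
  risk_direction: symptom
  bands:
    - {label: low, lower: 0, upper: 5, risk: low risk of depression}
    - {label: moderate, lower: 5, upper: 8, risk: moderate risk of depression}
    - {label: high, lower: 8, upper: 21, risk: serious risk of depression}

- id: MPSSS
  n_items: 12
  min_code: 1
  max_code: 7
  scoring_mode: sum
  construct: social_support
  risk_direction: resource
  bands:
    - {label: low, lower: 12, upper: 65, risk: low level of social support}
    - {label: moderate, lower: 65, upper: 79, risk: moderate level of social support}
    - {label: high, lower: 79, upper: 84, risk: high level of social support}
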