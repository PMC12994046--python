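# Default 20-variable biopsychosocial registry for ENT surgical prioritization.
# Variable ids, labels and ordering follow the published ENT panel framework;
# kinds, level codings and per-level impact scores are package defaults
# (clinically ordered, expert-style 1-10 scale) and are user-overridable.
variables:
  - id: Sever
    label: Severity
    kind: ordinal
    levels: [low, moderate, high, severe]
    scores: [2, 4, 7, 10]
  - id: Urg
    label: Urgency
    kind: ordinal
    levels: [routine, soon, urgent, emergent]
    scores: [1, 4, 7, 10]
  - id: Jclin
    label: Maximum waiting time indicated by physician (months)
    kind: continuous
    intervals: [[0, 3], [3, 6], [6, 12], [12, 24]]
    scores: [10, 7, 4, 2]
  - id: Tsuen
    label: Sleep disorder
    kind: ordinal
    levels: [none, mild, moderate, severe]
    scores: [1, 3, 6, 9]
  - id: Tlist
    label: Time on waiting list (months)
    kind: continuous
    intervals: [[0, 6], [6, 12], [12, 24], [24, 60]]
    scores: [1, 3, 6, 9]
  - id: Pmcx
    label: Expected improvement due to surgery
    kind: ordinal
    levels: [low, moderate, high]
    scores: [2, 5, 9]
  - id: Dest
    label: Capacity to study (exploratory)
    kind: ordinal
    levels: [unaffected, partially_affected, severely_affected]
    scores: [1, 5, 9]
  - id: Com
    label: Chances of developing comorbidities
    kind: ordinal
    levels: [low, moderate, high]
    scores: [2, 5, 9]
  - id: Lfam
    label: Capacity of participating in family activities
    kind: ordinal
    levels: [unaffected, limited, unable]
    scores: [1, 5, 9]
  - id: Hanor
    label: Affected anatomical area
    kind: categorical
    levels: [ear, nose, throat, head_neck]
    scores: [5, 4, 6, 8]
  - id: Opat
    label: Presence of other pathologies
    kind: binary
    scores: [7, 2]
  - id: Diag
    label: Diagnosis group
    kind: categorical
    levels: [otologic, rhinologic, pharyngolaryngeal, head_neck_mass]
    scores: [5, 4, 6, 9]
  - id: Olim
    label: Other physical limitations
    kind: binary
    scores: [6, 2]
  - id: Ncuid
    label: Need of a caregiver
    kind: binary
    scores: [8, 2]
  - id: Rcuid
    label: Patient cares for another person
    kind: binary
    scores: [7, 2]
  - id: Dolor
    label: Pain scale (0-10)
    kind: continuous
    intervals: [[0, 3], [3, 6], [6, 8], [8, 10]]
    scores: [1, 4, 7, 10]
  - id: Dtrab
    label: Capacity to work
    kind: ordinal
    levels: [unaffected, partially_affected, unable]
    scores: [1, 5, 9]
  - id: Acc
    label: Type of residence area (exploratory)
    kind: categorical
    levels: [urban, periurban, rural]
    scores: [2, 5, 8]
  - id: Dtras
    label: Difficulty in transferring to hospital
    kind: ordinal
    levels: [none, some, severe]
    scores: [1, 5, 9]
  - id: Ccrit
    label: Need for clinical bed
    kind: binary
    scores: [9, 1]
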