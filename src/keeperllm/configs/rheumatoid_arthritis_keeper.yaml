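# Illustrative extraction configuration for the synthetic toy vocabulary;
# not a validated clinical concept-set specification.
disease_name: rheumatoid arthritis
conceptual_definition: A chronic autoimmune inflammatory arthritis characterized by
  persistent symmetric polyarthritis of small joints, morning stiffness, and positive
  serologic markers such as rheumatoid factor or anti-CCP antibodies.
categories:
- category: clinical_presentation
  domains:
  - condition
  - observation
  window:
    start: -30
    end: 0
  concept_set:
    name: symptoms
    items:
    - concept_id: 20001
      include_descendants: false
      is_excluded: false
    - concept_id: 20002
      include_descendants: false
      is_excluded: false
    - concept_id: 20003
      include_descendants: false
      is_excluded: false
    - concept_id: 20004
      include_descendants: false
      is_excluded: false
- category: disease_history
  domains:
  - condition
  window:
    start: null
    end: -1
  concept_set:
    name: prior diagnoses
    items:
    - concept_id: 80809
      include_descendants: true
      is_excluded: false
- category: preliminary_diagnosis
  domains:
  - condition
  window:
    start: 0
    end: 30
  concept_set:
    name: index diagnoses
    items:
    - concept_id: 80809
      include_descendants: true
      is_excluded: false
- category: diagnostic_procedures
  domains:
  - measurement
  - procedure
  window:
    start: -30
    end: 30
  concept_set:
    name: laboratory tests
    items:
    - concept_id: 40001
      include_descendants: false
      is_excluded: false
    - concept_id: 40002
      include_descendants: false
      is_excluded: false
    - concept_id: 40003
      include_descendants: false
      is_excluded: false
- category: differential_diagnoses
  domains:
  - condition
  window:
    start: -90
    end: 30
  concept_set:
    name: differential diagnoses
    items:
    - concept_id: 22001
      include_descendants: false
      is_excluded: false
    - concept_id: 22002
      include_descendants: false
      is_excluded: false
    - concept_id: 22003
      include_descendants: false
      is_excluded: false
- category: treatment
  domains:
  - drug
  window:
    start: 0
    end: 90
  concept_set:
    name: treatments
    items:
    - concept_id: 30001
      include_descendants: false
      is_excluded: false
    - concept_id: 30002
      include_descendants: false
      is_excluded: false
    - concept_id: 30003
      include_descendants: false
      is_excluded: false
- category: comorbidities
  domains:
  - condition
  window:
    start: null
    end: -1
  concept_set:
    name: comorbidities
    items:
    - concept_id: 21001
      include_descendants: false
      is_excluded: false
    - concept_id: 21002
      include_descendants: false
      is_excluded: false
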