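{
  "expression": {
    "items": [
      {
        "concept": {
          "CONCEPT_ID": 30101
        },
        "includeDescendants": false,
        "isExcluded": false
      },
      {
        "concept": {
          "CONCEPT_ID": 30102
        },
        "includeDescendants": false,
        "isExcluded": false
      },
      {
        "concept": {
          "CONCEPT_ID": 30103
        },
        "includeDescendants": false,
        "isExcluded": false
      }
    ]
  },
  "name": "treatments"
}
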