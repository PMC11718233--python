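{
  "expression": {
    "items": [
      {
        "concept": {
          "CONCEPT_ID": 30001
        },
        "includeDescendants": false,
        "isExcluded": false
      },
      {
        "concept": {
          "CONCEPT_ID": 30002
        },
        "includeDescendants": false,
        "isExcluded": false
      },
      {
        "concept": {
          "CONCEPT_ID": 30003
        },
        "includeDescendants": false,
        "isExcluded": false
      }
    ]
  },
  "name": "treatments"
}
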