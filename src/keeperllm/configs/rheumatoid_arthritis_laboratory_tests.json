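{
  "expression": {
    "items": [
      {
        "concept": {
          "CONCEPT_ID": 40001
        },
        "includeDescendants": false,
        "isExcluded": false
      },
      {
        "concept": {
          "CONCEPT_ID": 40002
        },
        "includeDescendants": false,
        "isExcluded": false
      },
      {
        "concept": {
          "CONCEPT_ID": 40003
        },
        "includeDescendants": false,
        "isExcluded": false
      }
    ]
  },
  "name": "laboratory tests"
}
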