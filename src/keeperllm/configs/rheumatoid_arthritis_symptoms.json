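{
  "expression": {
    "items": [
      {
        "concept": {
          "CONCEPT_ID": 20001
        },
        "includeDescendants": false,
        "isExcluded": false
      },
      {
        "concept": {
          "CONCEPT_ID": 20002
        },
        "includeDescendants": false,
        "isExcluded": false
      },
      {
        "concept": {
          "CONCEPT_ID": 20003
        },
        "includeDescendants": false,
        "isExcluded": false
      },
      {
        "concept": {
          "CONCEPT_ID": 20004
        },
        "includeDescendants": false,
        "isExcluded": false
      }
    ]
  },
  "name": "symptoms"
}
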