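{
  "expression": {
    "items": [
      {
        "concept": {
          "CONCEPT_ID": 80809
        },
        "includeDescendants": true,
        "isExcluded": false
      }
    ]
  },
  "name": "diagnoses"
}
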