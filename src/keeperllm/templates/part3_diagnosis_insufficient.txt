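Keep in mind that a diagnosis code alone is insufficient evidence that the patient truly had {disease_name}. Look for corroborating evidence such as compatible symptoms, relevant laboratory tests, and disease-specific treatments before concluding the patient was a true case.
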