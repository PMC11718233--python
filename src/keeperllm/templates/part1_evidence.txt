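First, discuss the evidence in the data in favor of the patient having {disease_name}, and then discuss the evidence against it.
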