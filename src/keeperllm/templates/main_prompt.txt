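Did this patient have {disease_name} on the index date (day 0)?

{disease_name} is defined as follows: {conceptual_definition}

Below is the patient's structured data, with event timing given in days relative to the index date:

{profile_text}
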