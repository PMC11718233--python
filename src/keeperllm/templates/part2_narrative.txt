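Next, write a brief clinical narrative that is consistent with all of the data provided.
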