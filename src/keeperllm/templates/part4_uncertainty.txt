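When the evidence is ambiguous, choose the answer that is most likely given all of the data taken together: do not answer 'yes' when an alternative diagnosis explains the data better, and do not answer 'no' merely because some doubt remains.
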