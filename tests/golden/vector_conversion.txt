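Use "','" to concatenate all results into a single sentence.
Put "c('" in front of the sentence and "')" after the sentence
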