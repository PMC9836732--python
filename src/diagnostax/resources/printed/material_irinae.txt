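6 specimens (Suppl. material S1), Arctic Ocean (ZMBN116496, ZMBN116497, ZMBN116498, ZMBN116499, ZMBN116500, ZMBN116501).
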