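Complete specimen, 34.0 mm long and 2.0 mm wide; female with oocytes in body cavity.
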