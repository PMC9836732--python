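15 specimens (Suppl. material S1), Barents Sea (ZMBN116454, ZMBN116455, ZMBN116458, ZMBN116459, ZMBN116460, ZMBN116462, ZMBN116463, ZMBN116465, ZMBN116467, ZMBN116468, ZMBN116470, ZMBN116471, ZMBN116472, ZMBN116474); Norwegian coast (ZMBN116476).
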