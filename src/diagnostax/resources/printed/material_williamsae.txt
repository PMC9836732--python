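20 specimens (Suppl. material S1), Skagerrak (GNM14639, GNM15107, GNM15108); Barents Sea (ZMBN116246, ZMBN116247, ZMBN116248, ZMBN116249, ZMBN116251, ZMBN116252, ZMBN116253, ZMBN116254, ZMBN116255, ZMBN116257, ZMBN116260, ZMBN116262, ZMBN116263, ZMBN116266, ZMBN116269, ZMBN116270, ZMBN116271).
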