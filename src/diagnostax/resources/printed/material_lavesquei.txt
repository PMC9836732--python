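Type material. Holotype: ZMBN116322. Paratypes (16 specimens): Skagerrak (GNM15112); Norwegian coast (NTNU–VM61386, NTNU–VM61387, NTNU–VM68252, ZMBN116319, ZMBN116320, ZMBN116321, ZMBN116323, ZMBN116324, ZMBN116325, ZMBN116326, ZMBN116327, ZMBN116328, ZMBN116329, ZMBN116330, ZMBN116331, ZMBN116332).
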