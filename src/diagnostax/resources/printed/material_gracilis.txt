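20 specimens (Suppl. material S1), Skagerrak (GNM15110, GNM15111); Norwegian coast (ZMBN116276, ZMBN116278, ZMBN116282, ZMBN116283, ZMBN116284, ZMBN116285, ZMBN116287, ZMBN116289, ZMBN116293, ZMBN116295, ZMBN116297, ZMBN116298, ZMBN116301, ZMBN116306, ZMBN116307, ZMBN116309, ZMBN116310, 116313).
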