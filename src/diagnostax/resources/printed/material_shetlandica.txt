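30 specimens (Suppl. material S1), Skagerrak (GNM14640); Swedish coast (ZMBN116171, ZMBN116181, ZMBN116185, ZMBN116186, ZMBN116187, ZMBN116188, ZMBN116191, ZMBN116192, ZMBN116193, ZMBN116196, ZMBN116198, ZMBN116200, ZMBN116201, ZMBN116202, ZMBN116203, ZMBN116204, ZMBN116206); Norwegian coast (ZMBN116207, ZMBN116208, ZMBN116214, ZMBN116216, ZMBN116219, ZMBN116220, ZMBN116221, ZMBN116226, ZMBN116227, ZMBN116228, ZMBN116235, ZMBN116242).
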