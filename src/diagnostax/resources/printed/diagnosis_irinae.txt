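177–204: CGGGGGGTTTGGAAACTGGTTAATCCCC, 213–225: TGGGGCCCCAGAC, 249–258: CATAAGGTTC, 273–303: GGCCCTCATCCTACTAGTCAGCTCAGCTGCT, 305–321: GGCTGGT, 327–336: ATGAACTGTA, 342–372: ACCACTTTCAGACAACATCGCTCATGCCGGA, 381–399: AGATCTAGCAATTTTCTCA, 426: CCTAGGTTCTATTAACTTCATCACAACAGTC, 483–499: TCTAGAACGAATCCCAC, 535–573: TTATTACTATCACTACCAGTGCTAGCCGGAGCTATTACC, 594–612: CATTAACACATCATTCTTC, 618–636: AGCCGGTGGTGGTGATCCT.
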