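78–98: CCAACCCGGAGCCTATTTAGGT, 186–192: CGGAAAC, 210–219: GCTAGGCGCC, 228–234: GGCATTC, 264–276: TCTCCCGCCTGCC, 288– 292: CGTT, 306: C, 333–342: CGTCTACCCT, 351–369: AGACAATATGGCACACGCC, 381–402: AGATCTGGCTATTTTCTCCCTA, 453–459: AGTAATA, 511–522: TCAGCTATAATC, 535–558: TTACTTCTTTCTCTGCCAGTTCTG.
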