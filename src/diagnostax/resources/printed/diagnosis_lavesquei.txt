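78–99: TCAACCCGGTGCTTACCTCGGT, 156–174: TTTAGTTATGCCAGTCTTC, 261–264: GTTA, 270–279: TCCAGCACTT, 315–336: AGTTGGGACCGGTTGAACCGTT, 351–369: AGACAATATAGCTCATGCG, 405–411: CTTGGCT, 426–447: CCTAGGATCAATTAACTTTATC, 459–483: CAACATACGCTGAAAAGGTTTACGA, 510–525: GTCCGCGGTTATCACA, 534–558: ACTTCTTTTATCCCTTCCAGTCTTG, 573–580: CATGCTTC, 606–627: CTTTTTCGACCCAGCTGGTGGG.
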