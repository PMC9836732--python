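59–62: TATC, 75–96: TGGACAACCTGGGGCATTCCTG, 132–144: TCATGCTTTTTTA, 153–157: TTTCC, 216–234: TGCTCCTGATATAGCTTTC, 264–277: CCTCCCTCCAGCTT, 315–318: GGTT, 327–342: CTGAACAGTATACCCC, 381–399: AGATTTGGCTATTTTTTCT, 414–432: TATCTCCTCTATTCTTGGC, 450–454: TACA, 515–529: AAAAATCACTACCA, 543–573: TTCACTTCCTGTATTAGCAGGAGCTATTACA, 600–609: CACTTCCTTT, 630–640: CGACCCAATTT.
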