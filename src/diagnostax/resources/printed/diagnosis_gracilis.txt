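39–63: TGGTACTTCAATAAGACTTCTTATC, 84–96: TGGGGCATTCCTG, 111–132: TTATAACACAATTGTTACTGCT, 138–157: TTTTTTAATAATTTTTTTCC, 216–234: TGCTCCTGATATAGCTTTC, 264–277: CCTCCCTCCAGCTT, 315–327: AGCTGGGACAGGT, 333–351: AGTCTACCCTCCTTTATCT, 381–399: AGATTTGGCTATTTTTTCT, 414–432: TATCTCCTCTATTCTTGGC¸ 450–545: TACA, 516–529: AAAAATCACTACCA, 543–552: TTCACTTCCT, 600–609: CACTTCCTTT, 630–640: CGACCCAATTT.
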