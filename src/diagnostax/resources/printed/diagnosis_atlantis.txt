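60–84: TATTCGTATTGAGCTAGGGCAACCT, 132–150: ACATGCATTTTTAATAATC, 171–189: TTTTATTGGTGGATTTGGT, 213–231: GGGAGCTCCTGATATAGCC, 264–294: ACTACCACCAGCCTTAATCTTATTAGTAAGC, 345–363: ATTATCTGATAATATGGCT, 384–399: CCTTGCTATTTTTTCA, 477–484: GCTACGAC, 549–573: TCCAGTCTTAGCTGGTGCAATCACT, 558–591: CCGT, 615–630: TCCAGCTGGTGGTGGT.
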