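>SLC30A5_promoter_probe_del_-91_-84 probe with promoter -91..-84 deleted
GTGGCGGGAGGAGCCTAAGGGACGAGGAAAGGCGAGTGTTCTGCTTGCGCAGACGCAAGGCTGGGCGGGA
GTGAGGGTTGCTGGGCCTGATGACGTGGCTTGGCAACGTCCCTACCGCCGCTGCTTCCCGGGAACCTGGC
GCCGCCGGAACTGATCGCGGCCTAGTCCCGACGCGTGTGTGCTAGTGAGCCGGA
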