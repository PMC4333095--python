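>SLC30A5_promoter_probe region -156..+46 relative to TSS (no position 0)
GTGGCGGGAGGAGCCTAAGGGACGAGGAAAGGCGAGTGTTCTGCTTGCGCAGACGCAAGGCTGGGCACTC
CCCCGGGAGTGAGGGTTGCTGGGCCTGATGACGTGGCTTGGCAACGTCCCTACCGCCGCTGCTTCCCGGG
AACCTGGCGCCGCCGGAACTGATCGCGGCCTAGTCCCGACGCGTGTGTGCTAGTGAGCCGGA
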