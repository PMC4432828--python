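>alu_consensus_amplicon Alu repeat consensus amplicon (left-arm product)
GAGGCCGAGGCGGGAGGATCGCTTGAGCCCAGGAGTTCGAGACCAGCCTGGGCAACATAG
CGAGACCCCGTCTCTACAAAAAATACAAAAATTAGCCGGGCGTGGTGGCGCGCGCCTGTA
GTCCCAGCTACTCGGGAGGCTGAGGCAGGAGGATCGCTTGAGCCCAGGAGTTCGAGGCTG
CAGTGAGCTATGATCGCGCCACTGCACTCCAGCCTGGGC
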