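>line1_consensus_amplicon LINE-1 repeat consensus amplicon
AACTATAATAAACTCCACCCAATTCAAACTTCCGACCACTTTATTTACCGACTCAAACCT
AACAATAACTAACACGTCCCCTCCCCCAACCTCACTACCGCCTTACAATTTAATCTCAAA
CTACTACGCTAACAATAAATAAAACTCTAATAAACATAAAACCCTCTCAAACTAAACGCG
ACATATAATCTCCTAATATATCATTTACTAATCGCATTAAAAAAACACAATATTAAAATA
AAAATAACCCAATTTTCCAAATACCATCTATCACCCCTTTTCTTTAACTAAAAAAAAAAA
TTCCCTAACCCCTTACACTTCCGTACTAAACATACTCGTACTTCACTCACATACACCCAC
TATCCTTCACCCACTATCTAACACTTCCCATTAAAATAAACCTAATACCTCAAATAAAAA
TACAAAAAT
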