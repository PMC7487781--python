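>FP1 HBB amplification primer set 1, forward
cacttagacctcaccctgtg
>FP2 HBB amplification primer set 2, forward (stored verbatim; identical to RP1 in the source table)
tatgggacgcttgatgttttct
>RP1 HBB amplification primer set 1, reverse (stored verbatim; identical to FP2 in the source table)
tatgggacgcttgatgttttct
>RP2 HBB amplification primer set 2, reverse
ctctgcctattggtctattttccca
>HBB_ssODN single-stranded donor template for the HBB sickle-mutation correction assay
TCAGGGCAGAGCCATCTATTGCTTACATTTGCTTCTGACACAACTGTGTTCACTAGCAACCTCAAACAGACACCATGGTGCACCTGACTCCTGTAGAGAAGTCTGCGGTTACTGCCCTGTGGGGCAAGGTGAACGTGGATGAAGTTGGTGGTGAGGCCCTGGGCAGGT
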