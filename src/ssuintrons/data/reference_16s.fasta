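>REF16S synthetic intron-free 16S rRNA gene frame, 1542 nt, GC~0.67; deterministic stand-in (seed 20150709) for the community-standard coordinate frame
CTCGCTCATGCGAGGTACGTTGTACGCCAGACCGCTGGGCCCCCGATGGGCCCCGTCCAGCTCCCCCAAT
TATGCGTCCGACTTGATAAAGCCACCCGACTCGCCCTCGCCAACCAGGAGAGCACCTGGCTAGGCCCCCC
ACCATGGGGCCTCACCGGGCCTGGGACTCGGGTGTGGATATTCAAGGAAGCTCACCGGCGACAACGCCGC
CTAAGGTTGTCATAACACTGGAAGAGCTTGATATTTAGGCAAGGGCGCCGATACTCCTGTCGCGGGCCGC
CGGGCTCCTTCCGGGTTAAAGAACACACACGGGAAGGCCAGCCCGCCAAGAACCCACGCGAACGGTGCCG
GGCGTGCCGCCTTCCGTTTGTTTTCCCCGAACCCACTGCGCGCGCCTTAGGTCCCGCTCAGACCTCGTAA
GATACCACACTGGCGGGTCGATGCACGGCGCTATGCTCGGCCACGCGGGGTTCGGCCGGCGCCGTTCGGG
CATCGGCCCCAGCTACGCGAGCAATGTGTAACGCGCTGGACCCCTTGGGACCTAACACCGGCTGAGGAGT
GGCCGACGACGCGCTCCCGCGCGGGGCCACTTTTTTCTGGCAAAGTATTCGGCCGATCAGTGCAAGGGGC
ACCCCCCCCCGGGCCACGATTAAACGACCCGGGGTAGCGCTTGGGAACGCCCCAACCGGTCCCGCGCCGA
TCAGCCCTTGCCAACCTACGGCGCTCTGGGTCCAGCCCGCGGTCGCAAATGGCGGTCGTTGCAGCCGACT
TACCGGTGCATGGAAGTGGCGCACCATGGCTCGGAATGTGGGGCCCAGGGGGTCGGAGGGCTGCGCCCTG
GAGCCACCACCTGCAGCCGGCCACGGCTCCGGTCGCAAGAGGTACACTTGCAAGTGGGCGCCGGGAATGG
CGCTCGCGCCCGTCAGCGAACGTGACTAATCCTCTGTCGGCCCTAGGGGCGCCACTGGGTCTCACGCGAT
GTAGCGGGGATCGGGAGCGTTGGTCGTGTTCGCTACCCTGATCGCTGACCTCGTTAGTTTTCAGCCCGCG
GACTACCACACAATCGCGGGGACGGGAGTGCACTCTCGGCCTGTTCGCATAGTGCCGGGCGCGTCGTTCC
AGAGCTAGGAGAATGCTCCCGTGGTCAGGTAACTGTGCCTAGCGGCGCCCCCGGTTAACGACGCCTAGGA
TTCGCTCTTGGGACGGACTAGGTGGTGGGGGGAGGCCCCATCGCGCCGGGGTACTTGTGTTCCCCTCGCT
AGCAGCTGCCCCATGGGCCGGTTCCGACAGAAGAGTCCGCCTTAACCGGGGCGAACCGGCGGAGGGCCGC
GGGACCCACACTGAGGTCTGGTCCGCATTGAACAAGTCTGACAACAAGCCCGACGGCGGGCAGCCTCCTG
CCAGGGATGACCCTCGCACCGATAGGGACCAATTCGCAGAGGGCACGGGCGGACAGGCGAACGCGGTCCT
GGGCACGCGGATCCGGCCACGTCCCGCGAAGGCCTCGCTGGACCTCGGCGGGCGCTGTCCCGGCCGCGTG
CC
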