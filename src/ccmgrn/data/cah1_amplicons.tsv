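# qPCR tiling panel of the Cah1 locus (periplasmic carbonic anhydrase,
# chromosome_4:1849052-1853308, Chlamydomonas reinhardtii genome v.4).
# Coordinates are 1-based inclusive, relative to the surveyed window around
# the locus (promoter through 3' downstream region).
# locus_window: 1-5100
amplicon	start	end	forward	reverse
A	660	729	TAGCCTTTCAAGCCGCGCCA	GCGTCAAACCTCCTTCCAACCG
B	804	867	GCCGGAACTCCAACCAAGTAGC	GCATTTCTGCATGCGCACAGT
C	937	1000	CCGCCGTACCGTTGTCACTTT	CGCAGGGTGTGGACAACTATGG
D	1574	1637	TAGGGCGATGAACGGTTCTGGT	TCCTTGCCCTCCCTGTATGTGG
E	2485	2545	TGGAGTGCGAGCACGCTTAGTA	CCAAGGCACCCAGATGCATGAC
F	2940	3008	GTTCCACTTCCACTCCACCTCG	AAAGTCAAGAGTTGCGCCCACG
G	3602	3663	CATCAAGCTGGGTGAGCTGCTG	TGAGGCTGCCCTCGTACGTTA
H	3719	3781	CATCAGCTTCGGCCAGTGGAAC	GTGGAGTTGCACTCCTTCAGGC
I	4714	4773	ATGGAGTTGGTTCCACGATGGG	ACGTCCGGCCCACTGACTTTAT
J	4996	5062	CTGTCTGGCTGGCTGGGTTGTT	TGCATTGATCGGCATGTGCGAC
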