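#name	consensus	category
ABRE	ACGTG	hormone
CGTCA-motif	CGTCA	hormone
TGACG-motif	TGACG	hormone
TCA	CCATCTTTTT	hormone
SARE	TTCGACCATCTT	hormone
TGA	AACGAC	hormone
AuxRR-core	GGTCCAT	hormone
P-box	CCTTTTG	hormone
TATC-box	TATCCCA	hormone
GARE-motif	TCTGTTG	hormone
MBS	CAACTG	stress
LTR	CCGAAA	stress
WUN-motif	AAATTTCCT	stress
TC-rich repeats	ATTTTCTTCA	stress
MSA-like	TCCAACGG	development
motif I	AGACGCCA	development
NON-box	AGATTCGACG	development
MBSI	AAAAAACGGTTA	development
RY-element	CATGCA	development
CAT-box	GCCACT	development
HD-Zip 1	CAATAATTG	development
circadian	CAANNNNATC	development
GCN4_motif	TGAGTCA	development
GC-motif	CCCCCG	other
ARE	AAACCA	other
O2-site	GATGACATGG	other
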