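# Default peptide-binding-region residue positions for MHC class I exon 3.
# 1-based codon indices on the 74-codon (222 bp) reading frame, chosen as a
# homology-motivated spread over the alpha-2 domain positions that contact
# bound peptide in the chicken class I structure.  These ship as data, not
# code: substitute your own list when an alignment-derived set is available
# for your study system.
5
7
9
22
24
25
33
36
45
55
59
60
63
66
70
73
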