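# Synthetic illustrative mitochondrial nucleotide-pool / POLG-discrimination
# table (liver-like): NOT measured values. rATP dominates the ribo pool and
# POLG discriminates rGTP least, so the composite expectation is rA-dominant
# with rG second — the qualitative pattern of solid-tissue mtDNA.
# Units are arbitrary but shared between the rntp and dntp columns.
base	rntp	dntp	df
A	3000	12	1500
C	300	30	2500
G	400	25	600
U	500	35	2000
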