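"""Reference junction motifs from the W-linked retrocopy clusters of
*Plutella xylostella*.

These short sequences are the published landmarks of the retrotransposition
event that created the W-linked *Pxyfem* copies of *PxyMasc*: the target-site
duplication left by the integrating LTR retrotransposon, the conserved
34-nt element adjacent to the long copies, the switch-point microhomologies
between the retrocopy and its LTR donors, and the tandemly duplicated
junction of the short copies. They serve as inputs to the junction tools and
as default flank motifs for the synthetic scaffold generator.
"""

# 10-bp direct repeat found immediately outside both flanks of the
# retroelement insertion (target-site duplication).
TSD_10BP = "ACACAAGGCT"

# 34-nt conserved but unidentified element adjacent to exon-7 end of the
# long retrocopies.
CONSERVED_34BP = "ACCCCAGCAGTTACATGTTGGGAAGCAGAAATTT"

# Exact switch-point microhomology shared by the target mRNA (exon 4 end)
# and the first LTR donor.
SWITCH_POINT_LTR1 = "ATTT"

# Inexact switch point of the short copies: the chimera carries AAGCAG,
# one substitution away from each donor window.
SWITCH_DONOR_MRNA = "AAGAAG"
SWITCH_DONOR_LTR2 = "AACCAG"
SWITCH_POINT_LTR2 = "AAGCAG"

# 34-nt junction sequence of the short copies containing a 15-bp tandem
# duplication (the unit occurs at positions 1 and 20).
TANDEM_JUNCTION_34NT = "AGTCTGCTGGTTAAGAAGAAGTCTGCTGGTTAAG"
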