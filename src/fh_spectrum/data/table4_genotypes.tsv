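# Genotype classes of the 82 genetically confirmed carriers in the community
# screening study: single-gene heterozygotes and double heterozygotes.
label	n_individuals
LDLR_het	26
APOB_het	18
PCSK9_het	32
LDLR+APOB_double	3
LDLR+PCSK9_double	1
APOB+PCSK9_double	2
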