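# Per-category subject counts from the same community screening study
# (5,130 adults screened): number of clinically diagnosed FH subjects per
# DLCN category and, of those, the number carrying at least one
# pathogenic/likely-pathogenic variant in LDLR, APOB or PCSK9.
category	n_subjects	n_pv_positive
potential	58	12
possible	314	70
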