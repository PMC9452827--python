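# Published maximum-entropy donor-site scores (wild type vs mutant) for the
# CLCNKB exon 2 boundary variants, with the percent change as printed.
hgvs_c	site_type	wt_score	mut_score	printed_pct
c.228A>C	donor	8.55	5.41	-36.73
c.229G>A	donor	8.55	2.25	-73.68
c.229G>C	donor	8.55	3.78	-55.79
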