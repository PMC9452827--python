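# Published in-silico annotations for the 14 candidate exonic variants:
# signed location in exon (+d from 5' end, -d from 3' end), counts of
# silencers gained / enhancers broken, and percent change of the splice-site
# score where the screen reported one.
gene_id	hgvs_c	protein	exon_number	exon_length	location_in_exon	ess_gained	ese_broken	dmaxent_donor_pct	dmaxent_acceptor_pct
SLC12A1	c.595C>T	p.Arg199Cys	3	76	-34	6	1
SLC12A1	c.728G>A	p.Gly243Glu	5	140	4	0	0
SLC12A1	c.735C>G	p.Tyr245*	5	140	11	1	5
SLC12A1	c.904C>T	p.Arg302Trp	6	111	40	1	6
SLC12A1	c.905G>A	p.Arg302Gln	6	111	41	2	6
SLC12A1	c.1010C>T	p.Ala337Val	7	112	35	6	2
SLC12A1	c.1304C>T	p.Ala435Val	10	152	4	2	2
SLC12A1	c.1493C>T	p.Ala498Val	11	108	41	5	2
SLC12A1	c.2221A>T	p.Lys741*	17	141	67	2	4		2438.46
CLCNKB	c.226C>T	p.Arg76*	2	129	-4	4	1
CLCNKB	c.228A>C	p.76Arg=	2	129	-2	0	0	-36.73
CLCNKB	c.229G>A	p.Ala77Thr	2	129	-1	0	0	-73.68
CLCNKB	c.229G>C	p.Ala77Pro	2	129	-1	0	0	-55.79
CLCNKB	c.1979C>A	p.Ser660*	18	87	-38	3	5		410.71
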