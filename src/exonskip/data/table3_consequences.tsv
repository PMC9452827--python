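# Published exon-skipping consequence annotations for the validated variants.
# aa_lost/codon_start/codon_end apply to in-frame skips; fs_annotation to
# frameshift skips (p.<aa><start><aa>fs*K with K = termination - start).
mutation	gene_id	exon_number	splicing_change	frame	aa_lost	codon_start	codon_end	fs_annotation	protein_note
c.728G>A	SLC12A1	5	partial skipping of exon 5	frameshift				p.Gly242Glyfs*2	truncated protein (NKCC2)
c.735C>G	SLC12A1	5	partial skipping of exon 5	frameshift				p.Gly242Glyfs*2	truncated protein (NKCC2)
c.904C>T	SLC12A1	6	partial skipping of exon 6	in-frame	37	289	325		37 aa loss in TMH4 and cytoplasmic topological domain (NKCC2)
c.905G>A	SLC12A1	6	partial skipping of exon 6	in-frame	37	289	325		37 aa loss in TMH4 and cytoplasmic topological domain (NKCC2)
c.1304C>T	SLC12A1	10	complete skipping of exon 10	frameshift				p.Gly434Glyfs*58	truncated protein (NKCC2)
c.1493C>T	SLC12A1	11	partial skipping of exon 11	in-frame	36	485	520		36 aa loss in TMH8 and cytoplasmic topological domain (NKCC2)
c.2221A>T	SLC12A1	17	complete skipping of exon 17	in-frame	47	719	765		47 aa loss between TMH11 and TMH12 (NKCC2)
c.226C>T	CLCNKB	2	partial skipping of exon 2	in-frame	43	34	77		43 aa loss in TMH1 (ClC-Kb)
c.228A>C	CLCNKB	2	partial skipping of exon 2	in-frame	43	34	77		43 aa loss in TMH1 (ClC-Kb)
c.229G>A	CLCNKB	2	partial skipping of exon 2	in-frame	43	34	77		43 aa loss in TMH1 (ClC-Kb)
c.229G>C	CLCNKB	2	partial skipping of exon 2	in-frame	43	34	77		43 aa loss in TMH1 (ClC-Kb)
c.1979C>A	CLCNKB	18	complete skipping of exon 18	in-frame	29	644	672		29 aa loss in cytoplasmic topological domain (ClC-Kb)
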