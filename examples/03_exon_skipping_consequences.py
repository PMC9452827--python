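"""Predict what skipping each candidate exon does to the protein.

An exon whose length is a multiple of 3 deletes whole codons when skipped
(in-frame loss of length/3 amino acids over the codon range it touches);
any other length shifts the downstream frame toward a premature stop.
"""

from exonskip import skip_exon
from exonskip.fixtures import load_table1, reference_models

models = reference_models()
seen = set()
for _, row in load_table1().iterrows():
    key = (row["gene_id"], int(row["exon_number"]))
    if key in seen:
        continue
    seen.add(key)
    c = skip_exon(models[key[0]], key[1])
    frame = "in-frame " if c.frame_preserved else "frameshift"
    extra = (f"{c.aa_lost} aa lost, codons {c.first_codon}-{c.last_codon}"
             if c.frame_preserved else c.annotation)
    print(f"{key[0]:8s} exon {key[1]:>2} ({c.exon_length:>3} nt): {frame}  {extra}")

# The 129-nt CLCNKB exon 2 deletes 43 residues (codons 34-77, part of the
# first transmembrane helix of ClC-Kb); the 140- and 152-nt SLC12A1 exons
# shift the frame — with downstream sequence attached the premature stop
# would be located too (p.<aa><start><aa>fs*K, K = stop - start).
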