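# Methods

## Scope and model of the problem

`exonskip` treats an exonic single-nucleotide substitution as a potential
splicing mutation through two mechanisms: weakening of the donor/acceptor
consensus when the variant lies at an exon boundary, and perturbation of
exonic splicing regulatory elements (ESEs/ESSs) anywhere in the exon. The
package implements the screening arithmetic around these mechanisms — exon
placement, score deltas, motif-count deltas, the candidate filter, the
protein-level consequence of the resulting exon skip, and quantification of
exon-trap validation assays. It does **not** model spliceosome kinetics,
branch points, cryptic-site activation, RNA secondary structure or NMD, and
it does not predict *whether* a candidate actually skips — that is what the
wet-lab assay decides.

## Coordinates

All positions are HGVS cDNA (c.) coordinates: 1-based, closed intervals,
c.1 = A of the start codon. Genomic coordinates and strand are deliberately
out of scope; every operation works in transcript space. Transcripts may be
partial: only the exons under study need spans, and nothing requires exon 1
or the full CDS. Exons with consecutive published numbers must be
contiguous in c. space (validated, since cDNA has no gaps); non-consecutive
modelled exons may leave gaps.

The signed "location in exon" reports the distance to the nearer exon end:
`+d` = d-th base from the 5' end, `−d` = d-th base from the 3' end, ties
report `+`. The boundary base itself is distance 1, so "within 4 bases"
means `min(offset5, offset3) ≤ 4` — consistent with a variant at the 4th
nucleotide being reported as `+4`.

**Anchor reconstruction.** An annotated variant (cDNA position, exon
number, exon length, signed location) pins its exon's span uniquely:
`c_start = pos − d + 1` for `+d`, `c_end = pos + d − 1` for `−d`. Multiple
anchors for one exon must agree exactly; contradictions are reported with
both offending anchors rather than resolved silently. This is how the
packaged annotation table is turned back into transcript models, and the
round-trip (re-deriving every printed location from the rebuilt models) is
asserted in the tests.

## Splice-site scoring

Two model kinds are exposed behind one interface:

- **PWM** (`kind="pwm"`): per-position nucleotide frequencies (columns sum
  to 1) with background frequencies; score = Σ log2(f/bg). Zero frequencies
  score −inf rather than raising — the window is simply incompatible.
- **k-mer table** (`kind="kmer"`): direct window→score lookup, the form in
  which maximum-entropy site models are distributed. Missing windows raise.

Window conventions default to donor = 3 exonic + 6 intronic nt, acceptor =
20 intronic + 3 exonic nt (both configurable), matching the common usage of
the popular scoring services. The neural-network and maximum-entropy
internals of those services are not reproduced — published scores are
consumed as inputs for delta arithmetic, and the PWM scorer serves
synthetic and user-supplied models.

Deltas: `delta = mut − wt`; `flagged_loss ⇔ delta < 0`; percent change =
`100·(mut − wt)/wt`, undefined (error) at wt = 0, rounded
half-away-from-zero to 2 d.p. for reporting. Rounding mode chosen to match
how such percentages are conventionally printed.

## Motif deltas

Motif sets are explicit k-mer lists (membership) or a PWM with threshold.
For an SNV only occurrences overlapping the variant position can change, so
`motif_delta` diffs the variant-overlapping hits between alleles:
WT-only = broken, mutant-only = gained, counted per role. The minimal
complete window is variant ± (k−1); callers supply any window at least that
wide. Overlapping occurrences of the same motif count separately; a motif
listed in two sets counts once per set. The `disruption_sum`
(broken ESEs + gained ESSs) is the filter's regulatory quantity. No
published motif database is bundled — annotated counts from screening
services are accepted as inputs, and synthetic sets (seeded random
hexamers, ≥20 per role by default) serve the tests.

## Triage

`selected ⇔ (min(offset5, offset3) ≤ 4) ∨ (ese_broken + ess_gained > 5)`.
"More than 5" is implemented strictly (> 5): the annotated table contains a
boundary row with sum exactly 5 that is consistent with selection by
proximity alone, and no row requires ≥. Both thresholds are parameters
(`TriageParams`). First/last exons can be dropped before filtering via an
optional `terminal_exon` flag — they cannot be tested in an exon-trap
construct. Decisions record their inputs and whether counts came from the
live scanner or were supplied.

## Skipping consequences

`frame_preserved ⇔ exon_length mod 3 = 0`. In-frame skips lose
`exon_length/3` residues over codons `ceil(c_start/3)…ceil(c_end/3)` — the
first/last codon *touched*, so an exon starting mid-codon reports the codon
it participates in. Hybrid codons formed at non-aligned in-frame junctions
are not translated (needs flanking sequence the model may not carry); the
loss count follows the length/3 convention.

Frameshift skips locate the premature stop when sequence allows: the first
affected codon is `ceil(c_start/3)` (its first 0–2 bases come unchanged
from the upstream exon), and the scan reads triplets from there through the
downstream exon sequences. Annotation `p.<wt_aa><start><new_aa>fs*K` uses
`K = termination − start` — note this counts the stop's offset from the
first frameshifted codon, which is how the validated annotations the
package ships are written (one less than the strict HGVS `fs*` count, which
numbers the fs codon itself as 1). A transcript with no in-frame stop
before the modelled sequence ends gets a `runs_through` flag instead.

## Minigene quantification

Products: inclusion = backbone + exon length, exclusion = backbone
(263 bp default, the conventional trap-vector product). Exclusion percent =
`100·lower/(lower+upper)` from band densitometry (scale-invariant;
undefined when both bands are zero). Group comparison is an unpaired
**pooled-variance** Student t-test, two-sided — pooled rather than Welch
because replicate groups are small (n = 3 default) equal-design assay
repeats; implemented over `scipy.stats.ttest_ind(equal_var=True)` with the
degenerate both-groups-constant case mapped to t = 0, p = 1 (equal means)
or p = 0 (unequal). Classification: **complete** when the mutant shows no
inclusion band (mean intensity below a detection fraction, default 1% of
total signal — gel bands below that are not reliably called); **partial**
when both products are present and mutant exclusion is significantly higher
(p < 0.05); otherwise **none**. Densitometry itself (image analysis) is out
of scope; intensities arrive as numbers.

Two printed wild-type product sizes in the source figures (405 bp for a
140-nt insert, 415 bp for a 108-nt insert) are inconsistent with
backbone + length; they are carried verbatim in the fixture, flagged
`caption_artifact`, and excluded from checks rather than reconciled.

## Synthetic data

The generator emulates the study design: multi-exon transcripts whose exon
lengths default to the assayed set (140/111/112/87/129 nt — a mix of
frame-preserving and frame-shifting lengths), planted donor/acceptor
consensus at junctions (strong/weak/broken tags; strong donors carry the
invariant GT), planted motifs at requested offsets, and n = 3 assay
replicates with additive Gaussian noise (default sd 1–2 percentage points,
the scale of careful gel densitometry) clipped to [0, 100].

Ground truth is recorded **during construction**: which planted/incidental
motif occurrences the chosen substitution destroys or creates is recounted
by direct substring membership inside the generator — an independent code
path from the scanner under test — and proximity/frame labels follow from
the chosen offsets and lengths. Pipeline-vs-truth recovery is asserted
exact (100% over ≥1000 cases), not statistical. What passing does *not*
show: real exons have biased composition, overlapping regulatory layers and
context-dependent motif activity; the synthetic landscape validates the
bookkeeping, not biological motif calling.

All generators take explicit seeds (numpy `default_rng`); identical seeds
give byte-identical output.

## Problem sizes and numerics

The shipped checks run in seconds: 14 annotated variants, 1000 synthetic
recovery cases, 200-case brute-force motif property sweeps, 100 random
t-test comparisons (agreement to 1e-9 absolute against the textbook pooled
formula). Percent-change equality checks are exact at the printed 2-d.p.
precision. Scores use double precision throughout; the only deliberate
rounding is the 2-d.p. reporting form.

## Known limitations

- No intronic variants, indels, or multi-nucleotide substitutions.
- Acceptor-side strength tags in the generator are minimal (polypyrimidine
  tract + AG) and not used by the shipped property tests.
- Frameshift stop-scanning requires contiguous downstream exon sequence in
  the model; otherwise the termination codon is reported unavailable.
- The filter's regulatory criterion uses only broken-ESE and gained-ESS
  counts; enhancer gains and silencer losses are computed but not
  thresholded, mirroring how the annotations it consumes are reported.
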