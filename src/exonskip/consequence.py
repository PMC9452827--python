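"""Transcript- and protein-level consequences of skipping one exon.

Skipping an exon whose length is a multiple of 3 deletes whole codons
(in-frame deletion of length/3 amino acids); any other length shifts the
downstream reading frame, typically reaching a premature termination codon
(PTC).

Codon coordinates follow the convention of the first/last codon *touched*
by the exon — ceil(c/3) of its boundary positions — so an exon that starts
mid-codon still reports the codon it participates in.  The in-frame
amino-acid loss count is length/3 (hybrid codons formed at a non-aligned
in-frame junction are not translated; that would require flanking
sequence).

Frameshift annotations use the convention ``p.<aa><start><aa>fs*K`` with
``K = termination_codon − start_codon``, i.e. the stop lands K codons after
the first frameshifted codon.
"""

from __future__ import annotations

from dataclasses import dataclass

from .gene_models import TranscriptModel

__all__ = [
    "SkippingConsequence",
    "TerminationResult",
    "skip_exon",
    "find_termination",
]

_STOP_CODONS = {"TAA", "TAG", "TGA"}

_AA3 = {
    "TTT": "Phe", "TTC": "Phe", "TTA": "Leu", "TTG": "Leu",
    "CTT": "Leu", "CTC": "Leu", "CTA": "Leu", "CTG": "Leu",
    "ATT": "Ile", "ATC": "Ile", "ATA": "Ile", "ATG": "Met",
    "GTT": "Val", "GTC": "Val", "GTA": "Val", "GTG": "Val",
    "TCT": "Ser", "TCC": "Ser", "TCA": "Ser", "TCG": "Ser",
    "CCT": "Pro", "CCC": "Pro", "CCA": "Pro", "CCG": "Pro",
    "ACT": "Thr", "ACC": "Thr", "ACA": "Thr", "ACG": "Thr",
    "GCT": "Ala", "GCC": "Ala", "GCA": "Ala", "GCG": "Ala",
    "TAT": "Tyr", "TAC": "Tyr", "TAA": "Ter", "TAG": "Ter",
    "CAT": "His", "CAC": "His", "CAA": "Gln", "CAG": "Gln",
    "AAT": "Asn", "AAC": "Asn", "AAA": "Lys", "AAG": "Lys",
    "GAT": "Asp", "GAC": "Asp", "GAA": "Glu", "GAG": "Glu",
    "TGT": "Cys", "TGC": "Cys", "TGA": "Ter", "TGG": "Trp",
    "CGT": "Arg", "CGC": "Arg", "CGA": "Arg", "CGG": "Arg",
    "AGT": "Ser", "AGC": "Ser", "AGA": "Arg", "AGG": "Arg",
    "GGT": "Gly", "GGC": "Gly", "GGA": "Gly", "GGG": "Gly",
}


def _codon_of(c_pos: int) -> int:
    """1-based codon index containing cDNA position c_pos (ceil(c/3))."""
    return (c_pos + 2) // 3


@dataclass(frozen=True)
class TerminationResult:
    """Location of the premature stop reached after a frameshift."""

    termination_codon: int | None
    fs_offset: int | None  # the K of fs*K; termination = start + K
    runs_through: bool


def find_termination(joined_cds_seq: str, frameshift_start_codon: int) -> TerminationResult:
    """Scan for the first in-frame stop after a frameshift.

    ``joined_cds_seq`` is the exon-skipped transcript sequence from the
    start of the first frameshifted codon onward; codons are read in
    triplets from its first base.  The stop found at the i-th scanned codon
    (1-based) is codon ``frameshift_start_codon + i − 1`` of the mutant
    protein, reported as fs*K with K = termination − start.  If no stop
    occurs before the sequence ends, the transcript "runs through" and both
    indices are None.
    """
    seq = joined_cds_seq.upper()
    for i in range(len(seq) // 3):
        codon = seq[3 * i : 3 * i + 3]
        if codon in _STOP_CODONS:
            termination = frameshift_start_codon + i
            return TerminationResult(
                termination_codon=termination,
                fs_offset=termination - frameshift_start_codon,
                runs_through=False,
            )
    return TerminationResult(termination_codon=None, fs_offset=None, runs_through=True)


@dataclass(frozen=True)
class SkippingConsequence:
    """Predicted outcome of removing one exon from the mature transcript."""

    exon_number: int
    exon_length: int
    frame_preserved: bool
    first_codon: int
    last_codon: int
    aa_lost: int | None  # exon_length // 3 for in-frame skips, else None
    annotation: str
    termination_codon: int | None = None
    fs_offset: int | None = None
    runs_through: bool = False

    def __post_init__(self) -> None:
        if self.frame_preserved:
            if self.aa_lost is None or self.aa_lost * 3 != self.exon_length:
                raise ValueError("in-frame skip must lose exon_length/3 amino acids")
            if self.last_codon - self.first_codon + 1 < self.aa_lost:
                raise ValueError("codon range narrower than amino acids lost")
        elif self.termination_codon is not None:
            if self.termination_codon != self.first_codon + self.fs_offset:
                raise ValueError("termination codon inconsistent with fs offset")


def _skipped_downstream_seq(t: TranscriptModel, exon_number: int) -> str | None:
    """Sequence of the skipped transcript from the first frameshifted codon
    onward, or None when the model lacks the sequence needed to build it.

    The first affected codon may begin up to two bases before the skipped
    exon; those bases come unchanged from the upstream exon.  Downstream
    exons must be modelled contiguously with sequence for the scan to be
    meaningful up to wherever the model ends.
    """
    skipped = t.exon(exon_number)
    codon_start_c = 3 * (_codon_of(skipped.c_start) - 1) + 1
    prefix_len = skipped.c_start - codon_start_c  # 0..2 bases from upstream exon

    prefix = ""
    if prefix_len > 0:
        ups = [e for e in t.exons if e.c_end == skipped.c_start - 1]
        if not ups or ups[0].sequence is None or ups[0].length < prefix_len:
            return None
        prefix = ups[0].sequence[-prefix_len:]

    downstream = [e for e in t.exons if e.c_start > skipped.c_end]
    if not downstream or downstream[0].c_start != skipped.c_end + 1:
        return None
    parts = []
    expect = skipped.c_end + 1
    for e in downstream:
        if e.c_start != expect or e.sequence is None:
            break
        parts.append(e.sequence)
        expect = e.c_end + 1
    if not parts:
        return None
    return prefix + "".join(parts)


def skip_exon(t: TranscriptModel, exon_number: int) -> SkippingConsequence:
    """Predict the consequence of skipping ``exon_number`` of ``t``.

    In-frame skips report the amino-acid loss and the codon range touched.
    Frameshift skips additionally locate the premature stop when the model
    carries enough sequence (the upstream codon remainder plus downstream
    exons); otherwise the termination codon is left unavailable (None).
    """
    exon = t.exon(exon_number)  # KeyError for unmodelled exons
    first_codon = _codon_of(exon.c_start)
    last_codon = _codon_of(exon.c_end)
    frame_preserved = exon.length % 3 == 0

    if frame_preserved:
        aa_lost = exon.length // 3
        return SkippingConsequence(
            exon_number=exon_number,
            exon_length=exon.length,
            frame_preserved=True,
            first_codon=first_codon,
            last_codon=last_codon,
            aa_lost=aa_lost,
            annotation=f"in-frame deletion (codon {first_codon}-{last_codon})",
        )

    seq = _skipped_downstream_seq(t, exon_number)
    if seq is None:
        return SkippingConsequence(
            exon_number=exon_number,
            exon_length=exon.length,
            frame_preserved=False,
            first_codon=first_codon,
            last_codon=last_codon,
            aa_lost=None,
            annotation=(
                f"frameshift from codon {first_codon} "
                f"(exon length {exon.length} = 3n+{exon.length % 3}); "
                "termination unavailable without sequence"
            ),
        )

    term = find_termination(seq, first_codon)
    if term.runs_through:
        annotation = f"frameshift from codon {first_codon}; no stop before model end"
    else:
        new_codon = seq[:3]
        new_aa = _AA3.get(new_codon, "Xaa")
        annotation = f"p.{new_aa}{first_codon}fs*{term.fs_offset}"
        # with WT sequence for the same codon, report the reference residue too
        wt = _wt_codon_seq(t, first_codon)
        if wt is not None:
            annotation = f"p.{_AA3.get(wt, 'Xaa')}{first_codon}{new_aa}fs*{term.fs_offset}"
    return SkippingConsequence(
        exon_number=exon_number,
        exon_length=exon.length,
        frame_preserved=False,
        first_codon=first_codon,
        last_codon=last_codon,
        aa_lost=None,
        annotation=annotation,
        termination_codon=term.termination_codon,
        fs_offset=term.fs_offset,
        runs_through=term.runs_through,
    )


def _wt_codon_seq(t: TranscriptModel, codon: int) -> str | None:
    """The wild-type codon's bases, if the modelled exons cover all three."""
    c_positions = range(3 * (codon - 1) + 1, 3 * codon + 1)
    bases = []
    for c in c_positions:
        found = None
        for e in t.exons:
            if e.contains(c) and e.sequence is not None:
                found = e.sequence[c - e.c_start]
                break
        if found is None:
            return None
        bases.append(found)
    return "".join(bases)
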