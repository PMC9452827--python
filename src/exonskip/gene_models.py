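"""Transcript models and cDNA-coordinate arithmetic for exonic variants.

All coordinates are HGVS c. positions: 1-based, closed intervals, counted on
the coding sequence with c.1 the A of the start codon.  Transcripts may be
partial — only the exons under study need to be modelled — and no genomic
(g.) or strand handling is attempted.

The "location in exon" convention used throughout reports the distance to
whichever exon end is nearer: a positive value ``+d`` is the 1-based distance
from the exon's 5' end, a negative value ``-d`` the distance from its 3' end;
ties report the positive form.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "ExonSpan",
    "TranscriptModel",
    "CdnaVariant",
    "ExonContext",
    "UnsupportedVariantError",
    "NotExonicError",
    "AnchorContradictionError",
    "parse_cdna_variant",
    "locate_in_exon",
    "build_model_from_anchors",
    "load_gene_model",
    "save_gene_model",
    "attach_sequences_from_fasta",
    "read_variants_tsv",
]

_VALID_BASES = frozenset("ACGT")

# c.<pos><ref>><alt>, single-nucleotide substitution only
_SNV_RE = re.compile(r"^c\.(\d+)([A-Za-z])>([A-Za-z])$")
_INTRONIC_RE = re.compile(r"^c\.\d+[+-]\d+")
_INDEL_RE = re.compile(r"(del|ins|dup|inv)", re.IGNORECASE)


class UnsupportedVariantError(ValueError):
    """HGVS string describes a variant class outside the supported scope."""


class NotExonicError(ValueError):
    """cDNA position does not fall inside any modelled exon."""


class AnchorContradictionError(ValueError):
    """Two anchors imply different spans for the same exon."""


@dataclass(frozen=True)
class ExonSpan:
    """One exon's span in cDNA (c.) coordinates, optionally with sequence.

    ``exon_number`` is the published biological index and need not start at 1.
    """

    exon_number: int
    c_start: int
    c_end: int
    sequence: str | None = None

    def __post_init__(self) -> None:
        if self.c_start < 1:
            raise ValueError(f"exon {self.exon_number}: c_start must be >= 1")
        if self.c_start > self.c_end:
            raise ValueError(
                f"exon {self.exon_number}: c_start {self.c_start} > c_end {self.c_end}"
            )
        if self.sequence is not None:
            seq = self.sequence.upper()
            object.__setattr__(self, "sequence", seq)
            if len(seq) != self.length:
                raise ValueError(
                    f"exon {self.exon_number}: sequence length {len(seq)} "
                    f"!= span length {self.length}"
                )
            if not set(seq) <= _VALID_BASES:
                bad = sorted(set(seq) - _VALID_BASES)
                raise ValueError(f"exon {self.exon_number}: non-ACGT bases {bad}")

    @property
    def length(self) -> int:
        return self.c_end - self.c_start + 1

    def contains(self, c_pos: int) -> bool:
        return self.c_start <= c_pos <= self.c_end


@dataclass(frozen=True)
class TranscriptModel:
    """Ordered exon structure of one transcript in CDS coordinates.

    Exons must be strictly increasing and non-overlapping in c. space; exons
    with consecutive published numbers must additionally be contiguous
    (cDNA has no gaps between adjacent exons).
    """

    gene_id: str
    exons: tuple[ExonSpan, ...]
    coding: bool = True

    def __post_init__(self) -> None:
        exons = tuple(sorted(self.exons, key=lambda e: e.c_start))
        object.__setattr__(self, "exons", exons)
        seen: set[int] = set()
        for prev, cur in zip(exons, exons[1:]):
            if cur.c_start <= prev.c_end:
                raise ValueError(
                    f"{self.gene_id}: exon {cur.exon_number} overlaps exon "
                    f"{prev.exon_number}"
                )
            if prev.exon_number >= cur.exon_number:
                raise ValueError(
                    f"{self.gene_id}: exon numbers not increasing with c position"
                )
            if cur.exon_number == prev.exon_number + 1 and cur.c_start != prev.c_end + 1:
                raise ValueError(
                    f"{self.gene_id}: adjacent exons {prev.exon_number}/"
                    f"{cur.exon_number} are not contiguous "
                    f"(c.{prev.c_end} then c.{cur.c_start})"
                )
        for e in exons:
            if e.exon_number in seen:
                raise ValueError(f"{self.gene_id}: duplicate exon {e.exon_number}")
            seen.add(e.exon_number)

    def exon(self, exon_number: int) -> ExonSpan:
        for e in self.exons:
            if e.exon_number == exon_number:
                return e
        raise KeyError(f"{self.gene_id}: exon {exon_number} is not modelled")

    def exon_at(self, c_pos: int) -> ExonSpan:
        for e in self.exons:
            if e.contains(c_pos):
                return e
        raise NotExonicError(
            f"{self.gene_id}: c.{c_pos} is not exonic in model "
            f"(modelled exons: {[e.exon_number for e in self.exons]})"
        )


@dataclass(frozen=True)
class CdnaVariant:
    """A single-nucleotide substitution in cDNA coordinates."""

    c_pos: int
    ref: str
    alt: str
    label: str
    gene_id: str = ""

    def __post_init__(self) -> None:
        if self.c_pos < 1:
            raise ValueError("c_pos must be >= 1")
        if self.ref not in _VALID_BASES or self.alt not in _VALID_BASES:
            raise ValueError(f"ref/alt must be A, C, G or T: {self.ref}>{self.alt}")
        if self.ref == self.alt:
            raise ValueError(f"ref equals alt ({self.ref}) — not a substitution")


@dataclass(frozen=True)
class ExonContext:
    """Placement of a cDNA position within its exon.

    ``offset5``/``offset3`` are 1-based distances from the exon's 5'/3' ends
    (so the first base of the exon has offset5 = 1 and the last has
    offset3 = 1); they always satisfy offset5 + offset3 = exon_length + 1.
    """

    exon_number: int
    exon_length: int
    offset5: int
    offset3: int

    def __post_init__(self) -> None:
        if self.offset5 < 1 or self.offset3 < 1:
            raise ValueError("offsets are 1-based and must be >= 1")
        if self.offset5 + self.offset3 != self.exon_length + 1:
            raise ValueError(
                f"offset5 {self.offset5} + offset3 {self.offset3} != "
                f"exon_length {self.exon_length} + 1"
            )

    @property
    def reported_location(self) -> int:
        """Signed location: +offset5 if it is the smaller distance, else -offset3."""
        if self.offset5 <= self.offset3:
            return self.offset5
        return -self.offset3

    @property
    def boundary_distance(self) -> int:
        """Distance to the nearer exon end (1 = terminal base)."""
        return min(self.offset5, self.offset3)


def parse_cdna_variant(hgvs: str, gene_id: str = "") -> CdnaVariant:
    """Parse an HGVS cDNA substitution such as ``c.728G>A``.

    Only exonic single-nucleotide substitutions are supported.  Intronic
    offsets (``c.N+M``/``c.N-M``), indels/duplications and non-ACGT bases are
    rejected with a message naming the unsupported class.
    """
    s = hgvs.strip()
    if _INTRONIC_RE.match(s):
        raise UnsupportedVariantError(
            f"{hgvs!r}: intronic-offset positions are not supported "
            "(exonic substitutions only)"
        )
    if _INDEL_RE.search(s):
        raise UnsupportedVariantError(
            f"{hgvs!r}: insertions/deletions/duplications are not supported "
            "(single-nucleotide substitutions only)"
        )
    m = _SNV_RE.match(s)
    if not m:
        raise UnsupportedVariantError(
            f"{hgvs!r}: not a parseable cDNA substitution (expected 'c.<pos><ref>><alt>')"
        )
    pos, ref, alt = int(m.group(1)), m.group(2).upper(), m.group(3).upper()
    if ref not in _VALID_BASES or alt not in _VALID_BASES:
        raise UnsupportedVariantError(
            f"{hgvs!r}: ambiguous or non-ACGT base ({ref}>{alt})"
        )
    if ref == alt:
        raise UnsupportedVariantError(f"{hgvs!r}: ref and alt are identical")
    return CdnaVariant(c_pos=pos, ref=ref, alt=alt, label=hgvs.strip(), gene_id=gene_id)


def locate_in_exon(v: CdnaVariant, t: TranscriptModel) -> ExonContext:
    """Place a variant within its exon, computing both end distances."""
    exon = t.exon_at(v.c_pos)
    return ExonContext(
        exon_number=exon.exon_number,
        exon_length=exon.length,
        offset5=v.c_pos - exon.c_start + 1,
        offset3=exon.c_end - v.c_pos + 1,
    )


Anchor = tuple[str, int, int, int]  # (hgvs label, exon_number, exon_length, reported_location)


def _span_from_anchor(label: str, exon_length: int, location: int) -> tuple[int, int]:
    v = parse_cdna_variant(label)
    if location == 0 or abs(location) > exon_length:
        raise ValueError(f"anchor {label}: location {location} outside exon of length {exon_length}")
    if location > 0:
        c_start = v.c_pos - location + 1
        c_end = c_start + exon_length - 1
    else:
        c_end = v.c_pos + (-location) - 1
        c_start = c_end - exon_length + 1
    if c_start < 1:
        raise ValueError(f"anchor {label}: implied c_start {c_start} < 1")
    return c_start, c_end


def build_model_from_anchors(
    anchors: Iterable[Anchor], gene_id: str = ""
) -> TranscriptModel:
    """Reconstruct exon c. spans from (variant, exon, length, location) anchors.

    Each anchor pins one exon: from the variant's cDNA position and its
    reported signed location the span is solved directly.  Multiple anchors
    for the same exon must agree; a disagreement raises
    :class:`AnchorContradictionError` naming both anchors.
    """
    spans: dict[int, tuple[int, int]] = {}
    witness: dict[int, Anchor] = {}
    for anchor in anchors:
        label, exon_number, exon_length, location = anchor
        span = _span_from_anchor(label, exon_length, location)
        if exon_number in spans:
            if spans[exon_number] != span:
                raise AnchorContradictionError(
                    f"exon {exon_number}: anchor {witness[exon_number]!r} implies "
                    f"span {spans[exon_number]}, but anchor {anchor!r} implies {span}"
                )
        else:
            spans[exon_number] = span
            witness[exon_number] = anchor
    exons = tuple(
        ExonSpan(exon_number=n, c_start=s, c_end=e)
        for n, (s, e) in sorted(spans.items())
    )
    return TranscriptModel(gene_id=gene_id, exons=exons)


# ---------------------------------------------------------------------------
# File I/O: gene-model JSON, exon FASTA, variant TSV
# ---------------------------------------------------------------------------

def save_gene_model(t: TranscriptModel, path: str | Path) -> None:
    payload = {
        "gene_id": t.gene_id,
        "coding": t.coding,
        "exons": [
            {
                "exon_number": e.exon_number,
                "c_start": e.c_start,
                "c_end": e.c_end,
                **({"sequence": e.sequence} if e.sequence is not None else {}),
            }
            for e in t.exons
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def load_gene_model(path: str | Path) -> TranscriptModel:
    payload = json.loads(Path(path).read_text())
    exons = tuple(
        ExonSpan(
            exon_number=int(e["exon_number"]),
            c_start=int(e["c_start"]),
            c_end=int(e["c_end"]),
            sequence=e.get("sequence"),
        )
        for e in payload["exons"]
    )
    return TranscriptModel(
        gene_id=payload["gene_id"], exons=exons, coding=payload.get("coding", True)
    )


def attach_sequences_from_fasta(t: TranscriptModel, fasta: str | Path) -> TranscriptModel:
    """Attach exon sequences from a FASTA whose records are named
    ``<gene_id>|exon<N>``; records for unmodelled exons are ignored."""
    from Bio import SeqIO

    by_name = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta), "fasta")}
    exons = []
    for e in t.exons:
        key = f"{t.gene_id}|exon{e.exon_number}"
        seq = by_name.get(key, e.sequence)
        exons.append(ExonSpan(e.exon_number, e.c_start, e.c_end, sequence=seq))
    return TranscriptModel(gene_id=t.gene_id, exons=tuple(exons), coding=t.coding)


def read_variants_tsv(path: str | Path) -> list[CdnaVariant]:
    """Read variants from a TSV with columns ``gene_id`` and ``hgvs_c``."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", comment="#")
    out = []
    for i, row in df.iterrows():
        try:
            out.append(parse_cdna_variant(str(row["hgvs_c"]), gene_id=str(row["gene_id"])))
        except UnsupportedVariantError as exc:
            raise UnsupportedVariantError(f"row {i}: {exc}") from exc
    return out
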