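"""Scanning for exonic splicing regulatory motifs and SNV-induced deltas.

Exonic splicing enhancers (ESEs) and silencers (ESSs) are short exonic
k-mers bound by SR proteins and hnRNPs; a point mutation can destroy an
overlapping enhancer or create a new silencer, shifting the balance of
signals the spliceosome integrates when recognising the exon.

A motif set is either an explicit k-mer list (membership test) or a weight
matrix with a score threshold.  ``motif_delta`` counts, per regulatory role,
the motif occurrences overlapping the variant position that are present in
the wild-type window but not the mutant (broken) and vice versa (gained).
Only variant-overlapping occurrences can change under an SNV, so only those
are counted.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "MotifSet",
    "MotifDelta",
    "scan_hits",
    "motif_delta",
    "load_motif_set",
    "save_motif_set",
]

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}


@dataclass(frozen=True)
class MotifSet:
    """A named set of fixed-length splicing-regulatory motifs.

    ``role`` is "enhancer" or "silencer".  ``kind`` selects the hit test:
    "kmer" (window is a member of ``entries``) or "pwm" (window's log2-odds
    PWM score reaches ``threshold``).
    """

    name: str
    role: str
    k: int
    kind: str = "kmer"
    entries: frozenset[str] = frozenset()
    matrix: np.ndarray | None = None
    background: np.ndarray | None = None
    threshold: float | None = None

    def __post_init__(self) -> None:
        if self.role not in ("enhancer", "silencer"):
            raise ValueError(f"role must be enhancer|silencer, got {self.role!r}")
        if self.kind == "kmer":
            entries = frozenset(e.upper() for e in self.entries)
            object.__setattr__(self, "entries", entries)
            if any(len(e) != self.k for e in entries):
                raise ValueError(f"{self.name}: all k-mers must have length {self.k}")
            if any(set(e) - set(_BASES) for e in entries):
                raise ValueError(f"{self.name}: k-mers must be over ACGT")
        elif self.kind == "pwm":
            if self.matrix is None or self.threshold is None:
                raise ValueError("pwm kind requires matrix and threshold")
            m = np.asarray(self.matrix, dtype=float)
            object.__setattr__(self, "matrix", m)
            bg = (
                np.full(4, 0.25)
                if self.background is None
                else np.asarray(self.background, dtype=float)
            )
            object.__setattr__(self, "background", bg)
            if m.shape != (4, self.k):
                raise ValueError(f"{self.name}: matrix shape {m.shape} != (4, {self.k})")
        else:
            raise ValueError(f"kind must be kmer|pwm, got {self.kind!r}")

    def matches(self, window: str) -> bool:
        """Hit test for one k-length window."""
        window = window.upper()
        if len(window) != self.k:
            raise ValueError(f"window length {len(window)} != k {self.k}")
        if self.kind == "kmer":
            return window in self.entries
        idx = [_BASE_INDEX[b] for b in window]
        w = self.matrix[idx, range(self.k)]
        bg = self.background[idx]
        with np.errstate(divide="ignore"):
            return float(np.sum(np.log2(w / bg))) >= self.threshold


def scan_hits(mset: MotifSet, seq: str) -> list[tuple[int, str]]:
    """All motif occurrences in ``seq`` as (0-based offset, motif) pairs.

    For k-mer sets the motif is the matching k-mer itself; for PWM sets it
    is the set name (one matrix = one motif).  Ordered by offset; empty when
    the sequence is shorter than k.
    """
    seq = seq.upper()
    hits: list[tuple[int, str]] = []
    for off in range(len(seq) - mset.k + 1):
        window = seq[off : off + mset.k]
        if mset.matches(window):
            hits.append((off, window if mset.kind == "kmer" else mset.name))
    return hits


@dataclass(frozen=True)
class MotifDelta:
    """Per-role counts of motif occurrences broken/gained by one SNV.

    ``disruption_sum`` (broken enhancers + gained silencers) is the quantity
    the candidate-selection filter thresholds: both addends push the exon
    toward being skipped.
    """

    ese_broken: int = 0
    ese_gained: int = 0
    ess_broken: int = 0
    ess_gained: int = 0

    def __post_init__(self) -> None:
        for f in ("ese_broken", "ese_gained", "ess_broken", "ess_gained"):
            if getattr(self, f) < 0:
                raise ValueError(f"{f} must be >= 0")

    @property
    def disruption_sum(self) -> int:
        return self.ese_broken + self.ess_gained


def _as_sets(x: MotifSet | Iterable[MotifSet]) -> list[MotifSet]:
    return [x] if isinstance(x, MotifSet) else list(x)


def _overlapping(hits: Iterable[tuple[int, str]], pos: int, k: int) -> set[tuple[int, str]]:
    return {(off, m) for off, m in hits if off <= pos <= off + k - 1}


def motif_delta(
    ese: MotifSet | Sequence[MotifSet],
    ess: MotifSet | Sequence[MotifSet],
    wt_seq: str,
    mut_seq: str,
    variant_offset: int,
) -> MotifDelta:
    """Count motif occurrences broken and gained at an SNV.

    ``wt_seq`` and ``mut_seq`` are equal-length windows around the variant
    (identical except possibly at ``variant_offset``, 0-based).  For each
    motif set, occurrences overlapping the variant are diffed between
    alleles: present in WT only = broken, present in mutant only = gained.
    Overlapping occurrences of one motif count separately; a motif listed in
    two sets counts once per set.
    """
    wt_seq, mut_seq = wt_seq.upper(), mut_seq.upper()
    if len(wt_seq) != len(mut_seq):
        raise ValueError(
            f"window length mismatch: {len(wt_seq)} vs {len(mut_seq)}"
        )
    if not 0 <= variant_offset < len(wt_seq):
        raise ValueError(f"variant_offset {variant_offset} outside window")
    diffs = [i for i, (a, b) in enumerate(zip(wt_seq, mut_seq)) if a != b]
    if diffs and diffs != [variant_offset]:
        raise ValueError(
            f"windows differ at positions {diffs}, expected only {variant_offset}"
        )

    counts = {"ese_broken": 0, "ese_gained": 0, "ess_broken": 0, "ess_gained": 0}
    for role_key, sets in (("ese", _as_sets(ese)), ("ess", _as_sets(ess))):
        for mset in sets:
            wt_hits = _overlapping(scan_hits(mset, wt_seq), variant_offset, mset.k)
            mut_hits = _overlapping(scan_hits(mset, mut_seq), variant_offset, mset.k)
            counts[f"{role_key}_broken"] += len(wt_hits - mut_hits)
            counts[f"{role_key}_gained"] += len(mut_hits - wt_hits)
    return MotifDelta(**counts)


# ---------------------------------------------------------------------------
# File I/O — header "#name role k kind [threshold]", then one k-mer per line
# (kmer kind) or rows A/C/G/T and optional background (pwm kind).
# ---------------------------------------------------------------------------

def save_motif_set(mset: MotifSet, path: str | Path) -> None:
    header = f"#{mset.name} {mset.role} {mset.k} {mset.kind}"
    if mset.kind == "pwm":
        header += f" {mset.threshold!r}"
        body = [
            b + "\t" + "\t".join(repr(float(x)) for x in mset.matrix[i])
            for i, b in enumerate(_BASES)
        ]
        body.append("background\t" + "\t".join(repr(float(x)) for x in mset.background))
    else:
        body = sorted(mset.entries)
    Path(path).write_text("\n".join([header, *body]) + "\n")


def load_motif_set(path: str | Path) -> MotifSet:
    lines = [ln for ln in Path(path).read_text().splitlines() if ln.strip()]
    if not lines or not lines[0].startswith("#"):
        raise ValueError(f"{path}: missing '#name role k kind' header")
    head = lines[0][1:].split()
    name, role, k, kind = head[0], head[1], int(head[2]), head[3]
    if kind == "kmer":
        return MotifSet(name=name, role=role, k=k, kind="kmer", entries=frozenset(lines[1:]))
    threshold = float(head[4])
    rows: dict[str, list[float]] = {}
    for ln in lines[1:]:
        fields = ln.split("\t")
        rows[fields[0]] = [float(x) for x in fields[1:]]
    return MotifSet(
        name=name,
        role=role,
        k=k,
        kind="pwm",
        matrix=np.array([rows[b] for b in _BASES]),
        background=np.array(rows["background"]) if "background" in rows else None,
        threshold=threshold,
    )
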