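"""Synthetic transcripts, variants and assay replicates with known truth.

Every stage of the pipeline can be exercised without downloads: this module
generates transcripts with planted splice-site consensus sequences and
regulatory motifs, variant cases whose expected triage and skipping
outcomes are recorded *during construction* (constructive bookkeeping via a
direct substring recount — an independent code path from the scanner under
test), and noisy densitometry replicates around a known exclusion
percentage.

All generators are deterministic in their seed.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .gene_models import CdnaVariant, ExonSpan, TranscriptModel
from .minigene import BandQuant
from .motif_scan import MotifSet

__all__ = [
    "SyntheticGeneSpec",
    "SyntheticTranscript",
    "PlantedMotif",
    "VariantCase",
    "make_transcript",
    "make_motif_sets",
    "make_donor_pwm",
    "make_variant_cases",
    "make_assay_replicates",
    "emit_bundle",
]

_BASES = "ACGT"

# Donor consensus around the exon|intron junction: 3 exonic nt then the
# invariant GT and four further intronic nt (MAG|GTRAGT pattern).
_DONOR_STRONG = "CAGGTAAGT"
_DONOR_WEAK = "AATGTCTTT"
_DONOR_BROKEN = "CAGGAAAGT"  # GT destroyed


@dataclass(frozen=True)
class PlantedMotif:
    """One motif occurrence written into a generated exon (0-based offset)."""

    exon_number: int
    offset: int
    motif: str
    role: str  # "enhancer" | "silencer"


@dataclass(frozen=True)
class SyntheticGeneSpec:
    """Recipe for one synthetic transcript.

    ``planted_donors``/``planted_acceptors`` map exon number to a strength
    tag (strong|weak|broken) controlling the junction consensus written at
    that exon's 3'/5' flank.  Motif offsets are 0-based within the exon.
    """

    gene_id: str
    exon_lengths: tuple[int, ...]
    cds_offset: int = 0  # c. position of the first modelled base, minus 1
    planted_donors: dict[int, str] = field(default_factory=dict)
    planted_acceptors: dict[int, str] = field(default_factory=dict)
    planted_motifs: tuple[PlantedMotif, ...] = ()
    first_exon_number: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if any(l < 1 for l in self.exon_lengths):
            raise ValueError("exon lengths must be >= 1")
        n = len(self.exon_lengths)
        for pm in self.planted_motifs:
            idx = pm.exon_number - self.first_exon_number
            if not 0 <= idx < n:
                raise ValueError(f"planted motif on unmodelled exon {pm.exon_number}")
            if not 0 <= pm.offset <= self.exon_lengths[idx] - len(pm.motif):
                raise ValueError(
                    f"motif {pm.motif!r} at offset {pm.offset} overruns exon {pm.exon_number}"
                )


@dataclass(frozen=True)
class SyntheticTranscript:
    """A generated transcript plus the truth recorded while building it."""

    model: TranscriptModel
    donor_flanks: dict[int, str]  # exon_number -> 6 intronic nt after the exon
    acceptor_flanks: dict[int, str]  # exon_number -> 20 intronic nt before it
    planted: tuple[PlantedMotif, ...]
    spec: SyntheticGeneSpec

    def donor_window(self, exon_number: int) -> str:
        """3 exonic + 6 intronic nt around the exon's donor junction."""
        exon = self.model.exon(exon_number)
        return exon.sequence[-3:] + self.donor_flanks[exon_number]


def make_transcript(spec: SyntheticGeneSpec) -> SyntheticTranscript:
    """Generate a transcript with sequences honouring the planted features.

    Exon spans are contiguous cumulative sums starting at c.(cds_offset+1).
    Two planted motifs that overlap with conflicting bases raise an error
    naming both.  Identical seeds give identical output.
    """
    rng = np.random.default_rng(spec.seed)
    exons: list[ExonSpan] = []
    c = spec.cds_offset + 1
    donor_flanks: dict[int, str] = {}
    acceptor_flanks: dict[int, str] = {}

    for i, length in enumerate(spec.exon_lengths):
        number = spec.first_exon_number + i
        seq = list(rng.choice(list(_BASES), size=length))
        fixed: dict[int, tuple[str, PlantedMotif]] = {}
        for pm in spec.planted_motifs:
            if pm.exon_number != number:
                continue
            for j, base in enumerate(pm.motif.upper()):
                pos = pm.offset + j
                if pos in fixed and fixed[pos][0] != base:
                    raise ValueError(
                        f"motif collision in exon {number} at offset {pos}: "
                        f"{fixed[pos][1]} vs {pm}"
                    )
                fixed[pos] = (base, pm)
                seq[pos] = base
        # donor strength tag fixes the last 3 exonic nt and the intronic flank
        tag = spec.planted_donors.get(number)
        consensus = {"strong": _DONOR_STRONG, "weak": _DONOR_WEAK, "broken": _DONOR_BROKEN}
        if tag is not None:
            site = consensus[tag]
            if length >= 3:
                seq[-3:] = list(site[:3])
            donor_flanks[number] = site[3:]
        else:
            donor_flanks[number] = "".join(rng.choice(list(_BASES), size=6))
        atag = spec.planted_acceptors.get(number)
        if atag is not None:
            # polypyrimidine tract then the invariant AG for a strong site
            tract = "".join(rng.choice(["C", "T"], size=18)) + "AG"
            acceptor_flanks[number] = tract if atag == "strong" else (
                "".join(rng.choice(list(_BASES), size=18)) + ("AG" if atag == "weak" else "AA")
            )
        else:
            acceptor_flanks[number] = "".join(rng.choice(list(_BASES), size=20))
        exons.append(ExonSpan(number, c, c + length - 1, sequence="".join(seq)))
        c += length

    model = TranscriptModel(gene_id=spec.gene_id, exons=tuple(exons))
    return SyntheticTranscript(
        model=model,
        donor_flanks=donor_flanks,
        acceptor_flanks=acceptor_flanks,
        planted=spec.planted_motifs,
        spec=spec,
    )


def make_motif_sets(
    seed: int, n_ese: int = 20, n_ess: int = 20, k: int = 6
) -> tuple[MotifSet, MotifSet]:
    """Disjoint random hexamer (by default) enhancer and silencer sets."""
    rng = np.random.default_rng(seed)
    kmers: set[str] = set()
    while len(kmers) < n_ese + n_ess:
        kmers.add("".join(rng.choice(list(_BASES), size=k)))
    ordered = sorted(kmers)
    rng.shuffle(ordered)
    return (
        MotifSet(name="syn-ese", role="enhancer", k=k, entries=frozenset(ordered[:n_ese])),
        MotifSet(name="syn-ess", role="silencer", k=k, entries=frozenset(ordered[n_ese : n_ese + n_ess])),
    )


def make_donor_pwm(seed: int, n_sites: int = 200, pseudocount: float = 0.01):
    """A donor PWM trained on sampled GT-containing junction windows.

    Every training window carries the invariant GT at intronic positions
    1–2; other positions are drawn near the donor consensus.  Returns a
    :class:`~exonskip.splice_scoring.SpliceSiteModel` of kind "pwm" with a
    (3 exonic, 6 intronic) window.
    """
    from .splice_scoring import SpliceSiteModel

    rng = np.random.default_rng(seed)
    counts = np.zeros((4, 9))
    base_idx = {b: i for i, b in enumerate(_BASES)}
    for _ in range(n_sites):
        window = [
            rng.choice(list(_BASES)) if rng.random() < 0.4 else c
            for c in _DONOR_STRONG
        ]
        window[3], window[4] = "G", "T"  # invariant dinucleotide
        for pos, b in enumerate(window):
            counts[base_idx[b], pos] += 1
    freq = (counts + pseudocount) / (counts + pseudocount).sum(axis=0)
    return SpliceSiteModel(
        site_type="donor",
        kind="pwm",
        window=(3, 6),
        matrix=freq,
        background=np.full(4, 0.25),
    )


# ---------------------------------------------------------------------------
# Variant cases with constructive ground truth
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VariantCase:
    """A generated SNV with labels recorded at construction time."""

    variant: CdnaVariant
    exon_number: int
    exon_length: int
    offset5: int
    offset3: int
    wt_window: str
    mut_window: str
    window_offset: int  # variant position within the windows (0-based)
    expected_ese_broken: int
    expected_ese_gained: int
    expected_ess_broken: int
    expected_ess_gained: int
    expected_by_proximity: bool
    expected_by_regulatory: bool
    expected_selected: bool
    expected_frame_preserved: bool
    expected_aa_lost: int | None


def _overlap_hits_bruteforce(seq: str, pos: int, kmers: frozenset[str], k: int) -> set[tuple[int, str]]:
    # direct substring membership, independent of motif_scan.scan_hits
    hits = set()
    for off in range(max(0, pos - k + 1), min(len(seq) - k, pos) + 1):
        w = seq[off : off + k]
        if w in kmers:
            hits.add((off, w))
    return hits


def make_variant_cases(
    st: SyntheticTranscript,
    n: int,
    seed: int,
    ese: MotifSet,
    ess: MotifSet,
    max_boundary_distance: int = 4,
    disruption_threshold: int = 5,
) -> list[VariantCase]:
    """Generate ``n`` labelled SNV cases on a synthetic transcript.

    Positions are drawn with a bias toward exon boundaries and planted
    motifs so both selection criteria are exercised.  Expected motif deltas
    are recounted by brute-force substring membership on the constructed
    windows; expected triage booleans follow from the chosen offsets and
    those counts; expected skipping outcomes follow from the exon length.
    None of the labels is produced by the pipeline under test.
    """
    rng = np.random.default_rng(seed)
    exons = st.model.exons
    k = max(ese.k, ess.k)
    cases: list[VariantCase] = []
    for _ in range(n):
        exon = exons[rng.integers(len(exons))]
        mode = rng.random()
        if mode < 0.3:  # near a boundary
            d = int(rng.integers(1, max_boundary_distance + 2))
            pos0 = d - 1 if rng.random() < 0.5 else exon.length - d
            pos0 = min(max(pos0, 0), exon.length - 1)
        elif mode < 0.6 and st.planted:  # on a planted motif, when any exists
            pm = st.planted[int(rng.integers(len(st.planted)))]
            ex = st.model.exon(pm.exon_number)
            exon = ex
            pos0 = pm.offset + int(rng.integers(len(pm.motif)))
        else:
            pos0 = int(rng.integers(exon.length))
        ref = exon.sequence[pos0]
        alt = str(rng.choice([b for b in _BASES if b != ref]))
        c_pos = exon.c_start + pos0

        w_start = max(0, pos0 - (k - 1))
        w_end = min(exon.length, pos0 + k)
        wt_window = exon.sequence[w_start:w_end]
        window_offset = pos0 - w_start
        mut_window = wt_window[:window_offset] + alt + wt_window[window_offset + 1 :]

        wt_ese = _overlap_hits_bruteforce(wt_window, window_offset, ese.entries, ese.k)
        mut_ese = _overlap_hits_bruteforce(mut_window, window_offset, ese.entries, ese.k)
        wt_ess = _overlap_hits_bruteforce(wt_window, window_offset, ess.entries, ess.k)
        mut_ess = _overlap_hits_bruteforce(mut_window, window_offset, ess.entries, ess.k)
        ese_broken = len(wt_ese - mut_ese)
        ese_gained = len(mut_ese - wt_ese)
        ess_broken = len(wt_ess - mut_ess)
        ess_gained = len(mut_ess - wt_ess)

        offset5 = pos0 + 1
        offset3 = exon.length - pos0
        by_prox = min(offset5, offset3) <= max_boundary_distance
        by_reg = ese_broken + ess_gained > disruption_threshold
        cases.append(
            VariantCase(
                variant=CdnaVariant(
                    c_pos=c_pos,
                    ref=ref,
                    alt=alt,
                    label=f"c.{c_pos}{ref}>{alt}",
                    gene_id=st.model.gene_id,
                ),
                exon_number=exon.exon_number,
                exon_length=exon.length,
                offset5=offset5,
                offset3=offset3,
                wt_window=wt_window,
                mut_window=mut_window,
                window_offset=window_offset,
                expected_ese_broken=ese_broken,
                expected_ese_gained=ese_gained,
                expected_ess_broken=ess_broken,
                expected_ess_gained=ess_gained,
                expected_by_proximity=by_prox,
                expected_by_regulatory=by_reg,
                expected_selected=by_prox or by_reg,
                expected_frame_preserved=exon.length % 3 == 0,
                expected_aa_lost=exon.length // 3 if exon.length % 3 == 0 else None,
            )
        )
    return cases


def make_assay_replicates(
    true_exclusion: float, noise_sd: float, n: int, seed: int
) -> list[BandQuant]:
    """Replicate band quantifications around a known exclusion percentage.

    Each replicate's exclusion percent is true_exclusion plus Gaussian
    noise, clipped to [0, 100]; intensities are emitted on a 0–100 scale
    (lower = exclusion percent, upper = remainder)."""
    if not 0 <= true_exclusion <= 100:
        raise ValueError("true_exclusion must be within [0, 100]")
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    e = np.clip(true_exclusion + rng.normal(0.0, noise_sd, size=n), 0.0, 100.0)
    return [BandQuant(upper=float(100.0 - x), lower=float(x)) for x in e]


# ---------------------------------------------------------------------------
# File emission (the same formats the pipeline consumes)
# ---------------------------------------------------------------------------

def emit_bundle(out_dir: str | Path, seed: int, n_cases: int = 50) -> dict[str, Path]:
    """Write a self-consistent synthetic input bundle to ``out_dir``.

    Emits a gene-model JSON, exon FASTA, annotated variant TSV (triage
    input), motif-set files and a band-intensity TSV; returns the paths.
    """
    from .gene_models import save_gene_model

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    ese, ess = make_motif_sets(seed)
    lengths = tuple(int(rng.integers(60, 180)) for _ in range(4))
    planted = []
    for i, L in enumerate(lengths):
        motif = sorted(ese.entries)[int(rng.integers(len(ese.entries)))]
        planted.append(PlantedMotif(exon_number=i + 1, offset=int(rng.integers(0, L - 6)), motif=motif, role="enhancer"))
    spec = SyntheticGeneSpec(
        gene_id="SYNGENE", exon_lengths=lengths, planted_motifs=tuple(planted), seed=seed
    )
    st = make_transcript(spec)
    cases = make_variant_cases(st, n_cases, seed + 1, ese, ess)

    paths: dict[str, Path] = {}
    paths["gene_model"] = out / "gene_model.json"
    save_gene_model(st.model, paths["gene_model"])

    paths["fasta"] = out / "exons.fasta"
    with open(paths["fasta"], "w") as fh:
        for e in st.model.exons:
            fh.write(f">{st.model.gene_id}|exon{e.exon_number}\n{e.sequence}\n")

    paths["variants"] = out / "variants.tsv"
    with open(paths["variants"], "w") as fh:
        fh.write(
            "gene_id\thgvs_c\texon_number\texon_length\tlocation_in_exon\t"
            "ese_broken\tess_gained\n"
        )
        for case in cases:
            loc = case.offset5 if case.offset5 <= case.offset3 else -case.offset3
            fh.write(
                f"{case.variant.gene_id}\t{case.variant.label}\t{case.exon_number}\t"
                f"{case.exon_length}\t{loc}\t{case.expected_ese_broken}\t"
                f"{case.expected_ess_gained}\n"
            )

    from .motif_scan import save_motif_set

    paths["ese"] = out / "ese_motifs.txt"
    paths["ess"] = out / "ess_motifs.txt"
    save_motif_set(ese, paths["ese"])
    save_motif_set(ess, paths["ess"])

    paths["bands"] = out / "band_intensities.tsv"
    with open(paths["bands"], "w") as fh:
        fh.write("construct_id\tgroup\treplicate\tupper\tlower\n")
        for cid, (wt_e, mut_e) in {"ex2": (55.0, 85.0), "ex3": (40.0, 41.0)}.items():
            for group, true_e in (("WT", wt_e), ("MUT", mut_e)):
                reps = make_assay_replicates(true_e, 2.0, 3, seed + hash((cid, group)) % 1000)
                for j, q in enumerate(reps, 1):
                    fh.write(f"{cid}\t{group}\t{j}\t{q.upper:.4f}\t{q.lower:.4f}\n")
    return paths


def digest(values: Sequence[str]) -> str:
    """Stable digest of a sequence of strings (determinism checks)."""
    h = hashlib.sha256()
    for v in values:
        h.update(v.encode())
        h.update(b"\0")
    return h.hexdigest()
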