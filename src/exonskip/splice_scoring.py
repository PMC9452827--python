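"""Splice-site strength scoring and wild-type → mutant deltas.

Two pluggable model kinds score a fixed-width window straddling an
exon–intron junction:

* ``pwm`` — a position weight matrix of per-position nucleotide frequencies
  with background frequencies; the score is the log2 odds summed over
  positions, the conventional PWM score.
* ``kmer`` — a lookup table mapping every admissible window to a
  pre-computed score (the form in which maximum-entropy splice models are
  usually distributed).

Window conventions default to 3 exonic + 6 intronic nt for donor (5'
splice) sites and 20 intronic + 3 exonic nt for acceptor (3' splice) sites.

A mutant-minus-wild-type score delta below zero flags a potential loss of
the site; deltas are also expressed as percent change of the wild-type
score, which is how such changes are conventionally reported.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import numpy as np

__all__ = [
    "SpliceSiteModel",
    "SiteScoreDelta",
    "MissingKmerError",
    "ZeroBaselineError",
    "score_site",
    "site_delta",
    "delta_from_scores",
    "percent_change",
    "round_half_away",
    "load_pwm_tsv",
    "save_pwm_tsv",
    "load_kmer_table",
]

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}

DONOR_WINDOW = (3, 6)
ACCEPTOR_WINDOW = (20, 3)


class MissingKmerError(KeyError):
    """Window absent from a k-mer score table."""


class ZeroBaselineError(ZeroDivisionError):
    """Percent change is undefined for a zero wild-type score."""


def round_half_away(x: float, ndigits: int = 2) -> float:
    """Round with ties going away from zero (the convention used when
    percentages are printed to 2 decimal places)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class SpliceSiteModel:
    """A donor or acceptor scoring model (PWM or k-mer score table)."""

    site_type: str  # "donor" | "acceptor"
    kind: str  # "pwm" | "kmer"
    window: tuple[int, int]  # (n_exonic, n_intronic)
    matrix: np.ndarray | None = None  # shape (4, width), per-position frequencies
    background: np.ndarray | None = None  # shape (4,)
    table: dict[str, float] | None = None

    def __post_init__(self) -> None:
        if self.site_type not in ("donor", "acceptor"):
            raise ValueError(f"site_type must be donor|acceptor, got {self.site_type!r}")
        if self.kind == "pwm":
            if self.matrix is None or self.background is None:
                raise ValueError("pwm kind requires matrix and background")
            m = np.asarray(self.matrix, dtype=float)
            bg = np.asarray(self.background, dtype=float)
            object.__setattr__(self, "matrix", m)
            object.__setattr__(self, "background", bg)
            if m.shape != (4, self.width):
                raise ValueError(f"matrix shape {m.shape} != (4, {self.width})")
            if not np.allclose(m.sum(axis=0), 1.0, atol=1e-6):
                raise ValueError("matrix columns must sum to 1 (frequency form)")
            if not np.isclose(bg.sum(), 1.0, atol=1e-6):
                raise ValueError("background frequencies must sum to 1")
        elif self.kind == "kmer":
            if self.table is None:
                raise ValueError("kmer kind requires a score table")
            lengths = {len(k) for k in self.table}
            if lengths and lengths != {self.width}:
                raise ValueError(
                    f"k-mer lengths {sorted(lengths)} != window width {self.width}"
                )
        else:
            raise ValueError(f"kind must be pwm|kmer, got {self.kind!r}")

    @property
    def width(self) -> int:
        return self.window[0] + self.window[1]


def _check_window(seq: str, width: int) -> str:
    seq = seq.upper()
    if len(seq) != width:
        raise ValueError(f"window length {len(seq)} != model width {width}")
    bad = set(seq) - set(_BASES)
    if bad:
        raise ValueError(f"ambiguous/invalid bases in window: {sorted(bad)}")
    return seq


def score_site(model: SpliceSiteModel, seq: str) -> float:
    """Score one junction window under the model.

    PWM scores are sum over positions of log2(frequency / background); a
    position with zero modelled frequency scores -inf (the window is
    incompatible with the model).  k-mer models are a direct table lookup.
    """
    seq = _check_window(seq, model.width)
    if model.kind == "pwm":
        idx = [_BASE_INDEX[b] for b in seq]
        w = model.matrix[idx, range(model.width)]
        bg = model.background[idx]
        with np.errstate(divide="ignore"):
            return float(np.sum(np.log2(w / bg)))
    try:
        return float(model.table[seq])
    except KeyError:
        raise MissingKmerError(f"window {seq!r} not in score table") from None


@dataclass(frozen=True)
class SiteScoreDelta:
    """Wild-type vs mutant score for one splice site.

    ``percent_change`` is 100·(mut − wt)/wt (unrounded; None when the
    wild-type score is exactly zero).  ``flagged_loss`` is True exactly when
    the delta is negative, the usual screen for potential site loss.
    """

    wt_score: float
    mut_score: float

    @property
    def delta(self) -> float:
        return self.mut_score - self.wt_score

    @property
    def percent_change(self) -> float | None:
        if self.wt_score == 0:
            return None
        return 100.0 * self.delta / self.wt_score

    @property
    def flagged_loss(self) -> bool:
        return self.delta < 0

    def percent_change_2dp(self) -> float:
        """Percent change rounded half-away-from-zero to 2 d.p. (reporting form)."""
        return percent_change(self.wt_score, self.mut_score)


def delta_from_scores(wt_score: float, mut_score: float) -> SiteScoreDelta:
    """Build a delta from externally supplied scores (e.g. published values)."""
    return SiteScoreDelta(wt_score=float(wt_score), mut_score=float(mut_score))


def site_delta(model: SpliceSiteModel, wt_window: str, mut_window: str) -> SiteScoreDelta:
    """Score both alleles of an SNV-affected junction window.

    Windows must be equal length and differ in at most one position;
    identical windows give a zero, unflagged delta.
    """
    wt = _check_window(wt_window, model.width)
    mut = _check_window(mut_window, model.width)
    ndiff = sum(a != b for a, b in zip(wt, mut))
    if ndiff > 1:
        raise ValueError(f"windows differ at {ndiff} positions; SNV deltas only")
    return SiteScoreDelta(score_site(model, wt), score_site(model, mut))


def percent_change(wt: float, mut: float) -> float:
    """100·(mut − wt)/wt, rounded half-away-from-zero to 2 decimal places."""
    if wt == 0:
        raise ZeroBaselineError("percent change undefined for wild-type score 0")
    return round_half_away(100.0 * (mut - wt) / wt, 2)


# ---------------------------------------------------------------------------
# File I/O: PWM TSV (rows A/C/G/T + background) and two-column k-mer tables
# ---------------------------------------------------------------------------

def save_pwm_tsv(model: SpliceSiteModel, path: str | Path) -> None:
    if model.kind != "pwm":
        raise ValueError("only pwm models are written in matrix form")
    lines = [
        "#site_type\t" + model.site_type,
        "#window\t%d\t%d" % model.window,
    ]
    for i, b in enumerate(_BASES):
        lines.append(b + "\t" + "\t".join(repr(float(x)) for x in model.matrix[i]))
    lines.append(
        "background\t" + "\t".join(repr(float(x)) for x in model.background)
    )
    Path(path).write_text("\n".join(lines) + "\n")


def load_pwm_tsv(path: str | Path) -> SpliceSiteModel:
    site_type, window = "donor", None
    rows: dict[str, list[float]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        if line.startswith("#site_type"):
            site_type = line.split("\t")[1].strip()
        elif line.startswith("#window"):
            parts = line.split("\t")[1:]
            window = (int(parts[0]), int(parts[1]))
        elif not line.startswith("#"):
            fields = line.split("\t")
            rows[fields[0]] = [float(x) for x in fields[1:]]
    matrix = np.array([rows[b] for b in _BASES])
    if window is None:
        window = (0, matrix.shape[1])
    return SpliceSiteModel(
        site_type=site_type,
        kind="pwm",
        window=window,
        matrix=matrix,
        background=np.array(rows["background"]),
    )


def load_kmer_table(
    path: str | Path, site_type: str = "donor", window: tuple[int, int] | None = None
) -> SpliceSiteModel:
    """Load a two-column (k-mer, score) TSV as a k-mer score model."""
    table: dict[str, float] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        kmer, score = line.split("\t")[:2]
        table[kmer.strip().upper()] = float(score)
    if window is None:
        k = len(next(iter(table)))
        window = (0, k)
    return SpliceSiteModel(site_type=site_type, kind="kmer", window=window, table=table)
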