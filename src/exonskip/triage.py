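"""Candidate-selection filter for potential splicing variants.

An exonic SNV is selected as a splicing candidate when either criterion
holds:

1. proximity — it lies within ``max_boundary_distance`` bases (default 4)
   of the exon's 5' or 3' end, where it can weaken the splice-site
   consensus directly; or
2. regulatory — the number of enhancers it breaks plus the number of
   silencers it gains exceeds ``disruption_threshold`` (default 5, strict
   inequality).

The filter consumes either live motif-scan output or externally supplied
counts (e.g. annotations from a published screen); the decision records
which inputs it saw.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Any

import pandas as pd

from .gene_models import ExonContext
from .motif_scan import MotifDelta

__all__ = [
    "TriageParams",
    "TriageDecision",
    "TriageReport",
    "select_candidate",
    "triage_table",
    "context_from_location",
]


@dataclass(frozen=True)
class TriageParams:
    """Thresholds of the two-criterion filter."""

    max_boundary_distance: int = 4
    disruption_threshold: int = 5  # strict: selected when sum > threshold

    def __post_init__(self) -> None:
        if self.max_boundary_distance < 0 or self.disruption_threshold < 0:
            raise ValueError("thresholds must be >= 0")


@dataclass(frozen=True)
class TriageDecision:
    """Outcome of the filter for one variant, with its inputs echoed."""

    selected: bool
    by_proximity: bool
    by_regulatory: bool
    inputs: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.selected != (self.by_proximity or self.by_regulatory):
            raise ValueError("selected must equal (by_proximity or by_regulatory)")


def context_from_location(exon_number: int, exon_length: int, location: int) -> ExonContext:
    """Rebuild an :class:`ExonContext` from a signed location-in-exon value
    (+d = distance from 5' end, −d = distance from 3' end)."""
    if location == 0 or abs(location) > exon_length:
        raise ValueError(f"location {location} outside exon of length {exon_length}")
    if location > 0:
        offset5 = location
        offset3 = exon_length + 1 - location
    else:
        offset3 = -location
        offset5 = exon_length + 1 + location
    return ExonContext(
        exon_number=exon_number, exon_length=exon_length, offset5=offset5, offset3=offset3
    )


def select_candidate(
    ctx: ExonContext,
    counts: MotifDelta | tuple[int, int],
    p: TriageParams = TriageParams(),
) -> TriageDecision:
    """Apply the two-criterion filter to one placed variant.

    ``counts`` is either a :class:`MotifDelta` or a bare
    ``(ese_broken, ess_gained)`` pair (e.g. table-supplied annotations).
    """
    if isinstance(counts, MotifDelta):
        ese_broken, ess_gained = counts.ese_broken, counts.ess_gained
        provenance = "motif_scan"
    else:
        ese_broken, ess_gained = int(counts[0]), int(counts[1])
        provenance = "supplied"
    if ese_broken < 0 or ess_gained < 0:
        raise ValueError("counts must be >= 0")

    by_proximity = ctx.boundary_distance <= p.max_boundary_distance
    by_regulatory = (ese_broken + ess_gained) > p.disruption_threshold
    return TriageDecision(
        selected=by_proximity or by_regulatory,
        by_proximity=by_proximity,
        by_regulatory=by_regulatory,
        inputs={
            "exon_number": ctx.exon_number,
            "exon_length": ctx.exon_length,
            "boundary_distance": ctx.boundary_distance,
            "ese_broken": ese_broken,
            "ess_gained": ess_gained,
            "counts_provenance": provenance,
        },
    )


@dataclass(frozen=True)
class TriageReport:
    """Per-row decisions plus per-gene summary counts."""

    frame: pd.DataFrame
    per_gene_selected: dict[str, int]
    n_selected: int
    n_rows: int
    params: TriageParams


_REQUIRED_COLS = (
    "gene_id",
    "hgvs_c",
    "exon_number",
    "exon_length",
    "location_in_exon",
    "ese_broken",
    "ess_gained",
)


def triage_table(
    rows: pd.DataFrame,
    p: TriageParams = TriageParams(),
    exclude_terminal_exons: bool = False,
) -> TriageReport:
    """Run the filter over an annotated variant table.

    Expects columns gene_id, hgvs_c, exon_number, exon_length,
    location_in_exon, ese_broken, ess_gained (an optional boolean
    ``terminal_exon`` column marks first/last exons, which are dropped
    before filtering when ``exclude_terminal_exons`` is set — such exons
    cannot be tested in an exon-trap construct).  Rows with missing counts
    are excluded from the summary with a warning and flagged in an
    ``error`` column.
    """
    missing = [c for c in _REQUIRED_COLS if c not in rows.columns]
    if missing:
        raise ValueError(f"input table is missing columns: {missing}")

    df = rows.copy().reset_index(drop=True)
    if exclude_terminal_exons and "terminal_exon" in df.columns:
        df = df[~df["terminal_exon"].fillna(False).astype(bool)].reset_index(drop=True)

    selected, by_prox, by_reg, errors = [], [], [], []
    for i, row in df.iterrows():
        try:
            if pd.isna(row["ese_broken"]) or pd.isna(row["ess_gained"]):
                raise ValueError("missing ESE/ESS counts")
            ctx = context_from_location(
                int(row["exon_number"]), int(row["exon_length"]), int(row["location_in_exon"])
            )
            d = select_candidate(ctx, (int(row["ese_broken"]), int(row["ess_gained"])), p)
            selected.append(d.selected)
            by_prox.append(d.by_proximity)
            by_reg.append(d.by_regulatory)
            errors.append("")
        except (ValueError, KeyError) as exc:
            warnings.warn(f"row {i} ({row.get('hgvs_c', '?')}): {exc} — excluded")
            selected.append(False)
            by_prox.append(False)
            by_reg.append(False)
            errors.append(str(exc))

    out = df.assign(selected=selected, by_proximity=by_prox, by_regulatory=by_reg, error=errors)
    ok = out[out["error"] == ""]
    hits = ok[ok["selected"].astype(bool)]
    per_gene = hits.groupby("gene_id").size().to_dict() if len(hits) else {}
    return TriageReport(
        frame=out,
        per_gene_selected={str(k): int(v) for k, v in per_gene.items()},
        n_selected=int(ok["selected"].sum()),
        n_rows=int(len(out)),
        params=p,
    )
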