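"""Exon-trap (pSPL3-style) minigene products and band quantification.

A test exon cloned between the vector's own splice sites yields two
possible RT-PCR products: the exon-included transcript (backbone + exon
length) and the exon-excluded transcript (backbone only, 263 bp by
default).  Densitometry of the two bands gives the exon-exclusion
percentage

    exclusion % = 100 * lower / (lower + upper)

with the lower (smaller, exon-excluded) band in the numerator.  Replicate
exclusion percentages of wild-type and mutant constructs are compared with
an unpaired pooled-variance (Student) t-test; a mutant producing only the
backbone band is classified as complete skipping regardless of the test.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "MinigeneConstruct",
    "BandQuant",
    "SplicingComparison",
    "expected_products",
    "exclusion_percent",
    "compare_splicing",
    "bands_detected",
    "read_band_tsv",
    "quantify_table",
]

DEFAULT_BACKBONE_BP = 263


@dataclass(frozen=True)
class MinigeneConstruct:
    """One cloned test exon and the vector's backbone product size."""

    insert_exon_length: int
    backbone_product: int = DEFAULT_BACKBONE_BP

    def __post_init__(self) -> None:
        if self.insert_exon_length < 0 or self.backbone_product < 0:
            raise ValueError("sizes must be >= 0")


def expected_products(c: MinigeneConstruct) -> tuple[int, int]:
    """(inclusion, exclusion) RT-PCR product sizes in bp."""
    return (c.backbone_product + c.insert_exon_length, c.backbone_product)


def exclusion_percent(lower: float, upper: float) -> float:
    """Percent exon exclusion from band intensities: 100·lower/(lower+upper)."""
    if lower < 0 or upper < 0:
        raise ValueError("intensities must be >= 0")
    total = lower + upper
    if total == 0:
        raise ValueError("exclusion percent undefined: both band intensities are 0")
    return 100.0 * lower / total


@dataclass(frozen=True)
class BandQuant:
    """Densitometric intensities of one lane's two bands."""

    upper: float  # exon-included product
    lower: float  # exon-excluded (backbone-only) product

    @property
    def exclusion_percent(self) -> float:
        return exclusion_percent(self.lower, self.upper)


@dataclass(frozen=True)
class SplicingComparison:
    """WT-vs-mutant comparison of replicate exclusion percentages."""

    wt_replicates: tuple[float, ...]
    mut_replicates: tuple[float, ...]
    t_statistic: float
    p_value: float
    classification: str  # "none" | "partial" | "complete"


def _pooled_ttest(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    # zero variance in both groups: equal means -> no evidence (p = 1 convention);
    # unequal means -> unambiguous separation
    if np.var(a) == 0 and np.var(b) == 0:
        if np.mean(a) == np.mean(b):
            return 0.0, 1.0
        return float("inf") if np.mean(b) < np.mean(a) else float("-inf"), 0.0
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return float(t), float(p)


def compare_splicing(
    wt: Sequence[float],
    mut: Sequence[float],
    mut_inclusion_detected: bool = True,
    mut_exclusion_detected: bool = True,
    alpha: float = 0.05,
) -> SplicingComparison:
    """Compare WT and mutant replicate exclusion percentages.

    Classification: "complete" when the mutant shows no inclusion band
    (only the backbone product); "partial" when both products are present
    and the mutant's exclusion is significantly higher than wild type
    (two-sided pooled t-test, p < alpha); otherwise "none".
    """
    a = np.asarray(list(wt), dtype=float)
    b = np.asarray(list(mut), dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need >= 2 replicates per group for the t-test")
    t, p = _pooled_ttest(a, b)
    if not mut_inclusion_detected and mut_exclusion_detected:
        classification = "complete"
    elif p < alpha and b.mean() > a.mean():
        classification = "partial"
    else:
        classification = "none"
    return SplicingComparison(
        wt_replicates=tuple(float(x) for x in a),
        mut_replicates=tuple(float(x) for x in b),
        t_statistic=t,
        p_value=p,
        classification=classification,
    )


def bands_detected(
    quants: Sequence[BandQuant], detection_fraction: float = 0.01
) -> tuple[bool, bool]:
    """(inclusion detected, exclusion detected) from replicate intensities.

    A band counts as detected when its mean intensity exceeds
    ``detection_fraction`` of the mean total (default 1%)."""
    upper = float(np.mean([q.upper for q in quants]))
    lower = float(np.mean([q.lower for q in quants]))
    total = upper + lower
    if total == 0:
        raise ValueError("no signal in any band")
    return (upper / total > detection_fraction, lower / total > detection_fraction)


# ---------------------------------------------------------------------------
# Band-intensity tables
# ---------------------------------------------------------------------------

def read_band_tsv(path: str | Path) -> pd.DataFrame:
    """Read a band-intensity TSV with columns construct_id, group (WT|MUT),
    replicate, upper, lower."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"construct_id", "group", "replicate", "upper", "lower"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"band table missing columns: {sorted(missing)}")
    return df


def quantify_table(
    df: pd.DataFrame, alpha: float = 0.05, detection_fraction: float = 0.01
) -> pd.DataFrame:
    """Per-construct quantification report from a band-intensity table.

    For each construct the WT and MUT replicate lanes are reduced to
    exclusion percentages, compared, and classified.  Constructs with fewer
    than 2 replicates in either group get mean percentages but no test
    (t/p = NaN, classification from band presence only)."""
    rows = []
    for construct_id, sub in df.groupby("construct_id"):
        groups: dict[str, list[BandQuant]] = {"WT": [], "MUT": []}
        for _, r in sub.iterrows():
            groups[str(r["group"]).upper()].append(
                BandQuant(upper=float(r["upper"]), lower=float(r["lower"]))
            )
        wt = [q.exclusion_percent for q in groups["WT"]]
        mut = [q.exclusion_percent for q in groups["MUT"]]
        inc, exc = bands_detected(groups["MUT"], detection_fraction)
        if len(wt) >= 2 and len(mut) >= 2:
            cmp_ = compare_splicing(
                wt, mut, mut_inclusion_detected=inc, mut_exclusion_detected=exc, alpha=alpha
            )
            t, p, cls = cmp_.t_statistic, cmp_.p_value, cmp_.classification
        else:
            t, p = float("nan"), float("nan")
            cls = "complete" if (not inc and exc) else "untested"
        rows.append(
            {
                "construct_id": construct_id,
                "wt_exclusion_mean": float(np.mean(wt)) if wt else float("nan"),
                "mut_exclusion_mean": float(np.mean(mut)) if mut else float("nan"),
                "t_statistic": t,
                "p_value": p,
                "classification": cls,
            }
        )
    return pd.DataFrame(rows)
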