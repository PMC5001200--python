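"""Class-composition analyses of ranked entity lists.

Two views: the percentage of each class among the top-k entities at a
series of ranking cutoffs (used with ICD-10 chapter labels on the disease
ranking), and a fold-enrichment table contrasting the top fraction of a
ranking with the whole list (used with ATC level-3 codes on the drug
ranking, retaining classes enriched at least two-fold).

Entities may carry several classes (each counts toward every class it
carries) or none (they count in denominators only).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from .evaluate import nearest_int
from .kb_io import ClassMap

__all__ = ["EnrichmentTable", "class_distribution", "top_class_enrichment"]

#: The ten decile cutoffs of the disease-class distribution analysis.
DECILE_CUTOFFS = tuple(round(0.1 * k, 1) for k in range(1, 11))


def _top_k(n: int, fraction: float) -> int:
    if not (0 < fraction <= 1):
        raise ValueError(f"fraction {fraction} outside (0, 1]")
    return max(1, nearest_int(fraction * n))


def _class_percents(entities: Sequence[str], cmap: ClassMap) -> dict[str, float]:
    counts: dict[str, int] = {}
    for e in entities:
        for c in cmap.classes_of(e):
            counts[c] = counts.get(c, 0) + 1
    k = len(entities)
    return {c: 100.0 * n / k for c, n in counts.items()}


def class_distribution(
    ranked: Sequence[str],
    cmap: ClassMap,
    cutoffs: Sequence[float] = DECILE_CUTOFFS,
) -> pd.DataFrame:
    """Percentage of each class among the top-k entities at each cutoff.

    percent = (entities in the top k carrying the class) / k * 100; the
    top k at cutoff c is the first round(c * len(ranked)) entities.
    Unclassified entities contribute to k but to no class.  Returns a
    long-form frame with columns cutoff, class, percent covering every
    class observed anywhere in the ranked list.
    """
    if not ranked:
        raise ValueError("empty ranked list")
    classes = sorted({c for e in ranked for c in cmap.classes_of(e)})
    rows = []
    for c in cutoffs:
        k = _top_k(len(ranked), c)
        pct = _class_percents(ranked[:k], cmap)
        for cls in classes:
            rows.append({"cutoff": c, "class": cls, "percent": pct.get(cls, 0.0)})
    return pd.DataFrame(rows, columns=["cutoff", "class", "percent"])


@dataclass(frozen=True)
class EnrichmentTable:
    """Classes enriched in the top fraction of a ranking.

    ``table`` has columns class, percent_in_top, percent_overall, fold,
    sorted by fold descending; only classes with
    fold >= ``min_fold`` (and positive overall prevalence) are retained.
    """

    table: pd.DataFrame
    cutoff_used: float
    min_fold: float

    def write_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def top_class_enrichment(
    ranked: Sequence[str],
    cmap: ClassMap,
    top_fraction: float = 0.10,
    min_fold: float = 2.0,
) -> EnrichmentTable:
    """Fold enrichment of each class in the top fraction versus the whole list.

    fold = percent_in_top / percent_overall.  At ``top_fraction = 1`` the
    two percentages coincide and every fold is exactly 1.  The returned
    table keeps classes with fold >= ``min_fold``; pass ``min_fold = 0``
    to see all classes.
    """
    if not ranked:
        raise ValueError("empty ranked list")
    k = _top_k(len(ranked), top_fraction)
    top_pct = _class_percents(ranked[:k], cmap)
    overall_pct = _class_percents(ranked, cmap)
    rows = []
    for cls, base in overall_pct.items():
        if base <= 0:
            continue
        in_top = top_pct.get(cls, 0.0)
        fold = in_top / base
        if fold >= min_fold:
            rows.append(
                {
                    "class": cls,
                    "percent_in_top": in_top,
                    "percent_overall": base,
                    "fold": fold,
                }
            )
    table = pd.DataFrame(
        rows, columns=["class", "percent_in_top", "percent_overall", "fold"]
    ).sort_values(["fold", "class"], ascending=[False, True], ignore_index=True)
    return EnrichmentTable(table, cutoff_used=top_fraction, min_fold=min_fold)
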