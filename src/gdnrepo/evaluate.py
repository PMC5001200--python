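"""Retrospective and novel-prediction evaluation of a drug ranking.

Given a gold-standard drug list, computes overall recall (fraction of
gold drugs retrieved with positive score), mean and median percentile
position of the retrieved gold drugs, and a precision/recall/F1 table at
fractional ranking cutoffs (top 1 %, 5 %, ... of the drug universe).
Also provides the arithmetic helpers used for comparator studies whose
only available data are printed counts, fold-enrichment ratios, and a
random-drug percentile baseline.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .kb_io import GoldStandard
from .reposition import DrugRanking

__all__ = [
    "DEFAULT_CUTOFFS",
    "EvaluationReport",
    "retrospective_eval",
    "prf_from_counts",
    "fold_enrichment",
    "random_baseline",
    "nearest_int",
]

#: The six cutoffs used for the headline precision/recall/F1 figures.
DEFAULT_CUTOFFS = (0.01, 0.05, 0.10, 0.20, 0.50, 1.0)


def nearest_int(x: float) -> int:
    """Round half up to the nearest integer (1 % of 2484 -> 25)."""
    return int(math.floor(x + 0.5))


def _f1(precision: float, recall: float) -> float:
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)


@dataclass(frozen=True)
class EvaluationReport:
    """Evaluation of one drug ranking against one gold standard."""

    gold_label: str
    gold_size: int
    universe_size: int
    recall_overall: float
    n_retrieved: int
    mean_percentile: float
    median_percentile: float
    baseline_precision: float
    cutoff_table: pd.DataFrame  # columns: cutoff, k, n_hits, precision, recall, f1

    def to_dict(self) -> dict:
        return {
            "gold_label": self.gold_label,
            "gold_size": self.gold_size,
            "universe_size": self.universe_size,
            "recall_overall": self.recall_overall,
            "n_retrieved": self.n_retrieved,
            "mean_percentile": self.mean_percentile,
            "median_percentile": self.median_percentile,
            "baseline_precision": self.baseline_precision,
            "cutoffs": self.cutoff_table.to_dict(orient="records"),
        }

    def write_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2), encoding="utf-8")

    def write_tsv(self, path: str | Path) -> None:
        self.cutoff_table.to_csv(path, sep="\t", index=False)


def retrospective_eval(
    dr: DrugRanking,
    gold: GoldStandard,
    cutoffs: Sequence[float] = DEFAULT_CUTOFFS,
) -> EvaluationReport:
    """Evaluate a drug ranking against a gold-standard list.

    recall_overall = |gold ∩ ranked entries| / |gold|.  Mean and median
    percentiles are over the retrieved gold drugs only — unretrieved
    drugs lower recall but do not enter the percentile summaries.  For
    each fractional cutoff c the top k = round(c * universe_size) entries
    are taken; precision = hits / k and recall = hits / |gold|.
    """
    if not gold.drugs:
        raise ValueError("empty gold standard")
    ranked_drugs = [e.drug for e in dr.entries]
    retrieved = [e for e in dr.entries if e.drug in gold.drugs]
    n_retrieved = len(retrieved)
    recall_overall = n_retrieved / len(gold.drugs)
    pcts = [e.percentile for e in retrieved]
    mean_pct = float(np.mean(pcts)) if pcts else float("nan")
    median_pct = float(np.median(pcts)) if pcts else float("nan")

    rows = []
    for c in cutoffs:
        if not (0 < c <= 1):
            raise ValueError(f"cutoff fraction {c} outside (0, 1]")
        k = nearest_int(c * dr.universe_size)
        hits = sum(1 for d in ranked_drugs[:k] if d in gold.drugs)
        precision = hits / k if k else 0.0
        recall = hits / len(gold.drugs)
        rows.append(
            {
                "cutoff": c,
                "k": k,
                "n_hits": hits,
                "precision": precision,
                "recall": recall,
                "f1": _f1(precision, recall),
            }
        )
    table = pd.DataFrame(rows, columns=["cutoff", "k", "n_hits", "precision", "recall", "f1"])
    return EvaluationReport(
        gold_label=gold.label,
        gold_size=len(gold.drugs),
        universe_size=dr.universe_size,
        recall_overall=recall_overall,
        n_retrieved=n_retrieved,
        mean_percentile=mean_pct,
        median_percentile=median_pct,
        baseline_precision=n_retrieved / dr.universe_size if dr.universe_size else 0.0,
        cutoff_table=table,
    )


def prf_from_counts(tp: int, n_pred: int, n_gold: int) -> tuple[float, float, float]:
    """Precision, recall and F1 from raw counts.

    Used to place comparator methods on the same axes when only their
    printed counts are available (tp correct predictions out of n_pred,
    against an n_gold-drug gold standard).
    """
    if n_pred <= 0 or n_gold <= 0:
        raise ValueError("n_pred and n_gold must be positive")
    if not (0 <= tp <= min(n_pred, n_gold)):
        raise ValueError(f"tp={tp} inconsistent with n_pred={n_pred}, n_gold={n_gold}")
    precision = tp / n_pred
    recall = tp / n_gold
    return precision, recall, _f1(precision, recall)


def fold_enrichment(p_top: float, p_base: float, ndigits: int | None = 1) -> float:
    """Ratio of a prevalence in a top-ranked subset to its base prevalence.

    Both arguments must be in the same units (both proportions or both
    percentages).  Rounded to ``ndigits`` decimals (default 1; pass None
    for full precision).
    """
    if p_base <= 0:
        raise ValueError("base prevalence must be positive")
    ratio = p_top / p_base
    return ratio if ndigits is None else round(ratio, ndigits)


def random_baseline(
    dr: DrugRanking,
    universe: Iterable[str] | None,
    gold_size: int,
    n_draws: int,
    seed: int,
) -> tuple[float, float]:
    """Percentile baseline for randomly chosen drug sets of gold size.

    Draws ``n_draws`` sets of ``gold_size`` drugs uniformly without
    replacement from the universe, looks up each drug's percentile in the
    ranking (drugs absent from the entries are tied at the bottom,
    percentile 100), and returns the across-draw averages of the per-draw
    mean and median percentiles.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    pool = sorted(universe) if universe is not None else sorted(dr.universe)
    if gold_size > len(pool):
        raise ValueError(f"gold size {gold_size} exceeds universe of {len(pool)}")
    pct = {e.drug: e.percentile for e in dr.entries}
    rng = np.random.default_rng(seed)
    means, medians = [], []
    for _ in range(n_draws):
        picks = rng.choice(len(pool), size=gold_size, replace=False)
        vals = [pct.get(pool[i], 100.0) for i in picks]
        means.append(float(np.mean(vals)))
        medians.append(float(np.median(vals)))
    return float(np.mean(means)), float(np.mean(medians))
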