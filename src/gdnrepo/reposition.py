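"""Drug prioritization by aggregation of disease walk scores.

A drug's score is the sum of the steady-state ranking scores of the
distinct diseases it treats:  R_drug = sum_i R_disease_i.  A drug that
treats many top-ranked seed-related diseases therefore outranks one that
treats a few low-ranked diseases.  Validation is de novo: the target
disease's own treatment pairs are removed from the knowledge base before
scoring, while the drug universe is kept intact so every drug remains
rankable (at score zero if it treats nothing else relevant).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import pandas as pd

from .kb_io import TreatmentKB, normalize_name
from .rwr import DiseaseRanking

__all__ = [
    "RankedDrug",
    "DrugRanking",
    "de_novo_mask",
    "score_drugs",
    "percentile_rank",
    "remove_drugs",
]


def percentile_rank(rank: int, total: int) -> float:
    """Percentile position of a 1-based rank in a universe: 100*rank/total.

    Reported to two decimals, e.g. rank 19 of 2484 -> 0.76 %.
    """
    if not (1 <= rank <= total):
        raise ValueError(f"rank {rank} out of range 1..{total}")
    return round(100.0 * rank / total, 2)


@dataclass(frozen=True)
class RankedDrug:
    drug: str
    score: float
    n_diseases: int
    rank: int
    percentile: float


@dataclass(frozen=True)
class DrugRanking:
    """Drugs ordered by aggregated disease score.

    ``entries`` excludes zero-score drugs, but every drug in ``universe``
    counts in the denominator of the percentile positions.
    """

    entries: tuple[RankedDrug, ...]
    universe: frozenset[str]
    masked_disease: str = ""

    @property
    def universe_size(self) -> int:
        return len(self.universe)

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def drugs(self) -> tuple[str, ...]:
        return tuple(e.drug for e in self.entries)

    def entry_of(self, drug: str) -> RankedDrug | None:
        d = normalize_name(drug)
        for e in self.entries:
            if e.drug == d:
                return e
        return None

    def percentile_of(self, drug: str) -> float | None:
        e = self.entry_of(drug)
        return None if e is None else e.percentile

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "drug": [e.drug for e in self.entries],
                "score": [e.score for e in self.entries],
                "n_diseases": [e.n_diseases for e in self.entries],
                "rank": [e.rank for e in self.entries],
                "percentile": [e.percentile for e in self.entries],
            }
        )

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def de_novo_mask(kb: TreatmentKB, target: str) -> TreatmentKB:
    """Remove every treatment pair of the target disease.

    The drug universe is unchanged, so drugs that only treated the target
    stay rankable at score zero.  Idempotent; a target absent from the KB
    leaves it untouched.
    """
    t = normalize_name(target)
    pairs = frozenset(tr for tr in kb.pairs if tr[1] != t)
    return TreatmentKB(pairs, drug_universe=kb.drug_universe)


def _build(entries_raw: list[tuple[str, float, int]], universe: frozenset[str], masked: str) -> DrugRanking:
    entries_raw.sort(key=lambda t: (-t[1], t[0]))
    total = len(universe)
    entries = tuple(
        RankedDrug(d, s, n, k + 1, percentile_rank(k + 1, total))
        for k, (d, s, n) in enumerate(entries_raw)
    )
    return DrugRanking(entries, universe, masked_disease=masked)


def score_drugs(ranking: DiseaseRanking, kb: TreatmentKB) -> DrugRanking:
    """Score every drug as the sum of its treated diseases' walk scores.

    Each distinct disease counts once however many sources attest the
    pair.  Drugs whose treated diseases never appear in the ranking score
    zero and are excluded from entries while still counted in the
    universe.  ``kb`` is expected to be already masked for the target.
    """
    if not ranking.entries:
        raise ValueError("empty disease ranking: nothing to aggregate")
    score_by_disease = {e.disease: e.score for e in ranking.entries}

    treated: dict[str, set[str]] = {}
    for drug, disease, _source in kb.pairs:
        if disease in score_by_disease:
            treated.setdefault(drug, set()).add(disease)

    raw = [
        (drug, sum(score_by_disease[d] for d in ds), len(ds))
        for drug, ds in treated.items()
    ]
    return _build(raw, kb.drug_universe, masked=ranking.seed)


def remove_drugs(dr: DrugRanking, drugs: Iterable[str]) -> DrugRanking:
    """Drop the given drugs (e.g. already-approved ones) and re-rank.

    Novel-prediction mode: the removed drugs leave both the entries and
    the universe, so ranks, percentiles and cutoff sizes are relative to
    the remaining candidates.
    """
    drop = {normalize_name(d) for d in drugs}
    universe = frozenset(dr.universe - drop)
    raw = [(e.drug, e.score, e.n_diseases) for e in dr.entries if e.drug not in drop]
    return _build(raw, universe, masked=dr.masked_disease)
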