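"""Readers and writers for the tabular inputs of the repositioning pipeline.

Four kinds of input feed the pipeline: disease-gene association tables
(either a two-column ``simple`` dialect or the NHGRI-EBI GWAS Catalog
download dialect), drug-disease treatment pair tables (one TSV per source),
gold-standard drug lists (one drug per line), and class maps assigning
entities to class labels (ICD-10 chapter names for diseases, ATC level-3
codes for drugs).

All names pass through a single normalization (:func:`normalize_name`) so
that joins between tables are reliable without any ontology mapping:
case-fold, trim, and collapse internal whitespace.  Normalization is
idempotent.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "DiseaseGeneAssociations",
    "TreatmentKB",
    "GoldStandard",
    "ClassMap",
    "FormatError",
    "SOURCE_TAGS",
    "normalize_name",
    "read_associations",
    "write_associations",
    "read_treatment_kb",
    "write_treatment_kb",
    "read_gold",
    "write_gold",
    "read_class_map",
    "write_class_map",
]

#: Valid source tags for treatment pairs: drug labels, post-marketing
#: surveillance reports, clinical-trial registries, literature mining,
#: plus a catch-all.
SOURCE_TAGS = frozenset({"labels", "postmarket", "trials", "literature", "other"})

#: Gene-cell tokens that are not gene symbols and contribute no pair.
PLACEHOLDER_GENE_TOKENS = frozenset({"", "nr", "na", "intergenic"})

# GWAS-Catalog gene cells list several genes separated by commas,
# semicolons, or " - " (the catalog's intergenic "FLANKA - FLANKB" style).
_GENE_SEPARATOR = re.compile(r",|;| - ")

_WS = re.compile(r"\s+")


class FormatError(ValueError):
    """A required column or field is missing or malformed."""


def normalize_name(name: str) -> str:
    """Normalize an entity name: case-fold, trim, collapse whitespace."""
    return _WS.sub(" ", str(name).strip()).casefold()


def _split_gene_cell(cell: str) -> list[str]:
    """Split a multi-gene cell and drop placeholder tokens."""
    out = []
    for token in _GENE_SEPARATOR.split(str(cell)):
        g = normalize_name(token)
        if g not in PLACEHOLDER_GENE_TOKENS:
            out.append(g)
    return out


@dataclass(frozen=True)
class DiseaseGeneAssociations:
    """Mapping from disease/trait name to its set of associated gene symbols.

    Invariants enforced on construction: no empty disease names, no empty
    gene sets, all names normalized.
    """

    entries: Mapping[str, frozenset[str]]

    def __post_init__(self) -> None:
        clean: dict[str, frozenset[str]] = {}
        for disease, genes in self.entries.items():
            d = normalize_name(disease)
            gs = frozenset(normalize_name(g) for g in genes) - PLACEHOLDER_GENE_TOKENS
            if not d:
                raise FormatError("empty disease name in associations")
            if gs:
                clean[d] = gs
        object.__setattr__(self, "entries", clean)

    @property
    def n_pairs(self) -> int:
        """Number of distinct (disease, gene) pairs."""
        return sum(len(g) for g in self.entries.values())

    @property
    def diseases(self) -> list[str]:
        return sorted(self.entries)

    @property
    def genes(self) -> frozenset[str]:
        out: set[str] = set()
        for g in self.entries.values():
            out |= g
        return frozenset(out)

    def __len__(self) -> int:
        return len(self.entries)

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "DiseaseGeneAssociations":
        entries: dict[str, set[str]] = {}
        for disease, gene in pairs:
            entries.setdefault(disease, set()).add(gene)
        return cls({d: frozenset(g) for d, g in entries.items()})


@dataclass(frozen=True)
class TreatmentKB:
    """Source-tagged drug-disease treatment pairs.

    ``pairs`` holds distinct (drug, disease, source) triples.
    ``drug_universe`` is the set of rankable drugs; it defaults to the
    drugs appearing in ``pairs`` but survives de-novo masking unchanged,
    so masked drugs remain rankable at score zero.
    """

    pairs: frozenset[tuple[str, str, str]]
    drug_universe: frozenset[str] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        pairs = frozenset(
            (normalize_name(dr), normalize_name(di), src) for dr, di, src in self.pairs
        )
        for _, _, src in pairs:
            if src not in SOURCE_TAGS:
                raise FormatError(
                    f"unknown source tag {src!r}; expected one of {sorted(SOURCE_TAGS)}"
                )
        object.__setattr__(self, "pairs", pairs)
        universe = self.drug_universe
        if universe is None:
            universe = frozenset(dr for dr, _, _ in pairs)
        else:
            universe = frozenset(normalize_name(d) for d in universe)
        object.__setattr__(self, "drug_universe", universe)

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    @property
    def drugs(self) -> frozenset[str]:
        return frozenset(dr for dr, _, _ in self.pairs)

    @property
    def diseases(self) -> frozenset[str]:
        return frozenset(di for _, di, _ in self.pairs)

    @property
    def sources(self) -> frozenset[str]:
        return frozenset(src for _, _, src in self.pairs)

    def restrict_to_source(self, source: str) -> "TreatmentKB":
        """Per-source view; the drug universe shrinks to that source's drugs."""
        pairs = frozenset(t for t in self.pairs if t[2] == source)
        return TreatmentKB(pairs)

    def diseases_treated_by(self, drug: str) -> frozenset[str]:
        """Distinct diseases the drug treats, across all sources."""
        d = normalize_name(drug)
        return frozenset(di for dr, di, _ in self.pairs if dr == d)


@dataclass(frozen=True)
class GoldStandard:
    """A reference drug list (e.g. approved drugs, or trial-supported novel drugs)."""

    drugs: frozenset[str]
    label: str = ""

    def __post_init__(self) -> None:
        drugs = frozenset(normalize_name(d) for d in self.drugs) - {""}
        if not drugs:
            raise FormatError("empty gold standard is never meaningful")
        object.__setattr__(self, "drugs", drugs)

    def __len__(self) -> int:
        return len(self.drugs)


@dataclass(frozen=True)
class ClassMap:
    """Mapping from entity name to its (possibly multiple) class labels.

    Entities absent from the map are treated as unclassified: they count
    in denominators but belong to no class.
    """

    assignments: Mapping[str, frozenset[str]]

    def __post_init__(self) -> None:
        clean = {
            normalize_name(k): frozenset(str(c).strip() for c in v)
            for k, v in self.assignments.items()
        }
        object.__setattr__(self, "assignments", clean)

    def classes_of(self, entity: str) -> frozenset[str]:
        return self.assignments.get(normalize_name(entity), frozenset())

    @property
    def all_classes(self) -> frozenset[str]:
        out: set[str] = set()
        for cs in self.assignments.values():
            out |= cs
        return frozenset(out)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def _read_tsv(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    lower = {c.casefold(): c for c in df.columns}
    for col in required:
        if col.casefold() not in lower:
            raise FormatError(f"{path}: missing required column {col!r}")
    return df.rename(columns={v: k for k, v in lower.items()})


def read_associations(
    path: str | Path,
    dialect: str = "simple",
    *,
    trait_column: str = "DISEASE/TRAIT",
    mapped_gene_column: str = "MAPPED_GENE",
    reported_gene_column: str = "REPORTED GENE(S)",
) -> DiseaseGeneAssociations:
    """Read a disease-gene association table.

    Parameters
    ----------
    path
        TSV file with a header row.
    dialect
        ``"simple"`` expects columns ``disease`` and ``gene`` (one gene per
        row).  ``"gwas_catalog"`` expects the GWAS-Catalog download columns:
        the trait column plus a mapped-gene column (preferred, the catalog's
        curated field) falling back to the reported-gene column; a gene cell
        may list several genes.
    trait_column, mapped_gene_column, reported_gene_column
        Column names of the catalog dialect, overridable because catalog
        releases have renamed them.

    Returns
    -------
    DiseaseGeneAssociations
        With multi-gene cells split, names normalized, and placeholder gene
        tokens ("", "NR", "NA", "intergenic") dropped.
    """
    if dialect == "simple":
        df = _read_tsv(path, ["disease", "gene"])
        trait_col, gene_cols = "disease", ["gene"]
    elif dialect == "gwas_catalog":
        df = _read_tsv(path, [trait_column])
        gene_cols = []
        for col in (mapped_gene_column, reported_gene_column):
            if col.casefold() in df.columns:
                gene_cols.append(col.casefold())
        if not gene_cols:
            raise FormatError(
                f"{path}: missing required column {mapped_gene_column!r} "
                f"(or fallback {reported_gene_column!r})"
            )
        gene_cols = gene_cols[:1]  # mapped preferred over reported
        trait_col = trait_column.casefold()
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    pairs: list[tuple[str, str]] = []
    for _, row in df.iterrows():
        disease = normalize_name(row[trait_col])
        if not disease:
            continue
        for gene in _split_gene_cell(row[gene_cols[0]]):
            pairs.append((disease, gene))
    return DiseaseGeneAssociations.from_pairs(pairs)


def write_associations(assoc: DiseaseGeneAssociations, path: str | Path) -> None:
    """Write associations in the simple dialect (sorted, deterministic)."""
    rows = [
        {"disease": d, "gene": g}
        for d in sorted(assoc.entries)
        for g in sorted(assoc.entries[d])
    ]
    pd.DataFrame(rows, columns=["disease", "gene"]).to_csv(path, sep="\t", index=False)


def read_treatment_kb(paths: Sequence[tuple[str | Path, str]]) -> TreatmentKB:
    """Read and union treatment-pair TSVs, one ``(path, source_tag)`` each.

    Each file must have ``drug`` and ``disease`` columns.  Duplicate rows
    within a file collapse to one triple; the same pair in two sources
    yields two triples (union-of-sources design).
    """
    triples: set[tuple[str, str, str]] = set()
    for path, source in paths:
        if source not in SOURCE_TAGS:
            raise FormatError(
                f"unknown source tag {source!r}; expected one of {sorted(SOURCE_TAGS)}"
            )
        df = _read_tsv(path, ["drug", "disease"])
        for _, row in df.iterrows():
            drug = normalize_name(row["drug"])
            disease = normalize_name(row["disease"])
            if drug and disease:
                triples.add((drug, disease, source))
    return TreatmentKB(frozenset(triples))


def write_treatment_kb(kb: TreatmentKB, directory: str | Path) -> dict[str, Path]:
    """Write one ``treatments_<source>.tsv`` per source; returns the paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    out: dict[str, Path] = {}
    for source in sorted(kb.sources):
        rows = sorted((dr, di) for dr, di, src in kb.pairs if src == source)
        df = pd.DataFrame(rows, columns=["drug", "disease"])
        p = directory / f"treatments_{source}.tsv"
        df.to_csv(p, sep="\t", index=False)
        out[source] = p
    return out


def _read_lines(path: str | Path) -> list[str]:
    lines = []
    for raw in Path(path).read_text(encoding="utf-8").splitlines():
        line = raw.strip()
        if line and not line.startswith("#"):
            lines.append(line)
    return lines


def read_gold(path: str | Path, label: str = "") -> GoldStandard:
    """Read a gold-standard drug list: one drug per line, ``#`` comments."""
    drugs = {normalize_name(line) for line in _read_lines(path)}
    if not drugs:
        raise FormatError(f"{path}: empty gold standard after filtering")
    return GoldStandard(frozenset(drugs), label=label)


def write_gold(gold: GoldStandard, path: str | Path) -> None:
    Path(path).write_text("\n".join(sorted(gold.drugs)) + "\n", encoding="utf-8")


def read_class_map(path: str | Path) -> ClassMap:
    """Read an entity-to-class map: ``entity<TAB>class`` per line.

    Multiple lines for one entity aggregate into a multi-class assignment.
    """
    assignments: dict[str, set[str]] = {}
    for line in _read_lines(path):
        parts = line.split("\t")
        if len(parts) != 2:
            raise FormatError(f"{path}: expected 'entity<TAB>class', got {line!r}")
        entity, cls = normalize_name(parts[0]), parts[1].strip()
        if entity and cls:
            assignments.setdefault(entity, set()).add(cls)
    return ClassMap({k: frozenset(v) for k, v in assignments.items()})


def write_class_map(cmap: ClassMap, path: str | Path) -> None:
    lines = [
        f"{entity}\t{cls}"
        for entity in sorted(cmap.assignments)
        for cls in sorted(cmap.assignments[entity])
    ]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
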