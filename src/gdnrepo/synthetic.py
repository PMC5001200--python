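"""Synthetic fixture generator with planted genetic and treatment structure.

The generator emulates the statistical structure the repositioning method
relies on — genetic overlap between diseases standing in for shared
pathophysiology.  A seed disease receives a gene set; ``n_related``
diseases each copy a fraction of the seed's genes (so they connect to the
seed with controllable similarity) and fill the remainder with random
background genes; ``n_unrelated`` diseases draw only background genes.
Background genes come from a pool sized at ``gene_pool_factor`` times the
total requested gene slots, so any particular pair of background draws
overlaps with small probability (about ``genes_per_disease / pool``) —
enough chance overlap to give the background a sparse, weakly connected
texture like a real association catalog, while planted relatedness
dominates it by an order of magnitude.

"Signal" drugs sample the diseases they treat with probability
``true_drug_bias`` from the related set and otherwise from the
unrelated set; decoy drugs use the same two-step draw with an unbiased
coin.  At ``true_drug_bias = 0.5`` the two kinds of drug are therefore
identically distributed — the null fixture.  The seed disease itself is
never a sampled treatment (its pairs would be removed by de-novo
masking anyway, which has its own direct tests).

All randomness flows from one seed through independently spawned streams
per component (genes, signal drugs, decoy drugs), so changing the drug
counts does not perturb the gene draws and vice versa.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np

from .kb_io import (
    ClassMap,
    DiseaseGeneAssociations,
    GoldStandard,
    TreatmentKB,
    write_associations,
    write_class_map,
    write_gold,
    write_treatment_kb,
)

__all__ = ["SyntheticConfig", "SyntheticDataset", "generate", "write_dataset"]

#: Class label planted on diseases genetically related to the seed.
RELATED_CLASS = "seed-related"
BACKGROUND_CLASS = "background"


class ConfigError(ValueError):
    """Invalid or mutually inconsistent generator settings."""


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions of the synthetic benchmark.

    n_related / n_unrelated: diseases sharing genes with the seed versus
        pure background (defaults 20 / 200).
    genes_per_disease: gene-set size per disease; default 25, the order
        of magnitude of genes per trait in GWAS association catalogs.
    shared_fraction: fraction of the seed's genes copied into each
        related disease (default 0.5).
    n_true_drugs / n_decoy_drugs: planted treatments versus decoys
        (defaults 10 / 200).
    treats_per_drug: distinct diseases each drug treats (default 5).
    true_drug_bias: probability a signal drug's treated disease comes
        from the related pool; 0.5 reduces signal drugs to decoys (null
        fixture), 1.0 is maximal signal.  Default 0.9.
    gene_pool_factor: pool size as a multiple of total gene slots
        (default 10; pairwise accidental-overlap probability is then
        roughly genes_per_disease / (10 * n_diseases)).
    rng_seed: master seed; identical seeds give byte-identical fixtures.
    """

    n_related: int = 20
    n_unrelated: int = 200
    genes_per_disease: int = 25
    shared_fraction: float = 0.5
    n_true_drugs: int = 10
    n_decoy_drugs: int = 200
    treats_per_drug: int = 5
    true_drug_bias: float = 0.9
    gene_pool_factor: int = 10
    rng_seed: int = 0
    seed_disease: str = "seed disease"

    def __post_init__(self) -> None:
        counts = {
            "n_related": self.n_related,
            "n_unrelated": self.n_unrelated,
            "genes_per_disease": self.genes_per_disease,
            "n_true_drugs": self.n_true_drugs,
            "n_decoy_drugs": self.n_decoy_drugs,
            "treats_per_drug": self.treats_per_drug,
            "gene_pool_factor": self.gene_pool_factor,
        }
        for name, v in counts.items():
            if v < 1:
                raise ConfigError(f"{name} must be positive, got {v}")
        if not (0.0 < self.shared_fraction <= 1.0):
            raise ConfigError(f"shared_fraction must be in (0, 1], got {self.shared_fraction}")
        if not (0.5 <= self.true_drug_bias <= 1.0):
            raise ConfigError(f"true_drug_bias must be in [0.5, 1], got {self.true_drug_bias}")
        n_treatable = self.n_related + self.n_unrelated
        if self.treats_per_drug > n_treatable:
            raise ConfigError(
                f"treats_per_drug={self.treats_per_drug} exceeds "
                f"{n_treatable} treatable (non-seed) diseases"
            )
        if self.gene_pool_size - self.genes_per_disease < self.genes_per_disease:
            raise ConfigError(
                "gene pool too small for disjoint background draws; "
                "increase gene_pool_factor"
            )

    @property
    def n_diseases(self) -> int:
        return 1 + self.n_related + self.n_unrelated

    @property
    def gene_pool_size(self) -> int:
        return self.gene_pool_factor * self.n_diseases * self.genes_per_disease

    @property
    def n_shared_genes(self) -> int:
        return math.ceil(self.shared_fraction * self.genes_per_disease)


@dataclass(frozen=True)
class SyntheticDataset:
    """A generated fixture: every input the pipeline consumes."""

    config: SyntheticConfig
    associations: DiseaseGeneAssociations
    kb: TreatmentKB
    gold: GoldStandard
    class_map: ClassMap
    seed_disease: str
    related_diseases: tuple[str, ...]
    unrelated_diseases: tuple[str, ...]


def _draw_set(rng: np.random.Generator, pool: np.ndarray, k: int) -> frozenset[str]:
    return frozenset(rng.choice(pool, size=k, replace=False).tolist())


def generate(config: SyntheticConfig = SyntheticConfig()) -> SyntheticDataset:
    """Generate a fixture dataset under the given study conditions."""
    cfg = config
    streams = np.random.SeedSequence(cfg.rng_seed).spawn(3)
    gene_rng = np.random.default_rng(streams[0])
    true_rng = np.random.default_rng(streams[1])
    decoy_rng = np.random.default_rng(streams[2])

    pool = np.array([f"g{k:06d}" for k in range(cfg.gene_pool_size)])
    seed_genes = np.array(sorted(_draw_set(gene_rng, pool, cfg.genes_per_disease)))
    background = np.array(sorted(set(pool.tolist()) - set(seed_genes.tolist())))

    entries: dict[str, frozenset[str]] = {cfg.seed_disease: frozenset(seed_genes.tolist())}
    related = tuple(f"related disease {k:03d}" for k in range(1, cfg.n_related + 1))
    unrelated = tuple(f"unrelated disease {k:03d}" for k in range(1, cfg.n_unrelated + 1))
    n_private = cfg.genes_per_disease - cfg.n_shared_genes
    for name in related:
        shared = _draw_set(gene_rng, seed_genes, cfg.n_shared_genes)
        private = _draw_set(gene_rng, background, n_private) if n_private else frozenset()
        entries[name] = shared | private
    for name in unrelated:
        entries[name] = _draw_set(gene_rng, background, cfg.genes_per_disease)
    assoc = DiseaseGeneAssociations(entries)

    pairs: set[tuple[str, str, str]] = set()

    def _treated(rng: np.random.Generator, bias: float) -> set[str]:
        chosen: set[str] = set()
        while len(chosen) < cfg.treats_per_drug:
            rel_left = [d for d in related if d not in chosen]
            unrel_left = [d for d in unrelated if d not in chosen]
            use_related = rng.random() < bias
            pool_ = rel_left if (use_related and rel_left) else (unrel_left or rel_left)
            chosen.add(pool_[rng.integers(len(pool_))])
        return chosen

    true_drugs = tuple(f"signal drug {k:03d}" for k in range(1, cfg.n_true_drugs + 1))
    for drug in true_drugs:
        for disease in _treated(true_rng, cfg.true_drug_bias):
            pairs.add((drug, disease, "trials"))
    for k in range(1, cfg.n_decoy_drugs + 1):
        drug = f"decoy drug {k:03d}"
        for disease in _treated(decoy_rng, 0.5):
            pairs.add((drug, disease, "literature"))

    kb = TreatmentKB(frozenset(pairs))
    gold = GoldStandard(frozenset(true_drugs), label="planted")
    cmap = ClassMap(
        {**{d: frozenset({RELATED_CLASS}) for d in related},
         **{d: frozenset({BACKGROUND_CLASS}) for d in unrelated}}
    )
    return SyntheticDataset(
        config=cfg,
        associations=assoc,
        kb=kb,
        gold=gold,
        class_map=cmap,
        seed_disease=cfg.seed_disease,
        related_diseases=related,
        unrelated_diseases=unrelated,
    )


def write_dataset(ds: SyntheticDataset, outdir: str | Path) -> Mapping[str, Path]:
    """Write the fixture as the exact TSV dialects the readers consume.

    Deterministic: the same dataset writes byte-identical files.
    Returns the paths keyed by artifact name.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    paths["associations"] = outdir / "associations.tsv"
    write_associations(ds.associations, paths["associations"])
    for source, p in write_treatment_kb(ds.kb, outdir).items():
        paths[f"treatments_{source}"] = p
    paths["gold"] = outdir / "gold_planted.txt"
    write_gold(ds.gold, paths["gold"])
    paths["disease_classes"] = outdir / "disease_classes.tsv"
    write_class_map(ds.class_map, paths["disease_classes"])
    return paths
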