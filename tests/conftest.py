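import numpy as np
import pytest

from gdnrepo import (
    DiseaseGeneAssociations,
    build_gdn,
    column_normalize,
    de_novo_mask,
    rank_from_matrix,
    retrospective_eval,
    score_drugs,
)
from gdnrepo.synthetic import SyntheticConfig, generate


@pytest.fixture
def tiny_assoc() -> DiseaseGeneAssociations:
    """Three diseases, one overlapping pair (d1-d2 share g2), one loner."""
    return DiseaseGeneAssociations(
        {
            "d1": frozenset({"g1", "g2"}),
            "d2": frozenset({"g2", "g3"}),
            "d3": frozenset({"g4"}),
        }
    )


@pytest.fixture(scope="session")
def signal_dataset():
    """One deterministic signal-configuration fixture, shared across tests."""
    return generate(SyntheticConfig(rng_seed=7))


def run_repositioning(dataset, **eval_kwargs):
    """Full pipeline on a synthetic dataset; returns (disease_ranking, drug_ranking, report)."""
    net = build_gdn(dataset.associations)
    ranking = rank_from_matrix(column_normalize(net), dataset.seed_disease)
    masked = de_novo_mask(dataset.kb, dataset.seed_disease)
    drugs = score_drugs(ranking, masked)
    report = retrospective_eval(drugs, dataset.gold, **eval_kwargs)
    return ranking, drugs, report


def random_transition_matrix(rng: np.random.Generator, n: int):
    """A random weighted graph's column-normalized transition matrix."""
    from gdnrepo.gdn import GeneticDiseaseNetwork

    nodes = tuple(f"n{k:03d}" for k in range(n))
    edges = {}
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < min(1.0, 3.0 / n):
                edges[(i, j)] = float(rng.uniform(0.05, 1.0))
    return column_normalize(GeneticDiseaseNetwork(nodes, edges))
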