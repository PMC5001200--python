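"""Random walk with restart: fixed points, closed forms, oracle equivalence."""

import numpy as np
import pytest
import scipy.sparse as sp

from gdnrepo.gdn import GeneticDiseaseNetwork, TransitionMatrix, column_normalize
from gdnrepo.rwr import (
    ConvergenceError,
    RWRParams,
    rank_diseases,
    rank_from_matrix,
    rwr_steady_state,
    seed_vector,
)

from conftest import random_transition_matrix


def direct_solve(M: TransitionMatrix, p0: np.ndarray, gamma: float) -> np.ndarray:
    """Independent oracle: p = gamma * (I - (1-gamma) M)^-1 p0."""
    A = np.eye(M.n) - (1 - gamma) * M.matrix.toarray()
    return gamma * np.linalg.solve(A, p0)


def path_matrix(n: int) -> TransitionMatrix:
    nodes = tuple(f"p{k}" for k in range(n))
    edges = {(k, k + 1): 1.0 for k in range(n - 1)}
    return column_normalize(GeneticDiseaseNetwork(nodes, edges))


class TestParams:
    @pytest.mark.parametrize(
        "kwargs", [{"gamma": 0.0}, {"gamma": 1.5}, {"tol": 0.0}, {"norm": "l7"}, {"max_iter": 0}]
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            RWRParams(**kwargs)


class TestSteadyState:
    def test_seed_on_isolated_node_retains_only_restart_mass(self):
        """An isolated seed's column is zero: the walk term vanishes and the
        fixed point is gamma * p0 exactly (mass leaks, restart reinjects)."""
        net = GeneticDiseaseNetwork(("a", "b", "c"), {(1, 2): 1.0})
        M = column_normalize(net)
        p0 = seed_vector(M.nodes, ["a"])
        params = RWRParams(gamma=0.1)
        ss = rwr_steady_state(M, p0, params)
        assert ss.iterations == 2  # second sweep confirms the fixed point
        assert np.allclose(ss.p, params.gamma * p0)

    def test_two_node_graph_matches_closed_form(self):
        """p_seed = gamma / (1 - (1-gamma)^2) on a single-edge graph."""
        M = column_normalize(GeneticDiseaseNetwork(("a", "b"), {(0, 1): 0.5}))
        ss = rwr_steady_state(M, seed_vector(M.nodes, ["a"]), RWRParams(gamma=0.1))
        assert ss.p[0] == pytest.approx(0.52632, abs=1e-5)
        assert ss.p[1] == pytest.approx(0.47368, abs=1e-5)

    def test_triangle_symmetry_is_exact(self):
        nodes = ("a", "b", "c")
        edges = {(0, 1): 1.0, (0, 2): 1.0, (1, 2): 1.0}
        M = column_normalize(GeneticDiseaseNetwork(nodes, edges))
        ss = rwr_steady_state(M, seed_vector(nodes, ["a"]))
        assert ss.p[1] == ss.p[2]

    def test_path_graph_scores_decay_with_distance(self):
        M = path_matrix(5)
        p = direct_solve(M, seed_vector(M.nodes, ["p0"]), 0.1)
        ss = rwr_steady_state(M, seed_vector(M.nodes, ["p0"]))
        assert np.allclose(ss.p, p, atol=1e-5)
        # non-seed scores strictly decrease with distance from the seed
        assert all(ss.p[k] > ss.p[k + 1] for k in range(1, 4))

    def test_iterative_fixed_point_matches_direct_solve(self):
        """L1 stopping rule: the fixed point agrees with the linear solve
        to within 10*tol in L1 (the geometric tail is bounded by
        (1-gamma)/gamma times the last change)."""
        rng = np.random.default_rng(11)
        for _ in range(10):
            M = random_transition_matrix(rng, int(rng.integers(5, 60)))
            seed = M.nodes[int(rng.integers(M.n))]
            params = RWRParams()
            p0 = seed_vector(M.nodes, [seed])
            ss = rwr_steady_state(M, p0, params)
            exact = direct_solve(M, p0, params.gamma)
            assert np.abs(ss.p - exact).sum() < 10 * params.tol

    @pytest.mark.parametrize("norm", ["l2", "max"])
    def test_alternate_change_norms_still_reach_the_fixed_point(self, norm):
        """l2/max stopping rules carry no tight L1 guarantee but must still
        land close to the linear-solve fixed point."""
        rng = np.random.default_rng(17)
        for _ in range(5):
            M = random_transition_matrix(rng, int(rng.integers(5, 60)))
            seed = M.nodes[int(rng.integers(M.n))]
            p0 = seed_vector(M.nodes, [seed])
            ss = rwr_steady_state(M, p0, RWRParams(norm=norm))
            exact = direct_solve(M, p0, 0.1)
            assert np.allclose(ss.p, exact, atol=1e-4)

    def test_probability_mass_conserved_without_isolated_nodes(self):
        M = column_normalize(
            GeneticDiseaseNetwork(("a", "b", "c"), {(0, 1): 0.2, (1, 2): 0.9})
        )
        ss = rwr_steady_state(M, seed_vector(M.nodes, ["b"]))
        assert ss.p.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(ss.p >= 0)

    def test_mass_leaks_toward_isolated_neighbours_only_via_restart(self):
        # b walks to a and c; c is a sink column (isolated from the walk's view)
        net = GeneticDiseaseNetwork(("a", "b", "c", "d"), {(0, 1): 1.0})
        M = column_normalize(net)
        ss = rwr_steady_state(M, seed_vector(M.nodes, ["a"]))
        assert ss.p.sum() <= 1.0 + 1e-9

    def test_hitting_the_iteration_cap_raises(self):
        M = path_matrix(30)
        with pytest.raises(ConvergenceError, match="2 iterations"):
            rwr_steady_state(M, seed_vector(M.nodes, ["p0"]), RWRParams(max_iter=2))

    def test_bad_seed_vector_rejected(self):
        M = path_matrix(3)
        with pytest.raises(ValueError):
            rwr_steady_state(M, np.array([0.5, 0.2, 0.1]))


class TestRanking:
    def test_only_seed_nonzero_yields_empty_ranking(self):
        r = rank_diseases(np.array([1.0, 0.0, 0.0]), "a", ("a", "b", "c"))
        assert len(r) == 0

    def test_ties_break_lexicographically_with_consecutive_ranks(self):
        r = rank_diseases(np.array([0.5, 0.25, 0.25]), "s", ("s", "zeta", "beta"))
        assert [(e.disease, e.rank) for e in r.entries] == [("beta", 1), ("zeta", 2)]

    def test_path_ranking_orders_by_distance_from_seed(self):
        M = path_matrix(5)
        r = rank_from_matrix(M, "p0")
        assert r.diseases == ("p1", "p2", "p3", "p4")
        assert r.seed == "p0"
        scores = [e.score for e in r.entries]
        assert scores == sorted(scores, reverse=True)

    def test_isolated_nodes_are_excluded_from_the_ranked_list(self):
        net = GeneticDiseaseNetwork(("a", "b", "z"), {(0, 1): 1.0})
        r = rank_from_matrix(column_normalize(net), "a")
        assert "z" not in r.diseases
        assert len(r) == 1

    def test_identical_inputs_give_identical_rankings(self):
        M = path_matrix(8)
        r1 = rank_from_matrix(M, "p3")
        r2 = rank_from_matrix(M, "p3")
        assert r1 == r2

    def test_multi_seed_vector_splits_mass_uniformly(self):
        p0 = seed_vector(("a", "b", "c", "d"), ["b", "d"])
        assert p0.tolist() == [0.0, 0.5, 0.0, 0.5]
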