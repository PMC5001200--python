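"""Random walk with restart (RWR) over the genetic disease network.

The walker iterates  p(t+1) = (1 - gamma) * M @ p(t) + gamma * p0
until the change between successive vectors falls below a tolerance,
where M is the column-normalized adjacency matrix, gamma the restart
probability (0.1 by default) and p0 the seed distribution (probability
1.0 on the seed disease).  Diseases are ranked by the steady-state
probabilities; the seed itself and zero-score (unreachable) diseases
are excluded, which is why the ranked list can be shorter than the
node count.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .gdn import TransitionMatrix

__all__ = [
    "RWRParams",
    "ConvergenceError",
    "SteadyState",
    "RankedDisease",
    "DiseaseRanking",
    "seed_vector",
    "rwr_steady_state",
    "rank_diseases",
    "rank_from_matrix",
]

_NORMS = {"l1": 1, "l2": 2, "max": np.inf}


class ConvergenceError(RuntimeError):
    """Raised when the iteration cap is hit before the change drops below tol."""

    def __init__(self, max_iter: int, last_change: float):
        super().__init__(
            f"no convergence after {max_iter} iterations (last change {last_change:.3e})"
        )
        self.max_iter = max_iter
        self.last_change = last_change


@dataclass(frozen=True)
class RWRParams:
    """Walk parameters.

    gamma: restart probability in (0, 1); each step returns this much
        mass to the seed distribution.
    tol: convergence threshold on the change between successive
        probability vectors.
    max_iter: iteration cap.
    norm: which norm measures the change ("l1" default, "l2", "max").
    """

    gamma: float = 0.1
    tol: float = 1e-6
    max_iter: int = 10_000
    norm: str = "l1"

    def __post_init__(self) -> None:
        if not (0.0 < self.gamma < 1.0):
            raise ValueError(f"gamma must be in (0, 1), got {self.gamma}")
        if self.tol <= 0:
            raise ValueError(f"tol must be positive, got {self.tol}")
        if self.max_iter < 1:
            raise ValueError(f"max_iter must be >= 1, got {self.max_iter}")
        if self.norm not in _NORMS:
            raise ValueError(f"norm must be one of {sorted(_NORMS)}, got {self.norm!r}")


@dataclass(frozen=True)
class SteadyState:
    """Converged probability vector plus iteration metadata."""

    p: np.ndarray
    iterations: int
    final_change: float


def seed_vector(nodes: Sequence[str], seeds: Sequence[str]) -> np.ndarray:
    """Initial distribution p0: uniform over the seed diseases.

    With a single seed this is the canonical "probability 1.0 on the
    seed" start; multiple seeds share the mass uniformly.
    """
    if not seeds:
        raise ValueError("at least one seed disease required")
    p0 = np.zeros(len(nodes))
    index = {n: k for k, n in enumerate(nodes)}
    for s in seeds:
        if s not in index:
            raise KeyError(f"seed disease {s!r} not in the network")
        p0[index[s]] = 1.0 / len(seeds)
    return p0


def rwr_steady_state(
    M: TransitionMatrix, p0: np.ndarray, params: RWRParams = RWRParams()
) -> SteadyState:
    """Iterate the walk to its fixed point.

    Stops at the first p(t+1) whose distance from p(t), in the configured
    norm, is below ``params.tol``.  The result is nonnegative and sums to
    at most 1; it sums to exactly 1 unless the walk can reach a zero
    column (isolated node), where mass leaks.
    """
    p0 = np.asarray(p0, dtype=float)
    if p0.shape != (M.n,):
        raise ValueError(f"p0 has shape {p0.shape}, expected ({M.n},)")
    if np.any(p0 < 0) or not np.isclose(p0.sum(), 1.0):
        raise ValueError("p0 must be a probability vector (nonnegative, sums to 1)")

    ord_ = _NORMS[params.norm]
    restart = params.gamma * p0
    damp = 1.0 - params.gamma
    p = p0
    change = np.inf
    for it in range(1, params.max_iter + 1):
        p_next = damp * (M.matrix @ p) + restart
        change = float(np.linalg.norm(p_next - p, ord=ord_))
        p = p_next
        if change < params.tol:
            return SteadyState(p, it, change)
    raise ConvergenceError(params.max_iter, change)


@dataclass(frozen=True)
class RankedDisease:
    disease: str
    score: float
    rank: int


@dataclass(frozen=True)
class DiseaseRanking:
    """Diseases ordered by steady-state score, seed excluded.

    Ties break lexicographically by name; ranks run 1..len(entries).
    """

    entries: tuple[RankedDisease, ...]
    seed: str
    iterations_used: int = 0

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def diseases(self) -> tuple[str, ...]:
        return tuple(e.disease for e in self.entries)

    def score_of(self, disease: str) -> float:
        for e in self.entries:
            if e.disease == disease:
                return e.score
        return 0.0

    def percentile_of(self, disease: str) -> float | None:
        for e in self.entries:
            if e.disease == disease:
                return round(100.0 * e.rank / len(self.entries), 2)
        return None

    def to_frame(self):
        import pandas as pd

        n = len(self.entries)
        return pd.DataFrame(
            {
                "disease": [e.disease for e in self.entries],
                "score": [e.score for e in self.entries],
                "rank": [e.rank for e in self.entries],
                "percentile": [round(100.0 * e.rank / n, 2) for e in self.entries],
            }
        )


def rank_diseases(
    p: np.ndarray,
    seed: str,
    node_order: Sequence[str],
    *,
    score_floor: float = 0.0,
    iterations_used: int = 0,
) -> DiseaseRanking:
    """Rank diseases by steady-state score.

    Drops the seed and every disease with score <= ``score_floor``
    (exact zeros by default: isolated or unreachable nodes), then orders
    by descending score with lexicographic tie-break.
    """
    scored = [
        (node, float(s))
        for node, s in zip(node_order, p)
        if node != seed and s > score_floor
    ]
    scored.sort(key=lambda t: (-t[1], t[0]))
    entries = tuple(
        RankedDisease(d, s, k + 1) for k, (d, s) in enumerate(scored)
    )
    return DiseaseRanking(entries, seed=seed, iterations_used=iterations_used)


def rank_from_matrix(
    M: TransitionMatrix,
    seed: str,
    params: RWRParams = RWRParams(),
    *,
    score_floor: float = 0.0,
) -> DiseaseRanking:
    """Convenience: seed vector -> steady state -> ranking, in one call."""
    p0 = seed_vector(M.nodes, [seed])
    ss = rwr_steady_state(M, p0, params)
    return rank_diseases(
        ss.p, seed, M.nodes, score_floor=score_floor, iterations_used=ss.iterations
    )
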