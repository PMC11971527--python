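"""Structural connectome construction.

Weighted, symmetric, non-negative coupling matrices are the structural scaffold
of the whole-brain model: entry ``C[i, j]`` plays the role of fiber density
between regions *i* and *j*.  This module generates synthetic connectomes
(Watts-Strogatz small-world and Barabasi-Albert scale-free graphs with
exponentially distributed edge weights) and applies the standard tractography
clean-up pipeline: consensus thresholding across subjects, proportional
thresholding of the strongest links, symmetrization and max-normalization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .exceptions import InvalidConfigurationError, InvalidInputError

__all__ = [
    "WeightedConnectome",
    "generate_ws_network",
    "generate_ba_network",
    "consensus_threshold",
    "proportional_threshold",
    "symmetrize",
    "normalize_max",
    "normalize_strength",
]


@dataclass
class WeightedConnectome:
    """N x N symmetric non-negative coupling matrix with region labels.

    Attributes
    ----------
    weights:
        Square matrix of non-negative coupling weights; zero diagonal.
    labels:
        Region identifiers, one per row/column.
    """

    weights: np.ndarray
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise InvalidInputError(f"connectome matrix must be square, got shape {w.shape}")
        if np.any(w < 0):
            raise InvalidInputError("connectome weights must be non-negative")
        if not np.all(np.isfinite(w)):
            raise InvalidInputError("connectome weights must be finite")
        np.fill_diagonal(w, 0.0)
        self.weights = w
        if not self.labels:
            self.labels = [f"R{i:03d}" for i in range(w.shape[0])]
        elif len(self.labels) != w.shape[0]:
            raise InvalidInputError("number of labels must match matrix size")

    @property
    def n(self) -> int:
        return self.weights.shape[0]

    @property
    def density(self) -> float:
        """Fraction of nonzero off-diagonal entries (undirected)."""
        n = self.n
        iu = np.triu_indices(n, k=1)
        return float(np.count_nonzero(self.weights[iu]) / len(iu[0]))


def _ws_neighbor_count(n: int, density: float) -> int:
    """Nearest even integer to density*(n-1) -- the ring-lattice degree."""
    k = int(2 * round(density * (n - 1) / 2.0))
    return k


def _assign_exponential_weights(
    adjacency: np.ndarray, rng: np.random.Generator, rate: float = 1.0
) -> np.ndarray:
    """Give each undirected edge an independent Exp(rate) weight."""
    n = adjacency.shape[0]
    weights = np.zeros((n, n))
    iu = np.triu_indices(n, k=1)
    mask = adjacency[iu] > 0
    draws = rng.exponential(scale=1.0 / rate, size=int(mask.sum()))
    vals = np.zeros(len(iu[0]))
    vals[mask] = draws
    weights[iu] = vals
    return weights + weights.T


def generate_ws_network(
    n: int,
    density: float,
    rewiring_p: float,
    seed: int,
    *,
    rate: float = 1.0,
) -> WeightedConnectome:
    """Watts-Strogatz small-world connectome with exponential edge weights.

    The ring-lattice neighbour count is the nearest even integer to
    ``density * (n - 1)``; each edge is then rewired with probability
    ``rewiring_p`` and all surviving/rewired edges receive fresh
    exponentially distributed weights.

    Parameters
    ----------
    n:
        Number of regions (>= 3).
    density:
        Target fraction of possible undirected edges, in (0, 1).
    rewiring_p:
        Probability of rewiring each lattice edge, in [0, 1].
    seed:
        Seed for graph topology and weight draws.
    rate:
        Rate of the exponential weight distribution (default 1; pass the
        result through :func:`normalize_max` before simulation).
    """
    if n < 3:
        raise InvalidConfigurationError(f"n must be >= 3, got {n}")
    if not 0 < density < 1:
        raise InvalidConfigurationError(f"density must be in (0, 1), got {density}")
    if not 0 <= rewiring_p <= 1:
        raise InvalidConfigurationError(f"rewiring_p must be in [0, 1], got {rewiring_p}")
    k = _ws_neighbor_count(n, density)
    if k < 2 or k >= n:
        raise InvalidConfigurationError(
            f"density {density} infeasible for n={n}: implied neighbour count k={k}"
        )
    ss = np.random.SeedSequence(seed)
    graph_seed, weight_seed = (int(s) for s in ss.generate_state(2) >> 1)
    g = nx.watts_strogatz_graph(n, k, rewiring_p, seed=graph_seed)
    adjacency = nx.to_numpy_array(g, dtype=float)
    rng = np.random.default_rng(weight_seed)
    weights = _assign_exponential_weights(adjacency, rng, rate)
    return WeightedConnectome(weights)


def generate_ba_network(
    n: int,
    density: float,
    seed: int,
    *,
    rate: float = 1.0,
) -> WeightedConnectome:
    """Barabasi-Albert scale-free connectome with exponential edge weights.

    The attachment parameter is ``m = round(density * (n - 1) / 2)``;
    preferential attachment cannot hit an arbitrary density exactly, so
    inspect ``result.density`` for the realized value.
    """
    if n < 3:
        raise InvalidConfigurationError(f"n must be >= 3, got {n}")
    if not 0 < density < 1:
        raise InvalidConfigurationError(f"density must be in (0, 1), got {density}")
    m = max(1, int(round(density * (n - 1) / 2.0)))
    if m >= n:
        raise InvalidConfigurationError(
            f"density {density} infeasible for n={n}: attachment m={m}"
        )
    ss = np.random.SeedSequence(seed)
    graph_seed, weight_seed = (int(s) for s in ss.generate_state(2) >> 1)
    g = nx.barabasi_albert_graph(n, m, seed=graph_seed)
    adjacency = nx.to_numpy_array(g, dtype=float)
    rng = np.random.default_rng(weight_seed)
    weights = _assign_exponential_weights(adjacency, rng, rate)
    return WeightedConnectome(weights)


def consensus_threshold(
    connectomes: list[WeightedConnectome], min_fraction: float = 0.75
) -> WeightedConnectome:
    """Keep edges present in at least ``min_fraction`` of subjects.

    Retained edges carry the across-subject mean weight (the mean over all
    subjects, absent edges contributing zero, matching averaging the edge
    across the full cohort).
    """
    if not connectomes:
        raise InvalidInputError("consensus_threshold requires at least one connectome")
    if not 0 < min_fraction <= 1:
        raise InvalidConfigurationError(f"min_fraction must be in (0, 1], got {min_fraction}")
    n = connectomes[0].n
    if any(c.n != n for c in connectomes):
        raise InvalidInputError("all connectomes must share the same size")
    stack = np.stack([c.weights for c in connectomes])
    presence = (stack > 0).mean(axis=0)
    mean_w = stack.mean(axis=0)
    out = np.where(presence >= min_fraction, mean_w, 0.0)
    return WeightedConnectome(out, list(connectomes[0].labels))


def proportional_threshold(
    c: WeightedConnectome, keep_fraction: float = 0.35
) -> WeightedConnectome:
    """Retain the strongest ``keep_fraction`` of upper-triangle weights.

    The number kept is ``ceil(keep_fraction * n*(n-1)/2)``.  Ties are broken
    by a stable ordering: weight descending, then row index, then column
    index ascending.  Applied to the upper triangle and mirrored, so a
    symmetric input stays symmetric.
    """
    if not 0 < keep_fraction <= 1:
        raise InvalidConfigurationError(f"keep_fraction must be in (0, 1], got {keep_fraction}")
    n = c.n
    iu = np.triu_indices(n, k=1)
    m = len(iu[0])
    n_keep = int(np.ceil(keep_fraction * m))
    vals = c.weights[iu]
    # stable sort: weight desc, then (i, j) asc; np.lexsort keys are last-major
    order = np.lexsort((iu[1], iu[0], -vals))
    keep_idx = order[:n_keep]
    out = np.zeros_like(c.weights)
    out[iu[0][keep_idx], iu[1][keep_idx]] = vals[keep_idx]
    out = out + out.T
    return WeightedConnectome(out, list(c.labels))


def symmetrize(c: WeightedConnectome) -> WeightedConnectome:
    """Elementwise mean of the matrix and its transpose."""
    return WeightedConnectome((c.weights + c.weights.T) / 2.0, list(c.labels))


def normalize_max(c: WeightedConnectome, target_max: float = 0.3) -> WeightedConnectome:
    """Scale all weights so the maximum equals ``target_max`` (default 0.3)."""
    w_max = c.weights.max()
    if w_max <= 0:
        raise InvalidInputError("cannot max-normalize an all-zero connectome")
    return WeightedConnectome(c.weights * (target_max / w_max), list(c.labels))


def normalize_strength(
    c: WeightedConnectome, target_mean_strength: float = 0.6
) -> WeightedConnectome:
    """Scale weights so the mean node strength (row sum) hits the target.

    The dynamical regime of the coupled-oscillator model depends on the
    product of the global coupling G and the node strengths, so two
    connectomes are dynamically comparable only at matched strength scale.
    Empirical tractography matrices max-normalized to 0.3 are heavy-tailed
    and carry mean strengths well below synthetic exponential-weight graphs
    at the same maximum; normalizing the strength instead places the
    synchronization transition of the critical (a = 0) system inside the
    conventional G scan range (0 to 2).
    """
    s = c.weights.sum(axis=1).mean()
    if s <= 0:
        raise InvalidInputError("cannot strength-normalize an all-zero connectome")
    return WeightedConnectome(c.weights * (target_mean_strength / s), list(c.labels))
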