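"""Communication predictors derived from a structural connectome.

These matrices quantify geometric, topological and dynamical relations
between regions under different models of signal propagation on the white
matter network: diffusive (flow graphs, mean first passage time,
communicability), routed (shortest path length under a weight-to-cost
transform, search information, path transitivity), similarity-based
(matching index) and purely geometric (Euclidean distance). Stacked
together they form the design matrix of the communication-model regression
of FC on SC.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.linalg import expm
from scipy.sparse.csgraph import connected_components, dijkstra
from scipy.spatial.distance import pdist, squareform

from .matrices import ConnectomeMatrix, InvalidInputError

DEFAULT_T_GRID = (1.0, 2.5, 5.0, 10.0)
DEFAULT_GAMMA_GRID = (0.25, 0.5, 1.0, 2.0)


@dataclass(frozen=True)
class PredictorStack:
    """Ordered, named stack of symmetric n x n predictor matrices."""

    names: tuple[str, ...]
    matrices: tuple[np.ndarray, ...]

    @property
    def q(self) -> int:
        return len(self.matrices)


def _values(sc) -> np.ndarray:
    return sc.values if isinstance(sc, ConnectomeMatrix) else np.asarray(sc, dtype=float)


def _require_connected(adj: np.ndarray, what: str) -> None:
    n_comp, _ = connected_components(adj > 0, directed=False)
    if n_comp > 1:
        raise InvalidInputError(f"{what} requires a connected graph ({n_comp} components found)")


def flow_graph(sc, t: float) -> np.ndarray:
    """Continuous-time random-walk flow at time t.

    With node strengths s and random-walk Laplacian L = I - diag(s)^-1 SC,
    the flow is diag(s) exp(-t L) normalized by total strength, then
    symmetrized. Entries are joint probabilities (source drawn from the
    stationary distribution, walker observed at the target after time t);
    they sum to 1 for every t.
    """
    if t <= 0:
        raise InvalidInputError("flow-graph time must be positive")
    adj = _values(sc)
    _require_connected(adj, "flow graph")
    s = adj.sum(axis=1)
    lap = np.eye(len(s)) - adj / s[:, None]
    flow = (s[:, None] * expm(-t * lap)) / s.sum()
    return (flow + flow.T) / 2.0


def mean_first_passage(sc, zscore_columns: bool = True) -> np.ndarray:
    """Mean first passage time of a discrete-time random walk.

    Computed from the fundamental matrix Z = (I - P + 1 pi^T)^-1 of the
    walk with transition matrix P = diag(s)^-1 SC and stationary
    distribution pi = s / sum(s):  MFPT(i -> j) = (Z_jj - Z_ij) / pi_j.
    Columns are then z-scored over their off-diagonal entries to remove
    nodal accessibility biases, and the result is symmetrized by averaging
    with its transpose.
    """
    adj = _values(sc)
    _require_connected(adj, "mean first passage time")
    n = adj.shape[0]
    s = adj.sum(axis=1)
    p = adj / s[:, None]
    pi = s / s.sum()
    z = np.linalg.inv(np.eye(n) - p + np.outer(np.ones(n), pi))
    mfpt = (np.diag(z)[None, :] - z) / pi[None, :]
    np.fill_diagonal(mfpt, 0.0)
    if zscore_columns:
        off = ~np.eye(n, dtype=bool)
        out = np.zeros_like(mfpt)
        for j in range(n):
            col = mfpt[off[:, j], j]
            out[off[:, j], j] = (col - col.mean()) / col.std()
        mfpt = out
    return (mfpt + mfpt.T) / 2.0


def communicability(sc) -> np.ndarray:
    """Weighted sum over all walks between regions: exp(SC)."""
    return expm(_values(sc))


def matching_index(sc) -> np.ndarray:
    """Jaccard similarity of the (binarized) neighbor sets of node pairs.

    Neighborhoods exclude the pair itself; pairs whose union is empty get 0.
    Diagonal is 0.
    """
    adj = _values(sc) > 0
    n = adj.shape[0]
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            keep = np.ones(n, dtype=bool)
            keep[[i, j]] = False
            inter = np.sum(adj[i] & adj[j] & keep)
            union = np.sum((adj[i] | adj[j]) & keep)
            out[i, j] = out[j, i] = inter / union if union else 0.0
    return out


def weight_to_cost(sc, gamma: float) -> np.ndarray:
    """Convert connection weights to travel costs via SC^(-gamma).

    Absent edges become infinite cost.
    """
    if gamma <= 0:
        raise InvalidInputError("gamma must be positive")
    adj = _values(sc)
    costs = np.full(adj.shape, np.inf)
    mask = adj > 0
    costs[mask] = adj[mask] ** (-gamma)
    np.fill_diagonal(costs, 0.0)
    return costs


def shortest_path_length(costs: np.ndarray) -> np.ndarray:
    """All-pairs shortest path costs (Dijkstra) on a nonnegative cost matrix."""
    costs = np.asarray(costs, dtype=float)
    if (costs < 0).any():
        raise InvalidInputError("costs must be nonnegative")
    graph = np.where(np.isfinite(costs), costs, 0.0)
    dist = dijkstra(graph, directed=False)
    if not np.isfinite(dist).all():
        raise InvalidInputError("graph is disconnected; some pairs unreachable")
    return dist


def _shortest_path_nodes(costs: np.ndarray, dist: np.ndarray, i: int, j: int) -> list[int]:
    """Node sequence of the i->j shortest path, reconstructed backwards.

    At each step the lowest-index predecessor u with
    dist[i, u] + costs[u, v] == dist[i, v] wins, so paths are deterministic
    even when several shortest paths tie.
    """
    path = [j]
    v = j
    while v != i:
        finite = np.isfinite(costs[:, v])
        cand = np.flatnonzero(finite & np.isclose(dist[i] + costs[:, v], dist[i, v], rtol=1e-10, atol=1e-12))
        cand = cand[cand != v]
        if cand.size > 1:
            warnings.warn("degenerate shortest paths; lowest-index predecessor used", stacklevel=3)
        u = int(cand[0])
        path.append(u)
        v = u
    return path[::-1]


def search_information(sc, gamma: float) -> np.ndarray:
    """Bits needed for a random walker to follow the shortest path.

    SI(i -> j) = -log2 of the probability that a walker with transition
    probabilities proportional to weights takes the gamma-cost shortest
    path from i to j; symmetrized by averaging the two directions. When
    several shortest paths tie, the deterministic lowest-index path is used.
    """
    adj = _values(sc)
    _require_connected(adj, "search information")
    n = adj.shape[0]
    costs = weight_to_cost(adj, gamma)
    dist = shortest_path_length(costs)
    p = adj / adj.sum(axis=1)[:, None]
    si = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            path = _shortest_path_nodes(costs, dist, i, j)
            logprob = sum(np.log2(p[u, v]) for u, v in zip(path[:-1], path[1:]))
            si[i, j] = -logprob
    return (si + si.T) / 2.0


def path_transitivity(sc, gamma: float) -> np.ndarray:
    """Density of local detours around each shortest path.

    For the gamma-cost shortest path node sequence pi(i, j),
    PT = sum over ordered pairs u != v in pi of matching(u, v),
    divided by |pi| (|pi| - 1). For adjacent pairs (two-node paths) this
    reduces to the matching index of the pair.
    """
    adj = _values(sc)
    _require_connected(adj, "path transitivity")
    n = adj.shape[0]
    costs = weight_to_cost(adj, gamma)
    dist = shortest_path_length(costs)
    match = matching_index(adj)
    pt = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            path = _shortest_path_nodes(costs, dist, i, j)
            sub = match[np.ix_(path, path)]
            m = len(path)
            pt[i, j] = pt[j, i] = sub.sum() / (m * (m - 1))
    return pt


def euclidean_distance(coords: np.ndarray) -> np.ndarray:
    """Pairwise Euclidean distances between node coordinates (mm)."""
    coords = np.asarray(coords, dtype=float)
    if not np.isfinite(coords).all():
        raise InvalidInputError("coordinates must be finite")
    return squareform(pdist(coords))


def build_stack(
    sc,
    coords: np.ndarray,
    t_grid: tuple[float, ...] = DEFAULT_T_GRID,
    gamma_grid: tuple[float, ...] = DEFAULT_GAMMA_GRID,
) -> PredictorStack:
    """Assemble the full communication predictor stack.

    Default grids give Q = 20 predictors: 4 flow graphs, MFPT,
    communicability, matching index, 4 shortest-path, 4 path-transitivity
    and 4 search-information matrices, plus Euclidean distance.
    """
    names: list[str] = []
    mats: list[np.ndarray] = []

    def fmt(x: float) -> str:
        return f"{x:g}"

    for t in t_grid:
        names.append(f"flow_t{fmt(t)}")
        mats.append(flow_graph(sc, t))
    names.append("mfpt_z")
    mats.append(mean_first_passage(sc))
    names.append("communicability")
    mats.append(communicability(sc))
    names.append("matching")
    mats.append(matching_index(sc))
    for g in gamma_grid:
        names.append(f"spl_g{fmt(g)}")
        mats.append(shortest_path_length(weight_to_cost(sc, g)))
    for g in gamma_grid:
        names.append(f"pt_g{fmt(g)}")
        mats.append(path_transitivity(sc, g))
    for g in gamma_grid:
        names.append(f"si_g{fmt(g)}")
        mats.append(search_information(sc, g))
    names.append("euclidean")
    mats.append(euclidean_distance(coords))
    for name, mat in zip(names, mats):
        if not np.isfinite(mat).all():
            warnings.warn(f"predictor {name!r} contains non-finite entries", stacklevel=2)
    return PredictorStack(names=tuple(names), matrices=tuple(mats))
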