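"""Least-cost cost-distances over resistance rasters.

Movement is modelled on the 8-connected pixel graph: an orthogonal step
costs ``pixel_size * (r_a + r_b) / 2`` cost-metres and a diagonal step
``pixel_size * sqrt(2) * (r_a + r_b) / 2``, where ``r_a``/``r_b`` are the
resistances of the two pixels.  A dispersal budget ``B`` (cost-metres)
therefore buys a straight-line reach of ``B / r`` metres in homogeneous
habitat of resistance ``r`` — the unit convention behind the per-class
maximal dispersal distances.

Single-source fields and the site x site cost matrix are computed with
truncated Dijkstra searches (scipy); entries beyond the budget are +inf.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import dijkstra

__all__ = [
    "CostMatrix",
    "pixel_graph",
    "cost_distance_field",
    "build_cost_matrix",
    "max_distance_for_budget",
]


@dataclass
class CostMatrix:
    """Site x site least-cost cumulative costs in cost-metres.

    ``costs[i, j]`` is the cumulative resistance of the least-cost path
    between sites ``i`` and ``j``; unreachable pairs (beyond the budget)
    are ``+inf``.  The diagonal is zero and the matrix is symmetric for
    symmetric edge costs.
    """

    ids: np.ndarray
    costs: np.ndarray
    budget: float = math.inf

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids)
        self.costs = np.asarray(self.costs, dtype=float)
        n = len(self.ids)
        if self.costs.shape != (n, n):
            raise ValueError("costs must be square with one row per site id")
        if n and not np.allclose(np.diag(self.costs), 0.0):
            raise ValueError("cost matrix diagonal must be zero")

    def __len__(self) -> int:
        return len(self.ids)


def pixel_graph(resistance: np.ndarray, pixel_size: float) -> sparse.csr_matrix:
    """Sparse undirected 8-neighbour graph over the resistance grid.

    Only one direction per edge is stored; pass ``directed=False`` to the
    scipy shortest-path routines.
    """
    r = np.asarray(resistance, dtype=float)
    if r.ndim != 2 or r.size == 0:
        raise ValueError("resistance must be a non-empty 2-D array")
    if pixel_size <= 0:
        raise ValueError("pixel_size must be > 0")
    nrows, ncols = r.shape
    idx = np.arange(nrows * ncols, dtype=np.int32).reshape(nrows, ncols)
    half = pixel_size / 2.0
    diag_half = half * math.sqrt(2.0)

    rows_list, cols_list, data_list = [], [], []

    def add(src, dst, weight):
        rows_list.append(src.ravel())
        cols_list.append(dst.ravel())
        data_list.append(weight.ravel())

    if ncols > 1:  # horizontal
        add(idx[:, :-1], idx[:, 1:], (r[:, :-1] + r[:, 1:]) * half)
    if nrows > 1:  # vertical
        add(idx[:-1, :], idx[1:, :], (r[:-1, :] + r[1:, :]) * half)
    if nrows > 1 and ncols > 1:  # diagonals
        add(idx[:-1, :-1], idx[1:, 1:], (r[:-1, :-1] + r[1:, 1:]) * diag_half)
        add(idx[:-1, 1:], idx[1:, :-1], (r[:-1, 1:] + r[1:, :-1]) * diag_half)

    n = nrows * ncols
    if not rows_list:
        return sparse.csr_matrix((n, n))
    graph = sparse.coo_matrix(
        (
            np.concatenate(data_list),
            (np.concatenate(rows_list), np.concatenate(cols_list)),
        ),
        shape=(n, n),
    )
    return graph.tocsr()


def cost_distance_field(
    resistance: np.ndarray,
    origin: tuple[int, int],
    budget: float,
    pixel_size: float,
) -> np.ndarray:
    """Least cost from an origin pixel to every pixel, truncated at budget.

    Cells whose least cost exceeds the budget are ``+inf``.  An origin on
    a high-resistance pixel is valid (its own cost is zero).
    """
    if budget <= 0:
        raise ValueError("budget must be > 0")
    r = np.asarray(resistance, dtype=float)
    nrows, ncols = r.shape
    row, col = origin
    if not (0 <= row < nrows and 0 <= col < ncols):
        raise ValueError(f"origin {origin} outside grid {r.shape}")
    graph = pixel_graph(r, pixel_size)
    dist = dijkstra(graph, directed=False, indices=row * ncols + col, limit=budget)
    return dist.reshape(nrows, ncols)


def build_cost_matrix(
    resistance: np.ndarray,
    sites,
    budget: float,
    pixel_size: float,
    origin_xy: tuple[float, float] = (0.0, 0.0),
    batch_size: int | None = None,
) -> CostMatrix:
    """Site x site least-cost matrix: one truncated Dijkstra per site.

    ``sites`` is a :class:`~fraglands.landscape.SiteSet` whose coordinates
    are interpreted on the grid defined by ``origin_xy``/``pixel_size``.
    Entries above the budget are ``+inf``.  Sources are processed in
    batches to bound the dense distance block held in memory.
    """
    if budget <= 0:
        raise ValueError("budget must be > 0")
    n_sites = len(sites)
    if n_sites == 0:
        return CostMatrix(np.array([], dtype=int), np.zeros((0, 0)), budget)
    r = np.asarray(resistance, dtype=float)
    nrows, ncols = r.shape
    col = np.floor((sites.xy[:, 0] - origin_xy[0]) / pixel_size).astype(int)
    row = np.floor((sites.xy[:, 1] - origin_xy[1]) / pixel_size).astype(int)
    if (row < 0).any() or (row >= nrows).any() or (col < 0).any() or (col >= ncols).any():
        raise ValueError("site coordinates fall outside the resistance grid")
    nodes = row * ncols + col

    graph = pixel_graph(r, pixel_size)
    if batch_size is None:
        # keep each dense distance block near 256 MB
        batch_size = max(1, int(3.2e7 // max(1, graph.shape[0])))
    costs = np.empty((n_sites, n_sites), dtype=float)
    for start in range(0, n_sites, batch_size):
        batch = nodes[start : start + batch_size]
        dist = dijkstra(graph, directed=False, indices=batch, limit=budget)
        costs[start : start + batch_size, :] = dist[:, nodes]
    np.fill_diagonal(costs, 0.0)
    return CostMatrix(np.asarray(sites.ids), costs, budget)


def max_distance_for_budget(
    budget: float, resistance: float, pixel_size: float = 10.0
) -> float:
    """Straight-line reach (m) of a cost budget in homogeneous habitat.

    Returns ``budget / resistance`` floored to a whole pixel; 0 when the
    budget does not buy even one pixel (effectively impassable classes).
    """
    if budget <= 0:
        raise ValueError("budget must be > 0")
    if resistance < 1:
        raise ValueError("resistance must be >= 1")
    if pixel_size <= 0:
        raise ValueError("pixel_size must be > 0")
    return math.floor(budget / resistance / pixel_size) * pixel_size
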