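"""Similarity graphs of activity time series and their summary metrics.

A per-minute series S = (x_1, ..., x_n) is turned into an undirected graph
on nodes {1, ..., n} (one per time point): nodes u and v are joined by an
edge when they are close in time (|u - v| below the neighbourhood parameter
k) *and* similar in value (max(x_u, x_v) / min(x_u, x_v) below a ratio
threshold, 1.2 by default — i.e. within 20% of each other).  The resulting
banded graph captures local smoothness of the activity trace; its structure
is summarised by six metrics:

- mean number of edges per node (mean degree, 2E/n),
- connected components (substantial shifts in activity),
- bridges (edges whose removal disconnects; subtler fluctuations),
- missing edges between direct neighbours (adjacent minutes that fail the
  similarity test),
- time points without edges (isolated nodes),
- 3-cliques / triangles (smoothness of fluctuations).

The distance comparator is strict (|u - v| < k) by default; a ``less_equal``
variant is available because published mean-degree values at k = 2 exceed
the strict-comparator ceiling of 2, an inconsistency documented in
``docs/methods.md``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components
from sklearn.base import BaseEstimator, TransformerMixin

import pandas as pd

from .preprocess import ActivitySeries
from .variability import _as_values

__all__ = [
    "SimilarityGraphConfig",
    "SimilarityGraph",
    "GraphMetrics",
    "build_similarity_graph",
    "graph_metrics",
    "metrics_for_ks",
    "SimilarityGraphExtractor",
]

METRIC_NAMES = ("mean_edges", "components", "bridges", "missing_direct", "isolated", "triangles")


@dataclass(frozen=True)
class SimilarityGraphConfig:
    """Parameters of the graph construction.

    k : temporal neighbourhood; only pairs with comparator(|u - v|, k) are
        candidates for an edge.
    ratio_threshold : value-similarity bound on max/min (strict <).
    distance_comparator : ``strict_less`` (|u - v| < k) or ``less_equal``.
    zero_pair_rule : how to resolve the undefined ratio at zero counts —
        ``both_zero_similar`` treats (0, 0) as similar (ratio 1 by
        continuity) and (0, positive) as dissimilar; ``any_zero_dissimilar``
        rejects any pair containing a zero.
    """

    k: int = 2
    ratio_threshold: float = 1.2
    distance_comparator: str = "strict_less"
    zero_pair_rule: str = "both_zero_similar"

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if self.ratio_threshold <= 1:
            raise ValueError("ratio_threshold must be > 1")
        if self.distance_comparator not in ("strict_less", "less_equal"):
            raise ValueError(f"unknown distance_comparator {self.distance_comparator!r}")
        if self.zero_pair_rule not in ("both_zero_similar", "any_zero_dissimilar"):
            raise ValueError(f"unknown zero_pair_rule {self.zero_pair_rule!r}")

    @property
    def max_offset(self) -> int:
        return self.k - 1 if self.distance_comparator == "strict_less" else self.k


@dataclass
class SimilarityGraph:
    """Banded undirected graph over time points (0-based node ids internally)."""

    n: int
    config: SimilarityGraphConfig
    edge_u: np.ndarray  # edge endpoints with edge_u < edge_v
    edge_v: np.ndarray

    @property
    def n_edges(self) -> int:
        return len(self.edge_u)

    @property
    def edges(self) -> set[tuple[int, int]]:
        """Edge set as unordered (u, v) pairs with 1-based node ids."""
        return {(int(u) + 1, int(v) + 1) for u, v in zip(self.edge_u, self.edge_v)}

    def degrees(self) -> np.ndarray:
        deg = np.bincount(self.edge_u, minlength=self.n)
        deg += np.bincount(self.edge_v, minlength=self.n)
        return deg

    def adjacency(self) -> sp.csr_matrix:
        data = np.ones(2 * self.n_edges, dtype=np.int64)
        rows = np.concatenate([self.edge_u, self.edge_v])
        cols = np.concatenate([self.edge_v, self.edge_u])
        return sp.csr_matrix((data, (rows, cols)), shape=(self.n, self.n))

    def write_edge_list(self, path) -> None:
        """Export as 'u v' lines, 1-based node ids."""
        with open(path, "w") as fh:
            for u, v in zip(self.edge_u, self.edge_v):
                fh.write(f"{u + 1} {v + 1}\n")


@dataclass(frozen=True)
class GraphMetrics:
    edges_total: int
    mean_edges: float
    components: int
    bridges: int
    missing_direct: int
    isolated: int
    triangles: int

    def as_dict(self, k: int | None = None) -> dict[str, float]:
        suffix = f"_k{k}" if k is not None else ""
        d = {name: getattr(self, name) for name in METRIC_NAMES}
        return {name + suffix: val for name, val in d.items()}


def _similar(a: np.ndarray, b: np.ndarray, cfg: SimilarityGraphConfig) -> np.ndarray:
    lo = np.minimum(a, b)
    hi = np.maximum(a, b)
    with np.errstate(divide="ignore", invalid="ignore"):
        ok = (lo > 0) & (hi / lo < cfg.ratio_threshold)
    if cfg.zero_pair_rule == "both_zero_similar":
        ok |= hi == 0
    return ok


def build_similarity_graph(
    series: ActivitySeries | Sequence[float], cfg: SimilarityGraphConfig
) -> SimilarityGraph:
    """Build the similarity graph of a fully observed non-negative series."""
    x = _as_values(series)
    n = len(x)
    if n < 2:
        raise ValueError(f"need at least 2 time points, got {n}")
    if np.any(x < 0):
        raise ValueError("activity counts must be non-negative")
    us, vs = [], []
    for d in range(1, min(cfg.max_offset, n - 1) + 1):
        ok = _similar(x[:-d], x[d:], cfg)
        idx = np.nonzero(ok)[0]
        us.append(idx)
        vs.append(idx + d)
    u = np.concatenate(us) if us else np.empty(0, dtype=np.int64)
    v = np.concatenate(vs) if vs else np.empty(0, dtype=np.int64)
    return SimilarityGraph(n=n, config=cfg, edge_u=u, edge_v=v)


def _count_bridges(n: int, adj: sp.csr_matrix) -> int:
    """Bridges of a simple undirected graph via iterative Tarjan lowpoints.

    The graph is simple by construction, so there is exactly one edge back
    to the DFS parent and skipping the parent id suffices.
    """
    indptr, indices = adj.indptr, adj.indices
    disc = np.full(n, -1, dtype=np.int64)
    low = np.zeros(n, dtype=np.int64)
    parent = np.full(n, -1, dtype=np.int64)
    timer = 0
    bridges = 0
    for root in range(n):
        if disc[root] != -1:
            continue
        stack = [(root, int(indptr[root]))]  # (node, next neighbour pointer)
        disc[root] = low[root] = timer
        timer += 1
        while stack:
            node, ptr = stack[-1]
            if ptr < indptr[node + 1]:
                stack[-1] = (node, ptr + 1)
                nb = int(indices[ptr])
                if disc[nb] == -1:
                    parent[nb] = node
                    disc[nb] = low[nb] = timer
                    timer += 1
                    stack.append((nb, int(indptr[nb])))
                elif nb != parent[node]:
                    if disc[nb] < low[node]:
                        low[node] = disc[nb]
            else:
                stack.pop()
                if stack:
                    par = stack[-1][0]
                    if low[node] < low[par]:
                        low[par] = low[node]
                    if low[node] > disc[par]:
                        bridges += 1
    return bridges


def _count_triangles(adj: sp.csr_matrix) -> int:
    """Each triangle contributes 6 closed walks of length 3: tr(A^3)/6."""
    if adj.nnz == 0:
        return 0
    a2 = adj @ adj
    return int(a2.multiply(adj).sum() // 6)


def graph_metrics(graph: SimilarityGraph) -> GraphMetrics:
    """Compute the six similarity-graph summaries."""
    n = graph.n
    adj = graph.adjacency()
    n_comp, _ = connected_components(adj, directed=False)
    deg = graph.degrees()
    direct = int(np.sum(graph.edge_v - graph.edge_u == 1))
    return GraphMetrics(
        edges_total=graph.n_edges,
        mean_edges=2.0 * graph.n_edges / n,
        components=int(n_comp),
        bridges=_count_bridges(n, adj),
        missing_direct=(n - 1) - direct,
        isolated=int(np.sum(deg == 0)),
        triangles=_count_triangles(adj),
    )


def metrics_for_ks(
    series: ActivitySeries | Sequence[float],
    ks: Iterable[int],
    cfg: SimilarityGraphConfig = SimilarityGraphConfig(),
) -> dict[int, GraphMetrics]:
    """Graph metrics for several neighbourhood parameters on one series."""
    x = _as_values(series)
    out: dict[int, GraphMetrics] = {}
    for k in ks:
        cfg_k = SimilarityGraphConfig(
            k=int(k),
            ratio_threshold=cfg.ratio_threshold,
            distance_comparator=cfg.distance_comparator,
            zero_pair_rule=cfg.zero_pair_rule,
        )
        out[int(k)] = graph_metrics(build_similarity_graph(x, cfg_k))
    return out


class SimilarityGraphExtractor(TransformerMixin, BaseEstimator):
    """Six graph metrics per k, per series, as an sklearn transformer.

    ``transform`` returns a ``(n_series, 6 * len(ks))`` DataFrame with
    columns like ``mean_edges_k2``, ..., ``triangles_k5``.
    """

    def __init__(
        self,
        ks: Sequence[int] = (2, 5, 40),
        ratio_threshold: float = 1.2,
        distance_comparator: str = "strict_less",
        zero_pair_rule: str = "both_zero_similar",
    ):
        self.ks = ks
        self.ratio_threshold = ratio_threshold
        self.distance_comparator = distance_comparator
        self.zero_pair_rule = zero_pair_rule

    def _template(self) -> SimilarityGraphConfig:
        return SimilarityGraphConfig(
            k=max(2, int(min(self.ks))),
            ratio_threshold=self.ratio_threshold,
            distance_comparator=self.distance_comparator,
            zero_pair_rule=self.zero_pair_rule,
        )

    def fit(self, X, y=None):
        if not len(list(self.ks)):
            raise ValueError("ks must be nonempty")
        self._template()  # validates
        return self

    def transform(self, X) -> pd.DataFrame:
        tmpl = self._template()
        rows = []
        for s in X:
            row: dict[str, float] = {}
            for k, gm in metrics_for_ks(s, self.ks, tmpl).items():
                row.update(gm.as_dict(k=k))
            rows.append(row)
        cols = [f"{name}_k{int(k)}" for k in self.ks for name in METRIC_NAMES]
        return pd.DataFrame(rows, columns=cols)

    def get_feature_names_out(self, input_features=None):
        return np.asarray(
            [f"{name}_k{int(k)}" for k in self.ks for name in METRIC_NAMES], dtype=object
        )
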