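"""Covariation graphs: transitivity and indirect-path statistics.

A covariation graph is the unweighted adjacency over residue columns whose
pairs score within a top-n threshold after a minimum-sequence-distance
filter (pairs with |j - i| < d are discarded).  Indirect paths are weighted
shortest paths where each step's length is the structure centroid distance
between its endpoints, with the direct edge between the query pair removed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .core import CovariationMap
from .struct_eval import ContactMap, top_pairs


@dataclass
class CovariationGraph:
    adjacency: np.ndarray  # (L, L) bool, symmetric, zero diagonal
    n_pairs: int
    min_seq_dist: int

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency, dtype=bool)
        if not np.array_equal(a, a.T):
            raise ValueError("adjacency must be symmetric")
        if a.diagonal().any():
            raise ValueError("adjacency must have a zero diagonal")
        self.adjacency = a

    @property
    def edges(self) -> list[tuple[int, int]]:
        i, j = np.nonzero(np.triu(self.adjacency, k=1))
        return list(zip(i.tolist(), j.tolist()))

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_edges_from(self.edges)
        return g


def build_graph(
    cmap: CovariationMap, n_pairs: int, min_seq_dist: int = 0
) -> CovariationGraph:
    """Graph over the top ``n_pairs`` pairs with sequence distance >= d.

    Pairs with |j - i| < min_seq_dist are discarded before ranking; ties are
    broken deterministically as in top-pair selection.  If fewer eligible
    pairs exist, all of them are used (with a warning from the ranker).
    """
    ranked = top_pairs(cmap, n_pairs, min_sep=min_seq_dist, strict=False)
    length = cmap.n_columns
    adjacency = np.zeros((length, length), dtype=bool)
    for i, j, _ in ranked.pairs:
        adjacency[i, j] = adjacency[j, i] = True
    return CovariationGraph(adjacency, n_pairs=len(ranked), min_seq_dist=min_seq_dist)


def transitivity(graph: CovariationGraph) -> float:
    """3 x triangles / connected triples; 0 when no connected triples exist."""
    if graph.n_edges == 0:
        raise ValueError("transitivity is undefined on an empty graph")
    return float(nx.transitivity(graph.to_networkx()))


def _weighted_graph(
    graph: CovariationGraph, contacts: ContactMap
) -> nx.Graph:
    g = nx.Graph()
    dropped = 0
    for i, j in graph.edges:
        w = contacts.distances[i, j]
        if np.isnan(w):
            dropped += 1
            continue
        g.add_edge(i, j, weight=float(w))
    if dropped:
        warnings.warn(f"{dropped} edges dropped: endpoints unmapped to structure")
    return g


def indirect_path_stats(
    graph: CovariationGraph, contacts: ContactMap, pair: tuple[int, int]
) -> tuple[float, float, int] | None:
    """Shortest indirect path between a pair, measured in structure space.

    The direct edge (i, j) is removed; each remaining step is weighted by the
    centroid distance between its endpoints.  Returns (total path length in A,
    mean step length in A, number of steps), or None when no indirect path
    exists or the endpoints are not in the weighted graph.
    """
    i, j = pair
    g = _weighted_graph(graph, contacts)
    if g.has_edge(i, j):
        g.remove_edge(i, j)
    if i not in g or j not in g:
        return None
    try:
        length, path = nx.single_source_dijkstra(g, i, target=j, weight="weight")
    except nx.NetworkXNoPath:
        return None
    n_steps = len(path) - 1
    return float(length), float(length) / n_steps, n_steps


def connectivity_profile(
    cmap: CovariationMap,
    contacts: ContactMap,
    max_pairs: int,
    min_seq_dist: int = 0,
    grid: list[int] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Mean indirect-path statistics as the score threshold is relaxed.

    For each pair count k on the grid (default 0.25 L steps up to
    ``max_pairs``), the graph over the top k pairs is built and the shortest
    indirect path of every selected pair is computed.  Returns a per-threshold
    table (n_pairs, mean_path_length, mean_step_length, n_connected) and the
    per-pair table at the largest grid point (i, j, score, path_length,
    mean_step_length, n_steps).
    """
    length = cmap.n_columns
    if grid is None:
        step = max(1, round(0.25 * length))
        grid = list(range(step, max_pairs + 1, step))
        if grid[-1] != max_pairs:
            grid.append(max_pairs)
    rows = []
    pair_table = pd.DataFrame(
        columns=["i", "j", "score", "path_length", "mean_step_length", "n_steps"]
    )
    for k in grid:
        graph = build_graph(cmap, k, min_seq_dist)
        ranked = top_pairs(cmap, k, min_sep=min_seq_dist, strict=False)
        stats = []
        records = []
        for i, j, score in ranked.pairs:
            result = indirect_path_stats(graph, contacts, (i, j))
            if result is None:
                continue
            total, mean_step, n_steps = result
            stats.append((total, mean_step))
            records.append(
                {
                    "i": i,
                    "j": j,
                    "score": score,
                    "path_length": total,
                    "mean_step_length": mean_step,
                    "n_steps": n_steps,
                }
            )
        rows.append(
            {
                "n_pairs": k,
                "mean_path_length": np.mean([s[0] for s in stats]) if stats else np.nan,
                "mean_step_length": np.mean([s[1] for s in stats]) if stats else np.nan,
                "n_connected": len(stats),
            }
        )
        if k == grid[-1]:
            pair_table = pd.DataFrame.from_records(records)
    return pd.DataFrame(rows), pair_table


def transitivity_profile(
    cmap: CovariationMap,
    mode: str,
    grid: list[int],
    n_pairs: int | None = None,
    min_seq_dist: int = 6,
) -> pd.DataFrame:
    """Transitivity across a grid of graph sizes or sequence-distance cutoffs.

    mode 'vary_size': the grid lists pair counts at constant ``min_seq_dist``.
    mode 'vary_dist': the grid lists minimum sequence distances at constant
    graph size ``n_pairs``.  Grid points yielding an empty graph are reported
    as NaN.
    """
    if mode not in ("vary_size", "vary_dist"):
        raise ValueError(f"unknown mode {mode!r}")
    if not grid:
        raise ValueError("grid must be non-empty")
    rows = []
    for value in grid:
        if mode == "vary_size":
            k, d = int(value), min_seq_dist
        else:
            if n_pairs is None:
                raise ValueError("vary_dist mode requires n_pairs")
            k, d = n_pairs, int(value)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            graph = build_graph(cmap, k, d)
        tr = transitivity(graph) if graph.n_edges > 0 else np.nan
        rows.append({"grid_value": value, "n_edges": graph.n_edges, "transitivity": tr})
    return pd.DataFrame(rows)
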