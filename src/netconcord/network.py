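"""Global interaction network: loading, validation and shortest-path machinery.

The network is the fixed substrate on which topological significance is
scored.  It is deliberately simple: an undirected, unweighted graph over
case-normalized feature identifiers (gene symbols / protein ids).  Distances
are minimal edge counts; the scoring statistic counts *all* tied shortest
paths, so no arbitrary tie-breaking enters downstream results.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "InteractionNetwork",
    "NetworkParseError",
    "PathProfile",
    "load_network",
    "write_network",
    "shortest_path_lengths",
    "path_profile",
    "path_statistics",
]


class NetworkParseError(ValueError):
    """Raised when an edge-list file cannot be parsed."""


def _normalize(identifier: str) -> str:
    ident = identifier.strip().upper()
    if not ident:
        raise ValueError("empty node identifier")
    return ident


@dataclass
class InteractionNetwork:
    """Undirected, unweighted interaction graph.

    Invariants enforced on construction: no self-loops, unordered edges are
    unique, every endpoint is a node, identifiers are non-empty and
    upper-cased.
    """

    graph: nx.Graph
    name: str = "network"
    n_self_loops_dropped: int = 0
    n_duplicates_collapsed: int = 0

    def __post_init__(self) -> None:
        loops = list(nx.selfloop_edges(self.graph))
        if loops:
            raise ValueError(f"self-loops present: {loops[:3]}")
        for n in self.graph.nodes:
            if not isinstance(n, str) or not n.strip():
                raise ValueError(f"invalid node identifier: {n!r}")

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple[str, str]],
        nodes: Iterable[str] = (),
        name: str = "network",
    ) -> "InteractionNetwork":
        """Build a network, collapsing duplicate edges and dropping self-loops."""
        g = nx.Graph()
        n_loops = 0
        n_dups = 0
        for a, b in edges:
            a, b = _normalize(a), _normalize(b)
            if a == b:
                n_loops += 1
                g.add_node(a)
                continue
            if g.has_edge(a, b):
                n_dups += 1
                continue
            g.add_edge(a, b)
        for n in nodes:
            g.add_node(_normalize(n))
        if n_loops:
            logger.warning("%s: dropped %d self-loop(s)", name, n_loops)
        if n_dups:
            logger.info("%s: collapsed %d duplicate edge(s)", name, n_dups)
        return cls(g, name=name, n_self_loops_dropped=n_loops,
                   n_duplicates_collapsed=n_dups)

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def edges(self) -> set[frozenset[str]]:
        return {frozenset(e) for e in self.graph.edges}

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def degree(self, node: str) -> int:
        return self.graph.degree[node]

    def _csr(self) -> tuple[list[str], np.ndarray, np.ndarray]:
        """Cached compressed adjacency; invalidated when the graph size changes."""
        key = (self.graph.number_of_nodes(), self.graph.number_of_edges())
        cached = getattr(self, "_csr_cache", None)
        if cached is None or cached[0] != key:
            nodes = sorted(self.graph.nodes)
            indptr, indices = _csr_adjacency(self.graph, nodes)
            object.__setattr__(self, "_csr_cache", (key, nodes, indptr, indices))
            cached = self._csr_cache
        return cached[1], cached[2], cached[3]

    def restrict_to_members(self, features: Iterable[str],
                            label: str = "feature set") -> set[str]:
        """Intersect a feature set with the network; log how many were dropped."""
        feats = {_normalize(f) for f in features}
        kept = feats & self.nodes
        dropped = len(feats) - len(kept)
        if dropped:
            logger.info("%s: %d of %d %s absent from network, dropped",
                        self.name, dropped, len(feats), label)
        return kept


@dataclass(frozen=True)
class PathProfile:
    """Shortest-path participation of one node with respect to a seed set.

    ``seed_pairs_covered`` counts unordered seed pairs having at least one
    shortest path whose interior contains the node; ``paths_through`` counts
    every tied shortest path over all such pairs.
    """

    node: str
    seed_pairs_covered: int
    paths_through: int

    def __post_init__(self) -> None:
        if self.seed_pairs_covered > 0 and self.paths_through < self.seed_pairs_covered:
            raise ValueError("paths_through < seed_pairs_covered")


def load_network(path: str | Path, delimiter: str = "\t",
                 name: str | None = None) -> InteractionNetwork:
    """Load an edge list (two-column TSV) or SIF file.

    Lines starting with ``#`` are comments.  Two fields make an edge; three
    or more fields are read as SIF (``nodeA relation nodeB [nodeC ...]``)
    with the relation column ignored.  Identifiers are upper-cased,
    self-loops dropped with a warning, duplicate edges collapsed.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    edges: list[tuple[str, str]] = []
    isolated: list[str] = []
    n_content = 0
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = [f for f in line.split(delimiter) if f.strip()]
            n_content += 1
            if len(fields) == 1:
                raise NetworkParseError(
                    f"{path}:{lineno}: expected >=2 fields, got {len(fields)}: {line!r}")
            if len(fields) == 2:
                edges.append((fields[0], fields[1]))
            else:
                src = fields[0]
                for tgt in fields[2:]:
                    edges.append((src, tgt))
    if n_content == 0:
        raise NetworkParseError(f"{path}: no edges found (empty file)")
    return InteractionNetwork.from_edges(edges, nodes=isolated,
                                         name=name or path.stem)


def write_network(net: InteractionNetwork, path: str | Path,
                  delimiter: str = "\t") -> None:
    """Write the edge list in sorted order (round-trips with load_network)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# network: {net.name}\n")
        for a, b in sorted(tuple(sorted(e)) for e in net.graph.edges):
            fh.write(f"{a}{delimiter}{b}\n")


def _check_members(net: InteractionNetwork, nodes: Iterable[str]) -> list[str]:
    out = []
    for n in nodes:
        n = _normalize(n)
        if n not in net.graph:
            raise KeyError(f"node {n!r} not in network {net.name!r}")
        out.append(n)
    return out


def _csr_adjacency(graph: nx.Graph,
                   nodes: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
    """Compressed adjacency (indptr, indices) over ``nodes`` order."""
    index = {n: i for i, n in enumerate(nodes)}
    indptr = np.zeros(len(nodes) + 1, dtype=np.int64)
    for i, n in enumerate(nodes):
        indptr[i + 1] = indptr[i] + graph.degree[n]
    indices = np.empty(indptr[-1], dtype=np.int64)
    pos = indptr[:-1].copy()
    for n in nodes:
        i = index[n]
        for v in graph.adj[n]:
            indices[pos[i]] = index[v]
            pos[i] += 1
    return indptr, indices


def _bfs_dist_sigma_csr(indptr: np.ndarray, indices: np.ndarray, n: int,
                        source: int) -> tuple[np.ndarray, np.ndarray]:
    """Distances and shortest-path counts from ``source`` (frontier BFS).

    Unreachable nodes get distance +inf and count 0.
    """
    dist = np.full(n, -1, dtype=np.int64)
    sigma = np.zeros(n, dtype=float)
    dist[source] = 0
    sigma[source] = 1.0
    frontier = np.array([source], dtype=np.int64)
    d = 0
    while frontier.size:
        starts = indptr[frontier]
        counts = indptr[frontier + 1] - starts
        total = int(counts.sum())
        if total == 0:
            break
        offsets = np.concatenate(([0], np.cumsum(counts)[:-1]))
        take = np.repeat(starts - offsets, counts) + np.arange(total)
        nbr = indices[take]
        weight = np.repeat(sigma[frontier], counts)
        undiscovered = dist[nbr] == -1
        next_level = dist[nbr] == d + 1
        newly = nbr[undiscovered]
        dist[newly] = d + 1
        mask = undiscovered | next_level
        np.add.at(sigma, nbr[mask], weight[mask])
        frontier = np.unique(newly)
        d += 1
    out = dist.astype(float)
    out[dist < 0] = np.inf
    return out, sigma


def _bfs_dist_sigma(graph: nx.Graph, source: str,
                    index: Mapping[str, int]) -> tuple[np.ndarray, np.ndarray]:
    nodes = sorted(index, key=index.get)
    indptr, indices = _csr_adjacency(graph, nodes)
    return _bfs_dist_sigma_csr(indptr, indices, len(nodes), index[source])


def path_statistics(net: InteractionNetwork,
                    seeds: Iterable[str]) -> "pd.DataFrame":
    """Shortest-path participation of *every* node with respect to ``seeds``.

    For each unordered seed pair (s, t) in the same component and each node v
    with v not in {s, t}, v lies on a shortest s-t path iff
    d(s,v) + d(v,t) = d(s,t); the number of tied shortest paths through v is
    sigma_s(v) * sigma_t(v).  Pairs a seed belongs to never contribute to its
    own statistic (endpoints are not interior), so seed nodes are scored on
    the remaining pairs.

    Returns a DataFrame indexed by node with columns ``seed_pairs_covered``
    and ``paths_through``.
    """
    import pandas as pd

    seeds = sorted(set(_check_members(net, seeds)))
    if len(seeds) < 2:
        raise ValueError(f"insufficient seeds: need >=2, got {len(seeds)}")
    nodes, indptr, indices = net._csr()
    index = {n: i for i, n in enumerate(nodes)}
    dists = {}
    sigmas = {}
    for s in seeds:
        dists[s], sigmas[s] = _bfs_dist_sigma_csr(indptr, indices,
                                                  len(nodes), index[s])
    covered = np.zeros(len(nodes), dtype=np.int64)
    through = np.zeros(len(nodes), dtype=float)
    for i, s in enumerate(seeds):
        ds, ss = dists[s], sigmas[s]
        for t in seeds[i + 1:]:
            dt, st = dists[t], sigmas[t]
            d = ds[index[t]]
            if np.isinf(d):
                continue
            on_path = (ds + dt) == d
            on_path[index[s]] = False
            on_path[index[t]] = False
            pair_through = np.where(on_path, ss * st, 0.0)
            through += pair_through
            covered += pair_through > 0
    return pd.DataFrame(
        {"seed_pairs_covered": covered, "paths_through": through.astype(np.int64)},
        index=pd.Index(nodes, name="node"),
    )


def path_profile(net: InteractionNetwork, node: str,
                 seeds: Iterable[str]) -> PathProfile:
    """PathProfile of a single node (see :func:`path_statistics`)."""
    node = _check_members(net, [node])[0]
    stats = path_statistics(net, seeds)
    row = stats.loc[node]
    return PathProfile(node=node,
                       seed_pairs_covered=int(row["seed_pairs_covered"]),
                       paths_through=int(row["paths_through"]))


def shortest_path_lengths(net: InteractionNetwork, sources: Iterable[str],
                          targets: Iterable[str]) -> "pd.DataFrame":
    """Pairwise minimal edge-count distances; unreachable pairs are +inf."""
    import pandas as pd

    sources = sorted(set(_check_members(net, sources)))
    targets = sorted(set(_check_members(net, targets)))
    nodes = sorted(net.graph.nodes)
    index = {n: i for i, n in enumerate(nodes)}
    rows = {}
    for s in sources:
        dist, _ = _bfs_dist_sigma(net.graph, s, index)
        rows[s] = [dist[index[t]] for t in targets]
    return pd.DataFrame.from_dict(rows, orient="index", columns=targets)
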