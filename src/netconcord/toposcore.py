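"""Topological significance scoring of network nodes against a seed set.

A node is topologically significant when it participates in the shortest
paths among a differential seed set more than expected for a node of its
global connectivity.  The observed statistic is the number of tied shortest
paths between seed pairs whose interior contains the node
(:func:`netconcord.network.path_statistics`).  The null re-draws, for every
seed, a replacement node from the same logarithmic degree bin and recomputes
the statistic, so global hubs gain nothing from degree alone — high scores
require connectivity *specific* to the given seeds.  Empirical p-values use
the standard permutation pseudocount (1 + exceedances) / (R + 1).

"Hidden" nodes are significant nodes absent from the direct differential
sets: candidate regulators invisible to single-layer profiling (e.g. through
post-translational control or subproteome selection).
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .differential import DifferentialSet
from .network import InteractionNetwork, path_statistics

__all__ = [
    "degree_bins",
    "draw_matched_seed_sets",
    "score_nodes",
    "hidden_nodes",
]


def degree_bins(net: InteractionNetwork) -> dict[int, list[str]]:
    """Group nodes into logarithmic degree bins (boundaries at powers of 2).

    A node of degree d falls in bin floor(log2(d)); isolated nodes get their
    own bin.  Logarithmic bins keep matching stable on heavy-tailed degree
    distributions.
    """
    bins: dict[int, list[str]] = {}
    for node in sorted(net.graph.nodes):
        d = net.graph.degree[node]
        b = int(np.floor(np.log2(d))) if d > 0 else -1
        bins.setdefault(b, []).append(node)
    return bins


def _bin_of(degree: int) -> int:
    return int(np.floor(np.log2(degree))) if degree > 0 else -1


def draw_matched_seed_sets(net: InteractionNetwork, seeds: Sequence[str],
                           n_resamples: int,
                           rng: np.random.Generator) -> list[list[str]]:
    """Draw degree-matched random seed sets.

    For each resample, every seed is replaced by a node drawn from the same
    degree bin, without replacement within the resample so the set size is
    preserved.  Bins too small to supply enough distinct nodes are widened
    to the nearest neighboring bins.

    This function is the single source of null randomness, shared between
    the production scorer and any independent re-implementation given the
    same ``rng`` stream.
    """
    bins = degree_bins(net)
    sorted_bins = sorted(bins)
    seeds = list(seeds)
    need: dict[int, int] = {}
    for s in seeds:
        need[_bin_of(net.graph.degree[s])] = need.get(
            _bin_of(net.graph.degree[s]), 0) + 1

    # pre-widen any bin that cannot supply enough distinct nodes
    pools: dict[int, list[str]] = {}
    for b, count in need.items():
        pool = list(bins.get(b, []))
        radius = 1
        while len(pool) < count and radius <= max(sorted_bins) - min(sorted_bins):
            for nb in (b - radius, b + radius):
                pool.extend(bins.get(nb, []))
            radius += 1
        if len(pool) < count:
            raise ValueError(f"cannot degree-match {count} seeds in bin {b}")
        pools[b] = sorted(set(pool))

    out = []
    for _ in range(n_resamples):
        drawn: list[str] = []
        taken: set[str] = set()
        for b, count in sorted(need.items()):
            pool = [n for n in pools[b] if n not in taken]
            if len(pool) < count:
                # widened pools of nearby bins can collide; top up from the rest
                pool.extend(n for n in sorted(net.graph.nodes)
                            if n not in taken and n not in pool)
            picks = rng.choice(len(pool), size=count, replace=False)
            for i in picks:
                drawn.append(pool[i])
                taken.add(pool[i])
        out.append(drawn)
    return out


def score_nodes(net: InteractionNetwork, seeds: Iterable[str],
                n_resamples: int = 100, alpha: float = 0.05,
                rng_seed: int = 0) -> pd.DataFrame:
    """Score every network node for topological significance.

    Returns a DataFrame indexed by node with columns: degree, observed
    (paths_through w.r.t. the real seeds), seed_pairs_covered, null_mean,
    null_sd, pvalue, significant, is_seed.
    """
    if n_resamples < 10:
        raise ValueError("n_resamples must be >= 10")
    seed_set = net.restrict_to_members(seeds, label="seeds")
    if len(seed_set) < 2:
        raise ValueError(
            f"need >=2 seeds present in the network, got {len(seed_set)}")
    seed_list = sorted(seed_set)

    observed_tab = path_statistics(net, seed_list)
    observed = observed_tab["paths_through"].to_numpy(dtype=float)

    rng = np.random.default_rng(rng_seed)
    resamples = draw_matched_seed_sets(net, seed_list, n_resamples, rng)
    null = np.empty((n_resamples, len(observed_tab)), dtype=float)
    for r, rseeds in enumerate(resamples):
        null[r] = path_statistics(net, rseeds)["paths_through"].to_numpy(dtype=float)

    exceed = (null >= observed[None, :]).sum(axis=0)
    pvalue = (1.0 + exceed) / (n_resamples + 1.0)
    nodes = observed_tab.index
    degrees = np.array([net.graph.degree[n] for n in nodes])
    scores = pd.DataFrame(
        {
            "degree": degrees,
            "observed": observed.astype(np.int64),
            "seed_pairs_covered": observed_tab["seed_pairs_covered"],
            "null_mean": null.mean(axis=0),
            "null_sd": null.std(axis=0, ddof=1),
            "pvalue": pvalue,
            "significant": pvalue < alpha,
            "is_seed": nodes.isin(seed_list),
        },
        index=nodes,
    )
    return scores


def hidden_nodes(scores: pd.DataFrame,
                 direct: DifferentialSet) -> tuple[set[str], float]:
    """Significant nodes missing from the direct differential sets.

    Returns the hidden set and hidden_fraction = |hidden| / |significant|
    (0 when nothing is significant).
    """
    significant = set(scores.index[scores["significant"]])
    if not significant:
        return set(), 0.0
    hidden = significant - set(direct.all)
    return hidden, len(hidden) / len(significant)
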