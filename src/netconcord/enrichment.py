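"""Pathway over-representation, common-pathway calls and random-set FDR.

Enrichment is the classical upper-tail hypergeometric test of a query
feature set against each pathway in a collection, with the whole feature
universe (by default every node of the collection/network) as the reference
list, Benjamini-Hochberg control across pathways, and a deterministic
(p, name) ranking so top-10 lists are reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .network import InteractionNetwork
from .speccount import stepup_correct
from .toposcore import score_nodes

logger = logging.getLogger(__name__)

__all__ = [
    "PathwayCollection",
    "read_gmt",
    "write_gmt",
    "enrich",
    "common_pathways",
    "random_set_fdr",
]


def _norm(features: Iterable[str]) -> frozenset[str]:
    return frozenset(str(f).strip().upper() for f in features)


@dataclass(frozen=True)
class PathwayCollection:
    """Named feature sets over a common background universe."""

    pathways: Mapping[str, frozenset[str]]
    background: frozenset[str]

    def __post_init__(self) -> None:
        for name, members in self.pathways.items():
            if len(members) < 2:
                raise ValueError(f"pathway {name!r} has fewer than 2 members")
            if not members <= self.background:
                raise ValueError(
                    f"pathway {name!r} has members outside the background")

    @classmethod
    def from_sets(cls, pathways: Mapping[str, Iterable[str]],
                  background: Iterable[str] | None = None,
                  restrict: bool = True) -> "PathwayCollection":
        """Build a collection; without an explicit background, use the union.

        With ``restrict`` (default) pathway members outside the background
        are dropped (logged) and pathways left with <2 members removed, the
        usual treatment when a generic collection is mapped onto a fixed
        network universe.
        """
        norm = {str(k): _norm(v) for k, v in pathways.items()}
        if background is None:
            bg = frozenset().union(*norm.values()) if norm else frozenset()
        else:
            bg = _norm(background)
            if restrict:
                kept = {}
                n_dropped_members = 0
                for name, members in norm.items():
                    inside = members & bg
                    n_dropped_members += len(members) - len(inside)
                    if len(inside) >= 2:
                        kept[name] = inside
                if n_dropped_members or len(kept) < len(norm):
                    logger.info(
                        "collection restricted to background: %d member(s) "
                        "dropped, %d pathway(s) removed",
                        n_dropped_members, len(norm) - len(kept))
                norm = kept
        return cls(pathways=norm, background=bg)

    def __len__(self) -> int:
        return len(self.pathways)


def read_gmt(path: str | Path,
             background: Iterable[str] | None = None) -> PathwayCollection:
    """Read a GMT file (name, description, members...; tab-separated)."""
    path = Path(path)
    pathways: dict[str, list[str]] = {}
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(
                    f"{path}:{lineno}: GMT line needs name, description and "
                    f">=2 members")
            name = fields[0].strip()
            if name in pathways:
                raise ValueError(f"{path}:{lineno}: duplicate pathway {name!r}")
            pathways[name] = [f for f in fields[2:] if f.strip()]
    return PathwayCollection.from_sets(pathways, background=background)


def write_gmt(coll: PathwayCollection, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for name in sorted(coll.pathways):
            members = "\t".join(sorted(coll.pathways[name]))
            fh.write(f"{name}\tna\t{members}\n")


def enrich(query: Iterable[str], coll: PathwayCollection,
           alpha: float = 0.05) -> pd.DataFrame:
    """Hypergeometric over-representation of ``query`` in every pathway.

    p = P(X >= overlap) with X ~ Hypergeom(N=|background|, K=|pathway|,
    n=|query & background|); BH FDR across pathways; significant iff
    fdr < alpha; ranked by (p, name).
    """
    q = _norm(query) & coll.background
    if not q:
        raise ValueError("query has no overlap with the background universe")
    names = sorted(coll.pathways)
    N = len(coll.background)
    rows = []
    for name in names:
        members = coll.pathways[name]
        k = len(q & members)
        p = float(hypergeom.sf(k - 1, N, len(members), len(q)))
        rows.append((name, len(members), k, min(p, 1.0)))
    tab = pd.DataFrame(rows, columns=["pathway", "size", "overlap", "p"])
    tab["fdr"] = stepup_correct(tab["p"])
    tab = tab.sort_values(["p", "pathway"], kind="stable").reset_index(drop=True)
    tab["rank"] = np.arange(1, len(tab) + 1)
    tab["significant"] = tab["fdr"] < alpha
    return tab


def common_pathways(a: pd.DataFrame, b: pd.DataFrame, top_k: int = 10,
                    require_significant: bool = True) -> list[str]:
    """Pathways in both models' top-k (significant) rows.

    Ordered by summed rank, ties by name — the basis for "common pathway"
    calls between the two cell-line models.
    """
    def top(tab: pd.DataFrame) -> dict[str, int]:
        sel = tab[tab["rank"] <= top_k]
        if require_significant:
            sel = sel[sel["significant"]]
        return dict(zip(sel["pathway"], sel["rank"]))

    ra, rb = top(a), top(b)
    common = set(ra) & set(rb)
    return sorted(common, key=lambda n: (ra[n] + rb[n], n))


def random_set_fdr(net: InteractionNetwork, coll: PathwayCollection,
                   target_pathways: Sequence[str], n_sets: int = 10,
                   set_size: int = 300, top_k: int = 10,
                   exclude: Iterable[str] = (), rng_seed: int = 0,
                   n_resamples: int = 100, alpha: float = 0.05) -> dict[str, float]:
    """Specificity calibration with random gene sets.

    Draws ``n_sets`` uniform sets of ``set_size`` features from the
    background (minus an optional exclusion list, e.g. the differentially
    expressed features), runs topological scoring followed by enrichment of
    the significant nodes (falling back to the random set itself when no
    node is significant), and reports for each target pathway the fraction
    of random sets in which it lands among the top-k ranked pathways — the
    chance of calling that pathway from noise alone.
    """
    universe = sorted((coll.background & net.nodes) - _norm(exclude))
    if set_size > len(universe):
        raise ValueError(
            f"set_size {set_size} exceeds usable background {len(universe)}")
    rng = np.random.default_rng(rng_seed)
    hits = {t: 0 for t in target_pathways}
    for i in range(n_sets):
        picks = rng.choice(len(universe), size=set_size, replace=False)
        random_set = [universe[j] for j in picks]
        scores = score_nodes(net, random_set, n_resamples=n_resamples,
                             alpha=alpha,
                             rng_seed=int(rng.integers(2**31 - 1)))
        significant = sorted(scores.index[scores["significant"]])
        query = significant if significant else random_set
        try:
            tab = enrich(query, coll, alpha=alpha)
        except ValueError:
            continue
        top = tab[tab["rank"] <= top_k]["pathway"]
        for t in target_pathways:
            if t in set(top):
                hits[t] += 1
    return {t: hits[t] / n_sets for t in target_pathways}
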