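"""Synthetic two-model scenarios with planted ground truth.

The generator emulates the study design: two isogenic metastatic/parental
cell-line models whose *direct* differential profiles overlap weakly, while
a small set of shared "hidden regulators" — members of planted pathways,
absent from every differential list — provides the shortest-path
connectivity among both models' seeds.  Direct pathway analysis therefore
finds nothing in common; topological scoring recovers the regulators and,
through them, the planted pathways, reproducing the qualitative contrast
between single-layer and integrative analysis.

Layers generated:
  * a connected preferential-attachment interaction network with exact node
    and edge counts;
  * a pathway collection (GMT-shaped) over the network universe, a few
    pathways "planted" as the shared biology;
  * per-model expression statistics (log2 fold change + p-value), with seed
    features spiked and everything else null;
  * per-model spectral-count tables (negative-binomial, overdispersed, with
    spiked proteins);
  * per-model RPPA antibody tables with planted up-regulated proteins.

Every draw goes through one ``numpy`` Generator, so a configuration plus
seed reproduces the scenario byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .enrichment import PathwayCollection, write_gmt
from .network import InteractionNetwork, write_network

__all__ = [
    "ScenarioConfig",
    "ScenarioTruth",
    "Scenario",
    "generate_network",
    "generate_expression_stats",
    "generate_count_table",
    "generate_rppa_table",
    "generate_scenario",
    "write_scenario",
]

MODELS = ("model_A", "model_B")


@dataclass(frozen=True)
class ScenarioConfig:
    """Study-shaped defaults.

    Network and collection sizes are desk-scale stand-ins for the global
    interaction network; the count depth echoes the per-sample spectral
    totals of a MudPIT run, and the RPPA shape (242 antibodies, 120 unique
    proteins, 24-protein target pathway, 35/14 up-calls) mirrors the
    validation panel.
    """

    n_nodes: int = 300
    n_edges: int = 900
    n_pathways: int = 20
    pathway_size: int = 12
    n_planted_pathways: int = 3
    n_hidden_regulators: int = 8        # per planted pathway (split up/down)
    seeds_per_model: int = 16
    seed_overlap_fraction: float = 0.25
    count_depth: int = 7500             # expected spectra per sample
    n_count_proteins: int = 280
    n_spiked: int = 16                  # spiked proteins per model
    spike_fold: float = 5.0
    dispersion: float = 0.01            # NB: var = mu + dispersion * mu^2
    expression_log2fc: float = 2.0
    rppa_n_proteins: int = 120
    rppa_n_antibodies: int = 242
    rppa_pathway_size: int = 24
    rppa_n_up: tuple[int, int] = (35, 14)
    rppa_n_up_in_pathway: tuple[int, int] = (11, 6)
    rppa_effect: float = 0.6
    rng_seed: int = 11

    def __post_init__(self) -> None:
        if self.pathway_size < 3:
            raise ValueError("pathway_size must be >= 3")
        if not 0.0 <= self.seed_overlap_fraction <= 1.0:
            raise ValueError("seed_overlap_fraction must lie in [0, 1]")
        if self.spike_fold <= 1.0:
            raise ValueError("spike_fold must exceed 1")
        if self.dispersion <= 0.0:
            raise ValueError("dispersion must be positive")
        if self.n_edges < self.n_nodes - 1:
            raise ValueError("n_edges must allow a connected graph")
        if self.n_hidden_regulators > self.pathway_size:
            raise ValueError("more hidden regulators than pathway members")


@dataclass(frozen=True)
class ScenarioTruth:
    """Planted ground truth for every generated layer."""

    planted_pathways: tuple[str, ...]
    hidden_regulators: frozenset[str]
    model_seeds: dict          # model -> {"up": [...], "down": [...]}
    spiked_proteins: dict      # model -> {"up": [...], "down": [...]}
    rppa_up_truth: dict        # model -> [proteins]
    rppa_pathway: tuple[str, ...]

    def __post_init__(self) -> None:
        for model, sets in self.model_seeds.items():
            seeds = set(sets["up"]) | set(sets["down"])
            if seeds & self.hidden_regulators:
                raise ValueError(
                    f"{model}: hidden regulators leak into the seed sets")

    def to_dict(self) -> dict:
        return {
            "planted_pathways": list(self.planted_pathways),
            "hidden_regulators": sorted(self.hidden_regulators),
            "model_seeds": {m: {k: sorted(v) for k, v in s.items()}
                            for m, s in self.model_seeds.items()},
            "spiked_proteins": {m: {k: sorted(v) for k, v in s.items()}
                                for m, s in self.spiked_proteins.items()},
            "rppa_up_truth": {m: sorted(v)
                              for m, v in self.rppa_up_truth.items()},
            "rppa_pathway": list(self.rppa_pathway),
        }


@dataclass
class Scenario:
    config: ScenarioConfig
    network: InteractionNetwork
    pathways: PathwayCollection
    expression: dict        # model -> FeatureStats DataFrame
    counts: dict            # model -> SpectralCountTable DataFrame
    rppa: dict              # model -> RPPA DataFrame
    truth: ScenarioTruth


def _node_name(i: int) -> str:
    return f"G{i + 1:04d}"


def generate_network(n_nodes: int, n_edges: int,
                     rng_seed: int = 0,
                     rng: np.random.Generator | None = None,
                     name: str = "synthetic") -> InteractionNetwork:
    """Connected scale-free-like graph with exact node and edge counts.

    A preferential-attachment tree guarantees connectivity; the remaining
    edges are added between degree-weighted endpoint pairs, which keeps the
    heavy-tailed degree distribution of protein-interaction networks.
    """
    if n_nodes < 2:
        raise ValueError("need at least 2 nodes")
    if n_edges < n_nodes - 1:
        raise ValueError("n_edges too small for a connected graph")
    max_edges = n_nodes * (n_nodes - 1) // 2
    if n_edges > max_edges:
        raise ValueError(f"n_edges exceeds the simple-graph maximum {max_edges}")
    if rng is None:
        rng = np.random.default_rng(rng_seed)
    degree = np.zeros(n_nodes, dtype=np.int64)
    edges: set[tuple[int, int]] = set()

    def add(a: int, b: int) -> None:
        edges.add((min(a, b), max(a, b)))
        degree[a] += 1
        degree[b] += 1

    add(0, 1)
    for i in range(2, n_nodes):
        weights = degree[:i].astype(float)
        target = rng.choice(i, p=weights / weights.sum())
        add(i, int(target))
    while len(edges) < n_edges:
        w = degree.astype(float)
        a = int(rng.choice(n_nodes, p=w / w.sum()))
        b = int(rng.choice(n_nodes, p=w / w.sum()))
        if a == b or (min(a, b), max(a, b)) in edges:
            continue
        add(a, b)
    named = [(_node_name(a), _node_name(b)) for a, b in sorted(edges)]
    return InteractionNetwork.from_edges(named, name=name)


def generate_expression_stats(features: list[str], up: list[str],
                              down: list[str], rng: np.random.Generator,
                              spike_log2fc: float = 2.0) -> pd.DataFrame:
    """FeatureStats with spiked seeds and uniform-null everything else.

    Seed features get log2fc = +-(spike +- N(0, 0.3)) and p ~ 10**-U(3, 6);
    null features get log2fc ~ N(0, 0.35) and p ~ U(0, 1), so with no
    planted seeds the p-values are exactly uniform.
    """
    up_set, down_set = set(up), set(down)
    rows = []
    for f in features:
        if f in up_set or f in down_set:
            sign = 1.0 if f in up_set else -1.0
            lfc = sign * (spike_log2fc + rng.normal(0.0, 0.3))
            p = 10.0 ** -rng.uniform(3.0, 6.0)
        else:
            lfc = rng.normal(0.0, 0.35)
            p = rng.uniform(0.0, 1.0)
        rows.append((f, lfc, p))
    return pd.DataFrame(rows, columns=["feature", "log2fc", "pvalue"])


def _nb_draw(rng: np.random.Generator, mean: np.ndarray,
             dispersion: float) -> np.ndarray:
    """Negative-binomial counts with var = mu + dispersion * mu^2."""
    mean = np.maximum(mean, 1e-9)
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p)


def generate_count_table(proteins: list[str], up: list[str], down: list[str],
                         rng: np.random.Generator, count_depth: int = 7500,
                         spike_fold: float = 5.0,
                         dispersion: float = 0.01) -> pd.DataFrame:
    """Two-sample spectral counts with spiked proteins.

    Baseline abundances are log-normal, scaled so each sample's expected
    library size is ``count_depth``.  Up-spiked proteins have their
    metastatic mean multiplied by ``spike_fold``; down-spiked proteins
    divided by it.  Overdispersion is the realistic stress case for the
    downstream exact test.
    """
    base = rng.lognormal(mean=0.0, sigma=1.0, size=len(proteins))
    base *= count_depth / base.sum()
    up_set, down_set = set(up), set(down)
    factor = np.array([spike_fold if p in up_set
                       else 1.0 / spike_fold if p in down_set
                       else 1.0 for p in proteins])
    met = _nb_draw(rng, base * factor, dispersion)
    par = _nb_draw(rng, base, dispersion)
    return pd.DataFrame({"protein": proteins,
                         "count_met": met.astype(np.int64),
                         "count_par": par.astype(np.int64)})


def generate_rppa_table(proteins: list[str], up_truth: list[str],
                        rng: np.random.Generator,
                        n_antibodies: int = 242,
                        effect: float = 0.6) -> pd.DataFrame:
    """Antibody-level RPPA table with planted up-regulated proteins.

    Planted-up proteins get protein-level log2 differences in
    [0.35, 0.35 + effect]; all others in [-0.8, 0.25].  Antibody replicates
    add +-0.04 noise, small enough that the max-|value| collapse preserves
    the planted up-calls at the 0.3 threshold exactly.
    """
    if n_antibodies < len(proteins):
        raise ValueError("need at least one antibody per protein")
    up_set = set(up_truth)
    level = {}
    for p in proteins:
        if p in up_set:
            level[p] = rng.uniform(0.35, 0.35 + max(effect, 0.05))
        else:
            level[p] = rng.uniform(-0.8, 0.25)
    # every protein gets one antibody; the remainder are spread at random
    assignment = list(proteins)
    extra = rng.choice(len(proteins), size=n_antibodies - len(proteins),
                       replace=True)
    assignment.extend(proteins[i] for i in extra)
    rows = []
    for i, prot in enumerate(assignment):
        noise = rng.uniform(-0.04, 0.04)
        rows.append((f"AB{i + 1:03d}", prot, level[prot] + noise))
    return pd.DataFrame(rows, columns=["antibody", "protein", "log2diff"])


def generate_scenario(cfg: ScenarioConfig) -> Scenario:
    """Generate the full two-model scenario with planted truth."""
    rng = np.random.default_rng(cfg.rng_seed)
    net = generate_network(cfg.n_nodes, cfg.n_edges, rng=rng)
    nodes = sorted(net.graph.nodes)

    # --- pathway collection; the first n_planted_pathways are the shared biology
    capacity = cfg.n_planted_pathways * cfg.pathway_size + 2 * cfg.seeds_per_model
    if capacity > cfg.n_nodes:
        raise ValueError("pathway capacity plus seed demand exceeds node count")
    shuffled = [nodes[i] for i in rng.permutation(len(nodes))]
    pathways: dict[str, frozenset[str]] = {}
    planted_names = []
    cursor = 0
    for j in range(cfg.n_planted_pathways):
        name = f"PW_PLANTED_{j + 1:02d}"
        members = shuffled[cursor:cursor + cfg.pathway_size]
        cursor += cfg.pathway_size
        pathways[name] = frozenset(members)
        planted_names.append(name)
    planted_members = frozenset().union(*pathways.values())

    # --- hidden regulators: members of each planted pathway, split between
    #     the up and down directions so no regulator becomes a global hub
    per_dir = max(cfg.n_hidden_regulators // 2, 1)
    regulators: dict[str, list[str]] = {"up": [], "down": []}
    for name in planted_names:
        members = sorted(pathways[name])
        picks = rng.choice(len(members), size=2 * per_dir, replace=False)
        regulators["up"].extend(members[i] for i in picks[:per_dir])
        regulators["down"].extend(members[i] for i in picks[per_dir:])
    regulator_set = frozenset(regulators["up"]) | frozenset(regulators["down"])

    # --- model seeds: outside every planted pathway, partially shared per
    #     direction between the two models
    seed_pool = [n for n in shuffled if n not in planted_members]
    half = cfg.seeds_per_model // 2
    if half < 2:
        raise ValueError("seeds_per_model must be >= 4")
    n_shared = int(round(cfg.seed_overlap_fraction * half))
    n_own = half - n_shared
    if 2 * (n_shared + 2 * n_own) > len(seed_pool):
        raise ValueError("pathway capacity < seeds requested")

    model_seeds = {m: {} for m in MODELS}
    cursor = 0
    for direction in ("up", "down"):
        shared = seed_pool[cursor:cursor + n_shared]
        own_a = seed_pool[cursor + n_shared:cursor + n_shared + n_own]
        own_b = seed_pool[cursor + n_shared + n_own:
                          cursor + n_shared + 2 * n_own]
        cursor += n_shared + 2 * n_own
        model_seeds[MODELS[0]][direction] = sorted(shared + own_a)
        model_seeds[MODELS[1]][direction] = sorted(shared + own_b)

    # --- wire every regulator to its direction's seeds in both models
    #     (half of each model's total seed set)
    for direction in ("up", "down"):
        for reg in regulators[direction]:
            for model in MODELS:
                for s in model_seeds[model][direction]:
                    if not net.graph.has_edge(reg, s):
                        net.graph.add_edge(reg, s)

    # --- decoy pathways complete the collection (drawn over all nodes)
    for j in range(cfg.n_planted_pathways, cfg.n_pathways):
        name = f"PW_DECOY_{j + 1:02d}"
        picks = rng.choice(len(nodes), size=cfg.pathway_size, replace=False)
        pathways[name] = frozenset(nodes[i] for i in picks)
    coll = PathwayCollection.from_sets(pathways, background=nodes,
                                       restrict=False)

    # --- expression layer
    expression = {}
    for model in MODELS:
        expression[model] = generate_expression_stats(
            nodes, model_seeds[model]["up"], model_seeds[model]["down"],
            rng, spike_log2fc=cfg.expression_log2fc)

    # --- spectral-count layer: proteins are a node subset containing all seeds
    all_seeds = sorted({s for m in MODELS for d in ("up", "down")
                        for s in model_seeds[m][d]})
    others = [n for n in shuffled if n not in all_seeds]
    proteins = sorted(all_seeds + others[:max(cfg.n_count_proteins
                                              - len(all_seeds), 0)])
    counts = {}
    spiked = {}
    n_spike_half = min(cfg.n_spiked // 2, half)
    for model in MODELS:
        sp_up = model_seeds[model]["up"][:n_spike_half]
        sp_down = model_seeds[model]["down"][:cfg.n_spiked - n_spike_half]
        spiked[model] = {"up": sorted(sp_up), "down": sorted(sp_down)}
        counts[model] = generate_count_table(
            proteins, sp_up, sp_down, rng, count_depth=cfg.count_depth,
            spike_fold=cfg.spike_fold, dispersion=cfg.dispersion)

    # --- RPPA layer: panel includes the first planted pathway inside a
    #     24-protein target pathway; planted up-calls overlap it as in the
    #     validation design
    pw1 = sorted(pathways[planted_names[0]])
    non_pw = [n for n in shuffled if n not in pw1]
    rppa_pathway = sorted(pw1 + non_pw[:cfg.rppa_pathway_size - len(pw1)])
    rest = [n for n in non_pw[cfg.rppa_pathway_size - len(pw1):]]
    panel = sorted(rppa_pathway + rest[:cfg.rppa_n_proteins - len(rppa_pathway)])
    rppa = {}
    rppa_up_truth = {}
    for model, n_up, n_in in zip(MODELS, cfg.rppa_n_up,
                                 cfg.rppa_n_up_in_pathway):
        n_in_path = min(n_in, len(rppa_pathway), n_up)
        in_path = [rppa_pathway[i] for i in
                   rng.choice(len(rppa_pathway), size=n_in_path, replace=False)]
        off_path = [p for p in panel if p not in rppa_pathway]
        picks = rng.choice(len(off_path), size=n_up - n_in_path, replace=False)
        ups = sorted(in_path + [off_path[i] for i in picks])
        rppa_up_truth[model] = ups
        rppa[model] = generate_rppa_table(panel, ups, rng,
                                          n_antibodies=cfg.rppa_n_antibodies,
                                          effect=cfg.rppa_effect)

    truth = ScenarioTruth(
        planted_pathways=tuple(planted_names),
        hidden_regulators=regulator_set,
        model_seeds=model_seeds,
        spiked_proteins=spiked,
        rppa_up_truth=rppa_up_truth,
        rppa_pathway=tuple(rppa_pathway),
    )
    return Scenario(config=cfg, network=net, pathways=coll,
                    expression=expression, counts=counts, rppa=rppa,
                    truth=truth)


def write_scenario(scn: Scenario, outdir: str | Path) -> dict[str, Path]:
    """Write every layer as plain text (TSV / GMT / JSON); returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    paths["network"] = outdir / "network.tsv"
    write_network(scn.network, paths["network"])
    paths["pathways"] = outdir / "pathways.gmt"
    write_gmt(scn.pathways, paths["pathways"])
    for model in MODELS:
        for layer, frames in (("expression", scn.expression),
                              ("counts", scn.counts), ("rppa", scn.rppa)):
            key = f"{layer}_{model}"
            paths[key] = outdir / f"{key}.tsv"
            frames[model].to_csv(paths[key], sep="\t", index=False)
    paths["truth"] = outdir / "truth.json"
    with paths["truth"].open("w") as fh:
        json.dump({"config": dataclasses.asdict(scn.config),
                   "truth": scn.truth.to_dict()}, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths
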