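"""Orchestration of the full direct-vs-topological two-model comparison.

Stages:
  direct       — per-model differential calls on each omic layer, pathway
                 enrichment of the up/down sets, common pathways, concordance;
  topological  — per-model, per-direction node scoring, enrichment of the
                 significant nodes, common pathways, hidden fractions,
                 concordance of node sets;
  random_fdr   — specificity calibration with random feature sets;
  rppa         — antibody collapse, up-calls, pathway hypergeometric test.

Up- and down-regulated sets are analyzed separately throughout, never
pooled.  Every stage is a pure function of (inputs, config, rng seed); the
report carries a config hash so any number can be recomputed from the
archived intermediates.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

from . import __version__
from .comparison import compare_sets
from .differential import DifferentialSet, select_differential
from .enrichment import PathwayCollection, common_pathways, enrich, random_set_fdr
from .network import InteractionNetwork
from .rppa import collapse_antibodies, call_upregulated, panel_summary
from .speccount import differential_proteins, test_counts
from .toposcore import hidden_nodes, score_nodes

logger = logging.getLogger(__name__)

__all__ = ["run_direct", "run_topological", "run_full", "load_config"]

DEFAULTS: dict[str, Any] = {
    "thresholds": {"p_max": 0.05, "fc_min": 2.0},
    "toposcore": {"n_resamples": 100, "alpha": 0.05},
    "enrichment": {"alpha": 0.05, "top_k": 10},
    "random_fdr": {"n_sets": 10, "set_size": 24, "top_k": 10},
    "rng_seed": 11,
}


def load_config(path: str | Path) -> dict:
    with Path(path).open() as fh:
        cfg = yaml.safe_load(fh) or {}
    merged = json.loads(json.dumps(DEFAULTS))
    for key, val in cfg.items():
        if isinstance(val, Mapping) and isinstance(merged.get(key), dict):
            merged[key].update(val)
        else:
            merged[key] = val
    return merged


def _config_hash(config: Mapping) -> str:
    canon = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _diffset_json(ds: DifferentialSet) -> dict:
    return {"model": ds.model, "n_up": len(ds.up), "n_down": len(ds.down),
            "up": sorted(ds.up), "down": sorted(ds.down)}


def run_direct(models: Mapping[str, pd.DataFrame], coll: PathwayCollection,
               p_max: float = 0.05, fc_min: float = 2.0,
               enrich_alpha: float = 0.05, top_k: int = 10) -> dict:
    """Direct-layer analysis of one omic layer across >= 2 models."""
    if len(models) < 2:
        raise ValueError("need at least 2 models")
    diff: dict[str, DifferentialSet] = {}
    tables: dict[str, dict[str, pd.DataFrame | None]] = {}
    for model, stats in models.items():
        ds = select_differential(stats, p_max=p_max, fc_min=fc_min, model=model)
        diff[model] = ds
        tables[model] = {}
        for direction, feats in (("up", ds.up), ("down", ds.down)):
            if feats & coll.background:
                tables[model][direction] = enrich(feats, coll, alpha=enrich_alpha)
            else:
                tables[model][direction] = None
    names = sorted(models)
    a, b = names[0], names[1]
    common: dict[str, list[str]] = {}
    for direction in ("up", "down"):
        ta, tb = tables[a][direction], tables[b][direction]
        common[direction] = (common_pathways(ta, tb, top_k=top_k)
                             if ta is not None and tb is not None else [])
    concordance = compare_sets(diff[a], diff[b])
    return {
        "differential": diff,
        "enrichment": tables,
        "common_pathways": common,
        "concordance": concordance,
    }


def run_topological(models: Mapping[str, DifferentialSet],
                    net: InteractionNetwork, coll: PathwayCollection,
                    n_resamples: int = 100, alpha: float = 0.05,
                    rng_seed: int = 11, enrich_alpha: float = 0.05,
                    top_k: int = 10) -> dict:
    """Topological-layer analysis: scoring, enrichment, hidden fractions."""
    if len(models) < 2:
        raise ValueError("need at least 2 models")
    covered = {m: len(ds.all & net.nodes) / max(len(ds.all), 1)
               for m, ds in models.items()}
    for m, frac in covered.items():
        if frac < 0.5:
            logger.warning("%s: network covers only %.0f%% of features",
                           m, 100 * frac)
    scores: dict[str, dict[str, pd.DataFrame]] = {}
    sig_sets: dict[str, dict[str, frozenset[str]]] = {}
    hidden: dict[str, dict[str, float]] = {}
    tables: dict[str, dict[str, pd.DataFrame | None]] = {}
    for i, (model, ds) in enumerate(sorted(models.items())):
        scores[model] = {}
        sig_sets[model] = {}
        hidden[model] = {}
        tables[model] = {}
        for j, (direction, feats) in enumerate((("up", ds.up), ("down", ds.down))):
            seeds = feats & net.nodes
            if len(seeds) < 2:
                raise ValueError(
                    f"{model}/{direction}: fewer than 2 seeds on the network")
            tab = score_nodes(net, seeds, n_resamples=n_resamples, alpha=alpha,
                              rng_seed=rng_seed + 10 * i + j)
            scores[model][direction] = tab
            sig = frozenset(tab.index[tab["significant"]])
            sig_sets[model][direction] = sig
            _, frac = hidden_nodes(tab, ds)
            hidden[model][direction] = frac
            tables[model][direction] = (enrich(sig, coll, alpha=enrich_alpha)
                                        if sig & coll.background else None)
    names = sorted(models)
    a, b = names[0], names[1]
    common: dict[str, list[str]] = {}
    for direction in ("up", "down"):
        ta, tb = tables[a][direction], tables[b][direction]
        common[direction] = (common_pathways(ta, tb, top_k=top_k)
                             if ta is not None and tb is not None else [])
    node_sets = {
        m: DifferentialSet(model=m, up=sig_sets[m]["up"],
                           down=sig_sets[m]["down"] - sig_sets[m]["up"])
        for m in names
    }
    concordance = compare_sets(node_sets[a], node_sets[b])
    return {
        "scores": scores,
        "significant": sig_sets,
        "hidden_fraction": hidden,
        "enrichment": tables,
        "common_pathways": common,
        "concordance": concordance,
        "network_coverage": covered,
    }


def run_full(config: Mapping, scenario=None, outdir: str | Path | None = None) -> dict:
    """Run every stage on a generated (or supplied) scenario.

    ``config`` follows :data:`DEFAULTS` plus an optional ``scenario`` section
    forwarded to :class:`netconcord.simulate.ScenarioConfig` and an optional
    ``rppa`` section with explicit panel counts.  Stage failures are caught
    and reported per stage rather than aborting the whole report.
    """
    from .simulate import MODELS, ScenarioConfig, generate_scenario, write_scenario

    t0 = time.time()
    rng_seed = int(config.get("rng_seed", 11))
    if scenario is None:
        scn_cfg = dict(config.get("scenario", {}))
        scn_cfg.setdefault("rng_seed", rng_seed)
        if "rppa_n_up" in scn_cfg:
            scn_cfg["rppa_n_up"] = tuple(scn_cfg["rppa_n_up"])
        scenario = generate_scenario(ScenarioConfig(**scn_cfg))
    thresholds = config["thresholds"]
    topo_cfg = config["toposcore"]
    enr_cfg = config["enrichment"]

    report: dict[str, Any] = {
        "provenance": {
            "package": "netconcord",
            "version": __version__,
            "config_hash": _config_hash(config),
            "rng_seed": rng_seed,
        },
        "stages": {},
    }

    def stage(name, fn):
        try:
            report["stages"][name] = {"status": "ok", "result": fn()}
        except Exception as exc:  # partial report on stage failure
            logger.exception("stage %s failed", name)
            report["stages"][name] = {"status": "error", "error": str(exc)}

    def direct_stage():
        res = run_direct(scenario.expression, scenario.pathways,
                         p_max=thresholds["p_max"], fc_min=thresholds["fc_min"],
                         enrich_alpha=enr_cfg["alpha"], top_k=enr_cfg["top_k"])
        prot_sets = {}
        for model in MODELS:
            quant = test_counts(scenario.counts[model])
            prot_sets[model] = differential_proteins(
                quant, p_max=thresholds["p_max"], fc_min=thresholds["fc_min"],
                model=model)
        names = sorted(prot_sets)
        return {
            "expression": {
                "differential": {m: _diffset_json(d)
                                 for m, d in res["differential"].items()},
                "common_pathways": res["common_pathways"],
                "concordance": res["concordance"].to_dict(),
            },
            "proteins": {
                "differential": {m: _diffset_json(d)
                                 for m, d in prot_sets.items()},
                "concordance": compare_sets(prot_sets[names[0]],
                                            prot_sets[names[1]]).to_dict(),
            },
            "_diffsets": res["differential"],
        }

    stage("direct", direct_stage)

    def topo_stage():
        diffsets = report["stages"]["direct"]["result"]["_diffsets"]
        res = run_topological(diffsets, scenario.network, scenario.pathways,
                              n_resamples=topo_cfg["n_resamples"],
                              alpha=topo_cfg["alpha"], rng_seed=rng_seed,
                              enrich_alpha=enr_cfg["alpha"],
                              top_k=enr_cfg["top_k"])
        return {
            "hidden_fraction": res["hidden_fraction"],
            "common_pathways": res["common_pathways"],
            "concordance": res["concordance"].to_dict(),
            "n_significant": {m: {d: len(s) for d, s in per.items()}
                              for m, per in res["significant"].items()},
        }

    stage("topological", topo_stage)

    def random_stage():
        rf = config["random_fdr"]
        targets = list(scenario.truth.planted_pathways)
        exclude = set()
        for ds in report["stages"]["direct"]["result"]["_diffsets"].values():
            exclude |= set(ds.all)
        return random_set_fdr(
            scenario.network, scenario.pathways, targets,
            n_sets=rf["n_sets"],
            set_size=min(rf["set_size"], len(scenario.network.nodes) // 2),
            top_k=rf["top_k"], exclude=exclude, rng_seed=rng_seed,
            n_resamples=topo_cfg["n_resamples"], alpha=topo_cfg["alpha"])

    stage("random_fdr", random_stage)

    def rppa_stage():
        explicit = config.get("rppa")
        if explicit:
            # explicit panel counts: (N, K, n, k)
            from .rppa import HypergeomInput, pathway_hypergeom_test
            out = {}
            for model, counts in explicit.items():
                N, K, n, k = (int(counts[key]) for key in ("N", "K", "n", "k"))
                inp = HypergeomInput(k=k, K=K, m=n - k, M=N - K, n=n, N=N)
                out[model] = {"counts": dataclasses.asdict(inp),
                              "pvalue": pathway_hypergeom_test(inp)}
            return out
        out = {}
        for model in MODELS:
            collapsed = collapse_antibodies(scenario.rppa[model])
            up, fold = call_upregulated(collapsed)
            out[model] = panel_summary(collapsed["protein"],
                                       scenario.truth.rppa_pathway, up)
        return out

    stage("rppa", rppa_stage)

    if report["stages"]["direct"]["status"] == "ok":
        del report["stages"]["direct"]["result"]["_diffsets"]
    logger.info("full pipeline finished in %.1f s", time.time() - t0)

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_scenario(scenario, outdir / "inputs")
        with (outdir / "report.json").open("w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True, default=str)
            fh.write("\n")
        (outdir / "summary.txt").write_text(render_summary(report))
    return report


def render_summary(report: Mapping) -> str:
    """Human-readable digest of a pipeline report."""
    lines = [f"netconcord {report['provenance']['version']} "
             f"(config {report['provenance']['config_hash']}, "
             f"seed {report['provenance']['rng_seed']})"]
    stages = report["stages"]
    for name in ("direct", "topological", "random_fdr", "rppa"):
        st = stages.get(name, {})
        lines.append(f"\n[{name}] status: {st.get('status', 'missing')}")
        if st.get("status") != "ok":
            if "error" in st:
                lines.append(f"  error: {st['error']}")
            continue
        res = st["result"]
        if name == "direct":
            for layer in ("expression", "proteins"):
                conc = res[layer]["concordance"]
                lines.append(f"  {layer}: overall concordance "
                             f"{conc['overall_pct']}% "
                             f"(up {conc['category_pct_up']}%, "
                             f"down {conc['category_pct_down']}%)")
            cp = res["expression"]["common_pathways"]
            lines.append(f"  common pathways (expression): "
                         f"up={cp['up']} down={cp['down']}")
        elif name == "topological":
            conc = res["concordance"]
            lines.append(f"  node concordance {conc['overall_pct']}%")
            lines.append(f"  common pathways: up={res['common_pathways']['up']} "
                         f"down={res['common_pathways']['down']}")
            lines.append(f"  hidden fractions: {res['hidden_fraction']}")
        elif name == "random_fdr":
            lines.append(f"  per-target FDR: {res}")
        elif name == "rppa":
            for model, summary in res.items():
                lines.append(f"  {model}: p = {summary['pvalue']:.3f}")
    return "\n".join(lines) + "\n"
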