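"""End-to-end orchestration: cohort -> correlations -> networks -> inference.

A single :class:`PipelineConfig` (loadable from YAML) drives every
stage; ``run_pipeline`` executes the stages in order up to a requested
stage and writes plain-text outputs plus a machine-readable
``summary.json`` into the run directory.  All randomness derives from
the master seed, so a rerun with the same config reproduces the run.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as eio
from .cohort import CohortConfig, generate_cohort
from .communities import classify_node_roles, detect_communities, diversity_scores
from .inference import (behavior_hub_correlation, bootstrap_group_difference,
                        rewire_permutation_test)
from .lesion import DisruptionParams, disruption_profile
from .metrics import (eigencentrality_hub_scores, global_metrics,
                      normalize_to_baseline)
from .minimal import (extract_minimal_network, rank_minimal_centralities,
                      select_behavior_hubs)
from .networks import build_consensus_network, build_spearman_matrix, \
    threshold_to_network

__all__ = ["PipelineConfig", "run_pipeline", "STAGES"]

log = logging.getLogger("engramnet")

STAGES = ("simulate", "correlate", "network", "metrics", "consensus",
          "communities", "infer", "lesion", "minimal")


@dataclass
class PipelineConfig:
    """Every stage's effective parameters, echoed verbatim into the summary."""

    outdir: str = "engramnet_run"
    manifest: str | None = None          # None: generate a synthetic cohort
    cohort: dict = field(default_factory=dict)  # CohortConfig overrides
    alpha: float = 0.001
    min_fraction: float = 0.75
    role_quantile: float = 0.20
    n_boot: int = 1000
    n_perm: int = 1000
    disruption_threshold: float = 0.5
    disruption_max_iterations: int | None = None
    baseline_bin: int = 0
    analysis_bin: int | None = None      # None: the final bin
    behavior_block: int | None = None    # None: the last block
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _stage_index(name: str) -> int:
    if name not in STAGES:
        raise ValueError(f"unknown stage {name!r}; choose from {STAGES}")
    return STAGES.index(name)


def run_pipeline(config: PipelineConfig, until: str = "minimal") -> dict:
    """Run the analysis up to (and including) stage ``until``.

    Returns the summary dict, also written to ``<outdir>/summary.json``.
    Stage errors are re-raised annotated with the stage name.
    """
    last = _stage_index(until)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {"config": config.to_dict(),
                     "config_hash": config.config_hash(),
                     "stages_run": []}
    state: dict = {}
    for stage in STAGES[:last + 1]:
        log.info("stage %s", stage)
        try:
            _RUNNERS[stage](config, outdir, state, summary)
        except Exception as exc:  # annotate the failing stage
            raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc
        summary["stages_run"].append(stage)
        with open(outdir / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, default=str)
    return summary


# --- individual stages -------------------------------------------------------

def _analysis_bin(config: PipelineConfig, state: dict) -> int:
    if config.analysis_bin is not None:
        return config.analysis_bin
    return state["animals"][0].n_bins - 1


def _stage_simulate(config, outdir, state, summary):
    if config.manifest:
        animals, behavior = eio.read_cohort(config.manifest)
        log.info("loaded %d animals from %s", len(animals), config.manifest)
    else:
        cc = CohortConfig(seed=config.seed, **config.cohort)
        animals, behavior = generate_cohort(cc)
        eio.write_cohort(animals, behavior, outdir / "cohort")
        summary["cohort"] = {"n_animals": len(animals),
                             "hub_regions": list(cc.hub_regions),
                             "hub_gain": cc.hub_gain}
    state["animals"] = animals
    state["behavior"] = behavior
    state["groups"] = sorted({ts.group for ts in animals})


def _stage_correlate(config, outdir, state, summary):
    cdir = outdir / "correlations"
    cdir.mkdir(exist_ok=True)
    cms = {}
    for ts in state["animals"]:
        for b in range(ts.n_bins):
            cm = build_spearman_matrix(ts, b)
            cms[(ts.animal_id, b)] = cm
            eio.write_correlation_csv(cm, cdir / f"{ts.animal_id}_bin{b}.csv")
    state["cms"] = cms


def _stage_network(config, outdir, state, summary):
    ndir = outdir / "networks"
    ndir.mkdir(exist_ok=True)
    nets = {}
    for (animal, b), cm in state["cms"].items():
        net = threshold_to_network(cm, alpha=config.alpha)
        nets[(animal, b)] = net
        eio.write_network(net, ndir / f"{animal}_bin{b}")
    state["nets"] = nets


def _stage_metrics(config, outdir, state, summary):
    rows = []
    for ts in state["animals"]:
        for b in range(ts.n_bins):
            net = state["nets"][(ts.animal_id, b)]
            gm = global_metrics(net)
            hub = eigencentrality_hub_scores(net)
            gm["mean_hub_score"] = float(np.mean(list(hub.values())))
            for metric, value in gm.items():
                rows.append({"animal_id": ts.animal_id, "group": ts.group,
                             "bin": b, "metric": metric, "value": value})
    table = pd.DataFrame(rows)
    normalized = pd.concat([
        normalize_to_baseline(sub, baseline_bin=config.baseline_bin)
        for _, sub in table.groupby("metric")
    ], ignore_index=True)
    normalized.to_csv(outdir / "metrics.csv", index=False)
    state["metrics"] = normalized


def _stage_consensus(config, outdir, state, summary):
    cdir = outdir / "consensus"
    cdir.mkdir(exist_ok=True)
    consensus = {}
    b = _analysis_bin(config, state)
    for group in state["groups"]:
        members = [ts.animal_id for ts in state["animals"] if ts.group == group]
        nets = [state["nets"][(a, b)] for a in members]
        cms = [state["cms"][(a, b)] for a in members]
        cons = build_consensus_network(nets, cms,
                                       min_fraction=config.min_fraction)
        consensus[group] = cons
        eio.write_network(cons, cdir / f"{group}_bin{b}")
    state["consensus"] = consensus
    summary["consensus"] = {
        g: {"n_edges": c.number_of_edges(),
            "edge_density": c.number_of_edges() / (c.number_of_nodes()
                                                   * (c.number_of_nodes() - 1) / 2)}
        for g, c in consensus.items()}


def _stage_communities(config, outdir, state, summary):
    summary["communities"] = {}
    state["partitions"] = {}
    for group, cons in state["consensus"].items():
        part = detect_communities(cons, seed=config.seed)
        div = diversity_scores(cons, part)
        hub = eigencentrality_hub_scores(cons)
        roles = classify_node_roles(hub, div, quantile=config.role_quantile)
        roles.insert(0, "community", pd.Series(part.membership))
        roles.to_csv(outdir / f"roles_{group}.csv")
        state["partitions"][group] = part
        summary["communities"][group] = {
            "n_communities": part.n_communities,
            "modularity": part.modularity,
            "connector_hubs": roles.index[roles["role"] == "ConnectorHub"].tolist(),
            "provincial_hubs": roles.index[roles["role"] == "ProvincialHub"].tolist(),
        }


def _stage_infer(config, outdir, state, summary):
    groups = state["groups"]
    if len(groups) != 2:
        log.warning("inference needs exactly 2 groups, found %d; skipped",
                    len(groups))
        summary["inference"] = "skipped: need 2 groups"
        return
    # Put the reactivation-like group first so differences read as
    # treated-minus-control.
    ga, gb = groups[::-1] if groups[0] == "control" else groups
    rng = np.random.default_rng([config.seed, 1])

    # BCa bootstrap contrasts of baseline-normalized metrics, per bin.
    metrics = state["metrics"]
    boot_rows = []
    for (metric, b), sub in metrics.groupby(["metric", "bin"]):
        if b == config.baseline_bin:
            continue
        va = sub.loc[sub["group"] == ga, "normalized"].to_numpy()
        vb = sub.loc[sub["group"] == gb, "normalized"].to_numpy()
        res = bootstrap_group_difference(va, vb, n_boot=config.n_boot,
                                         seed=rng, metric=metric)
        row = {"metric": metric, "bin": b, "observed": res.observed,
               "stars": res.stars}
        for lv, (lo, hi) in res.intervals.items():
            row[f"ci{lv}_low"], row[f"ci{lv}_high"] = lo, hi
        boot_rows.append(row)
    pd.DataFrame(boot_rows).to_csv(outdir / "bootstrap_contrasts.csv",
                                   index=False)

    # Rewiring permutation test on the consensus networks.
    perm = rewire_permutation_test(state["consensus"][ga],
                                   state["consensus"][gb],
                                   n_perm=config.n_perm,
                                   seed=np.random.default_rng([config.seed, 2]))
    perm_table = perm.to_frame()
    perm_table.to_csv(outdir / "hub_permutation.csv")
    summary["inference"] = {
        "groups": [ga, gb],
        "significant_hub_shifts":
            perm_table.index[perm_table["p_value"] < 0.05].tolist(),
    }
    state["permutation"] = perm

    # Behavior-hub correlation from per-animal final-bin networks.
    behavior = state.get("behavior")
    if behavior is None:
        log.warning("no behavior table; behavior-hub correlation skipped")
        summary["behavior_correlation"] = "skipped: no behavior table"
        return
    b = _analysis_bin(config, state)
    hub_rows = {}
    for ts in state["animals"]:
        hub_rows[ts.animal_id] = eigencentrality_hub_scores(
            state["nets"][(ts.animal_id, b)])
    hub_df = pd.DataFrame.from_dict(hub_rows, orient="index")
    block = config.behavior_block or behavior["block_index"].max()
    late = (behavior[behavior["block_index"] == block]
            .set_index("animal_id")["percent_correct"])
    corr = behavior_hub_correlation(hub_df, late)
    corr.to_csv(outdir / "behavior_hub_correlation.csv")
    state["behavior_corr"] = corr
    summary["behavior_correlation"] = {
        "block": int(block),
        "positive_significant":
            corr.index[(corr["r"] > 0) & (corr["p"] < 0.05)].tolist(),
    }


def _stage_lesion(config, outdir, state, summary):
    params = DisruptionParams(
        activity_threshold=config.disruption_threshold,
        max_iterations=config.disruption_max_iterations)
    summary["lesion"] = {"params": {
        "activity_threshold": params.activity_threshold,
        "max_iterations": params.max_iterations}}
    for group, cons in state["consensus"].items():
        table, corr = disruption_profile(cons, params)
        table.to_csv(outdir / f"lesion_{group}.csv")
        summary["lesion"][group] = {"hub_dge_pearson_r": corr["r"],
                                    "hub_dge_pearson_p": corr["p"]}


def _stage_minimal(config, outdir, state, summary):
    corr = state.get("behavior_corr")
    if corr is None:
        log.warning("no behavior-hub correlations; minimal network skipped")
        summary["minimal_network"] = "skipped: no behavior correlations"
        return
    seeds = select_behavior_hubs(corr)
    if not seeds:
        summary["minimal_network"] = "skipped: no significant positive seeds"
        return
    groups = state["groups"]
    source_group = groups[0] if groups[0] != "control" else groups[-1]
    mn = extract_minimal_network(state["consensus"][source_group], seeds,
                                 louvain_seed=config.seed)
    eio.write_network(mn.graph, outdir / "minimal_network")
    rankings = rank_minimal_centralities(mn)
    for metric, table in rankings.items():
        table.to_csv(outdir / f"minimal_ranking_{metric}.csv")
    summary["minimal_network"] = {
        "source_group": source_group,
        "seeds": sorted(seeds), "members": sorted(map(str, mn.members)),
        "n_communities": mn.partition.n_communities,
        "modularity": mn.partition.modularity,
    }


_RUNNERS = {
    "simulate": _stage_simulate,
    "correlate": _stage_correlate,
    "network": _stage_network,
    "metrics": _stage_metrics,
    "consensus": _stage_consensus,
    "communities": _stage_communities,
    "infer": _stage_infer,
    "lesion": _stage_lesion,
    "minimal": _stage_minimal,
}
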