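"""Plain-text I/O: cohort CSVs, correlation tables, network exports."""

from __future__ import annotations

import itertools
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .networks import CorrelationMatrix, RoiTimeSeries

__all__ = [
    "write_cohort", "read_cohort", "write_correlation_csv",
    "read_correlation_csv", "write_network", "read_network_csv",
]


def write_timeseries_csv(ts: RoiTimeSeries, path: Path) -> None:
    df = pd.DataFrame(ts.samples, index=pd.Index(ts.region_names, name="region"))
    df.to_csv(path, float_format="%.6g")


def read_timeseries_csv(path: Path, animal_id: str, group: str,
                        bin_edges: list[int]) -> RoiTimeSeries:
    df = pd.read_csv(path, index_col="region")
    return RoiTimeSeries(animal_id=animal_id, group=group,
                         region_names=list(df.index),
                         samples=df.to_numpy(), bin_edges=bin_edges)


def write_cohort(animals: list[RoiTimeSeries], behavior: pd.DataFrame | None,
                 outdir: Path) -> Path:
    """One CSV per animal + manifest (+ behavior table). Returns manifest path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for ts in animals:
        fname = f"{ts.animal_id}.csv"
        write_timeseries_csv(ts, outdir / fname)
        rows.append({"animal_id": ts.animal_id, "group": ts.group,
                     "file": fname,
                     "bin_edges": ";".join(map(str, ts.bin_edges))})
    manifest = outdir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    if behavior is not None:
        behavior.to_csv(outdir / "behavior.csv", index=False)
    return manifest


def read_cohort(manifest: Path) -> tuple[list[RoiTimeSeries], pd.DataFrame | None]:
    manifest = Path(manifest)
    base = manifest.parent
    rows = pd.read_csv(manifest)
    animals = [
        read_timeseries_csv(base / r["file"], r["animal_id"], r["group"],
                            [int(x) for x in str(r["bin_edges"]).split(";")])
        for _, r in rows.iterrows()
    ]
    behavior_path = base / "behavior.csv"
    behavior = pd.read_csv(behavior_path) if behavior_path.exists() else None
    return animals, behavior


def write_correlation_csv(cm: CorrelationMatrix, path: Path) -> None:
    """Long format: region_i, region_j, rho, p_raw, p_adj (upper triangle)."""
    rows = []
    for i, j in itertools.combinations(range(len(cm.region_names)), 2):
        rows.append({"region_i": cm.region_names[i],
                     "region_j": cm.region_names[j],
                     "rho": cm.rho[i, j], "p_raw": cm.p_raw[i, j],
                     "p_adj": cm.p_adj[i, j]})
    pd.DataFrame(rows).to_csv(path, index=False)


def read_correlation_csv(path: Path, animal_id: str = "", group: str = "",
                         bin_index: int = -1) -> CorrelationMatrix:
    df = pd.read_csv(path)
    regions = sorted(set(df["region_i"]) | set(df["region_j"]))
    idx = {r: i for i, r in enumerate(regions)}
    n = len(regions)
    rho = np.eye(n)
    p_raw = np.zeros((n, n))
    p_adj = np.zeros((n, n))
    for _, r in df.iterrows():
        i, j = idx[r["region_i"]], idx[r["region_j"]]
        rho[i, j] = rho[j, i] = r["rho"]
        p_raw[i, j] = p_raw[j, i] = r["p_raw"]
        p_adj[i, j] = p_adj[j, i] = r["p_adj"]
    return CorrelationMatrix(region_names=regions, rho=rho, p_raw=p_raw,
                             p_adj=p_adj, m=n * (n - 1) // 2,
                             animal_id=animal_id, group=group,
                             bin_index=bin_index)


def write_network(net: nx.Graph, stem: Path) -> None:
    """Edge-list CSV and GraphML exports side by side."""
    stem = Path(stem)
    rows = [{"source": u, "target": v, "weight": d["weight"],
             "retention_fraction": d.get("retention_fraction", "")}
            for u, v, d in net.edges(data=True)]
    pd.DataFrame(rows, columns=["source", "target", "weight",
                                "retention_fraction"]
                 ).to_csv(stem.with_suffix(".csv"), index=False)
    clean = net.copy()
    clean.graph = {k: v for k, v in net.graph.items()
                   if isinstance(v, (str, int, float, bool))}
    nx.write_graphml(clean, stem.with_suffix(".graphml"))


def read_network_csv(path: Path, nodes: list | None = None) -> nx.Graph:
    g = nx.Graph()
    if nodes is not None:
        g.add_nodes_from(nodes)
    df = pd.read_csv(path)
    for _, r in df.iterrows():
        attrs = {"weight": float(r["weight"])}
        if "retention_fraction" in df.columns and pd.notna(r["retention_fraction"]):
            rf = r["retention_fraction"]
            if rf != "":
                attrs["retention_fraction"] = float(rf)
        g.add_edge(r["source"], r["target"], **attrs)
    return g
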