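"""Config-driven experiment orchestration.

One experiment = layout (loaded or generated) -> single-constraint benchmarks
-> alpha sweep of annealed reconstructions -> metric battery against an
optional reference network -> tidy CSV tables on disk.  Every random draw is
traceable to the master seed; a completed alpha point is marked on disk so an
interrupted run resumes where it stopped.
"""

from __future__ import annotations

import glob as globmod
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .anneal import (AnnealSchedule, Benchmarks, NetworkReconstruction,
                     derive_seed, replace_alpha, summary_stats)
from .core import (Digraph, Partition, SpatialNetwork, load_digraph,
                   load_positions, write_edge_list, write_positions,
                   write_partition)
from .modularity import find_modules
from .metrics import (degree_density_correlation, geographical_centrality,
                      hub_removal_impact, hub_zscores, locality,
                      match_partitions, recovery_rate, shuffled_match_null,
                      spatial_clusters)
from .powerlaw import PowerlawFitError, powerlaw_test
from .synth import LayoutSpec, ReferenceNetSpec, generate_reference, make_layout

log = logging.getLogger("connectopt")

DEFAULT_ALPHA_GRID = [0.0, 0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9,
                      0.95, 0.99, 1.0]

DEFAULT_METRICS = {
    "modules": True, "clusters": True, "match": True, "hubs": True,
    "locality": True, "recovery": True, "density": False,
    "centrality": False, "powerlaw": False, "robustness": False,
}


@dataclass
class RunConfig:
    """Resolved experiment protocol (see ``from_yaml`` for the file format)."""

    layout_file: str | None = None
    layout_spec: LayoutSpec | None = None
    reference_file: str | None = None
    reference_spec: ReferenceNetSpec | None = None
    K: int | None = None
    alpha_grid: list = field(default_factory=lambda: list(DEFAULT_ALPHA_GRID))
    realizations: int = 50
    schedule: AnnealSchedule = field(default_factory=AnnealSchedule)
    metrics: dict = field(default_factory=lambda: dict(DEFAULT_METRICS))
    module_restarts: int = 50
    out_dir: str = "out"
    master_seed: int = 0

    def __post_init__(self):
        if any(a < 0 or a > 1 for a in self.alpha_grid):
            raise ValueError("alpha grid must lie within [0, 1]")
        if self.realizations < 1:
            raise ValueError("realizations must be >= 1")
        if self.layout_file is None and self.layout_spec is None \
                and self.reference_spec is None:
            raise ValueError("a layout source is required")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        kw = dict(raw)
        if "schedule" in kw:
            kw["schedule"] = AnnealSchedule(**kw["schedule"])
        if "layout_spec" in kw:
            kw["layout_spec"] = LayoutSpec(**kw["layout_spec"])
        if "reference_spec" in kw:
            rs = dict(kw["reference_spec"])
            if "layout" in rs:
                rs["layout"] = LayoutSpec(**rs["layout"])
            if "hub_ranks" in rs:
                rs["hub_ranks"] = tuple(rs["hub_ranks"])
            kw["reference_spec"] = ReferenceNetSpec(**rs)
        if "metrics" in kw:
            kw["metrics"] = {**DEFAULT_METRICS, **kw["metrics"]}
        return cls(**kw)

    def snapshot(self) -> dict:
        out = asdict(self)
        return out


def _resolve_inputs(config: RunConfig):
    """Layout, K, optional reference network and planted labels."""
    reference = None
    planted = None
    if config.reference_spec is not None:
        refnet, truth = generate_reference(config.reference_spec)
        positions = refnet.positions
        reference = refnet.graph
        planted = truth.labels
    elif config.layout_file is not None:
        positions = load_positions(config.layout_file)
    else:
        positions, planted = make_layout(config.layout_spec)
    if config.reference_file is not None:
        reference = load_digraph(config.reference_file, n=positions.n,
                                 ids=positions.ids)
    K = config.K
    if K is None:
        if reference is None:
            raise ValueError("K is required when no reference network is given")
        K = reference.K
    return positions, K, reference, planted


def _compare_one(candidate: SpatialNetwork, reference: Digraph,
                 ref_modules, clusters: Partition | None,
                 config: RunConfig, seed: int) -> dict:
    """Per-candidate comparison row against the reference network."""
    row: dict = {}
    toggles = config.metrics
    g = candidate.graph
    if toggles.get("recovery"):
        row["R"] = recovery_rate(reference, g).R
        if clusters is not None:
            groups = clusters.groups()
            within = [recovery_rate(reference, g, subset=(gr, gr)).R
                      for gr in groups if len(gr) >= 2]
            between = []
            for a in range(len(groups)):
                for b in range(len(groups)):
                    if a != b:
                        rep = recovery_rate(reference, g,
                                            subset=(groups[a], groups[b]))
                        if not rep.flagged:
                            between.append(rep.R)
            row["R_within_clusters"] = summary_stats(within)[0]
            row["R_between_clusters"] = summary_stats(between)[0]
        bins = np.linspace(0, candidate.d_max * 1.0001, 5)
        for bi in range(4):
            rep = recovery_rate(reference, g,
                                distance_bin=(bins[bi], bins[bi + 1]),
                                spatial=candidate)
            row[f"R_dist_bin{bi}"] = rep.R
    if toggles.get("hubs"):
        ref_hubs = set(hub_zscores(reference).hub_indices.tolist())
        cand_hubs = set(hub_zscores(g).hub_indices.tolist())
        row["n_hub"] = len(cand_hubs)
        row["hub_overlap"] = len(ref_hubs & cand_hubs)
        row["hub_overlap_frac"] = (len(ref_hubs & cand_hubs) / len(ref_hubs)
                                   if ref_hubs else float("nan"))
    if toggles.get("locality"):
        row["F_local"] = locality(candidate).F
    if toggles.get("density"):
        rep = degree_density_correlation(candidate, [0.1, 0.3, 0.5],
                                         surrogate_reps=100, seed=seed)
        mid = rep.frame[rep.frame["r_norm"] == 0.3].iloc[0]
        row["deg_density_corr_r0.3"] = mid["corr"]
        row["deg_density_significant"] = bool(mid["significant"])
    if toggles.get("centrality"):
        rank = geographical_centrality(candidate).set_index("node")
        top = int(np.argmax(g.total_degree))
        row["max_degree_node_centrality_rank"] = int(rank.loc[top, "rank"])
    if toggles.get("powerlaw"):
        try:
            row["powerlaw_p"] = powerlaw_test(g.total_degree,
                                              surrogate_reps=100,
                                              seed=seed).p
        except PowerlawFitError:
            row["powerlaw_p"] = float("nan")
    if toggles.get("robustness"):
        rep = hub_removal_impact(g)
        row["hub_removal_L_ratio"] = rep.ratio
    if toggles.get("modules") and ref_modules is not None:
        cand_modules = find_modules(g, restarts=config.module_restarts,
                                    seed=seed)
        row["Q"] = cand_modules.Q
        rep = match_partitions(ref_modules.partition, cand_modules.partition)
        row["module_mismatch_vs_reference"] = rep.mismatch_rate
        if clusters is not None:
            rep2 = match_partitions(clusters, cand_modules.partition)
            row["module_mismatch_vs_clusters"] = rep2.mismatch_rate
    return row


def run_experiment(config: RunConfig) -> Path:
    """Execute the full protocol; returns the output directory."""
    t_start = time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fh = logging.FileHandler(out / "log.txt")
    fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(fh)
    log.setLevel(logging.INFO)
    try:
        return _run_experiment(config, out, t_start)
    finally:
        log.removeHandler(fh)
        fh.close()


def _run_experiment(config: RunConfig, out: Path, t_start: float) -> Path:
    positions, K, reference, planted = _resolve_inputs(config)
    (out / "resolved_config.yaml").write_text(
        yaml.safe_dump(config.snapshot(), sort_keys=True))
    write_positions(positions, out / "layout.csv")
    log.info("layout: n=%d dim=%d; K=%d; reference=%s",
             positions.n, positions.dim, K, reference is not None)

    model = NetworkReconstruction(positions, K, schedule=config.schedule)
    bench_path = out / "benchmarks.json"
    if bench_path.exists():
        b = json.loads(bench_path.read_text())
        model.benchmarks_ = Benchmarks(**b)
        log.info("benchmarks loaded from disk: %s", b)
    else:
        t0 = time.time()
        model.compute_benchmarks(
            seeds=[derive_seed(config.master_seed, 999, s) for s in range(2)])
        bench_path.write_text(json.dumps(
            {"W0": model.benchmarks_.W0, "L0": model.benchmarks_.L0}))
        log.info("benchmarks: W0=%.6g L0=%.6g (%.1fs)", model.benchmarks_.W0,
                 model.benchmarks_.L0, time.time() - t0)

    ref_modules = None
    clusters = None
    if reference is not None:
        if config.metrics.get("modules"):
            ref_modules = find_modules(reference,
                                       restarts=config.module_restarts,
                                       seed=derive_seed(config.master_seed, 998))
            log.info("reference %s", ref_modules.summary())
        if config.metrics.get("clusters"):
            k_clust = ref_modules.partition.k if ref_modules is not None \
                else (planted.k if planted is not None else 2)
            clusters = spatial_clusters(positions, k_clust, method="ward")
            write_partition(clusters, out / "spatial_clusters.csv",
                            ids=positions.ids)
        if reference is not None:
            write_edge_list(reference, out / "reference.edges",
                            ids=positions.ids)
        if ref_modules is not None:
            write_partition(ref_modules.partition, out / "reference_modules.csv",
                            ids=positions.ids)
            if clusters is not None and config.metrics.get("match"):
                rep = match_partitions(clusters, ref_modules.partition)
                null = shuffled_match_null(
                    clusters, ref_modules.partition, reps=200,
                    seed=derive_seed(config.master_seed, 997))
                (out / "reference_match.json").write_text(json.dumps({
                    "mismatch_rate": rep.mismatch_rate,
                    "shuffled_null": null,
                    "n_mismatched": int(len(rep.mismatched)),
                }, indent=2))

    sweep_rows = []
    compare_rows = []
    for ai, alpha in enumerate(config.alpha_grid):
        adir = out / f"alpha_{alpha:g}"
        done = adir / ".done"
        sub = replace_alpha(model, alpha)
        stats = {"W": [], "L": [], "N_hub": [], "K_hub": [], "F_local": []}
        t0 = time.time()
        for ri in range(config.realizations):
            seed = derive_seed(config.master_seed, ai, ri)
            epath = adir / f"alpha{alpha:g}_rep{ri}.edges"
            if done.exists() and epath.exists():
                net = SpatialNetwork(
                    load_digraph(epath, ids=positions.ids), positions)
                from .anneal import wiring_length, graph_distance_sum
                W, L = wiring_length(net), graph_distance_sum(net.graph)
            else:
                adir.mkdir(exist_ok=True)
                res = sub.fit(seed=seed)
                net, W, L = res.network, res.W, res.L
                write_edge_list(net.graph, epath, ids=positions.ids)
            hub = hub_zscores(net.graph)
            stats["W"].append(W)
            stats["L"].append(L)
            stats["N_hub"].append(hub.n_hub)
            stats["K_hub"].append(hub.k_hub)
            stats["F_local"].append(locality(net).F)
            if reference is not None:
                row = _compare_one(net, reference, ref_modules, clusters,
                                   config, seed)
                row.update({"alpha": alpha, "rep": ri})
                compare_rows.append(row)
        done.touch()
        for stat, vals in stats.items():
            mean, sd = summary_stats(vals)
            sweep_rows.append({
                "alpha": alpha, "statistic": stat, "mean": mean, "sd": sd,
                "n_realizations": config.realizations,
            })
        log.info("alpha=%g done (%.1fs)", alpha, time.time() - t0)

    pd.DataFrame(sweep_rows).to_csv(out / "sweep_summary.csv", index=False)
    if compare_rows:
        pd.DataFrame(compare_rows).to_csv(out / "comparison.csv", index=False)
    log.info("experiment complete in %.1fs", time.time() - t_start)
    return out


def compare_networks(reference_path, candidate_glob, positions_path,
                     metrics: dict | None = None,
                     module_restarts: int = 50, seed: int = 0) -> pd.DataFrame:
    """Standalone comparison of candidate networks against a reference.

    Same computations as the experiment's comparison stage, applicable to
    user-supplied data; candidates are matched by a filename glob.
    """
    positions = load_positions(positions_path)
    reference = load_digraph(reference_path, n=positions.n, ids=positions.ids)
    cfg = RunConfig(layout_file=str(positions_path),
                    metrics={**DEFAULT_METRICS, **(metrics or {})},
                    module_restarts=module_restarts, K=reference.K)
    ref_modules = find_modules(reference, restarts=module_restarts,
                               seed=seed) if cfg.metrics.get("modules") else None
    clusters = spatial_clusters(
        positions, ref_modules.partition.k if ref_modules else 2) \
        if cfg.metrics.get("clusters") else None
    rows = []
    for path in sorted(globmod.glob(str(candidate_glob))):
        g = load_digraph(path, n=positions.n, ids=positions.ids)
        net = SpatialNetwork(g, positions)
        row = _compare_one(net, reference, ref_modules, clusters, cfg, seed)
        row["candidate"] = path
        rows.append(row)
    if not rows:
        return pd.DataFrame()
    df = pd.DataFrame(rows)
    return df[["candidate"] + [c for c in df.columns if c != "candidate"]]
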