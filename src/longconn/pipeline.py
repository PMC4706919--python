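"""End-to-end orchestration: simulate/ingest -> connectome -> statistics ->
NBS -> functional annotation -> multiview clustering -> report.

One YAML (or dict) config drives every stage; a single global seed
deterministically derives per-stage seeds, so identical config + seed
reproduces every artifact and a byte-identical report (no timestamps are
written into the report; elapsed times go to the log only).

Effect-selection logic mirrors the longitudinal analysis convention: the
group-by-time interaction is tested first; when it is not significant the
group and time main effects are tested; when it *is* significant the
package instead reports the simple-effect t maps (unpaired group t per
session, paired time t per group) alongside the interaction components.
An explicit ``effects`` list in the config overrides this.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .annotation import CategoryMap, aggregate_to_major, categorize_edges, top_pairs
from .clustering import categorize_signatures_by_cluster, multiview_cluster
from .connectome import (
    FCStack,
    build_fc_stack,
    load_fc_stack,
    read_timeseries_tsv,
    save_fc_stack,
)
from .edge_stats import edgewise_stats
from .nbs import NBSConfig, NBSResult, nbs_test
from .simulate import SimulationConfig, generate_category_map, generate_cohort, write_cohort

__all__ = ["PipelineConfig", "RunReport", "run_pipeline"]

log = logging.getLogger("longconn.pipeline")

_STAGES = ("simulate", "connectome", "edge_stats", "nbs", "annotate", "cluster")


@dataclass
class PipelineConfig:
    """Everything one run needs; see ``from_yaml`` for the file layout."""

    out_dir: str
    seed: int = 0
    simulation: dict | None = None
    input_dir: str | None = None
    scale: str = "z"
    effects: list[str] | None = None
    nbs: dict = field(default_factory=dict)
    clustering: dict = field(default_factory=dict)
    category_map: str | None = None
    write_plots: bool = False

    def __post_init__(self) -> None:
        if (self.simulation is None) == (self.input_dir is None):
            raise ValueError(
                "exactly one of 'simulation' or 'input_dir' must be configured"
            )
        if self.scale not in ("z", "r"):
            raise ValueError("scale must be 'z' or 'r'")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides: Any) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)

    def to_dict(self) -> dict:
        return {
            "out_dir": self.out_dir,
            "seed": self.seed,
            "simulation": self.simulation,
            "input_dir": self.input_dir,
            "scale": self.scale,
            "effects": self.effects,
            "nbs": self.nbs,
            "clustering": self.clustering,
            "category_map": self.category_map,
            "write_plots": self.write_plots,
        }


@dataclass
class RunReport:
    """Per-stage summaries plus provenance; serializable to stable JSON."""

    stages: dict
    provenance: dict

    def to_json(self) -> str:
        return json.dumps(
            {"stages": self.stages, "provenance": self.provenance},
            indent=1,
            sort_keys=True,
            default=_jsonable,
        )

    def write(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())

    def write_text(self, path: str | Path) -> None:
        Path(path).write_text(self.human_readable())

    def human_readable(self) -> str:
        s = self.stages
        lines = ["longconn pipeline report", "========================", ""]
        lines.append(f"seed: {self.provenance['seed']}")
        lines.append(f"config hash: {self.provenance['config_sha256'][:12]}")
        if "simulate" in s:
            sim = s["simulate"]
            lines.append(
                f"cohort: {sim['n_controls']} controls vs {sim['n_patients']} patients, "
                f"{sim['n_nodes']} nodes, {sim['n_timepoints']} time points"
            )
        lines.append(f"edges tested: {s['edge_stats']['n_edges']}")
        for eff, res in s["nbs"].items():
            sig = res["n_significant_components"]
            lines.append(
                f"NBS [{eff}]: {res['n_components']} component(s), "
                f"{sig} significant, {res['n_significant_edges']} signature edge(s)"
            )
        ann = s.get("annotate", {})
        if ann.get("n_signatures", 0):
            lines.append(
                f"signatures annotated: {ann['n_signatures']} "
                f"(top major pair: {ann['top_major_pair']})"
            )
        cl = s.get("cluster", {})
        if cl:
            lines.append(
                f"clusters: k={cl['k']}, between-cluster signature share "
                f"{cl['between_percent']:.1f}% ({cl['between_total']}/{cl['total_signatures']})"
            )
        return "\n".join(lines) + "\n"


def _jsonable(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON-serializable: {type(o)}")


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31 derived from the global seed."""
    idx = _STAGES.index(stage)
    return int(
        np.random.SeedSequence([int(global_seed), idx]).generate_state(1)[0]
        & 0x7FFFFFFF
    )


def _config_hash(config: PipelineConfig) -> str:
    # out_dir is a location, not an analysis parameter: identical analyses
    # written to different places must hash (and report) identically
    d = config.to_dict()
    d.pop("out_dir")
    blob = json.dumps(d, sort_keys=True, default=_jsonable)
    return hashlib.sha256(blob.encode()).hexdigest()


def _load_cohort_inputs(input_dir: Path):
    design = pd.read_csv(input_dir / "design.tsv", sep="\t")
    ts = [
        read_timeseries_tsv(
            input_dir / "timeseries" / f"{r.subject_id}_{r.session}.tsv",
            subject_id=r.subject_id,
            session=r.session,
        )
        for r in design.itertuples(index=False)
    ]
    return ts, design


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute all stages, persisting every intermediate artifact under
    ``config.out_dir``; returns (and writes) the run report."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages: dict[str, Any] = {}
    t_start = time.perf_counter()

    def _log(stage: str, **kw) -> None:
        fields = " ".join(f"{k}={v}" for k, v in kw.items())
        log.info("stage=%s %s elapsed=%.2fs", stage, fields, time.perf_counter() - t_start)

    # -- simulate / ingest ---------------------------------------------------
    if config.simulation is not None:
        sim_cfg = dict(config.simulation)
        sim_cfg.setdefault("seed", stage_seed(config.seed, "simulate"))
        sim = SimulationConfig.from_dict(sim_cfg)
        cohort = generate_cohort(sim)
        write_cohort(cohort, out / "simulate")
        timeseries, design = cohort.timeseries, cohort.design
        truth = cohort.truth
        stages["simulate"] = {
            "n_nodes": sim.n_nodes,
            "n_timepoints": sim.n_timepoints,
            "n_controls": sim.n_controls,
            "n_patients": sim.n_patients,
            "effect_type": sim.effect_type,
            "n_effect_edges": len(truth["effect_edges"]),
            "seed": sim.seed,
        }
        _log("simulate", nodes=sim.n_nodes, subjects=sim.n_controls + sim.n_patients)
    else:
        timeseries, design = _load_cohort_inputs(Path(config.input_dir))
        truth = None
        _log("ingest", dir=config.input_dir, n_series=len(timeseries))

    # -- connectome ----------------------------------------------------------
    stack = build_fc_stack(timeseries, design)
    save_fc_stack(stack, out / "connectome")
    n = stack.n_nodes
    stages["connectome"] = {
        "n_nodes": n,
        "n_matrices": len(stack.matrices),
        "n_unique_features": n * (n + 1) // 2,
    }
    _log("connectome", matrices=len(stack.matrices))

    # -- edge statistics + NBS ----------------------------------------------
    nbs_cfg = NBSConfig(seed=stage_seed(config.seed, "nbs"), **config.nbs)
    (out / "edge_stats").mkdir(exist_ok=True)
    (out / "nbs").mkdir(exist_ok=True)

    if config.effects is not None:
        effect_plan = list(config.effects)
        adaptive = False
    else:
        effect_plan = ["interaction"]
        adaptive = True

    nbs_results: dict[str, NBSResult] = {}
    stages["nbs"] = {}
    stat_counts = {}
    queue = list(effect_plan)
    while queue:
        eff = queue.pop(0)
        res = nbs_test(stack, eff, nbs_cfg, scale=config.scale)
        res.stats.write_tsv(out / "edge_stats" / f"{eff}.tsv")
        res.write_components_tsv(out / "nbs" / f"{eff}_components.tsv")
        res.write_null_tsv(out / "nbs" / f"{eff}_null.tsv")
        nbs_results[eff] = res
        stages["nbs"][eff] = res.summary()
        stat_counts[eff] = res.stats.n_edges
        _log("nbs", effect=eff, significant=len(res.significant_components))
        if adaptive and eff == "interaction":
            if res.significant_components:
                # significant interaction: report the simple effects
                for which, kw in (
                    ("group_t_unpaired", {"session": "acute"}),
                    ("group_t_unpaired", {"session": "subacute"}),
                    ("time_t_paired", {"group": "control"}),
                    ("time_t_paired", {"group": "patient"}),
                ):
                    smap = edgewise_stats(stack, which, scale=config.scale, **kw)
                    tag = f"{which}_{list(kw.values())[0]}"
                    smap.write_tsv(out / "edge_stats" / f"{tag}.tsv")
                stages["nbs"]["simple_effects_reported"] = True
            else:
                queue.extend(["group", "time"])
    stages["edge_stats"] = {
        "scale": config.scale,
        "n_edges": next(iter(stat_counts.values())),
        "effects": sorted(stat_counts),
    }

    signature_edges = []
    for eff, res in nbs_results.items():
        signature_edges.extend(res.significant_edge_ids())
    with open(out / "nbs" / "signature_edges.json", "w") as fh:
        json.dump(sorted(signature_edges), fh)

    # -- annotation ----------------------------------------------------------
    (out / "annotate").mkdir(exist_ok=True)
    if config.category_map is not None:
        cmap = CategoryMap.read_tsv(config.category_map)
    else:
        cmap = generate_category_map(
            n, seed=stage_seed(config.seed, "annotate"), node_ids=stack.node_ids
        )
    cmap.write_tsv(out / "annotate" / "category_map.tsv")
    ann_summary: dict[str, Any] = {"n_signatures": len(signature_edges)}
    if signature_edges:
        sub = categorize_edges(signature_edges, cmap, level="sub")
        major = aggregate_to_major(sub, cmap)
        major.counts.to_csv(out / "annotate" / "pairs_major.tsv", sep="\t")
        sub.counts.to_csv(out / "annotate" / "pairs_sub.tsv", sep="\t")
        ranked = top_pairs(major)
        ranked.to_csv(out / "annotate" / "ranked_major_pairs.tsv", sep="\t", index=False)
        top_pairs(sub).to_csv(out / "annotate" / "ranked_sub_pairs.tsv", sep="\t", index=False)
        ann_summary["top_major_pair"] = (
            f"{ranked.iloc[0].category_a}-{ranked.iloc[0].category_b}"
        )
        ann_summary["major_pair_counts"] = {
            f"{a}|{b}": int(c) for (a, b), c in major.pair_counts().items()
        }
        if config.write_plots:
            from .annotation import plot_pair_heatmap

            plot_pair_heatmap(major, out / "annotate" / "pairs_major.png")
            plot_pair_heatmap(sub, out / "annotate" / "pairs_sub.png")
    stages["annotate"] = ann_summary
    _log("annotate", signatures=len(signature_edges))

    # -- multiview clustering ------------------------------------------------
    (out / "cluster").mkdir(exist_ok=True)
    cl_kwargs = dict(config.clustering)
    cl_kwargs.setdefault("k", 8)
    assign = multiview_cluster(
        stack.matrices,
        seed=stage_seed(config.seed, "cluster"),
        node_ids=stack.node_ids,
        **cl_kwargs,
    )
    assign.write_tsv(out / "cluster" / "assignment.tsv")
    with open(out / "cluster" / "diagnostics.json", "w") as fh:
        json.dump(
            {
                "per_view_agreement": assign.per_view_agreement,
                "n_iterations": assign.n_iterations,
                "eigengap": assign.eigengap,
            },
            fh,
            indent=1,
            sort_keys=True,
        )
    cluster_summary: dict[str, Any] = {"k": assign.k, "n_iterations": assign.n_iterations}
    pair = categorize_signatures_by_cluster(signature_edges, assign)
    pair.write_tsv(out / "cluster" / "signature_cluster_pairs.tsv")
    cluster_summary.update(
        {
            "total_signatures": pair.total,
            "within_total": pair.within_total,
            "between_total": pair.between_total,
            "between_percent": pair.between_percent,
        }
    )
    stages["cluster"] = cluster_summary
    _log("cluster", k=assign.k, iterations=assign.n_iterations)

    # -- report --------------------------------------------------------------
    report = RunReport(
        stages=stages,
        provenance={
            "seed": config.seed,
            "config_sha256": _config_hash(config),
            "stage_seeds": {s: stage_seed(config.seed, s) for s in _STAGES},
            "package_version": __version__,
            "scale": config.scale,
        },
    )
    report.write(out / "report.json")
    report.write_text(out / "report.txt")
    _log("report", path=str(out / "report.json"))
    return report
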