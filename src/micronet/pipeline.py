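"""End-to-end per-group analysis: filter -> correlate -> RMT threshold ->
network -> topology/keystones -> stability, with per-group error isolation
and a fixed-seed reproducibility guarantee.

Each habitat group's samples form their own network (taxa are filtered within
the group by default). All randomness derives from one global seed through
per-stage offsets, so identical config + seed reproduces every artifact
byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .abundance import AbundanceTable, prevalence_filter, read_table, transform_for_correlation
from .rmt import build_network, correlate, rmt_threshold_scan, write_edge_list
from .stability import (cohesion, natural_connectivity, random_removal_curve,
                        targeted_removal, vulnerability)
from .topology import detect_modules, keystone_sets, topology_panel, zi_pi

log = logging.getLogger("micronet")


@dataclass
class RunConfig:
    """All pipeline parameters; round-trips through dict/JSON unchanged."""

    table_path: str = ""
    group_map_path: str = ""
    out_dir: str = ""
    seed: int = 0
    min_prevalence: float = 0.20
    min_count: int = 4
    filter_per_group: bool = True
    transform: str = "log_relative"
    pseudocount: float = 1e-6
    corr_method: str = "pearson"
    t_min: float = 0.30
    t_max: float = 0.95
    t_step: float = 0.01
    alpha: float = 0.05
    min_taxa: int = 20
    top_fraction: float = 0.10
    removal_fractions_max: float = 0.50
    removal_fraction_step: float = 0.05
    n_replicates: int = 100
    n_null: int = 200

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(**d)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class GroupReport:
    group: str
    error: str | None = None
    n_samples: int = 0
    n_taxa_filtered: int = 0
    chosen_threshold: float | None = None
    rmt_fallback: bool | None = None
    topology: dict = field(default_factory=dict)
    role_counts: dict = field(default_factory=dict)
    keystones: dict = field(default_factory=dict)
    stability: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return asdict(self)


def _stage_seed(seed: int, group_index: int, stage: int) -> int:
    # deterministic per-(group, stage) stream, kept below 2**31
    return int((seed * 1_000_003 + group_index * 101 + stage) % (2**31 - 1))


def analyze_group(table: AbundanceTable, config: RunConfig, group: str,
                  group_index: int = 0, apply_filter: bool = True) -> GroupReport:
    """Run every stage on one group's samples, collecting the full report."""
    report = GroupReport(group=group, n_samples=table.n_samples)
    if apply_filter:
        filtered = prevalence_filter(table, config.min_prevalence, config.min_count)
    else:
        filtered = table
    report.n_taxa_filtered = filtered.n_taxa
    mat = transform_for_correlation(filtered, config.transform, config.pseudocount)
    corr = correlate(mat, method=config.corr_method)
    scan = rmt_threshold_scan(corr, config.t_min, config.t_max, config.t_step,
                              config.alpha, config.min_taxa)
    report.chosen_threshold = scan.chosen_threshold
    report.rmt_fallback = scan.used_fallback
    net = build_network(corr, scan.chosen_threshold)
    if net.number_of_nodes() == 0:
        raise ValueError("network empty at the chosen threshold")
    partition = detect_modules(net)
    panel = topology_panel(net, partition)
    report.topology = panel.to_dict()
    report.topology["n_modules"] = partition.n_modules
    report.topology["n_major_modules"] = partition.n_major_modules()
    roles = zi_pi(net, partition)
    report.role_counts = {k: int(v) for k, v in
                          roles["role"].value_counts().sort_index().items()}
    hubs, top_deg = keystone_sets(net, roles, config.top_fraction)
    report.keystones = {"hub_nodes": sorted(hubs), "top_degree_nodes": sorted(top_deg)}

    stab: dict = {"natural_connectivity": natural_connectivity(net)}
    if net.number_of_nodes() >= 3:
        try:
            v, v_node = vulnerability(net)
            stab["vulnerability"] = v
            stab["vulnerability_node"] = v_node
        except ValueError as exc:
            stab["vulnerability_error"] = str(exc)
    try:
        coh = cohesion(filtered, n_null=config.n_null,
                       seed=_stage_seed(config.seed, group_index, 1))
        stab["neg_pos_cohesion"] = coh.neg_pos_ratio
        stab["neg_pos_cohesion_ratio_of_means"] = coh.neg_pos_ratio_of_means
    except ValueError as exc:
        stab["cohesion_error"] = str(exc)
    if net.number_of_nodes() >= 10:
        fr = np.round(np.arange(0.0, config.removal_fractions_max + 1e-9,
                                config.removal_fraction_step), 10)
        curve = random_removal_curve(net, fr, config.n_replicates,
                                     seed=_stage_seed(config.seed, group_index, 2))
        stab["nc_slope_random"] = curve.nc_slope
        stab["avgd_slope_random"] = curve.avgd_slope
        report.stability_curve = curve  # kept in memory for writers
    for label, nodes in (("hub", hubs), ("top10", top_deg)):
        if nodes and net.number_of_nodes() - len(nodes) >= 2:
            try:
                t = targeted_removal(net, nodes, label)
                stab[f"mdp_nc_{label}"] = t.mdp_nc
                stab[f"mdp_avgd_{label}"] = t.mdp_avgd
                stab[f"tdp_nc_{label}"] = t.tdp_nc
                stab[f"tdp_avgd_{label}"] = t.tdp_avgd
            except ValueError as exc:
                stab[f"targeted_{label}_error"] = str(exc)
    report.stability = stab
    report._artifacts = {"network": net, "scan": scan, "roles": roles,
                         "partition": partition}
    return report


def run_pipeline(config: RunConfig, table: AbundanceTable | None = None,
                 ) -> list[GroupReport]:
    """Analyse every sample group; a failing group is reported, not fatal."""
    if table is None:
        table = read_table(config.table_path, config.group_map_path or None)
    out_dir = Path(config.out_dir) if config.out_dir else None
    per_group = config.filter_per_group
    if not per_group:
        table = prevalence_filter(table, config.min_prevalence, config.min_count)
    reports: list[GroupReport] = []
    for gi, group in enumerate(table.group_labels()):
        sub = table.subset_group(group)
        try:
            report = analyze_group(sub, config, group, gi, apply_filter=per_group)
        except Exception as exc:  # error isolation across groups
            log.error("group %s failed at analysis: %s", group, exc)
            report = GroupReport(group=group, error=str(exc),
                                 n_samples=sub.n_samples)
        reports.append(report)
        if out_dir is not None:
            _write_group(out_dir, report)
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
        manifest = {
            "config": config.to_dict(),
            "config_hash": config.config_hash(),
            "seed": config.seed,
            "micronet_version": __version__,
        }
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
        compare_groups(reports).to_csv(out_dir / "comparison.tsv", sep="\t",
                                       index=False)
        (out_dir / "reports.json").write_text(
            json.dumps([r.to_dict() for r in reports], indent=1)
        )
    return reports


def _write_group(out_dir: Path, report: GroupReport) -> None:
    gdir = out_dir / f"group_{report.group}"
    gdir.mkdir(parents=True, exist_ok=True)
    (gdir / "report.json").write_text(json.dumps(report.to_dict(), indent=1))
    art = getattr(report, "_artifacts", None)
    if not art:
        return
    write_edge_list(art["network"], gdir / "edges.tsv")
    import networkx as nx

    nx.write_graphml(art["network"], gdir / "network.graphml")
    art["scan"].to_frame().to_csv(gdir / "rmt_scan.tsv", sep="\t", index=False)
    art["roles"].to_csv(gdir / "node_roles.tsv", sep="\t")
    pd.Series(art["partition"].module_of, name="module").rename_axis("node").to_csv(
        gdir / "modules.tsv", sep="\t"
    )
    curve = getattr(report, "stability_curve", None)
    if curve is not None:
        curve.to_frame().to_csv(gdir / "removal_curve.tsv", sep="\t", index=False)


def compare_groups(reports: list[GroupReport]) -> pd.DataFrame:
    """Long-format metric x group table with stable metric ordering."""
    metric_order: list[str] = []
    values: dict[tuple[str, str], object] = {}
    for rep in reports:
        flat: dict[str, object] = {
            "n_samples": rep.n_samples,
            "n_taxa_filtered": rep.n_taxa_filtered,
            "chosen_threshold": rep.chosen_threshold,
        }
        flat.update(rep.topology)
        flat.update({f"role_{k}": v for k, v in sorted(rep.role_counts.items())})
        flat.update(rep.stability)
        if rep.error:
            flat["error"] = rep.error
        for metric, value in flat.items():
            if metric not in metric_order:
                metric_order.append(metric)
            values[(metric, rep.group)] = value
    rows = []
    for metric in metric_order:
        for rep in reports:
            v = values.get((metric, rep.group), "NA")
            if v is None:
                v = "NA"
            rows.append({"metric": metric, "group": rep.group, "value": v})
    return pd.DataFrame(rows, columns=["metric", "group", "value"])
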