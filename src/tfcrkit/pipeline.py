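"""End-to-end orchestration: per-stage calling, linking, statistics, and
multi-stage dynamics, driven by a single config.

Every step is also callable as a library function; the CLI in
:mod:`tfcrkit.cli` is a thin wrapper around :func:`run_single_stage` and
:func:`run_panel`.  Given the same config and inputs the outputs are
byte-identical: all randomness derives from ``RunConfig.seed`` and every
writer uses fixed float formatting and sorted keys.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import yaml

from . import (
    association_stats,
    gene_linking,
    genome_io,
    spatial_context,
    stage_dynamics,
    tfcr_caller,
)

logger = logging.getLogger(__name__)

REPORT_SCHEMA_VERSION = 1


@dataclass
class StageInputs:
    name: str
    tfbs: str
    atac: str | None = None
    expression: str | None = None
    tads: str | None = None


@dataclass
class RunConfig:
    stages: list[StageInputs]
    genes: str
    family_map: str | None = None
    pstf_list: str | None = None
    gene_format: str = "bed"
    output_dir: str = "tfcrkit_run"
    seed: int = 0
    # caller
    bandwidth_bp: float = tfcr_caller.DEFAULT_BANDWIDTH_BP
    grid_step_bp: int = tfcr_caller.DEFAULT_GRID_STEP_BP
    contribution_threshold: float = tfcr_caller.DEFAULT_CONTRIBUTION_THRESHOLD
    n_tc_bins: int = tfcr_caller.DEFAULT_N_TC_BINS
    # linking
    thresholds: tuple[int, int, int] | None = None  # None -> published defaults
    derive_thresholds: bool = False
    # stats
    fit_offset: float = 0.03
    estimate_offset: bool = False
    # dynamics
    fcm_clusters: int = 6
    fcm_fuzzifier: float = 2.0
    min_overlap_bp: int = 1
    run_spatial: bool = True

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        stages = [StageInputs(**s) for s in raw.pop("stages")]
        if "thresholds" in raw and raw["thresholds"] is not None:
            raw["thresholds"] = tuple(raw["thresholds"])
        return cls(stages=stages, **raw)

    def validate(self) -> None:
        paths = [self.genes, self.family_map, self.pstf_list]
        for s in self.stages:
            paths += [s.tfbs, s.atac, s.expression, s.tads]
        missing = [p for p in paths if p is not None and not os.path.exists(p)]
        if missing:
            raise FileNotFoundError(f"missing input paths: {missing}")


@dataclass
class StageResult:
    name: str
    tfcrs: list
    links_gene_to_tfcr: list
    links_tfcr_to_gene: list
    thresholds: gene_linking.RegionThresholds
    expression: genome_io.ExpressionTable | None
    stats: dict
    counts: dict = field(default_factory=dict)


def _resolve_thresholds(config: RunConfig, links) -> gene_linking.RegionThresholds:
    if config.thresholds is not None:
        return gene_linking.RegionThresholds(*config.thresholds, provenance="default")
    if config.derive_thresholds:
        return gene_linking.derive_thresholds(links)
    return gene_linking.RegionThresholds(
        *gene_linking.DEFAULT_THRESHOLDS, provenance="default"
    )


def _stage_statistics(
    tfcrs, links, expr: genome_io.ExpressionTable | None
) -> dict:
    """Per-region Spearman of TC / TW / CAS against log-expression, plus the
    saturating log fit of expression on complexity."""
    if expr is None:
        return {}
    by_id = {t.tfcr_id: t for t in tfcrs}
    rows = []
    for l in links:
        if l.is_no_tfcr or l.region is None:
            continue
        t = by_id.get(l.tfcr_id)
        e = expr.log_expr(l.gene_id)
        if t is None or e is None:
            continue
        rows.append((l.region, t.tc, t.tw, t.cas, e))
    out: dict = {"per_region": {}, "n_links_used": len(rows)}
    for region in gene_linking.REGIONS:
        sub = [r for r in rows if r[0] == region]
        entry: dict = {"n": len(sub)}
        if len(sub) >= 3:
            for key, idx in (("tc", 1), ("tw", 2), ("cas", 3)):
                pairs = [(r[idx], r[4]) for r in sub if r[idx] is not None]
                if len(pairs) >= 3:
                    res = association_stats.spearman(
                        [p[0] for p in pairs], [p[1] for p in pairs]
                    )
                    entry[f"rho_{key}_expr"] = None if res.undefined else round(res.rho, 6)
                    entry[f"stars_{key}_expr"] = res.stars
        out["per_region"][region] = entry
    if len(rows) >= 3:
        fit = association_stats.fit_log_model(
            [r[1] for r in rows], [r[4] for r in rows]
        )
        out["log_fit"] = {
            "a": round(fit.a, 6),
            "b": round(fit.b, 6),
            "c": fit.c,
            "r_squared": round(fit.r_squared, 6),
        }
    return out


def run_single_stage(
    config: RunConfig,
    stage_name: str,
    genes: list | None = None,
    family_map: dict | None = None,
    write_outputs: bool = True,
) -> StageResult:
    """Call, score, link and characterise one stage."""
    stage = next((s for s in config.stages if s.name == stage_name), None)
    if stage is None:
        raise ValueError(f"stage {stage_name!r} not in manifest")
    if family_map is None:
        family_map = (
            genome_io.read_family_map(config.family_map) if config.family_map else {}
        )
    if genes is None:
        genes = genome_io.read_gene_tss(config.genes, format=config.gene_format)
    tfbs = genome_io.read_fimo_tfbs(stage.tfbs, family_map)
    tracks = tfcr_caller.kde_density(
        tfbs, bandwidth_bp=config.bandwidth_bp, grid_step_bp=config.grid_step_bp
    )
    tfcrs = tfcr_caller.call_tfcrs(
        tracks, tfbs, contribution_threshold=config.contribution_threshold, stage=stage_name
    )
    if len(tfcrs) >= config.n_tc_bins:
        tfcr_caller.assign_tc_bins(tfcrs, n_bins=config.n_tc_bins)
    if stage.atac:
        atac = genome_io.read_bed(stage.atac, scored=True)
        tfcr_caller.annotate_cas(tfcrs, atac)
    links_g2t = gene_linking.link_nearest(tfcrs, genes, direction="gene_to_tfcr")
    links_t2g = gene_linking.link_nearest(tfcrs, genes, direction="tfcr_to_gene")
    thresholds = _resolve_thresholds(config, links_t2g)
    links_g2t = gene_linking.classify_regions(links_g2t, thresholds)
    links_t2g = gene_linking.classify_regions(links_t2g, thresholds)
    expr = (
        genome_io.read_expression_table(stage.expression) if stage.expression else None
    )
    stats = _stage_statistics(tfcrs, links_g2t, expr)
    stats["region_proportions_tfcr_to_gene"] = {
        k: round(v, 6) for k, v in gene_linking.region_proportions(links_t2g).items()
    }
    counts = {
        "n_tfbs": len(tfbs),
        "n_tfcrs": len(tfcrs),
        "n_links_gene_to_tfcr": len(links_g2t),
        "n_links_tfcr_to_gene": len(links_t2g),
        "n_no_tfcr_genes": sum(1 for l in links_g2t if l.is_no_tfcr),
    }
    logger.info("stage %s: %s", stage_name, counts)
    result = StageResult(
        name=stage_name,
        tfcrs=tfcrs,
        links_gene_to_tfcr=links_g2t,
        links_tfcr_to_gene=links_t2g,
        thresholds=thresholds,
        expression=expr,
        stats=stats,
        counts=counts,
    )
    if write_outputs:
        _write_stage_outputs(config, result)
    return result


def _write_stage_outputs(config: RunConfig, result: StageResult) -> None:
    stage_dir = os.path.join(config.output_dir, result.name)
    os.makedirs(stage_dir, exist_ok=True)
    genome_io.write_tfcr_table(result.tfcrs, os.path.join(stage_dir, "tfcrs.bed"))
    header = "tfcr_id\tgene_id\tchrom\tpeak_pos\ttss\tdistance\tregion\tdirection"
    lines = [header]
    for l in result.links_gene_to_tfcr + result.links_tfcr_to_gene:
        lines.append(
            "\t".join(
                [
                    l.tfcr_id if l.tfcr_id is not None else "no_TFCR",
                    l.gene_id,
                    l.chrom,
                    str(l.peak_pos) if l.peak_pos is not None else "NA",
                    str(l.tss),
                    str(l.distance) if l.distance is not None else "NA",
                    l.region if l.region is not None else "NA",
                    l.direction,
                ]
            )
        )
    with open(os.path.join(stage_dir, "links.tsv"), "w") as fh:
        fh.write("\n".join(lines) + "\n")
    with open(os.path.join(stage_dir, "stats.json"), "w") as fh:
        json.dump(result.stats, fh, indent=1, sort_keys=True)
        fh.write("\n")


def run_panel(config: RunConfig) -> dict:
    """Run every stage plus the cross-stage and spatial analyses.

    Returns (and writes) a single JSON-serialisable report aggregating the
    per-stage counts and statistics, gained/lost/stable dynamics,
    long-range distance bins, fuzzy trajectory clustering, and TAD / PSTF
    comparisons where the inputs are configured.
    """
    if len(config.stages) < 2:
        raise ValueError("run_panel needs >= 2 stages")
    config.validate()
    os.makedirs(config.output_dir, exist_ok=True)
    genes = genome_io.read_gene_tss(config.genes, format=config.gene_format)
    family_map = (
        genome_io.read_family_map(config.family_map) if config.family_map else {}
    )
    results = [
        run_single_stage(config, s.name, genes=genes, family_map=family_map)
        for s in config.stages
    ]
    collection = stage_dynamics.StageCollection(
        [
            stage_dynamics.StageData(
                name=r.name,
                tfcrs=r.tfcrs,
                links=r.links_gene_to_tfcr + r.links_tfcr_to_gene,
                expression=r.expression,
            )
            for r in results
        ]
    )
    report: dict = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "seed": config.seed,
        "stages": {
            r.name: {
                "counts": r.counts,
                "thresholds": {
                    "t1": r.thresholds.t1,
                    "t2": r.thresholds.t2,
                    "t3": r.thresholds.t3,
                    "provenance": r.thresholds.provenance,
                },
                "stats": r.stats,
            }
            for r in results
        },
    }

    gl_all = stage_dynamics.gained_lost(collection, scope="all", min_overlap_bp=config.min_overlap_bp)
    gl_lr = stage_dynamics.gained_lost(collection, scope="LR_only", min_overlap_bp=config.min_overlap_bp)
    report["dynamics"] = {
        "gained_lost_all": {
            s: {k: sorted(v) for k, v in d.items()} for s, d in gl_all.items()
        },
        "gained_lost_lr": {
            s: {k: sorted(v) for k, v in d.items()} for s, d in gl_lr.items()
        },
    }
    stable_all = stage_dynamics.stable_regions(collection, scope="all")
    stable_lr = stage_dynamics.stable_regions(collection, scope="LR_only")
    report["dynamics"]["n_stable_regions_all"] = len(stable_all)
    report["dynamics"]["n_stable_regions_lr"] = len(stable_lr)
    report["dynamics"]["lr_distance_bins"] = {
        r.name: stage_dynamics.lr_distance_bins(
            [l for l in r.links_tfcr_to_gene if l.region == "R4"]
        )
        for r in results
    }

    ids, matrix = stage_dynamics.tc_trajectories(collection)
    if len(ids) >= config.fcm_clusters:
        clustering = stage_dynamics.fuzzy_cmeans(
            matrix,
            entity_ids=ids,
            c=config.fcm_clusters,
            m=config.fcm_fuzzifier,
            seed=config.seed,
        )
        labels = clustering.hard_labels
        report["trajectories"] = {
            "n_genes": len(ids),
            "cluster_sizes": {
                f"Cluster{k + 1}": int(np.sum(labels == k))
                for k in range(config.fcm_clusters)
            },
            "center_peak_stage": {
                f"Cluster{k + 1}": collection.names[int(np.argmax(clustering.centers[k]))]
                for k in range(config.fcm_clusters)
            },
            "n_iterations": clustering.n_iter,
        }
        _write_memberships(config, clustering, collection.names)

    if config.run_spatial:
        report["spatial"] = _spatial_section(config, results)

    with open(os.path.join(config.output_dir, "report.json"), "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
        fh.write("\n")
    with open(os.path.join(config.output_dir, "config_echo.json"), "w") as fh:
        json.dump(_config_echo(config), fh, indent=1, sort_keys=True)
        fh.write("\n")
    return report


def _write_memberships(config, clustering, stage_names) -> None:
    path = os.path.join(config.output_dir, "trajectory_memberships.tsv")
    c = clustering.memberships.shape[1]
    header = "gene_id\thard_cluster\t" + "\t".join(f"u{k + 1}" for k in range(c))
    lines = [header]
    for gid, row, hard in zip(
        clustering.entity_ids, clustering.memberships, clustering.hard_labels
    ):
        lines.append(
            f"{gid}\tCluster{hard + 1}\t" + "\t".join(f"{u:.6f}" for u in row)
        )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def _spatial_section(config: RunConfig, results) -> dict:
    pstf_list = (
        genome_io.read_name_list(config.pstf_list) if config.pstf_list else None
    )
    section: dict = {}
    for stage_cfg, result in zip(config.stages, results):
        entry: dict = {}
        lr_links = [l for l in result.links_tfcr_to_gene if l.region == "R4"]
        if stage_cfg.tads:
            tads = genome_io.read_bed(stage_cfg.tads)
            assignments = spatial_context.assign_tads(lr_links, tads)
            entry["same_tad"] = sum(1 for a in assignments if a.status == "same_TAD")
            entry["not_same_tad"] = sum(
                1 for a in assignments if a.status == "not_same_TAD"
            )
        if pstf_list:
            annotations = spatial_context.annotate_pstf(result.tfcrs, pstf_list)
            by_group: dict[str, list[float]] = {"PSTF": [], "not_PSTF": []}
            tc_by_id = {t.tfcr_id: t.tc for t in result.tfcrs}
            for a in annotations:
                by_group[a.group].append(tc_by_id[a.tfcr_id])
            entry["n_pstf_tfcrs"] = len(by_group["PSTF"])
            entry["n_not_pstf_tfcrs"] = len(by_group["not_PSTF"])
            if all(len(v) >= 2 for v in by_group.values()):
                cmp = spatial_context.group_compare(by_group)
                entry["tc_pstf_vs_not"] = cmp["comparisons"][0]
                entry["tc_medians"] = {
                    g: cmp["groups"][g]["median"] for g in cmp["groups"]
                }
        section[result.name] = entry
    return section


def _config_echo(config: RunConfig) -> dict:
    echo = {
        k: v
        for k, v in vars(config).items()
        if not k.startswith("_") and k != "stages"
    }
    echo["stages"] = [vars(s) for s in config.stages]
    if echo.get("thresholds") is not None:
        echo["thresholds"] = list(echo["thresholds"])
    return echo
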