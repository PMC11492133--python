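"""Synthetic input bundles with known ground truth.

The generator emulates the statistical structure of motif hits in
accessible chromatin around early-embryo genes, without any sequence:

* every gene gets one planted TFBS cluster whose distance to the TSS is
  drawn from a bimodal-plus-tail mixture — a promoter mode (|N(500, 300)|
  bp), a mid-range mode (N(27 kb, 8 kb), truncated above 2 kb) and a
  long-range tail (uniform on 50 001..300 000 bp) — mirroring the distance
  landmarks the distance-threshold derivation is meant to recover;
* cluster complexity is planted as a number of distinct TF families, each
  contributing one site scattered N(center, sigma_site); some families add
  a second overlapping site to exercise family deduplication;
* a subset of TF families is labelled phase-separation-associated (PSTF);
  PSTF-flagged clusters receive extra families, planting a complexity and
  expression shift between PSTF and not_PSTF groups;
* expression follows a saturating log law of planted complexity,
  log10(FPKM + 1) = a log10(TC_true + c) + b + noise;
* ATAC peaks span each cluster with score proportional to site count;
  TADs tile each chromosome.

All outputs are written in the standard formats the readers consume
(FIMO-dialect TSV, BED, TSV, plain-text lists) plus a truth JSON; the same
seed regenerates a byte-identical bundle.
"""

from __future__ import annotations

import json
import os
from dataclasses import asdict, dataclass, field

import numpy as np

DEFAULT_STAGE_NAMES = ("2Cell", "4Cell", "8Cell", "ICM", "primed_hESC")


@dataclass
class SyntheticConfig:
    """Study conditions for the generator."""

    seed: int = 0
    n_chroms: int = 4
    n_genes: int = 500
    gene_spacing_bp: int = 750_000
    gene_jitter_bp: int = 50_000
    # TSS-distance mixture: promoter / mid-range / long-range
    mixture_weights: tuple[float, float, float] = (0.45, 0.35, 0.20)
    promoter_mean_bp: float = 500.0
    promoter_sd_bp: float = 300.0
    mid_mean_bp: float = 27_000.0
    mid_sd_bp: float = 8_000.0
    mid_truncate_bp: float = 2_000.0
    far_min_bp: int = 50_001
    far_max_bp: int = 300_000
    # cluster structure
    base_families: int = 3
    family_lambda: float = 3.0
    pstf_fraction: float = 0.35  # fraction of clusters flagged PSTF
    pstf_extra_families: int = 2
    sigma_site_bp: float = 150.0
    duplicate_site_prob: float = 0.25
    n_families_pool: int = 20
    n_pstf_families: int = 6
    tfs_per_family: int = 4
    # expression law: log10(FPKM+1) = a*log10(TC_true + c) + b + N(0, sigma)
    expr_a: float = 1.5
    expr_b: float = 0.2
    expr_c: float = 0.03
    expr_sigma: float = 0.15
    # ATAC peaks and TADs
    atac_halfwidth_bp: int = 400
    atac_score_per_site: float = 2.0
    atac_score_sigma: float = 1.0
    tad_width_bp: int = 800_000
    essential_fraction_promoter: float = 0.7
    essential_fraction_other: float = 0.2

    def __post_init__(self) -> None:
        if abs(sum(self.mixture_weights) - 1.0) > 1e-9:
            raise ValueError("mixture weights must sum to 1")
        for name in ("promoter_sd_bp", "mid_sd_bp", "sigma_site_bp", "expr_sigma"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


@dataclass
class ClusterTruth:
    cluster_id: str
    gene_id: str | None  # None for stage-transient clusters
    chrom: str
    center: int
    tss_distance: int | None
    category: str | None  # R1..R4 from the realised distance
    n_families: int
    pstf: bool


@dataclass
class BundleTruth:
    seed: int
    clusters: list[ClusterTruth]
    expr_params: dict
    zga_genes: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(
            {
                "seed": self.seed,
                "expr_params": self.expr_params,
                "zga_genes": self.zga_genes,
                "clusters": [asdict(c) for c in self.clusters],
            },
            indent=1,
            sort_keys=True,
        )


@dataclass
class BundlePaths:
    directory: str
    tfbs: str
    atac: str
    genes: str
    expression: str
    tads: str
    family_map: str
    pstf_list: str
    zga_genes: str
    essential_genes: str
    truth: str


# ---------------------------------------------------------------------------
# Internals
# ---------------------------------------------------------------------------


def _tf_pool(config: SyntheticConfig):
    """Family and TF names; the first n_pstf_families are PSTF families."""
    families = [f"FAM{j:02d}" for j in range(config.n_families_pool)]
    tf_names = {
        fam: [f"TF_{fam}_{i}" for i in range(config.tfs_per_family)] for fam in families
    }
    pstf_families = families[: config.n_pstf_families]
    regular_families = families[config.n_pstf_families :]
    pstf_tfs = [tf for fam in pstf_families for tf in tf_names[fam]]
    return families, tf_names, pstf_families, regular_families, pstf_tfs


def _gene_layout(config: SyntheticConfig, rng: np.random.Generator):
    """TSS positions on a jittered lattice; spacing keeps planted clusters
    closer to their own gene than to any neighbour."""
    per_chrom = int(np.ceil(config.n_genes / config.n_chroms))
    genes = []
    count = 0
    for ci in range(config.n_chroms):
        chrom = f"chr{ci + 1}"
        for gi in range(per_chrom):
            if count >= config.n_genes:
                break
            tss = (gi + 1) * config.gene_spacing_bp + int(
                rng.integers(-config.gene_jitter_bp, config.gene_jitter_bp + 1)
            )
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append((f"G{count:04d}", chrom, tss, strand))
            count += 1
    chrom_length = (per_chrom + 1) * config.gene_spacing_bp + config.gene_jitter_bp
    return genes, chrom_length


def _sample_distance(config: SyntheticConfig, rng: np.random.Generator) -> int:
    u = rng.random()
    w1, w2, _ = config.mixture_weights
    if u < w1:
        return int(round(abs(rng.normal(config.promoter_mean_bp, config.promoter_sd_bp))))
    if u < w1 + w2:
        while True:
            d = rng.normal(config.mid_mean_bp, config.mid_sd_bp)
            if d > config.mid_truncate_bp:
                return int(round(d))
    return int(rng.integers(config.far_min_bp, config.far_max_bp + 1))


def _category(distance: int) -> str:
    if distance <= 2_000:
        return "R1"
    if distance <= 27_000:
        return "R2"
    if distance <= 50_000:
        return "R3"
    return "R4"


def _place_cluster_sites(
    center: int,
    families: list[str],
    tf_names: dict[str, list[str]],
    config: SyntheticConfig,
    rng: np.random.Generator,
):
    """One site per family around the center, plus occasional overlapping
    same-family duplicates (family-dedup fodder)."""
    rows = []
    for fam in families:
        mid = int(round(rng.normal(center, config.sigma_site_bp)))
        width = int(rng.integers(8, 21))
        start = mid - width // 2
        tf = tf_names[fam][int(rng.integers(len(tf_names[fam])))]
        rows.append((start, start + width, tf, fam))
        if rng.random() < config.duplicate_site_prob and len(tf_names[fam]) > 1:
            # second TF of the same family at an overlapping locus
            shift = int(rng.integers(-4, 5))
            tf2 = tf_names[fam][int(rng.integers(len(tf_names[fam])))]
            rows.append((start + shift, start + shift + width, tf2, fam))
    return rows


def _expression_value(
    tc_true: float, config: SyntheticConfig, rng: np.random.Generator
) -> float:
    y = (
        config.expr_a * np.log10(tc_true + config.expr_c)
        + config.expr_b
        + rng.normal(0.0, config.expr_sigma)
    )
    return float(max(0.0, 10.0 ** max(0.0, y) - 1.0))


def _maternal_expression(rng: np.random.Generator) -> float:
    """Stage-independent noise standing in for maternal transcripts."""
    y = abs(rng.normal(0.6, 0.3))
    return float(max(0.0, 10.0**y - 1.0))


# ---------------------------------------------------------------------------
# Writers (all deterministic given their inputs)
# ---------------------------------------------------------------------------


def _write_fimo(path: str, rows, rng: np.random.Generator) -> None:
    header = (
        "motif_id\tmotif_alt_id\tsequence_name\tstart\tstop\tstrand\t"
        "score\tp-value\tq-value\tmatched_sequence"
    )
    lines = [header]
    for chrom, start, end, tf in rows:
        strand = "+" if rng.random() < 0.5 else "-"
        score = rng.normal(12.0, 3.0)
        lines.append(
            f"M_{tf}\t{tf}\t{chrom}\t{start + 1}\t{end}\t{strand}\t"
            f"{score:.4f}\t1.0e-05\t1.0e-02\t{'N' * (end - start)}"
        )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def _write_lines(path: str, lines) -> None:
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + ("\n" if lines else ""))


def _write_bundle_files(
    out_dir: str,
    config: SyntheticConfig,
    genes,
    site_rows,
    atac_rows,
    expr,
    chrom_length: int,
    family_map: dict[str, str],
    pstf_tfs: list[str],
    zga: list[str],
    essential: list[str],
    truth: BundleTruth,
    rng: np.random.Generator,
) -> BundlePaths:
    os.makedirs(out_dir, exist_ok=True)
    paths = BundlePaths(
        directory=out_dir,
        tfbs=os.path.join(out_dir, "tfbs.fimo.tsv"),
        atac=os.path.join(out_dir, "atac_peaks.bed"),
        genes=os.path.join(out_dir, "genes.bed"),
        expression=os.path.join(out_dir, "expression.tsv"),
        tads=os.path.join(out_dir, "tads.bed"),
        family_map=os.path.join(out_dir, "family_map.tsv"),
        pstf_list=os.path.join(out_dir, "pstf_tfs.txt"),
        zga_genes=os.path.join(out_dir, "zga_genes.txt"),
        essential_genes=os.path.join(out_dir, "essential_genes.txt"),
        truth=os.path.join(out_dir, "truth.json"),
    )
    site_rows = sorted(site_rows)
    _write_fimo(paths.tfbs, site_rows, rng)
    _write_lines(
        paths.atac,
        [
            f"{chrom}\t{start}\t{end}\tpeak{i}\t{score:.4f}\t."
            for i, (chrom, start, end, score) in enumerate(sorted(atac_rows))
        ],
    )
    gene_lines = []
    for gene_id, chrom, tss, strand in genes:
        if strand == "+":
            start, end = tss, tss + 1_000
        else:
            start, end = tss - 999, tss + 1
        gene_lines.append(f"{chrom}\t{start}\t{end}\t{gene_id}\t0\t{strand}")
    _write_lines(paths.genes, gene_lines)
    _write_lines(
        paths.expression,
        ["gene_id\tFPKM"] + [f"{g}\t{expr[g]:.6f}" for g in sorted(expr)],
    )
    tad_lines = []
    for ci in range(config.n_chroms):
        chrom = f"chr{ci + 1}"
        for start in range(0, chrom_length, config.tad_width_bp):
            tad_lines.append(f"{chrom}\t{start}\t{min(start + config.tad_width_bp, chrom_length)}")
    _write_lines(paths.tads, tad_lines)
    _write_lines(paths.family_map, [f"{tf}\t{fam}" for tf, fam in sorted(family_map.items())])
    _write_lines(paths.pstf_list, sorted(pstf_tfs))
    _write_lines(paths.zga_genes, sorted(zga))
    _write_lines(paths.essential_genes, sorted(essential))
    with open(paths.truth, "w") as fh:
        fh.write(truth.to_json() + "\n")
    return paths


# ---------------------------------------------------------------------------
# Public API
# ---------------------------------------------------------------------------


def generate_bundle(
    config: SyntheticConfig, out_dir: str
) -> tuple[BundlePaths, BundleTruth]:
    """Write a complete single-stage input bundle and its ground truth."""
    rng = np.random.default_rng(config.seed)
    families, tf_names, pstf_families, regular_families, pstf_tfs = _tf_pool(config)
    family_map = {tf: fam for fam in families for tf in tf_names[fam]}
    genes, chrom_length = _gene_layout(config, rng)

    clusters: list[ClusterTruth] = []
    site_rows = []
    atac_rows = []
    expr: dict[str, float] = {}
    for gene_id, chrom, tss, _strand in genes:
        distance = _sample_distance(config, rng)
        sign = 1 if rng.random() < 0.5 else -1
        center = tss + sign * distance
        for _ in range(100):
            if 10_000 <= center <= chrom_length - 10_000:
                break
            sign = -sign
            center = tss + sign * distance
        else:
            raise RuntimeError(f"could not place cluster for {gene_id} on {chrom}")
        pstf = rng.random() < config.pstf_fraction
        n_fam = config.base_families + int(rng.poisson(config.family_lambda))
        fam_pool = list(regular_families)
        chosen = [
            fam_pool[i]
            for i in rng.choice(len(fam_pool), size=min(n_fam, len(fam_pool)), replace=False)
        ]
        if pstf:
            extra = config.pstf_extra_families
            pstf_chosen = [
                pstf_families[i]
                for i in rng.choice(len(pstf_families), size=min(extra, len(pstf_families)), replace=False)
            ]
            chosen = chosen + pstf_chosen
        n_fam_total = len(chosen)
        cluster_id = f"{gene_id}_cl"
        for start, end, tf, _fam in _place_cluster_sites(center, chosen, tf_names, config, rng):
            site_rows.append((chrom, start, end, tf))
        n_sites = n_fam_total  # ATAC score tracks planted family count
        atac_rows.append(
            (
                chrom,
                center - config.atac_halfwidth_bp,
                center + config.atac_halfwidth_bp,
                max(0.1, config.atac_score_per_site * n_sites + rng.normal(0, config.atac_score_sigma)),
            )
        )
        expr[gene_id] = _expression_value(n_fam_total, config, rng)
        clusters.append(
            ClusterTruth(
                cluster_id=cluster_id,
                gene_id=gene_id,
                chrom=chrom,
                center=center,
                tss_distance=distance,
                category=_category(distance),
                n_families=n_fam_total,
                pstf=pstf,
            )
        )

    essential = [
        gene_id
        for (gene_id, _, _, _), c in zip(genes, clusters)
        if rng.random()
        < (
            config.essential_fraction_promoter
            if c.category == "R1"
            else config.essential_fraction_other
        )
    ]
    truth = BundleTruth(
        seed=config.seed,
        clusters=clusters,
        expr_params={
            "a": config.expr_a,
            "b": config.expr_b,
            "c": config.expr_c,
            "sigma": config.expr_sigma,
        },
    )
    paths = _write_bundle_files(
        out_dir,
        config,
        genes,
        site_rows,
        atac_rows,
        expr,
        chrom_length,
        family_map,
        pstf_tfs,
        [],
        essential,
        truth,
        rng,
    )
    return paths, truth


@dataclass
class PanelTruth:
    seed: int
    stage_names: list[str]
    zga_genes: list[str]
    zga_stage_index: int
    stage_truths: dict[str, BundleTruth]
    expr_params: dict


def generate_stage_panel(
    config: SyntheticConfig,
    out_dir: str,
    n_stages: int = 5,
    zga_stage_index: int = 2,
    zga_gene_fraction: float = 0.3,
    stage_names: tuple[str, ...] | None = None,
    transient_fraction: float = 0.08,
) -> tuple[dict[str, BundlePaths], PanelTruth]:
    """Write one bundle per developmental stage with a shared gene set.

    ZGA-flagged genes have a single-family (near-zero-complexity) cluster
    before ``zga_stage_index``, a complexity burst at that stage and a mild
    decay afterwards.  Expression is independent noise (maternal
    transcripts) at every stage before the index, for all genes, and
    follows the complexity law from the index onward.  A small fraction of
    stage-specific "transient" clusters in intergenic deadzones provides
    gained/lost turnover.
    """
    if not (0 <= zga_stage_index < n_stages):
        raise ValueError("zga_stage_index out of range")
    if not (0.0 <= zga_gene_fraction <= 1.0):
        raise ValueError("zga_gene_fraction must be in [0, 1]")
    if stage_names is None:
        stage_names = tuple(DEFAULT_STAGE_NAMES[:n_stages]) if n_stages <= len(
            DEFAULT_STAGE_NAMES
        ) else tuple(f"stage{i}" for i in range(n_stages))
    if len(stage_names) != n_stages:
        raise ValueError("stage_names length must equal n_stages")

    rng = np.random.default_rng(config.seed)
    families, tf_names, pstf_families, regular_families, pstf_tfs = _tf_pool(config)
    family_map = {tf: fam for fam in families for tf in tf_names[fam]}
    genes, chrom_length = _gene_layout(config, rng)

    n_zga = int(round(zga_gene_fraction * len(genes)))
    zga_idx = set(rng.choice(len(genes), size=n_zga, replace=False).tolist())
    zga_genes = sorted(genes[i][0] for i in zga_idx)

    # shared, stage-invariant cluster skeleton
    skeleton = []
    for gi, (gene_id, chrom, tss, _strand) in enumerate(genes):
        distance = _sample_distance(config, rng)
        sign = 1 if rng.random() < 0.5 else -1
        center = tss + sign * distance
        for _ in range(100):
            if 10_000 <= center <= chrom_length - 10_000:
                break
            sign = -sign
            center = tss + sign * distance
        else:
            raise RuntimeError(f"could not place cluster for {gene_id}")
        pstf = rng.random() < config.pstf_fraction
        base = config.base_families + int(rng.poisson(config.family_lambda))
        skeleton.append((gene_id, chrom, tss, center, distance, pstf, base, gi in zga_idx))

    # ZGA complexity trajectory: quiescent, burst at activation, mild decay
    def _zga_families(stage_i: int) -> int:
        if stage_i < zga_stage_index:
            return 1
        return max(5, 9 - 2 * (stage_i - zga_stage_index))

    per_chrom = int(np.ceil(config.n_genes / config.n_chroms))
    essential = None
    stage_paths: dict[str, BundlePaths] = {}
    stage_truths: dict[str, BundleTruth] = {}
    for si, stage in enumerate(stage_names):
        clusters: list[ClusterTruth] = []
        site_rows = []
        atac_rows = []
        expr: dict[str, float] = {}
        for gene_id, chrom, tss, center, distance, pstf, base, is_zga in skeleton:
            n_fam = _zga_families(si) if is_zga else base
            fam_pool = list(regular_families)
            chosen = [
                fam_pool[i]
                for i in rng.choice(len(fam_pool), size=min(n_fam, len(fam_pool)), replace=False)
            ]
            if pstf:
                pstf_chosen = [
                    pstf_families[i]
                    for i in rng.choice(
                        len(pstf_families),
                        size=min(config.pstf_extra_families, len(pstf_families)),
                        replace=False,
                    )
                ]
                chosen = chosen + pstf_chosen
            n_total = len(chosen)
            for start, end, tf, _fam in _place_cluster_sites(center, chosen, tf_names, config, rng):
                site_rows.append((chrom, start, end, tf))
            atac_rows.append(
                (
                    chrom,
                    center - config.atac_halfwidth_bp,
                    center + config.atac_halfwidth_bp,
                    max(
                        0.1,
                        config.atac_score_per_site * n_total
                        + rng.normal(0, config.atac_score_sigma),
                    ),
                )
            )
            if si < zga_stage_index:
                expr[gene_id] = _maternal_expression(rng)
            else:
                expr[gene_id] = _expression_value(n_total, config, rng)
            clusters.append(
                ClusterTruth(
                    cluster_id=f"{gene_id}_cl",
                    gene_id=gene_id,
                    chrom=chrom,
                    center=center,
                    tss_distance=distance,
                    category=_category(distance),
                    n_families=n_total,
                    pstf=pstf,
                )
            )
        # stage-specific transient clusters in intergenic deadzones
        n_transient = int(round(transient_fraction * len(skeleton)))
        for ti in range(n_transient):
            gi = int(rng.integers(len(genes)))
            gene_id, chrom, tss, _strand = genes[gi]
            center = tss + config.gene_spacing_bp // 2 + int(rng.integers(-30_000, 30_001))
            center = min(max(center, 10_000), chrom_length - 10_000)
            n_fam = 2 + int(rng.poisson(1.0))
            chosen = [
                regular_families[i]
                for i in rng.choice(len(regular_families), size=n_fam, replace=False)
            ]
            for start, end, tf, _fam in _place_cluster_sites(center, chosen, tf_names, config, rng):
                site_rows.append((chrom, start, end, tf))
            clusters.append(
                ClusterTruth(
                    cluster_id=f"{stage}_transient{ti}",
                    gene_id=None,
                    chrom=chrom,
                    center=center,
                    tss_distance=None,
                    category=None,
                    n_families=n_fam,
                    pstf=False,
                )
            )
        if essential is None:
            essential = [
                c.gene_id
                for c in clusters
                if c.gene_id is not None
                and rng.random()
                < (
                    config.essential_fraction_promoter
                    if c.category == "R1"
                    else config.essential_fraction_other
                )
            ]
        truth = BundleTruth(
            seed=config.seed,
            clusters=clusters,
            expr_params={
                "a": config.expr_a,
                "b": config.expr_b,
                "c": config.expr_c,
                "sigma": config.expr_sigma,
            },
            zga_genes=zga_genes,
        )
        stage_paths[stage] = _write_bundle_files(
            os.path.join(out_dir, stage),
            config,
            genes,
            site_rows,
            atac_rows,
            expr,
            chrom_length,
            family_map,
            pstf_tfs,
            zga_genes,
            essential,
            truth,
            rng,
        )
        stage_truths[stage] = truth
    panel_truth = PanelTruth(
        seed=config.seed,
        stage_names=list(stage_names),
        zga_genes=zga_genes,
        zga_stage_index=zga_stage_index,
        stage_truths=stage_truths,
        expr_params=stage_truths[stage_names[0]].expr_params,
    )
    with open(os.path.join(out_dir, "panel_truth.json"), "w") as fh:
        json.dump(
            {
                "seed": config.seed,
                "stage_names": list(stage_names),
                "zga_genes": zga_genes,
                "zga_stage_index": zga_stage_index,
            },
            fh,
            indent=1,
            sort_keys=True,
        )
        fh.write("\n")
    return stage_paths, panel_truth
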