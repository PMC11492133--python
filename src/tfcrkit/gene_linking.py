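"""Pair TFCRs with genes by nearest TSS and classify links by distance.

Distance is the absolute bp separation between the gene TSS and the TFCR
peak position, clamped to 0 when the TSS falls inside the TFCR interval.
Links are classified into four regions by distance d:

* R1 (proximal, promoter-like):        0 <= d <= t1
* R2:                                  t1 < d <= t2
* R3:                                  t2 < d <= t3
* R4 (long-range, LR-TFCR):            d > t3

The published cuts t1/t2/t3 = 2 kb / 27 kb / 50 kb are the authoritative
defaults; :func:`derive_thresholds` re-derives data-driven candidates from
the distance density as a reproducibility diagnostic.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import gaussian_kde, rankdata

from .genome_io import TFCR, ExpressionTable, GeneRecord

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLDS = (2_000, 27_000, 50_000)

REGIONS = ("R1", "R2", "R3", "R4")


@dataclass(frozen=True)
class TFCRGeneLink:
    """A TFCR paired with a gene (or a ``no_TFCR`` placeholder)."""

    tfcr_id: str | None
    gene_id: str
    chrom: str
    peak_pos: int | None
    tss: int
    distance: int | None  # None only for no_TFCR links
    direction: str  # "tfcr_to_gene" | "gene_to_tfcr"
    region: str | None = None

    @property
    def is_no_tfcr(self) -> bool:
        return self.tfcr_id is None


@dataclass
class RegionThresholds:
    """Distance cuts t1 < t2 < t3 separating R1..R4."""

    t1: int
    t2: int
    t3: int
    provenance: str = "default"  # "default" | "derived"
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0 < self.t1 < self.t2 < self.t3):
            raise ValueError(f"need 0 < t1 < t2 < t3, got {(self.t1, self.t2, self.t3)}")


def _link_distance(tfcr: TFCR, gene: GeneRecord) -> int:
    if tfcr.interval.contains(gene.chrom, gene.tss):
        return 0
    return abs(gene.tss - tfcr.peak_pos)


def link_nearest(
    tfcrs: list[TFCR],
    genes: list[GeneRecord],
    direction: str = "gene_to_tfcr",
) -> list[TFCRGeneLink]:
    """Minimum-distance pairing in the requested direction.

    ``tfcr_to_gene``: each TFCR is paired with its nearest gene(s);
    ``gene_to_tfcr``: each gene with its nearest TFCR(s).  Exact distance
    ties are all retained.  In gene_to_tfcr mode a gene on a chromosome
    with no TFCR yields a placeholder link with ``tfcr_id=None``.
    """
    if not genes:
        raise ValueError("empty gene list: nearest gene is undefined")
    if direction not in ("tfcr_to_gene", "gene_to_tfcr"):
        raise ValueError(f"unknown direction {direction!r}")

    genes_by_chrom: dict[str, list[GeneRecord]] = {}
    for g in genes:
        genes_by_chrom.setdefault(g.chrom, []).append(g)
    for chrom in genes_by_chrom:
        genes_by_chrom[chrom].sort(key=lambda g: g.tss)
    tfcrs_by_chrom: dict[str, list[TFCR]] = {}
    for t in tfcrs:
        tfcrs_by_chrom.setdefault(t.chrom, []).append(t)
    for chrom in tfcrs_by_chrom:
        tfcrs_by_chrom[chrom].sort(key=lambda t: t.peak_pos)

    links: list[TFCRGeneLink] = []

    def _nearest(candidates, key_pos, query_pos, dist_fn):
        """All candidates minimising dist_fn, found around query_pos."""
        positions = np.asarray([key_pos(c) for c in candidates], dtype=np.int64)
        i = int(np.searchsorted(positions, query_pos))
        best: list = []
        best_d = None
        # scan outward; positions are sorted so a window around the insertion
        # point contains every possible minimiser, but interval containment
        # (distance 0) can beat positional distance, so check a safety margin
        # of the widest interval on the chromosome
        margin = max((c.interval.width for c in candidates), default=0) if dist_fn else 0
        lo = i
        while lo > 0 and (best_d is None or query_pos - positions[lo - 1] <= best_d + margin):
            lo -= 1
            d = dist_fn(candidates[lo])
            if best_d is None or d < best_d:
                best, best_d = [candidates[lo]], d
            elif d == best_d:
                best.append(candidates[lo])
        hi = i
        while hi < len(candidates) and (
            best_d is None or positions[hi] - query_pos <= best_d + margin
        ):
            d = dist_fn(candidates[hi])
            if best_d is None or d < best_d:
                best, best_d = [candidates[hi]], d
            elif d == best_d:
                best.append(candidates[hi])
            hi += 1
        return best, best_d

    if direction == "tfcr_to_gene":
        for chrom, chrom_tfcrs in sorted(tfcrs_by_chrom.items()):
            chrom_genes = genes_by_chrom.get(chrom, [])
            for t in chrom_tfcrs:
                if not chrom_genes:
                    continue  # a TFCR on a gene-free chromosome has no link
                best_d = None
                best: list[GeneRecord] = []
                # genes are points; a simple outward scan suffices
                positions = np.asarray([g.tss for g in chrom_genes], dtype=np.int64)
                i = int(np.searchsorted(positions, t.peak_pos))
                lo, hi = i - 1, i
                while True:
                    cand = []
                    if lo >= 0:
                        cand.append(lo)
                    if hi < len(chrom_genes):
                        cand.append(hi)
                    if not cand:
                        break
                    progressed = False
                    for j in list(cand):
                        d = _link_distance(t, chrom_genes[j])
                        if best_d is None or d < best_d:
                            best, best_d = [chrom_genes[j]], d
                        elif d == best_d:
                            best.append(chrom_genes[j])
                    # stop once both frontiers are beyond any possible tie
                    span = t.interval.width
                    if lo < 0 or t.peak_pos - positions[lo] > best_d + span:
                        lo = -1
                    else:
                        lo -= 1
                        progressed = True
                    if hi >= len(chrom_genes) or positions[hi] - t.peak_pos > best_d + span:
                        hi = len(chrom_genes)
                    else:
                        hi += 1
                        progressed = True
                    if not progressed:
                        break
                for g in sorted(best, key=lambda g: g.gene_id):
                    links.append(
                        TFCRGeneLink(
                            tfcr_id=t.tfcr_id,
                            gene_id=g.gene_id,
                            chrom=chrom,
                            peak_pos=t.peak_pos,
                            tss=g.tss,
                            distance=best_d,
                            direction=direction,
                        )
                    )
    else:
        for g in sorted(genes, key=lambda g: (g.chrom, g.tss, g.gene_id)):
            chrom_tfcrs = tfcrs_by_chrom.get(g.chrom, [])
            if not chrom_tfcrs:
                links.append(
                    TFCRGeneLink(
                        tfcr_id=None,
                        gene_id=g.gene_id,
                        chrom=g.chrom,
                        peak_pos=None,
                        tss=g.tss,
                        distance=None,
                        direction=direction,
                    )
                )
                continue
            best, best_d = _nearest(
                chrom_tfcrs,
                key_pos=lambda t: t.peak_pos,
                query_pos=g.tss,
                dist_fn=lambda t: _link_distance(t, g),
            )
            for t in sorted(best, key=lambda t: t.tfcr_id):
                links.append(
                    TFCRGeneLink(
                        tfcr_id=t.tfcr_id,
                        gene_id=g.gene_id,
                        chrom=g.chrom,
                        peak_pos=t.peak_pos,
                        tss=g.tss,
                        distance=best_d,
                        direction=direction,
                    )
                )
    return links


def derive_thresholds(
    links: list[TFCRGeneLink],
    defaults: tuple[int, int, int] = DEFAULT_THRESHOLDS,
    grid_points: int = 512,
) -> RegionThresholds:
    """Derive candidate distance cuts from the link-distance density.

    A Gaussian KDE of log10(distance + 1) is evaluated on a uniform log
    grid.  With at least two density modes: t1 is the local minimum between
    the first two modes, t2 the second mode, and t3 the smaller of the
    default 50 kb and the 99th distance percentile.  The 99 percentile
    values of the distance set and the extrema locations are returned as
    diagnostics.  A unimodal density, or fewer than 100 positive distances,
    falls back to the published defaults.
    """
    distances = np.asarray(
        [l.distance for l in links if l.distance is not None and l.distance > 0],
        dtype=float,
    )
    if len(distances) < 100:
        logger.warning(
            "derive_thresholds: only %d positive distances (< 100); using defaults",
            len(distances),
        )
        return RegionThresholds(*defaults, provenance="default")

    logd = np.log10(distances + 1.0)
    percentiles = np.percentile(distances, np.arange(1, 100))
    kde = gaussian_kde(logd)
    grid = np.linspace(logd.min(), logd.max(), grid_points)
    dens = kde(grid)

    # interior local extrema of the density on the grid
    d1 = np.diff(dens)
    maxima = [i for i in range(1, len(dens) - 1) if d1[i - 1] > 0 and d1[i] <= 0]
    minima = [i for i in range(1, len(dens) - 1) if d1[i - 1] < 0 and d1[i] >= 0]
    diagnostics = {
        "mode_distances": [float(10 ** grid[i] - 1) for i in maxima],
        "minimum_distances": [float(10 ** grid[i] - 1) for i in minima],
        "percentiles": percentiles.tolist(),
    }
    if len(maxima) < 2:
        return RegionThresholds(*defaults, provenance="default", diagnostics=diagnostics)

    m1, m2 = maxima[0], maxima[1]
    between = [i for i in minima if m1 < i < m2]
    if not between:
        return RegionThresholds(*defaults, provenance="default", diagnostics=diagnostics)
    valley = min(between, key=lambda i: dens[i])
    t1 = int(round(10 ** grid[valley] - 1))
    t2 = int(round(10 ** grid[m2] - 1))
    t3 = int(min(defaults[2], round(float(np.percentile(distances, 99)))))
    try:
        return RegionThresholds(t1, t2, t3, provenance="derived", diagnostics=diagnostics)
    except ValueError:
        return RegionThresholds(*defaults, provenance="default", diagnostics=diagnostics)


def classify_regions(
    links: list[TFCRGeneLink], thresholds: RegionThresholds
) -> list[TFCRGeneLink]:
    """Attach an R1..R4 label to every link; total and exclusive.

    Boundary memberships: d = t1 -> R1, d = t2 -> R2, d = t3 -> R3.
    no_TFCR placeholder links pass through unlabelled.
    """
    out = []
    for l in links:
        if l.is_no_tfcr:
            out.append(l)
            continue
        if l.distance is None:
            raise ValueError(f"link {l.tfcr_id}->{l.gene_id} has no distance")
        d = l.distance
        if d <= thresholds.t1:
            region = "R1"
        elif d <= thresholds.t2:
            region = "R2"
        elif d <= thresholds.t3:
            region = "R3"
        else:
            region = "R4"
        out.append(
            TFCRGeneLink(
                tfcr_id=l.tfcr_id,
                gene_id=l.gene_id,
                chrom=l.chrom,
                peak_pos=l.peak_pos,
                tss=l.tss,
                distance=l.distance,
                direction=l.direction,
                region=region,
            )
        )
    return out


def region_proportions(links: list[TFCRGeneLink]) -> dict[str, float]:
    """Fraction of classified links per region; sums to 1."""
    classified = [l for l in links if l.region is not None]
    if not classified:
        raise ValueError("no classified links")
    counts = {r: 0 for r in REGIONS}
    for l in classified:
        counts[l.region] += 1
    n = len(classified)
    return {r: counts[r] / n for r in REGIONS}


def expression_groups(expr: ExpressionTable, scheme: str = "HL") -> dict[str, str]:
    """Group genes by expression.

    ``HL``: H iff FPKM > 1 (strict), else L.  ``E6`` / ``Q100``: equal-size
    rank bins from low (E1/Q1) to high; tied values share the lower bin.
    """
    if len(expr) == 0:
        raise ValueError("empty expression table")
    if scheme == "HL":
        return {g: ("H" if v > 1.0 else "L") for g, v in expr.items()}
    if scheme in ("E6", "Q100"):
        k = 6 if scheme == "E6" else 100
        prefix = "E" if scheme == "E6" else "Q"
        genes = sorted(expr)
        values = np.asarray([expr.get(g) for g in genes], dtype=float)
        rank0 = rankdata(values, method="min") - 1
        bins = np.minimum((rank0 * k) // len(values), k - 1).astype(int)
        return {g: f"{prefix}{int(b) + 1}" for g, b in zip(genes, bins)}
    raise ValueError(f"unknown expression grouping scheme {scheme!r}")
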