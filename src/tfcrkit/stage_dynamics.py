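"""Cross-stage TFCR dynamics.

Stages (e.g. 2Cell -> 4Cell -> 8Cell -> ICM -> primed-hESC) are called
independently, so TFCR identity across stages is positional: two TFCRs in
consecutive stages are "the same" element when their intervals overlap by
at least 1 bp.  On top of that notion this module derives gained / lost /
kept sets per stage, stage-stable regions (the interval intersection chain
across all stages), long-range distance histograms, and soft (fuzzy
c-means) clustering of per-gene complexity trajectories.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .gene_linking import TFCRGeneLink
from .genome_io import TFCR, ExpressionTable, GenomicInterval

logger = logging.getLogger(__name__)

LR_DISTANCE_BIN_LABELS = ("50-100k", "100-150k", "150-200k", ">200k")
_LR_EDGES = (100_000, 150_000, 200_000)


@dataclass
class StageData:
    name: str
    tfcrs: list[TFCR]
    links: list[TFCRGeneLink] = field(default_factory=list)
    expression: ExpressionTable | None = None


@dataclass
class StageCollection:
    """Ordered developmental stages with their TFCR calls."""

    stages: list[StageData]

    def __post_init__(self) -> None:
        names = [s.name for s in self.stages]
        if len(set(names)) != len(names):
            raise ValueError("stage names must be unique")

    @property
    def names(self) -> list[str]:
        return [s.name for s in self.stages]

    def __len__(self) -> int:
        return len(self.stages)

    def __getitem__(self, i: int) -> StageData:
        return self.stages[i]


@dataclass
class TrajectoryClustering:
    """Soft c-means clustering of z-standardised trajectories."""

    entity_ids: list[str]
    matrix: np.ndarray  # entities x stages, standardised
    memberships: np.ndarray  # entities x c
    centers: np.ndarray  # c x stages
    fuzzifier: float
    seed: int
    n_iter: int
    objective: float

    @property
    def hard_labels(self) -> np.ndarray:
        return np.argmax(self.memberships, axis=1)


# ---------------------------------------------------------------------------
# Interval overlap machinery
# ---------------------------------------------------------------------------


def overlap_pairs(
    a: list[TFCR], b: list[TFCR], min_overlap_bp: int = 1
) -> set[tuple[str, str]]:
    """All (a_id, b_id) pairs whose intervals overlap >= min_overlap_bp.

    Sweep per chromosome over start-sorted inputs; symmetric in a and b.
    """
    by_chrom_a: dict[str, list[TFCR]] = {}
    for t in a:
        by_chrom_a.setdefault(t.chrom, []).append(t)
    by_chrom_b: dict[str, list[TFCR]] = {}
    for t in b:
        by_chrom_b.setdefault(t.chrom, []).append(t)
    pairs: set[tuple[str, str]] = set()
    for chrom, la in by_chrom_a.items():
        lb = by_chrom_b.get(chrom)
        if not lb:
            continue
        lb = sorted(lb, key=lambda t: t.interval.start)
        b_starts = np.asarray([t.interval.start for t in lb], dtype=np.int64)
        max_b_width = max(t.interval.width for t in lb)
        for ta in la:
            # b intervals overlapping ta have start < ta.end and
            # start > ta.start - width(b) >= ta.start - max_b_width
            j = int(np.searchsorted(b_starts, ta.interval.start - max_b_width))
            for tb in lb[j:]:
                if tb.interval.start >= ta.interval.end:
                    break
                if ta.interval.overlap(tb.interval) >= min_overlap_bp:
                    pairs.add((ta.tfcr_id, tb.tfcr_id))
    return pairs


def gained_lost(
    stages: StageCollection,
    scope: str = "all",
    min_overlap_bp: int = 1,
) -> dict[str, dict[str, set[str]]]:
    """Per-stage gained / lost / kept TFCR id sets.

    Gained at stage s (s > first): no overlap partner in stage s-1.
    Lost at stage s (s < last): no overlap partner in stage s+1.
    Kept: the stage's remaining TFCRs.  Gained is undefined (empty) at the
    first stage and lost at the last.  ``scope="LR_only"`` first restricts
    every stage to TFCRs carrying an R4 link.
    """
    if len(stages) < 2:
        raise ValueError("gained/lost needs at least 2 stages")
    per_stage_tfcrs = [_scoped_tfcrs(s, scope) for s in stages.stages]
    result: dict[str, dict[str, set[str]]] = {}
    for i, stage in enumerate(stages.stages):
        ids = {t.tfcr_id for t in per_stage_tfcrs[i]}
        gained: set[str] = set()
        lost: set[str] = set()
        if i > 0:
            partnered = {p[0] for p in overlap_pairs(per_stage_tfcrs[i], per_stage_tfcrs[i - 1], min_overlap_bp)}
            gained = ids - partnered
        if i < len(stages) - 1:
            partnered = {p[0] for p in overlap_pairs(per_stage_tfcrs[i], per_stage_tfcrs[i + 1], min_overlap_bp)}
            lost = ids - partnered
        result[stage.name] = {"gained": gained, "lost": lost, "kept": ids - gained - lost}
    return result


def _scoped_tfcrs(stage: StageData, scope: str) -> list[TFCR]:
    if scope == "all":
        return stage.tfcrs
    if scope == "LR_only":
        lr_ids = {l.tfcr_id for l in stage.links if l.region == "R4"}
        return [t for t in stage.tfcrs if t.tfcr_id in lr_ids]
    raise ValueError(f"unknown scope {scope!r}")


@dataclass(frozen=True)
class StableRegion:
    interval: GenomicInterval
    tfcr_ids_per_stage: tuple[tuple[str, ...], ...]


def _merge_union(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    if not intervals:
        return []
    intervals = sorted(intervals)
    merged = [list(intervals[0])]
    for s, e in intervals[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [tuple(x) for x in merged]


def stable_regions(stages: StageCollection, scope: str = "all") -> list[StableRegion]:
    """Interval fragments present (>= 1 bp) in every stage.

    Sequential intersection of the per-stage interval-set unions; each
    surviving fragment is annotated with the overlapping TFCR ids of every
    stage.  Any empty stage yields an empty result with a warning.
    """
    per_stage = [_scoped_tfcrs(s, scope) for s in stages.stages]
    if any(not ts for ts in per_stage):
        logger.warning("stable_regions: at least one stage has no TFCRs in scope")
        return []
    chroms = set.intersection(*({t.chrom for t in ts} for ts in per_stage))
    out: list[StableRegion] = []
    for chrom in sorted(chroms):
        frags = _merge_union(
            [(t.interval.start, t.interval.end) for t in per_stage[0] if t.chrom == chrom]
        )
        for ts in per_stage[1:]:
            other = _merge_union(
                [(t.interval.start, t.interval.end) for t in ts if t.chrom == chrom]
            )
            frags = _intersect_sorted(frags, other)
            if not frags:
                break
        for s, e in frags:
            ids_per_stage = tuple(
                tuple(
                    sorted(
                        t.tfcr_id
                        for t in ts
                        if t.chrom == chrom and t.interval.start < e and t.interval.end > s
                    )
                )
                for ts in per_stage
            )
            out.append(
                StableRegion(
                    interval=GenomicInterval(chrom, s, e),
                    tfcr_ids_per_stage=ids_per_stage,
                )
            )
    return out


def _intersect_sorted(
    a: list[tuple[int, int]], b: list[tuple[int, int]]
) -> list[tuple[int, int]]:
    out = []
    i = j = 0
    while i < len(a) and j < len(b):
        s = max(a[i][0], b[j][0])
        e = min(a[i][1], b[j][1])
        if e - s >= 1:
            out.append((s, e))
        if a[i][1] < b[j][1]:
            i += 1
        else:
            j += 1
    return out


def lr_distance_bins(links: list[TFCRGeneLink]) -> dict[str, int]:
    """Histogram of R4 (long-range) link distances.

    Bins: 50-100k, 100-150k, 150-200k, >200k; counts sum to the number of
    links passed.  Passing a non-R4 link is an error.
    """
    counts = {label: 0 for label in LR_DISTANCE_BIN_LABELS}
    for l in links:
        if l.region != "R4":
            raise ValueError(f"lr_distance_bins expects R4 links, got {l.region}")
        d = l.distance
        if d <= _LR_EDGES[0]:
            counts["50-100k"] += 1
        elif d <= _LR_EDGES[1]:
            counts["100-150k"] += 1
        elif d <= _LR_EDGES[2]:
            counts["150-200k"] += 1
        else:
            counts[">200k"] += 1
    return counts


# ---------------------------------------------------------------------------
# Trajectories
# ---------------------------------------------------------------------------


def tc_trajectories(stages: StageCollection) -> tuple[list[str], np.ndarray]:
    """Per-gene complexity trajectory across stages, z-standardised.

    A gene's value at a stage is the complexity of its nearest TFCR there
    (maximum TC over exact-distance ties).  Genes lacking a TFCR in any
    stage are excluded (count logged).  Rows are standardised to mean 0,
    sd 1 before clustering; a constant row is excluded (its shape is
    undefined after standardisation).
    """
    if len(stages) < 2:
        raise ValueError("trajectories need >= 2 stages")
    tc_by_id = [{t.tfcr_id: t.tc for t in s.tfcrs} for s in stages.stages]
    per_stage_gene_tc: list[dict[str, float]] = []
    for s, tcmap in zip(stages.stages, tc_by_id):
        gene_tc: dict[str, float] = {}
        for l in s.links:
            if l.is_no_tfcr or l.direction != "gene_to_tfcr":
                continue
            tc = tcmap.get(l.tfcr_id)
            if tc is None:
                continue
            prev = gene_tc.get(l.gene_id)
            if prev is None or tc > prev:
                gene_tc[l.gene_id] = tc
        per_stage_gene_tc.append(gene_tc)
    usable = sorted(set.intersection(*(set(d) for d in per_stage_gene_tc)))
    total = len(set.union(*(set(d) for d in per_stage_gene_tc)))
    if total > len(usable):
        logger.info(
            "tc_trajectories: excluded %d genes missing a TFCR in some stage",
            total - len(usable),
        )
    rows = np.asarray(
        [[d[g] for d in per_stage_gene_tc] for g in usable], dtype=float
    )
    sd = rows.std(axis=1, ddof=0)
    keep = sd > 0
    if (~keep).any():
        logger.info("tc_trajectories: excluded %d constant trajectories", int((~keep).sum()))
    rows = rows[keep]
    ids = [g for g, k in zip(usable, keep) if k]
    rows = (rows - rows.mean(axis=1, keepdims=True)) / rows.std(axis=1, ddof=0, keepdims=True)
    return ids, rows


def fuzzy_cmeans(
    matrix: np.ndarray,
    entity_ids: list[str] | None = None,
    c: int = 6,
    m: float = 2.0,
    seed: int = 0,
    max_iter: int = 300,
    tol: float = 1e-6,
) -> TrajectoryClustering:
    """Soft c-means clustering of trajectory rows.

    Standard updates: memberships u_ij proportional to d_ij^(-2/(m-1)),
    centers are u^m-weighted means; iteration stops when the maximum
    center shift drops below ``tol``.  A point coinciding with a center
    gets membership 1 there (limit rule).  Deterministic under a fixed
    seed; the objective sum(u^m d^2) is checked to be non-increasing.
    """
    X = np.asarray(matrix, dtype=float)
    n, _ = X.shape
    if n < c:
        raise ValueError(f"need >= {c} rows for c={c} clusters")
    if m <= 1:
        raise ValueError("fuzzifier m must be > 1")
    rng = np.random.default_rng(seed)
    u = rng.dirichlet(np.ones(c), size=n)  # rows sum to 1
    centers = _fcm_centers(X, u, m)
    prev_obj = np.inf
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        d2 = _sq_distances(X, centers)
        u = _fcm_memberships(d2, m)
        obj = float(np.sum((u**m) * d2))
        if obj > prev_obj + 1e-9:
            raise AssertionError("fuzzy c-means objective increased")
        prev_obj = obj
        new_centers = _fcm_centers(X, u, m)
        shift = float(np.max(np.abs(new_centers - centers)))
        centers = new_centers
        if shift < tol:
            break
    if entity_ids is None:
        entity_ids = [str(i) for i in range(n)]
    return TrajectoryClustering(
        entity_ids=list(entity_ids),
        matrix=X,
        memberships=u,
        centers=centers,
        fuzzifier=m,
        seed=seed,
        n_iter=n_iter,
        objective=prev_obj,
    )


def _sq_distances(X: np.ndarray, centers: np.ndarray) -> np.ndarray:
    diff = X[:, None, :] - centers[None, :, :]
    return np.sum(diff * diff, axis=2)


def _fcm_memberships(d2: np.ndarray, m: float) -> np.ndarray:
    zero = d2 <= 1e-300
    u = np.zeros_like(d2)
    any_zero = zero.any(axis=1)
    if any_zero.any():
        rows = np.flatnonzero(any_zero)
        for i in rows:  # limit rule: all mass on coincident center(s)
            hits = np.flatnonzero(zero[i])
            u[i, hits] = 1.0 / len(hits)
    rest = ~any_zero
    if rest.any():
        power = d2[rest] ** (-1.0 / (m - 1.0))
        u[rest] = power / power.sum(axis=1, keepdims=True)
    return u


def _fcm_centers(X: np.ndarray, u: np.ndarray, m: float) -> np.ndarray:
    w = u**m
    return (w.T @ X) / w.sum(axis=0)[:, None]
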