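"""TAD co-localisation and phase-separation TF annotation.

A link's TFCR and gene are each assigned to the topologically associating
domain (TAD) containing them — the TFCR by its peak position, the gene by
its TSS, both with half-open containment — and the link is labelled
``same_TAD`` only when both land in the same domain.  TFCRs are annotated
with phase-separation-associated transcription factors (PSTFs, an
LLPS-database-derived name list) by case-insensitive TF-name matching over
their contributing sites.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np

from .association_stats import welch_ttest
from .gene_linking import TFCRGeneLink
from .genome_io import TFCR, GenomicInterval

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TADAssignment:
    link: TFCRGeneLink
    tfcr_tad: str | None
    gene_tad: str | None

    @property
    def status(self) -> str:
        if self.tfcr_tad is not None and self.tfcr_tad == self.gene_tad:
            return "same_TAD"
        return "not_same_TAD"


@dataclass(frozen=True)
class PSTFAnnotation:
    tfcr_id: str
    n_pstf: int
    n_tfs: int

    @property
    def has_pstf(self) -> bool:
        return self.n_pstf >= 1

    @property
    def pct_pstf(self) -> float:
        return self.n_pstf / self.n_tfs if self.n_tfs else 0.0

    @property
    def group(self) -> str:
        return "PSTF" if self.has_pstf else "not_PSTF"


def _validate_tads(tads: list[GenomicInterval]) -> dict[str, list[GenomicInterval]]:
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for tad in tads:
        by_chrom.setdefault(tad.chrom, []).append(tad)
    offenders = []
    for chrom in by_chrom:
        by_chrom[chrom].sort(key=lambda t: t.start)
        for prev, cur in zip(by_chrom[chrom], by_chrom[chrom][1:]):
            if cur.start < prev.end:
                offenders.append((prev, cur))
    if offenders:
        desc = "; ".join(
            f"{p.chrom}:{p.start}-{p.end} vs {c.chrom}:{c.start}-{c.end}"
            for p, c in offenders[:5]
        )
        raise ValueError(f"overlapping TADs: {desc}")
    return by_chrom


def _tad_id(tad: GenomicInterval) -> str:
    return f"{tad.chrom}:{tad.start}-{tad.end}"


def assign_tads(
    links: list[TFCRGeneLink], tads: list[GenomicInterval]
) -> list[TADAssignment]:
    """Assign each link's TFCR peak and gene TSS to containing TADs.

    TADs must be non-overlapping within the sample.  Containment is
    half-open: a point exactly at a TAD end belongs to the next TAD.
    Points outside every TAD get no id and hence ``not_same_TAD``.
    """
    by_chrom = _validate_tads(tads)
    starts = {c: np.asarray([t.start for t in ts], dtype=np.int64) for c, ts in by_chrom.items()}

    def _locate(chrom: str, pos: int | None) -> str | None:
        if pos is None or chrom not in by_chrom:
            return None
        i = int(np.searchsorted(starts[chrom], pos, side="right")) - 1
        if i >= 0 and by_chrom[chrom][i].contains(chrom, pos):
            return _tad_id(by_chrom[chrom][i])
        return None

    out = []
    for l in links:
        out.append(
            TADAssignment(
                link=l,
                tfcr_tad=_locate(l.chrom, l.peak_pos),
                gene_tad=_locate(l.chrom, l.tss),
            )
        )
    return out


def annotate_pstf(tfcrs: list[TFCR], pstf_list: set[str] | list[str]) -> list[PSTFAnnotation]:
    """Count distinct PSTF names among each TFCR's contributing TFs.

    Matching is case-insensitive on TF names.  The percentage denominator
    is the number of distinct TFs on the TFCR.
    """
    if not pstf_list:
        raise ValueError("empty PSTF list")
    pstf_upper = {name.upper() for name in pstf_list}
    seen_tfs = {tf.upper() for t in tfcrs for tf in t.tf_names}
    unmatched = pstf_upper - seen_tfs
    if unmatched:
        logger.info(
            "annotate_pstf: %d PSTF names not seen among contributing TFs", len(unmatched)
        )
    out = []
    for t in tfcrs:
        tfs = {tf.upper() for tf in t.tf_names}
        out.append(
            PSTFAnnotation(
                tfcr_id=t.tfcr_id,
                n_pstf=len(tfs & pstf_upper),
                n_tfs=len(tfs),
            )
        )
    return out


def group_compare(values_by_group: dict[str, list[float]]) -> dict:
    """Pairwise Welch comparisons plus per-group summaries.

    Groups with fewer than 2 values are excluded (logged).  Returns
    ``{"groups": {name: {n, median, iqr}}, "comparisons": [...]}`` with one
    comparison row per unordered pair.
    """
    usable = {}
    for name, values in values_by_group.items():
        if len(values) < 2:
            logger.info("group_compare: excluding group %s (n=%d < 2)", name, len(values))
            continue
        usable[name] = np.asarray(values, dtype=float)
    if len(usable) < 2:
        raise ValueError("group_compare needs >= 2 usable groups")
    summaries = {
        name: {
            "n": int(len(v)),
            "median": float(np.median(v)),
            "iqr": float(np.percentile(v, 75) - np.percentile(v, 25)),
        }
        for name, v in usable.items()
    }
    comparisons = []
    for ga, gb in itertools.combinations(sorted(usable), 2):
        t, p, star = welch_ttest(usable[ga], usable[gb])
        comparisons.append(
            {"group_a": ga, "group_b": gb, "t": t, "p": p, "stars": star}
        )
    return {"groups": summaries, "comparisons": comparisons}
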