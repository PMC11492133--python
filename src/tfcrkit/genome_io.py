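"""Readers and writers for the external formats the pipeline touches.

All coordinates are stored internally as 0-based half-open intervals
(``start`` inclusive, ``end`` exclusive), the BED convention.  FIMO output
is 1-based inclusive and is shifted exactly once, at the parsing boundary.
"""

from __future__ import annotations

import logging
import math
import os
from dataclasses import dataclass, field

import pandas as pd

logger = logging.getLogger(__name__)

FIMO_COLUMNS = [
    "motif_id",
    "motif_alt_id",
    "sequence_name",
    "start",
    "stop",
    "strand",
    "score",
    "p-value",
    "q-value",
    "matched_sequence",
]

UNKNOWN_FAMILY = "UNKNOWN"


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )

    @property
    def width(self) -> int:
        return self.end - self.start

    def overlap(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def contains(self, chrom: str, pos: int) -> bool:
        return self.chrom == chrom and self.start <= pos < self.end


@dataclass(frozen=True)
class ScoredPeak:
    """An accessibility peak (e.g. ATAC-seq) with a non-negative score."""

    interval: GenomicInterval
    score: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.score):
            raise ValueError("peak score must be finite")


@dataclass(frozen=True)
class TFBSRecord:
    """One motif hit: interval, TF identity and family, FIMO scan score."""

    interval: GenomicInterval
    tf_name: str
    tf_family: str
    scan_score: float

    @property
    def midpoint(self) -> int:
        return (self.interval.start + self.interval.end) // 2

    @property
    def chrom(self) -> str:
        return self.interval.chrom


@dataclass(frozen=True)
class GeneRecord:
    """A gene reduced to its transcription start site.

    The TSS is the interval start on the + strand and ``end - 1`` on the
    - strand (0-based).
    """

    gene_id: str
    chrom: str
    tss: int
    strand: str

    @classmethod
    def from_interval(cls, gene_id: str, interval: GenomicInterval) -> "GeneRecord":
        if interval.strand == "-":
            tss = interval.end - 1
        elif interval.strand == "+":
            tss = interval.start
        else:
            raise ValueError(f"gene {gene_id}: strand required to define a TSS")
        return cls(gene_id=gene_id, chrom=interval.chrom, tss=tss, strand=interval.strand)


class ExpressionTable:
    """gene_id -> FPKM-like expression, with log10(x+1) convenience.

    Missing genes are distinguishable from zero-expression genes:
    :meth:`get` returns ``None`` for absent ids.
    """

    def __init__(self, values: dict[str, float]):
        for g, v in values.items():
            if v < 0 or not math.isfinite(v):
                raise ValueError(f"gene {g}: expression must be finite and >= 0")
        self._values = dict(values)

    def __len__(self) -> int:
        return len(self._values)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._values

    def __iter__(self):
        return iter(self._values)

    def get(self, gene_id: str):
        return self._values.get(gene_id)

    def items(self):
        return self._values.items()

    def log_expr(self, gene_id: str):
        """log10(FPKM + 1); None for genes absent from the table."""
        v = self._values.get(gene_id)
        if v is None:
            return None
        return math.log10(v + 1.0)


# ---------------------------------------------------------------------------
# TFCR record (produced by tfcr_caller, serialised here)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Contribution:
    """A TFBS contributing kernel weight to a TFCR peak."""

    tfbs: TFBSRecord
    weight: float
    distance: int


@dataclass
class TFCR:
    """A called TF-binding-site clustered region."""

    tfcr_id: str
    stage: str
    interval: GenomicInterval
    peak_pos: int
    tc: float
    contributions: list[Contribution] = field(default_factory=list)
    cas: float | None = None
    tc_bin: str | None = None

    @property
    def tw(self) -> int:
        """Width of the region (bp)."""
        return self.interval.width

    @property
    def cw(self) -> float:
        """Unit-base complexity: complexity per bp of width."""
        return self.tc / self.tw

    @property
    def families(self) -> set[str]:
        return {c.tfbs.tf_family for c in self.contributions}

    @property
    def tf_names(self) -> set[str]:
        return {c.tfbs.tf_name for c in self.contributions}

    @property
    def chrom(self) -> str:
        return self.interval.chrom


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------


def read_family_map(path: str | os.PathLike) -> dict[str, str]:
    """Read a two-column TSV mapping TF name -> TF family."""
    mapping: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise FormatError(f"{path}:{lineno}: expected two tab-separated columns")
            mapping[parts[0]] = parts[1]
    return mapping


def read_name_list(path: str | os.PathLike) -> list[str]:
    """Read a plain-text one-name-per-line list (gene or TF names)."""
    out = []
    with open(path) as fh:
        for line in fh:
            name = line.strip()
            if name and not name.startswith("#"):
                out.append(name)
    return out


def read_fimo_tfbs(
    path: str | os.PathLike, family_map: dict[str, str] | None = None
) -> list[TFBSRecord]:
    """Parse FIMO tab-separated output into TFBS records.

    FIMO reports 1-based inclusive coordinates; they are converted here to
    0-based half-open.  The TF name is taken from ``motif_alt_id`` when
    present (FIMO's convention for the human-readable name), falling back
    to ``motif_id``.  Exactly duplicated hits (same motif, interval and
    strand) are collapsed.  Records are returned sorted by (chrom, start).
    """
    family_map = family_map or {}
    try:
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    except pd.errors.EmptyDataError:
        return []
    for col in FIMO_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"{path}: missing mandatory FIMO column '{col}'")
    records = []
    seen = set()
    for idx, row in df.iterrows():
        lineno = idx + 2  # header occupies line 1
        try:
            start1 = int(row["start"])
            stop1 = int(row["stop"])
        except (TypeError, ValueError):
            raise FormatError(
                f"{path}:{lineno}: non-integer coordinate "
                f"(start={row['start']!r}, stop={row['stop']!r})"
            ) from None
        alt = row["motif_alt_id"]
        tf_name = alt if isinstance(alt, str) and alt else str(row["motif_id"])
        key = (str(row["motif_id"]), str(row["sequence_name"]), start1, stop1, str(row["strand"]))
        if key in seen:
            continue
        seen.add(key)
        interval = GenomicInterval(
            chrom=str(row["sequence_name"]),
            start=start1 - 1,
            end=stop1,
            strand=str(row["strand"]),
        )
        records.append(
            TFBSRecord(
                interval=interval,
                tf_name=tf_name,
                tf_family=family_map.get(tf_name, UNKNOWN_FAMILY),
                scan_score=float(row["score"]),
            )
        )
    records.sort(key=lambda r: (r.interval.chrom, r.interval.start, r.interval.end, r.tf_name))
    return records


def _bed_rows(path: str | os.PathLike):
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            yield lineno, line.split("\t")


def read_bed(path: str | os.PathLike, scored: bool = False):
    """Read BED3/BED6 intervals, optionally with the column-5 score.

    Returns a list of :class:`ScoredPeak` when ``scored`` else
    :class:`GenomicInterval`, sorted by (chrom, start).
    """
    out = []
    for lineno, parts in _bed_rows(path):
        if len(parts) < 3:
            raise FormatError(f"{path}:{lineno}: BED row needs >= 3 columns")
        try:
            start, end = int(parts[1]), int(parts[2])
        except ValueError:
            raise FormatError(f"{path}:{lineno}: non-integer BED coordinate") from None
        if start >= end:
            raise FormatError(f"{path}:{lineno}: start >= end ({start} >= {end})")
        strand = parts[5] if len(parts) >= 6 and parts[5] in "+-." else "."
        iv = GenomicInterval(chrom=parts[0], start=start, end=end, strand=strand)
        if scored:
            if len(parts) < 5:
                raise FormatError(f"{path}:{lineno}: scored BED needs >= 5 columns")
            out.append(ScoredPeak(interval=iv, score=float(parts[4])))
        else:
            out.append(iv)
    key = (lambda p: (p.interval.chrom, p.interval.start)) if scored else (
        lambda iv: (iv.chrom, iv.start)
    )
    out.sort(key=key)
    return out


def _parse_gtf_attributes(attr: str) -> dict[str, str]:
    out = {}
    for item in attr.strip().split(";"):
        item = item.strip()
        if not item:
            continue
        if " " in item:
            k, v = item.split(" ", 1)
            out[k] = v.strip().strip('"')
    return out


def read_gene_tss(
    path: str | os.PathLike, format: str = "bed", feature_type: str = "gene"
) -> list[GeneRecord]:
    """Read gene TSS annotation from BED6 or GTF.

    BED mode expects one row per gene with the id in column 4 and strand in
    column 6.  GTF mode uses rows of the configured ``feature_type`` and the
    ``gene_id`` attribute.  Duplicate gene ids keep the first occurrence.
    """
    genes: list[GeneRecord] = []
    seen: set[str] = set()

    def _add(gene_id: str, iv: GenomicInterval, lineno: int) -> None:
        if gene_id in seen:
            logger.warning("%s:%d: duplicate gene_id %s; keeping first", path, lineno, gene_id)
            return
        seen.add(gene_id)
        genes.append(GeneRecord.from_interval(gene_id, iv))

    if format == "bed":
        for lineno, parts in _bed_rows(path):
            if len(parts) < 6:
                raise FormatError(f"{path}:{lineno}: gene BED needs 6 columns (id + strand)")
            iv = GenomicInterval(parts[0], int(parts[1]), int(parts[2]), parts[5])
            _add(parts[3], iv, lineno)
    elif format == "gtf":
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) < 9:
                    raise FormatError(f"{path}:{lineno}: GTF row needs 9 columns")
                if parts[2] != feature_type:
                    continue
                strand = parts[6]
                if strand not in "+-":
                    raise FormatError(
                        f"{path}:{lineno}: gene without strand; TSS undefined"
                    )
                attrs = _parse_gtf_attributes(parts[8])
                if "gene_id" not in attrs:
                    raise FormatError(f"{path}:{lineno}: missing gene_id attribute")
                iv = GenomicInterval(parts[0], int(parts[3]) - 1, int(parts[4]), strand)
                _add(attrs["gene_id"], iv, lineno)
    else:
        raise ValueError(f"unknown gene annotation format {format!r}")
    genes.sort(key=lambda g: (g.chrom, g.tss, g.gene_id))
    return genes


def read_expression_table(path: str | os.PathLike) -> ExpressionTable:
    """Read a two-column TSV of gene_id and FPKM (header optional)."""
    values: dict[str, float] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise FormatError(f"{path}:{lineno}: expected gene_id<TAB>FPKM")
            try:
                v = float(parts[1])
            except ValueError:
                if lineno == 1:  # tolerated header row
                    continue
                raise FormatError(f"{path}:{lineno}: non-numeric expression") from None
            values[parts[0]] = v
    return ExpressionTable(values)


# ---------------------------------------------------------------------------
# TFCR table round trip
# ---------------------------------------------------------------------------

_TFCR_HEADER = [
    "chrom",
    "start",
    "end",
    "tfcr_id",
    "TC",
    "strand",
    "peak_pos",
    "TW",
    "cw",
    "CAS",
    "tc_bin",
    "n_families",
]


def write_tfcr_table(tfcrs: list[TFCR], path: str | os.PathLike) -> None:
    """Write TFCRs as BED6+ (with a '#'-prefixed header) plus a TSV twin.

    The TSV twin lives next to ``path`` with a ``.tsv`` suffix.  Floats are
    written with 6 decimals; :func:`read_tfcr_table` reproduces them.
    """
    path = str(path)

    def _lines():
        yield "#" + "\t".join(_TFCR_HEADER)
        for t in tfcrs:
            yield "\t".join(
                [
                    t.interval.chrom,
                    str(t.interval.start),
                    str(t.interval.end),
                    t.tfcr_id,
                    f"{t.tc:.6f}",
                    ".",
                    str(t.peak_pos),
                    str(t.tw),
                    f"{t.cw:.6f}" if t.tw else "NA",
                    f"{t.cas:.6f}" if t.cas is not None else "NA",
                    t.tc_bin if t.tc_bin is not None else "NA",
                    str(len(t.families)),
                ]
            )

    content = "\n".join(_lines()) + "\n"
    with open(path, "w") as fh:
        fh.write(content)
    twin = os.path.splitext(path)[0] + ".tsv"
    if twin != path:
        with open(twin, "w") as fh:
            fh.write(content)


def read_tfcr_table(path: str | os.PathLike, stage: str = "") -> list[TFCR]:
    """Read a table written by :func:`write_tfcr_table`.

    Contributions are not serialised, so the returned records carry TC, CAS
    and the bin label but empty contribution lists.
    """
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < len(_TFCR_HEADER):
                raise FormatError(f"{path}:{lineno}: truncated TFCR row")
            iv = GenomicInterval(parts[0], int(parts[1]), int(parts[2]))
            out.append(
                TFCR(
                    tfcr_id=parts[3],
                    stage=stage,
                    interval=iv,
                    peak_pos=int(parts[6]),
                    tc=float(parts[4]),
                    cas=None if parts[9] == "NA" else float(parts[9]),
                    tc_bin=None if parts[10] == "NA" else parts[10],
                )
            )
    return out
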