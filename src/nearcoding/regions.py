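"""Near-coding region construction and variant position classification.

Builds the set of "near-coding" intervals around dominant disease genes:
proximal promoters (from candidate cis-regulatory elements with a
percentile-based fallback), UTR exons, and UTR introns, with every
protein-coding (CDS) base subtracted so that no retained variant can have a
coding consequence. Also classifies variant positions against the region
set, flagging deep-intronic positions (>20 bp from the nearest exon
boundary).

All internal coordinates are 0-based half-open (BED convention). The TSS
base itself belongs to the *downstream* span of the promoter: the interval
"-U bp to +D bp from the TSS" on the plus strand is ``[tss - U, tss + D)``,
strand-mirrored on the minus strand.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

logger = logging.getLogger(__name__)

Interval = tuple[int, int]

PROMOTER = "promoter"
FIVE_UTR = "five_utr"
THREE_UTR = "three_utr"
FIVE_UTR_INTRON = "five_utr_intron"
THREE_UTR_INTRON = "three_utr_intron"

REGION_CLASSES = (PROMOTER, FIVE_UTR, THREE_UTR, FIVE_UTR_INTRON, THREE_UTR_INTRON)
INTRON_CLASSES = frozenset({FIVE_UTR_INTRON, THREE_UTR_INTRON})
UTR_CLASSES = frozenset({FIVE_UTR, THREE_UTR, FIVE_UTR_INTRON, THREE_UTR_INTRON})

#: bases from the nearest exon boundary beyond which an intronic position is
#: "deep" (strict: the 21st intronic base onward).
DEEP_INTRON_DISTANCE = 20


class NonCodingTranscriptError(ValueError):
    """Raised when a UTR operation is applied to a transcript without a CDS."""


@dataclass(frozen=True)
class CisElement:
    """A candidate cis-regulatory element (e.g. a promoter-like interval)."""

    chrom: str
    start: int
    end: int
    label: str = "promoter-like"

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"empty cis element [{self.start}, {self.end})")


@dataclass(frozen=True)
class PromoterConfig:
    """Percentile extents (bp) of promoter-like elements around the TSS.

    The 25th percentiles define the minimal promoter used to patch deficient
    elements; the 75th percentiles define the fallback promoter for
    transcripts with no TSS-overlapping element.
    """

    up_p25: int = 181
    down_p25: int = 67
    up_p75: int = 266
    down_p75: int = 139

    def __post_init__(self) -> None:
        for name in ("up_p25", "down_p25", "up_p75", "down_p75"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.up_p75 < self.up_p25 or self.down_p75 < self.down_p25:
            raise ValueError("75th percentile extents must be >= 25th")


@dataclass
class TranscriptModel:
    """Exon/CDS geometry for one transcript.

    ``exons`` are sorted, non-overlapping genomic intervals; ``cds_start``
    and ``cds_end`` bound the genomic coding span (half-open). A
    non-coding transcript is represented with ``cds_start is None``.
    """

    transcript_id: str
    gene_symbol: str
    chrom: str
    strand: str
    exons: list[Interval]
    cds_start: int | None = None
    cds_end: int | None = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"bad strand {self.strand!r}")
        if not self.exons:
            raise ValueError("transcript must have at least one exon")
        for (s, e) in self.exons:
            if e <= s:
                raise ValueError(f"empty exon [{s}, {e})")
        for (_, e0), (s1, _) in zip(self.exons, self.exons[1:]):
            if s1 < e0:
                raise ValueError("exons must be sorted and non-overlapping")
        if (self.cds_start is None) != (self.cds_end is None):
            raise ValueError("cds_start and cds_end must be set together")
        if self.cds_start is not None:
            if self.cds_end <= self.cds_start:
                raise ValueError("empty CDS span")
            if self.cds_start < self.exons[0][0] or self.cds_end > self.exons[-1][1]:
                raise ValueError("CDS outside transcript span")

    @property
    def is_coding(self) -> bool:
        return self.cds_start is not None

    @property
    def span(self) -> Interval:
        return (self.exons[0][0], self.exons[-1][1])

    @property
    def tss(self) -> int:
        """Genomic coordinate of the first transcribed base."""
        if self.strand == "+":
            return self.exons[0][0]
        return self.exons[-1][1] - 1

    def cds_intervals(self) -> list[Interval]:
        """Exonic CDS intervals (genomic, sorted)."""
        if not self.is_coding:
            return []
        out = []
        for s, e in self.exons:
            cs, ce = max(s, self.cds_start), min(e, self.cds_end)
            if ce > cs:
                out.append((cs, ce))
        return out

    def introns(self) -> list[Interval]:
        return [
            (e0, s1) for (_, e0), (s1, _) in zip(self.exons, self.exons[1:]) if s1 > e0
        ]


@dataclass(frozen=True)
class NearCodingRegion:
    """A classified near-coding interval linked to one transcript."""

    chrom: str
    start: int
    end: int
    region_class: str
    transcript_id: str
    gene_symbol: str = ""

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"empty region [{self.start}, {self.end})")
        if self.region_class not in REGION_CLASSES:
            raise ValueError(f"unknown region class {self.region_class!r}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class RegionAssignment:
    """Region classes containing a variant position, plus deep-intron flag."""

    region_classes: set[str] = field(default_factory=set)
    deep_intronic: bool = False

    def __post_init__(self) -> None:
        if self.deep_intronic and not (self.region_classes & INTRON_CLASSES):
            raise ValueError("deep_intronic requires an intron region class")

    def __bool__(self) -> bool:
        return bool(self.region_classes)


def derive_promoter(
    tx: TranscriptModel,
    ccres: list[CisElement],
    cfg: PromoterConfig = PromoterConfig(),
) -> Interval:
    """Derive the proximal promoter interval for one transcript.

    If a cis element overlaps the TSS and already spans at least the 25th
    percentile extents on both sides, it is used unchanged; a deficient side
    is extended to exactly the 25th percentile distance. With no overlapping
    element, the 75th percentile extents around the TSS are used. Among
    several overlapping elements the one with the largest span wins, ties
    broken by leftmost start. Elements on other chromosomes are ignored.
    """
    tss = tx.tss
    overlapping = [c for c in ccres if c.chrom == tx.chrom and c.start <= tss < c.end]
    if not overlapping:
        if tx.strand == "+":
            return (tss - cfg.up_p75, tss + cfg.down_p75)
        return (tss + 1 - cfg.down_p75, tss + 1 + cfg.up_p75)

    best = min(overlapping, key=lambda c: (-(c.end - c.start), c.start))
    if tx.strand == "+":
        up, down = tss - best.start, best.end - tss
        start = best.start if up >= cfg.up_p25 else tss - cfg.up_p25
        end = best.end if down >= cfg.down_p25 else tss + cfg.down_p25
    else:
        up, down = best.end - (tss + 1), (tss + 1) - best.start
        end = best.end if up >= cfg.up_p25 else tss + 1 + cfg.up_p25
        start = best.start if down >= cfg.down_p25 else tss + 1 - cfg.down_p25
    return (start, end)


def extract_utr_regions(tx: TranscriptModel) -> list[NearCodingRegion]:
    """Extract UTR exon and UTR intron regions from one coding transcript.

    Exonic bases 5' of the CDS are five_utr and 3' are three_utr
    (strand-aware). An intron lying wholly outside the CDS span on the 5'
    side is a five_utr_intron (symmetric at the 3' end); introns between
    coding exons are excluded.
    """
    if not tx.is_coding:
        raise NonCodingTranscriptError(
            f"transcript {tx.transcript_id} has no CDS; UTRs are undefined"
        )
    left_label = FIVE_UTR if tx.strand == "+" else THREE_UTR
    right_label = THREE_UTR if tx.strand == "+" else FIVE_UTR
    left_intron = FIVE_UTR_INTRON if tx.strand == "+" else THREE_UTR_INTRON
    right_intron = THREE_UTR_INTRON if tx.strand == "+" else FIVE_UTR_INTRON

    out: list[NearCodingRegion] = []

    def add(start: int, end: int, label: str) -> None:
        if end > start:
            out.append(
                NearCodingRegion(
                    tx.chrom, start, end, label, tx.transcript_id, tx.gene_symbol
                )
            )

    for s, e in tx.exons:
        add(s, min(e, tx.cds_start), left_label)
        add(max(s, tx.cds_end), e, right_label)
    for s, e in tx.introns():
        if e <= tx.cds_start:
            add(s, e, left_intron)
        elif s >= tx.cds_end:
            add(s, e, right_intron)
        # introns overlapping the CDS span separate coding exons: excluded
    return out


def _merge(intervals: list[Interval]) -> list[Interval]:
    merged: list[list[int]] = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def _subtract_one(region: Interval, blocks: list[Interval]) -> list[Interval]:
    """Subtract sorted disjoint ``blocks`` from ``region``."""
    pieces = []
    cur = region[0]
    for s, e in blocks:
        if e <= region[0] or s >= region[1]:
            continue
        if s > cur:
            pieces.append((cur, min(s, region[1])))
        cur = max(cur, e)
        if cur >= region[1]:
            break
    if cur < region[1]:
        pieces.append((cur, region[1]))
    return pieces


def subtract_cds(
    regions: list[NearCodingRegion], all_tx: list[TranscriptModel]
) -> list[NearCodingRegion]:
    """Remove every base that is CDS-exonic in *any* transcript.

    Regions may be split; empty remnants are dropped; class and transcript
    attribution are preserved.
    """
    cds_by_chrom: dict[str, list[Interval]] = {}
    for tx in all_tx:
        cds_by_chrom.setdefault(tx.chrom, []).extend(tx.cds_intervals())
    cds_by_chrom = {c: _merge(iv) for c, iv in cds_by_chrom.items()}

    out: list[NearCodingRegion] = []
    for r in regions:
        blocks = cds_by_chrom.get(r.chrom, [])
        for s, e in _subtract_one((r.start, r.end), blocks):
            out.append(
                NearCodingRegion(
                    r.chrom, s, e, r.region_class, r.transcript_id, r.gene_symbol
                )
            )
    return out


def build_near_coding_regions(
    transcripts: list[TranscriptModel],
    ccres: list[CisElement],
    cfg: PromoterConfig = PromoterConfig(),
) -> list[NearCodingRegion]:
    """Full region set: promoters + UTR exons/introns, CDS-subtracted."""
    regions: list[NearCodingRegion] = []
    for tx in transcripts:
        s, e = derive_promoter(tx, ccres, cfg)
        regions.append(
            NearCodingRegion(tx.chrom, s, e, PROMOTER, tx.transcript_id, tx.gene_symbol)
        )
        regions.extend(extract_utr_regions(tx))
    return subtract_cds(regions, transcripts)


def assign_region(
    chrom: str,
    pos: int,
    ref: str,
    alt: str,
    regions: list[NearCodingRegion],
) -> RegionAssignment:
    """Classify a variant position against the near-coding region set.

    Returns every region class whose interval overlaps the reference span
    of the variant (``[pos, pos + len(ref))``, at least one base). The
    deep-intronic flag is set when the overlap with an intron-class region
    lies more than ``DEEP_INTRON_DISTANCE`` bases from both flanking exon
    boundaries of that intron.
    """
    span_start = pos
    span_end = pos + max(1, len(ref))
    classes: set[str] = set()
    deep = False
    for r in regions:
        if r.chrom != chrom or span_end <= r.start or span_start >= r.end:
            continue
        classes.add(r.region_class)
        if r.region_class in INTRON_CLASSES:
            ov_start = max(span_start, r.start)
            ov_end = min(span_end, r.end)
            d_left = ov_start - r.start + 1
            d_right = r.end - ov_end + 1
            if min(d_left, d_right) > DEEP_INTRON_DISTANCE:
                deep = True
    if not classes:
        logger.debug("position %s:%d outside all near-coding regions", chrom, pos)
    return RegionAssignment(classes, deep and bool(classes & INTRON_CLASSES))


def total_bases(regions: list[NearCodingRegion]) -> int:
    """Total near-coding bases, counting overlapping regions once."""
    by_chrom: dict[str, list[Interval]] = {}
    for r in regions:
        by_chrom.setdefault(r.chrom, []).append((r.start, r.end))
    return sum(e - s for iv in by_chrom.values() for s, e in _merge(iv))
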