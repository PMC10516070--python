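"""Sequence-level annotation of UTR variants on spliced transcripts.

Covers the 5'UTR translational-effect classes — upstream start codon
(uAUG) gain and loss, upstream stop loss, and upstream-ORF frameshift,
each with overlapping-ORF (oORF) logic and Kozak context strength — plus
disruption of the Kozak -3 position of the main CDS start, and 3'UTR
polyadenylation-signal disruption with rescue-motif rescanning.

An upstream ORF (uORF) is an upstream AUG whose first in-frame stop codon
lies entirely within the 5'UTR; when no such stop exists the ORF runs past
the CDS start and is an overlapping ORF (oORF), in frame with the CDS when
``(cds_offset - aug) % 3 == 0`` and out of frame otherwise. Kozak strength
is read from positions -3 and +4 around an AUG: strong = purine at -3 AND
G at +4; moderate = exactly one; weak = neither, with positions off the
sequence end counting as failing.

All motif logic operates on the DNA alphabet; ``U`` in inputs is
normalised to ``T``. Variants are expressed in transcript coordinates
(0-based, 5'->3'); ``project_to_transcript`` maps genomic VCF-style
variants onto a spliced transcript.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .regions import TranscriptModel

logger = logging.getLogger(__name__)

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
START_CODON = "ATG"

STRONG = "strong"
MODERATE = "moderate"
WEAK = "weak"

UAUG_GAIN = "uAUG_gain"
UAUG_LOSS = "uAUG_loss"
USTOP_LOSS = "uSTOP_loss"
UFRAMESHIFT = "uFrameshift"

UORF = "uORF"
INFRAME_OORF = "inFrame_oORF"
OUTOFFRAME_OORF = "outOfFrame_oORF"
OORF_OUTCOMES = frozenset({INFRAME_OORF, OUTOFFRAME_OORF})

#: the 12 hexamers whose creation rescues a disrupted polyadenylation signal
#: (DNA alphabet; includes the two canonical signals themselves).
POLYA_RESCUE_MOTIFS = (
    "AATAAA", "ATTAAA", "AGTAAA", "TATAAA", "CATAAA", "GATAAA",
    "AATATA", "AATACA", "AATAGA", "AAAAAG", "ACTAAA", "AAAAAA",
)
POLYA_SIGNALS = ("AATAAA", "ATTAAA")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def normalize(seq: str) -> str:
    return seq.upper().replace("U", "T")


@dataclass(frozen=True)
class TranscriptVariant:
    """A variant in spliced-transcript coordinates (0-based).

    ``ref`` may be empty for a pure insertion before ``pos``.
    """

    pos: int
    ref: str
    alt: str

    @property
    def delta(self) -> int:
        return len(self.alt) - len(self.ref)

    @property
    def end(self) -> int:
        return self.pos + len(self.ref)


@dataclass
class SplicedTranscriptSequence:
    """A spliced mRNA sequence (5'->3') with the CDS start located.

    ``genome_positions`` maps each transcript base to its genomic
    coordinate (descending for minus-strand transcripts); it is optional
    for purely sequence-level use.
    """

    sequence: str
    cds_offset: int
    cds_end_offset: int | None = None
    genome_positions: list[int] | None = None
    strand: str = "+"
    transcript_id: str = ""
    _index: dict[int, int] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self.sequence = normalize(self.sequence)
        if self.sequence[self.cds_offset : self.cds_offset + 3] != START_CODON:
            raise ValueError(
                f"no ATG at cds_offset {self.cds_offset} "
                f"({self.sequence[self.cds_offset:self.cds_offset + 3]!r})"
            )
        if self.genome_positions is not None:
            if len(self.genome_positions) != len(self.sequence):
                raise ValueError("genome map length mismatch")
            self._index = {g: i for i, g in enumerate(self.genome_positions)}

    @classmethod
    def from_transcript(
        cls, tx: TranscriptModel, genome: dict[str, str]
    ) -> "SplicedTranscriptSequence":
        """Splice a transcript's exons out of a genome and locate the CDS."""
        if not tx.is_coding:
            raise ValueError(f"{tx.transcript_id}: non-coding transcript")
        chrom_seq = genome[tx.chrom]
        if isinstance(chrom_seq, (bytes, bytearray)):
            chrom_seq = chrom_seq.decode()
        parts = [chrom_seq[s:e] for s, e in tx.exons]
        coords = [g for s, e in tx.exons for g in range(s, e)]
        seq = "".join(parts)
        if tx.strand == "-":
            seq = revcomp(seq)
            coords = coords[::-1]
        # transcript bases 5' of the CDS start
        if tx.strand == "+":
            cds_offset = sum(
                max(0, min(e, tx.cds_start) - s) for s, e in tx.exons
            )
        else:
            cds_offset = sum(max(0, e - max(s, tx.cds_end)) for s, e in tx.exons)
        cds_len = sum(e - s for s, e in tx.cds_intervals())
        return cls(
            sequence=seq,
            cds_offset=cds_offset,
            cds_end_offset=cds_offset + cds_len,
            genome_positions=coords,
            strand=tx.strand,
            transcript_id=tx.transcript_id,
        )

    def transcript_index(self, genomic_pos: int) -> int | None:
        return self._index.get(genomic_pos)


def kozak_strength(seq: str, aug_index: int) -> str:
    """Kozak context of the AUG at ``aug_index``: strong/moderate/weak.

    Only positions -3 and +4 are read; bases off either sequence end count
    as failing their test.
    """
    seq = normalize(seq)
    if seq[aug_index : aug_index + 3] != START_CODON:
        raise ValueError(f"no ATG at index {aug_index}")
    minus3_ok = aug_index >= 3 and seq[aug_index - 3] in "AG"
    plus4_ok = aug_index + 3 < len(seq) and seq[aug_index + 3] == "G"
    if minus3_ok and plus4_ok:
        return STRONG
    if minus3_ok or plus4_ok:
        return MODERATE
    return WEAK


@dataclass(frozen=True)
class UTRConsequence:
    """One 5'UTR translational-effect call."""

    effect_class: str
    orf_outcome: str
    kozak: str
    uaug_position: int


@dataclass(frozen=True)
class PolyASignalCall:
    """Outcome of scanning a 3'UTR variant against polyA signal hexamers."""

    motif_interval: tuple[int, int] | None
    disrupted: bool
    rescue_motif: str | None = None


def apply_variant(seq: str, v: TranscriptVariant) -> str:
    if seq[v.pos : v.end] != v.ref:
        raise ValueError(
            f"reference mismatch at {v.pos}: expected {v.ref!r}, "
            f"found {seq[v.pos:v.end]!r}"
        )
    return seq[: v.pos] + v.alt + seq[v.end :]


def _map_ref_to_alt(p: int, v: TranscriptVariant) -> int | None:
    """Map a ref index to the alt sequence; None inside the edited span."""
    if p < v.pos:
        return p
    if p >= v.end:
        return p + v.delta
    return None


def _map_alt_to_ref(p: int, v: TranscriptVariant) -> int | None:
    if p < v.pos:
        return p
    if p >= v.pos + len(v.alt):
        return p - v.delta
    return None


def upstream_augs(seq: str, cds_offset: int) -> list[int]:
    return [
        i for i in range(0, cds_offset) if seq[i : i + 3] == START_CODON
    ]


def orf_outcome(seq: str, aug: int, cds_offset: int) -> tuple[str, int | None]:
    """(outcome, stop_index) for the ORF starting at ``aug``.

    A uORF terminates at an in-frame stop lying entirely within the 5'UTR;
    otherwise the ORF overlaps the CDS start (oORF), in or out of frame.
    """
    k = aug + 3
    while k + 3 <= cds_offset:
        if seq[k : k + 3] in STOP_CODONS:
            return UORF, k
        k += 3
    if (cds_offset - aug) % 3 == 0:
        return INFRAME_OORF, None
    return OUTOFFRAME_OORF, None


def annotate_five_prime(
    variant: TranscriptVariant, ref_seq: SplicedTranscriptSequence
) -> list[UTRConsequence]:
    """Call 5'UTR translational effects of one variant.

    Compares the full sets of upstream AUGs, their frames, and stops
    between the reference and alternate spliced sequences. Emits uAUG_gain
    for AUGs present only in the alternate, uAUG_loss for AUGs present only
    in the reference, uSTOP_loss when a reference uORF's stop no longer
    terminates it, and uFrameshift for a frame-changing indel strictly
    inside a reference uORF body. Each call carries the ORF outcome and
    the Kozak strength of the relevant AUG, read from the alternate
    sequence for gains and the reference sequence otherwise.

    Variants not overlapping the 5'UTR, or not analysable on the spliced
    sequence (e.g. the edit removes the main start codon), yield an empty
    list.
    """
    ref = ref_seq.sequence
    cds = ref_seq.cds_offset
    in_utr = variant.pos < cds or (not variant.ref and variant.pos <= cds)
    if not in_utr:
        return []
    if variant.end > cds:
        logger.debug("edit extends into the CDS; not a pure 5'UTR variant")
        return []
    alt = apply_variant(ref, variant)
    alt_cds = cds + variant.delta
    if alt[alt_cds : alt_cds + 3] != START_CODON:
        logger.debug("alternate sequence lacks the CDS start codon")
        return []

    ref_augs = upstream_augs(ref, cds)
    alt_augs = upstream_augs(alt, alt_cds)

    surviving: list[tuple[int, int]] = []
    lost: list[int] = []
    for a in ref_augs:
        b = _map_ref_to_alt(a, variant)
        if b is not None and 0 <= b < alt_cds and alt[b : b + 3] == START_CODON:
            surviving.append((a, b))
        else:
            lost.append(a)
    survived_alt = {b for _, b in surviving}
    gained = [b for b in alt_augs if b not in survived_alt]

    out: list[UTRConsequence] = []
    for b in gained:
        outcome, _ = orf_outcome(alt, b, alt_cds)
        out.append(UTRConsequence(UAUG_GAIN, outcome, kozak_strength(alt, b), b))
    for a in lost:
        outcome, _ = orf_outcome(ref, a, cds)
        out.append(UTRConsequence(UAUG_LOSS, outcome, kozak_strength(ref, a), a))
    for a, b in surviving:
        ref_out, ref_stop = orf_outcome(ref, a, cds)
        if ref_out != UORF:
            continue
        koz = kozak_strength(ref, a)
        if (
            variant.delta % 3 != 0
            and variant.pos >= a + 3
            and variant.end <= ref_stop
        ):
            alt_out, _ = orf_outcome(alt, b, alt_cds)
            out.append(UTRConsequence(UFRAMESHIFT, alt_out, koz, a))
            continue
        s_alt = _map_ref_to_alt(ref_stop, variant)
        stop_intact = (
            s_alt is not None
            and s_alt + 3 <= alt_cds
            and (s_alt - b) % 3 == 0
            and alt[s_alt : s_alt + 3] in STOP_CODONS
        )
        if not stop_intact:
            alt_out, new_stop = orf_outcome(alt, b, alt_cds)
            # a new stop terminating the uORF *earlier* than the original
            # stop position is not a stop loss
            if ref_stop <= variant.pos:
                old_pos_alt = ref_stop
            else:
                old_pos_alt = max(variant.pos, ref_stop + variant.delta)
            if alt_out == UORF and new_stop is not None and new_stop < old_pos_alt:
                continue
            out.append(UTRConsequence(USTOP_LOSS, alt_out, koz, a))
    return out


def high_impact_utr_filter(c: UTRConsequence) -> bool:
    """High-impact 5'UTR rule used by the prioritisation cascade.

    True for uAUG gains, uSTOP losses, and uFrameshifts producing an oORF
    with a strong or moderate Kozak context, and for uAUG losses with a
    strong Kozak context.
    """
    oorf = c.orf_outcome in OORF_OUTCOMES
    strong_or_moderate = c.kozak in (STRONG, MODERATE)
    if c.effect_class == UAUG_GAIN:
        return oorf and strong_or_moderate
    if c.effect_class == USTOP_LOSS:
        return oorf and strong_or_moderate
    if c.effect_class == UAUG_LOSS:
        return c.kozak == STRONG
    if c.effect_class == UFRAMESHIFT:
        return oorf and strong_or_moderate
    return False


def kozak_minus3_disruption(
    variant: TranscriptVariant, seq: SplicedTranscriptSequence
) -> bool:
    """Substitution at the -3 position of the CDS AUG, purine -> pyrimidine.

    The rule covers single-base substitutions only; indels at the position
    return False.
    """
    if len(variant.ref) != 1 or len(variant.alt) != 1:
        return False
    if variant.pos != seq.cds_offset - 3:
        return False
    ref = normalize(variant.ref)
    alt = normalize(variant.alt)
    if seq.sequence[variant.pos] != ref:
        raise ValueError(f"reference mismatch at -3 position {variant.pos}")
    return ref in "AG" and alt in "CT"


def _map_span_to_alt(s: int, e: int, v: TranscriptVariant) -> tuple[int, int]:
    """Alt-sequence span covering all bases derived from ref span [s, e)."""
    if s <= v.pos:
        ns = s
    elif s >= v.end:
        ns = s + v.delta
    else:
        ns = v.pos
    if e <= v.pos:
        ne = e
    elif e >= v.end:
        ne = e + v.delta
    else:
        ne = v.pos + len(v.alt)
    return ns, max(ns, ne)


def polya_disruption(variant: TranscriptVariant, utr3_seq: str) -> PolyASignalCall:
    """Polyadenylation-signal disruption scan in a 3'UTR sequence.

    ``variant`` is in 3'UTR-local coordinates. A variant overlapping an
    AATAAA/ATTAAA occurrence is disruptive unless the altered window
    re-creates one of the 12 known signal motifs at any offset overlapping
    the original hexamer; the created motif is recorded in that case.
    """
    seq = normalize(utr3_seq)
    span_start, span_end = variant.pos, max(variant.pos + 1, variant.end)
    hits = []
    for motif in POLYA_SIGNALS:
        start = 0
        while True:
            m = seq.find(motif, start)
            if m < 0:
                break
            if m < span_end and m + 6 > span_start:
                hits.append(m)
            start = m + 1
    if not hits:
        return PolyASignalCall(None, False, None)

    alt = apply_variant(seq, variant)
    first_rescue: str | None = None
    first_hit = min(hits)
    for m in sorted(hits):
        ns, ne = _map_span_to_alt(m, m + 6, variant)
        rescue = None
        for j in range(max(0, ns - 5), min(len(alt) - 6, ne - 1) + 1):
            if alt[j : j + 6] in POLYA_RESCUE_MOTIFS:
                rescue = alt[j : j + 6]
                break
        if rescue is None:
            return PolyASignalCall((m, m + 6), True, None)
        if first_rescue is None:
            first_rescue = rescue
    return PolyASignalCall((first_hit, first_hit + 6), False, first_rescue)


def project_to_transcript(
    tx_seq: SplicedTranscriptSequence, chrom: str, pos: int, ref: str, alt: str
) -> TranscriptVariant | None:
    """Project a genomic VCF-style variant onto a spliced transcript.

    ``pos`` is 0-based. Returns None when any edited base falls outside
    the spliced exons or the edited bases are not contiguous in transcript
    space (e.g. a deletion spanning an exon-intron junction).
    """
    if tx_seq.genome_positions is None:
        raise ValueError("transcript sequence carries no genomic map")
    ref = normalize(ref)
    alt = normalize(alt)
    # trim shared prefix (VCF anchor bases), then shared suffix
    while ref and alt and ref[0] == alt[0]:
        ref, alt, pos = ref[1:], alt[1:], pos + 1
    while ref and alt and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    minus = tx_seq.strand == "-"

    if not ref and not alt:
        return None
    if not ref:
        # insertion between genomic pos-1 and pos
        anchor = tx_seq.transcript_index(pos - 1)
        if anchor is None:
            return None
        tpos = anchor + 1 if not minus else anchor
        return TranscriptVariant(tpos, "", alt if not minus else revcomp(alt))

    idx = [tx_seq.transcript_index(pos + i) for i in range(len(ref))]
    if any(i is None for i in idx):
        return None
    step = -1 if minus else 1
    if any(b - a != step for a, b in zip(idx, idx[1:])):
        return None
    tpos = min(idx)
    tref = ref if not minus else revcomp(ref)
    talt = alt if not minus else revcomp(alt)
    if tx_seq.sequence[tpos : tpos + len(tref)] != tref:
        raise ValueError(
            f"{tx_seq.transcript_id}: genome/transcript reference mismatch "
            f"at {chrom}:{pos}"
        )
    return TranscriptVariant(tpos, tref, talt)
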