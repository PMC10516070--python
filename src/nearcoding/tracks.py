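"""Overlay-track annotations and their track-specific sub-filters.

Covers simple positional overlap against functional element tracks (IRES,
miRNA binding sites, translated dORFs, RBP binding sites, TFBS
footprints), the benign-score exclusion applied to the high-background
IRES/miRNA tracks, the RBP binding-loss rule, dORF start/stop boundary
hits, the TFBS core-DHS footprint filter, and per-transcription-factor
aggregation of binding-change model predictions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

logger = logging.getLogger(__name__)

IRES = "IRES"
MIRNA = "miRNA"
DORF = "dORF"
RBP = "RBP"
TFBS = "TFBS"
TRACKS = (IRES, MIRNA, DORF, RBP, TFBS)

#: benign-evidence thresholds applied to IRES/miRNA overlaps
BENIGN_CADD_MAX = 22.7
BENIGN_PHYLOP_MAX = 1.879

#: TFBS binding-change classification and retention thresholds
TFBS_GAIN_THRESHOLD = 0.04
TFBS_LOSS_THRESHOLD = -0.04
TFBS_RETAIN_MEAN_LOSS = -0.4

#: RBP loss rule constants
RBP_MIN_REF_AFFINITY = 0.1
RBP_LOSS_RATIO = 1.0 / 3.0


@dataclass(frozen=True)
class FunctionalTrackElement:
    """One interval of a functional track, with track-specific attributes.

    dORF elements should carry ``start_codon`` and ``stop_codon``
    sub-intervals; TFBS footprints carry an ``in_core_dhs`` flag; RBP sites
    carry ``ref_affinity``/``alt_affinity``.
    """

    chrom: str
    start: int
    end: int
    track: str
    attributes: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"empty element [{self.start}, {self.end})")
        if self.track not in TRACKS:
            raise ValueError(f"unknown track {self.track!r}")


@dataclass(frozen=True)
class RBPSiteCall:
    ref_affinity: float
    alt_affinity: float
    loss: bool


@dataclass(frozen=True)
class TFBinding:
    """Per-model binding-change predictions for one transcription factor."""

    tf_name: str
    model_predictions: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.model_predictions) < 1:
            raise ValueError(f"{self.tf_name}: needs at least one model prediction")


@dataclass
class TFBSAggregate:
    """Per-TF mean binding-change scores for one variant, classified."""

    per_tf_score: dict[str, float]
    losses: dict[str, float]
    gains: dict[str, float]
    mean_loss_score: float | None
    mean_gain_score: float | None
    mean_total_score: float | None
    retained: bool


def _variant_span(pos: int, ref: str) -> tuple[int, int]:
    return pos, pos + max(1, len(ref))


def overlap_track(
    chrom: str,
    pos: int,
    ref: str,
    elements: list[FunctionalTrackElement],
    track: str,
) -> list[FunctionalTrackElement]:
    """All elements of ``track`` overlapping the variant's reference span."""
    s, e = _variant_span(pos, ref)
    return [
        el
        for el in elements
        if el.track == track and el.chrom == chrom and s < el.end and e > el.start
    ]


def benign_score_exclusion(
    cadd: float | None, phylop: float | None
) -> bool:
    """Exclude (True) when either score positively supports benignity.

    Applied only to IRES and miRNA overlaps. A missing score cannot trigger
    exclusion: exclusion requires positive evidence.
    """
    if cadd is not None and cadd <= BENIGN_CADD_MAX:
        return True
    if phylop is not None and phylop <= BENIGN_PHYLOP_MAX:
        return True
    return False


def rbp_loss(ref_affinity: float, alt_affinity: float) -> RBPSiteCall:
    """RBP binding-loss call: active reference site losing >2/3 of affinity."""
    for name, a in (("ref", ref_affinity), ("alt", alt_affinity)):
        if not 0.0 <= a <= 1.0:
            raise ValueError(f"{name}_affinity {a} outside [0, 1]")
    if ref_affinity == 0.0:
        return RBPSiteCall(ref_affinity, alt_affinity, False)
    loss = ref_affinity >= RBP_MIN_REF_AFFINITY and (
        alt_affinity / ref_affinity < RBP_LOSS_RATIO
    )
    return RBPSiteCall(ref_affinity, alt_affinity, loss)


def fabian_aggregate(
    bindings: list[TFBinding],
    loss_threshold: float = TFBS_LOSS_THRESHOLD,
    gain_threshold: float = TFBS_GAIN_THRESHOLD,
    retain_threshold: float = TFBS_RETAIN_MEAN_LOSS,
) -> TFBSAggregate:
    """Aggregate per-model binding-change predictions to a retention call.

    Each TF's score is the arithmetic mean of its model predictions;
    scores <= ``loss_threshold`` are predicted losses and
    >= ``gain_threshold`` predicted gains. The variant is retained when
    the mean over loss-classified TF scores is <= ``retain_threshold``.
    """
    per_tf = {
        b.tf_name: sum(b.model_predictions) / len(b.model_predictions)
        for b in bindings
    }
    losses = {tf: s for tf, s in per_tf.items() if s <= loss_threshold}
    gains = {tf: s for tf, s in per_tf.items() if s >= gain_threshold}
    mean_loss = sum(losses.values()) / len(losses) if losses else None
    mean_gain = sum(gains.values()) / len(gains) if gains else None
    mean_total = sum(per_tf.values()) / len(per_tf) if per_tf else None
    retained = mean_loss is not None and mean_loss <= retain_threshold
    return TFBSAggregate(per_tf, losses, gains, mean_loss, mean_gain, mean_total, retained)


def tfbs_core_dhs_filter(
    chrom: str,
    pos: int,
    ref: str,
    footprints: list[FunctionalTrackElement],
) -> bool:
    """Keep (True) only variants inside a footprint in a core DHS region."""
    return any(
        el.attributes.get("in_core_dhs")
        for el in overlap_track(chrom, pos, ref, footprints, TFBS)
    )


def dorf_boundary_hit(
    chrom: str, pos: int, ref: str, dorf: FunctionalTrackElement
) -> bool:
    """True when the variant hits a dORF's start- or stop-codon interval.

    Falls back to whole-element overlap, with a warning, when the codon
    sub-intervals are missing from the element attributes.
    """
    s, e = _variant_span(pos, ref)
    start_codon = dorf.attributes.get("start_codon")
    stop_codon = dorf.attributes.get("stop_codon")
    if start_codon is None or stop_codon is None:
        logger.warning(
            "dORF element %s:%d-%d lacks codon sub-intervals; "
            "falling back to whole-interval overlap",
            dorf.chrom, dorf.start, dorf.end,
        )
        return dorf.chrom == chrom and s < dorf.end and e > dorf.start
    if dorf.chrom != chrom:
        return False
    for cs, ce in (tuple(start_codon), tuple(stop_codon)):
        if s < ce and e > cs:
            return True
    return False
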