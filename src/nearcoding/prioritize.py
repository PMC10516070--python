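"""Arm-aware, region-specific variant prioritisation cascade.

Applies cohort/allele-frequency pre-filters and ClinVar-benign exclusion,
then assembles per-region annotation triggers: the high-impact 5'UTR
translational rules, IRES/miRNA overlap with benign-score exclusion,
Kozak -3 disruption, polyadenylation-signal disruption, RBP binding loss,
dORF boundary hits, splice-disruption score thresholds on all UTR exons
and introns, TFBS binding-loss in promoters, and CADD/PhyloP evidence
flags everywhere except deep introns. A variant is retained exactly when
at least one annotation triggers.

The de novo arm uses a sensitive splice-score cutoff (0.2) and the burden
arm a stricter one (0.5); allele-frequency pre-filters also differ
between arms.
"""

from __future__ import annotations

import importlib.resources
import logging
from dataclasses import dataclass, field

import pandas as pd

from . import seq_effects, tracks
from .regions import (
    FIVE_UTR,
    PROMOTER,
    THREE_UTR,
    UTR_CLASSES,
    NearCodingRegion,
    RegionAssignment,
    TranscriptModel,
    assign_region,
)
from .seq_effects import (
    SplicedTranscriptSequence,
    TranscriptVariant,
    UTRConsequence,
    high_impact_utr_filter,
    project_to_transcript,
)

logger = logging.getLogger(__name__)

DE_NOVO = "de_novo"
BURDEN = "burden"

ANNOTATION_LABELS = (
    "uorf_high_impact",
    "ires",
    "kozak",
    "polya",
    "mirna",
    "rbp_loss",
    "dorf_boundary",
    "spliceai",
    "tfbs_loss",
    "cadd_flag",
    "phylop_flag",
)

CLINVAR_BENIGN = frozenset(
    {"benign", "likely benign", "benign/likely benign", "protective"}
)


@dataclass
class ScoreBundle:
    """Pre-computed scores and frequencies carried by one variant."""

    cadd_phred: float | None = None
    phylop: float | None = None
    spliceai_max: float | None = None
    clinvar_status: str | None = None
    af_internal: float = 0.0
    af_gnomad_popmax: float = 0.0
    ac_internal: int = 0


@dataclass
class CohortFlags:
    """Cohort-level booleans consumed by the de novo pre-filter."""

    pass_filter: bool = True
    is_proband: bool = True
    parents_unaffected_no_hpo: bool = True
    has_coding_diagnosis: bool = False
    in_green_dominant_panel_region: bool = True


@dataclass
class AnnotatedVariant:
    """One variant with its region classes, scores, and annotation inputs.

    ``track_hits`` carries per-track booleans *after* the track-specific
    sub-filters (RBP loss rule, dORF boundary rule, TFBS core-DHS +
    binding-loss aggregation); the IRES/miRNA flags are raw overlaps, with
    the benign-score exclusion applied inside the cascade since it reads
    the variant's scores.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    region: RegionAssignment
    scores: ScoreBundle = field(default_factory=ScoreBundle)
    utr_consequences: list[UTRConsequence] = field(default_factory=list)
    kozak_hit: bool = False
    polya_hit: bool = False
    track_hits: dict[str, bool] = field(default_factory=dict)
    gene_symbol: str = ""
    transcript_id: str = ""
    variant_id: str = ""


@dataclass
class PrioritizationDecision:
    retained: bool
    triggered_annotations: set[str]
    arm: str

    def __post_init__(self) -> None:
        assert self.retained == bool(self.triggered_annotations), (
            "retained flag must mirror a non-empty trigger set"
        )


@dataclass(frozen=True)
class ArmThresholds:
    """Score cutoffs and allele-frequency limits for one analysis arm."""

    arm: str
    spliceai_cutoff: float
    cadd_flag: float = 25.3
    phylop_flag: float = 7.367
    benign_cadd: float = tracks.BENIGN_CADD_MAX
    benign_phylop: float = tracks.BENIGN_PHYLOP_MAX
    af_max: float = 5e-5
    af_gnomad_max: float = 5e-4
    ac_max: int = 5
    af_inclusive: bool = False

    @classmethod
    def de_novo(cls) -> "ArmThresholds":
        return cls(arm=DE_NOVO, spliceai_cutoff=0.2)

    @classmethod
    def burden(cls) -> "ArmThresholds":
        return cls(
            arm=BURDEN,
            spliceai_cutoff=0.5,
            af_gnomad_max=5e-5,
            af_inclusive=True,
        )

    @classmethod
    def for_arm(cls, arm: str) -> "ArmThresholds":
        if arm == DE_NOVO:
            return cls.de_novo()
        if arm == BURDEN:
            return cls.burden()
        raise ValueError(f"unknown arm {arm!r}")


def dnv_prefilter(
    scores: ScoreBundle,
    flags: CohortFlags,
    thresholds: ArmThresholds | None = None,
    exclude_if_either: bool = True,
) -> bool:
    """De novo arm pre-filter: call quality, rarity, cohort eligibility.

    Internal rarity excludes a variant when AF >= 5e-5 or AC >= 5
    (``exclude_if_either``; with False, both must hold to exclude);
    population-maximum external frequency must be < 5e-4. The proband must
    pass call filters, carry the region in a confidently disease-associated
    dominant panel gene, have unaffected parents with no phenotype terms,
    and no existing coding diagnosis.
    """
    thr = thresholds or ArmThresholds.de_novo()
    if not (
        flags.pass_filter
        and flags.is_proband
        and flags.parents_unaffected_no_hpo
        and not flags.has_coding_diagnosis
        and flags.in_green_dominant_panel_region
    ):
        return False
    af = scores.af_internal
    if af is None:
        logger.warning("missing internal AF treated as 0")
        af = 0.0
    af_hit = af >= thr.af_max
    ac_hit = scores.ac_internal >= thr.ac_max
    if exclude_if_either:
        if af_hit or ac_hit:
            return False
    elif af_hit and ac_hit:
        return False
    popmax = scores.af_gnomad_popmax or 0.0
    return popmax < thr.af_gnomad_max


def burden_prefilter(
    scores: ScoreBundle, thresholds: ArmThresholds | None = None
) -> bool:
    """Burden arm rarity pre-filter (inclusive AF bounds, AC < 5)."""
    thr = thresholds or ArmThresholds.burden()
    af = scores.af_internal or 0.0
    popmax = scores.af_gnomad_popmax or 0.0
    return (
        af <= thr.af_max
        and popmax <= thr.af_gnomad_max
        and scores.ac_internal < thr.ac_max
    )


def clinvar_benign_exclusion(status: str | None) -> bool:
    """True (exclude) for benign / likely benign / combined / protective."""
    if status is None:
        return False
    norm = status.strip().lower().replace("_", " ")
    return norm in CLINVAR_BENIGN


def prioritize(
    v: AnnotatedVariant,
    arm: str = DE_NOVO,
    thresholds: ArmThresholds | None = None,
) -> PrioritizationDecision:
    """Assemble region-gated annotation triggers and decide retention."""
    thr = thresholds or ArmThresholds.for_arm(arm)
    triggered: set[str] = set()
    classes = v.region.region_classes
    s = v.scores
    if not classes:
        return PrioritizationDecision(False, set(), arm)

    benign_scores = tracks.benign_score_exclusion(s.cadd_phred, s.phylop)

    if FIVE_UTR in classes:
        if any(high_impact_utr_filter(c) for c in v.utr_consequences):
            triggered.add("uorf_high_impact")
        if v.track_hits.get("ires") and not benign_scores:
            triggered.add("ires")
        if v.kozak_hit:
            triggered.add("kozak")
    if THREE_UTR in classes:
        if v.polya_hit:
            triggered.add("polya")
        if v.track_hits.get("mirna") and not benign_scores:
            triggered.add("mirna")
        if v.track_hits.get("rbp_loss"):
            triggered.add("rbp_loss")
        if v.track_hits.get("dorf_boundary"):
            triggered.add("dorf_boundary")
    if classes & UTR_CLASSES:
        if s.spliceai_max is not None and s.spliceai_max >= thr.spliceai_cutoff:
            triggered.add("spliceai")
    if PROMOTER in classes and v.track_hits.get("tfbs_loss"):
        triggered.add("tfbs_loss")
    if not v.region.deep_intronic:
        if s.cadd_phred is not None and s.cadd_phred >= thr.cadd_flag:
            triggered.add("cadd_flag")
        if s.phylop is not None and s.phylop >= thr.phylop_flag:
            triggered.add("phylop_flag")
    return PrioritizationDecision(bool(triggered), triggered, arm)


# ---------------------------------------------------------------------------
# Pipeline orchestration: raw variant -> AnnotatedVariant -> decision
# ---------------------------------------------------------------------------


def annotate_variant(
    chrom: str,
    pos: int,
    ref: str,
    alt: str,
    scores: ScoreBundle,
    regions: list[NearCodingRegion],
    spliced: dict[str, SplicedTranscriptSequence],
    track_elements: list[tracks.FunctionalTrackElement] | None = None,
    tf_predictions: pd.DataFrame | None = None,
    variant_id: str = "",
) -> AnnotatedVariant:
    """Run all annotation layers for one raw variant.

    ``spliced`` maps transcript_id to its spliced sequence; ``tf_predictions``
    is a long table (variant_id, tf_name, model_id, value) of per-model
    binding-change predictions.
    """
    track_elements = track_elements or []
    region = assign_region(chrom, pos, ref, alt, regions)
    utr_cons: list[UTRConsequence] = []
    kozak_hit = False
    polya_hit = False
    gene_symbol = ""
    transcript_id = ""

    span_end = pos + max(1, len(ref))
    host_tx = {
        r.transcript_id: r.region_class
        for r in regions
        if r.chrom == chrom
        and r.start < span_end
        and r.end > pos
        and r.region_class in (FIVE_UTR, THREE_UTR)
    }
    for tx_id, rclass in host_tx.items():
        seq = spliced.get(tx_id)
        if seq is None:
            continue
        tvar = project_to_transcript(seq, chrom, pos, ref, alt)
        if tvar is None:
            continue
        transcript_id = transcript_id or tx_id
        if rclass == FIVE_UTR:
            utr_cons.extend(seq_effects.annotate_five_prime(tvar, seq))
            kozak_hit = kozak_hit or seq_effects.kozak_minus3_disruption(tvar, seq)
        elif rclass == THREE_UTR and seq.cds_end_offset is not None:
            off = seq.cds_end_offset
            if tvar.pos >= off:
                local = TranscriptVariant(tvar.pos - off, tvar.ref, tvar.alt)
                call = seq_effects.polya_disruption(local, seq.sequence[off:])
                polya_hit = polya_hit or call.disrupted

    for r in regions:
        if r.chrom == chrom and r.start < span_end and r.end > pos and r.gene_symbol:
            gene_symbol = r.gene_symbol
            break

    track_hits: dict[str, bool] = {}
    track_hits["ires"] = bool(
        tracks.overlap_track(chrom, pos, ref, track_elements, tracks.IRES)
    )
    track_hits["mirna"] = bool(
        tracks.overlap_track(chrom, pos, ref, track_elements, tracks.MIRNA)
    )
    rbp_hits = tracks.overlap_track(chrom, pos, ref, track_elements, tracks.RBP)
    track_hits["rbp_loss"] = any(
        tracks.rbp_loss(
            el.attributes.get("ref_affinity", 0.0),
            el.attributes.get("alt_affinity", 0.0),
        ).loss
        for el in rbp_hits
    )
    dorf_hits = tracks.overlap_track(chrom, pos, ref, track_elements, tracks.DORF)
    track_hits["dorf_boundary"] = any(
        tracks.dorf_boundary_hit(chrom, pos, ref, el) for el in dorf_hits
    )
    tfbs_ok = tracks.tfbs_core_dhs_filter(chrom, pos, ref, track_elements)
    tfbs_retained = False
    if tfbs_ok and tf_predictions is not None and len(tf_predictions):
        rows = tf_predictions[tf_predictions["variant_id"] == variant_id]
        bindings = [
            tracks.TFBinding(tf, tuple(grp["value"]))
            for tf, grp in rows.groupby("tf_name")
        ]
        if bindings:
            tfbs_retained = tracks.fabian_aggregate(bindings).retained
    track_hits["tfbs_loss"] = tfbs_retained

    return AnnotatedVariant(
        chrom=chrom,
        pos=pos,
        ref=ref,
        alt=alt,
        region=region,
        scores=scores,
        utr_consequences=utr_cons,
        kozak_hit=kozak_hit,
        polya_hit=polya_hit,
        track_hits=track_hits,
        gene_symbol=gene_symbol,
        transcript_id=transcript_id,
        variant_id=variant_id,
    )


def run_cascade(
    variants: pd.DataFrame,
    regions: list[NearCodingRegion],
    transcripts: list[TranscriptModel],
    genome: dict[str, str],
    track_elements: list[tracks.FunctionalTrackElement] | None = None,
    tf_predictions: pd.DataFrame | None = None,
    arm: str = DE_NOVO,
) -> pd.DataFrame:
    """Annotate and prioritise a variant table end to end.

    ``variants`` columns: variant_id, chrom, pos (0-based), ref, alt, and
    optional score columns (cadd_phred, phylop, spliceai_max,
    clinvar_status, af_internal, ac_internal, af_gnomad_popmax). Returns
    one row per variant with the decision and triggered annotations; the
    arm's rarity pre-filter and ClinVar-benign exclusion are applied ahead
    of the cascade.
    """
    thr = ArmThresholds.for_arm(arm)
    spliced = {}
    for tx in transcripts:
        if tx.is_coding:
            spliced[tx.transcript_id] = SplicedTranscriptSequence.from_transcript(
                tx, genome
            )
    rows = []
    for rec in variants.to_dict("records"):
        clnsig = rec.get("clinvar_status")
        if not isinstance(clnsig, str) or not clnsig:
            clnsig = None
        scores = ScoreBundle(
            cadd_phred=_opt(rec.get("cadd_phred")),
            phylop=_opt(rec.get("phylop")),
            spliceai_max=_opt(rec.get("spliceai_max")),
            clinvar_status=clnsig,
            af_internal=rec.get("af_internal", 0.0) or 0.0,
            af_gnomad_popmax=rec.get("af_gnomad_popmax", 0.0) or 0.0,
            ac_internal=int(rec.get("ac_internal", 0) or 0),
        )
        vid = str(rec.get("variant_id", ""))
        excluded = clinvar_benign_exclusion(scores.clinvar_status)
        if arm == BURDEN:
            prefilter_ok = burden_prefilter(scores, thr)
        else:
            prefilter_ok = dnv_prefilter(scores, CohortFlags(), thr)
        if excluded or not prefilter_ok:
            decision = PrioritizationDecision(False, set(), arm)
        else:
            av = annotate_variant(
                rec["chrom"],
                int(rec["pos"]),
                rec["ref"],
                rec["alt"],
                scores,
                regions,
                spliced,
                track_elements,
                tf_predictions,
                variant_id=vid,
            )
            decision = prioritize(av, arm, thr)
        rows.append(
            {
                "variant_id": vid,
                "chrom": rec["chrom"],
                "pos": int(rec["pos"]),
                "ref": rec["ref"],
                "alt": rec["alt"],
                "retained": decision.retained,
                "triggered_annotations": ",".join(
                    sorted(decision.triggered_annotations)
                ),
            }
        )
    return pd.DataFrame(rows)


def _opt(x) -> float | None:
    if x is None:
        return None
    try:
        xf = float(x)
    except (TypeError, ValueError):
        return None
    return None if pd.isna(xf) else xf


# ---------------------------------------------------------------------------
# Replay of the published candidate de novo table
# ---------------------------------------------------------------------------


def load_table1() -> list[AnnotatedVariant]:
    """The 11 published candidate de novo variants, as printed.

    Each row encodes the printed region annotation and variant annotation
    (splice-disruption score, CADD/PhyloP, 5'UTR effect) of one candidate
    variant; Kozak strengths not printed in the table are set to values
    consistent with the accompanying text.
    """
    path = importlib.resources.files("nearcoding.data").joinpath("table1.tsv")
    with importlib.resources.as_file(path) as p:
        df = pd.read_csv(p, sep="\t")
    out = []
    for rec in df.to_dict("records"):
        classes = set(str(rec["region_classes"]).split(","))
        region = RegionAssignment(classes, bool(rec["deep_intronic"]))
        cons = []
        if isinstance(rec["utr_effect"], str) and rec["utr_effect"] not in ("", "-"):
            eff, outcome, koz = rec["utr_effect"].split(":")
            cons.append(UTRConsequence(eff, outcome, koz, 0))
        chrom, pos, ref, alt = (
            rec["chrom"],
            int(rec["pos"]),
            rec["ref"],
            rec["alt"],
        )
        out.append(
            AnnotatedVariant(
                chrom=chrom,
                pos=pos,
                ref=ref,
                alt=alt,
                region=region,
                scores=ScoreBundle(
                    cadd_phred=_opt(rec["cadd_phred"]),
                    phylop=_opt(rec["phylop"]),
                    spliceai_max=_opt(rec["spliceai_max"]),
                ),
                utr_consequences=cons,
                gene_symbol=rec["gene"],
                transcript_id=rec["transcript"],
                variant_id=f"{chrom}:{pos}{ref}>{alt}",
            )
        )
    return out


def replay_table1(
    rows: list[AnnotatedVariant] | None = None, arm: str = DE_NOVO
) -> int:
    """Number of the published candidate variants retained under ``arm``."""
    if rows is None:
        rows = load_table1()
    return sum(prioritize(v, arm).retained for v in rows)
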