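"""Seeded synthetic fixtures for every input the pipeline consumes.

Generates a toy genome with non-overlapping multi-exon transcripts on both
strands (5'UTR with one intervening intron, split CDS, 3'UTR, some with a
3'UTR intron), promoter-like cis elements over a configurable fraction of
TSSs, and a set of planted variants whose annotation class is known by
construction: the generator writes the required sequence context (start
codon context, upstream stops, polyadenylation hexamers), synthesises
score columns consistent with the intended truth, and then verifies every
planted call by running the package's own annotation cascade before
returning. Background variants are verified to trigger nothing.

A separate cohort simulator draws matched-cohort inputs (participants with
sex/ancestry labels, kinship pairs, Bernoulli carrier status per arm) for
the burden-testing module.

All generators are deterministic for a fixed seed and spec.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .prioritize import BURDEN, DE_NOVO, run_cascade
from .regions import (
    CisElement,
    NearCodingRegion,
    PromoterConfig,
    TranscriptModel,
    build_near_coding_regions,
    extract_utr_regions,
)
from .seq_effects import (
    START_CODON,
    STOP_CODONS,
    SplicedTranscriptSequence,
)
from .tracks import FunctionalTrackElement

logger = logging.getLogger(__name__)

EFFECT_CLASSES = (
    "uAUG_gain_oORF",
    "uSTOP_loss",
    "uAUG_loss",
    "uFrameshift",
    "polyA_disrupt",
    "kozak_minus3",
    "spliceai_high",
    "tfbs_loss",
    "rbp_loss",
    "benign_background",
)

#: triggered-annotation label each planted class must produce
EXPECTED_TRIGGER = {
    "uAUG_gain_oORF": "uorf_high_impact",
    "uSTOP_loss": "uorf_high_impact",
    "uAUG_loss": "uorf_high_impact",
    "uFrameshift": "uorf_high_impact",
    "polyA_disrupt": "polya",
    "kozak_minus3": "kozak",
    "spliceai_high": "spliceai",
    "tfbs_loss": "tfbs_loss",
    "rbp_loss": "rbp_loss",
}

_BASES = "ACGT"
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


class PlantingError(RuntimeError):
    """A planted effect could not be constructed or did not verify."""


@dataclass
class CohortSpec:
    """Matched-cohort simulation parameters.

    Defaults are the conditions of the package's power analysis: 2,000
    participants per arm with carrier probabilities 0.10 (cases) versus
    0.05 (controls), a two-ancestry mix, and a handful of injected
    third-degree-or-closer relative pairs.
    """

    n_cases: int = 2000
    n_controls: int = 2000
    carrier_p_case: float = 0.10
    carrier_p_control: float = 0.05
    ancestry_mix: tuple[tuple[str, float], ...] = (("EUR", 0.8), ("SAS", 0.2))
    related_pairs: int = 5

    def __post_init__(self) -> None:
        for p in (self.carrier_p_case, self.carrier_p_control):
            if not 0.0 <= p <= 1.0:
                raise ValueError("carrier probabilities must be in [0, 1]")
        if abs(sum(f for _, f in self.ancestry_mix) - 1.0) > 1e-9:
            raise ValueError("ancestry fractions must sum to 1")


@dataclass
class FixtureSpec:
    """Parameters of the synthetic genome/variant fixture."""

    seed: int = 0
    n_transcripts: int = 15
    genome_length: int | None = None  # derived from the layout when None
    fraction_with_ccre: float = 0.6
    planted_effects: tuple[tuple[str, int], ...] = (
        ("uAUG_gain_oORF", 2),
        ("uSTOP_loss", 1),
        ("uAUG_loss", 1),
        ("uFrameshift", 1),
        ("polyA_disrupt", 1),
        ("kozak_minus3", 1),
        ("spliceai_high", 2),
        ("tfbs_loss", 1),
        ("rbp_loss", 1),
        ("benign_background", 4),
    )
    cohort: CohortSpec = field(default_factory=CohortSpec)

    def __post_init__(self) -> None:
        for cls, n in self.planted_effects:
            if cls not in EFFECT_CLASSES:
                raise ValueError(f"unknown planted effect class {cls!r}")
            if n < 0:
                raise ValueError("planted counts must be >= 0")


@dataclass(frozen=True)
class TruthEntry:
    effect_class: str
    expected_triggers: frozenset[str]
    expected_retained: dict


@dataclass
class PlantedFixture:
    """Planted variants with ground truth and supporting tracks."""

    variants: pd.DataFrame
    truth: dict[str, TruthEntry]
    track_elements: list[FunctionalTrackElement]
    tf_predictions: pd.DataFrame
    regions: list[NearCodingRegion]


# ---------------------------------------------------------------------------
# Genome and transcript generation
# ---------------------------------------------------------------------------


def _tx_coords(tx: TranscriptModel) -> list[int]:
    coords = [g for s, e in tx.exons for g in range(s, e)]
    return coords[::-1] if tx.strand == "-" else coords


def make_genome_and_transcripts(
    spec: FixtureSpec,
) -> tuple[dict[str, bytearray], list[TranscriptModel], list[CisElement]]:
    """Build a toy genome, transcript models, and a cis-element track.

    Transcripts are non-overlapping, on both strands, each with a 5'UTR
    split by an intron, a CDS split by a coding intron, and a 3'UTR (every
    third transcript's 3'UTR also carries an intron). Promoter-like cis
    elements are placed over ``fraction_with_ccre`` of TSSs with extents
    spanning both deficient and sufficient cases.
    """
    rng = np.random.default_rng(spec.seed)
    chrom = "chr1"
    cursor = 400
    layouts = []
    for i in range(spec.n_transcripts):
        strand = "+" if rng.random() < 0.5 else "-"
        u1 = int(rng.integers(90, 141))
        i1 = int(rng.integers(120, 261))
        u2 = int(rng.integers(25, 61))
        cds_len = int(rng.integers(60, 91)) * 3
        c1 = int(rng.integers(24, cds_len - 24))
        i2 = int(rng.integers(100, 201))
        u3a = int(rng.integers(130, 181))
        segs: list[tuple[str, int]] = [
            ("exon", u1),
            ("intron", i1),
            ("exon", u2 + c1),
            ("intron", i2),
        ]
        if i % 3 == 0:
            i3 = int(rng.integers(100, 151))
            u3b = int(rng.integers(80, 121))
            segs += [("exon", (cds_len - c1) + 40), ("intron", i3), ("exon", u3b)]
            # 40 bp of 3'UTR in the CDS-end exon, rest after the intron
        else:
            segs += [("exon", (cds_len - c1) + u3a)]
        total = sum(n for _, n in segs)
        g0 = cursor
        cursor = g0 + total + int(rng.integers(600, 901))
        layouts.append((strand, segs, u1, u2, cds_len, g0, total))

    genome_len = spec.genome_length or (cursor + 400)
    if genome_len < cursor + 400:
        raise ValueError(
            f"genome_length {genome_len} too small for {spec.n_transcripts} "
            f"transcripts (needs >= {cursor + 400})"
        )
    seq = rng.integers(0, 4, size=genome_len)
    genome = {chrom: bytearray("".join(_BASES[b] for b in seq).encode())}

    transcripts: list[TranscriptModel] = []
    for i, (strand, segs, u1, u2, cds_len, g0, total) in enumerate(layouts):
        # lay segments genomically: transcript order left->right on '+',
        # right->left on '-'
        exons: list[tuple[int, int]] = []
        if strand == "+":
            pos = g0
            for kind, n in segs:
                if kind == "exon":
                    exons.append((pos, pos + n))
                pos += n
        else:
            pos = g0 + total
            for kind, n in segs:
                if kind == "exon":
                    exons.append((pos - n, pos))
                pos -= n
            exons.sort()
        # CDS transcript span [u1+u2, u1+u2+cds_len)
        coords_tmp = [g for s, e in exons for g in range(s, e)]
        if strand == "-":
            coords_tmp = coords_tmp[::-1]
        cds_lo = coords_tmp[u1 + u2]
        cds_hi = coords_tmp[u1 + u2 + cds_len - 1]
        cds_start, cds_end = min(cds_lo, cds_hi), max(cds_lo, cds_hi) + 1
        tx = TranscriptModel(
            transcript_id=f"TX{i + 1:03d}",
            gene_symbol=f"GENE{i + 1}",
            chrom=chrom,
            strand=strand,
            exons=exons,
            cds_start=cds_start,
            cds_end=cds_end,
        )
        transcripts.append(tx)
        coords = _tx_coords(tx)
        _write_tx(genome, tx, coords, u1 + u2, START_CODON)
        _write_tx(genome, tx, coords, u1 + u2 + cds_len - 3, "TAA")

    ccres: list[CisElement] = []
    for tx in transcripts:
        if rng.random() >= spec.fraction_with_ccre:
            continue
        up_ext = int(rng.integers(100, 321))
        down_ext = int(rng.integers(30, 161))
        tss = tx.tss
        if tx.strand == "+":
            ccres.append(CisElement(tx.chrom, tss - up_ext, tss + down_ext))
        else:
            ccres.append(CisElement(tx.chrom, tss + 1 - down_ext, tss + 1 + up_ext))
    return genome, transcripts, ccres


def genome_as_str(genome: dict[str, bytearray]) -> dict[str, str]:
    return {c: bytes(s).decode() for c, s in genome.items()}


def _write_tx(
    genome: dict[str, bytearray],
    tx: TranscriptModel,
    coords: list[int],
    t: int,
    bases: str,
) -> None:
    """Write ``bases`` at transcript position ``t`` (transcript orientation)."""
    for k, b in enumerate(bases):
        g = coords[t + k]
        genome[tx.chrom][g] = ord(b if tx.strand == "+" else _COMP[b])


# ---------------------------------------------------------------------------
# Variant planting
# ---------------------------------------------------------------------------


@dataclass
class _Planted:
    chrom: str
    pos: int  # 0-based genomic VCF position
    ref: str
    alt: str
    effect_class: str
    scores: dict


def _benign_scores() -> dict:
    return {
        "cadd_phred": 12.0,
        "phylop": 0.5,
        "spliceai_max": 0.01,
        "clinvar_status": "",
        "af_internal": 1e-6,
        "ac_internal": 1,
        "af_gnomad_popmax": 1e-6,
    }


class _TxEditor:
    """Transcript-space view of the genome with write-through edits."""

    def __init__(self, genome: dict[str, bytearray], tx: TranscriptModel):
        self.genome = genome
        self.tx = tx
        self.coords = _tx_coords(tx)
        self.spl = SplicedTranscriptSequence.from_transcript(
            tx, genome_as_str(genome)
        )
        self.seq = list(self.spl.sequence)
        self.cds = self.spl.cds_offset
        self.cds_end = self.spl.cds_end_offset

    def write(self, t: int, bases: str) -> None:
        _write_tx(self.genome, self.tx, self.coords, t, bases)
        for k, b in enumerate(bases):
            self.seq[t + k] = b

    def scrub_stops(self, start: int, end: int, frame_anchor: int | None = None,
                    protect: tuple[int, int] | None = None) -> None:
        """Rewrite stop codons in [start, end) to non-stops.

        With ``frame_anchor`` only codons in that frame are scrubbed;
        otherwise all offsets. ``protect`` shields a codon interval.
        """
        step = 3 if frame_anchor is not None else 1
        k = start if frame_anchor is None else start + (
            (frame_anchor - start) % 3
        )
        while k + 3 <= end:
            if protect and k + 3 > protect[0] and k < protect[1]:
                k += step
                continue
            if "".join(self.seq[k : k + 3]) in STOP_CODONS:
                self.write(k, "C")
            k += step

    def snv(self, t: int, alt_base: str, effect: str) -> _Planted:
        g = self.coords[t]
        ref_g = chr(self.genome[self.tx.chrom][g])
        alt_g = alt_base if self.tx.strand == "+" else _COMP[alt_base]
        if ref_g == alt_g:
            raise PlantingError(f"SNV ref==alt at {g}")
        return _Planted(self.tx.chrom, g, ref_g, alt_g, effect, _benign_scores())

    def deletion(self, t: int, effect: str) -> _Planted:
        """One-base deletion of transcript base ``t``, VCF-anchored."""
        gdel = self.coords[t]
        anchor = gdel - 1
        chrom_seq = self.genome[self.tx.chrom]
        ref = chr(chrom_seq[anchor]) + chr(chrom_seq[gdel])
        return _Planted(self.tx.chrom, anchor, ref, ref[0], effect, _benign_scores())


def _plant_uaug_gain(ed: _TxEditor) -> _Planted:
    cds = ed.cds
    p = cds - 20
    p -= (cds - p) % 3 == 0  # force out-of-frame
    if p < 6:
        raise PlantingError("5'UTR too short for uAUG gain")
    ed.write(p - 3, "A")
    ed.write(p, "ACG")
    ed.write(p + 3, "G")
    ed.scrub_stops(p + 3, cds, frame_anchor=p)
    return ed.snv(p + 1, "T", "uAUG_gain_oORF")


def _plant_ustop_loss(ed: _TxEditor) -> _Planted:
    cds = ed.cds
    p = max(3, cds - 30)
    q = p + 6
    if q + 3 > cds:
        raise PlantingError("5'UTR too short for uSTOP loss")
    ed.write(p - 3, "A")
    ed.write(p, START_CODON)
    ed.write(p + 3, "G")
    ed.write(q, "TGA")
    ed.scrub_stops(q + 3, cds, frame_anchor=p)
    return ed.snv(q + 1, "C", "uSTOP_loss")


def _plant_uaug_loss(ed: _TxEditor) -> _Planted:
    cds = ed.cds
    p = max(3, cds - 15)
    if p + 4 > cds:
        raise PlantingError("5'UTR too short for uAUG loss")
    ed.write(p - 3, "A")
    ed.write(p, START_CODON)
    ed.write(p + 3, "G")
    return ed.snv(p + 1, "C", "uAUG_loss")


def _plant_uframeshift(ed: _TxEditor) -> _Planted:
    cds = ed.cds
    p = max(3, cds - 33)
    q = p + 9
    if q + 3 > cds:
        raise PlantingError("5'UTR too short for uFrameshift")
    ed.write(p - 3, "A")
    ed.write(p, START_CODON)
    ed.write(p + 3, "GCC")
    ed.write(p + 6, "CAC")
    ed.write(q, "TGA")
    ed.scrub_stops(3, cds, frame_anchor=None, protect=(q, q + 3))
    return ed.deletion(p + 4, "uFrameshift")


def _plant_polya(ed: _TxEditor) -> _Planted:
    off = ed.cds_end
    u3_len = len(ed.seq) - off
    if u3_len < 20:
        raise PlantingError("3'UTR too short for polyA signal")
    r = off + (u3_len // 2)
    ed.write(r - 5, "CCCCC")
    ed.write(r, "AATAAA")
    ed.write(r + 6, "CCCCC"[: max(0, min(5, len(ed.seq) - (r + 6)))])
    return ed.snv(r + 2, "C", "polyA_disrupt")


def _plant_kozak_minus3(ed: _TxEditor) -> _Planted:
    if ed.cds < 6:
        raise PlantingError("no -3 position")
    # full gccRccAUG context: no stop codon can overlap the -3 base
    ed.write(ed.cds - 6, "GCCACC")
    return ed.snv(ed.cds - 3, "C", "kozak_minus3")


def _plant_spliceai(ed: _TxEditor) -> _Planted:
    introns = [
        r for r in extract_utr_regions(ed.tx) if r.region_class.endswith("_intron")
    ]
    if not introns:
        raise PlantingError("no UTR intron on transcript")
    r = introns[0]
    g = (r.start + r.end) // 2
    ref_g = chr(ed.genome[ed.tx.chrom][g])
    alt_g = "A" if ref_g != "A" else "G"
    out = _Planted(ed.tx.chrom, g, ref_g, alt_g, "spliceai_high", _benign_scores())
    out.scores["spliceai_max"] = 0.8
    return out


def _plant_tfbs(ed: _TxEditor) -> tuple[_Planted, FunctionalTrackElement, list[dict]]:
    tss = ed.tx.tss
    g = tss - 30 if ed.tx.strand == "+" else tss + 30
    ref_g = chr(ed.genome[ed.tx.chrom][g])
    alt_g = "A" if ref_g != "A" else "G"
    out = _Planted(ed.tx.chrom, g, ref_g, alt_g, "tfbs_loss", _benign_scores())
    footprint = FunctionalTrackElement(
        ed.tx.chrom, g - 10, g + 10, "TFBS", {"in_core_dhs": True}
    )
    return out, footprint, [
        {"tf_name": "TF1", "model_id": "m1", "value": -0.5},
        {"tf_name": "TF1", "model_id": "m2", "value": -0.3},
    ]


def _plant_rbp(ed: _TxEditor) -> tuple[_Planted, FunctionalTrackElement]:
    from .seq_effects import TranscriptVariant, polya_disruption

    off = ed.cds_end
    u3_len = len(ed.seq) - off
    if u3_len < 30:
        raise PlantingError("3'UTR too short for RBP site")
    u3 = "".join(ed.seq[off:])
    for t in range(off + (u3_len // 3), len(ed.seq)):
        ref_b = ed.seq[t]
        alt_b = "A" if ref_b != "A" else "G"
        # avoid sites where the edit would disrupt a natural polyA signal
        if polya_disruption(TranscriptVariant(t - off, ref_b, alt_b), u3).disrupted:
            continue
        out = ed.snv(t, alt_b, "rbp_loss")
        g = ed.coords[t]
        el = FunctionalTrackElement(
            ed.tx.chrom, g - 5, g + 6, "RBP",
            {"ref_affinity": 0.3, "alt_affinity": 0.05},
        )
        return out, el
    raise PlantingError("no polyA-neutral RBP site found in 3'UTR")


def _plant_background(ed: _TxEditor, rng: np.random.Generator, flavor: int) -> _Planted:
    """A variant verified to trigger nothing (optionally ClinVar-benign)."""
    from .seq_effects import TranscriptVariant, annotate_five_prime, polya_disruption

    cds, cds_end = ed.cds, ed.cds_end
    candidates = list(range(5, cds - 6)) + list(range(cds_end + 5, len(ed.seq) - 6))
    spl = SplicedTranscriptSequence(
        "".join(ed.seq), cds, cds_end, transcript_id=ed.tx.transcript_id
    )
    for i in rng.permutation(len(candidates)):
        t = candidates[int(i)]
        if t == cds - 3:
            continue
        ref_b = ed.seq[t]
        for alt_b in _BASES:
            if alt_b == ref_b:
                continue
            tv = TranscriptVariant(t, ref_b, alt_b)
            if t < cds and annotate_five_prime(tv, spl):
                continue
            if t >= cds_end:
                local = TranscriptVariant(t - cds_end, ref_b, alt_b)
                if polya_disruption(local, "".join(ed.seq[cds_end:])).disrupted:
                    continue
            out = ed.snv(t, alt_b, "benign_background")
            if flavor % 3 == 2:
                out.scores["clinvar_status"] = "Benign"
                out.scores["spliceai_max"] = 0.9
            return out
    raise PlantingError("no neutral background position found")


_PLANTERS = {
    "uAUG_gain_oORF": _plant_uaug_gain,
    "uSTOP_loss": _plant_ustop_loss,
    "uAUG_loss": _plant_uaug_loss,
    "uFrameshift": _plant_uframeshift,
    "polyA_disrupt": _plant_polya,
    "kozak_minus3": _plant_kozak_minus3,
    "spliceai_high": _plant_spliceai,
}


def plant_variants(
    spec: FixtureSpec,
    genome: dict[str, bytearray],
    transcripts: list[TranscriptModel],
    ccres: list[CisElement] | None = None,
) -> PlantedFixture:
    """Plant one variant per effect-class instance, with verified truth.

    The genome is edited in place to write the sequence context each class
    needs; scores are synthesised consistently with the intended truth.
    Every planted variant is verified by running the full annotation
    cascade; a mismatch raises :class:`PlantingError`.
    """
    rng = np.random.default_rng([spec.seed, 1])
    instances = [
        cls for cls, n in spec.planted_effects for _ in range(n)
    ]
    # seed-stable host assignment: one planted variant per transcript
    if len(instances) > len(transcripts):
        raise PlantingError(
            f"{len(instances)} planted variants but only "
            f"{len(transcripts)} transcripts"
        )
    hosts = list(range(len(transcripts)))

    planted: list[_Planted] = []
    track_elements: list[FunctionalTrackElement] = []
    tf_rows: list[dict] = []
    background_i = 0
    for idx, cls in enumerate(instances):
        tx = transcripts[hosts[idx]]
        ed = _TxEditor(genome, tx)
        if cls == "tfbs_loss":
            p, footprint, preds = _plant_tfbs(ed)
            track_elements.append(footprint)
        elif cls == "rbp_loss":
            p, el = _plant_rbp(ed)
            track_elements.append(el)
        elif cls == "benign_background":
            p = _plant_background(ed, rng, background_i)
            background_i += 1
            preds = None
        else:
            p = _PLANTERS[cls](ed)
            preds = None
        planted.append(p)
        if cls == "tfbs_loss":
            for row in preds:
                tf_rows.append({"variant_id": f"V{idx + 1:03d}", **row})

    rows = []
    truth: dict[str, TruthEntry] = {}
    for idx, p in enumerate(planted):
        vid = f"V{idx + 1:03d}"
        rows.append(
            {
                "variant_id": vid,
                "chrom": p.chrom,
                "pos": p.pos,
                "ref": p.ref,
                "alt": p.alt,
                **p.scores,
            }
        )
        if p.effect_class == "benign_background":
            triggers: frozenset[str] = frozenset()
        else:
            triggers = frozenset({EXPECTED_TRIGGER[p.effect_class]})
        retained = {
            DE_NOVO: bool(triggers),
            BURDEN: bool(triggers),
        }
        truth[vid] = TruthEntry(p.effect_class, triggers, retained)

    variants = pd.DataFrame(rows)
    tf_predictions = pd.DataFrame(
        tf_rows, columns=["variant_id", "tf_name", "model_id", "value"]
    )
    regions = build_near_coding_regions(
        transcripts, ccres or [], PromoterConfig()
    )
    fixture = PlantedFixture(variants, truth, track_elements, tf_predictions, regions)
    _verify_fixture(fixture, transcripts, genome)
    return fixture


def _verify_fixture(
    fixture: PlantedFixture,
    transcripts: list[TranscriptModel],
    genome: dict[str, bytearray],
) -> None:
    gstr = genome_as_str(genome)
    for arm in (DE_NOVO, BURDEN):
        decisions = run_cascade(
            fixture.variants,
            fixture.regions,
            transcripts,
            gstr,
            fixture.track_elements,
            fixture.tf_predictions,
            arm=arm,
        ).set_index("variant_id")
        for vid, entry in fixture.truth.items():
            got = decisions.loc[vid]
            want_retained = entry.expected_retained[arm]
            got_triggers = set(filter(None, got["triggered_annotations"].split(",")))
            if bool(got["retained"]) != want_retained or (
                want_retained and got_triggers != set(entry.expected_triggers)
            ):
                raise PlantingError(
                    f"{vid} ({entry.effect_class}, arm={arm}): expected "
                    f"retained={want_retained} triggers="
                    f"{sorted(entry.expected_triggers)}, got "
                    f"retained={got['retained']} triggers={sorted(got_triggers)}"
                )


def make_fixture(
    spec: FixtureSpec | None = None,
) -> tuple[
    dict[str, bytearray],
    list[TranscriptModel],
    list[CisElement],
    PlantedFixture,
]:
    """Convenience: genome + transcripts + cis elements + planted variants."""
    spec = spec or FixtureSpec()
    genome, transcripts, ccres = make_genome_and_transcripts(spec)
    fixture = plant_variants(spec, genome, transcripts, ccres)
    return genome, transcripts, ccres, fixture


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------


@dataclass
class CohortTables:
    participants: pd.DataFrame
    king_pairs: pd.DataFrame
    carriers: pd.DataFrame


def simulate_cohort(spec: FixtureSpec) -> CohortTables:
    """Draw a matched-cohort input set with planted carrier probabilities.

    Cases are probands (one per family); controls are unaffected parents
    from distinct families. Carrier status is Bernoulli per arm;
    ``related_pairs`` kinship pairs at or above the third-degree threshold
    are injected among the controls.
    """
    c = spec.cohort
    rng = np.random.default_rng([spec.seed, 2])
    labels = [label for label, _ in c.ancestry_mix]
    fractions = [f for _, f in c.ancestry_mix]

    def draw(n: int, prefix: str, role_pool: tuple[str, ...], affected: bool):
        recs = []
        for i in range(n):
            recs.append(
                {
                    "participant_id": f"{prefix}{i + 1:05d}",
                    "family_id": f"FAM_{prefix}{i + 1:05d}",
                    "role": role_pool[int(rng.integers(len(role_pool)))],
                    "affected": affected,
                    "sex": "XX" if rng.random() < 0.5 else "XY",
                    "ancestry": labels[
                        int(rng.choice(len(labels), p=fractions))
                    ],
                    "max_ancestry_fraction": 0.995,
                    "n_panel_genes": int(rng.integers(5, 81)),
                    "is_case": affected,
                }
            )
        return recs

    cases = draw(c.n_cases, "P", ("proband",), True)
    controls = draw(c.n_controls, "C", ("mother", "father"), False)
    participants = pd.DataFrame(cases + controls)

    king_rows = []
    if c.related_pairs > 0 and c.n_controls >= 2 * c.related_pairs:
        picks = rng.choice(c.n_controls, size=2 * c.related_pairs, replace=False)
        for j in range(c.related_pairs):
            a, b = int(picks[2 * j]), int(picks[2 * j + 1])
            king_rows.append(
                {
                    "id1": f"C{a + 1:05d}",
                    "id2": f"C{b + 1:05d}",
                    "king": float(rng.uniform(0.0442, 0.25)),
                }
            )
    king_pairs = pd.DataFrame(king_rows, columns=["id1", "id2", "king"])

    carrier_rows = []
    for rec in cases:
        carrier_rows.append(
            {
                "participant_id": rec["participant_id"],
                "carrier": bool(rng.random() < c.carrier_p_case),
            }
        )
    for rec in controls:
        carrier_rows.append(
            {
                "participant_id": rec["participant_id"],
                "carrier": bool(rng.random() < c.carrier_p_control),
            }
        )
    carriers = pd.DataFrame(carrier_rows, columns=["participant_id", "carrier"])
    return CohortTables(participants, king_pairs, carriers)
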