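"""Independent brute-force oracles used by the test suite.

Each oracle re-derives its quantity with explicit loops and elementary
arithmetic, independently of the library code paths it checks.
"""

from __future__ import annotations

from collections import defaultdict
from math import comb

STOPS = {"TAA", "TAG", "TGA"}


# ---------------------------------------------------------------------------
# 5'UTR translational-effect oracle
# ---------------------------------------------------------------------------


def _augs(seq: str, cds: int) -> list[int]:
    out = []
    for i in range(cds):
        if seq[i : i + 3] == "ATG":
            out.append(i)
    return out


def _outcome(seq: str, aug: int, cds: int) -> tuple[str, int | None]:
    k = aug + 3
    while k + 3 <= cds:
        if seq[k : k + 3] in STOPS:
            return "uORF", k
        k += 3
    if (cds - aug) % 3 == 0:
        return "inFrame_oORF", None
    return "outOfFrame_oORF", None


def _kozak(seq: str, aug: int) -> str:
    m3 = aug >= 3 and seq[aug - 3] in "AG"
    p4 = aug + 3 < len(seq) and seq[aug + 3] == "G"
    if m3 and p4:
        return "strong"
    if m3 or p4:
        return "moderate"
    return "weak"


def oracle_five_prime(
    seq: str, cds: int, pos: int, ref: str, alt: str
) -> set[tuple]:
    """Expected (effect, outcome, kozak, aug) tuples for one UTR variant."""
    delta = len(alt) - len(ref)
    if not (pos < cds or (not ref and pos <= cds)):
        return set()
    if pos + len(ref) > cds:
        return set()
    alt_seq = seq[:pos] + alt + seq[pos + len(ref) :]
    acds = cds + delta
    if alt_seq[acds : acds + 3] != "ATG":
        return set()

    events: set[tuple] = set()
    ref_augs = _augs(seq, cds)
    alt_augs = _augs(alt_seq, acds)

    def fwd(p):  # ref index -> alt index
        if p < pos:
            return p
        if p >= pos + len(ref):
            return p + delta
        return None

    def back(p):  # alt index -> ref index
        if p < pos:
            return p
        if p >= pos + len(alt):
            return p - delta
        return None

    surviving = []
    for a in ref_augs:
        b = fwd(a)
        if b is not None and 0 <= b < acds and alt_seq[b : b + 3] == "ATG":
            surviving.append((a, b))
        else:
            o, _ = _outcome(seq, a, cds)
            events.add(("uAUG_loss", o, _kozak(seq, a), a))
    survived_alt = {b for _, b in surviving}
    for b in alt_augs:
        if b in survived_alt:
            continue
        o, _ = _outcome(alt_seq, b, acds)
        events.add(("uAUG_gain", o, _kozak(alt_seq, b), b))

    for a, b in surviving:
        o_ref, stop_ref = _outcome(seq, a, cds)
        if o_ref != "uORF":
            continue
        koz = _kozak(seq, a)
        if delta % 3 != 0 and pos >= a + 3 and pos + len(ref) <= stop_ref:
            o_alt, _ = _outcome(alt_seq, b, acds)
            events.add(("uFrameshift", o_alt, koz, a))
            continue
        sb = fwd(stop_ref)
        intact = (
            sb is not None
            and sb + 3 <= acds
            and (sb - b) % 3 == 0
            and alt_seq[sb : sb + 3] in STOPS
        )
        if intact:
            continue
        o_alt, stop_alt = _outcome(alt_seq, b, acds)
        old = stop_ref if stop_ref <= pos else max(pos, stop_ref + delta)
        if o_alt == "uORF" and stop_alt is not None and stop_alt < old:
            continue
        events.add(("uSTOP_loss", o_alt, koz, a))
    return events


# ---------------------------------------------------------------------------
# Fisher exact (hypergeometric enumeration, exact integer arithmetic)
# ---------------------------------------------------------------------------


def oracle_fisher_p(a: int, b: int, c: int, d: int) -> float:
    """Two-sided exact P: sum of table probabilities <= the observed one."""
    n1, n2, k = a + b, c + d, a + c
    p_obs = comb(n1, a) * comb(n2, c)
    total = 0
    for x in range(max(0, k - n2), min(k, n1) + 1):
        p = comb(n1, x) * comb(n2, k - x)
        if p <= p_obs:
            total += p
    return total / comb(n1 + n2, k)


def oracle_required_n(a: int, b: int, c: int, d: int, alpha: float):
    """Scan cohort scale factors directly, recomputing the exact P."""
    n1, n2 = a + b, c + d
    p1, p2 = a / n1, c / n2
    for nc in range(n1, 200_000):
        nk = round(n2 * nc / n1)
        aa, cc = round(p1 * nc), round(p2 * nk)
        if oracle_fisher_p(aa, nc - aa, cc, nk - cc) <= alpha:
            return nc, nk
    raise AssertionError("oracle scan did not converge")


# ---------------------------------------------------------------------------
# Per-base region labeller
# ---------------------------------------------------------------------------


def brute_force_region_labels(transcripts, ccres, cfg):
    """(chrom, base) -> set of (region_class, transcript_id), CDS-subtracted.

    Works one base at a time: transcript bases are classified by their
    position along the spliced transcript relative to the CDS; intronic
    bases by which side of the CDS their whole intron lies on; promoter
    bases from the derived promoter interval. Any base that is CDS-exonic
    in any transcript is then removed.
    """
    from nearcoding.regions import derive_promoter

    labels: dict[tuple[str, int], set] = defaultdict(set)
    cds_bases: set[tuple[str, int]] = set()
    for tx in transcripts:
        coords = [g for s, e in tx.exons for g in range(s, e)]
        if tx.strand == "-":
            coords = coords[::-1]
        cds_idx = [
            i for i, g in enumerate(coords) if tx.cds_start <= g < tx.cds_end
        ]
        first, last = min(cds_idx), max(cds_idx)
        for i, g in enumerate(coords):
            if tx.cds_start <= g < tx.cds_end:
                cds_bases.add((tx.chrom, g))
            elif i < first:
                labels[(tx.chrom, g)].add(("five_utr", tx.transcript_id))
            elif i > last:
                labels[(tx.chrom, g)].add(("three_utr", tx.transcript_id))
        for (s0, e0), (s1, e1) in zip(tx.exons, tx.exons[1:]):
            for g in range(e0, s1):
                if e0 >= tx.cds_end or s1 <= tx.cds_start:
                    five_side = (
                        s1 <= tx.cds_start
                        if tx.strand == "+"
                        else e0 >= tx.cds_end
                    )
                    cls = "five_utr_intron" if five_side else "three_utr_intron"
                    labels[(tx.chrom, g)].add((cls, tx.transcript_id))
        ps, pe = derive_promoter(tx, ccres, cfg)
        for g in range(ps, pe):
            labels[(tx.chrom, g)].add(("promoter", tx.transcript_id))
    return {
        k: v for k, v in labels.items() if k not in cds_bases
    }, cds_bases
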