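# Methods

This note documents the models, conventions, and numerical choices behind
`nearcoding`, and what the synthetic fixtures do and do not demonstrate.

## Coordinates and conventions

All in-memory intervals are 0-based half-open (BED convention); GFF3 and
VCF I/O convert from their native 1-based forms. The phrase "−U bp to
+D bp from the TSS" is realised as the half-open interval
`[tss − U, tss + D)` on the plus strand — the TSS base itself belongs to
the downstream span — and is strand-mirrored on the minus strand. TSS
inclusivity is not universally standardised; this convention is fixed
here and applied symmetrically everywhere (promoter derivation, cCRE
extent measurement, fallback windows).

## Region construction

Promoters are anchored on promoter-like candidate cis-regulatory elements
(cCREs). Because open-chromatin annotation is tissue-dependent — an
inactive promoter may be marked only by a minimal nucleosome-free region —
the builder treats the cCRE as authoritative only when it is at least as
large as a "minimal promoter": 181 bp upstream and 67 bp downstream of
the TSS (the 25th percentiles of observed promoter-like cCRE extents,
kept here as configurable defaults in `PromoterConfig`). A deficient side
is extended to exactly the minimal extent; with no TSS-overlapping cCRE
at all, the 75th-percentile window (−266/+139 bp) is used. When several
cCREs overlap one TSS the one with the largest span is chosen, ties
broken by leftmost start (the choice is not otherwise determined; any
fixed rule would do, and this one is deterministic and order-independent).

UTR exons are the exonic bases outside the CDS span; an intron is a UTR
intron when it lies wholly 5' (or wholly 3') of the CDS — in particular
an intron flanking the exon that contains the CDS start counts as a
5'UTR intron. Introns between coding exons are excluded. Finally every
base that is CDS-exonic in *any* input transcript is subtracted, so no
retained variant can have a protein-coding consequence under any
transcript model; regions may be split and empty remnants are dropped,
with class and transcript attribution preserved.

A position in an intron-class region is *deep intronic* when it lies
strictly more than 20 bases from both flanking exon boundaries (the 21st
intronic base onward, counting the first intronic base as distance 1).

## 5'UTR translational effects

Analysis runs on the spliced transcript sequence with the CDS start
located. An upstream AUG (uAUG) is any AUG strictly 5' of the CDS start.
Scanning in-frame from a uAUG, the first stop codon lying *entirely*
within the 5'UTR terminates an upstream ORF (uORF); if no such stop
exists the ORF runs past the CDS start — an overlapping ORF (oORF),
in-frame when `(cds_offset − aug) % 3 == 0`, out-of-frame otherwise. A
stop codon straddling the CDS junction does not rescue a uORF: the ORF
still overlaps the CDS start, which is exactly the oORF definition.

Variant consequences are computed by comparing the full uAUG/stop
structure of the reference and alternate sequences, with positions
related through the edit (offset mapping; positions inside the edited
span have no image):

* **uAUG gain** — AUG present only in the alternate; outcome and Kozak
  strength read from the alternate.
* **uAUG loss** — AUG present only in the reference; outcome and Kozak
  read from the reference.
* **uSTOP loss** — a reference uORF whose stop no longer terminates it in
  the alternate (destroyed, frame-shifted away, or displaced). The
  outcome is recomputed on the alternate: oORF when no replacement stop
  precedes the CDS, uORF when a later stop exists. A *new* stop
  terminating the ORF earlier than the original stop position is not a
  stop loss.
* **uFrameshift** — a non-3n indel strictly inside a reference uORF body
  (between the start and stop codons); the outcome is recomputed on the
  alternate. When a frameshift is emitted for an AUG, the uSTOP-loss
  check for that same AUG is suppressed: one physical event, one call.

Kozak context strength reads only positions −3 and +4 around the AUG:
strong = purine at −3 AND G at +4; moderate = exactly one; weak =
neither; positions off the sequence end count as failing. This is the
convention of the standard uORF-annotation tooling; the published
effect classes ("strong or moderate") are consumed downstream by the
high-impact filter: uAUG gains, uSTOP losses, and uFrameshifts must
produce an oORF with strong/moderate Kozak; uAUG losses require a strong
Kozak.

The Kozak −3 rule for the *main* CDS start flags substitutions (only) at
exactly three bases 5' of the CDS AUG changing a purine to a pyrimidine.
Whether the original analysis also considered indels at that position is
not determinable; restricting to substitutions matches the stated rule
text and is the conservative reading.

Polyadenylation-signal logic operates in the DNA alphabet (U normalised
to T). A 3'UTR variant overlapping an AATAAA/ATTAAA occurrence is
disruptive unless the altered window re-creates one of the 12 known
signal hexamers at any offset overlapping the original hexamer; for
multi-nucleotide variants the whole mapped window is rescanned. The
created motif is reported when disruption is rescued.

## Overlay tracks

IRES and miRNA-site overlaps are noisy (large element footprints), so
they are additionally gated on scores: a variant whose CADD ≤ 22.7 *or*
PhyloP ≤ 1.879 — thresholds corresponding to supporting evidence of
benignity — is excluded. A missing score cannot trigger exclusion:
exclusion requires positive evidence. RBP binding loss requires an
active reference site (affinity ≥ 0.1) losing more than two thirds of its
affinity (alt/ref < 1/3); a zero reference affinity is an inactive site,
never a loss. dORF hits count only at the start or stop codon of a
translated dORF (whole-element fallback with a warning when codon
sub-intervals are absent). TFBS candidates must sit inside a footprint
flagged as core-DHS; per-TF binding-change scores are the arithmetic mean
of that TF's model predictions, classified gain at ≥ +0.04 and loss at
≤ −0.04, and the variant is retained when the mean over loss-classified
TF scores is ≤ −0.4. Whether the original retention rule used the mean
of losses or any single TF's loss score is ambiguous in the source
description; the mean reading is implemented (it is the one consistent
with "a loss score" in the singular), and the per-TF scores plus
gain/total means are all exposed for inspection.

## Prioritisation cascade

Annotation triggers are gated by region class: 5'UTR exons expose the
high-impact uORF rules, IRES overlap, and the Kozak −3 flag; 3'UTR exons
expose polyA disruption, miRNA, RBP loss, and dORF boundaries; every UTR
exon or intron exposes the splice-score trigger; promoters expose TFBS
loss; CADD ≥ 25.3 and PhyloP ≥ 7.367 evidence flags apply everywhere
*except* deep introns, where those scores are too noisy to interpret. A
variant in a promoter/UTR overlap region is eligible for the union of
both menus. The decision is retained iff at least one trigger fired; the
invariant is asserted on every constructed decision.

The two analysis arms differ in splice-score cutoff (0.2 de novo, 0.5
burden — so the burden-retained set is nested within the de novo set at
equal annotations) and in rarity pre-filters: the de novo arm excludes
internal AF ≥ 5×10⁻⁵ *or* AC ≥ 5 and external population-maximum
AF ≥ 5×10⁻⁴ (the disjunctive internal reading is consistent with the
retained set being described as AF ≤ 0.005%; a conjunctive switch is
exposed); the burden arm uses inclusive bounds AF ≤ 5×10⁻⁵ for both
internal and external frequencies and AC < 5. ClinVar statuses benign /
likely benign / benign–likely benign / protective are excluded
case-insensitively in all arms before the cascade.

The packaged candidate-variant table (`data/table1.tsv`) encodes the
eleven published candidate de novo variants with their printed region and
variant annotations. Two encoding choices were needed: Kozak strengths
for the two uAUG-gain rows are not printed (one is described in the text
as a strong start-codon context and is encoded strong; the other is
encoded moderate — either value satisfies the printed filter), and the
3'UTR-intron candidate 30 bp from its acceptor is encoded deep-intronic,
retained through its splice score alone, consistent with the deep-intron
score exemption.

## Burden testing

Genotype QC follows standard aggregated-callset practice: GQ ≥ 20,
DP ≥ 10, heterozygous allele balance within [0.2, 0.8], homozygous allele
balance ≤ 0.02; a variant is dropped when its missingness across matched
participants exceeds 5% or when ≥ 25% of its case calls fail.

Variant-count outliers are removed per genetically inferred ancestry
group using z = (x − μ)/σ with the group mean and *sample* standard
deviation (ddof = 1); |z| ≥ 2 (inclusive) is dropped. Note an algebraic
consequence: with sample SD, a single outlier in a group of n cannot
exceed |z| = (n−1)/√n, so tiny groups effectively cannot lose members —
degenerate groups (σ = 0 or fewer than two members) are kept whole with
a warning.

Relatedness pruning removes, iteratively and uniformly at random among
currently involved individuals (seeded), one participant at a time until
no pair with kinship ≥ 0.0442 (third-degree or closer) remains. Matching
then pairs each proband with one control of identical sex and ancestry
from a different family, with replacement; cases without an eligible
control are dropped and logged. Ancestry strata require more than 200
cases *and* 200 controls (configurable; toy cohorts in tests set the
minimum to zero), and cases are first restricted to at most 100 assigned
panel genes to limit panel-size noise. The assignment mechanics (shuffle
cases, draw a uniformly random eligible control) are this package's
choice; the source procedure does not specify them beyond 1:1 matching
with replacement.

Each annotation label yields a 2×2 carrier table (carrier = at least one
retained variant). The two-sided Fisher exact P sums the probabilities
of all tables at the observed margins no more probable than the observed
one (scipy's implementation of the conventional definition; the test
suite checks it against exact-integer hypergeometric enumeration on all
tables with N ≤ 60 to 10⁻¹²). The odds ratio is the sample
cross-product ratio; the 95% CI inverts the conditional likelihood of
the non-central hypergeometric distribution (conditional MLE). Tables
with an empty carrier or non-carrier margin are reported degenerate with
P = 1 and an undefined OR. The family-wise threshold is Bonferroni:
0.05/16 = 0.003125, displayed as 0.0031 (two significant figures), with
16 the default number of region/variant annotation tests.

The sample-size estimate scales the observed table up by a common factor
— cases one participant at a time, controls preserving the observed
case:control ratio — holding carrier proportions fixed (rounded to the
nearest count) and recomputing the exact P until it reaches the target
alpha. Joint scaling (rather than independent case/control increments)
is the reading consistent with "increasing the number of case and
control participants by 1" from a balanced design. Equal carrier
proportions return a non-converged sentinel rather than looping forever.

## Synthetic data: what it shows and what it does not

`make_genome_and_transcripts` packs non-overlapping multi-exon
transcripts on both strands — a 5'UTR split by an intron, a CDS split by
a coding intron, a 3'UTR with an intron on every third transcript — with
promoter-like cCREs over a configurable fraction of TSSs, extents drawn
to cover both deficient and sufficient cases. `plant_variants` *writes
the sequence context* each effect class requires (Kozak context bases,
upstream stops, polyA hexamers, stop-scrubbed frames), synthesises score
columns consistent with the intended truth (planted scores sit clear of
every threshold, e.g. CADD 12 vs the 25.3 flag; threshold-boundary
behaviour is tested separately with hand-built cases), and then verifies
every planted variant — and every background variant — by running the
full cascade under both arms before returning. Defaults: 15 transcripts
hosting 11 planted effects across all trigger classes plus 4 verified
background variants (one of which is ClinVar-benign with a high splice
score, to exercise the exclusion). The cohort simulator draws 2,000
participants per arm with carrier probabilities 0.10 (cases) versus 0.05
(controls) — the conditions of the power analysis — a 80/20 two-ancestry
mix, and 5 injected related pairs.

Because planting is construction-plus-verification, a perfect round trip
(sensitivity and specificity 1.0) demonstrates that the pipeline wiring,
region gating, coordinate handling (both strands, spliced transcripts,
VCF anchoring), and threshold plumbing are correct — not that the
annotation rules would achieve any particular accuracy on real genomes,
where uncertainty lives in the upstream scores and element annotations
that this package consumes as given. Likewise the toy genome has uniform
base composition, no repeats, no overlapping genes, and no linkage
structure; base-count totals on it are not comparable to genome-scale
values.

## Problem sizes and numerical notes

Test and acceptance runs use desk-scale inputs chosen to exercise every
code path: ~15-transcript genomes (tens of kilobases), 1,000–1,200 random
sequence/variant pairs for the annotator oracle, all 2×2 tables with
N ≤ 60 (deduplicated by the symmetries that leave P invariant) for the
Fisher oracle, and 200 replicates at 2,000 participants per arm for the
power check. Exact-integer arithmetic (`math.comb`) makes the Fisher
oracle free of rounding; agreement is required to 10⁻¹². All generators
and stochastic procedures take explicit seeds and are bit-reproducible;
the toy genome alphabet excludes N.

## Known limitations

* SpliceAI/CADD/PhyloP/ClinVar/TF-binding predictions are consumed as
  inputs; the package neither computes nor calibrates them.
* Splice-affecting annotation is a threshold on a provided score — no
  splicing model is run on the sequence.
* uORF analysis considers AUG starts only (no near-cognate starts) and
  does not model translation efficiency.
* The burden test treats carriers collectively per annotation label; it
  is not powered for per-gene inference and none is offered.
* The Fisher CI method (conditional MLE) is one of several defensible
  conventions; tables built from other conventions may differ slightly.
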