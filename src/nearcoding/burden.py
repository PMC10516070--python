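"""Matched case-control cohort construction and carrier burden testing.

Implements genotype-level QC on aggregated variant calls, per-ancestry
variant-count Z-score outlier removal, kinship-based relatedness pruning,
1:1 sex/ancestry matching of probands to unaffected controls (with
replacement), per-annotation 2x2 carrier Fisher exact tests with
Bonferroni correction, and the iterative sample-size (power) estimate
obtained by scaling the observed carrier table until significance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

#: kinship coefficient at or above which two participants are third-degree
#: relatives or closer
KING_THRESHOLD = 0.0442

#: |z| at or above which a participant's variant count is an outlier
ZSCORE_CUTOFF = 2.0

GQ_MIN = 20
DP_MIN = 10
HET_AB_RANGE = (0.2, 0.8)
HOM_AB_MAX = 0.02
MISSINGNESS_MAX = 0.05
CASE_FAIL_MAX = 0.25

DEFAULT_N_TESTS = 16
DEFAULT_MIN_STRATUM = 200
DEFAULT_MAX_PANEL_GENES = 100


@dataclass(frozen=True)
class Participant:
    """Cohort participant metadata used for matching and QC."""

    participant_id: str
    family_id: str
    role: str  # proband / mother / father
    affected: bool
    sex: str
    ancestry_label: str | None
    max_ancestry_fraction: float = 1.0
    hpo_terms: tuple[str, ...] = ()
    n_panel_genes: int = 0


@dataclass(frozen=True)
class GenotypeCall:
    gq: float
    dp: float
    ab: float | None
    genotype: str  # het / hom / ref / missing

    def passes(self) -> bool:
        if self.genotype == "missing":
            return False
        if self.gq < GQ_MIN or self.dp < DP_MIN:
            return False
        if self.genotype == "het":
            return self.ab is not None and HET_AB_RANGE[0] <= self.ab <= HET_AB_RANGE[1]
        if self.genotype == "hom":
            return self.ab is not None and self.ab <= HOM_AB_MAX
        return True


class BonferroniAlpha(NamedTuple):
    exact: float
    rounded: float


@dataclass
class BurdenResult:
    """A 2x2 carrier table with exact test results.

    ``a``/``b`` are carrier/non-carrier cases, ``c``/``d`` carrier and
    non-carrier controls. The odds ratio is the sample cross-product ratio;
    the 95% CI comes from inverting the conditional likelihood of the
    non-central hypergeometric distribution. ``degenerate`` marks tables
    with an empty carrier or non-carrier margin, reported with P = 1.
    """

    annotation_label: str
    a: int
    b: int
    c: int
    d: int
    odds_ratio: float
    p_value: float
    ci95: tuple[float, float]
    adjusted_alpha: float
    degenerate: bool = False

    @property
    def n_cases(self) -> int:
        return self.a + self.b

    @property
    def n_controls(self) -> int:
        return self.c + self.d


class RequiredN(NamedTuple):
    n_cases: int | None
    n_controls: int | None
    converged: bool
    reason: str = ""


# ---------------------------------------------------------------------------
# Genotype QC
# ---------------------------------------------------------------------------


def genotype_qc(calls: pd.DataFrame) -> set[str]:
    """Return the variant ids surviving genotype-level QC.

    ``calls`` is a long table with columns variant_id, participant_id,
    is_case, genotype (het/hom/ref/missing), gq, dp, ab. A call passes when
    GQ >= 20, DP >= 10, heterozygous allele balance in [0.2, 0.8], and
    homozygous allele balance <= 0.02. A variant is dropped when its
    missingness across all participants exceeds 5% or when at least 25% of
    its case calls fail.
    """
    if calls.empty:
        return set()
    kept: set[str] = set()
    for vid, grp in calls.groupby("variant_id"):
        missing = (grp["genotype"] == "missing").mean()
        if missing > MISSINGNESS_MAX:
            continue
        case_rows = grp[grp["is_case"].astype(bool)]
        if len(case_rows):
            fails = 0
            for rec in case_rows.itertuples():
                if rec.genotype == "missing":
                    continue
                call = GenotypeCall(
                    rec.gq, rec.dp, None if pd.isna(rec.ab) else rec.ab, rec.genotype
                )
                if not call.passes():
                    fails += 1
            if fails / len(case_rows) >= CASE_FAIL_MAX:
                continue
        kept.add(str(vid))
    return kept


# ---------------------------------------------------------------------------
# Participant-level filters
# ---------------------------------------------------------------------------


def zscore_filter(
    counts: pd.Series, ancestry: pd.Series, cutoff: float = ZSCORE_CUTOFF
) -> tuple[list[str], pd.DataFrame]:
    """Drop participants whose variant count is an outlier in their ancestry.

    ``counts`` maps participant_id -> near-coding variant count;
    ``ancestry`` maps participant_id -> ancestry group. Z-scores use the
    group mean and sample standard deviation; participants with
    ``|z| >= cutoff`` (inclusive) are dropped. Degenerate groups (fewer
    than two members, or zero spread) are kept whole with a warning.
    """
    records = []
    kept: list[str] = []
    for group, ids in ancestry.groupby(ancestry):
        x = counts.loc[ids.index].astype(float)
        mu = x.mean()
        sigma = x.std(ddof=1) if len(x) > 1 else 0.0
        if not sigma > 0:
            logger.warning("ancestry group %s has no spread; keeping all", group)
            z = pd.Series(0.0, index=x.index)
            kept.extend(x.index)
        else:
            z = (x - mu) / sigma
            kept.extend(z.index[z.abs() < cutoff])
        for pid in x.index:
            records.append(
                {
                    "participant_id": pid,
                    "ancestry": group,
                    "x": x[pid],
                    "mu": mu,
                    "sigma": sigma,
                    "z": z[pid],
                }
            )
    order = {pid: i for i, pid in enumerate(counts.index)}
    kept.sort(key=order.__getitem__)
    return kept, pd.DataFrame(records)


def prune_related(
    participant_ids: Sequence[str],
    king_pairs: Iterable[tuple[str, str, float]],
    threshold: float = KING_THRESHOLD,
    seed: int = 0,
) -> list[str]:
    """Iteratively remove random related participants until no pair remains.

    ``king_pairs`` are (id1, id2, kinship) tuples; pairs at or above
    ``threshold`` are relatedness edges. At each step one participant is
    chosen uniformly at random among those still involved in an edge and
    removed; the sequence is reproducible for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    kept = set(participant_ids)
    edges = [
        (a, b)
        for a, b, s in king_pairs
        if s >= threshold and a in kept and b in kept and a != b
    ]
    while edges:
        involved = sorted({p for e in edges for p in e})
        victim = involved[int(rng.integers(len(involved)))]
        kept.discard(victim)
        edges = [e for e in edges if victim not in e]
    return [p for p in participant_ids if p in kept]


def match_case_control(
    cases: pd.DataFrame,
    controls: pd.DataFrame,
    seed: int = 0,
    min_stratum_n: int = DEFAULT_MIN_STRATUM,
    max_panel_genes: int | None = DEFAULT_MAX_PANEL_GENES,
) -> list[tuple[str, str]]:
    """Match each case 1:1 to a control on sex and ancestry, with replacement.

    Both frames need columns participant_id, family_id, sex, ancestry;
    ``cases`` may carry n_panel_genes (cases above ``max_panel_genes`` are
    dropped first). Ancestries without more than ``min_stratum_n`` cases
    *and* controls are excluded entirely. Within each (sex, ancestry)
    stratum the cases are shuffled and each is assigned a uniformly random
    control not sharing its family id; controls may be reused. Cases with
    no eligible control are dropped with a log message.
    """
    rng = np.random.default_rng(seed)
    cases = cases.copy()
    if max_panel_genes is not None and "n_panel_genes" in cases.columns:
        cases = cases[cases["n_panel_genes"] <= max_panel_genes]

    case_counts = cases["ancestry"].value_counts()
    ctrl_counts = controls["ancestry"].value_counts()
    eligible_ancestries = {
        anc
        for anc in set(case_counts.index) & set(ctrl_counts.index)
        if case_counts[anc] > min_stratum_n and ctrl_counts[anc] > min_stratum_n
    }
    dropped = set(case_counts.index) - eligible_ancestries
    if dropped:
        logger.info("ancestry strata excluded (too small): %s", sorted(dropped))

    pairs: list[tuple[str, str]] = []
    case_meta = cases.set_index("participant_id")
    ctrl_meta = controls.set_index("participant_id")
    for (sex, anc), stratum in cases.groupby(["sex", "ancestry"], sort=True):
        if anc not in eligible_ancestries:
            continue
        pool = controls[(controls["sex"] == sex) & (controls["ancestry"] == anc)]
        if pool.empty:
            logger.warning("no controls in stratum (%s, %s); cases dropped", sex, anc)
            continue
        ids = list(stratum["participant_id"])
        rng.shuffle(ids)
        pool_ids = list(pool["participant_id"])
        pool_fams = list(pool["family_id"])
        for cid in ids:
            fam = case_meta.at[cid, "family_id"]
            elig = [p for p, f in zip(pool_ids, pool_fams) if f != fam]
            if not elig:
                logger.warning("case %s has no family-distinct control; dropped", cid)
                continue
            pairs.append((cid, elig[int(rng.integers(len(elig)))]))

    for cid, pid in pairs:
        assert case_meta.at[cid, "sex"] == ctrl_meta.at[pid, "sex"]
        assert case_meta.at[cid, "ancestry"] == ctrl_meta.at[pid, "ancestry"]
        assert case_meta.at[cid, "family_id"] != ctrl_meta.at[pid, "family_id"]
    return pairs


# ---------------------------------------------------------------------------
# Burden testing
# ---------------------------------------------------------------------------


def bonferroni_alpha(
    family_alpha: float = 0.05, n_tests: int = DEFAULT_N_TESTS
) -> BonferroniAlpha:
    """Per-test alpha, exact and rounded to two significant figures."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    exact = family_alpha / n_tests
    return BonferroniAlpha(exact, float(f"{exact:.2g}"))


def _fisher_p(a: int, b: int, c: int, d: int) -> float:
    return float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])


def fisher_burden(
    case_carrier_flags: Sequence[bool],
    control_carrier_flags: Sequence[bool],
    annotation_label: str = "all",
    n_tests: int = DEFAULT_N_TESTS,
    family_alpha: float = 0.05,
    compute_ci: bool = True,
) -> BurdenResult:
    """Two-sided Fisher exact test on a carrier/non-carrier 2x2 table.

    The two-sided P sums the probabilities of all tables (at the observed
    margins) no more probable than the observed one. The odds ratio is the
    sample (a*d)/(b*c), infinite or undefined with zero cells, flagged via
    ``degenerate`` when a whole margin is empty.
    """
    case_flags = [bool(x) for x in case_carrier_flags]
    ctrl_flags = [bool(x) for x in control_carrier_flags]
    if not case_flags or not ctrl_flags:
        raise ValueError("burden test requires non-empty case and control arms")
    a = sum(case_flags)
    b = len(case_flags) - a
    c = sum(ctrl_flags)
    d = len(ctrl_flags) - c
    return fisher_burden_table(
        a, b, c, d, annotation_label, n_tests, family_alpha, compute_ci
    )


def fisher_burden_table(
    a: int,
    b: int,
    c: int,
    d: int,
    annotation_label: str = "all",
    n_tests: int = DEFAULT_N_TESTS,
    family_alpha: float = 0.05,
    compute_ci: bool = True,
) -> BurdenResult:
    """``fisher_burden`` on an explicit 2x2 table."""
    adjusted = bonferroni_alpha(family_alpha, n_tests).exact
    degenerate = (a + c == 0) or (b + d == 0)
    if degenerate:
        logger.warning(
            "%s: empty carrier margin (a=%d c=%d); OR undefined, P=1",
            annotation_label, a, c,
        )
        return BurdenResult(
            annotation_label, a, b, c, d,
            float("nan"), 1.0, (float("nan"), float("nan")), adjusted,
            degenerate=True,
        )
    p = _fisher_p(a, b, c, d)
    if b * c > 0:
        odds = (a * d) / (b * c)
    else:
        odds = float("inf") if a * d > 0 else float("nan")
    ci = (float("nan"), float("nan"))
    if compute_ci:
        res = stats.contingency.odds_ratio([[a, b], [c, d]], kind="conditional")
        interval = res.confidence_interval(confidence_level=0.95)
        ci = (float(interval.low), float(interval.high))
    return BurdenResult(annotation_label, a, b, c, d, odds, p, ci, adjusted)


def burden_test_matched(
    pairs: list[tuple[str, str]],
    carriers_by_label: dict[str, set[str]],
    n_tests: int | None = None,
    family_alpha: float = 0.05,
) -> list[BurdenResult]:
    """One burden test per annotation label over matched case-control pairs."""
    if not pairs:
        raise ValueError("no matched pairs to test")
    n = n_tests if n_tests is not None else max(1, len(carriers_by_label))
    cases = [c for c, _ in pairs]
    controls = [p for _, p in pairs]
    results = []
    for label in sorted(carriers_by_label):
        carriers = carriers_by_label[label]
        results.append(
            fisher_burden(
                [c in carriers for c in cases],
                [p in carriers for p in controls],
                annotation_label=label,
                n_tests=n,
                family_alpha=family_alpha,
            )
        )
    return results


def required_n(
    a: int,
    b: int,
    c: int,
    d: int,
    alpha: float,
    max_n: int = 2_000_000,
) -> RequiredN:
    """Smallest jointly scaled cohort sizes reaching P <= alpha.

    Starting from the observed table, both cohorts are scaled up by a
    common factor — the case arm one participant at a time, the control
    arm preserving the observed case:control ratio — with carrier counts
    held at the observed proportions (rounded to the nearest integer) and
    the exact P recomputed at each size. Equal carrier proportions never
    reach significance and yield a non-converged sentinel.
    """
    n1, n2 = a + b, c + d
    if n1 == 0 or n2 == 0:
        raise ValueError("empty cohort")
    p1, p2 = a / n1, c / n2
    if p1 <= p2:
        return RequiredN(None, None, False, "case carrier proportion not greater")
    k = 0
    while n1 + k <= max_n:
        nc = n1 + k
        nk = round(n2 * nc / n1)
        aa = round(p1 * nc)
        cc = round(p2 * nk)
        if _fisher_p(aa, nc - aa, cc, nk - cc) <= alpha:
            return RequiredN(nc, nk, True)
        k += 1
    return RequiredN(None, None, False, f"no significance by n_cases={max_n}")
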