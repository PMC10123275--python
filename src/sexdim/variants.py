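"""Case-control and family-based statistics on genotype counts.

Works from genotype count triples (hom-ref, het, hom-alt) per study group
and from trio transmission counts: minor-allele frequency, the exact
conditional Hardy-Weinberg test, genotype-table chi-square association,
carrier- and allele-based Fisher exact tests for rare variants, and the
transmission disequilibrium test (TDT) with its exact-binomial companion.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenotypeCounts:
    """Genotype counts for one variant in one study group.

    n11: homozygous reference, n12: heterozygous, n22: homozygous
    alternative individuals.
    """

    n11: int
    n12: int
    n22: int
    group_label: str = ""

    def __post_init__(self) -> None:
        for c in (self.n11, self.n12, self.n22):
            if c < 0 or int(c) != c:
                raise ValueError("genotype counts must be non-negative integers")

    @property
    def total(self) -> int:
        return self.n11 + self.n12 + self.n22

    @property
    def alt_alleles(self) -> int:
        return self.n12 + 2 * self.n22

    @property
    def ref_alleles(self) -> int:
        return 2 * self.n11 + self.n12

    @property
    def carriers(self) -> int:
        """Individuals carrying at least one alternative allele."""
        return self.n12 + self.n22


@dataclass(frozen=True)
class TrioCounts:
    """Transmitted (b) and untransmitted (c) minor-allele counts from
    heterozygous parents, with an optional maternal/paternal split."""

    b: int
    c: int
    b_maternal: int | None = None
    c_maternal: int | None = None
    b_paternal: int | None = None
    c_paternal: int | None = None

    def __post_init__(self) -> None:
        if self.b < 0 or self.c < 0:
            raise ValueError("transmission counts must be non-negative")
        split = (self.b_maternal, self.c_maternal,
                 self.b_paternal, self.c_paternal)
        if all(v is not None for v in split):
            if self.b_maternal + self.b_paternal != self.b:
                raise ValueError("maternal + paternal transmissions != b")
            if self.c_maternal + self.c_paternal != self.c:
                raise ValueError("maternal + paternal non-transmissions != c")

    @property
    def informative(self) -> int:
        return self.b + self.c


@dataclass(frozen=True)
class AssociationResult:
    statistic: float | None
    df: int | None
    p_two_sided: float
    method: str  # genotype-chi2 | carrier-fisher | allele-fisher
    case_freq: float
    control_freq: float


@dataclass(frozen=True)
class TdtResult:
    b: int
    c: int
    transmission_rate: float
    chi2: float
    p_chi2: float
    p_binomial: float


# ---------------------------------------------------------------------------
# allele frequency and Hardy-Weinberg
# ---------------------------------------------------------------------------

def maf(counts: GenotypeCounts) -> float:
    """Minor allele frequency: min(f, 1-f) of the alternative allele."""
    if counts.total == 0:
        raise ValueError("empty genotype table")
    f = counts.alt_alleles / (2 * counts.total)
    return min(f, 1.0 - f)


def hwe_exact(counts: GenotypeCounts) -> float:
    """Exact conditional Hardy-Weinberg test p-value.

    Conditions on the observed allele counts and sums, over all
    heterozygote counts of the correct parity, the probabilities of
    configurations no likelier than the observed one. Robust for rare
    variants where the chi-square approximation fails.
    """
    if counts.total == 0:
        raise ValueError("empty genotype table")
    n = counts.total
    n_rare = min(counts.alt_alleles, counts.ref_alleles)
    if n_rare == 0:
        return 1.0

    def logprob(h: int) -> float:
        # P(h | allele counts) up to the common normalizer:
        #   n! 2^h / ( ((n_common-? )/2)! h! ((n_rare-h)/2)! )
        n_hom_rare = (n_rare - h) // 2
        n_hom_common = n - h - n_hom_rare
        return (
            h * math.log(2.0)
            - math.lgamma(n_hom_common + 1)
            - math.lgamma(h + 1)
            - math.lgamma(n_hom_rare + 1)
        )

    hets = range(n_rare % 2, n_rare + 1, 2)
    logs = {h: logprob(h) for h in hets}
    mx = max(logs.values())
    probs = {h: math.exp(lp - mx) for h, lp in logs.items()}
    norm = sum(probs.values())
    obs = probs[counts.n12]
    p = sum(v for v in probs.values() if v <= obs * (1 + 1e-12)) / norm
    return min(1.0, p)


def hwe_chi2(counts: GenotypeCounts) -> float:
    """Chi-square (1 df) Hardy-Weinberg test; offered for large samples."""
    if counts.total == 0:
        raise ValueError("empty genotype table")
    n = counts.total
    f = counts.alt_alleles / (2 * n)
    exp = np.array([(1 - f) ** 2, 2 * f * (1 - f), f**2]) * n
    obs = np.array([counts.n11, counts.n12, counts.n22])
    mask = exp > 0
    chi2 = float(((obs[mask] - exp[mask]) ** 2 / exp[mask]).sum())
    return float(stats.chi2.sf(chi2, df=1))


# ---------------------------------------------------------------------------
# case-control association
# ---------------------------------------------------------------------------

def _freqs(case: GenotypeCounts, control: GenotypeCounts) -> tuple[float, float]:
    return (
        case.alt_alleles / (2 * case.total),
        control.alt_alleles / (2 * control.total),
    )


def genotype_chi2(
    case: GenotypeCounts, control: GenotypeCounts
) -> AssociationResult:
    """Pearson chi-square on the 2x3 genotype table, no continuity correction.

    Genotype columns empty in both groups are dropped with a warning and
    the degrees of freedom reduced accordingly.
    """
    if case.total == 0 or control.total == 0:
        raise ValueError("both groups need at least one individual")
    table = np.array(
        [[case.n11, case.n12, case.n22], [control.n11, control.n12, control.n22]]
    )
    keep = table.sum(axis=0) > 0
    if not keep.all():
        logger.warning(
            "genotype_chi2: dropping %d empty genotype column(s)",
            int((~keep).sum()),
        )
        table = table[:, keep]
    if table.shape[1] < 2:
        raise ValueError("fewer than two non-empty genotype columns")
    chi2, p, df, _ = stats.chi2_contingency(table, correction=False)
    cf, kf = _freqs(case, control)
    return AssociationResult(float(chi2), int(df), float(p), "genotype-chi2", cf, kf)


def carrier_fisher(
    case: GenotypeCounts, control: GenotypeCounts
) -> AssociationResult:
    """Two-sided Fisher exact test on carriers vs non-carriers.

    Carriers collapse heterozygous and homozygous-alternative genotypes —
    the appropriate 2x2 reduction for rare variants. Two-sidedness follows
    the sum-of-smaller-probabilities rule (all tables with hypergeometric
    probability at most that of the observed one).
    """
    if case.total == 0 or control.total == 0:
        raise ValueError("both groups need at least one individual")
    table = [
        [case.carriers, case.n11],
        [control.carriers, control.n11],
    ]
    _, p = stats.fisher_exact(table, alternative="two-sided")
    return AssociationResult(
        None, None, float(p), "carrier-fisher",
        case.carriers / case.total, control.carriers / control.total,
    )


def allele_fisher(
    case: GenotypeCounts | tuple[int, int],
    control: GenotypeCounts | tuple[int, int],
) -> AssociationResult:
    """Two-sided Fisher exact test on the 2x2 allele-count table.

    Accepts genotype counts or raw ``(alt_alleles, ref_alleles)`` pairs —
    the latter for allele-frequency-database controls where genotype
    tables are unavailable.
    """

    def _alleles(g):
        if isinstance(g, GenotypeCounts):
            return g.alt_alleles, g.ref_alleles
        alt, ref = g
        return int(alt), int(ref)

    ca, cr = _alleles(case)
    ka, kr = _alleles(control)
    if ca + cr == 0 or ka + kr == 0:
        raise ValueError("both groups need at least one allele")
    _, p = stats.fisher_exact([[ca, cr], [ka, kr]], alternative="two-sided")
    return AssociationResult(
        None, None, float(p), "allele-fisher", ca / (ca + cr), ka / (ka + kr)
    )


def associate(
    case: GenotypeCounts,
    control: GenotypeCounts,
    test: str = "auto",
) -> AssociationResult:
    """Dispatch between the genotype chi-square and the carrier Fisher test.

    ``auto`` uses the chi-square when every expected cell count of the 2x3
    table is at least 5, and the carrier Fisher test otherwise (the usual
    validity rule; rare variants always fall to Fisher).
    """
    if test == "chi2":
        return genotype_chi2(case, control)
    if test == "fisher-carrier":
        return carrier_fisher(case, control)
    if test == "fisher-allele":
        return allele_fisher(case, control)
    if test != "auto":
        raise ValueError(f"unknown test '{test}'")
    table = np.array(
        [[case.n11, case.n12, case.n22], [control.n11, control.n12, control.n22]],
        dtype=float,
    )
    table = table[:, table.sum(axis=0) > 0]
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / table.sum()
    if (expected < 5).any():
        return carrier_fisher(case, control)
    return genotype_chi2(case, control)


# ---------------------------------------------------------------------------
# trios
# ---------------------------------------------------------------------------

def tdt(trio: TrioCounts) -> TdtResult:
    """Transmission disequilibrium test.

    chi2 = (b - c)^2 / (b + c) on 1 df (McNemar form); the exact two-sided
    binomial p-value at p0 = 0.5 is reported alongside for small counts.
    """
    n = trio.informative
    if n == 0:
        raise ValueError("no informative transmissions")
    chi2 = (trio.b - trio.c) ** 2 / n
    p_chi2 = float(stats.chi2.sf(chi2, df=1))
    p_binom = float(stats.binomtest(trio.b, n, 0.5).pvalue)
    return TdtResult(trio.b, trio.c, trio.b / n, float(chi2), p_chi2, p_binom)


class MendelianError(ValueError):
    """Child genotype incompatible with the parental genotypes."""


def _mendel_ok(f: int, m: int, c: int) -> bool:
    f_gametes = {0} if f == 0 else {1} if f == 2 else {0, 1}
    m_gametes = {0} if m == 0 else {1} if m == 2 else {0, 1}
    return any(a + b == c for a in f_gametes for b in m_gametes)


def count_transmissions(
    trios: Iterable[tuple[int, int, int]],
) -> tuple[TrioCounts, int]:
    """Tally minor-allele transmissions from heterozygous parents.

    Genotypes are 0/1/2 copies of the minor allele, ordered (father,
    mother, child). For a het parent paired with a homozygous mate the
    transmitted allele is forced by the child. When both parents are het
    and the child is het, which parent transmitted the minor allele is
    ambiguous; the pair contributes one transmission and one
    non-transmission in aggregate (standard TDT accounting) and is left
    out of the maternal/paternal split. Mendelian-inconsistent trios are
    excluded and counted, never repaired.

    Returns the counts and the number of excluded trios.
    """
    b = c = 0
    bm = cm = bp_ = cp = 0
    ambiguous = 0
    excluded = 0
    for fgt, mgt, cgt in trios:
        if not all(g in (0, 1, 2) for g in (fgt, mgt, cgt)):
            raise ValueError("genotypes must be coded 0/1/2")
        if not _mendel_ok(fgt, mgt, cgt):
            excluded += 1
            logger.warning(
                "Mendelian-inconsistent trio excluded: f=%d m=%d c=%d",
                fgt, mgt, cgt,
            )
            continue
        if fgt == 1 and mgt == 1:
            if cgt == 2:
                b += 2; bm += 1; bp_ += 1
            elif cgt == 0:
                c += 2; cm += 1; cp += 1
            else:  # het child: one transmitted, one not; parent unknown
                b += 1; c += 1; ambiguous += 1
            continue
        for parent, other, is_mother in ((fgt, mgt, False), (mgt, fgt, True)):
            if parent != 1:
                continue
            transmitted = cgt - other // 2  # other parent is homozygous here
            if transmitted == 1:
                b += 1
                if is_mother: bm += 1
                else: bp_ += 1
            else:
                c += 1
                if is_mother: cm += 1
                else: cp += 1
    if ambiguous:
        counts = TrioCounts(b, c)
    else:
        counts = TrioCounts(b, c, bm, cm, bp_, cp)
    return counts, excluded


# ---------------------------------------------------------------------------
# tabular interface
# ---------------------------------------------------------------------------

def read_genotype_counts(path) -> dict[tuple[str, str], GenotypeCounts]:
    """Read a delimited counts table: variant, group, n11, n12, n22."""
    import pandas as pd

    df = pd.read_csv(path, sep=None, engine="python")
    required = {"variant", "group", "n11", "n12", "n22"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"counts table lacks columns: {sorted(missing)}")
    out = {}
    for _, row in df.iterrows():
        out[(str(row["variant"]), str(row["group"]))] = GenotypeCounts(
            int(row["n11"]), int(row["n12"]), int(row["n22"]),
            group_label=str(row["group"]),
        )
    return out


def read_trio_genotypes(path) -> list[tuple[int, int, int]]:
    """Read trio genotypes: family_id, father_gt, mother_gt, child_gt."""
    import pandas as pd

    df = pd.read_csv(path, sep=None, engine="python")
    required = {"family_id", "father_gt", "mother_gt", "child_gt"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"trio table lacks columns: {sorted(missing)}")
    return [
        (int(r["father_gt"]), int(r["mother_gt"]), int(r["child_gt"]))
        for _, r in df.iterrows()
    ]
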