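"""Sex-dimorphism screening of sex-stratified GWAS summary statistics.

Workflow: ingest per-SNP summary statistics carrying separate female and
male effect estimates, restrict to candidate gene regions (core gene plus a
flanking window, 500 kb by default), verify that the effect allele is
assigned identically in both sexes, drop strand-ambiguous (palindromic)
SNPs with allele frequency near 0.5, harmonize effect directions so the
tested allele is the minor allele, and score each SNP with

    z = (beta_female - beta_male) / sqrt(se_female**2 + se_male**2)

A SNP is called sex-dimorphic when |z| >= 3 and trait-associated when a
per-analysis GWAS p-value is below genome-wide significance (5e-8).
"""

from __future__ import annotations

import gzip
import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import pandas as pd
from scipy.stats import norm

logger = logging.getLogger(__name__)

GENOME_WIDE_P = 5e-8
DIMORPHISM_Z = 3.0
DEFAULT_FLANK = 500_000

#: complementary base pairs on opposite strands
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


class ColumnMapError(KeyError):
    """A mapped summary-statistics column is missing from the input file."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SummaryRecord:
    """One SNP's per-sex association summary.

    ``freq_tested`` is the frequency of ``tested_allele``; it may be None
    for datasets that do not report allele frequency, in which case
    palindromic filtering and direction harmonization cannot be performed.
    """

    chrom: str
    pos: int
    rsid: str
    tested_allele: str
    other_allele: str
    freq_tested: float | None
    beta_female: float | None
    se_female: float | None
    p_female: float | None
    beta_male: float | None
    se_male: float | None
    p_male: float | None
    p_combined: float | None = None
    harmonized: bool = False
    in_core_gene: bool = False

    def __post_init__(self) -> None:
        if self.tested_allele == self.other_allele:
            raise ValueError(f"{self.rsid}: tested and other allele identical")
        if self.freq_tested is not None and not 0.0 <= self.freq_tested <= 1.0:
            raise ValueError(f"{self.rsid}: freq_tested outside [0, 1]")
        for se in (self.se_female, self.se_male):
            if se is not None and se <= 0:
                raise ValueError(f"{self.rsid}: standard error must be > 0")

    @property
    def is_palindromic(self) -> bool:
        """A/T or C/G allele pair: strand orientation is unresolvable."""
        return _COMPLEMENT.get(self.tested_allele) == self.other_allele

    @property
    def maf(self) -> float | None:
        if self.freq_tested is None:
            return None
        return min(self.freq_tested, 1.0 - self.freq_tested)


@dataclass(frozen=True)
class GeneRegion:
    """A candidate gene interval extended by a symmetric flank.

    Coordinates are 1-based and closed on both ends. For merged regions
    (two nearby genes analyzed jointly) the core spans both genes and
    ``core_intervals`` keeps the individual gene bodies.
    """

    name: str
    chrom: str
    core_start: int
    core_end: int
    flank: int = DEFAULT_FLANK
    core_intervals: tuple[tuple[int, int], ...] = field(default=())

    def __post_init__(self) -> None:
        if self.core_start > self.core_end:
            raise ValueError(f"{self.name}: core_start > core_end")
        if not self.core_intervals:
            object.__setattr__(
                self, "core_intervals", ((self.core_start, self.core_end),)
            )

    @property
    def region_start(self) -> int:
        return max(1, self.core_start - self.flank)

    @property
    def region_end(self) -> int:
        return self.core_end + self.flank

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.region_start <= pos <= self.region_end

    def in_core(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and any(
            s <= pos <= e for s, e in self.core_intervals
        )

    @classmethod
    def merged(
        cls,
        name: str,
        chrom: str,
        intervals: Sequence[tuple[int, int]],
        flank: int = DEFAULT_FLANK,
    ) -> "GeneRegion":
        starts = [s for s, _ in intervals]
        ends = [e for _, e in intervals]
        return cls(
            name=name,
            chrom=chrom,
            core_start=min(starts),
            core_end=max(ends),
            flank=flank,
            core_intervals=tuple(sorted(intervals)),
        )


#: candidate regions shipped with the package (GRCh37, 1-based closed)
DEFAULT_REGIONS: tuple[GeneRegion, ...] = (
    GeneRegion("CKB", "14", 103_986_004, 103_989_167),
    GeneRegion.merged(
        "CKMT1B/GATM",
        "15",
        [(43_885_055, 43_891_604), (45_653_322, 45_694_425)],
    ),
)


@dataclass(frozen=True)
class DimorphismResult:
    """Per-SNP dimorphism score and classification flags."""

    rsid: str
    chrom: str
    pos: int
    z: float | None
    p_dimorphism: float | None
    excluded: str | None  # reason, or None if analyzed
    harmonized: bool
    is_trait_associated_female: bool
    is_trait_associated_male: bool
    is_trait_associated_combined: bool
    is_dimorphic: bool
    in_core_gene: bool


# ---------------------------------------------------------------------------
# ingestion
# ---------------------------------------------------------------------------

#: canonical column-map keys -> SummaryRecord field, required flag
_MAP_KEYS = {
    "chrom": True,
    "pos": True,
    "rsid": True,
    "tested_allele": True,
    "other_allele": True,
    "freq": False,
    "beta_female": False,
    "se_female": False,
    "p_female": False,
    "beta_male": False,
    "se_male": False,
    "p_male": False,
    "p_combined": False,
}


def _open_text(path):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_summary_stats(
    path, column_map: dict[str, str], sep: str | None = None
) -> list[SummaryRecord]:
    """Read a delimited summary-statistics file into records.

    ``column_map`` maps canonical keys (chrom, pos, rsid, tested_allele,
    other_allele, freq, beta_female, se_female, p_female, beta_male,
    se_male, p_male, p_combined) to column names in the file. Rows whose
    numeric fields fail to parse are skipped and counted. Gzip input is
    handled transparently; the delimiter is sniffed unless given.
    """
    with _open_text(path) as fh:
        df = pd.read_csv(fh, sep=sep, engine="python")

    for key, required in _MAP_KEYS.items():
        col = column_map.get(key)
        if col is None:
            if required:
                raise ColumnMapError(f"column map lacks required key '{key}'")
            continue
        if col not in df.columns:
            raise ColumnMapError(
                f"mapped column '{col}' (for '{key}') not found in {path}"
            )

    def _num(row, key):
        col = column_map.get(key)
        if col is None:
            return None
        v = row[col]
        if pd.isna(v):
            raise ValueError(key)
        return float(v)

    records: list[SummaryRecord] = []
    skipped = 0
    for _, row in df.iterrows():
        try:
            rec = SummaryRecord(
                chrom=str(row[column_map["chrom"]]),
                pos=int(row[column_map["pos"]]),
                rsid=str(row[column_map["rsid"]]),
                tested_allele=str(row[column_map["tested_allele"]]).upper(),
                other_allele=str(row[column_map["other_allele"]]).upper(),
                freq_tested=_num(row, "freq") if "freq" in column_map else None,
                beta_female=_num(row, "beta_female"),
                se_female=_num(row, "se_female"),
                p_female=_num(row, "p_female"),
                beta_male=_num(row, "beta_male"),
                se_male=_num(row, "se_male"),
                p_male=_num(row, "p_male"),
                p_combined=_num(row, "p_combined"),
            )
        except (ValueError, TypeError) as exc:
            skipped += 1
            logger.warning("skipping unparseable row (%s): %s", exc, dict(row))
            continue
        records.append(rec)
    if skipped:
        logger.info("read_summary_stats: skipped %d unparseable rows", skipped)
    read_summary_stats.last_skipped = skipped
    return records


read_summary_stats.last_skipped = 0


# ---------------------------------------------------------------------------
# filtering and harmonization
# ---------------------------------------------------------------------------

def extract_region(
    records: Iterable[SummaryRecord], region: GeneRegion
) -> list[SummaryRecord]:
    """Records inside the closed region interval, tagged with core membership."""
    out = []
    for rec in records:
        if region.contains(rec.chrom, rec.pos):
            out.append(replace(rec, in_core_gene=region.in_core(rec.chrom, rec.pos)))
    return out


def flag_palindromic(
    record: SummaryRecord, maf_low: float = 0.48, maf_high: float = 0.52
) -> bool:
    """True when the record must be excluded as strand-ambiguous.

    Exclusion requires both an A/T or C/G allele pair and a minor-allele
    frequency inside the closed window [maf_low, maf_high]. Without a
    frequency the ambiguity cannot be assessed; the record is kept with a
    warning (frequency-free mode skips harmonization entirely).
    """
    if record.freq_tested is None:
        if record.is_palindromic:
            logger.warning(
                "%s: palindromic alleles but no frequency; kept unfiltered",
                record.rsid,
            )
        return False
    return record.is_palindromic and maf_low <= record.maf <= maf_high


def harmonize_effects(record: SummaryRecord) -> SummaryRecord:
    """Re-express the record so the tested allele is the minor allele.

    When the tested allele is the major allele (freq > 0.5) the alleles are
    swapped, both per-sex betas are negated and the frequency complemented.
    Frequency exactly 0.5, or absent, leaves the record untouched.
    Standard errors and p-values are direction-free and unchanged.
    """
    if record.freq_tested is None or record.freq_tested <= 0.5:
        return record
    return replace(
        record,
        tested_allele=record.other_allele,
        other_allele=record.tested_allele,
        freq_tested=1.0 - record.freq_tested,
        beta_female=None if record.beta_female is None else -record.beta_female,
        beta_male=None if record.beta_male is None else -record.beta_male,
        harmonized=True,
    )


class AlleleMismatchError(ValueError):
    """Female and male rows carry irreconcilable allele assignments."""


def check_allele_consistency(
    female: SummaryRecord, male: SummaryRecord
) -> SummaryRecord | None:
    """Merge per-sex rows of the same SNP into one record, aligning alleles.

    If the male row's tested/other alleles are swapped relative to the
    female row, the male beta is negated and its frequency complemented.
    Returns None (exclusion) when the allele pairs neither match nor swap —
    including palindromic strand-complement cases that cannot be resolved.
    Raises on rsid mismatch (a usage error, not a data property).
    """
    if female.rsid != male.rsid:
        raise AlleleMismatchError(
            f"rsid mismatch: {female.rsid} vs {male.rsid}"
        )
    f_pair = (female.tested_allele, female.other_allele)
    if (male.tested_allele, male.other_allele) == f_pair:
        beta_m, se_m, p_m = male.beta_male, male.se_male, male.p_male
    elif (male.other_allele, male.tested_allele) == f_pair:
        beta_m = None if male.beta_male is None else -male.beta_male
        se_m, p_m = male.se_male, male.p_male
    else:
        logger.info("%s: irreconcilable alleles between sexes; excluded", female.rsid)
        return None
    return replace(female, beta_male=beta_m, se_male=se_m, p_male=p_m)


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------

def compute_z(record: SummaryRecord) -> float:
    """Dimorphism z: effect-size difference in pooled standard-error units."""
    if None in (
        record.beta_female,
        record.beta_male,
        record.se_female,
        record.se_male,
    ):
        raise ValueError(f"{record.rsid}: incomplete per-sex estimates")
    if record.se_female <= 0 or record.se_male <= 0:
        raise ValueError(f"{record.rsid}: non-positive standard error")
    return (record.beta_female - record.beta_male) / math.sqrt(
        record.se_female**2 + record.se_male**2
    )


def z_to_p(z: float) -> float:
    """Two-sided normal p-value, 2*(1 - Phi(|z|))."""
    if not math.isfinite(z):
        raise ValueError("z must be finite")
    return float(2.0 * norm.sf(abs(z)))


def classify(
    record: SummaryRecord,
    z: float | None,
    excluded: str | None = None,
    z_threshold: float = DIMORPHISM_Z,
    gwas_threshold: float = GENOME_WIDE_P,
) -> DimorphismResult:
    """Assemble the per-SNP result with threshold flags.

    Dimorphism uses |z| >= z_threshold (inclusive, "at least 3");
    trait association uses a strict p < gwas_threshold.
    """

    def _assoc(p):
        return p is not None and p < gwas_threshold

    return DimorphismResult(
        rsid=record.rsid,
        chrom=record.chrom,
        pos=record.pos,
        z=None if excluded else z,
        p_dimorphism=None if (excluded or z is None) else z_to_p(z),
        excluded=excluded,
        harmonized=record.harmonized,
        is_trait_associated_female=_assoc(record.p_female),
        is_trait_associated_male=_assoc(record.p_male),
        is_trait_associated_combined=_assoc(record.p_combined),
        is_dimorphic=(
            excluded is None and z is not None and abs(z) >= z_threshold
        ),
        in_core_gene=record.in_core_gene,
    )


def analyze_region(
    records: Iterable[SummaryRecord],
    region: GeneRegion,
    z_threshold: float = DIMORPHISM_Z,
    gwas_threshold: float = GENOME_WIDE_P,
    maf_low: float = 0.48,
    maf_high: float = 0.52,
    compute_scores: bool | None = None,
    force_unharmonized: bool = False,
) -> list[DimorphismResult]:
    """Full per-region screen: extract, filter, harmonize, score, classify.

    Steps run in the fixed order: palindromic exclusion -> direction
    harmonization -> z computation (allele consistency is expected to have
    been resolved at merge time via :func:`check_allele_consistency`).

    When the dataset carries no allele frequencies harmonization cannot be
    performed; in that frequency-free mode z-scores are not computed by
    default (``compute_scores=False`` is implied) and only per-SNP GWAS
    p-value flags are reported. Pass ``force_unharmonized=True`` to score
    anyway — the resulting z-signs are not strand-safe.
    """
    results: list[DimorphismResult] = []
    for rec in extract_region(records, region):
        if flag_palindromic(rec, maf_low, maf_high):
            results.append(
                classify(rec, None, excluded="palindromic-ambiguous",
                         z_threshold=z_threshold, gwas_threshold=gwas_threshold)
            )
            continue
        freq_free = rec.freq_tested is None
        if freq_free and not force_unharmonized:
            do_score = False
        else:
            do_score = True if compute_scores is None else compute_scores
        if freq_free and force_unharmonized:
            logger.warning(
                "%s: computing z without direction harmonization "
                "(no allele frequency available)", rec.rsid,
            )
        rec = harmonize_effects(rec)
        if not do_score:
            results.append(
                classify(rec, None, z_threshold=z_threshold,
                         gwas_threshold=gwas_threshold)
            )
            continue
        try:
            z = compute_z(rec)
        except ValueError:
            results.append(
                classify(rec, None, excluded="missing-fields",
                         z_threshold=z_threshold, gwas_threshold=gwas_threshold)
            )
            continue
        results.append(
            classify(rec, z, z_threshold=z_threshold,
                     gwas_threshold=gwas_threshold)
        )
    return results


def region_summary(results: Sequence[DimorphismResult], region: GeneRegion) -> dict:
    """Counts and percentages of dimorphic SNPs inside the core vs the flank."""
    core = [r for r in results if r.in_core_gene]
    flank = [r for r in results if not r.in_core_gene]

    def _block(rs):
        analyzed = [r for r in rs if r.excluded is None and r.z is not None]
        dim = [r for r in analyzed if r.is_dimorphic]
        return {
            "n_snps": len(rs),
            "n_analyzed": len(analyzed),
            "n_excluded": sum(1 for r in rs if r.excluded is not None),
            "n_dimorphic": len(dim),
            "pct_dimorphic": (100.0 * len(dim) / len(rs)) if rs else 0.0,
        }

    return {
        "region": region.name,
        "chrom": region.chrom,
        "region_start": region.region_start,
        "region_end": region.region_end,
        "core": _block(core),
        "flank": _block(flank),
        "total": _block(list(results)),
    }


def results_to_frame(results: Sequence[DimorphismResult]) -> pd.DataFrame:
    """Tabular view of per-SNP results, one row per SNP."""
    return pd.DataFrame(
        {
            "rsid": [r.rsid for r in results],
            "chrom": [r.chrom for r in results],
            "pos": [r.pos for r in results],
            "z": [r.z for r in results],
            "p_dimorphism": [r.p_dimorphism for r in results],
            "excluded": [r.excluded for r in results],
            "harmonized": [r.harmonized for r in results],
            "trait_assoc_female": [r.is_trait_associated_female for r in results],
            "trait_assoc_male": [r.is_trait_associated_male for r in results],
            "trait_assoc_combined": [r.is_trait_associated_combined for r in results],
            "is_dimorphic": [r.is_dimorphic for r in results],
            "in_core_gene": [r.in_core_gene for r in results],
        }
    )


def read_regions(path, flank: int = DEFAULT_FLANK) -> list[GeneRegion]:
    """Read regions from a BED-like 4-column file: name, chrom, start, end."""
    df = pd.read_csv(path, sep=None, engine="python", header=None,
                     names=["name", "chrom", "start", "end"], comment="#")
    return [
        GeneRegion(str(r["name"]), str(r["chrom"]), int(r["start"]),
                   int(r["end"]), flank=flank)
        for _, r in df.iterrows()
    ]
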