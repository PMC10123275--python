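"""Synthetic inputs for every pipeline stage.

Generates sex-stratified GWAS summary statistics with planted sex-specific
effects, palindromic and major-allele-tested records; case-control genotype
counts under Hardy-Weinberg with a tunable allelic odds ratio; obesity
trios with a tunable minor-allele transmission rate; and paired-depot
expression matrices with specified inter-gene correlation structure, group
offsets and covariate effects. All generators are deterministic given the
seed and return a truth object next to the data.

The defaults mirror the study conditions of the analyses downstream: a
single candidate region on chromosome 14, GWAS standard errors of a few
thousandths (sex-stratified samples in the 4e5 range), 192-per-group
mutation-screen counts, 781 trios, and 1,479 paired-depot expression
donors of whom 31 are non-obese.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .gwas import GeneRegion
from .variants import GenotypeCounts, TrioCounts

_BASES = ("A", "C", "G", "T")
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


def _spawn(seed: int, salt: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), salt]))


@dataclass
class SimulationConfig:
    """One bundle of knobs for all four generators.

    Only the block relevant to a generator is read by it; the seed is
    shared (each generator derives an independent stream from it).
    """

    seed: int = 0

    # --- summary statistics ---
    n_snps: int = 10_000
    region: GeneRegion = field(
        default_factory=lambda: GeneRegion("CKB", "14", 103_986_004, 103_989_167)
    )
    fraction_palindromic: float = 0.05
    fraction_major_tested: float = 0.5
    beta_female: float = 0.0
    beta_male: float = 0.0
    n_dimorphic: int = 0          # SNPs carrying the planted (beta_f, beta_m)
    se_female: float = 0.0034     # scale of per-sex standard errors
    se_male: float = 0.0037

    # --- trios ---
    n_trios: int = 781
    transmission_rate: float = 0.5
    trio_allele_freq: float = 0.005

    # --- case-control ---
    n_cases: int = 192
    n_controls: int = 192
    allele_freq: float = 0.39
    odds_ratio: float = 1.0

    # --- expression ---
    n_subjects: int = 1_479
    n_non_obese: int = 31
    genes: tuple[str, ...] = ("CKB", "CKMT1B", "GATM")
    # depot-specific inter-gene correlation targets (order = genes)
    vat_corr: tuple[tuple[float, ...], ...] = (
        (1.00, 0.43, 0.12),
        (0.43, 1.00, 0.21),
        (0.12, 0.21, 1.00),
    )
    sat_corr: tuple[tuple[float, ...], ...] = (
        (1.00, -0.26, -0.37),
        (-0.26, 1.00, 0.12),
        (-0.37, 0.12, 1.00),
    )
    # per-gene mean offsets: VAT above SAT, CKMT1B raised in obese VAT
    vat_offset: tuple[float, ...] = (0.8, 0.8, 0.8)
    obese_vat_offset: tuple[float, ...] = (0.0, 0.5, 0.0)
    noise_sd: float = 1.0
    sex_effect: float = 0.3
    age_effect: float = 0.01
    # phenotype -> (anchor gene index, target correlation, missing fraction)
    phenotypes: dict = field(
        default_factory=lambda: {
            "bmi": (0, -0.06, 0.0),
            "body_fat": (0, 0.11, 0.55),
            "nefa": (0, 0.30, 0.97),
            "hba1c": (0, -0.07, 0.47),
        }
    )


# ---------------------------------------------------------------------------
# GWAS summary statistics
# ---------------------------------------------------------------------------

def gen_summary_stats(config: SimulationConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a sex-stratified summary-statistics table plus its truth.

    Per SNP, true per-sex effects are the configured values for the first
    ``n_dimorphic`` SNPs and zero (null) otherwise; observed betas add
    independent normal noise at the per-sex standard error (the two sex
    strata are disjoint samples, so their errors are independent). A
    configured fraction of SNPs is emitted palindromic with MAF inside
    [0.48, 0.52]; an independent fraction is emitted with the major allele
    as the tested allele, to exercise direction harmonization. Returns
    (observed table, truth table).
    """
    cfg = config
    rng = _spawn(cfg.seed, 1)
    n = cfg.n_snps
    region = cfg.region
    if not 0 <= cfg.fraction_palindromic <= 1:
        raise ValueError("fraction_palindromic outside [0, 1]")
    if cfg.se_female <= 0 or cfg.se_male <= 0:
        raise ValueError("standard errors must be positive")

    pos = np.sort(
        rng.choice(
            np.arange(region.region_start, region.region_end + 1),
            size=n, replace=False,
        )
    )
    palindromic = rng.random(n) < cfg.fraction_palindromic
    major_tested = rng.random(n) < cfg.fraction_major_tested

    tested = np.empty(n, dtype="U1")
    other = np.empty(n, dtype="U1")
    for i in range(n):
        a = _BASES[rng.integers(4)]
        if palindromic[i]:
            b = _COMPLEMENT[a]
        else:
            choices = [x for x in _BASES if x not in (a, _COMPLEMENT[a])]
            b = choices[rng.integers(len(choices))]
        tested[i], other[i] = a, b

    maf = np.where(
        palindromic,
        rng.uniform(0.48, 0.50, n),
        rng.uniform(0.05, 0.50, n),
    )
    freq = np.where(major_tested, 1.0 - maf, maf)

    true_bf = np.zeros(n)
    true_bm = np.zeros(n)
    k = min(cfg.n_dimorphic, n)
    true_bf[:k] = cfg.beta_female
    true_bm[:k] = cfg.beta_male
    # truth is stated for the minor allele; flip for major-tested records
    sign = np.where(major_tested, -1.0, 1.0)

    se_f = cfg.se_female * rng.uniform(0.8, 1.2, n)
    se_m = cfg.se_male * rng.uniform(0.8, 1.2, n)
    beta_f = sign * true_bf + rng.normal(0.0, se_f)
    beta_m = sign * true_bm + rng.normal(0.0, se_m)

    from scipy.stats import norm

    p_f = 2 * norm.sf(np.abs(beta_f / se_f))
    p_m = 2 * norm.sf(np.abs(beta_m / se_m))
    beta_c = (beta_f / se_f**2 + beta_m / se_m**2) / (1 / se_f**2 + 1 / se_m**2)
    se_c = np.sqrt(1.0 / (1 / se_f**2 + 1 / se_m**2))
    p_c = 2 * norm.sf(np.abs(beta_c / se_c))

    rsids = [f"rs{900_000_000 + i}" for i in range(n)]
    observed = pd.DataFrame(
        {
            "chrom": region.chrom,
            "pos": pos,
            "rsid": rsids,
            "tested_allele": tested,
            "other_allele": other,
            "freq_tested": freq,
            "beta_female": beta_f,
            "se_female": se_f,
            "p_female": np.clip(p_f, np.nextafter(0, 1), 1.0),
            "beta_male": beta_m,
            "se_male": se_m,
            "p_male": np.clip(p_m, np.nextafter(0, 1), 1.0),
            "p_combined": np.clip(p_c, np.nextafter(0, 1), 1.0),
        }
    )
    truth = pd.DataFrame(
        {
            "rsid": rsids,
            "pos": pos,
            "true_beta_female": true_bf,
            "true_beta_male": true_bm,
            "palindromic": palindromic,
            "major_tested": major_tested,
            "maf": maf,
        }
    )
    return observed, truth


# ---------------------------------------------------------------------------
# trios
# ---------------------------------------------------------------------------

def gen_trios(config: SimulationConfig) -> tuple[pd.DataFrame, TrioCounts]:
    """Simulate trio genotypes with distorted transmission.

    Parent genotypes are Hardy-Weinberg draws at the configured minor
    allele frequency; each heterozygous parent transmits the minor allele
    with probability ``transmission_rate``; homozygous parents transmit
    their only allele. Children are therefore always Mendelian-consistent.
    Returns (trio table, true transmission counts).
    """
    cfg = config
    if not 0 < cfg.transmission_rate < 1:
        raise ValueError("transmission_rate must lie in (0, 1)")
    rng = _spawn(cfg.seed, 2)
    f = cfg.trio_allele_freq
    fathers = rng.binomial(2, f, cfg.n_trios)
    mothers = rng.binomial(2, f, cfg.n_trios)

    def _transmit(gt: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        het = gt == 1
        minor = np.where(
            het, rng.random(len(gt)) < cfg.transmission_rate, gt == 2
        )
        return minor.astype(int), het, minor & het

    f_allele, f_het, f_trans = _transmit(fathers)
    m_allele, m_het, m_trans = _transmit(mothers)
    children = f_allele + m_allele

    b_pat = int(f_trans.sum())
    c_pat = int((f_het & ~f_trans).sum())
    b_mat = int(m_trans.sum())
    c_mat = int((m_het & ~m_trans).sum())
    truth = TrioCounts(
        b_pat + b_mat, c_pat + c_mat, b_mat, c_mat, b_pat, c_pat
    )
    table = pd.DataFrame(
        {
            "family_id": [f"fam{i:05d}" for i in range(cfg.n_trios)],
            "father_gt": fathers,
            "mother_gt": mothers,
            "child_gt": children,
        }
    )
    return table, truth


# ---------------------------------------------------------------------------
# case-control genotype counts
# ---------------------------------------------------------------------------

def gen_case_control(config: SimulationConfig) -> pd.DataFrame:
    """Simulate a genotype-count table for one variant in two groups.

    Controls are Hardy-Weinberg draws at the configured allele frequency;
    cases at the frequency implied by the allelic odds-ratio model,
    odds_case = odds_control * OR, also in Hardy-Weinberg proportions
    within the group.
    """
    cfg = config
    if cfg.odds_ratio <= 0 or not 0 < cfg.allele_freq < 1:
        raise ValueError("need odds_ratio > 0 and allele_freq in (0, 1)")
    rng = _spawn(cfg.seed, 3)
    f0 = cfg.allele_freq
    odds = f0 / (1 - f0) * cfg.odds_ratio
    f1 = odds / (1 + odds)

    def _draw(n, f, label):
        gts = rng.binomial(2, f, n)
        return {
            "variant": "simvar",
            "group": label,
            "n11": int((gts == 0).sum()),
            "n12": int((gts == 1).sum()),
            "n22": int((gts == 2).sum()),
        }

    return pd.DataFrame(
        [_draw(cfg.n_cases, f1, "cases"), _draw(cfg.n_controls, f0, "controls")]
    )


def counts_from_row(row: pd.Series) -> GenotypeCounts:
    return GenotypeCounts(
        int(row["n11"]), int(row["n12"]), int(row["n22"]),
        group_label=str(row["group"]),
    )


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def gen_expression(config: SimulationConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a paired-depot expression matrix with metadata.

    Per depot, gene vectors are multivariate normal with the configured
    target correlation matrix; VAT and SAT samples of the same subject
    share a subject id. Group mean offsets (VAT above SAT; an extra shift
    for obese VAT where configured) and additive sex/age effects are
    applied afterwards, so the planted inter-gene correlations survive
    covariate residualization. Phenotypes are generated as noisy linear
    functions of an anchor gene to hit a target correlation, with a
    configured fraction set missing. Returns (values, sample_meta) with
    values genes x samples.
    """
    cfg = config
    rng = _spawn(cfg.seed, 4)
    g = len(cfg.genes)
    n = cfg.n_subjects

    meta_rows = []
    blocks = []
    sex = rng.random(n) < 0.7  # female-majority cohort
    age = np.clip(rng.normal(47.0, 12.0, n), 18, 85)
    obese = np.zeros(n, dtype=bool)
    obese[cfg.n_non_obese:] = True

    for depot, corr in (("VAT", cfg.vat_corr), ("SAT", cfg.sat_corr)):
        C = np.asarray(corr, dtype=float)
        if C.shape != (g, g):
            raise ValueError(f"{depot} correlation matrix is not {g}x{g}")
        eig = np.linalg.eigvalsh(C)
        if eig.min() < -1e-10:
            raise ValueError(
                f"{depot} correlation matrix is not positive semi-definite"
            )
        L = np.linalg.cholesky(C + 1e-12 * np.eye(g))
        latent = (L @ rng.standard_normal((g, n))) * cfg.noise_sd
        shift = np.zeros((g, n))
        if depot == "VAT":
            shift += np.asarray(cfg.vat_offset)[:, None]
            shift += np.outer(np.asarray(cfg.obese_vat_offset), obese)
        shift += cfg.sex_effect * sex[None, :]
        shift += cfg.age_effect * age[None, :]
        blocks.append(latent + shift)
        for i in range(n):
            meta_rows.append(
                {
                    "sample": f"{depot}_{i:05d}",
                    "subject": f"subj{i:05d}",
                    "depot": depot,
                    "group": "obese" if obese[i] else "non-obese",
                    "sex": "F" if sex[i] else "M",
                    "age": age[i],
                }
            )

    values = np.concatenate(blocks, axis=1)
    meta = pd.DataFrame(meta_rows).set_index("sample")

    # phenotypes anchored on a gene's VAT latent signal, shared across depots
    vat_latent = blocks[0]
    for name, (gi, rho, miss) in cfg.phenotypes.items():
        if not -1 < rho < 1:
            raise ValueError(f"phenotype '{name}': correlation must be in (-1, 1)")
        anchor = vat_latent[gi] - vat_latent[gi].mean()
        anchor = anchor / anchor.std()
        noise = rng.standard_normal(n)
        ph = rho * anchor + np.sqrt(1 - rho**2) * noise
        ph_full = np.tile(ph, 2)
        drop = rng.random(n) < miss
        ph_full[np.tile(drop, 2)] = np.nan
        meta[name] = ph_full

    frame = pd.DataFrame(values, index=list(cfg.genes), columns=meta.index)
    return frame, meta


# ---------------------------------------------------------------------------
# file output
# ---------------------------------------------------------------------------

def write_outputs(kind: str, config: SimulationConfig, out_dir) -> dict[str, str]:
    """Run one generator and write its data + truth as TSV under out_dir.

    Returns {role: path}. ``kind`` is one of summary | trios | casecontrol
    | expression.
    """
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}

    def _save(df: pd.DataFrame, name: str, role: str, index=False):
        p = out / name
        df.to_csv(p, sep="\t", index=index)
        paths[role] = str(p)

    if kind == "summary":
        obs, truth = gen_summary_stats(config)
        _save(obs, "summary_stats.tsv", "data")
        _save(truth, "summary_truth.tsv", "truth")
    elif kind == "trios":
        table, truth = gen_trios(config)
        _save(table, "trios.tsv", "data")
        _save(
            pd.DataFrame([dataclasses.asdict(truth)]), "trios_truth.tsv", "truth"
        )
    elif kind == "casecontrol":
        _save(gen_case_control(config), "genotype_counts.tsv", "data")
    elif kind == "expression":
        frame, meta = gen_expression(config)
        _save(frame, "expression.tsv", "data", index=True)
        _save(meta, "sample_meta.tsv", "meta", index=True)
    else:
        raise ValueError(f"unknown generator kind '{kind}'")
    return paths
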