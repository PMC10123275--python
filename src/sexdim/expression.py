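"""Adipose-tissue expression correlation screen and group comparisons.

Operates on an already-normalized gene x sample expression matrix with
per-sample metadata (depot, obesity group, sex, age, clinical phenotypes).
Provides Pearson correlation with Fisher-z confidence intervals, a
per-depot correlation screen with Hommel multiple-testing adjustment,
Kruskal-Wallis with Dunn pairwise post-hoc tests (tie-corrected), and
linear residualization on sex/age covariates.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

#: phenotype columns understood by the screen (metadata may carry a subset)
PHENOTYPE_COLUMNS = (
    "bmi", "body_fat", "waist", "whr", "homa_ir", "hba1c",
    "nefa", "crp", "fpi", "fpg", "hdl", "ldl", "leptin",
)


@dataclass(frozen=True)
class CorrelationResult:
    pair: str
    n: int
    rho: float
    ci_low: float
    ci_high: float
    p_raw: float
    p_adj: float | None = None


@dataclass(frozen=True)
class PairwiseComparison:
    group_a: str
    group_b: str
    z: float
    p_raw: float
    p_adj: float


@dataclass(frozen=True)
class GroupComparisonResult:
    groups: tuple[str, ...]
    h_statistic: float
    df: int
    p_value: float
    epsilon_squared: float
    pairwise: tuple[PairwiseComparison, ...]


class ExpressionDataset:
    """Gene x sample normalized expression with per-sample metadata.

    ``values``: DataFrame indexed by gene, columns are sample ids.
    ``sample_meta``: DataFrame indexed by sample id with at least a
    ``depot`` column (VAT | SAT); usually also ``subject``, ``group``
    (obese | non-obese), ``sex``, ``age`` and phenotype columns, with
    missing values allowed.
    """

    def __init__(self, values: pd.DataFrame, sample_meta: pd.DataFrame):
        if values.shape[1] != sample_meta.shape[0]:
            raise ValueError(
                f"{values.shape[1]} expression columns vs "
                f"{sample_meta.shape[0]} metadata rows"
            )
        if not values.columns.equals(sample_meta.index):
            sample_meta = sample_meta.loc[values.columns]
        if "age" in sample_meta and (sample_meta["age"].dropna() < 0).any():
            raise ValueError("negative age in sample metadata")
        self.values = values
        self.sample_meta = sample_meta

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    def subset(self, mask: pd.Series) -> "ExpressionDataset":
        aligned = mask.reindex(self.sample_meta.index).fillna(False).astype(bool)
        keep = self.sample_meta.index[aligned]
        return ExpressionDataset(self.values[keep], self.sample_meta.loc[keep])

    def depot(self, label: str) -> "ExpressionDataset":
        return self.subset(self.sample_meta["depot"] == label)


# ---------------------------------------------------------------------------
# correlation
# ---------------------------------------------------------------------------

def pearson_with_ci(
    x: Sequence[float], y: Sequence[float], conf: float = 0.95
) -> CorrelationResult:
    """Pearson r with two-sided t-test p and Fisher-z confidence interval.

    Missing values are removed pairwise; at least 3 complete pairs are
    required and both vectors must vary.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    n = len(x)
    if n < 3:
        raise ValueError(f"need >= 3 complete pairs, got {n}")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance: correlation undefined")
    r, p = stats.pearsonr(x, y)
    r = float(np.clip(r, -1.0, 1.0))
    if abs(r) == 1.0:
        lo = hi = r
    else:
        zcrit = stats.norm.ppf(0.5 + conf / 2)
        fz = np.arctanh(r)
        half = zcrit / np.sqrt(n - 3)
        lo, hi = np.tanh(fz - half), np.tanh(fz + half)
    return CorrelationResult("", n, r, float(lo), float(hi), float(p))


def hommel_adjust(p_values: Sequence[float]) -> list[float]:
    """Hommel step-up adjusted p-values.

    Controls the family-wise error rate through the closure principle with
    Simes local tests; uniformly no larger than Bonferroni and never
    smaller than the raw p-values.
    """
    p = list(p_values)
    if not p:
        return []
    if any(not 0 < v <= 1 for v in p):
        raise ValueError("p-values must lie in (0, 1]")
    if len(p) == 1:
        return [float(p[0])]
    _, adj, _, _ = multipletests(p, method="hommel")
    return [float(v) for v in adj]


def correlation_screen(
    dataset: ExpressionDataset,
    genes: Sequence[str],
    phenotypes: Sequence[str] = (),
    depot: str | None = None,
    subset_filter: Callable[[pd.DataFrame], pd.Series] | None = None,
    max_age: float | None = None,
    adjust: bool = True,
) -> list[CorrelationResult]:
    """All gene-gene and gene-phenotype Pearson correlations in one depot.

    Per-pair sample size reflects pairwise-complete observations, so
    phenotypes with heavy missingness yield smaller n without shrinking
    the rest of the screen. The Hommel adjustment is applied across all
    pairs of this invocation (one family per screen; per the displayed
    panel). ``max_age`` keeps samples with age <= max_age, the menopause-
    motivated subset.
    """
    ds = dataset
    if depot is not None:
        ds = ds.depot(depot)
    if max_age is not None:
        ds = ds.subset(ds.sample_meta["age"] <= max_age)
    if subset_filter is not None:
        mask = subset_filter(ds.sample_meta)
        ds = ds.subset(mask)
    if ds.values.shape[1] == 0:
        raise ValueError(
            "empty sample subset after filters "
            f"(depot={depot!r}, max_age={max_age!r})"
        )
    missing = [g for g in genes if g not in ds.values.index]
    if missing:
        raise KeyError(f"genes not in expression matrix: {missing}")

    results: list[CorrelationResult] = []
    for ga, gb in itertools.combinations(genes, 2):
        res = pearson_with_ci(ds.values.loc[ga], ds.values.loc[gb])
        results.append(
            CorrelationResult(f"{ga}~{gb}", res.n, res.rho, res.ci_low,
                              res.ci_high, res.p_raw)
        )
    for g in genes:
        for ph in phenotypes:
            if ph not in ds.sample_meta.columns:
                logger.warning("phenotype '%s' absent from metadata; skipped", ph)
                continue
            y = ds.sample_meta[ph].astype(float).to_numpy()
            if np.isnan(y).all():
                logger.warning("phenotype '%s' all-missing; skipped", ph)
                continue
            try:
                res = pearson_with_ci(ds.values.loc[g], y)
            except ValueError as exc:
                logger.warning("pair %s~%s skipped: %s", g, ph, exc)
                continue
            results.append(
                CorrelationResult(f"{g}~{ph}", res.n, res.rho, res.ci_low,
                                  res.ci_high, res.p_raw)
            )
    if adjust and results:
        adjusted = hommel_adjust([r.p_raw for r in results])
        results = [
            CorrelationResult(r.pair, r.n, r.rho, r.ci_low, r.ci_high,
                              r.p_raw, a)
            for r, a in zip(results, adjusted)
        ]
    return results


def correlations_to_frame(results: Sequence[CorrelationResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "pair": [r.pair for r in results],
            "n": [r.n for r in results],
            "rho": [r.rho for r in results],
            "ci_low": [r.ci_low for r in results],
            "ci_high": [r.ci_high for r in results],
            "p_raw": [r.p_raw for r in results],
            "p_adj": [r.p_adj for r in results],
        }
    )


# ---------------------------------------------------------------------------
# group comparisons
# ---------------------------------------------------------------------------

def kruskal_dunn(
    values: Sequence[float], group_labels: Sequence[str]
) -> GroupComparisonResult:
    """Kruskal-Wallis test with epsilon-squared effect size and Dunn post-hocs.

    H uses the standard tie correction. Epsilon-squared is
    H / ((n^2 - 1)/(n + 1)) = H/(n - 1). Dunn pairwise z-statistics use the
    tie-corrected variance; two-sided pairwise p-values are Hommel-adjusted
    as one family.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(group_labels)
    ok = ~np.isnan(values)
    values, labels = values[ok], labels[ok]
    groups = [str(g) for g in pd.unique(labels)]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    samples = [values[labels == g] for g in groups]
    if any(len(s) == 0 for s in samples):
        raise ValueError("every group needs at least one observation")
    h, p = stats.kruskal(*samples)
    n = len(values)
    eps2 = float(h) / (n - 1) if n > 1 else float("nan")

    ranks = stats.rankdata(values)
    mean_ranks = {g: ranks[labels == g].mean() for g in groups}
    sizes = {g: int((labels == g).sum()) for g in groups}
    _, tie_counts = np.unique(values, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts).sum()) / (12.0 * (n - 1)))
    var_base = n * (n + 1) / 12.0 - tie_term

    raw: list[tuple[str, str, float, float]] = []
    for ga, gb in itertools.combinations(groups, 2):
        se = np.sqrt(var_base * (1.0 / sizes[ga] + 1.0 / sizes[gb]))
        z = (mean_ranks[ga] - mean_ranks[gb]) / se if se > 0 else 0.0
        raw.append((ga, gb, float(z), float(2 * stats.norm.sf(abs(z)))))
    adj = hommel_adjust([max(min(t[3], 1.0), np.nextafter(0, 1)) for t in raw])
    pairwise = tuple(
        PairwiseComparison(ga, gb, z, pr, pa)
        for (ga, gb, z, pr), pa in zip(raw, adj)
    )
    return GroupComparisonResult(
        tuple(groups), float(h), len(groups) - 1, float(p), eps2, pairwise
    )


# ---------------------------------------------------------------------------
# covariate adjustment
# ---------------------------------------------------------------------------

def adjust_covariates(
    values: pd.DataFrame,
    covariates: pd.DataFrame,
    age_bins: Sequence[float] | None = None,
) -> pd.DataFrame:
    """Residualize each gene on sex and age, preserving the gene's mean.

    Sex enters as a binary indicator and age as a linear term, or as
    indicator-coded bins when ``age_bins`` is given. Covariate columns
    that are constant are dropped (nothing to remove). Residuals are
    orthogonal to the retained covariate columns.
    """
    if values.shape[1] != covariates.shape[0]:
        raise ValueError("covariate rows must match expression columns")
    cols = []
    if "sex" in covariates:
        sex = covariates["sex"]
        levels = pd.unique(sex.dropna())
        if len(levels) > 2:
            raise ValueError("sex must be binary")
        cols.append((sex == levels[0]).astype(float).to_numpy())
    if "age" in covariates:
        age = covariates["age"].astype(float).to_numpy()
        if np.isnan(age).any():
            raise ValueError("age must be complete for used samples")
        if age_bins is not None:
            binned = np.digitize(age, np.asarray(age_bins))
            for level in np.unique(binned)[1:]:
                cols.append((binned == level).astype(float))
        else:
            cols.append(age)

    design = [c for c in cols if np.std(c) > 0]
    if not design:
        return values.copy()
    X = np.column_stack([np.ones(values.shape[1])] + design)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("collinear covariate design")
    Y = values.to_numpy(dtype=float).T
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    adjusted = resid.T + Y.mean(axis=0)[:, None]
    return pd.DataFrame(adjusted, index=values.index, columns=values.columns)
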