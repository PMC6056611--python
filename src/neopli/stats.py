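"""Cohort-level statistics relating connectivity to postmenstrual age.

The battery mirrors a standard clinical-cohort analysis: per-band
correlation of subject mPLI with PMA (Pearson when the band's mPLI
distribution has no outliers, Spearman otherwise, outliers being |z| >
3.29), ordinary least-squares regression of mPLI on PMA, hierarchical
regression steps adding gestational age and birth weight, Mann-Whitney
group contrasts (sex, asphyxia), a per-pair topographic correlation map,
and within-subject longitudinal trends.

Conventions fixed here: all p-values are two-sided; significance thresholds
are alpha = 0.005 for global (whole-head) analyses and alpha = 1e-4 for
local (per-pair) analyses, a threshold-based multiplicity control; outlier
gating looks at the mPLI values only, not at PMA; models with missing
covariates use listwise deletion and always report the number of complete
cases.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import scipy.stats
import statsmodels.api as sm

from .montage import Montage
from .pli import PLIMatrix

__all__ = [
    "ALPHA_GLOBAL",
    "ALPHA_LOCAL",
    "OUTLIER_Z",
    "CorrelationResult",
    "RegressionResult",
    "HierarchicalStep",
    "GroupContrast",
    "TopographyResult",
    "detect_outliers",
    "correlate_band",
    "fit_linear_model",
    "hierarchical_regression",
    "mann_whitney",
    "topography_correlations",
    "longitudinal_trend",
    "spearman_exact",
]

ALPHA_GLOBAL = 0.005   # whole-head analyses
ALPHA_LOCAL = 1e-4     # per-pair analyses
OUTLIER_Z = 3.29


@dataclass
class CorrelationResult:
    coefficient: float
    p_value: float
    method: str          # "pearson" | "spearman"
    n: int

    def significant(self, alpha: float = ALPHA_GLOBAL) -> bool:
        return self.p_value < alpha


@dataclass
class RegressionResult:
    """OLS of y on a single predictor x with intercept.

    ``r`` is the signed multiple correlation (sign of the slope), so for a
    single predictor it equals the Pearson correlation of x and y.
    """

    intercept_b0: float
    slope_b1: float
    t_b0: float
    t_b1: float
    p_b0: float
    p_b1: float
    f_stat: float
    df_model: int
    df_resid: int
    p_model: float
    r: float
    r_squared: float
    n: int


@dataclass
class HierarchicalStep:
    added_covariate: str
    r_squared_change: float
    f_change: float
    df1: int
    df2: int
    p_change: float
    r_squared_full: float
    n: int


@dataclass
class GroupContrast:
    u: float
    z: float
    p: float
    n1: int
    n2: int


@dataclass
class TopographyResult:
    """Per-pair correlation of pwPLI with PMA over the cohort.

    ``coefficients``/``p_values`` are length-210 arrays in canonical pair
    order (NaN where a pair had zero variance across the cohort).
    ``ranking`` orders valid pairs from most negative coefficient upward,
    ties broken by canonical pair index.
    """

    pair_labels: list[tuple[str, str]]
    coefficients: np.ndarray
    p_values: np.ndarray
    significant: np.ndarray
    ranking: np.ndarray
    n: int
    alpha: float = ALPHA_LOCAL

    def top(self, k: int = 10) -> list[tuple[tuple[str, str], float, float]]:
        """The k most negative correlations: (labels, r, p)."""
        out = []
        for idx in self.ranking[:k]:
            out.append((self.pair_labels[idx], float(self.coefficients[idx]),
                        float(self.p_values[idx])))
        return out


def detect_outliers(values: Sequence[float], z_threshold: float = OUTLIER_Z
                    ) -> np.ndarray:
    """Indices whose |z| exceeds the threshold (sample sd, n-1 denominator).

    A zero-variance sample has no outliers by definition.
    """
    x = np.asarray(values, dtype=np.float64)
    if x.size < 3:
        raise ValueError("need at least 3 values for outlier detection")
    sd = x.std(ddof=1)
    if sd == 0:
        return np.array([], dtype=int)
    z = (x - x.mean()) / sd
    return np.flatnonzero(np.abs(z) > z_threshold)


def correlate_band(pma: Sequence[float], mpli: Sequence[float]) -> CorrelationResult:
    """Correlate subject mPLI with PMA, outlier-gated.

    Pearson when the mPLI sample contains no outliers (|z| > 3.29),
    Spearman (rank correlation, robust to the outliers) otherwise.  The
    gate inspects the mPLI values only.
    """
    x = np.asarray(pma, dtype=np.float64)
    y = np.asarray(mpli, dtype=np.float64)
    if x.size != y.size:
        raise ValueError("pma and mpli must be the same length")
    if x.size < 3:
        raise ValueError("need at least 3 subjects")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values in correlation input")
    if detect_outliers(y).size == 0:
        r, p = scipy.stats.pearsonr(x, y)
        method = "pearson"
    else:
        r, p = scipy.stats.spearmanr(x, y)
        method = "spearman"
    return CorrelationResult(coefficient=float(r), p_value=float(p),
                             method=method, n=int(x.size))


def fit_linear_model(pma: Sequence[float], mpli: Sequence[float]) -> RegressionResult:
    """OLS of mPLI on PMA with intercept (all predictors entered at once).

    Reports B0, B1, their t statistics on n-2 df, the model F(1, n-2), and
    R/R^2; for a single predictor R equals the Pearson correlation and
    F = t_B1^2.
    """
    x = np.asarray(pma, dtype=np.float64)
    y = np.asarray(mpli, dtype=np.float64)
    if x.size != y.size or x.size < 3:
        raise ValueError("need >= 3 paired observations")
    if np.ptp(x) == 0:
        raise ValueError("constant predictor: slope not identifiable")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    b0, b1 = model.params
    r2 = float(model.rsquared)
    return RegressionResult(
        intercept_b0=float(b0),
        slope_b1=float(b1),
        t_b0=float(model.tvalues[0]),
        t_b1=float(model.tvalues[1]),
        p_b0=float(model.pvalues[0]),
        p_b1=float(model.pvalues[1]),
        f_stat=float(model.fvalue),
        df_model=int(model.df_model),
        df_resid=int(model.df_resid),
        p_model=float(model.f_pvalue),
        r=float(np.sign(b1) * math.sqrt(r2)) if r2 > 0 else 0.0,
        r_squared=r2,
        n=int(x.size),
    )


def hierarchical_regression(
    pma: Sequence[float],
    mpli: Sequence[float],
    covariates: dict[str, Sequence[float]],
) -> list[HierarchicalStep]:
    """Hierarchical OLS: add each covariate to mPLI ~ PMA in turn.

    Covariates are added cumulatively in the given order.  For each step,
    subjects missing any variable of that step's model are dropped
    (listwise deletion), and both the nested and the augmented model are
    refit on that step's complete cases so the R^2 change is well defined:

        F_change = (dR^2 / 1) / ((1 - R^2_full) / (n - p_full - 1))

    A covariate collinear with the model it joins is fatal, named.
    """
    base_x = np.asarray(pma, dtype=np.float64)
    y_all = np.asarray(mpli, dtype=np.float64)
    names = list(covariates)
    cols = [np.asarray(covariates[nm], dtype=np.float64) for nm in names]
    steps: list[HierarchicalStep] = []
    for k, nm in enumerate(names):
        step_cols = [base_x] + cols[: k + 1]
        stack = np.column_stack(step_cols + [y_all])
        keep = np.all(np.isfinite(stack), axis=1)
        n = int(keep.sum())
        p_full = k + 2  # PMA + covariates so far
        if n < p_full + 2:
            raise ValueError(f"too few complete cases ({n}) for step {nm!r}")
        y = y_all[keep]
        x_red = np.column_stack(step_cols[:-1])[keep]
        x_full = np.column_stack(step_cols)[keep]
        if np.linalg.matrix_rank(sm.add_constant(x_full)) < p_full + 1:
            raise ValueError(f"covariate {nm!r} is collinear with the model")
        red = sm.OLS(y, sm.add_constant(x_red)).fit()
        full = sm.OLS(y, sm.add_constant(x_full)).fit()
        dr2 = float(full.rsquared - red.rsquared)
        df2 = n - p_full - 1
        denom = (1.0 - full.rsquared) / df2
        f_change = dr2 / denom if denom > 0 else math.inf
        p_change = float(scipy.stats.f.sf(f_change, 1, df2))
        steps.append(HierarchicalStep(
            added_covariate=nm,
            r_squared_change=dr2,
            f_change=float(f_change),
            df1=1,
            df2=df2,
            p_change=p_change,
            r_squared_full=float(full.rsquared),
            n=n,
        ))
    return steps


def mann_whitney(group_a: Sequence[float], group_b: Sequence[float]) -> GroupContrast:
    """Mann-Whitney U contrast with tie-corrected normal approximation.

    U is the statistic of the first group.  z = (U - n1 n2 / 2) / sigma
    with the tie-corrected sigma (no continuity correction).  The p-value
    is exact (scipy enumeration) for small tie-free samples, asymptotic
    otherwise.
    """
    a = np.asarray(group_a, dtype=np.float64)
    b = np.asarray(group_b, dtype=np.float64)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    res = scipy.stats.mannwhitneyu(a, b, alternative="two-sided")
    u = float(res.statistic)
    n1, n2 = a.size, b.size
    nt = n1 + n2
    pooled = np.concatenate([a, b])
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts))
    mu = n1 * n2 / 2.0
    var = n1 * n2 / 12.0 * ((nt + 1) - tie_term / (nt * (nt - 1)))
    z = 0.0 if var == 0 else (u - mu) / math.sqrt(var)
    return GroupContrast(u=u, z=float(z), p=float(res.pvalue), n1=n1, n2=n2)


def topography_correlations(
    pwpli_matrices: Sequence[PLIMatrix],
    pma: Sequence[float],
    montage: Montage | None = None,
    alpha: float = ALPHA_LOCAL,
) -> TopographyResult:
    """Pearson correlation of each pair's pwPLI with PMA across the cohort.

    Returns all 210 coefficients in canonical pair order, a significance
    flag at the local alpha, and the ranking from most negative upward
    (ties by pair index).  Zero-variance pairs are recorded as missing and
    excluded from the ranking with a warning.
    """
    montage = montage or (Montage() if pwpli_matrices[0].n_channels == 21 else None)
    x = np.asarray(pma, dtype=np.float64)
    if len(pwpli_matrices) != x.size:
        raise ValueError("one pwPLI matrix per subject required")
    if x.size < 3:
        raise ValueError("need at least 3 subjects")
    tri = np.stack([m.upper_triangle() for m in pwpli_matrices])  # subjects x 210
    n_pairs = tri.shape[1]
    xc = x - x.mean()
    yc = tri - tri.mean(axis=0)
    sx = math.sqrt(float(xc @ xc))
    sy = np.sqrt((yc**2).sum(axis=0))
    coeffs = np.full(n_pairs, np.nan)
    valid = sy > 0
    if not np.all(valid):
        warnings.warn(
            f"{int((~valid).sum())} pair(s) with zero variance excluded "
            "from topography ranking"
        )
    coeffs[valid] = (xc @ yc[:, valid]) / (sx * sy[valid])
    coeffs[valid] = np.clip(coeffs[valid], -1.0, 1.0)
    n = x.size
    pvals = np.full(n_pairs, np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = coeffs[valid] * np.sqrt((n - 2) / np.maximum(1 - coeffs[valid] ** 2, 1e-300))
    pvals[valid] = 2 * scipy.stats.t.sf(np.abs(t), n - 2)
    sig = np.zeros(n_pairs, dtype=bool)
    sig[valid] = pvals[valid] < alpha
    order = np.lexsort((np.arange(n_pairs)[valid], coeffs[valid]))
    ranking = np.flatnonzero(valid)[order]
    labels = (montage.pair_labels() if montage is not None
              else [(str(i), str(j)) for i, j in
                    zip(*np.triu_indices(pwpli_matrices[0].n_channels, k=1))])
    return TopographyResult(
        pair_labels=labels, coefficients=coeffs, p_values=pvals,
        significant=sig, ranking=ranking, n=n, alpha=alpha,
    )


def spearman_exact(x: Sequence[float], y: Sequence[float],
                   exact_max_n: int = 8) -> CorrelationResult:
    """Spearman rank correlation with an exact permutation p for small n.

    rho is the tie-corrected rank correlation (Pearson on mid-ranks).  For
    n <= ``exact_max_n`` the two-sided p-value is the exact fraction of the
    n! permutations of one ranking with |rho| >= |rho_observed| (a strictly
    monotone series of 6 points gives p = 2/720); beyond that the usual
    t approximation is used.
    """
    xa = np.asarray(x, dtype=np.float64)
    ya = np.asarray(y, dtype=np.float64)
    n = xa.size
    if n != ya.size or n < 3:
        raise ValueError("need >= 3 paired observations")
    rx = scipy.stats.rankdata(xa)
    ry = scipy.stats.rankdata(ya)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if n <= exact_max_n:
        target = abs(rho) - 1e-12
        count = 0
        total = 0
        rxc = rx - rx.mean()
        denom_x = math.sqrt(float(rxc @ rxc))
        ryc = ry - ry.mean()
        denom_y = math.sqrt(float(ryc @ ryc))
        for perm in itertools.permutations(range(n)):
            r = float(rxc @ ryc[list(perm)]) / (denom_x * denom_y)
            if abs(r) >= target:
                count += 1
            total += 1
        p = count / total
    else:
        p = float(scipy.stats.spearmanr(xa, ya).pvalue)
    return CorrelationResult(coefficient=rho, p_value=p, method="spearman", n=n)


def longitudinal_trend(
    pma_points: Sequence[float],
    mpli_points: Sequence[float],
    min_points: int = 6,
) -> tuple[CorrelationResult, RegressionResult]:
    """Within-subject trend over repeated recordings.

    Requires at least ``min_points`` time points (the inclusion rule is
    more than five recordings).  Returns the Spearman rank correlation with
    an exact small-sample p, plus the OLS line of mPLI on PMA.
    """
    x = np.asarray(pma_points, dtype=np.float64)
    y = np.asarray(mpli_points, dtype=np.float64)
    if x.size < min_points:
        raise ValueError(
            f"longitudinal trend needs >= {min_points} time points, got {x.size}"
        )
    return spearman_exact(x, y), fit_linear_model(x, y)
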