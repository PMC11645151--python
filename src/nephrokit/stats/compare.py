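"""Two-group comparisons, rank correlation, KS comparison, and power.

All tests are two-sided.  The t test defaults to the Welch (unequal
variance) variant; Mann-Whitney uses the exact null distribution for
small samples and the tie-corrected normal approximation otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats

EXACT_MW_MAX_N = 8


@dataclass(frozen=True)
class GroupComparison:
    test: str
    statistic: float
    p_value: float
    effect: dict = field(default_factory=dict)

    def summary(self) -> str:
        eff = ", ".join(f"{k}={v:.4g}" for k, v in self.effect.items())
        return (f"{self.test}: statistic={self.statistic:.4g}, "
                f"p={self.p_value:.4g}" + (f" ({eff})" if eff else ""))


def _split_two_groups(values, groups):
    values = np.asarray(values)
    groups = np.asarray(groups)
    levels = pd.unique(groups)
    if levels.size != 2:
        raise ValueError(f"exactly two groups required, got {levels.size}")
    a = values[groups == levels[0]]
    b = values[groups == levels[1]]
    return a, b, levels


def group_compare(values, groups, test: str = "t",
                  pooled: bool = False) -> GroupComparison:
    """Compare two groups with t, Mann-Whitney, chi-square or Fisher tests.

    For ``chi2``/``fisher`` the values are treated as categorical and the
    test runs on the 2xK contingency table (Fisher requires 2x2).
    """
    a, b, levels = _split_two_groups(values, groups)
    if test == "t":
        if min(a.size, b.size) < 2:
            raise ValueError("t test needs n >= 2 per group")
        res = stats.ttest_ind(a.astype(float), b.astype(float),
                              equal_var=pooled)
        effect = {"mean_diff": float(a.mean() - b.mean())}
        return GroupComparison("welch_t" if not pooled else "pooled_t",
                               float(res.statistic), float(res.pvalue), effect)
    if test == "mannwhitney":
        if min(a.size, b.size) < 1:
            raise ValueError("Mann-Whitney needs n >= 1 per group")
        ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
        if max(a.size, b.size) <= EXACT_MW_MAX_N and not ties:
            method = "exact"
        else:
            method = "asymptotic"
        res = stats.mannwhitneyu(a.astype(float), b.astype(float),
                                 alternative="two-sided", method=method)
        effect = {"median_diff": float(np.median(a) - np.median(b))}
        return GroupComparison(f"mannwhitney_{method}", float(res.statistic),
                               float(res.pvalue), effect)
    if test in ("chi2", "fisher"):
        table = pd.crosstab(np.asarray(groups), np.asarray(values)).to_numpy()
        if test == "fisher":
            if table.shape != (2, 2):
                raise ValueError("Fisher's exact test requires a 2x2 table")
            odds, p = stats.fisher_exact(table, alternative="two-sided")
            return GroupComparison("fisher", float(odds), float(p),
                                   {"odds_ratio": float(odds)})
        chi2, p, dof, _ = stats.chi2_contingency(table)
        return GroupComparison("chi2", float(chi2), float(p), {"dof": dof})
    raise ValueError(f"unknown test {test!r}")


@dataclass(frozen=True)
class SpearmanResult:
    rho: float
    p_value: float
    n: int
    adjusted_slope: float | None = None
    adjusted_p: float | None = None
    adjusted_scale: str | None = None


def spearman(x, y, covariates=None, adjusted_scale: str = "rank") -> SpearmanResult:
    """Spearman rank correlation with average ranks for ties.

    p follows the t approximation.  With ``covariates`` an OLS companion
    regression of y on x adjusting for them is reported — on average
    ranks (``adjusted_scale='rank'``) or the raw scale (``'raw'``).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need at least 3 finite pairs")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("pairs must be finite")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        raise ValueError("constant vector: correlation undefined")
    rho, p = stats.spearmanr(x, y)
    adj_slope = adj_p = None
    if covariates is not None:
        import statsmodels.api as sm

        Z = np.atleast_2d(np.asarray(covariates, dtype=float))
        if Z.shape[0] != x.size:
            Z = Z.T
        if adjusted_scale == "rank":
            xx = stats.rankdata(x)
            yy = stats.rankdata(y)
        elif adjusted_scale == "raw":
            xx, yy = x, y
        else:
            raise ValueError("adjusted_scale must be 'rank' or 'raw'")
        X = sm.add_constant(np.column_stack([xx, Z]))
        fit = sm.OLS(yy, X).fit()
        adj_slope = float(fit.params[1])
        adj_p = float(fit.pvalues[1])
    return SpearmanResult(float(rho), float(p), int(x.size),
                          adj_slope, adj_p,
                          adjusted_scale if covariates is not None else None)


@dataclass(frozen=True)
class KSResult:
    D: float
    p_value: float
    n_a: int
    n_b: int


def ks_2sample(a, b) -> KSResult:
    """Asymptotic two-sample Kolmogorov-Smirnov test.

    D is the supremum ECDF distance; p comes from the Kolmogorov series
    evaluated at sqrt(n_eff) * D with effective n = n_a*n_b/(n_a+n_b).
    """
    a = np.sort(np.asarray(a, dtype=float))
    b = np.sort(np.asarray(b, dtype=float))
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    grid = np.concatenate([a, b])
    cdf_a = np.searchsorted(a, grid, side="right") / a.size
    cdf_b = np.searchsorted(b, grid, side="right") / b.size
    D = float(np.max(np.abs(cdf_a - cdf_b)))
    n_eff = a.size * b.size / (a.size + b.size)
    p = float(special.kolmogorov(np.sqrt(n_eff) * D))
    return KSResult(D, min(1.0, p), int(a.size), int(b.size))


def ttest_power(n1: int, n2: int, delta: float, sd: float,
                alpha: float = 0.05) -> float:
    """Power of the two-sided two-sample t test via the noncentral t.

    df = n1 + n2 - 2; noncentrality delta / (sd * sqrt(1/n1 + 1/n2)).
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    if sd <= 0:
        raise ValueError("sd must be > 0")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    df = n1 + n2 - 2
    nc = delta / (sd * np.sqrt(1.0 / n1 + 1.0 / n2))
    tcrit = stats.t.ppf(1.0 - alpha / 2.0, df)
    power = stats.nct.sf(tcrit, df, nc) + stats.nct.cdf(-tcrit, df, nc)
    return float(power)
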