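"""Covariate-adjusted group means and sqrt-scale regression.

``AdjustedMeansModel`` fits ordinary least squares with a group indicator
plus covariates and reports per-group least-squares means — the model
prediction for each group with every covariate held at its grand mean —
with 95% confidence intervals from the model error variance.
``sqrt_regression`` applies the same machinery to sqrt-transformed
right-skewed outcomes and reports the group effect on the sqrt scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm


def _design(group, covariates):
    group = np.asarray(group)
    levels = pd.unique(group)
    if levels.size != 2:
        raise ValueError("exactly two groups required")
    g = (group == levels[1]).astype(float)
    if covariates is None:
        Z = np.empty((group.size, 0))
        names: list[str] = []
    else:
        if isinstance(covariates, pd.DataFrame):
            names = list(covariates.columns)
            Z = covariates.to_numpy(dtype=float)
        else:
            Z = np.atleast_2d(np.asarray(covariates, dtype=float))
            if Z.shape[0] != group.size:
                Z = Z.T
            names = [f"x{i}" for i in range(Z.shape[1])]
    X = np.column_stack([np.ones(group.size), g, Z])
    colnames = ["const", "group"] + names
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        bad = []
        for j in range(X.shape[1]):
            keep = [k for k in range(X.shape[1]) if k != j]
            if np.linalg.matrix_rank(X[:, keep]) == rank:
                bad.append(colnames[j])
        raise ValueError(f"rank-deficient design; collinear columns: {bad}")
    return X, Z, g, levels, colnames


@dataclass
class AdjustedMeansResults:
    """Least-squares means per group with 95% CIs and the group contrast."""

    levels: tuple
    means: dict
    conf_ints: dict
    difference: float
    difference_ci: tuple[float, float]
    p_value: float
    model: object = field(repr=False, default=None)

    def summary(self) -> str:
        lines = ["Covariate-adjusted (least-squares) means",
                 "========================================"]
        for lvl in self.levels:
            lo, hi = self.conf_ints[lvl]
            lines.append(f"  {lvl!s:>8}: {self.means[lvl]:.4f} "
                         f"[{lo:.4f}, {hi:.4f}]")
        lo, hi = self.difference_ci
        lines.append(f"  difference: {self.difference:.4f} [{lo:.4f}, {hi:.4f}]"
                     f"  p={self.p_value:.4g}")
        return "\n".join(lines)


class AdjustedMeansModel:
    """OLS with a two-level group indicator and optional covariates."""

    def __init__(self, outcome, group, covariates=None):
        self.outcome = np.asarray(outcome, dtype=float)
        self.X, self.Z, self.g, self.levels, self.colnames = \
            _design(group, covariates)

    def fit(self, alpha: float = 0.05) -> AdjustedMeansResults:
        fit = sm.OLS(self.outcome, self.X).fit()
        zbar = self.Z.mean(axis=0) if self.Z.size else np.empty(0)
        rows = np.vstack([
            np.concatenate([[1.0, 0.0], zbar]),
            np.concatenate([[1.0, 1.0], zbar]),
        ])
        pred = fit.get_prediction(rows)
        ci = pred.conf_int(alpha=alpha)
        means = {self.levels[0]: float(pred.predicted_mean[0]),
                 self.levels[1]: float(pred.predicted_mean[1])}
        cis = {self.levels[0]: (float(ci[0, 0]), float(ci[0, 1])),
               self.levels[1]: (float(ci[1, 0]), float(ci[1, 1]))}
        diff = float(fit.params[1])
        dlo, dhi = fit.conf_int(alpha=alpha)[1]
        return AdjustedMeansResults(tuple(self.levels), means, cis, diff,
                                    (float(dlo), float(dhi)),
                                    float(fit.pvalues[1]), model=fit)


def adjusted_means(outcome, group, covariates=None,
                   alpha: float = 0.05) -> AdjustedMeansResults:
    """Per-group least-squares means at covariate grand means, with CIs."""
    return AdjustedMeansModel(outcome, group, covariates).fit(alpha=alpha)


@dataclass
class SqrtRegressionResults:
    """Group effect on the sqrt-transformed outcome scale."""

    effect: float
    conf_int: tuple[float, float]
    p_value: float
    adjusted: AdjustedMeansResults = field(repr=False, default=None)

    def summary(self) -> str:
        lo, hi = self.conf_int
        return (f"sqrt-scale group effect: {self.effect:.4f} "
                f"[95% CI: {lo:.4f}, {hi:.4f}], p={self.p_value:.4g}")


def sqrt_regression(outcome, group, covariates=None,
                    alpha: float = 0.05) -> SqrtRegressionResults:
    """OLS of sqrt(outcome) on group (+ covariates) for right-skewed data.

    The group effect, CI and p are reported on the transformed scale.
    """
    outcome = np.asarray(outcome, dtype=float)
    if np.any(outcome < 0):
        raise ValueError("sqrt transform requires nonnegative outcomes")
    res = adjusted_means(np.sqrt(outcome), group, covariates, alpha=alpha)
    return SqrtRegressionResults(res.difference, res.difference_ci,
                                 res.p_value, adjusted=res)
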