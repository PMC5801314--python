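"""Hierarchical regression of cognitive composites on demographics and MMN
indices, with nested-model comparison and collinearity diagnostics.

The central object is :class:`HierarchicalRegression`: a reduced model
(age + education) and a full model additionally containing an MMN index
(ΔMMN or the long-ISI MMN) are fitted by ordinary least squares; the added
predictor's contribution is summarized by ΔR², the nested F-test

    F = ΔR² (n - k_full - 1) / (m (1 - R²_full)),   df = (m, n - k_full - 1),

standardized β (coefficients of the same model on z-scored variables),
per-predictor variance inflation factors VIF_j = 1 / (1 - R²_j) with their
tolerances 1/VIF, and a Shapiro-Wilk check of the full-model residuals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sst

__all__ = [
    "HierarchicalRegression",
    "HierarchicalRegressionResults",
    "fit_hierarchical",
    "fit_deviant_interaction",
    "vif_diagnostics",
    "residual_normality",
    "pearson_r",
]

#: collinearity flags: individual VIF > 10, mean VIF > 1, tolerance < 0.1
VIF_INDIVIDUAL_LIMIT = 10.0
VIF_MEAN_LIMIT = 1.0
TOLERANCE_LIMIT = 0.1


def vif_diagnostics(design: pd.DataFrame) -> pd.DataFrame:
    """Variance inflation factor per predictor (constant excluded).

    VIF_j comes from regressing predictor j on the remaining predictors;
    tolerance is its reciprocal.  Flags follow the conventional limits
    (individual VIF > 10, mean VIF > 1, tolerance < 0.1).
    """
    cols = [c for c in design.columns if design[c].nunique() > 1]
    if len(cols) < len(design.columns):
        constant = set(design.columns) - set(cols)
        raise ValueError(f"constant predictor(s): {', '.join(sorted(constant))}")
    if len(cols) < 2:
        raise ValueError("need at least 2 predictors")
    X = design[cols].to_numpy(dtype=float)
    rows = []
    for j, name in enumerate(cols):
        others = np.delete(X, j, axis=1)
        fit = sm.OLS(X[:, j], sm.add_constant(others)).fit()
        r2 = min(fit.rsquared, 1.0 - 1e-12)
        vif = 1.0 / (1.0 - r2)
        rows.append({"predictor": name, "vif": vif, "tolerance": 1.0 / vif})
    out = pd.DataFrame(rows).set_index("predictor")
    out["flag"] = (out["vif"] > VIF_INDIVIDUAL_LIMIT) | (
        out["tolerance"] < TOLERANCE_LIMIT
    )
    out.attrs["mean_vif"] = float(out["vif"].mean())
    out.attrs["mean_vif_flag"] = bool(out["vif"].mean() > VIF_MEAN_LIMIT)
    return out


def residual_normality(results) -> tuple[float, float]:
    """Shapiro-Wilk W and p of a fitted model's residuals (advisory)."""
    resid = np.asarray(results.resid, dtype=float)
    if resid.size < 3:
        raise ValueError("need at least 3 residuals")
    w, p = sst.shapiro(resid)
    return float(w), float(p)


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Pearson product-moment correlation coefficient."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3 or y.size != x.size:
        raise ValueError("need paired samples of size >= 3")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance")
    return float(sst.pearsonr(x, y).statistic)


def _standardized_betas(data: pd.DataFrame, outcome: str, predictors: Sequence[str]) -> pd.Series:
    z = (data - data.mean()) / data.std(ddof=1)
    fit = sm.OLS(z[outcome], sm.add_constant(z[list(predictors)])).fit()
    return fit.params.drop("const")


@dataclass
class HierarchicalRegressionResults:
    """Reduced/full model pair with change statistics and diagnostics."""

    outcome: str
    base: tuple[str, ...]
    added: tuple[str, ...]
    n: int
    reduced: "sm.regression.linear_model.RegressionResultsWrapper"
    full: Optional["sm.regression.linear_model.RegressionResultsWrapper"]
    std_beta_reduced: pd.Series
    std_beta_full: Optional[pd.Series]
    delta_r2: Optional[float]
    f_change: Optional[float]
    df_change: Optional[tuple[int, int]]
    p_change: Optional[float]
    vif: Optional[pd.DataFrame]
    shapiro_w: float
    shapiro_p: float

    @property
    def r2_reduced(self) -> float:
        return float(self.reduced.rsquared)

    @property
    def r2_full(self) -> Optional[float]:
        return None if self.full is None else float(self.full.rsquared)

    def summary(self) -> str:
        """Plain-text table in the ΔR² / B / β / p layout."""
        lines = [
            f"Hierarchical regression: {self.outcome} (n = {self.n})",
            f"{'predictor':<22}{'dR2':>8}{'B':>10}{'beta':>8}{'p':>10}",
        ]
        mdl = self.reduced
        lines.append(
            f"{'Model 1':<22}{self.r2_reduced:>8.3f}{'':>10}{'':>8}{mdl.f_pvalue:>10.3f}"
        )
        for name in self.base:
            lines.append(
                f"  {name:<20}{'':>8}{mdl.params[name]:>10.3f}"
                f"{self.std_beta_reduced[name]:>8.2f}{mdl.pvalues[name]:>10.3f}"
            )
        if self.full is not None:
            lines.append(
                f"{'Model 2':<22}{self.delta_r2:>8.3f}{'':>10}{'':>8}{self.p_change:>10.3f}"
            )
            for name in (*self.base, *self.added):
                lines.append(
                    f"  {name:<20}{'':>8}{self.full.params[name]:>10.3f}"
                    f"{self.std_beta_full[name]:>8.2f}{self.full.pvalues[name]:>10.3f}"
                )
            lines.append(
                f"F_change({self.df_change[0]}, {self.df_change[1]}) = "
                f"{self.f_change:.2f}, p = {self.p_change:.4f}; "
                f"Shapiro-Wilk W = {self.shapiro_w:.3f} (p = {self.shapiro_p:.3f})"
            )
        return "\n".join(lines)


class HierarchicalRegression:
    """OLS model pair: outcome ~ base covariates [+ added MMN index].

    Parameters
    ----------
    data : DataFrame with one row per subject (complete cases are used).
    outcome : name of the dependent composite score.
    base : covariates always present (default age and education).
    added : MMN index column(s) entered in the second step, or None for the
        reduced model alone.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        outcome: str,
        base: Sequence[str] = ("age_years", "education_years"),
        added: Optional[Sequence[str]] = None,
    ):
        self.outcome = outcome
        self.base = tuple(base)
        self.added = tuple(added) if added else ()
        cols = [outcome, *self.base, *self.added]
        missing = [c for c in cols if c not in data.columns]
        if missing:
            raise ValueError(f"missing column(s): {', '.join(missing)}")
        self.data = data[cols].dropna().astype(float)
        n, k_full = len(self.data), len(self.base) + len(self.added)
        if n <= k_full + 1:
            raise ValueError(f"n = {n} too small for {k_full} predictors")

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, outcome: str, added=None, **kw):
        return cls(data, outcome, added=added, **kw)

    def fit(self) -> HierarchicalRegressionResults:
        d = self.data
        n = len(d)

        def ols(predictors):
            X = sm.add_constant(d[list(predictors)])
            if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
                raise ValueError(
                    f"rank-deficient design: {', '.join(predictors)} are collinear"
                )
            return sm.OLS(d[self.outcome], X).fit()

        reduced = ols(self.base)
        beta_red = _standardized_betas(d, self.outcome, self.base)

        if not self.added:
            w, p = residual_normality(reduced)
            return HierarchicalRegressionResults(
                outcome=self.outcome, base=self.base, added=(), n=n,
                reduced=reduced, full=None, std_beta_reduced=beta_red,
                std_beta_full=None, delta_r2=None, f_change=None,
                df_change=None, p_change=None, vif=None, shapiro_w=w, shapiro_p=p,
            )

        full = ols((*self.base, *self.added))
        m = len(self.added)
        k_full = len(self.base) + m
        delta_r2 = float(full.rsquared - reduced.rsquared)
        df2 = n - k_full - 1
        f_change = delta_r2 * df2 / (m * max(1.0 - full.rsquared, 1e-300))
        p_change = float(sst.f.sf(f_change, m, df2))
        beta_full = _standardized_betas(d, self.outcome, (*self.base, *self.added))
        vif = vif_diagnostics(d[[*self.base, *self.added]])
        w, p = residual_normality(full)
        return HierarchicalRegressionResults(
            outcome=self.outcome, base=self.base, added=self.added, n=n,
            reduced=reduced, full=full, std_beta_reduced=beta_red,
            std_beta_full=beta_full, delta_r2=delta_r2,
            f_change=float(f_change), df_change=(m, df2), p_change=p_change,
            vif=vif, shapiro_w=w, shapiro_p=p,
        )


def fit_hierarchical(
    data: pd.DataFrame,
    outcome: str,
    added: Optional[str | Sequence[str]] = None,
    base: Sequence[str] = ("age_years", "education_years"),
) -> HierarchicalRegressionResults:
    """Functional wrapper over :class:`HierarchicalRegression`."""
    if isinstance(added, str):
        added = (added,)
    return HierarchicalRegression(data, outcome, base=base, added=added).fit()


def fit_deviant_interaction(
    data: pd.DataFrame,
    outcome: str,
    families: Sequence[str],
    base: Sequence[str] = ("age_years", "education_years"),
    mmn_prefix: str = "opt1_",
) -> HierarchicalRegressionResults:
    """Short-ISI MMN x deviant-family block entered as one step.

    ``data`` must hold one column per family (``<mmn_prefix><family>``);
    the full model adds all family-specific MMN columns at once and the
    block is tested by the nested F on its joint contribution, mirroring a
    MMN x Deviant Type term without per-family multiple testing.
    """
    cols = []
    for fam in families:
        col = f"{mmn_prefix}{fam}"
        if col not in data.columns:
            raise ValueError(f"missing family column {col!r}")
        cols.append(col)
    sub = data[[outcome, *base, *cols]].dropna()
    if len(cols) >= 2:
        X = sub[cols].to_numpy()
        if np.linalg.matrix_rank(X - X.mean(axis=0)) < len(cols):
            raise ValueError(
                f"identical MMN scores across families: {', '.join(cols)} are collinear"
            )
    return HierarchicalRegression(sub, outcome, base=base, added=cols).fit()
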