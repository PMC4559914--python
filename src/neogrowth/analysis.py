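"""Cohort statistics: tertiles, screened multiple regression, group tests.

The growth-determinants analysis follows a two-stage procedure: every
candidate covariate is first screened by simple linear regression
against the outcome (change in weight Z-score from birth to 36 weeks
PCA/discharge), and only candidates significant at p < 0.10 enter the
multivariable ordinary-least-squares model.  Each retained term is
reported with its coefficient, partial correlation and p-value, plus
the model's overall r-squared and F p-value.  The partial correlation
is derived from the term's t statistic,

    r_partial = sign(t) * sqrt(t^2 / (t^2 + df_resid)),

which equals the correlation between outcome and predictor after
removing the other predictors from both.

:class:`DeltaZModel` packages the procedure as a model object:
``DeltaZModel.from_dataframe(df, outcome, candidates).fit()`` returns a
:class:`DeltaZResults` with estimates, uncertainties and ``summary()``.
Cumulative amino-acid intake enters as a tertile score (1-3), a linear
trend across thirds of the cohort.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "TertileAssignment",
    "TermResult",
    "RegressionResult",
    "GroupComparison",
    "PairedTestResult",
    "assign_tertiles",
    "univariate_screen",
    "fit_multiple_regression",
    "paired_change_test",
    "group_compare",
    "DeltaZModel",
    "DeltaZResults",
]

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# tertiles


@dataclass(frozen=True)
class TertileAssignment:
    variable: str
    cut_lo: float
    cut_hi: float
    labels: np.ndarray  # 1 (lowest) .. 3 (highest) per subject


def assign_tertiles(values: Sequence[float], variable: str = "value") -> TertileAssignment:
    """Split subjects into thirds of a variable; labels 1 (lowest) to 3.

    Cuts are the empirical 1/3 and 2/3 quantiles; values tied with a
    cut take the lower label.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < 3:
        raise ValueError("need at least 3 values for tertiles")
    if not np.all(np.isfinite(arr)):
        raise ValueError("values must be finite")
    if np.ptp(arr) == 0:
        raise ValueError("all values equal; tertiles are degenerate")
    cut_lo, cut_hi = np.quantile(arr, [1 / 3, 2 / 3])
    labels = np.where(arr <= cut_lo, 1, np.where(arr <= cut_hi, 2, 3))
    return TertileAssignment(variable, float(cut_lo), float(cut_hi), labels.astype(int))


# ---------------------------------------------------------------------------
# screening and multiple regression


def univariate_screen(
    outcome: Sequence[float],
    candidates: pd.DataFrame,
    alpha: float = 0.10,
) -> tuple[list[str], dict[str, float]]:
    """Simple-regression screen: keep candidates with slope p < alpha.

    Returns the selected column names (in the candidate-frame order)
    and the per-candidate p-values.  Constant candidates cannot carry a
    slope and are excluded with a log message.
    """
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    y = np.asarray(outcome, dtype=float)
    pvals: dict[str, float] = {}
    selected: list[str] = []
    for name in candidates.columns:
        x = candidates[name].to_numpy(float)
        if np.ptp(x) == 0:
            logger.info("screen: candidate %r is constant; excluded", name)
            continue
        res = stats.linregress(x, y)
        pvals[name] = float(res.pvalue)
        if res.pvalue < alpha:
            selected.append(name)
    return selected, pvals


@dataclass(frozen=True)
class TermResult:
    name: str
    coefficient: float
    r_partial: float
    pvalue: float
    stderr: float
    tvalue: float


@dataclass(frozen=True)
class RegressionResult:
    """Multivariable OLS fit in the shape of the audit's result tables."""

    terms: tuple[TermResult, ...]
    model_r2: float
    model_p: float
    n: int
    intercept: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "variable": t.name,
                    "coefficient": t.coefficient,
                    "r_partial": t.r_partial,
                    "p": t.pvalue,
                }
                for t in self.terms
            ]
        )


def _collinear_columns(X: pd.DataFrame) -> list[str]:
    names = list(X.columns)
    bad = []
    for name in names:
        others = [c for c in names if c != name]
        if not others:
            continue
        r2 = (
            sm.OLS(X[name].to_numpy(float), sm.add_constant(X[others].to_numpy(float)))
            .fit()
            .rsquared
        )
        if r2 > 1 - 1e-10:
            bad.append(name)
    return bad


def fit_multiple_regression(
    outcome: Sequence[float], predictors: pd.DataFrame
) -> RegressionResult:
    """Ordinary least squares of the outcome on all predictor columns.

    Per-term partial correlations use the t-statistic identity with the
    residual degrees of freedom.  Exact collinearity raises, naming the
    offending columns.
    """
    y = np.asarray(outcome, dtype=float)
    if predictors.shape[1] < 1:
        raise ValueError("need at least one predictor")
    if len(y) <= predictors.shape[1] + 1:
        raise ValueError("need n > number of predictors + 1")
    X = sm.add_constant(predictors.astype(float), has_constant="add")
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        bad = _collinear_columns(predictors.astype(float))
        raise ValueError(f"exact collinearity among predictors: {bad or list(predictors.columns)}")
    fit = sm.OLS(y, X).fit()
    df_resid = fit.df_resid
    terms = []
    for name in predictors.columns:
        t = float(fit.tvalues[name])
        terms.append(
            TermResult(
                name=name,
                coefficient=float(fit.params[name]),
                r_partial=float(np.sign(t) * np.sqrt(t**2 / (t**2 + df_resid))),
                pvalue=float(fit.pvalues[name]),
                stderr=float(fit.bse[name]),
                tvalue=t,
            )
        )
    return RegressionResult(
        terms=tuple(terms),
        model_r2=float(fit.rsquared),
        model_p=float(fit.f_pvalue),
        n=int(fit.nobs),
        intercept=float(fit.params["const"]),
    )


# ---------------------------------------------------------------------------
# group comparisons


@dataclass(frozen=True)
class PairedTestResult:
    mean_difference: float
    statistic: float
    pvalue: float
    n: int
    degenerate: bool = False


def paired_change_test(before: Sequence[float], after: Sequence[float]) -> PairedTestResult:
    """Paired comparison of means between two timepoints.

    A one-factor repeated-measures analysis with two timepoints reduces
    to the paired t test.  Zero-variance differences give a degenerate
    flagged result rather than a spurious p-value.
    """
    b = np.asarray(before, dtype=float)
    a = np.asarray(after, dtype=float)
    if b.shape != a.shape:
        raise ValueError(f"paired vectors differ in length: {b.size} vs {a.size}")
    if b.size < 2:
        raise ValueError("need at least 2 pairs")
    if b.size == 2:
        warnings.warn("paired test on n=2: one residual degree of freedom")
    d = a - b
    if np.ptp(d) == 0:
        p = 1.0 if d[0] == 0 else float("nan")
        return PairedTestResult(float(d[0]), float("nan"), p, b.size, degenerate=True)
    t, p = stats.ttest_rel(a, b)
    return PairedTestResult(float(d.mean()), float(t), float(p), b.size)


@dataclass(frozen=True)
class GroupComparison:
    test: str
    statistic: float
    pvalue: float


def group_compare(
    variable: Sequence,
    groups: Sequence,
    categorical: bool = False,
    normal: bool = True,
) -> GroupComparison:
    """Between-group test dispatch.

    Categorical variables get a chi-square test, switching to Fisher's
    exact test on 2x2 tables whenever any expected cell count is below
    5 or any observed cell is empty (the chi-square approximation is
    unreliable in both cases).  Continuous variables get one-way ANOVA
    when flagged normal, otherwise Mann-Whitney U (two groups) or
    Kruskal-Wallis.
    """
    g = pd.Series(list(groups))
    levels = g.unique()
    if len(levels) < 2:
        raise ValueError("need at least 2 groups")
    v = pd.Series(list(variable))
    if categorical:
        table = pd.crosstab(v, g).to_numpy()
        expected = stats.contingency.expected_freq(table)
        sparse = (expected < 5).any() or (table == 0).any()
        if sparse and table.shape == (2, 2):
            _, p = stats.fisher_exact(table)
            return GroupComparison("fisher_exact", float("nan"), float(p))
        if (expected < 5).any():
            warnings.warn("expected cell < 5 on a non-2x2 table; chi-square approximate")
        chi2, p, _, _ = stats.chi2_contingency(table)
        return GroupComparison("chi2", float(chi2), float(p))
    samples = [v[g == lev].to_numpy(float) for lev in levels]
    if normal:
        stat, p = stats.f_oneway(*samples)
        return GroupComparison("anova", float(stat), float(p))
    if len(samples) == 2:
        stat, p = stats.mannwhitneyu(*samples, alternative="two-sided")
        return GroupComparison("mannwhitneyu", float(stat), float(p))
    stat, p = stats.kruskal(*samples)
    return GroupComparison("kruskal", float(stat), float(p))


# ---------------------------------------------------------------------------
# model object


class DeltaZModel:
    """Screen-then-fit model for change in weight Z-score.

    Candidate covariates are screened by simple regression at
    ``alpha`` (default 0.10); survivors enter a multivariable OLS.
    Build from arrays or with :meth:`from_dataframe`, then call
    :meth:`fit`.
    """

    def __init__(
        self,
        outcome: Sequence[float],
        candidates: pd.DataFrame,
        alpha: float = 0.10,
        outcome_name: str = "delta_z_weight",
    ):
        self.outcome = np.asarray(outcome, dtype=float)
        if len(self.outcome) != len(candidates):
            raise ValueError("outcome and candidates differ in length")
        self.candidates = candidates.reset_index(drop=True)
        self.alpha = alpha
        self.outcome_name = outcome_name

    @classmethod
    def from_dataframe(
        cls,
        data: pd.DataFrame,
        outcome: str,
        candidates: Optional[Sequence[str]] = None,
        alpha: float = 0.10,
    ) -> "DeltaZModel":
        if candidates is None:
            candidates = [c for c in data.columns if c != outcome]
        complete = data[[outcome, *candidates]].dropna()
        return cls(
            complete[outcome].to_numpy(float),
            complete[list(candidates)],
            alpha=alpha,
            outcome_name=outcome,
        )

    def fit(self) -> "DeltaZResults":
        selected, screen_p = univariate_screen(self.outcome, self.candidates, self.alpha)
        if selected:
            reg = fit_multiple_regression(self.outcome, self.candidates[selected])
        else:
            logger.warning("no candidate passed the p<%.2g screen; intercept-only model", self.alpha)
            reg = RegressionResult(
                terms=(),
                model_r2=0.0,
                model_p=float("nan"),
                n=len(self.outcome),
                intercept=float(np.mean(self.outcome)),
            )
        return DeltaZResults(self, selected, screen_p, reg)


class DeltaZResults:
    """Fitted screen-then-fit model: estimates, diagnostics, summary table."""

    def __init__(
        self,
        model: DeltaZModel,
        selected: list[str],
        screen_pvalues: dict[str, float],
        regression: RegressionResult,
    ):
        self.model = model
        self.selected = selected
        self.screen_pvalues = screen_pvalues
        self.regression = regression

    @property
    def params(self) -> pd.Series:
        return pd.Series({t.name: t.coefficient for t in self.regression.terms})

    @property
    def pvalues(self) -> pd.Series:
        return pd.Series({t.name: t.pvalue for t in self.regression.terms})

    @property
    def partial_r(self) -> pd.Series:
        return pd.Series({t.name: t.r_partial for t in self.regression.terms})

    @property
    def rsquared(self) -> float:
        return self.regression.model_r2

    @property
    def nobs(self) -> int:
        return self.regression.n

    def to_frame(self) -> pd.DataFrame:
        return self.regression.to_frame()

    def summary(self) -> str:
        lines = [
            f"Screened multiple linear regression: {self.model.outcome_name}",
            f"n = {self.nobs}, screen alpha = {self.model.alpha:g}, "
            f"candidates = {self.model.candidates.shape[1]}, retained = {len(self.selected)}",
            f"model r2 = {self.rsquared:.3f}, model p = {self.regression.model_p:.3g}",
            "",
            f"{'variable':<32}{'coef':>10}{'r_partial':>12}{'p':>12}",
        ]
        for t in self.regression.terms:
            lines.append(f"{t.name:<32}{t.coefficient:>10.3f}{t.r_partial:>12.2f}{t.pvalue:>12.3g}")
        if not self.regression.terms:
            lines.append("(no terms retained)")
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover
        return f"<DeltaZResults n={self.nobs} r2={self.rsquared:.3f} terms={len(self.regression.terms)}>"
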