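"""Covariate-adjusted association models for BMI and obesity.

Linear models are ordinary least squares (statsmodels behind this surface);
logistic models are maximum-likelihood fits whose predicted probabilities
feed the ROC machinery.  Predictors enter in a fixed configured order
(covariates -> SNP score -> CNV terms); candidate covariate x predictor
interactions are screened one at a time and the ones passing a Bonferroni
threshold (default alpha = 0.002) are added jointly to the final model.
Independent variables are mean-centered before fitting so that the intercept
is the expected response at covariate means.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .io import ValidationError

logger = logging.getLogger("snpcnv")


@dataclass
class ModelFit:
    """Summary of one fitted regression."""

    response: str
    terms: list[str]                     # includes 'const'
    params: pd.Series
    bse: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    n: int
    kind: str = "linear"                 # 'linear' | 'logistic'
    r2: float = float("nan")
    rss: float = float("nan")
    fvalue: float = float("nan")
    df_model: int = 0
    df_resid: int = 0
    centering: dict = field(default_factory=dict)
    fitted: np.ndarray | None = None     # predicted values / probabilities

    @property
    def odds_ratios(self) -> pd.Series:
        if self.kind != "logistic":
            raise ValidationError("odds ratios only defined for logistic fits")
        return np.exp(self.params)

    def to_dict(self) -> dict:
        d = {
            "response": self.response, "kind": self.kind, "n": self.n,
            "terms": self.terms,
            "params": self.params.to_dict(), "bse": self.bse.to_dict(),
            "tvalues": self.tvalues.to_dict(), "pvalues": self.pvalues.to_dict(),
            "df_model": self.df_model, "df_resid": self.df_resid,
            "centering": self.centering,
        }
        if self.kind == "linear":
            d.update(r2=self.r2, rss=self.rss, fvalue=self.fvalue)
        else:
            d["odds_ratios"] = self.odds_ratios.to_dict()
        return d


# ---------------------------------------------------------------------------
# Design-matrix helpers
# ---------------------------------------------------------------------------

def center_predictors(design: pd.DataFrame, terms: list[str] | None = None
                      ) -> tuple[pd.DataFrame, dict[str, float]]:
    """Mean-center the named columns (all numeric columns when None).

    Returns the centered design and a record of subtracted means, enabling
    back-transformation of the intercept.
    """
    design = design.copy()
    if terms is None:
        terms = [c for c in design.columns
                 if np.issubdtype(design[c].dtype, np.number)]
    record = {}
    for t in terms:
        m = float(design[t].mean())
        design[t] = design[t] - m
        record[t] = m
    return design, record


def _check_rank(X: pd.DataFrame) -> None:
    mat = X.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(mat)
    if rank < mat.shape[1]:
        # name the offending columns via QR pivoting on the correlation structure
        bad = []
        for j, col in enumerate(X.columns):
            sub = np.delete(mat, j, axis=1)
            if np.linalg.matrix_rank(sub) == rank:
                bad.append(col)
        raise ValidationError(f"design matrix is rank deficient; collinear terms: {bad}")


def variance_inflation(design: pd.DataFrame) -> pd.Series:
    """VIF per column (excluding the constant), 1/(1 - R^2_j)."""
    X = design.drop(columns=[c for c in ("const",) if c in design.columns])
    out = {}
    for col in X.columns:
        others = sm.add_constant(X.drop(columns=[col]).to_numpy(dtype=float))
        r2 = sm.OLS(X[col].to_numpy(dtype=float), others).fit().rsquared
        out[col] = np.inf if r2 >= 1.0 else 1.0 / (1.0 - r2)
    return pd.Series(out)


# ---------------------------------------------------------------------------
# Model fitting
# ---------------------------------------------------------------------------

def fit_linear(response: pd.Series | np.ndarray, design: pd.DataFrame,
               center: bool = True, response_name: str = "BMI") -> ModelFit:
    """OLS fit of the response on the design (a constant is added).

    Coefficient SEs use the unbiased residual-variance estimator;
    R^2 = 1 - RSS/TSS.  A rank-deficient design raises, naming the
    collinear terms.
    """
    y = np.asarray(response, dtype=float)
    if center:
        design, record = center_predictors(design)
    else:
        record = {}
    X = sm.add_constant(design.astype(float), has_constant="add")
    if len(y) < X.shape[1]:
        raise ValidationError("need n >= number of terms")
    _check_rank(X)
    res = sm.OLS(y, X).fit()
    return ModelFit(
        response=response_name, terms=list(X.columns),
        params=res.params, bse=res.bse, tvalues=res.tvalues, pvalues=res.pvalues,
        n=int(res.nobs), kind="linear", r2=float(res.rsquared),
        rss=float(res.ssr), fvalue=float(res.fvalue),
        df_model=int(res.df_model), df_resid=int(res.df_resid),
        centering=record, fitted=np.asarray(res.fittedvalues),
    )


def fit_logistic(outcome: pd.Series | np.ndarray, design: pd.DataFrame,
                 center: bool = True, response_name: str = "obese") -> ModelFit:
    """Maximum-likelihood logistic fit; predicted probabilities are exposed
    for ROC analysis and odds ratios as exp(coefficient)."""
    y = np.asarray(outcome, dtype=float)
    classes = np.unique(y)
    if not np.array_equal(classes, [0.0, 1.0]):
        raise ValidationError("outcome must be binary with both classes present")
    if center:
        design, record = center_predictors(design)
    else:
        record = {}
    X = sm.add_constant(design.astype(float), has_constant="add")
    _check_rank(X)
    try:
        try:
            res = sm.Logit(y, X).fit(disp=0, maxiter=200, warn_convergence=False)
            retry = not res.mle_retvals.get("converged", True)
        except np.linalg.LinAlgError:
            retry = True  # singular Hessian mid-Newton; quasi-separation
        if retry:
            res = sm.Logit(y, X).fit(disp=0, method="bfgs", maxiter=500,
                                     warn_convergence=False)
    except Exception as exc:  # statsmodels raises on perfect separation
        raise ValidationError(f"logistic fit failed (separation?): {exc}") from exc
    if not res.mle_retvals.get("converged", True):
        raise ValidationError("logistic fit did not converge (complete separation?)")
    return ModelFit(
        response=response_name, terms=list(X.columns),
        params=res.params, bse=res.bse, tvalues=res.tvalues, pvalues=res.pvalues,
        n=int(res.nobs), kind="logistic",
        df_model=int(res.df_model), df_resid=int(res.df_resid),
        centering=record, fitted=np.asarray(res.predict(X)),
    )


# ---------------------------------------------------------------------------
# Interaction scan, nested comparisons
# ---------------------------------------------------------------------------

def scan_interactions(response, design: pd.DataFrame,
                      candidates: list[tuple[str, str]],
                      alpha: float = 0.002) -> tuple[list[str], ModelFit]:
    """Screen covariate x predictor product terms one at a time.

    Each candidate is added alone to the base design; candidates whose
    interaction coefficient has p < alpha are accepted and then added
    jointly to form the final model.  Candidate order is the configured
    order, making the scan deterministic.
    """
    accepted = []
    for a, b in candidates:
        name = f"{a}*{b}"
        aug = design.copy()
        aug[name] = design[a] * design[b]
        fit = fit_linear(response, aug)
        if fit.pvalues[name] < alpha:
            accepted.append(name)
        logger.info("interaction %s: p = %.3g (%saccepted at alpha=%g)",
                    name, fit.pvalues[name], "" if fit.pvalues[name] < alpha else "not ",
                    alpha)
    final_design = design.copy()
    for name in accepted:
        a, b = name.split("*")
        final_design[name] = design[a] * design[b]
    return accepted, fit_linear(response, final_design)


def nested_f_test(reduced: ModelFit, full: ModelFit) -> tuple[float, int, int, float]:
    """F-test for nested OLS fits: F = ((RSS_r - RSS_f)/q) / (RSS_f/(n - p_f))."""
    _check_nested(reduced, full)
    q = reduced.df_resid - full.df_resid
    if q <= 0:
        return 0.0, 0, full.df_resid, 1.0
    f = ((reduced.rss - full.rss) / q) / (full.rss / full.df_resid)
    p = float(stats.f.sf(f, q, full.df_resid))
    return float(f), int(q), int(full.df_resid), p


def incremental_r2(reduced: ModelFit, full: ModelFit) -> float:
    """Delta R^2 when adding the full model's extra terms."""
    _check_nested(reduced, full)
    return full.r2 - reduced.r2


def _check_nested(reduced: ModelFit, full: ModelFit) -> None:
    if reduced.n != full.n:
        raise ValidationError("nested comparison requires identical subjects")
    if not set(reduced.terms) <= set(full.terms):
        raise ValidationError("models are not nested")


def r2_decomposition(response, design: pd.DataFrame,
                     blocks: list[tuple[str, list[str]]]) -> pd.DataFrame:
    """Sequential R^2 attribution by adding term blocks in the given order."""
    rows, cols, prev = [], [], 0.0
    for label, terms in blocks:
        cols.extend(terms)
        fit = fit_linear(response, design[cols])
        rows.append({"block": label, "r2_cumulative": fit.r2,
                     "delta_r2": fit.r2 - prev})
        prev = fit.r2
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Descriptive 2x2 tests
# ---------------------------------------------------------------------------

def pearson_chi2_2x2(table) -> tuple[float, int, float]:
    """Pearson chi-square for a 2x2 table, no continuity correction.

    chi2 = N (ad - bc)^2 / ((a+b)(c+d)(a+c)(b+d)); p from chi2(1).  A zero
    margin makes the statistic undefined and raises.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValidationError("need a 2x2 table of non-negative counts")
    a, b, c, d = t.ravel()
    n = t.sum()
    margins = [(a + b), (c + d), (a + c), (b + d)]
    if n == 0 or any(m == 0 for m in margins):
        raise ValidationError("zero margin: chi-square undefined")
    chi2 = n * (a * d - b * c) ** 2 / np.prod(margins)
    return float(chi2), 1, float(stats.chi2.sf(chi2, 1))
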