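"""Design-based estimation for stratified multistage surveys.

Variance estimation throughout is Taylor linearization with the
with-replacement approximation: score/residual contributions are summed
to primary-sampling-unit (PSU) totals and their between-PSU covariance
is accumulated within strata with the n_h/(n_h - 1) factor.  Design
degrees of freedom are (#PSUs - #strata).  Strata containing a single
PSU either raise or are centered at the grand mean ("adjust", default,
with a logged warning).

`SurveyLogit` follows the statsmodels Model/Results convention: the
model object holds data and design, ``fit()`` returns a results object
carrying coefficients, the sandwich covariance, odds ratios with
t-based confidence intervals, and a ``summary()`` table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

logger = logging.getLogger(__name__)


class ConvergenceError(RuntimeError):
    pass


@dataclass
class SurveyDesign:
    """Per-row stratum id, PSU id and sampling weight.

    PSUs are identified by the (stratum, psu) pair, so PSU labels may
    repeat across strata without ambiguity.
    """

    strata: np.ndarray
    psu: np.ndarray
    weights: np.ndarray
    lonely_psu: str = "adjust"  # or "error"

    def __post_init__(self) -> None:
        self.strata = np.asarray(self.strata)
        self.psu = np.asarray(self.psu)
        self.weights = np.asarray(self.weights, dtype=float)
        if not (len(self.strata) == len(self.psu) == len(self.weights)):
            raise ValueError("strata, psu and weights must have equal length")
        if not np.isfinite(self.weights).all() or (self.weights <= 0).any():
            raise ValueError("weights must be finite and positive")
        # integer codes for fast grouping
        strat_keys = pd.factorize(self.strata)[0]
        pair = pd.factorize(pd.MultiIndex.from_arrays([self.strata, self.psu]).to_flat_index())[0]
        self._strat_codes = strat_keys
        self._psu_codes = pair
        self.n_strata = int(strat_keys.max()) + 1
        self.n_psus = int(pair.max()) + 1
        # stratum of each PSU
        self._psu_stratum = np.zeros(self.n_psus, dtype=int)
        self._psu_stratum[pair] = strat_keys

    @property
    def df_design(self) -> int:
        return self.n_psus - self.n_strata

    @classmethod
    def from_frame(cls, df: pd.DataFrame, strata: str = "stratum", psu: str = "psu",
                   weight: str = "weight", **kw) -> "SurveyDesign":
        return cls(df[strata].to_numpy(), df[psu].to_numpy(), df[weight].to_numpy(), **kw)

    def subset(self, mask: np.ndarray) -> "SurveyDesign":
        mask = np.asarray(mask)
        return SurveyDesign(self.strata[mask], self.psu[mask], self.weights[mask],
                           lonely_psu=self.lonely_psu)

    def linearized_cov(self, contributions: np.ndarray) -> np.ndarray:
        """Between-PSU covariance (within strata) of summed per-row
        contribution vectors — the B matrix of the sandwich."""
        U = np.atleast_2d(np.asarray(contributions, dtype=float))
        if U.shape[0] != len(self.weights):
            U = U.T
        p = U.shape[1]
        # PSU totals
        totals = np.zeros((self.n_psus, p))
        np.add.at(totals, self._psu_codes, U)
        B = np.zeros((p, p))
        grand_mean = totals.mean(axis=0)
        for h in range(self.n_strata):
            sel = self._psu_stratum == h
            t = totals[sel]
            n_h = t.shape[0]
            if n_h == 1:
                if self.lonely_psu == "error":
                    raise ValueError(f"stratum {h} has a single PSU")
                logger.warning("stratum %s has a single PSU; centering at the grand mean", h)
                d = t[0] - grand_mean
                B += np.outer(d, d)
                continue
            d = t - t.mean(axis=0)
            B += (n_h / (n_h - 1)) * d.T @ d
        return B


def weighted_mean_se(values, design: SurveyDesign) -> tuple[float, float]:
    """Survey-weighted mean with linearized standard error."""
    y = np.asarray(values, dtype=float)
    w = design.weights
    wsum = w.sum()
    mean = float((w * y).sum() / wsum)
    z = w * (y - mean) / wsum
    var = design.linearized_cov(z[:, None])[0, 0]
    return mean, float(np.sqrt(var))


def rao_scott_chisq(a, b, design: SurveyDesign) -> tuple[float, int, float]:
    """First-order Rao-Scott corrected chi-square test of independence.

    The Pearson statistic on weighted cell proportions (scaled by n) is
    divided by the mean generalized design effect of the cell
    proportions; the reference variance uses the with-replacement
    finite-sample factor p(1-p)/(n-1), so with equal weights and one
    PSU per row in a single stratum the statistic reduces exactly to
    the classical Pearson X².  Referred to chi-square on (R-1)(C-1) df.
    """
    a = pd.Categorical(np.asarray(a))
    b = pd.Categorical(np.asarray(b))
    R, C = len(a.categories), len(b.categories)
    if R < 2 or C < 2:
        raise ValueError("both factors need at least 2 observed levels")
    n = len(a.codes)
    w = design.weights
    wsum = w.sum()
    P = np.zeros((R, C))
    np.add.at(P, (a.codes, b.codes), w)
    P /= wsum
    if (P.sum(axis=1) == 0).any() or (P.sum(axis=0) == 0).any():
        raise ValueError("empty row or column in the contingency table")
    expected = np.outer(P.sum(axis=1), P.sum(axis=0))
    X2 = n * float(((P - expected) ** 2 / expected).sum())

    deffs = []
    for r in range(R):
        for c in range(C):
            p = P[r, c]
            if p <= 0 or p >= 1:
                continue
            ind = ((a.codes == r) & (b.codes == c)).astype(float)
            z = w * (ind - p) / wsum
            v_design = design.linearized_cov(z[:, None])[0, 0]
            v_srs = p * (1 - p) / (n - 1)
            deffs.append(v_design / v_srs)
    dbar = float(np.mean(deffs)) if deffs else 1.0
    stat = X2 / dbar
    df = (R - 1) * (C - 1)
    return stat, df, float(stats.chi2.sf(stat, df))


def survey_linear(y, X, design: SurveyDesign) -> tuple[np.ndarray, np.ndarray]:
    """Survey-weighted least squares with sandwich covariance.

    Returns (params, cov).  Point estimates solve the weighted normal
    equations; the covariance is A^{-1} B A^{-1} with A = X'WX and B the
    stratified between-PSU covariance of weighted score totals.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    w = design.weights
    A = X.T @ (X * w[:, None])
    beta = np.linalg.solve(A, X.T @ (w * y))
    resid = y - X @ beta
    U = X * (w * resid)[:, None]
    B = design.linearized_cov(U)
    Ainv = np.linalg.inv(A)
    return beta, Ainv @ B @ Ainv


@dataclass
class SurveyLogitResults:
    """Fitted survey-weighted logistic regression."""

    params: np.ndarray
    cov_params: np.ndarray
    exog_names: list
    df_design: int
    nobs: int
    weighted_nobs: float
    n_iter: int
    converged: bool
    model: "SurveyLogit" = field(repr=False, default=None)

    @property
    def bse(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov_params))

    @property
    def tvalues(self) -> np.ndarray:
        return self.params / self.bse

    @property
    def pvalues(self) -> np.ndarray:
        return 2 * stats.t.sf(np.abs(self.tvalues), self.df_design)

    def conf_int(self, alpha: float = 0.05, use_t: bool = True) -> np.ndarray:
        q = stats.t.ppf(1 - alpha / 2, self.df_design) if use_t else stats.norm.ppf(1 - alpha / 2)
        return np.column_stack([self.params - q * self.bse, self.params + q * self.bse])

    def odds_ratios(self, alpha: float = 0.05) -> pd.DataFrame:
        ci = self.conf_int(alpha)
        return pd.DataFrame({
            "OR": np.exp(self.params),
            "ci_low": np.exp(ci[:, 0]),
            "ci_high": np.exp(ci[:, 1]),
            "p": self.pvalues,
        }, index=self.exog_names)

    def summary(self) -> str:
        ci = self.conf_int()
        lines = [
            "Survey-weighted logistic regression",
            f"  n = {self.nobs}  weighted n = {self.weighted_nobs:.1f}  design df = {self.df_design}",
            f"  converged: {self.converged} in {self.n_iter} iterations",
            f"{'term':<24}{'coef':>10}{'SE':>10}{'t':>8}{'p':>9}{'OR':>8}{'[95% CI]':>18}",
        ]
        for i, name in enumerate(self.exog_names):
            lines.append(
                f"{str(name):<24}{self.params[i]:>10.4f}{self.bse[i]:>10.4f}"
                f"{self.tvalues[i]:>8.2f}{self.pvalues[i]:>9.4f}{np.exp(self.params[i]):>8.3f}"
                f"   [{np.exp(ci[i, 0]):.3f}, {np.exp(ci[i, 1]):.3f}]"
            )
        return "\n".join(lines)


class SurveyLogit:
    """Survey-weighted (pseudo-maximum-likelihood) logistic regression.

    Parameters
    ----------
    endog : binary outcome (0/1)
    exog : design matrix, full rank after dummy coding; include the
        intercept column explicitly or use :meth:`from_formula`
    design : :class:`SurveyDesign`
    """

    def __init__(self, endog, exog, design: SurveyDesign, exog_names=None):
        self.endog = np.asarray(endog, dtype=float)
        exog = np.asarray(exog, dtype=float)
        if exog.ndim == 1:
            exog = exog[:, None]
        self.exog = exog
        self.design = design
        if exog_names is None:
            exog_names = [f"x{i}" for i in range(exog.shape[1])]
        self.exog_names = list(exog_names)
        if set(np.unique(self.endog)) - {0.0, 1.0}:
            raise ValueError("endog must be binary 0/1")
        if len(self.endog) != exog.shape[0] or len(design.weights) != exog.shape[0]:
            raise ValueError("endog, exog and design must have equal length")

    @classmethod
    def from_formula(cls, formula: str, data: pd.DataFrame, design: SurveyDesign) -> "SurveyLogit":
        import patsy

        y, X = patsy.dmatrices(formula, data, return_type="dataframe")
        return cls(y.to_numpy().ravel(), X.to_numpy(), design, exog_names=list(X.columns))

    def fit(self, max_iter: int = 50, tol: float = 1e-8) -> SurveyLogitResults:
        X, y, w = self.exog, self.endog, self.design.weights
        beta = np.zeros(X.shape[1])
        converged = False
        n_iter = 0
        for it in range(max_iter):
            n_iter = it + 1
            p = expit(X @ beta)
            grad = X.T @ (w * (y - p))
            Wdiag = w * p * (1 - p)
            H = X.T @ (X * Wdiag[:, None])
            try:
                step = np.linalg.solve(H, grad)
            except np.linalg.LinAlgError as e:
                raise ConvergenceError(f"singular information matrix: {e}") from e
            beta = beta + step
            if np.abs(beta).max() > 30:
                raise ConvergenceError("separation detected: a coefficient is diverging")
            if np.abs(grad).max() < tol * max(1.0, w.sum() / len(w)):
                converged = True
                break
        if not converged:
            raise ConvergenceError(f"no convergence in {max_iter} Newton iterations")
        p = expit(X @ beta)
        A = X.T @ (X * (w * p * (1 - p))[:, None])
        U = X * (w * (y - p))[:, None]
        B = self.design.linearized_cov(U)
        Ainv = np.linalg.inv(A)
        cov = Ainv @ B @ Ainv
        cov = (cov + cov.T) / 2.0
        return SurveyLogitResults(
            params=beta, cov_params=cov, exog_names=self.exog_names,
            df_design=self.design.df_design, nobs=len(y),
            weighted_nobs=float(w.sum()), n_iter=n_iter, converged=converged,
            model=self,
        )
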