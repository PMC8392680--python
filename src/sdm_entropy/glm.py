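"""Binomial-logit maximum-likelihood core.

The workflow is built on the ordinary logistic regression model

    P = e^y / (1 + e^y),    y = alpha + beta_1 x_1 + ... + beta_k x_k,

fitted by maximum likelihood (IRLS via statsmodels). Predictors are
standardized internally for numerical stability and the coefficients are
reported back on the original scale; the likelihood is invariant under that
affine reparameterization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .data import OccurrenceDataset

#: |standardized coefficient| beyond which a fit is flagged as separated.
SEPARATION_CAP = 30.0


class RankDeficientDesignError(ValueError):
    """Design matrix is not full rank (constant or collinear predictors)."""


@dataclass
class LogisticModel:
    """A fitted binomial-logit model.

    ``aic = 2k - 2*log_likelihood`` with ``k = 1 + len(included_variables)``
    (the intercept counts). ``converged`` is False when IRLS failed or when
    any standardized coefficient exceeds :data:`SEPARATION_CAP`, the
    heuristic for complete/quasi-complete separation.
    """

    intercept: float
    coefficients: dict[str, float]
    included_variables: list[str]
    log_likelihood: float
    aic: float
    fitted_probability: np.ndarray = field(repr=False)
    converged: bool = True

    @property
    def k(self) -> int:
        return 1 + len(self.included_variables)

    def linear_predictor(self, dataset: OccurrenceDataset) -> np.ndarray:
        eta = np.full(dataset.n, self.intercept, dtype=float)
        for name in self.included_variables:
            if name not in dataset.predictors.columns:
                raise KeyError(f"predictor {name!r} missing from dataset")
            eta += self.coefficients[name] * dataset.predictors[name].to_numpy(dtype=float)
        return eta


def _design(dataset: OccurrenceDataset, variables: list[str]):
    """Standardized design with intercept; raises naming degenerate columns."""
    for name in variables:
        if name not in dataset.predictors.columns:
            raise KeyError(f"variable {name!r} not in dataset")
    X = dataset.predictors[list(variables)].to_numpy(dtype=float)
    mu = X.mean(axis=0) if X.size else np.empty(0)
    sd = X.std(axis=0, ddof=0) if X.size else np.empty(0)
    constant = [v for v, s in zip(variables, sd) if s == 0]
    if constant:
        raise RankDeficientDesignError(f"constant predictor column(s): {constant}")
    Xs = (X - mu) / sd if X.size else X
    design = np.column_stack([np.ones(dataset.n), Xs]) if variables else np.ones((dataset.n, 1))
    if np.linalg.matrix_rank(design) < design.shape[1]:
        collinear = _collinear_columns(Xs, variables)
        raise RankDeficientDesignError(f"collinear predictor column(s): {collinear}")
    return design, mu, sd


def _collinear_columns(Xs: np.ndarray, variables: list[str]) -> list[str]:
    # QR with pivoting: trailing pivots of a rank-deficient R are dependent
    from scipy.linalg import qr

    _, r, piv = qr(Xs, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(Xs.shape) * np.finfo(float).eps if diag.size else 0.0
    rank = int(np.sum(diag > tol))
    return [variables[i] for i in sorted(piv[rank:])]


def fit_logistic(dataset: OccurrenceDataset, variables: list[str] | None = None) -> LogisticModel:
    """Maximum-likelihood fit of the logit model on the given variables.

    ``variables=[]`` (or None) fits the intercept-only (null) model, whose
    fitted probability in every cell is the species prevalence n1/n.
    Deterministic: no randomness is involved in IRLS.
    """
    variables = list(variables or [])
    if dataset.n < len(variables) + 2:
        raise ValueError("need n >= k + 1 cells to fit")
    design, mu, sd = _design(dataset, variables)
    y = dataset.presence.astype(float)
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        res = sm.GLM(y, design, family=sm.families.Binomial()).fit(
            maxiter=100, tol=1e-10
        )
    params = np.asarray(res.params, dtype=float)
    converged = bool(getattr(res, "converged", True))
    if any("separat" in str(w.message).lower() for w in caught):
        converged = False  # statsmodels flagged (quasi-)complete separation
    if variables and np.max(np.abs(params[1:])) > SEPARATION_CAP:
        converged = False  # quasi-complete separation on standardized scale
    beta_std = params[1:]
    if variables:
        beta = beta_std / sd
        alpha = params[0] - float(np.sum(beta_std * mu / sd))
    else:
        beta = np.empty(0)
        alpha = params[0]
    llf = float(res.llf)
    return LogisticModel(
        intercept=float(alpha),
        coefficients={v: float(b) for v, b in zip(variables, beta)},
        included_variables=variables,
        log_likelihood=llf,
        aic=2.0 * (1 + len(variables)) - 2.0 * llf,
        fitted_probability=np.asarray(res.fittedvalues, dtype=float),
        converged=converged,
    )


def predict_probability(model: LogisticModel, dataset: OccurrenceDataset) -> np.ndarray:
    """Element-wise inverse logit of the model's linear predictor."""
    eta = model.linear_predictor(dataset)
    with np.errstate(over="ignore"):
        return 1.0 / (1.0 + np.exp(-eta))


def rao_score_test(dataset: OccurrenceDataset, variable: str) -> tuple[float, float]:
    """Rao's score test of adding one variable to the intercept-only model.

    Under H0: beta = 0 the statistic

        U^2 / I,   U = sum x_i (y_i - ybar),
                   I = ybar (1 - ybar) * sum (x_i - xbar)^2

    is chi-square with 1 degree of freedom. Only the null model is fitted,
    which makes the univariate screen of many candidates cheap.
    """
    if variable not in dataset.predictors.columns:
        raise KeyError(f"variable {variable!r} not in dataset")
    x = dataset.predictors[variable].to_numpy(dtype=float)
    y = dataset.presence.astype(float)
    ybar = y.mean()
    ssx = float(np.sum((x - x.mean()) ** 2))
    if ssx == 0.0:
        warnings.warn(f"variable {variable!r} is constant; score test undefined")
        return 0.0, 1.0
    u = float(np.sum(x * (y - ybar)))
    info = ybar * (1.0 - ybar) * ssx
    statistic = u * u / info
    return statistic, float(stats.chi2.sf(statistic, df=1))


def null_model_closed_form(n1: int, n0: int) -> tuple[float, float, float]:
    """Closed-form (alpha, log-likelihood, AIC) of the intercept-only MLE."""
    n = n1 + n0
    p = n1 / n
    alpha = np.log(p / (1 - p))
    llf = n1 * np.log(p) + n0 * np.log(1 - p)
    return float(alpha), float(llf), float(2.0 - 2.0 * llf)
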