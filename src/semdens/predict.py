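"""Logistic prediction and evaluation of linguistic predictors.

Binary logistic regression (maximum likelihood via statsmodels) with Wald
chi-square tests per coefficient, the single-predictor decision boundary
(the predictor value where the fitted probability crosses 0.5), confusion
metrics, and train-to-holdout transfer.  Small clinical samples often sit
near quasi-complete separation; when detected, the model is refit with a
small ridge penalty and flagged rather than reported with divergent
coefficients.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .errors import (DegenerateInputError, InvalidInputError, NoBoundaryError)

logger = logging.getLogger(__name__)

RIDGE_LAMBDA = 1e-4
SEPARATION_PROB_TOL = 1e-6
SEPARATION_COEF_BOUND = 1e3


@dataclass
class LogisticModel:
    predictor_names: list[str]            # without intercept
    coefficients: np.ndarray              # [intercept, slopes...]
    standard_errors: np.ndarray
    converged: bool
    log_likelihood: float
    separation: bool = False

    def coef(self, name: str) -> float:
        return float(self.coefficients[self._idx(name)])

    def se(self, name: str) -> float:
        return float(self.standard_errors[self._idx(name)])

    def _idx(self, name: str) -> int:
        if name == "intercept":
            return 0
        try:
            return 1 + self.predictor_names.index(name)
        except ValueError:
            raise InvalidInputError(f"no predictor named {name!r}") from None

    def predict_proba(self, features) -> np.ndarray:
        X = _design(features, self.predictor_names)
        eta = X @ self.coefficients
        return 1.0 / (1.0 + np.exp(-eta))


def _design(features, names: list[str]) -> np.ndarray:
    if isinstance(features, pd.DataFrame):
        missing = [n for n in names if n not in features.columns]
        if missing:
            raise InvalidInputError(f"holdout features missing predictors {missing}")
        X = features[names].to_numpy(dtype=float)
    else:
        X = np.asarray(features, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if X.shape[1] != len(names):
            raise InvalidInputError(
                f"expected {len(names)} predictor column(s), got {X.shape[1]}")
    if np.isnan(X).any():
        raise InvalidInputError("missing predictor values")
    return np.column_stack([np.ones(len(X)), X])


def _ridge_fit(X: np.ndarray, y: np.ndarray, lam: float) -> tuple[np.ndarray, np.ndarray, float]:
    """Newton iterations on the ridge-penalized log-likelihood (intercept
    unpenalized); SEs from the inverse penalized Hessian."""
    beta = np.zeros(X.shape[1])
    pen = lam * np.eye(X.shape[1])
    pen[0, 0] = 0.0
    for _ in range(200):
        p = 1.0 / (1.0 + np.exp(-(X @ beta)))
        W = p * (1 - p)
        H = X.T @ (X * W[:, None]) + pen
        g = X.T @ (y - p) - pen @ beta
        step = np.linalg.solve(H, g)
        beta = beta + step
        if np.max(np.abs(step)) < 1e-10:
            break
    p = np.clip(1.0 / (1.0 + np.exp(-(X @ beta))), 1e-12, 1 - 1e-12)
    llf = float(np.sum(y * np.log(p) + (1 - y) * np.log(1 - p)))
    cov = np.linalg.inv(X.T @ (X * (p * (1 - p))[:, None]) + pen)
    return beta, np.sqrt(np.diag(cov)), llf


def fit_logistic(features, labels,
                 predictor_names: Sequence[str] | None = None) -> LogisticModel:
    """Maximum-likelihood logistic fit of binary labels on predictors.

    On detected quasi-complete separation (fitted probabilities within 1e-6
    of 0/1 together with divergent coefficients, or an optimizer failure),
    refits with a small ridge penalty (lambda = 1e-4) and flags the model.
    """
    if isinstance(features, pd.DataFrame):
        names = list(features.columns) if predictor_names is None else list(predictor_names)
    else:
        arr = np.asarray(features, dtype=float)
        ncol = 1 if arr.ndim == 1 else arr.shape[1]
        names = (list(predictor_names) if predictor_names is not None
                 else [f"x{i}" for i in range(ncol)])
    X = _design(features, names)
    y = np.asarray(labels, dtype=float)
    classes = np.unique(y)
    if not np.isin(classes, (0.0, 1.0)).all():
        raise InvalidInputError("labels must be binary 0/1")
    if len(classes) < 2:
        raise InvalidInputError("labels contain a single class")
    for c in classes:
        if (y == c).sum() < 2:
            raise InvalidInputError("need at least 2 participants per class")

    separation = False
    try:
        import warnings
        with np.errstate(all="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, X).fit(disp=0, maxiter=200)
        p = np.asarray(res.predict(X))
        extreme = bool(((p < SEPARATION_PROB_TOL) | (p > 1 - SEPARATION_PROB_TOL)).any())
        diverged = (np.max(np.abs(res.params)) > SEPARATION_COEF_BOUND
                    or not np.isfinite(res.bse).all())
        converged = bool(res.mle_retvals.get("converged", False))
        if extreme and (diverged or not converged):
            separation = True
        elif not converged:
            raise RuntimeError("logistic fit did not converge (no separation detected)")
        if not separation:
            return LogisticModel(predictor_names=names,
                                 coefficients=np.asarray(res.params, dtype=float),
                                 standard_errors=np.asarray(res.bse, dtype=float),
                                 converged=True,
                                 log_likelihood=float(res.llf))
    except (PerfectSeparationError, np.linalg.LinAlgError):
        separation = True

    logger.info("quasi-complete separation detected; refitting with ridge "
                "penalty lambda=%g", RIDGE_LAMBDA)
    beta, bse, llf = _ridge_fit(X, y, RIDGE_LAMBDA)
    return LogisticModel(predictor_names=names, coefficients=beta,
                         standard_errors=bse, converged=True,
                         log_likelihood=llf, separation=True)


def wald_chi2(model: LogisticModel, predictor: str) -> tuple[float, float]:
    """Wald statistic (coef / SE)^2 and its chi-square(1) p-value."""
    se = model.se(predictor)
    if se == 0:
        raise DegenerateInputError(f"zero standard error for {predictor!r}")
    stat = (model.coef(predictor) / se) ** 2
    return float(stat), float(scipy.stats.chi2.sf(stat, df=1))


def decision_boundary(model: LogisticModel, predictor: str | None = None) -> float:
    """Predictor value where the fitted probability is 0.5: -b0 / b1.

    Only defined for single-predictor models with nonzero slope.
    """
    if len(model.predictor_names) != 1:
        raise InvalidInputError("decision boundary requires a single-predictor model")
    name = predictor if predictor is not None else model.predictor_names[0]
    slope = model.coef(name)
    if slope == 0:
        raise NoBoundaryError("zero slope: no decision boundary")
    return float(-model.coefficients[0] / slope)


@dataclass(frozen=True)
class ConfusionMetrics:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.n

    @property
    def precision(self) -> float | None:
        d = self.tp + self.fp
        return self.tp / d if d else None

    @property
    def recall(self) -> float | None:
        d = self.tp + self.fn
        return self.tp / d if d else None

    @property
    def sensitivity(self) -> float | None:
        return self.recall

    @property
    def specificity(self) -> float | None:
        d = self.tn + self.fp
        return self.tn / d if d else None

    @property
    def f1(self) -> float | None:
        p, r = self.precision, self.recall
        if p is None or r is None or (p + r) == 0:
            return None
        return 2 * p * r / (p + r)

    def as_dict(self) -> dict:
        return {"tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn,
                "accuracy": self.accuracy, "precision": self.precision,
                "recall": self.recall, "specificity": self.specificity,
                "f1": self.f1}


def confusion_metrics(predicted: Sequence[int], actual: Sequence[int]) -> ConfusionMetrics:
    """Confusion counts and derived fractions; undefined ratios stay None."""
    predicted = np.asarray(predicted).astype(int)
    actual = np.asarray(actual).astype(int)
    if predicted.shape != actual.shape or predicted.size == 0:
        raise InvalidInputError("predicted and actual must be equal-length, non-empty")
    tp = int(((predicted == 1) & (actual == 1)).sum())
    fp = int(((predicted == 1) & (actual == 0)).sum())
    tn = int(((predicted == 0) & (actual == 0)).sum())
    fn = int(((predicted == 0) & (actual == 1)).sum())
    return ConfusionMetrics(tp=tp, fp=fp, tn=tn, fn=fn)


def evaluate_transfer(model: LogisticModel, features, labels,
                      threshold: float = 0.5) -> ConfusionMetrics:
    """Classify holdout data with the training coefficients at the threshold."""
    p = model.predict_proba(features)
    predicted = (p >= threshold).astype(int)
    return confusion_metrics(predicted, np.asarray(labels).astype(int))


def pearson_r(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Product-moment correlation with a two-sided t-based p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise InvalidInputError("need equal-length sequences of at least 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise DegenerateInputError("zero variance in pearson_r input")
    r, p = scipy.stats.pearsonr(x, y)
    return float(r), float(p)
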