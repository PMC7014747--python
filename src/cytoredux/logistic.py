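"""Logistic modelling: IRLS fits, univariate screens, split-sample
validation, Hosmer-Lemeshow calibration, and the fixed published scorer.

Outcome coding is suboptimal = 1 throughout our own fits.  The published
coefficient equation (age in years continuous; CA125/HE4 high indicators;
serous-histology indicator) is applied verbatim as a frozen scorer and is
never re-estimated or sign-corrected: the originally reported odds-ratio
directions are internally inconsistent, so the raw linear predictor is
exposed and both possible outcome readings are documented rather than
resolved.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit
from sklearn.base import BaseEstimator, ClassifierMixin

from .cohort import Cohort
from .diagnostics import (
    as_binary,
    auc_se_ci_hanley,
    roc_auc,
    youden_cutoff,
)
from .errors import CohortError, ConvergenceError, SeparationError

_ETA_DIVERGENCE = 30.0  # |linear predictor| beyond this signals separation


def split_cohort(cohort: Cohort, train_fraction: float, seed=None,
                 stratify: bool = False):
    """Random disjoint train/validation split, reproducible by seed.

    The training size is round-half-up of ``n * train_fraction``; with
    ``stratify=True`` the rounding applies per outcome class.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must be in (0, 1)")
    n = len(cohort)
    if n < 4:
        raise CohortError("cohort too small to split (need n >= 4)")
    rng = np.random.default_rng(seed)

    def _take(indices, fraction):
        k = int(math.floor(len(indices) * fraction + 0.5))
        perm = rng.permutation(indices)
        return list(perm[:k]), list(perm[k:])

    if stratify:
        y = cohort.outcomes
        tr0, va0 = _take(np.flatnonzero(y == 0), train_fraction)
        tr1, va1 = _take(np.flatnonzero(y == 1), train_fraction)
        train_idx, val_idx = sorted(tr0 + tr1), sorted(va0 + va1)
    else:
        train_idx, val_idx = _take(np.arange(n), train_fraction)
        train_idx, val_idx = sorted(train_idx), sorted(val_idx)
    prov = cohort.provenance
    return (
        cohort.subset(train_idx, f"{prov} [train seed={seed}]"),
        cohort.subset(val_idx, f"{prov} [validation seed={seed}]"),
    )


@dataclass(frozen=True)
class CovariateEncoding:
    """Encoding used by the multivariable model: continuous age plus three
    indicators (CA125 high, HE4 high, serous histology)."""

    ca125_cutoff: float = 313.60
    he4_cutoff: float = 777.10

    terms = ("age", "ca125_high", "he4_high", "histology_serous")

    def encode_record(self, record) -> np.ndarray:
        return np.array(
            [
                float(record.age),
                float(record.ca125 >= self.ca125_cutoff),
                float(record.he4 >= self.he4_cutoff),
                float(record.histology == "serous"),
            ]
        )

    def design(self, cohort: Cohort):
        """(X, y) with X a DataFrame over :attr:`terms` and y the binary
        outcome (1 = suboptimal)."""
        X = pd.DataFrame(
            [self.encode_record(r) for r in cohort], columns=list(self.terms)
        )
        return X, cohort.outcomes


class IRLSLogisticRegression(BaseEstimator, ClassifierMixin):
    """Maximum-likelihood logistic regression via iteratively reweighted
    least squares (Newton-Raphson on the log-likelihood).

    Convergence criterion: max absolute score (gradient) below ``tol``.
    Complete or quasi-complete separation raises :class:`SeparationError`
    rather than returning diverged coefficients; hitting ``max_iter``
    without convergence raises :class:`ConvergenceError`.

    Fitted attributes: ``coef_``, ``intercept_``, ``bse_`` (intercept
    first), ``cov_params_``, ``loglik_path_``, ``n_iter_``, ``converged_``.
    """

    def __init__(self, tol: float = 1e-8, max_iter: int = 50,
                 fit_intercept: bool = True):
        self.tol = tol
        self.max_iter = max_iter
        self.fit_intercept = fit_intercept

    def _design(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if self.fit_intercept:
            X = np.column_stack([np.ones(len(X)), X])
        return X

    def fit(self, X, y):
        y = np.asarray(as_binary(y), dtype=float)
        D = self._design(X)
        n, k = D.shape
        if n <= k:
            raise ValueError(f"need more observations ({n}) than terms ({k})")
        col_sd = D.std(axis=0)
        start = 1 if self.fit_intercept else 0
        if np.any(col_sd[start:] == 0):
            raise ValueError("design contains a zero-variance column")

        beta = np.zeros(k)
        loglik_path = []
        converged = False
        n_iter = 0
        for n_iter in range(1, self.max_iter + 1):
            eta = D @ beta
            p = expit(eta)
            loglik_path.append(float(np.sum(y * eta - np.logaddexp(0.0, eta))))
            score = D.T @ (y - p)
            if np.max(np.abs(score)) < self.tol:
                converged = True
                break
            if np.max(np.abs(eta)) > _ETA_DIVERGENCE:
                raise SeparationError(
                    "fitted probabilities saturating at 0/1: data appear "
                    "completely separated; coefficients diverge"
                )
            w = p * (1.0 - p)
            info = D.T @ (D * w[:, None])
            try:
                delta = np.linalg.solve(info, score)
            except np.linalg.LinAlgError:
                raise SeparationError(
                    "singular information matrix during IRLS (separation or "
                    "collinear design)"
                ) from None
            beta = beta + delta
        if not converged:
            raise ConvergenceError(
                f"IRLS did not converge in {self.max_iter} iterations"
            )

        p = expit(D @ beta)
        if np.all((p < 1e-6) | (p > 1 - 1e-6)):
            # every observation perfectly predicted: the MLE does not exist
            raise SeparationError(
                "all fitted probabilities saturate at 0/1: data are "
                "completely separated"
            )
        w = p * (1.0 - p)
        cov = np.linalg.inv(D.T @ (D * w[:, None]))
        self.classes_ = np.array([0, 1])
        if self.fit_intercept:
            self.intercept_ = float(beta[0])
            self.coef_ = beta[1:].copy()
        else:
            self.intercept_ = 0.0
            self.coef_ = beta.copy()
        self.params_ = beta.copy()
        self.bse_ = np.sqrt(np.diag(cov))
        self.cov_params_ = cov
        self.loglik_path_ = np.array(loglik_path)
        self.loglik_ = loglik_path[-1]
        self.n_iter_ = n_iter
        self.converged_ = True
        self.n_obs_ = n
        return self

    def decision_function(self, X) -> np.ndarray:
        D = self._design(X)
        return D @ self.params_

    def predict_proba(self, X) -> np.ndarray:
        p = expit(self.decision_function(X))
        return np.column_stack([1 - p, p])

    def predict(self, X) -> np.ndarray:
        return (self.decision_function(X) >= 0).astype(int)


@dataclass(frozen=True)
class LogisticFit:
    """Converged IRLS fit: coefficients, Wald inference, odds ratios."""

    terms: tuple
    coef: np.ndarray          # intercept first when present
    bse: np.ndarray
    odds_ratios: np.ndarray   # exp(coef) for non-intercept terms
    or_ci: np.ndarray         # (k, 2) Wald 95% CI on the OR scale
    p_values: np.ndarray
    converged: bool
    n_iter: int
    n: int
    loglik: float
    loglik_path: np.ndarray


def _fit_to_result(est: IRLSLogisticRegression, terms) -> LogisticFit:
    beta, bse = est.params_, est.bse_
    z = stats.norm.ppf(0.975)
    lo, hi = beta - z * bse, beta + z * bse
    p = 2.0 * stats.norm.sf(np.abs(beta) / bse)
    return LogisticFit(
        terms=tuple(terms),
        coef=beta,
        bse=bse,
        odds_ratios=np.exp(beta),
        or_ci=np.column_stack([np.exp(lo), np.exp(hi)]),
        p_values=p,
        converged=est.converged_,
        n_iter=est.n_iter_,
        n=est.n_obs_,
        loglik=est.loglik_,
        loglik_path=est.loglik_path_,
    )


def fit_logistic_irls(design, outcome, tol: float = 1e-8, max_iter: int = 50,
                      add_intercept: bool = True,
                      terms=None) -> LogisticFit:
    """Fit a logistic model by IRLS on an explicit design matrix.

    ``design`` may be a DataFrame (column names become term names) or an
    array.  An intercept is prepended unless ``add_intercept=False``.
    """
    if isinstance(design, pd.DataFrame):
        names = list(design.columns)
        X = design.to_numpy(dtype=float)
    else:
        X = np.asarray(design, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        names = list(terms) if terms is not None else [f"x{i}" for i in range(X.shape[1])]
    est = IRLSLogisticRegression(tol=tol, max_iter=max_iter,
                                 fit_intercept=add_intercept).fit(X, outcome)
    all_terms = (["intercept"] if add_intercept else []) + names
    return _fit_to_result(est, all_terms)


def univariate_screen(cohort: Cohort,
                      encoding: CovariateEncoding = CovariateEncoding()) -> dict:
    """One single-predictor logistic fit per encoded covariate.

    For a binary predictor the fitted OR equals the 2x2 cross-product
    ratio.  Separation in any single screen propagates as an error for
    that predictor's entry (stored as the exception instance).
    """
    cohort.require_both_classes()
    X, y = encoding.design(cohort)
    out = {}
    for term in encoding.terms:
        try:
            out[term] = fit_logistic_irls(X[[term]], y)
        except (SeparationError, ConvergenceError, ValueError) as exc:
            out[term] = exc
    return out


@dataclass(frozen=True)
class PublishedModel:
    """Frozen published coefficient vector for the four-term model.

    logit p = 0.12*age - 2.38*ca125_high - 1.86*he4_high
              - 2.74*histology_serous - 3.37
    """

    age: float = 0.12
    ca125_high: float = -2.38
    he4_high: float = -1.86
    histology_serous: float = -2.74
    intercept: float = -3.37


def published_model_predict(record, model: PublishedModel = PublishedModel(),
                            encoding: CovariateEncoding = CovariateEncoding()):
    """Linear predictor and inverse-logit probability of the published
    equation for one patient record."""
    x = encoding.encode_record(record)
    lp = (
        model.intercept
        + model.age * x[0]
        + model.ca125_high * x[1]
        + model.he4_high * x[2]
        + model.histology_serous * x[3]
    )
    return float(lp), float(expit(lp))


def published_model_probabilities(cohort: Cohort,
                                  model: PublishedModel = PublishedModel(),
                                  encoding: CovariateEncoding = CovariateEncoding()):
    return np.array([published_model_predict(r, model, encoding)[1] for r in cohort])


@dataclass(frozen=True)
class HLResult:
    statistic: float
    groups_used: int
    df: int
    p_value: float


def hosmer_lemeshow(probabilities, outcomes, groups: int = 10) -> HLResult:
    """Hosmer-Lemeshow goodness-of-fit chi-square (deciles of risk).

    Observations are grouped by probability quantiles with tied
    probabilities kept together; the statistic sums (O - E)^2 / E over
    groups and both outcome classes, with df = groups - 2.
    """
    p = np.asarray(probabilities, dtype=float)
    y = as_binary(outcomes)
    if len(p) != len(y):
        raise ValueError("probabilities and outcomes must have equal length")
    if groups < 2:
        raise ValueError("need at least 2 groups")
    if len(p) < 2 * groups:
        raise ValueError(f"need n >= {2 * groups} observations for {groups} groups")
    if len(np.unique(p)) < groups:
        raise ValueError(
            f"only {len(np.unique(p))} distinct probabilities for {groups} "
            "groups; use fewer groups"
        )
    quantiles = np.quantile(p, np.linspace(0, 1, groups + 1)[1:-1])
    edges = np.unique(quantiles)
    bins = np.searchsorted(edges, p, side="left")
    used = np.unique(bins)
    if len(used) < 2:
        raise ValueError("ties collapse the risk groups; use fewer groups")
    statistic = 0.0
    for b in used:
        mask = bins == b
        n_g = int(mask.sum())
        o = float(y[mask].sum())
        e = float(p[mask].sum())
        if 0 < e < n_g:
            statistic += (o - e) ** 2 / e + ((n_g - o) - (n_g - e)) ** 2 / (n_g - e)
        elif e != o:
            statistic = float("inf")
    df = len(used) - 2
    # with exactly two risk groups the statistic is still informative but
    # carries no degrees of freedom; the p-value is undefined
    p_value = float(stats.chi2.sf(statistic, df)) if df >= 1 else float("nan")
    return HLResult(
        statistic=float(statistic),
        groups_used=int(len(used)),
        df=df,
        p_value=p_value,
    )


@dataclass(frozen=True)
class ValidationResult:
    auc: float
    auc_se: float
    auc_ci: tuple
    auc_p: float
    cutoff: float
    sensitivity: float
    specificity: float
    n: int


def evaluate_validation(probabilities, truth) -> ValidationResult:
    """Discrimination summary of predicted probabilities on held-out data:
    AUC with Hanley-McNeil CI and the Youden-optimal operating point."""
    roc = roc_auc(probabilities, truth)
    se, ci = auc_se_ci_hanley(roc.auc, roc.n_pos, roc.n_neg)
    p = 2.0 * stats.norm.sf(abs(roc.auc - 0.5) / se) if se > 0 else 0.0
    cut = youden_cutoff(probabilities, truth)
    return ValidationResult(
        auc=roc.auc,
        auc_se=se,
        auc_ci=ci,
        auc_p=float(p),
        cutoff=cut.cutoff,
        sensitivity=cut.sensitivity,
        specificity=cut.specificity,
        n=roc.n_pos + roc.n_neg,
    )
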