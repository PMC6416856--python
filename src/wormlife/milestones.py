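"""Median developmental-milestone timing from logistic attainment models.

Each worm is scored 0 (has not reached the milestone) or 1 (has reached it)
at each observation time. A binomial GLM of status on time (logit link)
turns these records into an attainment curve; the median milestone time t50
is the time at which the fitted curve crosses probability 0.5,

    t50 = -beta0 / beta1,

with a delta-method confidence interval propagated from the coefficient
covariance. Species are compared with a 2-df likelihood-ratio test of the
model with a species main effect and species x time interaction against the
pooled intercept + slope model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "LogisticAttainment",
    "LogisticMilestoneFit",
    "LRTResult",
    "DegenerateDataError",
    "fit_attainment",
    "median_milestone_table",
    "compare_species_lrt",
]

MAX_ABS_SLOPE = 1e4  # |beta1| beyond this is treated as separation


class DegenerateDataError(ValueError):
    """Raised when a group has a single status class or a single time."""


@dataclass(frozen=True)
class LogisticMilestoneFit:
    """Fitted intercept/slope logistic attainment model for one group."""

    beta0: float
    beta1: float
    t50: float
    log_likelihood: float
    n_obs: int
    converged: bool
    separation_detected: bool
    cov: np.ndarray | None = None

    def t50_ci(self, level: float = 0.95) -> tuple[float, float]:
        """Delta-method confidence interval for t50 = -beta0/beta1."""
        if self.separation_detected or self.cov is None or self.beta1 == 0:
            return (float("nan"), float("nan"))
        grad = np.array([-1.0 / self.beta1, self.beta0 / self.beta1**2])
        var = float(grad @ self.cov @ grad)
        se = np.sqrt(max(var, 0.0))
        z = stats.norm.ppf(0.5 + level / 2)
        return (self.t50 - z * se, self.t50 + z * se)


@dataclass(frozen=True)
class LRTResult:
    chisq: float
    df: int
    p_value: float


class LogisticAttainment(BaseEstimator):
    """Binary attainment-vs-time logistic model, scikit-learn style.

    Fits ``P(status = 1 | t) = expit(beta0 + beta1 * t)`` by maximum
    likelihood (IRLS via statsmodels) and exposes the median attainment
    time ``t50_ = -beta0/beta1``.

    Parameters
    ----------
    max_iter : int
        Maximum IRLS iterations.
    tol : float
        Relative log-likelihood convergence tolerance.

    Attributes
    ----------
    coef_ : ndarray of shape (2,)
        ``[beta0, beta1]`` (intercept, slope per day).
    t50_ : float
        Median milestone time in days.
    log_likelihood_ : float
    separation_detected_ : bool
        True when the statuses are perfectly ordered by time; ``t50_`` is
        then the midpoint of the empirical transition interval and the
        slope is reported as +inf.
    """

    def __init__(self, max_iter: int = 100, tol: float = 1e-10):
        self.max_iter = max_iter
        self.tol = tol

    def fit(self, X, y):
        t = np.asarray(X, dtype=float).reshape(-1)
        status = np.asarray(y, dtype=float).reshape(-1)
        if t.shape != status.shape:
            raise ValueError("time and status must have equal length")
        if not np.isin(status, [0.0, 1.0]).all():
            raise ValueError("status must be binary 0/1")
        if np.unique(status).size < 2:
            raise DegenerateDataError(
                "all observations share one status class; attainment time "
                "is not identifiable"
            )
        if np.unique(t).size < 2:
            raise DegenerateDataError("need at least two distinct time values")

        sep, midpoint = _detect_separation(t, status)
        if sep:
            self.coef_ = np.array([-np.inf, np.inf])
            self.t50_ = midpoint
            self.log_likelihood_ = 0.0
            self.cov_ = None
            self.converged_ = True
            self.separation_detected_ = True
            self.n_obs_ = t.size
            return self

        exog = sm.add_constant(t)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = sm.GLM(status, exog, family=sm.families.Binomial())
                res = model.fit(maxiter=self.max_iter, tol=self.tol)
        except Exception:
            # IRLS blew up on quasi-separated data; fall back to the
            # transition-interval midpoint with an infinite-slope flag
            self.coef_ = np.array([-np.inf, np.inf])
            self.t50_ = midpoint
            self.log_likelihood_ = 0.0
            self.cov_ = None
            self.converged_ = True
            self.separation_detected_ = True
            self.n_obs_ = t.size
            return self
        beta0, beta1 = res.params
        if abs(beta1) > MAX_ABS_SLOPE or not np.isfinite(res.llf):
            # quasi-separation slipped past the exact check
            self.coef_ = np.array([beta0, beta1])
            self.t50_ = midpoint
            self.log_likelihood_ = float(res.llf) if np.isfinite(res.llf) else 0.0
            self.cov_ = None
            self.converged_ = True
            self.separation_detected_ = True
            self.n_obs_ = t.size
            return self
        self.coef_ = np.array([beta0, beta1])
        self.t50_ = float(-beta0 / beta1)
        self.log_likelihood_ = float(res.llf)
        self.cov_ = np.asarray(res.cov_params())
        self.converged_ = bool(res.converged)
        self.separation_detected_ = False
        self.n_obs_ = t.size
        if not self.converged_:
            raise RuntimeError(
                f"IRLS failed to converge in {self.max_iter} iterations "
                f"(deviance trace: {getattr(res, 'fit_history', None)})"
            )
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "coef_")
        t = np.asarray(X, dtype=float).reshape(-1)
        if self.separation_detected_:
            p1 = (t > self.t50_).astype(float) + 0.5 * (t == self.t50_)
        else:
            from scipy.special import expit

            p1 = expit(self.coef_[0] + self.coef_[1] * t)
        return np.column_stack([1 - p1, p1])

    def predict(self, X):
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)

    def to_result(self) -> LogisticMilestoneFit:
        check_is_fitted(self, "coef_")
        return LogisticMilestoneFit(
            beta0=float(self.coef_[0]),
            beta1=float(self.coef_[1]),
            t50=float(self.t50_),
            log_likelihood=float(self.log_likelihood_),
            n_obs=int(self.n_obs_),
            converged=bool(self.converged_),
            separation_detected=bool(self.separation_detected_),
            cov=self.cov_,
        )


def _detect_separation(t: np.ndarray, status: np.ndarray) -> tuple[bool, float]:
    """Perfect separation: every status-0 time precedes every status-1 time.

    Returns (separated, midpoint of the empirical transition interval).
    """
    t0_max = t[status == 0].max()
    t1_min = t[status == 1].min()
    return bool(t0_max < t1_min), float((t0_max + t1_min) / 2.0)


def fit_attainment(obs: pd.DataFrame) -> LogisticMilestoneFit:
    """Fit the attainment model to one group's (time, status) records."""
    return (
        LogisticAttainment().fit(obs["time"].to_numpy(), obs["status"].to_numpy())
    ).to_result()


def median_milestone_table(
    obs: pd.DataFrame, ci_level: float = 0.95
) -> pd.DataFrame:
    """Per species x temperature x milestone median attainment times.

    Groups whose fit fails (single status class, too few times) yield a
    flagged row with NaN estimates rather than raising.
    """
    rows = []
    for (species, temp, milestone), sub in obs.groupby(
        ["species", "temperature", "milestone"], sort=True
    ):
        row = {
            "species": species,
            "temperature": temp,
            "milestone": milestone,
            "n_obs": len(sub),
        }
        try:
            fit = fit_attainment(sub)
            lo, hi = fit.t50_ci(ci_level)
            row.update(
                t50=fit.t50, ci_low=lo, ci_high=hi,
                separation=fit.separation_detected, failed=False,
            )
        except (DegenerateDataError, RuntimeError) as exc:
            row.update(
                t50=np.nan, ci_low=np.nan, ci_high=np.nan,
                separation=False, failed=True, failure_reason=str(exc),
            )
        rows.append(row)
    return pd.DataFrame(rows)


def compare_species_lrt(obs_a: pd.DataFrame, obs_b: pd.DataFrame) -> LRTResult:
    """2-df likelihood-ratio test for a species difference in attainment.

    The full model adds a species indicator and its interaction with time
    to the pooled intercept + slope model; the statistic is
    ``2 (LL_full - LL_reduced)`` referred to chi-square with 2 df.
    """
    for grp in (obs_a, obs_b):
        if np.unique(grp["status"]).size < 2:
            raise DegenerateDataError("a group has a single status class")
    t = np.concatenate([obs_a["time"].to_numpy(float),
                        obs_b["time"].to_numpy(float)])
    y = np.concatenate([obs_a["status"].to_numpy(float),
                        obs_b["status"].to_numpy(float)])
    g = np.concatenate([np.zeros(len(obs_a)), np.ones(len(obs_b))])

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        reduced = sm.GLM(
            y, sm.add_constant(t), family=sm.families.Binomial()
        ).fit(maxiter=200)
        full_exog = np.column_stack([np.ones_like(t), t, g, g * t])
        full = sm.GLM(y, full_exog, family=sm.families.Binomial()).fit(maxiter=200)
    chisq = max(0.0, 2.0 * (full.llf - reduced.llf))
    p = float(stats.chi2.sf(chisq, df=2))
    return LRTResult(chisq=float(chisq), df=2, p_value=p)
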