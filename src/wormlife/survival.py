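"""Survivorship curves, median lifespans, and proportional-hazards comparison.

Lifespans are integer days since egg lay (day 0 = the day embryos were
laid). The Kaplan-Meier product-limit estimator handles optional right
censoring (worms lost or escaped before death); group comparisons use a
fixed-effect Cox proportional-hazards model with a single group indicator
and the Efron correction for the heavy ties produced by daily scoring.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .config import Config

__all__ = [
    "KMCurve",
    "PHResult",
    "km_fit",
    "median_lifespan",
    "adult_lifespan_transform",
    "ph_compare",
    "cox_partial_loglik",
]


class NoEventsError(ValueError):
    """All records are censored; no survivorship curve can be estimated."""


@dataclass(frozen=True)
class KMCurve:
    """Product-limit survivorship estimate.

    ``survival[i]`` is S(t) just after ``event_times[i]``; S = 1 before the
    first event time. ``at_risk`` and ``deaths`` are the n_i and d_i entering
    each factor (1 - d_i/n_i).
    """

    event_times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    deaths: np.ndarray

    def survival_at(self, t: float) -> float:
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.event_times,
                "survival": self.survival,
                "n_risk": self.at_risk,
                "n_deaths": self.deaths,
            }
        )


@dataclass(frozen=True)
class PHResult:
    log_hazard_ratio: float
    std_error: float
    z_value: float
    p_value: float
    monotone_likelihood: bool = False


def _extract(records: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    days = records["day_of_death"].to_numpy(float)
    if "censored" in records.columns:
        observed = ~records["censored"].to_numpy(bool)
    else:
        observed = np.ones(len(records), bool)
    return days, observed


def km_fit(records: pd.DataFrame) -> KMCurve:
    """Kaplan-Meier product-limit estimate over distinct event days.

    Censored records remain at risk through their recorded day and leave
    the risk set afterwards.
    """
    days, observed = _extract(records)
    if not observed.any():
        raise NoEventsError("all records are censored; no deaths observed")
    event_times = np.unique(days[observed])
    surv = []
    at_risk = []
    deaths = []
    s = 1.0
    for t in event_times:
        n_i = int(np.sum(days >= t))
        d_i = int(np.sum((days == t) & observed))
        s *= 1.0 - d_i / n_i
        at_risk.append(n_i)
        deaths.append(d_i)
        surv.append(s)
    return KMCurve(
        event_times=event_times.astype(float),
        survival=np.array(surv),
        at_risk=np.array(at_risk, dtype=int),
        deaths=np.array(deaths, dtype=int),
    )


def median_lifespan(curve: KMCurve) -> float:
    """Smallest event time with S(t) <= 0.5, or NaN when S never reaches 0.5."""
    below = curve.survival <= 0.5 + 1e-12
    if not below.any():
        return float("nan")
    return float(curve.event_times[np.argmax(below)])


def adult_lifespan_transform(
    records: pd.DataFrame, config: Config
) -> pd.DataFrame:
    """Convert total lifespans to adult lifespans by the species offset.

    Subtracts the species' development time (egg to adulthood) from each
    death day. Records that would go negative are clamped to 0 and flagged
    in a ``clamped`` column (they died before the nominal maturation day).
    """
    species = records["species"].unique()
    missing = [s for s in species if s not in config.adult_offset_days]
    if missing:
        raise KeyError(f"no adult offset configured for species {missing}")
    out = records.copy()
    offsets = out["species"].map(config.adult_offset_days)
    adjusted = out["day_of_death"] - offsets
    out["clamped"] = adjusted < 0
    out["day_of_death"] = adjusted.clip(lower=0)
    return out


# ---------------------------------------------------------------------------
# Cox proportional hazards, single binary covariate, Efron ties
# ---------------------------------------------------------------------------

def _efron_terms(days, observed, x):
    """Per-event-time (d0, d1, n0, n1): deaths and risk-set sizes by group."""
    terms = []
    for t in np.unique(days[observed]):
        at_risk = days >= t
        dead = (days == t) & observed
        terms.append(
            (
                int(np.sum(dead & (x == 0))),
                int(np.sum(dead & (x == 1))),
                int(np.sum(at_risk & (x == 0))),
                int(np.sum(at_risk & (x == 1))),
            )
        )
    return terms


def cox_partial_loglik(days, observed, x, beta: float) -> float:
    """Efron-corrected Cox partial log-likelihood for a binary covariate."""
    ll = 0.0
    eb = np.exp(beta)
    for d0, d1, n0, n1 in _efron_terms(days, observed, x):
        d = d0 + d1
        ll += d1 * beta
        for j in range(d):
            a = n0 - (j / d) * d0
            b = n1 - (j / d) * d1
            ll -= np.log(a + b * eb)
    return ll


def _score_hessian(terms, beta: float) -> tuple[float, float]:
    eb = np.exp(beta)
    score = 0.0
    hess = 0.0
    for d0, d1, n0, n1 in terms:
        d = d0 + d1
        score += d1
        for j in range(d):
            a = n0 - (j / d) * d0
            b = n1 - (j / d) * d1
            denom = a + b * eb
            frac = b * eb / denom
            score -= frac
            hess -= frac * (1.0 - frac)
    return score, hess


def ph_compare(
    records_a: pd.DataFrame,
    records_b: pd.DataFrame,
    tol: float = 1e-10,
    max_iter: int = 60,
) -> PHResult:
    """Proportional-hazards comparison of two lifespan groups.

    The covariate is an indicator for membership in ``records_b``; a
    positive log hazard ratio means group B dies faster. The partial
    likelihood is maximized by Newton iteration until the score is below
    ``tol``. If the likelihood is monotone (e.g. every group-A death
    precedes every group-B death) the estimate diverges; the result is
    flagged rather than raised.
    """
    days_a, obs_a = _extract(records_a)
    days_b, obs_b = _extract(records_b)
    if not obs_a.any() or not obs_b.any():
        raise NoEventsError("each group needs at least one observed death")
    days = np.concatenate([days_a, days_b])
    observed = np.concatenate([obs_a, obs_b])
    x = np.concatenate([np.zeros(len(days_a)), np.ones(len(days_b))])

    terms = _efron_terms(days, observed, x)
    beta = 0.0
    for _ in range(max_iter):
        score, hess = _score_hessian(terms, beta)
        if abs(score) < tol:
            break
        if hess == 0.0:
            break
        step = -score / hess
        # dampen wild steps on nearly-monotone likelihoods
        step = float(np.clip(step, -5.0, 5.0))
        beta += step
        if abs(beta) > 50.0:
            return PHResult(
                log_hazard_ratio=float(np.sign(beta) * np.inf),
                std_error=float("inf"),
                z_value=float(np.sign(beta) * np.inf),
                p_value=float("nan"),
                monotone_likelihood=True,
            )
    score, hess = _score_hessian(terms, beta)
    # a monotone partial likelihood (e.g. fully separated death orders)
    # drives the maximizer off to +-inf; the score also decays to 0 out
    # there, so detect it by the implausible magnitude of the estimate
    if abs(score) >= max(tol, 1e-8) or abs(beta) > 10.0:
        return PHResult(
            log_hazard_ratio=float(np.sign(beta) * np.inf) if beta else 0.0,
            std_error=float("inf"),
            z_value=float(np.sign(beta) * np.inf) if beta else 0.0,
            p_value=float("nan"),
            monotone_likelihood=True,
        )
    se = float(np.sqrt(-1.0 / hess)) if hess < 0 else float("inf")
    z = beta / se if np.isfinite(se) and se > 0 else 0.0
    p = float(2.0 * stats.norm.sf(abs(z)))
    return PHResult(
        log_hazard_ratio=float(beta),
        std_error=se,
        z_value=float(z),
        p_value=p,
        monotone_likelihood=False,
    )
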