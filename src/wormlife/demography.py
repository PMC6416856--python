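"""Life tables and the intrinsic rate of natural increase.

A cohort's fitness is summarized by the intrinsic rate of increase r, the
unique real root of the Euler-Lotka equation

    sum_x exp(-r * x) * l_x * m_x = 1,

where ages x are integer days since egg lay, l_x is survivorship from egg
to age x, and m_x is per-capita fecundity at age x. Life tables are built
from three assays: plate-level embryo-to-adult viability, adult lifespans,
and per-female daily fecundity schedules. Confidence intervals come from a
seeded percentile bootstrap over individuals (females with their schedules,
worms with their lifespans, plates with their viabilities).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import Config

__all__ = [
    "LifeTable",
    "RateEstimate",
    "viability_summary",
    "build_life_table",
    "euler_lotka_r",
    "bootstrap_r_ci",
]


@dataclass(frozen=True)
class LifeTable:
    """Age grid (days, day 0 = egg laid) with survivorship and fecundity."""

    ages: np.ndarray
    l_x: np.ndarray
    m_x: np.ndarray

    def __post_init__(self):
        ages = np.asarray(self.ages)
        l_x = np.asarray(self.l_x, dtype=float)
        m_x = np.asarray(self.m_x, dtype=float)
        if not (len(ages) == len(l_x) == len(m_x)):
            raise ValueError("ages, l_x, m_x must have equal length")
        if len(ages) == 0:
            raise ValueError("life table is empty")
        if (np.diff(ages) <= 0).any():
            raise ValueError("ages must be strictly increasing")
        if (l_x < -1e-12).any() or (l_x > 1 + 1e-12).any():
            raise ValueError("l_x must lie in [0, 1]")
        if (np.diff(l_x) > 1e-12).any():
            raise ValueError("l_x must be nonincreasing")
        if ages[0] == 0 and abs(l_x[0] - 1.0) > 1e-12:
            raise ValueError("l_0 must equal 1")
        if (m_x < 0).any():
            raise ValueError("m_x must be nonnegative")
        object.__setattr__(self, "ages", ages)
        object.__setattr__(self, "l_x", l_x)
        object.__setattr__(self, "m_x", m_x)

    @property
    def net_reproductive_rate(self) -> float:
        return float(np.sum(self.l_x * self.m_x))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"age": self.ages, "l_x": self.l_x, "m_x": self.m_x})

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "LifeTable":
        df = df.sort_values("age")
        return cls(
            ages=df["age"].to_numpy(),
            l_x=df["l_x"].to_numpy(float),
            m_x=df["m_x"].to_numpy(float),
        )


@dataclass(frozen=True)
class RateEstimate:
    r: float
    net_reproductive_rate: float
    ci_low: float
    ci_high: float
    bootstrap_reps: int
    seed: int
    n_failed: int = 0
    flagged: bool = False


def viability_summary(records: pd.DataFrame) -> pd.DataFrame:
    """Per species x temperature median plate viability (matured/initial)."""
    if len(records) == 0:
        raise ValueError("no viability records")
    df = records.copy()
    df["viability"] = df["matured"] / df["embryos_initial"]
    keys = [c for c in ("species", "temperature") if c in df.columns]
    out = (
        df.groupby(keys, sort=True)["viability"]
        .agg(n_plates="size", median_viability="median")
        .reset_index()
    )
    return out


def _survival_to_age(death_days: np.ndarray, ages: np.ndarray) -> np.ndarray:
    """P(alive after day x) among assayed adults, no censoring."""
    return (death_days[None, :] > ages[:, None]).mean(axis=1)


def _mean_daily_fecundity(schedules: list[np.ndarray], n_days: int) -> np.ndarray:
    """Mean embryos laid per female observed on each adult day.

    Females with no observation on a day (already dead or done laying) are
    excluded from that day's denominator.
    """
    out = np.zeros(n_days)
    for d in range(n_days):
        vals = [s[d] for s in schedules if len(s) > d]
        out[d] = float(np.mean(vals)) if vals else 0.0
    return out


def build_life_table(
    viability: float,
    lifespans: pd.DataFrame,
    schedules: list[np.ndarray],
    config: Config,
    maturation_day: int,
) -> LifeTable:
    """Assemble a life table from the three cohort assays.

    Survivorship: l_0 = 1, a linear ramp down to the embryo-to-adult
    viability at the maturation age, then viability times the adult
    survival curve (the lifespan assay follows worms that did mature, so
    its survival is conditional on maturation). Fecundity: adult day d maps
    to calendar age maturation_day + d; m_x is the mean embryos laid per
    female still observed on that day, halved under ``daughters_half``
    scaling.
    """
    if not 0.0 <= viability <= 1.0:
        raise ValueError("viability must lie in [0, 1]")
    if maturation_day < 0:
        raise ValueError("maturation_day must be nonnegative")
    death_days = lifespans.loc[
        ~lifespans.get("censored", pd.Series(False, index=lifespans.index)),
        "day_of_death",
    ].to_numpy(float)
    if death_days.size == 0:
        raise ValueError("no uncensored lifespan records")
    max_sched = max((len(s) for s in schedules), default=0)
    last_age = int(max(death_days.max(), maturation_day + max_sched))
    ages = np.arange(0, last_age + 1)

    l_x = np.ones_like(ages, dtype=float)
    ramp = ages <= maturation_day
    if maturation_day > 0:
        l_x[ramp] = 1.0 + (viability - 1.0) * ages[ramp] / maturation_day
    adult = ages > maturation_day
    l_x[adult] = viability * _survival_to_age(death_days, ages[adult])
    l_x = np.minimum.accumulate(l_x)

    m_x = np.zeros_like(ages, dtype=float)
    if max_sched:
        daily = _mean_daily_fecundity(schedules, max_sched)
        m_x[maturation_day + 1 : maturation_day + 1 + max_sched] = daily
    if config.offspring_scaling == "daughters_half":
        m_x = m_x / 2.0
    return LifeTable(ages=ages, l_x=l_x, m_x=m_x)


def _euler_lotka_f(r: float, ages, lm) -> float:
    return float(np.sum(np.exp(-r * ages) * lm)) - 1.0


def euler_lotka_r(
    table: LifeTable, f_tol: float = 1e-13, max_iter: int = 500
) -> float:
    """Solve the Euler-Lotka equation for r by bracketed bisection.

    The left side is strictly decreasing in r whenever some l_x * m_x > 0
    at a positive age, so the real root is unique. The initial bracket
    [-10, 10] per day is expanded geometrically if needed; bisection runs
    until |f(r)| < ``f_tol``.
    """
    mask = table.l_x * table.m_x > 0
    if not mask.any():
        raise ValueError("no age with positive l_x * m_x; r undefined")
    ages = table.ages[mask].astype(float)
    lm = (table.l_x * table.m_x)[mask]
    r0 = float(lm.sum())
    if r0 <= 0:
        raise ValueError("net reproductive rate must be positive")
    if abs(r0 - 1.0) < 1e-15:
        return 0.0

    lo, hi = -10.0, 10.0
    while _euler_lotka_f(hi, ages, lm) > 0:
        hi *= 2.0
        if hi > 1e6:
            raise RuntimeError("failed to bracket the Euler-Lotka root above")
    while _euler_lotka_f(lo, ages, lm) < 0:
        lo *= 2.0
        if lo < -1e6:
            raise RuntimeError("failed to bracket the Euler-Lotka root below")

    mid = 0.5 * (lo + hi)
    for _ in range(max_iter):
        f_mid = _euler_lotka_f(mid, ages, lm)
        if abs(f_mid) < f_tol:
            return mid
        if f_mid > 0:
            lo = mid
        else:
            hi = mid
        new_mid = 0.5 * (lo + hi)
        if new_mid == mid:  # interval exhausted at float precision
            return mid
        mid = new_mid
    return mid


def bootstrap_r_ci(
    lifespans: pd.DataFrame,
    schedules: list[np.ndarray],
    viability_records: pd.DataFrame,
    config: Config,
    maturation_day: int,
    max_failure_fraction: float = 0.10,
) -> RateEstimate:
    """Point estimate and percentile bootstrap CI for r.

    Resampling units are individuals: worms (lifespans), females with
    their complete daily schedules, and plates (viability). The group
    viability entering each life table is the median plate viability of
    the resample. Resamples whose net reproductive rate is zero are
    recorded as failed; an estimate with more than ``max_failure_fraction``
    failures is flagged.
    """
    rng = np.random.default_rng(config.random_seed)
    v_plates = (
        viability_records["matured"] / viability_records["embryos_initial"]
    ).to_numpy(float)
    death_days = lifespans["day_of_death"].to_numpy(float)
    censored = (
        lifespans["censored"].to_numpy(bool)
        if "censored" in lifespans.columns
        else np.zeros(len(lifespans), bool)
    )
    death_days = death_days[~censored]

    def point_r(deaths, scheds, v_sample):
        viability = float(np.median(v_sample))
        table = build_life_table(
            viability,
            pd.DataFrame({"day_of_death": deaths}),
            scheds,
            config,
            maturation_day,
        )
        if table.net_reproductive_rate <= 0:
            return None
        return euler_lotka_r(table)

    r_hat = point_r(death_days, schedules, v_plates)
    if r_hat is None:
        raise ValueError("point estimate undefined: no reproduction observed")

    reps = []
    n_failed = 0
    n_l, n_s, n_v = len(death_days), len(schedules), len(v_plates)
    for _ in range(config.bootstrap_reps):
        deaths = death_days[rng.integers(0, n_l, n_l)]
        scheds = [schedules[i] for i in rng.integers(0, n_s, n_s)]
        v_sample = v_plates[rng.integers(0, n_v, n_v)]
        r_b = point_r(deaths, scheds, v_sample)
        if r_b is None:
            n_failed += 1
        else:
            reps.append(r_b)
    alpha = 1.0 - config.ci_level
    if reps:
        ci_low, ci_high = np.quantile(reps, [alpha / 2, 1 - alpha / 2])
    else:
        ci_low = ci_high = math.nan
    flagged = n_failed > max_failure_fraction * config.bootstrap_reps
    table = build_life_table(
        float(np.median(v_plates)),
        pd.DataFrame({"day_of_death": death_days}),
        schedules,
        config,
        maturation_day,
    )
    return RateEstimate(
        r=float(r_hat),
        net_reproductive_rate=table.net_reproductive_rate,
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        bootstrap_reps=config.bootstrap_reps,
        seed=config.random_seed,
        n_failed=n_failed,
        flagged=flagged,
    )


def schedules_from_frame(fecundity: pd.DataFrame) -> list[np.ndarray]:
    """Per-female daily-count vectors (adult day 1..max observed) from a
    long-format fecundity table. Days missing inside a female's observed
    range count as zero; days past her last observation are absent."""
    out = []
    for _, sub in fecundity.groupby("female_id", sort=True):
        last = int(sub["day"].max())
        vec = np.zeros(last)
        vec[sub["day"].to_numpy(int) - 1] = sub["count"].to_numpy(float)
        out.append(vec)
    return out
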