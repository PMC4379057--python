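"""Chronological life span from outgrowth kinetics.

An aging culture is sampled at successive age points (days) and each
sample is inoculated into fresh medium; the fewer viable cells remain,
the longer the lag of the resulting outgrowth curve.  With Delta_t_n
the lag shift of the age-n outgrowth relative to the initial age point
and delta the mean doubling time across age points, the survival
percentage is

    S_n = 100 * 2**(-Delta_t_n / delta)

(100% by definition at the initial age point, where Delta_t = 0), and
the survival integral SI — the scalar chronological-life-span summary —
is the trapezoid area under the survival-versus-age curve:

    SI = sum_n  (S_n + S_{n-1}) / 2 * (Age_n - Age_{n-1})
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .growth import GrowthParameters

__all__ = [
    "AgingSeries",
    "SurvivalCurve",
    "lag_shift",
    "mean_doubling_time",
    "survival_percent",
    "survival_integral",
    "survival_curve",
]


@dataclass
class AgingSeries:
    """Aggregated growth parameters of one strain along an aging course.

    ``ages`` are the age points in days, strictly increasing; the first
    one is the reference at which viability is 100% by definition.
    ``params`` holds the replicate-aggregated growth parameters of the
    outgrowth assay at each age point; ``replicate_lags`` optionally
    carries the per-replicate lag times for spread reporting.
    """

    sample: str
    condition: str
    ages: list[float]
    params: list[GrowthParameters]
    replicate_lags: list[np.ndarray] | None = None

    def __post_init__(self):
        if len(self.ages) != len(self.params):
            raise ValueError("ages and params differ in length")
        if len(self.ages) < 2:
            raise ValueError("need >=2 age points")
        if np.any(np.diff(self.ages) <= 0):
            raise ValueError("age points must be strictly increasing")


@dataclass(frozen=True)
class SurvivalCurve:
    """A survival-versus-age curve and its summary statistics.

    ``delta_t`` are the lag shifts in hours (0 at the first age),
    ``delta_mean`` the mean doubling time delta in hours, ``survival``
    the percentages S_n (100 at the first age), ``survival_sd`` their
    replicate SDs when available, and ``survival_integral`` the
    trapezoid area in percent*days.  ``over_100`` flags age points whose
    survival exceeds 100% (negative lag shift; reported, never
    clamped).  ``dropped_ages`` lists age points excluded because their
    growth fit was invalid.
    """

    sample: str
    condition: str
    ages: tuple[float, ...]
    delta_t: tuple[float, ...]
    delta_mean: float
    survival: tuple[float, ...]
    survival_sd: tuple[float, ...] | None
    survival_integral: float
    over_100: tuple[bool, ...]
    dropped_ages: tuple[float, ...] = ()


def lag_shift(initial: GrowthParameters, aged: GrowthParameters) -> float:
    """Delta_t: lag of the aged outgrowth minus the initial lag, hours.

    May be negative (apparent survival above 100%); callers flag but do
    not clamp.  Both fits must be valid with finite lag times computed
    against the same baseline OD.
    """
    for name, p in (("initial", initial), ("aged", aged)):
        if not p.valid or not math.isfinite(p.lag_time):
            raise ValueError(f"{name} age point has no valid lag time")
    return aged.lag_time - initial.lag_time


def mean_doubling_time(series: AgingSeries) -> float:
    """delta: mean of the doubling times over the valid age points."""
    vals = [
        p.doubling_time
        for p in series.params
        if p.valid and math.isfinite(p.doubling_time)
    ]
    if not vals:
        raise ValueError(
            f"no valid age point for {series.sample}_{series.condition}"
        )
    return float(np.mean(vals))


def survival_percent(delta_t: float, delta_mean: float) -> float:
    """S = 100 * 2**(-Delta_t / delta): each doubling time of lag shift
    halves the estimated fraction of viable cells."""
    if delta_mean <= 0:
        raise ValueError("mean doubling time must be positive")
    return 100.0 * 2.0 ** (-delta_t / delta_mean)


def survival_integral(ages, survival) -> float:
    """Trapezoid area under the survival curve, percent*days."""
    ages = np.asarray(ages, dtype=float)
    survival = np.asarray(survival, dtype=float)
    if ages.size != survival.size:
        raise ValueError("ages and survival differ in length")
    if ages.size < 2:
        raise ValueError("need >=2 age points to integrate")
    if np.any(np.diff(ages) <= 0):
        raise ValueError("age points must be strictly increasing")
    steps = np.diff(ages)
    mids = 0.5 * (survival[1:] + survival[:-1])
    return float(np.sum(mids * steps))


def survival_curve(series: AgingSeries) -> SurvivalCurve:
    """Compose lag shifts, delta, survival percentages and SI.

    Age points whose growth fit is invalid are dropped (reported in
    ``dropped_ages``), never interpolated; the initial age point must be
    valid, as all shifts are relative to it.  When per-replicate lag
    times are attached, the replicate spread of S is carried through as
    a standard deviation per age point.
    """
    initial = series.params[0]
    if not initial.valid or not math.isfinite(initial.lag_time):
        raise ValueError(
            "invalid growth fit at the initial age point: no reference lag"
        )
    delta = mean_doubling_time(series)

    kept_ages: list[float] = []
    dts: list[float] = []
    surv: list[float] = []
    sds: list[float] | None = (
        [] if series.replicate_lags is not None else None
    )
    dropped: list[float] = []
    for i, (age, p) in enumerate(zip(series.ages, series.params)):
        if not p.valid or not math.isfinite(p.lag_time):
            dropped.append(age)
            continue
        dt = lag_shift(initial, p)
        kept_ages.append(age)
        dts.append(dt)
        surv.append(survival_percent(dt, delta))
        if sds is not None:
            lags = np.asarray(series.replicate_lags[i], dtype=float)
            rep_dt = lags - initial.lag_time
            rep_s = 100.0 * 2.0 ** (-rep_dt / delta)
            sds.append(float(rep_s.std(ddof=1)) if rep_s.size > 1 else 0.0)
    if len(kept_ages) < 2:
        raise ValueError("fewer than 2 valid age points: cannot integrate")
    si = survival_integral(kept_ages, surv)
    return SurvivalCurve(
        sample=series.sample,
        condition=series.condition,
        ages=tuple(kept_ages),
        delta_t=tuple(dts),
        delta_mean=delta,
        survival=tuple(surv),
        survival_sd=tuple(sds) if sds is not None else None,
        survival_integral=si,
        over_100=tuple(s > 100.0 + 1e-12 for s in surv),
        dropped_ages=tuple(dropped),
    )
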