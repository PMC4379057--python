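"""Growth-parameter extraction from processed OD curves.

A microbial growth curve rarely looks exponential on a large scale, so
the maximal specific growth rate is estimated piecewise: an exponential
OD(0)*exp(mu*T) is least-squares fitted (in OD space) to every sliding
window of omega+1 consecutive points, and mu_max is the largest fitted
mu among the admissible windows.  The lag time is the intersection of
that winning exponential with a baseline OD, the doubling time is
ln 2 / mu_max, and the yield of biomass is the plateau OD found by
scanning for time windows whose linear-regression slope is compatible
with zero.

Four sanity checks guard against the failure modes of noisy plates:
mu_max must be positive, the fitted OD(0) must be positive, the OD at
the time of mu_max must not be below a noise threshold, and the time of
mu_max must not sit at the endpoints of the user-supplied search
interval (no local maximum found) — the last check can be relaxed with
``allow_at_cutoff``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares
from scipy.stats import linregress

from .plate_io import PlateExperiment, TimeSeries

__all__ = [
    "ExtractionConfig",
    "GrowthParameters",
    "ReplicateSummary",
    "windowed_exponential_fit",
    "extract_growth_parameters",
    "extract_yield",
    "aggregate_replicates",
    "fitness_ratio",
]

# warning codes
NEG_MU = "NEG_MU"
NONPOS_OD0 = "NONPOS_OD0"
BELOW_OD_THRESHOLD = "BELOW_OD_THRESHOLD"
AT_CUTOFF = "AT_CUTOFF"
NO_PLATEAU = "NO_PLATEAU"
TOO_FEW_POINTS = "TOO_FEW_POINTS"

#: warnings that invalidate a result (AT_CUTOFF only when not allowed)
_FATAL = {NEG_MU, NONPOS_OD0, BELOW_OD_THRESHOLD, TOO_FEW_POINTS}


@dataclass(frozen=True)
class ExtractionConfig:
    """Tunable parameters of the growth-parameter extraction.

    Attributes
    ----------
    window_omega
        Interval size for the piecewise exponential fit: each window
        spans ``window_omega + 1`` consecutive points.  Default 10
        (about 100 minutes at a typical ~10-minute kinetic cycle).
    min_od_at_mu
        OD threshold below which specific growth rates are not
        determined — at low OD the relative noise level makes local
        fits unreliable.
    mu_time_interval
        Optional (t_lo, t_hi) in hours; the time of mu_max must fall
        inside it.  ``None`` searches the whole curve.
    allow_at_cutoff
        Accept a mu_max whose time sits at an endpoint of the search
        interval (no interior local maximum) as valid, still flagged.
    lag_baseline_od
        Baseline OD whose intersection with the winning exponential
        defines the lag time.  ``None`` (default) uses the median of
        each curve's first 3 processed values — with equal inoculation
        volumes the starting ODs are virtually identical and serve as
        the natural baseline.
    yield_window
        Duration in hours of the plateau-scanning regression window.
    yield_slope_tol
        Absolute slope (OD/hour) below which a regression window counts
        as a plateau ("slope compatible with zero").
    smoothing_half_width
        Centred-moving-average half width applied before fitting; 0
        disables smoothing.  Default 2 (a 5-point window, under an hour
        at typical cycle times): a moving average leaves the rate of an
        exponential stretch unchanged while damping the low-OD noise
        that otherwise inflates the maximum over windows for slow
        growers.
    """

    window_omega: int = 10
    min_od_at_mu: float = 0.03
    mu_time_interval: tuple[float, float] | None = None
    allow_at_cutoff: bool = False
    lag_baseline_od: float | None = None
    yield_window: float = 5.0
    yield_slope_tol: float = 0.005
    smoothing_half_width: int = 2

    def __post_init__(self):
        if self.window_omega < 3:
            raise ValueError("window_omega must be >= 3")
        if self.mu_time_interval is not None:
            t_lo, t_hi = self.mu_time_interval
            if not t_lo < t_hi:
                raise ValueError("mu_time_interval must satisfy t_lo < t_hi")
            object.__setattr__(
                self, "mu_time_interval", (float(t_lo), float(t_hi))
            )
        if self.lag_baseline_od is not None and self.lag_baseline_od <= 0:
            raise ValueError("lag_baseline_od must be positive")
        if self.yield_slope_tol < 0:
            raise ValueError("yield_slope_tol must be >= 0")
        if self.yield_window <= 0:
            raise ValueError("yield_window must be positive")
        if self.smoothing_half_width < 0:
            raise ValueError("smoothing_half_width must be >= 0")

    def to_dict(self) -> dict:
        return {
            "window_omega": self.window_omega,
            "min_od_at_mu": self.min_od_at_mu,
            "mu_time_interval": list(self.mu_time_interval)
            if self.mu_time_interval
            else None,
            "allow_at_cutoff": self.allow_at_cutoff,
            "lag_baseline_od": self.lag_baseline_od,
            "yield_window": self.yield_window,
            "yield_slope_tol": self.yield_slope_tol,
            "smoothing_half_width": self.smoothing_half_width,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ExtractionConfig":
        d = dict(d)
        if d.get("mu_time_interval") is not None:
            d["mu_time_interval"] = tuple(d["mu_time_interval"])
        return cls(**d)


@dataclass(frozen=True, eq=False)
class GrowthParameters:
    """Extracted growth parameters for one well.

    ``valid`` implies mu_max > 0, od0_fit > 0, doubling_time equal to
    ln 2 / mu_max, and a finite lag time.  Equality treats NaN fields
    (parameters that could not be determined) as equal, so saved and
    reloaded results compare field-for-field.
    """

    mu_max: float = math.nan
    t_at_mu_max: float = math.nan
    od0_fit: float = math.nan
    lag_time: float = math.nan
    doubling_time: float = math.nan
    yield_biomass: float = math.nan
    warnings: tuple[str, ...] = ()
    valid: bool = False

    _NUMERIC = (
        "mu_max", "t_at_mu_max", "od0_fit", "lag_time",
        "doubling_time", "yield_biomass",
    )

    def __eq__(self, other):
        if not isinstance(other, GrowthParameters):
            return NotImplemented
        if (self.warnings, self.valid) != (other.warnings, other.valid):
            return False
        for name in self._NUMERIC:
            a, b = getattr(self, name), getattr(other, name)
            if a != b and not (math.isnan(a) and math.isnan(b)):
                return False
        return True

    def __hash__(self):
        return hash((self.warnings, self.valid))

    def to_dict(self) -> dict:
        return {
            "mu_max": self.mu_max,
            "t_at_mu_max": self.t_at_mu_max,
            "od0_fit": self.od0_fit,
            "lag_time": self.lag_time,
            "doubling_time": self.doubling_time,
            "yield_biomass": self.yield_biomass,
            "warnings": list(self.warnings),
            "valid": self.valid,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GrowthParameters":
        d = dict(d)
        d["warnings"] = tuple(d.get("warnings", ()))
        return cls(**d)


@dataclass(frozen=True)
class ReplicateSummary:
    """Mean and unbiased sample variance of one parameter over replicates."""

    sample: str
    condition: str
    parameter: str
    n: int
    mean: float
    variance: float
    well_ids: tuple[str, ...] = ()
    n_excluded: int = 0

    @property
    def empty(self) -> bool:
        return self.n == 0


def windowed_exponential_fit(
    series: TimeSeries, start_index: int, omega: int
) -> tuple[float, float, float]:
    """Fit OD(0)*exp(mu*T) to points start_index..start_index+omega.

    The least squares is taken in OD space (not on log-transformed
    values); a log-linear regression provides the initial guess only.
    T is the absolute time of the plate, so the fitted OD(0) is the
    back-extrapolated OD at time zero.

    Returns
    -------
    (mu, od0, residual)
        mu in 1/hour, od0 in OD units, and the root-mean-square
        residual of the fit.

    Raises
    ------
    ValueError
        If the window extends past the series or contains a
        non-positive value (such windows are skipped by the caller).
    """
    stop = start_index + omega + 1
    if start_index < 0 or stop > len(series):
        raise ValueError("window extends beyond the series")
    t = series.times[start_index:stop]
    y = series.values[start_index:stop]
    if np.any(y <= 0):
        raise ValueError("window contains non-positive OD values")

    # log-linear initial guess: ln y = ln od0 + mu * t
    slope, intercept = np.polyfit(t, np.log(y), 1)
    mu0, od0_0 = float(slope), float(np.exp(intercept))

    # parametrise od0 = exp(a) to keep it positive; exact analytic jacobian
    t_ref = t[0]  # centre time to keep exp() well-scaled during iteration

    def residuals(p):
        mu, log_od0_ref = p
        return np.exp(log_od0_ref + mu * (t - t_ref)) - y

    def jac(p):
        mu, log_od0_ref = p
        f = np.exp(log_od0_ref + mu * (t - t_ref))
        return np.column_stack([(t - t_ref) * f, f])

    p0 = np.array([mu0, np.log(od0_0) + mu0 * t_ref])
    sol = least_squares(residuals, p0, jac=jac, method="lm", xtol=1e-14, ftol=1e-14)
    mu = float(sol.x[0])
    od0 = float(np.exp(sol.x[1] - mu * t_ref))
    rms = float(np.sqrt(np.mean(sol.fun**2)))
    return mu, od0, rms


def _admissible_windows(series: TimeSeries, config: ExtractionConfig):
    """Yield (start, midpoint_index) for windows the fit may consider.

    A window of omega+1 points starting at s is admissible when its
    midpoint time falls inside mu_time_interval, its midpoint OD is not
    below min_od_at_mu, and all its values are positive.  Also returns
    the first and last start positions whose midpoints lie in the time
    interval, for the at-cutoff check.
    """
    omega = config.window_omega
    n = len(series)
    in_interval: list[int] = []
    admissible: list[int] = []
    for s in range(0, n - omega):
        mid = s + omega // 2
        t_mid = series.times[mid]
        if config.mu_time_interval is not None:
            t_lo, t_hi = config.mu_time_interval
            if not (t_lo <= t_mid <= t_hi):
                continue
        in_interval.append(s)
        if series.values[mid] < config.min_od_at_mu:
            continue
        if np.any(series.values[s : s + omega + 1] <= 0):
            continue
        admissible.append(s)
    return admissible, in_interval


def extract_growth_parameters(
    series: TimeSeries, config: ExtractionConfig | None = None
) -> GrowthParameters:
    """Extract mu_max, lag time, doubling time and yield from one curve.

    The series must already be processed (background-corrected and,
    where a calibration is in use, corrected for detector saturation).
    See the module docstring for the procedure and the sanity checks.
    """
    from .preprocess import smooth_series

    if config is None:
        config = ExtractionConfig()
    series = smooth_series(series, config.smoothing_half_width)
    omega = config.window_omega
    warnings: list[str] = []

    if len(series) < omega + 1:
        return GrowthParameters(warnings=(TOO_FEW_POINTS,), valid=False)

    admissible, in_interval = _admissible_windows(series, config)
    if not admissible:
        return GrowthParameters(warnings=(BELOW_OD_THRESHOLD,), valid=False)

    best: tuple[float, float, float, int] | None = None  # mu, od0, rms, start
    for s in admissible:
        try:
            mu, od0, rms = windowed_exponential_fit(series, s, omega)
        except ValueError:
            continue
        # ties on mu broken by earliest midpoint (first-seen wins)
        if best is None or mu > best[0]:
            best = (mu, od0, rms, s)
    if best is None:
        return GrowthParameters(warnings=(BELOW_OD_THRESHOLD,), valid=False)

    mu_max, od0_fit, _, s_best = best
    mid = s_best + omega // 2
    t_at_mu = float(series.times[mid])

    if mu_max <= 0:
        warnings.append(NEG_MU)
    if od0_fit <= 0:
        warnings.append(NONPOS_OD0)
    if series.values[mid] < config.min_od_at_mu:
        warnings.append(BELOW_OD_THRESHOLD)
    at_cutoff = in_interval and s_best in (in_interval[0], in_interval[-1])
    if at_cutoff:
        warnings.append(AT_CUTOFF)

    yield_od, yield_warnings = extract_yield(series, config)
    warnings.extend(yield_warnings)

    fatal = set(warnings) & _FATAL
    if AT_CUTOFF in warnings and not config.allow_at_cutoff:
        fatal.add(AT_CUTOFF)
    valid = not fatal

    lag = math.nan
    doubling = math.nan
    if mu_max > 0 and od0_fit > 0:
        baseline = config.lag_baseline_od
        if baseline is None:
            head = series.values[:3]
            baseline = float(np.median(head))
        if baseline > 0:
            # intersection of the winning exponential with the baseline OD
            lag = math.log(baseline / od0_fit) / mu_max
        doubling = math.log(2.0) / mu_max
    if not math.isfinite(lag):
        valid = False

    return GrowthParameters(
        mu_max=mu_max,
        t_at_mu_max=t_at_mu,
        od0_fit=od0_fit,
        lag_time=lag,
        doubling_time=doubling,
        yield_biomass=yield_od,
        warnings=tuple(warnings),
        valid=valid,
    )


def extract_yield(
    series: TimeSeries, config: ExtractionConfig | None = None
) -> tuple[float, tuple[str, ...]]:
    """Plateau OD: the yield of biomass reached in stationary phase.

    A line is regressed on every window of duration ``yield_window``
    hours; windows whose absolute slope is within ``yield_slope_tol``
    are plateau windows, and the yield is the maximal OD among their
    points.  Returns (nan, (NO_PLATEAU,)) when no window qualifies.
    """
    if config is None:
        config = ExtractionConfig()
    t = series.times
    v = series.values
    n = len(series)
    best = -math.inf
    found = False
    for s in range(n):
        # window = all points within yield_window hours of t[s]
        e = int(np.searchsorted(t, t[s] + config.yield_window, side="right"))
        if e - s < 2:
            continue
        if t[e - 1] - t[s] < config.yield_window * 0.5:
            continue  # trailing stub much shorter than the requested window
        slope = linregress(t[s:e], v[s:e]).slope
        if abs(slope) <= config.yield_slope_tol:
            found = True
            best = max(best, float(v[s:e].max()))
        if e == n:
            break
    if not found:
        return math.nan, (NO_PLATEAU,)
    return best, ()


def aggregate_replicates(
    results: dict[str, GrowthParameters],
    experiment: PlateExperiment,
    parameters: tuple[str, ...] = (
        "mu_max",
        "lag_time",
        "doubling_time",
        "yield_biomass",
    ),
) -> list[ReplicateSummary]:
    """Mean and variance per (sample, condition) over replicate wells.

    Blacklisted and invalid wells are excluded and counted in
    ``n_excluded``.  The variance is the unbiased (n-1) sample variance,
    0 when a single well contributes, and a group with no usable well
    yields an ``n=0`` summary with NaN mean.
    """
    summaries: list[ReplicateSummary] = []
    for (sample, condition), wells in experiment.groups().items():
        usable: list[tuple[str, GrowthParameters]] = []
        excluded = 0
        for w in wells:
            p = results.get(w.well_id)
            if p is None:
                continue
            if w.blacklisted or not p.valid:
                excluded += 1
                continue
            usable.append((w.well_id, p))
        for param in parameters:
            vals = np.array(
                [getattr(p, param) for _, p in usable], dtype=float
            )
            vals = vals[np.isfinite(vals)]
            n = vals.size
            summaries.append(
                ReplicateSummary(
                    sample=sample,
                    condition=condition,
                    parameter=param,
                    n=n,
                    mean=float(vals.mean()) if n else math.nan,
                    variance=float(vals.var(ddof=1)) if n > 1 else (0.0 if n else math.nan),
                    well_ids=tuple(w for w, _ in usable),
                    n_excluded=excluded,
                )
            )
    return summaries


def fitness_ratio(
    summaries: list[ReplicateSummary], reference_condition: str
) -> list[dict]:
    """Growth-rate ratio of every condition to a reference condition.

    For each sample, the ratio of the mean mu_max in a condition to the
    mean mu_max in ``reference_condition`` — the standard fitness
    normalisation for trait-profiling panels.
    """
    mu = [s for s in summaries if s.parameter == "mu_max"]
    reference: dict[str, ReplicateSummary] = {}
    for s in mu:
        if s.condition == reference_condition:
            reference[s.sample] = s
    rows: list[dict] = []
    for s in mu:
        ref = reference.get(s.sample)
        if ref is None or ref.n == 0:
            raise ValueError(
                f"no valid reference condition {reference_condition!r} "
                f"for sample {s.sample!r}"
            )
        if not ref.mean > 0:
            raise ValueError(
                f"reference growth rate is not positive for sample {s.sample!r}"
            )
        rows.append(
            {
                "sample": s.sample,
                "condition": s.condition,
                "reference_condition": reference_condition,
                "ratio": s.mean / ref.mean if s.n else math.nan,
                "n": s.n,
            }
        )
    return rows
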