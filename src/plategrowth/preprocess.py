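"""Background correction, high-density OD calibration and smoothing.

Plate-reader optical densities need two corrections before growth
parameters can be extracted: subtraction of the medium background
(estimated from medium-only wells of the same condition) and a
non-linearity correction at high cell density, where the detector
saturates and the measured OD under-reports the true cell density.

The non-linearity correction is a zero-intercept cubic fitted to serial
dilution data (measured OD against the OD implied by the dilution
factor).  Order of operations: background-correct first, then calibrate,
then (optionally) smooth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .plate_io import PlateExperiment, TimeSeries, WellRecord

__all__ = [
    "CalibrationModel",
    "mean_blank_series",
    "background_correct",
    "fit_high_density_calibration",
    "apply_calibration",
    "smooth_series",
]


@dataclass(frozen=True)
class CalibrationModel:
    """Zero-intercept cubic mapping measured OD to dilution-inferred OD.

    f(x) = c1*x + c2*x**2 + c3*x**3, valid (and checked strictly
    increasing) on [0, valid_max] of measured OD.
    """

    c1: float
    c2: float
    c3: float
    valid_max: float

    def __post_init__(self):
        if self.valid_max <= 0:
            raise ValueError("valid_max must be positive")
        if not self.is_monotone_increasing():
            raise ValueError(
                "calibration polynomial is not strictly increasing on "
                f"[0, {self.valid_max:g}]"
            )

    def __call__(self, x):
        x = np.asarray(x, dtype=float)
        return self.c1 * x + self.c2 * x**2 + self.c3 * x**3

    def derivative(self, x):
        x = np.asarray(x, dtype=float)
        return self.c1 + 2 * self.c2 * x + 3 * self.c3 * x**2

    def is_monotone_increasing(self, n_check: int = 512) -> bool:
        """True when f' > 0 everywhere on [0, valid_max].

        The derivative is a quadratic; positivity is checked at its
        stationary point when that lies inside the range, plus the
        endpoints, with a dense grid as a belt-and-braces check.
        """
        xs = [0.0, self.valid_max]
        if self.c3 != 0:
            x_star = -self.c2 / (3 * self.c3)
            if 0 < x_star < self.valid_max:
                xs.append(x_star)
        if any(self.derivative(x) <= 0 for x in xs):
            return False
        grid = np.linspace(0, self.valid_max, n_check)
        return bool(np.all(self.derivative(grid) > 0))

    def inverse(self, y):
        """Numerically invert f on [0, valid_max] (monotone cubic).

        Raises ``ValueError`` for targets outside [f(0), f(valid_max)].
        """
        y = np.asarray(y, dtype=float)
        y_max = float(self(self.valid_max))
        if np.any(y < -1e-12) or np.any(y > y_max * (1 + 1e-12)):
            raise ValueError(
                f"value outside invertible range [0, {y_max:g}]"
            )
        lo = np.zeros_like(y)
        hi = np.full_like(y, self.valid_max)
        for _ in range(80):  # bisection: monotone, no derivative pitfalls
            mid = 0.5 * (lo + hi)
            too_low = self(mid) < y
            lo = np.where(too_low, mid, lo)
            hi = np.where(too_low, hi, mid)
        return 0.5 * (lo + hi)

    def to_dict(self) -> dict:
        return {
            "c1": self.c1,
            "c2": self.c2,
            "c3": self.c3,
            "valid_max": self.valid_max,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CalibrationModel":
        return cls(
            c1=float(d["c1"]),
            c2=float(d["c2"]),
            c3=float(d["c3"]),
            valid_max=float(d["valid_max"]),
        )


def mean_blank_series(experiment: PlateExperiment, condition: str) -> TimeSeries:
    """Pointwise mean raw OD over the medium-only wells of one condition.

    This is the background reference subtracted from every sample
    replicate grown in the same medium.
    """
    blanks = experiment.blank_wells(condition)
    if not blanks:
        raise ValueError(f"no blank wells for condition {condition}")
    values = np.mean([w.raw.values for w in blanks], axis=0)
    return TimeSeries(experiment.times, values)


def background_correct(experiment: PlateExperiment) -> PlateExperiment:
    """Subtract the per-condition blank mean from every well, pointwise.

    Sample wells are corrected against the blanks of their own
    condition; blank wells are corrected too (so blanks average exactly
    zero at every time point afterwards).  Negative corrected values are
    retained — the growth-fitting sanity checks treat them as unusable,
    but clipping here would bias blanks and early time points.
    """
    blank_means: dict[str, np.ndarray] = {}
    conditions = {w.condition for w in experiment.wells}
    for cond in experiment.conditions():
        blank_means[cond] = mean_blank_series(experiment, cond).values
    for cond in conditions - set(blank_means):
        # blank-only conditions: still centre them on zero
        blank_means[cond] = mean_blank_series(experiment, cond).values
    for w in experiment.wells:
        w.processed = w.raw.with_values(w.raw.values - blank_means[w.condition])
    return experiment


def fit_high_density_calibration(
    measured, calculated
) -> CalibrationModel:
    """Least-squares fit of the zero-intercept cubic to dilution data.

    Parameters
    ----------
    measured
        ODs read in the plate reader for the serial dilutions.
    calculated
        ODs inferred from the dilution factors (the accurate values).

    The polynomial is constrained through the origin (no constant term)
    and must come out strictly increasing on [0, max(measured)];
    otherwise the dilution series does not constrain a usable
    correction and an error is raised.
    """
    x = np.asarray(measured, dtype=float)
    y = np.asarray(calculated, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("measured and calculated must be 1-d and equal length")
    if x.size < 4:
        raise ValueError("need at least 4 dilution pairs to fit a cubic")
    if np.any(x < 0):
        raise ValueError("measured ODs must be non-negative")
    design = np.column_stack([x, x**2, x**3])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    c1, c2, c3 = (float(c) for c in coef)
    try:
        return CalibrationModel(c1=c1, c2=c2, c3=c3, valid_max=float(x.max()))
    except ValueError:
        raise ValueError(
            "fitted calibration is not monotone on the measured range; "
            "collect more or better dilution data"
        ) from None


def apply_calibration(
    series: TimeSeries, model: CalibrationModel
) -> tuple[TimeSeries, bool]:
    """Correct a background-corrected series for detector saturation.

    Each value x is replaced by f(max(x, 0)) — negative
    background-corrected values map to f(0) = 0.  Values above the
    calibrated range are still corrected (the cubic extrapolates) but
    reported via the returned out-of-range flag.
    """
    x = np.maximum(series.values, 0.0)
    out_of_range = bool(np.any(x > model.valid_max))
    return series.with_values(np.asarray(model(x), dtype=float)), out_of_range


def smooth_series(series: TimeSeries, half_width: int) -> TimeSeries:
    """Centred moving average of window 2*half_width+1, shrinking at edges.

    ``half_width=0`` is the identity.  Near the edges the mean is taken
    over whatever points fall within half_width of the index, so the
    window shrinks rather than padding.
    """
    if half_width < 0:
        raise ValueError("half_width must be >= 0")
    if half_width == 0:
        return series
    v = series.values
    n = v.size
    out = np.empty(n)
    for i in range(n):
        lo = max(0, i - half_width)
        hi = min(n, i + half_width + 1)
        out[i] = v[lo:hi].mean()
    return series.with_values(out)
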