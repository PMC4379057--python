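"""Synthetic plate experiments with known ground truth.

Wells are generated from a shifted logistic,

    OD(t) = N0                                       for t <  lag_offset
    OD(t) = K / (1 + ((K - N0)/N0) * exp(-r (t - t0)))  for t >= lag_offset

(with t0 = lag_offset), which gives realistic lag, exponential and
plateau phases so that every extractor is exercised.  Observations add
the medium background, a slow linear drift (an evaporation proxy),
optional detector saturation (the inverse of a calibration cubic) and
noise OD*(1+e1) + e2 with independent zero-mean Gaussian e1, e2.

Aging experiments are generated by inverting the outgrowth logic: a
culture with viable fraction f starts its regrowth log2(1/f) doubling
times later, so the well's lag offset at an age point is
lag0 + delta_true * log2(1/f).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .plate_io import TimeSeries
from .preprocess import CalibrationModel

__all__ = [
    "WellSpec",
    "SimSpec",
    "simulate_growth_curve",
    "distort_high_density",
    "simulate_plate",
    "simulate_aging_experiment",
    "logistic_od",
]


@dataclass(frozen=True)
class WellSpec:
    """Ground-truth growth model for one well.

    r is the logistic rate (1/h), n0 the inoculation OD, k the carrying
    capacity (plateau OD) and lag_offset the time (h) at which growth
    starts.
    """

    r: float = 0.5
    n0: float = 0.01
    k: float = 1.2
    lag_offset: float = 1.0

    def __post_init__(self):
        if self.r <= 0:
            raise ValueError("r must be positive")
        if not 0 < self.n0 < self.k:
            raise ValueError("need 0 < n0 < k")
        if self.lag_offset < 0:
            raise ValueError("lag_offset must be >= 0")


@dataclass(frozen=True)
class SimSpec:
    """Plate-level simulation conditions.

    Defaults emulate a 48-hour kinetic run at a ~10-minute cycle with
    2% multiplicative and 0.002 OD additive measurement noise, a medium
    background of 0.08 OD and 0.01 OD of linear blank drift over the
    whole run.
    """

    cycle_minutes: float = 10.0
    total_hours: float = 48.0
    noise_multiplicative: float = 0.02
    noise_additive: float = 0.002
    medium_od: float = 0.08
    blank_drift: float = 0.01
    calibration: CalibrationModel | None = None
    seed: int = 0

    def __post_init__(self):
        if self.cycle_minutes <= 0:
            raise ValueError("cycle_minutes must be positive")
        if self.total_hours <= 0:
            raise ValueError("total_hours must be positive")

    @property
    def times(self) -> np.ndarray:
        n = int(self.total_hours * 60.0 / self.cycle_minutes) + 1
        return np.arange(n) * (self.cycle_minutes / 60.0)


def logistic_od(t, well: WellSpec) -> np.ndarray:
    """Noise-free shifted-logistic OD at times t (hours)."""
    t = np.asarray(t, dtype=float)
    tau = t - well.lag_offset
    od = well.k / (
        1.0 + ((well.k - well.n0) / well.n0) * np.exp(-well.r * np.clip(tau, 0, None))
    )
    return np.where(tau < 0, well.n0, od)


def _truth_record(well: WellSpec, baseline: float | None = None) -> dict:
    """Analytic growth parameters of the continuous curve.

    The maximal specific growth rate of the logistic is attained as
    growth starts, mu = r (1 - n0/k); the analytic lag is where the
    back-extrapolated maximal exponential through (lag_offset, n0)
    crosses the baseline OD (the starting OD n0 by default, for which
    the lag equals lag_offset exactly).
    """
    mu = well.r * (1.0 - well.n0 / well.k)
    b = well.n0 if baseline is None else baseline
    lag = well.lag_offset + math.log(b / well.n0) / mu
    return {
        "r": well.r,
        "n0": well.n0,
        "k": well.k,
        "lag_offset": well.lag_offset,
        "mu_true": mu,
        "lag_true": lag,
        "doubling_true": math.log(2.0) / mu,
    }


def simulate_growth_curve(
    well: WellSpec,
    sim: SimSpec | None = None,
    seed: int | np.random.Generator | None = None,
    baseline: float | None = None,
) -> tuple[TimeSeries, dict]:
    """One well's noisy OD trajectory plus its ground-truth record.

    The returned series is the *cell* OD (no medium background): what a
    perfect background correction would recover.  Noise sds of zero
    give the analytic logistic exactly; the same seed gives the same
    series.
    """
    sim = sim or SimSpec()
    rng = _rng(seed if seed is not None else sim.seed)
    t = sim.times
    od = logistic_od(t, well)
    od = _add_noise(od, sim, rng)
    return TimeSeries(t, od), _truth_record(well, baseline)


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _add_noise(od: np.ndarray, sim: SimSpec, rng: np.random.Generator) -> np.ndarray:
    if sim.noise_multiplicative == 0 and sim.noise_additive == 0:
        return od
    e1 = rng.normal(0.0, sim.noise_multiplicative, od.shape)
    e2 = rng.normal(0.0, sim.noise_additive, od.shape)
    return od * (1.0 + e1) + e2


def distort_high_density(
    series: TimeSeries, model: CalibrationModel
) -> TimeSeries:
    """Apply the detector's saturation: the inverse of the calibration.

    Produces what the plate reader would report for a given true cell
    density, so that ``apply_calibration`` recovers the input.  Values
    outside the invertible range [0, f(valid_max)] raise ``ValueError``.
    """
    return series.with_values(np.asarray(model.inverse(series.values), dtype=float))


def simulate_plate(
    layout: list[tuple[str, str, str, WellSpec | None]],
    sim: SimSpec | None = None,
    seed: int | None = None,
    blank_label: str = "blank",
) -> tuple[str, pd.DataFrame]:
    """Write a matrix-dialect export plus a ground-truth table.

    ``layout`` rows are (well_id, sample, condition, WellSpec); rows
    whose sample equals ``blank_label`` are medium-only wells (their
    WellSpec is ignored and may be None).  Every condition present
    among sample wells must also have at least one blank well.  The
    truth table has one row per non-blank well.
    """
    sim = sim or SimSpec()
    rng = _rng(seed if seed is not None else sim.seed)
    t = sim.times
    drift = sim.blank_drift * (t / t[-1]) if len(t) > 1 else np.zeros_like(t)

    blank_conditions = {c for _, s, c, _ in layout if s == blank_label}
    sample_conditions = {c for _, s, c, _ in layout if s != blank_label}
    missing = sorted(sample_conditions - blank_conditions)
    if missing:
        raise ValueError(
            f"layout has no blank wells for condition(s): {', '.join(missing)}"
        )

    columns: list[np.ndarray] = []
    well_ids: list[str] = []
    labels: list[str] = []
    truth_rows: list[dict] = []
    for well_id, sample, condition, spec in layout:
        if sample == blank_label:
            true = np.zeros_like(t)
        else:
            if spec is None:
                raise ValueError(f"well {well_id}: sample well without a WellSpec")
            true = logistic_od(t, spec)
            truth_rows.append(
                {"well": well_id, "sample": sample, "condition": condition}
                | _truth_record(spec)
            )
        total = true + sim.medium_od + drift
        if sim.calibration is not None:
            total = np.asarray(sim.calibration.inverse(total), dtype=float)
        columns.append(_add_noise(total, sim, rng))
        well_ids.append(well_id)
        labels.append(f"{sample}_{condition}")

    lines = ["Instrument\tsimulated-reader", f"Cycles\t{len(t)}"]
    lines.append("Well\t" + "\t".join(well_ids))
    lines.append("Time[s]\t" + "\t".join(labels))
    for i, ti in enumerate(t):
        row = [repr(float(ti) * 3600.0)] + [repr(float(col[i])) for col in columns]
        lines.append("\t".join(row))
    export = "\n".join(lines) + "\n"
    return export, pd.DataFrame(truth_rows)


def simulate_aging_experiment(
    viability: list[tuple[float, float]],
    well: WellSpec | None = None,
    sim: SimSpec | None = None,
    seed: int | None = None,
    n_replicates: int = 3,
    n_blanks: int = 2,
    sample: str = "FY4",
    condition: str = "SC",
) -> tuple[dict[float, str], dict]:
    """Outgrowth exports for an aging course with requested viabilities.

    ``viability`` lists (age_days, viable_fraction) with fractions in
    (0, 1] and the first fraction equal to 1 (the reference age point).
    Each age point gets one matrix export whose sample wells carry a
    lag offset of lag0 + delta_true * log2(1/fraction), so the lag
    shift encodes the requested viability exactly in the noise-free
    limit.

    Returns the exports keyed by age and a truth record with the
    fractions, the implied survival percentages and their trapezoid
    survival integral.
    """
    well = well or WellSpec()
    sim = sim or SimSpec()
    if not viability or len(viability) < 2:
        raise ValueError("need >=2 age points")
    ages = [a for a, _ in viability]
    fractions = [f for _, f in viability]
    if any(f <= 0 or f > 1 for f in fractions):
        raise ValueError("viable fractions must lie in (0, 1]")
    if fractions[0] != 1:
        raise ValueError("the first (reference) fraction must be 1")
    if any(b <= a for a, b in zip(ages, ages[1:])):
        raise ValueError("age points must be strictly increasing")

    truth = _truth_record(well)
    delta_true = truth["doubling_true"]
    master = _rng(seed if seed is not None else sim.seed)
    exports: dict[float, str] = {}
    for age, fraction in viability:
        shift = delta_true * math.log2(1.0 / fraction)
        aged = replace(well, lag_offset=well.lag_offset + shift)
        layout: list[tuple[str, str, str, WellSpec | None]] = [
            (f"A{j + 1}", sample, condition, aged) for j in range(n_replicates)
        ]
        layout += [
            (f"B{j + 1}", "blank", condition, None) for j in range(n_blanks)
        ]
        exports[age], _ = simulate_plate(
            layout, sim=sim, seed=int(master.integers(2**31))
        )
    survival = [100.0 * f for f in fractions]
    from .cls import survival_integral

    truth_out = {
        "ages": ages,
        "fractions": fractions,
        "survival": survival,
        "delta_true": delta_true,
        "lag_shifts": [delta_true * math.log2(1.0 / f) for f in fractions],
        "si_true": survival_integral(ages, survival),
        **truth,
    }
    return exports, truth_out
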