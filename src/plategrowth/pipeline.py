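"""Glue: run the preprocessing + extraction chain over whole plates.

The order of operations is fixed: background-correct against the
per-condition blanks first, then correct for detector saturation (when
a calibration is supplied), then smooth/fit.  These functions are what
the command-line layer and the batch scripts call.
"""

from __future__ import annotations

import math

import numpy as np

from .cls import AgingSeries
from .growth import (
    ExtractionConfig,
    GrowthParameters,
    extract_growth_parameters,
)
from .plate_io import PlateExperiment
from .preprocess import CalibrationModel, apply_calibration, background_correct

__all__ = [
    "process_experiment",
    "extract_plate",
    "analyze_aging",
    "aging_series_from_plates",
    "AGING_CONFIG",
]

#: Default lag-extraction settings for aging (outgrowth) courses: a
#: longer fitting window and heavier smoothing than the plain growth
#: defaults.  Survival depends only on lag *shifts* between age points,
#: so the curve-shape biases these settings introduce cancel, while
#: their noise damping directly steadies the shift estimates.
AGING_CONFIG = ExtractionConfig(window_omega=16, smoothing_half_width=8)


def process_experiment(
    experiment: PlateExperiment,
    calibration: CalibrationModel | None = None,
) -> PlateExperiment:
    """Background-correct every well, then calibrate the sample wells."""
    background_correct(experiment)
    if calibration is not None:
        for w in experiment.wells:
            w.processed, _ = apply_calibration(w.processed, calibration)
    return experiment


def extract_plate(
    experiment: PlateExperiment,
    config: ExtractionConfig | None = None,
    calibration: CalibrationModel | None = None,
    blacklist: set[str] | None = None,
) -> dict[str, GrowthParameters]:
    """Process a plate and extract growth parameters per non-blank well."""
    config = config or ExtractionConfig()
    process_experiment(experiment, calibration)
    if blacklist:
        for w in experiment.wells:
            if w.well_id in blacklist:
                w.blacklisted = True
    results: dict[str, GrowthParameters] = {}
    for w in experiment.sample_wells():
        results[w.well_id] = extract_growth_parameters(w.processed, config)
    return results


def analyze_aging(
    per_age: list[tuple[float, PlateExperiment]],
    config: ExtractionConfig | None = None,
    calibration: CalibrationModel | None = None,
    blacklist: set[str] | None = None,
) -> list[tuple[float, PlateExperiment, dict[str, GrowthParameters]]]:
    """Extract growth parameters at every age point of an aging course.

    ``config`` defaults to :data:`AGING_CONFIG` — a longer fitting
    window and heavier smoothing than the plain growth defaults: the
    survival computation consumes lag *shifts* between age points, so
    the curve-shape bias these settings introduce cancels between ages,
    while their noise damping steadies the shifts.

    Lag-time shifts between age points are only meaningful when every
    lag is computed against the *same* baseline OD, so when the config
    leaves ``lag_baseline_od`` unset, a common baseline is derived once
    from the initial (first-age) plate and applied to all age points.
    Per-curve baselines would inject each well's starting-OD noise
    straight into the survival percentages.

    The common baseline is placed where the maximal rate is actually
    measured: the median, over the sample wells of *all* age points, of
    the OD at the time of mu_max (a first extraction pass collects it,
    a second one computes the lags against it).  The lag-shift Delta_t
    does not depend on where a common baseline sits (outgrowth curves
    are time-shifted copies of one another), but the error of an
    individual lag does: extrapolating a fitted exponential to a
    baseline a factor F away from the fitted window multiplies the
    growth-rate noise by ln F.  Anchoring the baseline at the winning
    windows' own OD makes that lever arm near zero at every age point,
    and pooling the whole course makes the anchor itself quiet.  When
    no well yields a usable fit the starting OD is used as a fallback.
    """
    from dataclasses import replace as _replace

    from .preprocess import smooth_series

    config = config or AGING_CONFIG
    if not per_age:
        raise ValueError("no age points")
    per_age = sorted(per_age, key=lambda item: item[0])
    for _, exp in per_age:
        process_experiment(exp, calibration)
        if blacklist:
            for w in exp.wells:
                if w.well_id in blacklist:
                    w.blacklisted = True
    if config.lag_baseline_od is None:
        ods_at_mu, heads = [], []
        for _, exp in per_age:
            for w in exp.sample_wells():
                if w.blacklisted:
                    continue
                smoothed = smooth_series(w.processed, config.smoothing_half_width)
                heads.append(float(np.median(smoothed.values[:3])))
                p = extract_growth_parameters(w.processed, config)
                if p.mu_max > 0 and math.isfinite(p.t_at_mu_max):
                    idx = int(np.searchsorted(smoothed.times, p.t_at_mu_max))
                    idx = min(idx, len(smoothed) - 1)
                    od_mid = float(smoothed.values[idx])
                    if od_mid > 0:
                        ods_at_mu.append(od_mid)
        if ods_at_mu:
            baseline = float(np.median(ods_at_mu))
        else:
            baseline = float(np.median(heads)) if heads else math.nan
        if not (baseline > 0):
            raise ValueError(
                "cannot derive a positive common lag baseline from the "
                "aging course; set lag_baseline_od explicitly"
            )
        config = _replace(config, lag_baseline_od=baseline)
    out = []
    for age, exp in per_age:
        results = {
            w.well_id: extract_growth_parameters(w.processed, config)
            for w in exp.sample_wells()
        }
        out.append((age, exp, results))
    return out


def aging_series_from_plates(
    per_age: list[tuple[float, PlateExperiment, dict[str, GrowthParameters]]],
    sample: str,
    condition: str,
) -> AgingSeries:
    """Build one strain's :class:`AgingSeries` from analysed age points.

    For each age point the replicate wells of (sample, condition) are
    aggregated: the age point's lag and doubling time are the means over
    valid, non-blacklisted wells, and the per-replicate lags are kept
    for spread reporting.  An age point with no valid well is carried as
    an invalid entry (dropped later by :func:`survival_curve`).
    """
    ages: list[float] = []
    params: list[GrowthParameters] = []
    rep_lags: list[np.ndarray] = []
    for age, experiment, results in per_age:
        wells = experiment.groups().get((sample, condition), [])
        lags, doublings, mus = [], [], []
        for w in wells:
            p = results.get(w.well_id)
            if p is None or w.blacklisted or not p.valid:
                continue
            if math.isfinite(p.lag_time) and math.isfinite(p.doubling_time):
                lags.append(p.lag_time)
                doublings.append(p.doubling_time)
                mus.append(p.mu_max)
        ages.append(age)
        if lags:
            params.append(
                GrowthParameters(
                    mu_max=float(np.mean(mus)),
                    od0_fit=math.nan,
                    t_at_mu_max=math.nan,
                    lag_time=float(np.mean(lags)),
                    doubling_time=float(np.mean(doublings)),
                    valid=True,
                )
            )
        else:
            params.append(GrowthParameters(valid=False))
        rep_lags.append(np.asarray(lags, dtype=float))
    return AgingSeries(
        sample=sample,
        condition=condition,
        ages=ages,
        params=params,
        replicate_lags=rep_lags,
    )
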