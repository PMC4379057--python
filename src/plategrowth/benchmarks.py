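"""Synthetic-recovery benchmarks.

Self-contained studies that generate plates with known ground truth,
push them through the full pipeline and report recovery errors.  They
double as regression guards for the extraction defaults and as the
quantities reported by ``scripts/acceptance.py``.
"""

from __future__ import annotations

import io

import numpy as np
import pandas as pd

from .cls import survival_curve
from .growth import extract_growth_parameters
from .pipeline import aging_series_from_plates, analyze_aging
from .plate_io import parse_plate_export
from .simulate import SimSpec, WellSpec, simulate_aging_experiment, simulate_growth_curve

__all__ = ["growth_recovery_study", "cls_recovery_study", "DEFAULT_VIABILITY"]

#: viability course used by the end-to-end aging benchmark
DEFAULT_VIABILITY = [
    (2, 1.00),
    (5, 0.60),
    (7, 0.30),
    (10, 0.10),
    (12, 0.03),
    (14, 0.01),
]


def growth_recovery_study(
    seed: int,
    n_wells: int = 96,
    noisy: bool = False,
    cycle_minutes: float = 15.0,
) -> pd.DataFrame:
    """Extraction errors over a plate of simulated logistic wells.

    Wells use the generator defaults (N0 = 0.01, K = 1.2) with rates
    drawn uniformly from 0.2-0.7 1/h and lag offsets from 0.5-3 h; the
    noisy variant applies the default measurement noise.  Returns one
    row per well with relative rate and yield errors and the absolute
    lag error against the analytic continuous-curve lag.
    """
    rng = np.random.default_rng(seed)
    sim = SimSpec(
        cycle_minutes=cycle_minutes,
        noise_multiplicative=0.02 if noisy else 0.0,
        noise_additive=0.002 if noisy else 0.0,
    )
    rows = []
    for _ in range(n_wells):
        well = WellSpec(
            r=float(rng.uniform(0.2, 0.7)),
            lag_offset=float(rng.uniform(0.5, 3.0)),
        )
        series, truth = simulate_growth_curve(
            well, sim, seed=int(rng.integers(2**31))
        )
        p = extract_growth_parameters(series)
        rows.append(
            {
                "r": well.r,
                "mu_max": p.mu_max,
                "mu_rel_err": abs(p.mu_max - well.r) / well.r,
                "lag_abs_err": abs(p.lag_time - truth["lag_true"]),
                "yield_rel_err": abs(p.yield_biomass - well.k) / well.k,
                "valid": p.valid,
            }
        )
    return pd.DataFrame(rows)


def cls_recovery_study(
    seed: int,
    n_seeds: int = 20,
    viability=None,
) -> pd.DataFrame:
    """End-to-end survival recovery over repeated aging experiments.

    Each repetition simulates a full outgrowth course (three replicate
    wells and blanks per age point, default noise and kinetic cycle),
    re-parses the exports, runs the aging pipeline and compares the
    recovered survival percentages and survival integral with the
    requested viabilities.  Returns one row per repetition.
    """
    viability = viability or DEFAULT_VIABILITY
    rng = np.random.default_rng(seed)
    rows = []
    for _ in range(n_seeds):
        exports, truth = simulate_aging_experiment(
            viability, seed=int(rng.integers(2**31))
        )
        plates = [
            (age, parse_plate_export(io.StringIO(text), dialect="matrix"))
            for age, text in exports.items()
        ]
        per_age = analyze_aging(plates)
        series = aging_series_from_plates(per_age, "FY4", "SC")
        curve = survival_curve(series)
        s_err = float(
            np.max(np.abs(np.asarray(curve.survival) - np.asarray(truth["survival"])))
        )
        si_rel = abs(curve.survival_integral - truth["si_true"]) / truth["si_true"]
        rows.append(
            {
                "initial_survival": curve.survival[0],
                "max_survival_err": s_err,
                "si_rel_err": float(si_rel),
                "si": curve.survival_integral,
                "si_true": truth["si_true"],
            }
        )
    return pd.DataFrame(rows)
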