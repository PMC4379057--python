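import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from plategrowth import CalibrationModel, SimSpec, TimeSeries, WellSpec  # noqa: E402

#: coefficients of the saturation-correction cubic used throughout the tests
PRINTED_CUBIC = (4.7757, -0.445, 1.4078)


@pytest.fixture
def printed_model() -> CalibrationModel:
    """The dilution-calibrated saturation cubic, valid to 1.4 measured OD."""
    c1, c2, c3 = PRINTED_CUBIC
    return CalibrationModel(c1=c1, c2=c2, c3=c3, valid_max=1.4)


@pytest.fixture
def noiseless_sim() -> SimSpec:
    return SimSpec(noise_multiplicative=0.0, noise_additive=0.0, cycle_minutes=15.0)


@pytest.fixture
def exp_series() -> TimeSeries:
    """Noise-free exponential 0.02 * exp(0.4 t) on a 15-min grid."""
    t = np.arange(0, 12.01, 0.25)
    return TimeSeries(t, 0.02 * np.exp(0.4 * t))


@pytest.fixture
def logistic_series(noiseless_sim):
    """Noise-free default logistic well (r=0.5, N0=0.01, K=1.2, lag 1 h)."""
    from plategrowth import simulate_growth_curve

    return simulate_growth_curve(WellSpec(), noiseless_sim)


MATRIX_EXPORT = (
    "Instrument\tsimulated-reader\n"
    "Start\t2024-01-01\n"
    "Well\tA1\tA2\tB1\tB2\n"
    "Time[s]\tFY4_YPD\tFY4_YPD\tW303_YPD\tblank_YPD\n"
    "0\t0.10\t0.11\t0.12\t0.08\n"
    "600\t0.15\t0.16\t0.17\t0.08\n"
    "1200\t0.22\t0.23\t0.25\t0.09\n"
)

LONG_EXPORT = (
    "well,sample,condition,time_s,od\n"
    "A1,FY4,YPD,0,0.10\n"
    "A1,FY4,YPD,600,0.15\n"
    "A1,FY4,YPD,1200,0.22\n"
    "B2,blank,YPD,0,0.08\n"
    "B2,blank,YPD,600,0.08\n"
    "B2,blank,YPD,1200,0.09\n"
)


@pytest.fixture
def matrix_export() -> str:
    return MATRIX_EXPORT


@pytest.fixture
def long_export() -> str:
    return LONG_EXPORT
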