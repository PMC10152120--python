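import numpy as np
import pytest

from stpdosim.tac import curve_from_arrays

LN2 = np.log(2.0)


def monoexp(A0, half_life, t):
    return A0 * 2.0 ** (-np.asarray(t, dtype=float) / half_life)


def exact_curve(A0=100.0, half_life=32.5, times=(24.0, 48.0, 72.0),
                patient="P1", cycle=2, voi_id="kidney_left",
                voi_type="kidney_left"):
    """Noiseless samples on an exact monoexponential curve."""
    times = np.asarray(times, dtype=float)
    return curve_from_arrays(patient, cycle, voi_id, voi_type,
                             times, monoexp(A0, half_life, times))


@pytest.fixture
def kidney_curve():
    return exact_curve()


def tia_numeric_oracle(A0, half_life, n_grid=200_000, horizon_halflives=20.0):
    """Independent TIA oracle: trapezoid on [0, 20*T] plus analytic tail."""
    T = half_life
    t = np.linspace(0.0, horizon_halflives * T, n_grid)
    body = np.trapezoid(monoexp(A0, T, t), t)
    # analytic tail of A0*2^(-t/T) from the horizon to infinity
    tail = A0 * 2.0 ** (-horizon_halflives) * T / LN2
    return body + tail
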