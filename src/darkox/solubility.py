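"""Dissolved-oxygen solubility (Benson–Krause) and percent-saturation
conversion, as used for optical DO sensor calibration.

The closed form is the Benson–Krause equilibrium fit adopted by Standard
Methods / USGS: at 10 degC, zero salinity and 760 mmHg it gives
11.288 mg L-1. Pressure enters as simple Henry-law proportionality to the
chosen reference of 760 mmHg (no vapour-pressure correction), which is the
appropriate level of detail for field-sonde conversions.
"""

from __future__ import annotations

import numpy as np

STANDARD_PRESSURE_MMHG = 760.0


def o2_saturation(
    temperature: float,
    salinity: float = 0.0,
    pressure: float = STANDARD_PRESSURE_MMHG,
):
    """Equilibrium DO concentration, mg L-1.

    Parameters
    ----------
    temperature : degC, valid -2..40.
    salinity : practical salinity (~per mille), >= 0.
    pressure : total pressure, mmHg, > 0.
    """
    temperature = np.asarray(temperature, dtype=float)
    if np.any(temperature < -2.0) or np.any(temperature > 40.0):
        raise ValueError("temperature outside the -2..40 degC validity range")
    if np.any(np.asarray(salinity) < 0):
        raise ValueError("salinity must be >= 0")
    if np.any(np.asarray(pressure) <= 0):
        raise ValueError("pressure must be > 0")
    t_k = temperature + 273.15
    ln_c = (
        -139.34411
        + 1.575701e5 / t_k
        - 6.642308e7 / t_k**2
        + 1.243800e10 / t_k**3
        - 8.621949e11 / t_k**4
    )
    ln_c = ln_c - np.asarray(salinity, dtype=float) * (
        0.017674 - 10.754 / t_k + 2140.7 / t_k**2
    )
    return np.exp(ln_c) * np.asarray(pressure, dtype=float) / STANDARD_PRESSURE_MMHG


def percent_sat_to_mgL(
    percent: float,
    temperature: float,
    salinity: float = 0.0,
    pressure: float = STANDARD_PRESSURE_MMHG,
):
    """Convert a percent-saturation sonde reading to mg L-1."""
    percent = np.asarray(percent, dtype=float)
    if np.any(percent < 0):
        raise ValueError("percent saturation must be >= 0")
    return percent / 100.0 * o2_saturation(temperature, salinity, pressure)
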