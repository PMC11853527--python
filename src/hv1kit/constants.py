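"""Physical constants shared by every module.

Temperature enters every thermodynamic expression through RT; it is set in
exactly one place (``DEFAULT_TEMPERATURE_K``) so that a single override
propagates consistently. 294 K is the midpoint of the 19-22 degC recording
range typical for whole-cell proton-current work.
"""

import numpy as np

#: Gas constant in kcal mol^-1 K^-1 (used for perturbation energies).
R_KCAL = 1.9872e-3

#: Gas constant in J mol^-1 K^-1.
R_J = 8.314462618

#: Faraday constant in C mol^-1.
FARADAY = 96485.33212

#: Default absolute temperature (K).
DEFAULT_TEMPERATURE_K = 294.0

LN10 = float(np.log(10.0))


def rt_over_f_mv(T: float = DEFAULT_TEMPERATURE_K) -> float:
    """RT/F in millivolts (25.33 mV at 294 K): the e-fold voltage scale."""
    return 1000.0 * R_J * T / FARADAY


def nernst_slope_mv(T: float = DEFAULT_TEMPERATURE_K) -> float:
    """ln(10)*RT/F in millivolts (58.3 mV at 294 K): mV per pH unit."""
    return LN10 * rt_over_f_mv(T)
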