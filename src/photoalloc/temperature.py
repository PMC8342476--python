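"""Peaked Arrhenius temperature response.

Every temperature-dependent kinetic quantity follows the same two-factor
form: an Arrhenius acceleration with activation energy E, damped by a
thermal-deactivation term controlled by the deactivation energy H and an
entropy factor S.  An infinite H disables deactivation, leaving a plain
Arrhenius curve.  At 25 degC both factors cancel and the function returns
the reference value k25 exactly.
"""

from __future__ import annotations

import math

from .errors import ValidationError
from .params import (
    ArrheniusEntry,
    R_GAS,
    T25_K,
    TEMPERATURE_QUANTITIES,
    default_temperature_params,
)

_EXP_CLAMP = 700.0  # largest exponent fed to math.exp


def _safe_exp(x: float) -> float:
    return math.exp(min(x, _EXP_CLAMP))


def arrhenius_extended(T_K: float, entry: ArrheniusEntry) -> float:
    """Evaluate the peaked Arrhenius response at an absolute temperature.

    ``f(T) = k25 * exp[E (T - 298.15) / (298.15 R T)]
    * [1 + exp((298.15 S - H)/(298.15 R))] / [1 + exp((T S - H)/(T R))]``
    """
    if T_K <= 0:
        raise ValidationError("absolute temperature must be positive")
    arr = _safe_exp(entry.E * (T_K - T25_K) / (T25_K * R_GAS * T_K))
    if math.isinf(entry.H):
        peak = 1.0
    else:
        num = 1.0 + _safe_exp((T25_K * entry.S - entry.H) / (T25_K * R_GAS))
        den = 1.0 + _safe_exp((T_K * entry.S - entry.H) / (T_K * R_GAS))
        peak = num / den
    return entry.k25 * arr * peak


def temperature_factors(
    T_celsius: float, tparams: dict | None = None
) -> dict:
    """Scaling factor relative to 25 degC for each tracked quantity.

    Quantities absent from ``tparams`` get a factor of 1 (pass through
    unchanged).
    """
    tparams = default_temperature_params() if tparams is None else tparams
    t_k = T_celsius + 273.15
    factors = {}
    for name in TEMPERATURE_QUANTITIES:
        entry = tparams.get(name)
        if entry is None:
            factors[name] = 1.0
        else:
            factors[name] = arrhenius_extended(t_k, entry) / entry.k25
    return factors


def apply_temperature(
    values: dict, T_celsius: float, tparams: dict | None = None
) -> dict:
    """Scale each 25-degC quantity in ``values`` by its own response curve.

    ``values`` maps quantity names (a subset of the tracked quantities plus
    arbitrary extras, which pass through unchanged) to their 25-degC values.
    """
    factors = temperature_factors(T_celsius, tparams)
    return {k: v * factors.get(k, 1.0) for k, v in values.items()}
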