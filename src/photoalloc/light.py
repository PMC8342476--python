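"""Irradiance to electron transport, and electron transport to ATP/NADPH.

Absorbed light is split between the linear chain (where it is shared
equally by PSI and PSII, hence the factor 0.5) and the cyclic chain.  Each
chain converts its absorbed irradiance into a realised electron-transport
rate through the non-rectangular hyperbola, saturating at the chain's
nitrogen-determined Jmax.  NADPH comes exclusively from the linear chain
(one NADPH per two electrons); ATP comes from both, with the cyclic yield
set by the Q-cycle proton stoichiometry (two protons per electron) and a
configurable proton cost per ATP.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import ValidationError
from .params import StoichiometryConstants


@dataclass(frozen=True)
class LightFluxes:
    I_LET: float
    I_CET: float
    J_LET: float
    J_CET: float

    @property
    def J_t(self) -> float:
        return self.J_LET + self.J_CET


@dataclass(frozen=True)
class EnergySupply:
    atp_rate: float  # umol ATP m-2 s-1
    nadph_rate: float  # umol NADPH m-2 s-1


@dataclass(frozen=True)
class EnergyPartition:
    """Fractions of the energy supply assigned to the five consuming pools.

    The pools are the Calvin-Benson cycle and the photorespiratory pathway,
    each in the mesophyll and the bundle sheath, plus the C4 cycle.  The
    fractions are decision variables of the optimizer; they must be
    non-negative and sum to one.
    """

    cb_mesophyll: float
    cb_bundle_sheath: float
    pr_mesophyll: float
    pr_bundle_sheath: float
    c4_cycle: float

    def __post_init__(self) -> None:
        vals = self.as_tuple()
        if any(v < -1e-12 for v in vals):
            raise ValidationError("energy fractions must be non-negative")
        if abs(sum(vals) - 1.0) > 1e-9:
            raise ValidationError(
                f"energy fractions must sum to 1 (got {sum(vals)!r})"
            )

    def as_tuple(self) -> tuple[float, float, float, float, float]:
        return (
            self.cb_mesophyll,
            self.cb_bundle_sheath,
            self.pr_mesophyll,
            self.pr_bundle_sheath,
            self.c4_cycle,
        )

    def as_dict(self) -> dict:
        return {
            "cb_mesophyll": self.cb_mesophyll,
            "cb_bundle_sheath": self.cb_bundle_sheath,
            "pr_mesophyll": self.pr_mesophyll,
            "pr_bundle_sheath": self.pr_bundle_sheath,
            "c4_cycle": self.c4_cycle,
        }

    def j_pools(self, J_t: float) -> tuple[float, float, float]:
        """Aggregated electron-transport pools ``(J_mc, J_mp, J_s)``.

        J_mc feeds the mesophyll Calvin-Benson cycle and photorespiration,
        J_mp the C4 cycle, and J_s the bundle-sheath Calvin-Benson cycle
        and photorespiration.
        """
        j_mc = (self.cb_mesophyll + self.pr_mesophyll) * J_t
        j_mp = self.c4_cycle * J_t
        j_s = (self.cb_bundle_sheath + self.pr_bundle_sheath) * J_t
        return j_mc, j_mp, j_s


def absorbed_irradiance(
    I: float, p: float, constants: StoichiometryConstants | None = None
) -> tuple[float, float]:
    """Split incident irradiance into the LET and CET absorbed shares."""
    if I < 0:
        raise ValidationError("irradiance must be non-negative")
    if not 0 <= p <= 1:
        raise ValidationError("p must lie in [0, 1]")
    c = constants or StoichiometryConstants()
    base = I * c.alpha * (1.0 - c.f)
    return base * p * 0.5, base * (1.0 - p)


def electron_transport(
    I_abso: float, Jmax: float, Theta: float = 0.7
) -> float:
    """Realised electron transport: smaller root of the hyperbola.

    ``Theta * J^2 - (I + Jmax) * J + I * Jmax = 0``; the smaller root is
    continuous in both arguments and bounded by ``min(I_abso, Jmax)``.
    """
    if I_abso < 0 or Jmax < 0:
        raise ValidationError("inputs must be non-negative")
    if not 0 < Theta <= 1:
        raise ValidationError("Theta must lie in (0, 1]")
    if I_abso == 0.0 or Jmax == 0.0:
        return 0.0
    s = I_abso + Jmax
    disc = s * s - 4.0 * Theta * I_abso * Jmax
    assert disc >= 0.0, "hyperbola discriminant negative"
    return (s - math.sqrt(disc)) / (2.0 * Theta)


def energy_supply(
    J_LET: float, J_CET: float, constants: StoichiometryConstants | None = None
) -> EnergySupply:
    """ATP and NADPH production rates from the two chains.

    NADPH: one per two LET electrons.  ATP: LET electrons divided by the
    electrons-per-ATP ratio; CET electrons pump two protons each, converted
    to ATP at ``h_per_atp`` protons per ATP.
    """
    if J_LET < 0 or J_CET < 0:
        raise ValidationError("electron transport rates must be non-negative")
    c = constants or StoichiometryConstants()
    atp = J_LET / c.e_ATP + J_CET * 2.0 / c.h_per_atp
    nadph = J_LET / 2.0
    return EnergySupply(atp_rate=atp, nadph_rate=nadph)


def partition_energy(
    J_t: float, partition: EnergyPartition
) -> tuple[float, float, float]:
    """Aggregate a partition into the pools ``(J_mc, J_mp, J_s)``."""
    if J_t < 0:
        raise ValidationError("J_t must be non-negative")
    return partition.j_pools(J_t)
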