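"""Light- and enzyme-limited CO2 assimilation for C3, C3-C4 and C4 leaves.

Two independent limitations are evaluated and the leaf operates at their
minimum.  The enzyme-limited rate extends the two-compartment C3-C4 model:
PEPC pumps CO2 into the bundle sheath at a rate set by Michaelis-Menten
kinetics on mesophyll CO2; the bundle-sheath CO2 level balances the pump,
the glycine-shuttle CO2 release (a fraction ``xi`` of mesophyll
oxygenation), photorespiratory release and Rubisco consumption against
leakage through the bundle-sheath conductance.  Bundle-sheath O2 rises with
the fraction of PSII operating there, which the model sets to the LET
proportion ``p``.  The light-limited rate allocates the ATP and NADPH
produced by the electron-transport chains across five consuming pools with
the demand stoichiometry (3 + 3.5*phi) ATP and (2 + 2*phi) NADPH per
carboxylation (phi the oxygenation ratio) and 2 ATP per C4-cycle turn.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy.optimize import brentq

from .errors import ConvergenceError, ValidationError
from .light import EnergyPartition, LightFluxes, absorbed_irradiance, electron_transport, energy_supply
from .nitrogen import Allocation, Capacities, capacities
from .params import Environment, SpeciesParams, StoichiometryConstants
from .temperature import temperature_factors

#: ratio of O2 to CO2 diffusivity through the bundle-sheath interface
O2_CO2_CONDUCTANCE_RATIO = 0.047

#: ATP / NADPH demand per carboxylation: Calvin-Benson cycle and
#: photorespiration (the latter per oxygenation, i.e. times phi)
ATP_PER_CARBOXYLATION = 3.0
ATP_PER_OXYGENATION = 3.5
NADPH_PER_CARBOXYLATION = 2.0
NADPH_PER_OXYGENATION = 2.0
ATP_PER_C4_TURN = 2.0

_CS_XTOL = 1e-10  # absolute tolerance on the bundle-sheath CO2 solve, ubar
_OS_TOL = 1e-10  # fixed-point tolerance on bundle-sheath O2, mbar


@dataclass(frozen=True)
class AssimilationResult:
    """Net assimilation with its component limitations and diagnostics."""

    A: float
    A_j_ATP: float
    A_j_NADPH: float
    A_j: float
    A_c: float
    limiting: str  # one of {"ATP", "NADPH", "enzyme"}
    diagnostics: dict


def gamma_star(O_mbar: float, S_co: float) -> float:
    """CO2 compensation point of Rubisco (ubar) from O2 and specificity."""
    return 500.0 * O_mbar / S_co


class SimulationContext:
    """Precomputed per-(species, environment) state for fast evaluation.

    Resolves mesophyll CO2, applies the temperature response to the kinetic
    constants once, and exposes :meth:`evaluate` for repeated calls with
    different allocations (the optimizer's hot path).
    """

    def __init__(
        self,
        species: SpeciesParams,
        env: Environment,
        constants: StoichiometryConstants | None = None,
        tparams: dict | None = None,
    ):
        self.species = species
        self.env = env
        self.constants = constants or StoichiometryConstants()
        self.tfac = temperature_factors(env.T, tparams)
        kin = species.kinetics
        self.Kc = kin.K_c * self.tfac["K_c"]  # ubar
        self.Ko = kin.K_o * self.tfac["K_o"]  # mbar
        self.Sco = kin.S_co * self.tfac["S_co"]
        self.Kp = species.K_p * self.tfac["K_p"]  # ubar
        self.kcat = species.k_ccat * self.tfac["k_ccat"]  # s-1
        self.Cm = env.resolve_cm(species, self.constants)  # ubar
        self.Om = env.O  # mbar
        self.os_gain_per_A = 1.0 / (
            O2_CO2_CONDUCTANCE_RATIO * species.g_s * 1000.0
        )  # mbar per (umol m-2 s-1), before multiplying by the PSII fraction

    # -- mesophyll Rubisco ------------------------------------------------

    def _mesophyll_enzyme(self, vcmax_m: float, Os_independent: bool = True):
        """Enzyme-limited mesophyll carboxylation and oxygenation."""
        if vcmax_m <= 0.0 or self.Cm <= 0.0:
            return 0.0, 0.0
        kc_eff = self.Kc * (1.0 + self.Om / self.Ko)
        vc = vcmax_m * self.Cm / (self.Cm + kc_eff)
        phi = 2.0 * gamma_star(self.Om, self.Sco) / self.Cm
        return vc, phi * vc

    # -- bundle-sheath steady state ---------------------------------------

    def _solve_bundle_sheath(self, vp, shuttle, base_a, vcs_of, p_psii):
        """Solve the coupled bundle-sheath CO2/O2 steady state.

        ``vcs_of(Cs, Os) -> (Vc_s, Vo_s)`` supplies the bundle-sheath
        Rubisco rates under the active limitation.  ``base_a`` is the
        mesophyll contribution to net assimilation (Vc_m - 0.5 Vo_m).
        Returns ``(Cs, Os, Vc_s, Vo_s, A)``.
        """
        gs = self.species.g_s
        cm = self.Cm

        def residual(cs, os_):
            vc_s, vo_s = vcs_of(cs, os_)
            return vp + shuttle + 0.5 * vo_s - vc_s - gs * (cs - cm)

        os_ = self.Om
        cs = cm
        for it in range(200):
            # bracket the CO2 balance root
            lo = 1e-12
            r_lo = residual(lo, os_)
            if r_lo <= 0.0:
                cs_new = lo
            else:
                hi = max(cm, 1.0) + (vp + shuttle) / gs + 1.0
                while residual(hi, os_) > 0.0:
                    hi *= 2.0
                    if hi > 1e12:
                        raise ConvergenceError(
                            "bundle-sheath CO2 balance has no finite root"
                        )
                cs_new = brentq(residual, lo, hi, args=(os_,), xtol=_CS_XTOL)
            vc_s, vo_s = vcs_of(cs_new, os_)
            a = base_a + vc_s - 0.5 * vo_s
            os_new = max(0.0, self.Om + p_psii * a * self.os_gain_per_A)
            if abs(os_new - os_) < _OS_TOL * max(1.0, abs(os_new)):
                return cs_new, os_new, vc_s, vo_s, a
            os_ = os_new if it < 10 else 0.5 * (os_ + os_new)
            cs = cs_new
        raise ConvergenceError(
            f"bundle-sheath O2 fixed point did not converge (Cs={cs:.3g}, "
            f"Os={os_:.3g})"
        )

    # -- enzyme-limited branch --------------------------------------------

    def enzyme_limited(self, caps: Capacities, p: float) -> tuple[float, dict]:
        """Enzyme-limited assimilation A_c and its diagnostics."""
        sp = self.species
        vcmax = caps.E_tot * self.kcat
        vpmax = caps.V_pmax * self.tfac["V_pmax"]
        vp = (
            self.Cm * vpmax / (self.Cm + self.Kp)
            if vpmax > 0.0 and self.Cm > 0.0
            else 0.0
        )
        vcmax_m = (1.0 - sp.beta) * vcmax
        vcmax_s = sp.beta * vcmax
        vc_m, vo_m = self._mesophyll_enzyme(vcmax_m)
        shuttle = 0.5 * sp.xi * vo_m
        # the shuttle moves CO2 release into the bundle sheath but leaves
        # the leaf-level balance unchanged
        base_a = vc_m - 0.5 * vo_m

        if vcmax_s <= 0.0 and vp <= 0.0 and shuttle <= 0.0:
            diag = {
                "C_s": self.Cm,
                "O_s": self.Om,
                "V_p": 0.0,
                "Vc_m": vc_m,
                "Vo_m": vo_m,
                "Vc_s": 0.0,
                "Vo_s": 0.0,
            }
            return base_a, diag

        def vcs_of(cs, os_):
            if vcmax_s <= 0.0 or cs <= 0.0:
                return 0.0, 0.0
            kc_eff = self.Kc * (1.0 + os_ / self.Ko)
            vc = vcmax_s * cs / (cs + kc_eff)
            vo = vcmax_s * 2.0 * gamma_star(os_, self.Sco) / (cs + kc_eff)
            return vc, vo

        cs, os_, vc_s, vo_s, a = self._solve_bundle_sheath(
            vp, shuttle, base_a, vcs_of, p
        )
        diag = {
            "C_s": cs,
            "O_s": os_,
            "V_p": vp,
            "Vc_m": vc_m,
            "Vo_m": vo_m,
            "Vc_s": vc_s,
            "Vo_s": vo_s,
        }
        return a, diag

    # -- light-limited branch ---------------------------------------------

    def light_fluxes(self, caps: Capacities, p: float) -> LightFluxes:
        c = self.constants
        i_let, i_cet = absorbed_irradiance(self.env.I, p, c)
        jmax_let = caps.Jmax_LET * self.tfac["J_max"]
        jmax_cet = caps.Jmax_CET * self.tfac["J_max"]
        j_let = electron_transport(i_let, jmax_let, c.Theta)
        j_cet = electron_transport(i_cet, jmax_cet, c.Theta)
        return LightFluxes(I_LET=i_let, I_CET=i_cet, J_LET=j_let, J_CET=j_cet)

    def _light_branch(
        self,
        budget: float,
        cb_cost: float,
        pr_cost: float,
        vp: float,
        partition: EnergyPartition,
        p: float,
    ) -> tuple[float, dict]:
        """Assimilation under one energy currency's pool budgets."""
        phi_m = (
            2.0 * gamma_star(self.Om, self.Sco) / self.Cm
            if self.Cm > 0.0
            else 0.0
        )
        vc_m = partition.cb_mesophyll * budget / cb_cost
        if phi_m > 0.0:
            vc_m = min(vc_m, partition.pr_mesophyll * budget / (pr_cost * phi_m))
        if self.species.beta >= 1.0 or self.Cm <= 0.0:
            vc_m = 0.0
        vo_m = phi_m * vc_m
        shuttle = 0.5 * self.species.xi * vo_m
        base_a = vc_m - 0.5 * vo_m

        cb_s = partition.cb_bundle_sheath * budget / cb_cost
        pr_s = partition.pr_bundle_sheath * budget / pr_cost

        if self.species.beta <= 0.0 or cb_s <= 0.0:
            # no bundle-sheath Rubisco activity possible under this budget
            if vp <= 0.0 and shuttle <= 0.0:
                return base_a, {"C_s": self.Cm, "O_s": self.Om, "V_p": vp}

            def vcs_of(cs, os_):
                return 0.0, 0.0

        else:

            def vcs_of(cs, os_):
                if cs <= 0.0:
                    return 0.0, 0.0
                phi_s = 2.0 * gamma_star(os_, self.Sco) / cs
                vc = cb_s if phi_s <= 0.0 else min(cb_s, pr_s / phi_s)
                return vc, phi_s * vc

        cs, os_, vc_s, vo_s, a = self._solve_bundle_sheath(
            vp, shuttle, base_a, vcs_of, p
        )
        return a, {
            "C_s": cs,
            "O_s": os_,
            "V_p": vp,
            "Vc_m": vc_m,
            "Vo_m": vo_m,
            "Vc_s": vc_s,
            "Vo_s": vo_s,
        }

    def light_limited(
        self, caps: Capacities, partition: EnergyPartition, p: float
    ) -> tuple[float, float, float, dict]:
        """ATP-, NADPH-limited and combined light-limited assimilation."""
        fluxes = self.light_fluxes(caps, p)
        supply = energy_supply(fluxes.J_LET, fluxes.J_CET, self.constants)
        # the C4 cycle consumes ATP only; its flux under light limitation is
        # set by the ATP budget of its pool (zero for species without PEPC)
        vp = (
            partition.c4_cycle * supply.atp_rate / ATP_PER_C4_TURN
            if caps.V_pmax > 0.0
            else 0.0
        )
        a_atp, d_atp = self._light_branch(
            supply.atp_rate,
            ATP_PER_CARBOXYLATION,
            ATP_PER_OXYGENATION,
            vp,
            partition,
            p,
        )
        a_nadph, d_nadph = self._light_branch(
            supply.nadph_rate,
            NADPH_PER_CARBOXYLATION,
            NADPH_PER_OXYGENATION,
            vp,
            partition,
            p,
        )
        a_j = min(a_atp, a_nadph)
        diag = {
            "fluxes": fluxes,
            "supply": supply,
            "ATP": d_atp,
            "NADPH": d_nadph,
        }
        return a_atp, a_nadph, a_j, diag

    # -- full forward pass -------------------------------------------------

    def evaluate(
        self, alloc: Allocation, partition: EnergyPartition
    ) -> AssimilationResult:
        caps = capacities(alloc, self.env, self.species, self.constants)
        a_c, diag_c = self.enzyme_limited(caps, alloc.p)
        a_atp, a_nadph, a_j, diag_j = self.light_limited(
            caps, partition, alloc.p
        )
        return net_assimilation(
            a_atp, a_nadph, a_j, a_c, {"enzyme": diag_c, "light": diag_j, "capacities": caps}
        )


def net_assimilation(
    a_atp: float,
    a_nadph: float,
    a_j: float,
    a_c: float,
    diagnostics: dict | None = None,
) -> AssimilationResult:
    """Combine component rates: A = min(A_j, A_c); ties label "enzyme"."""
    for value in (a_j, a_c):
        if not value == value or value in (float("inf"), float("-inf")):
            raise ValidationError("component rates must be finite")
    if a_c <= a_j:
        limiting = "enzyme"
        a = a_c
    else:
        limiting = "ATP" if a_atp <= a_nadph else "NADPH"
        a = a_j
    return AssimilationResult(
        A=a,
        A_j_ATP=a_atp,
        A_j_NADPH=a_nadph,
        A_j=a_j,
        A_c=a_c,
        limiting=limiting,
        diagnostics=diagnostics or {},
    )


def light_limited(
    caps: Capacities,
    partition: EnergyPartition,
    species: SpeciesParams,
    env: Environment,
    p: float,
    constants: StoichiometryConstants | None = None,
    tparams: dict | None = None,
) -> tuple[float, float, float]:
    """Functional wrapper: (A_j_ATP, A_j_NADPH, A_j) for given capacities."""
    ctx = SimulationContext(species, env, constants, tparams)
    a_atp, a_nadph, a_j, _ = ctx.light_limited(caps, partition, p)
    return a_atp, a_nadph, a_j


def enzyme_limited(
    caps: Capacities,
    species: SpeciesParams,
    env: Environment,
    p: float,
    constants: StoichiometryConstants | None = None,
    tparams: dict | None = None,
) -> float:
    """Functional wrapper: enzyme-limited rate A_c for given capacities."""
    ctx = SimulationContext(species, env, constants, tparams)
    a_c, _ = ctx.enzyme_limited(caps, p)
    return a_c


def simulate(
    species: SpeciesParams,
    env: Environment,
    alloc: Allocation,
    partition: EnergyPartition,
    constants: StoichiometryConstants | None = None,
    tparams: dict | None = None,
) -> AssimilationResult:
    """Full forward pass: capacities -> temperature -> light -> A."""
    ctx = SimulationContext(species, env, constants, tparams)
    return ctx.evaluate(alloc, partition)
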