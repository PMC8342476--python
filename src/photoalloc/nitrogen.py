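"""Mapping nitrogen allocations to biochemical capacities.

The photosynthetic nitrogen pool is split into three fractions: Rubisco
(``n_Etot``), the C4-cycle enzymes PEPC and PPDK (``n_C4``) and the
thylakoids (``n_Jmax``).  Thylakoid nitrogen is further split between the
linear and cyclic electron-transport chains by the LET proportion ``p``,
which fixes the abundances of the photosystems and light-harvesting
complexes per chlorophyll and thereby the cytochrome-f content and the
maximal electron-transport rates of the two chains.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import InfeasibleAllocationError, ValidationError
from .params import Environment, SpeciesParams, StoichiometryConstants

_SUM_TOL = 1e-9


@dataclass(frozen=True)
class Allocation:
    """Nitrogen allocation fractions plus the LET proportion.

    ``n_Etot + n_C4 + n_Jmax`` must equal one (nitrogen conservation);
    ``p`` is the proportion of linear electron transport.
    """

    n_Etot: float
    n_C4: float
    n_Jmax: float
    p: float
    scenario: str | None = None

    def __post_init__(self) -> None:
        for name in ("n_Etot", "n_C4", "n_Jmax", "p"):
            value = getattr(self, name)
            if not -_SUM_TOL <= value <= 1 + _SUM_TOL:
                raise ValidationError(f"{name} must lie in [0, 1], got {value}")
        total = self.n_Etot + self.n_C4 + self.n_Jmax
        if abs(total - 1.0) > _SUM_TOL:
            raise ValidationError(
                f"nitrogen fractions must sum to 1 (got {total!r})"
            )

    def as_dict(self) -> dict:
        return {
            "n_Etot": self.n_Etot,
            "n_C4": self.n_C4,
            "n_Jmax": self.n_Jmax,
            "p": self.p,
        }


@dataclass(frozen=True)
class ThylakoidComposition:
    """Complex abundances and nitrogen bookkeeping per chlorophyll."""

    PSI_LET: float
    PSI_CET: float
    PSII: float
    LHC_LET: float
    LHC_CET: float
    N_thy_LET: float = 0.0
    N_thy_CET: float = 0.0
    N_LH_LET: float = 0.0
    N_LH_CET: float = 0.0
    cyt_LET: float = 0.0
    cyt_CET: float = 0.0


@dataclass(frozen=True)
class Capacities:
    """Derived maximal rates for a given allocation."""

    N_ps: float  # umol m-2
    E_tot: float  # Rubisco catalytic sites, umol m-2
    V_pmax: float  # umol m-2 s-1
    Chl: float  # umol m-2
    Jmax_LET: float  # umol e- m-2 s-1
    Jmax_CET: float  # umol e- m-2 s-1
    composition: ThylakoidComposition

    def as_dict(self) -> dict:
        d = {
            "N_ps": self.N_ps,
            "E_tot": self.E_tot,
            "V_pmax": self.V_pmax,
            "Chl": self.Chl,
            "Jmax_LET": self.Jmax_LET,
            "Jmax_CET": self.Jmax_CET,
        }
        d.update(vars(self.composition))
        return d


def photosynthetic_nitrogen(
    N_t: float, constants: StoichiometryConstants | None = None
) -> float:
    """Photosynthetic nitrogen pool (umol m-2) from leaf nitrogen (mmol m-2).

    A configurable linear map: a fixed fraction (``nps_fraction``, default
    0.75) of total leaf nitrogen is available to the photosynthetic
    apparatus, converted from mmol to umol.  The map is monotone and zero
    at zero.
    """
    if N_t < 0:
        raise ValidationError("leaf nitrogen must be non-negative")
    constants = constants or StoichiometryConstants()
    return constants.nps_fraction * N_t * 1000.0


def rubisco_sites(
    n_Etot: float, N_ps: float, constants: StoichiometryConstants | None = None
) -> float:
    """Rubisco catalytic sites E_tot = n_Etot * N_ps * c_E (umol m-2)."""
    if n_Etot < 0 or N_ps < 0:
        raise ValidationError("inputs must be non-negative")
    constants = constants or StoichiometryConstants()
    return n_Etot * N_ps * constants.c_E


def c4_capacity(
    n_C4: float, N_ps: float, constants: StoichiometryConstants | None = None
) -> float:
    """Maximal C4-cycle activity V_pmax (umol m-2 s-1).

    PEPC and PPDK are co-limiting: the nitrogen cost per unit of flux is the
    sum of their per-site nitrogen requirements divided by their turnover
    numbers.
    """
    if n_C4 < 0 or N_ps < 0:
        raise ValidationError("inputs must be non-negative")
    constants = constants or StoichiometryConstants()
    denom = (
        constants.mw_star_ppdk / constants.kcat_PPDK
        + constants.mw_star_pepc / constants.kcat_PEPC
    )
    return n_C4 * N_ps / denom


def chlorophyll(
    n_Jmax: float, N_ps: float, constants: StoichiometryConstants | None = None
) -> float:
    """Chlorophyll content (umol m-2), linear in thylakoid nitrogen."""
    if n_Jmax < 0 or N_ps < 0:
        raise ValidationError("inputs must be non-negative")
    constants = constants or StoichiometryConstants()
    return constants.n_Chl * n_Jmax * N_ps


def thylakoid_split(
    p: float, constants: StoichiometryConstants | None = None
) -> ThylakoidComposition:
    """Share the chlorophyll between PSI, PSII and LHC of the two chains.

    PSI splits between LET and CET in proportion to ``p``; PSII belongs to
    the LET entirely.  The LHC abundances absorb the remaining chlorophyll
    of each chain.  A negative LHC abundance means the allocation is
    infeasible (too little chlorophyll on that chain to cover its
    photosystems) and raises :class:`InfeasibleAllocationError`.
    """
    if not 0 <= p <= 1:
        raise ValidationError("p must lie in [0, 1]")
    c = constants or StoichiometryConstants()
    psi_let = c.PSI * p
    psi_cet = c.PSI * (1.0 - p)
    psii = c.PSII
    lhc_let = (1000.0 * p - psii * c.pII_Chl - psi_let * c.pI_Chl) / c.l_Chl
    lhc_cet = (1000.0 * (1.0 - p) - psi_cet * c.pI_Chl) / c.l_Chl
    if lhc_let < 0 or lhc_cet < 0:
        raise InfeasibleAllocationError(
            f"negative light-harvesting complex abundance at p={p} "
            f"(LHC_LET={lhc_let:.3f}, LHC_CET={lhc_cet:.3f})"
        )
    return ThylakoidComposition(
        PSI_LET=psi_let,
        PSI_CET=psi_cet,
        PSII=psii,
        LHC_LET=lhc_let,
        LHC_CET=lhc_cet,
    )


def jmax_let(
    n_Jmax: float,
    N_ps: float,
    p: float,
    Chl: float,
    constants: StoichiometryConstants | None = None,
) -> tuple[float, float, float, float]:
    """Maximal LET electron transport from thylakoid nitrogen.

    Returns ``(Jmax_LET, cyt_LET, N_thy_LET, N_LH_LET)``.  Thylakoid
    nitrogen per chlorophyll in excess of the light-harvesting machinery is
    assigned to cytochrome f, which sets Jmax through its empirical electron
    capacity; the Jmax is clamped at zero when the light-harvesting cost
    exceeds the available thylakoid nitrogen.
    """
    c = constants or StoichiometryConstants()
    thy_n = n_Jmax * N_ps * p
    if thy_n == 0:
        return 0.0, 0.0, 0.0, 0.0
    if Chl <= 0:
        raise ValidationError("zero chlorophyll with positive thylakoid nitrogen")
    comp = thylakoid_split(p, c)
    n_thy = thy_n / Chl
    n_lh = (
        comp.PSII * c.pII_N * c.pII_Chl * 1e-3
        + comp.PSI_LET * c.pI_N * c.pI_Chl * 1e-3
        + comp.LHC_LET * c.l_N * c.l_Chl * 1e-3
    )
    cyt = (n_thy - n_lh) / c.c_N
    jmax = max(0.0, cyt * Chl * c.cyt_Jmax / 1000.0)
    return jmax, cyt, n_thy, n_lh


def jmax_cet(
    n_Jmax: float,
    N_ps: float,
    p: float,
    Chl: float,
    constants: StoichiometryConstants | None = None,
) -> tuple[float, float, float, float]:
    """Maximal CET electron transport; analogous to the LET case.

    The cyclic chain carries no PSII, and its Jmax scales with cytochrome f
    by an extra factor ``Jmax_CL`` because PSII is the nitrogen-expensive
    photosystem.  Returns ``(Jmax_CET, cyt_CET, N_thy_CET, N_LH_CET)``.
    """
    c = constants or StoichiometryConstants()
    thy_n = n_Jmax * N_ps * (1.0 - p)
    if thy_n == 0:
        return 0.0, 0.0, 0.0, 0.0
    if Chl <= 0:
        raise ValidationError("zero chlorophyll with positive thylakoid nitrogen")
    comp = thylakoid_split(p, c)
    n_thy = thy_n / Chl
    n_lh = (
        comp.PSI_CET * c.pI_N * c.pI_Chl * 1e-3
        + comp.LHC_CET * c.l_N * c.l_Chl * 1e-3
    )
    cyt = (n_thy - n_lh) / c.c_N
    jmax = max(0.0, cyt * Chl * c.cyt_Jmax * c.Jmax_CL / 1000.0)
    return jmax, cyt, n_thy, n_lh


def capacities(
    alloc: Allocation,
    env: Environment,
    species: SpeciesParams | None = None,
    constants: StoichiometryConstants | None = None,
) -> Capacities:
    """All capacities implied by an allocation in one consistent call."""
    c = constants or StoichiometryConstants()
    n_ps = photosynthetic_nitrogen(env.N_t, c)
    e_tot = rubisco_sites(alloc.n_Etot, n_ps, c)
    v_pmax = c4_capacity(alloc.n_C4, n_ps, c)
    chl = chlorophyll(alloc.n_Jmax, n_ps, c)
    if chl <= 0:
        comp = ThylakoidComposition(0.0, 0.0, 0.0, 0.0, 0.0)
        if alloc.n_Jmax * n_ps > 0:
            raise ValidationError("zero chlorophyll with thylakoid nitrogen")
        return Capacities(n_ps, e_tot, v_pmax, chl, 0.0, 0.0, comp)
    jl, cyt_l, nthy_l, nlh_l = jmax_let(alloc.n_Jmax, n_ps, alloc.p, chl, c)
    jc, cyt_c, nthy_c, nlh_c = jmax_cet(alloc.n_Jmax, n_ps, alloc.p, chl, c)
    comp = thylakoid_split(alloc.p, c)
    comp = ThylakoidComposition(
        PSI_LET=comp.PSI_LET,
        PSI_CET=comp.PSI_CET,
        PSII=comp.PSII,
        LHC_LET=comp.LHC_LET,
        LHC_CET=comp.LHC_CET,
        N_thy_LET=nthy_l,
        N_thy_CET=nthy_c,
        N_LH_LET=nlh_l,
        N_LH_CET=nlh_c,
        cyt_LET=cyt_l,
        cyt_CET=cyt_c,
    )
    return Capacities(
        N_ps=n_ps,
        E_tot=e_tot,
        V_pmax=v_pmax,
        Chl=chl,
        Jmax_LET=jl,
        Jmax_CET=jc,
        composition=comp,
    )
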