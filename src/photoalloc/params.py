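"""Shared domain types: stoichiometric constants, environments, species,
temperature-response parameters and measurement tables.

The stoichiometric constants are the fixed biochemical bookkeeping factors of
the model (nitrogen costs and chlorophyll shares of the photosystems, enzyme
turnover numbers and molecular weights, electron/ATP ratios).  A species
(photosynthetic type) is characterised by six parameters: the Rubisco
distribution between mesophyll and bundle sheath (beta), the Rubisco turnover
number (k_ccat, from which the remaining Rubisco kinetics follow through a
trade-off relation), the glycine-shuttle fraction (xi), the PEPC Michaelis
constant for bicarbonate (K_p), the bundle-sheath CO2 conductance (g_s) and
per-pool allocation bounds.  An environment is irradiance, temperature,
mesophyll CO2, O2 and total leaf nitrogen.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace

import pandas as pd

from .errors import ValidationError

R_GAS = 8.314  # universal gas constant, J mol-1 K-1
T25_K = 298.15  # 25 degC in Kelvin

#: Quantities a measurement table may contain.
MEASUREMENT_QUANTITIES = frozenset(
    {"A", "Chl", "PSII", "cyt_f", "Rubisco_N", "C4_N", "thylakoid_N"}
)

#: Valid independent-variable kinds for response curves.
X_KINDS = frozenset({"Ci", "T", "N", "none"})

PHOTOSYNTHETIC_TYPES = ("C3", "C3-C4", "C4-like", "C4")


@dataclass(frozen=True)
class StoichiometryConstants:
    """Fixed stoichiometric and biochemical constants of the model.

    Units follow the field comments; all values are strictly positive.
    """

    c_E: float = 1.27e-3  # Rubisco catalytic sites per N, umol (umol N)-1
    c_N: float = 8.85  # N cost of cytochrome f, mol N (mmol cyt)-1
    cyt_Jmax: float = 172.0  # e- capacity of cyt f, mmol e- (mmol cyt s)-1
    e_ATP: float = 4.0 / 3.0  # electrons per ATP in linear electron transport
    f: float = 0.15  # spectral quality correction, unitless
    alpha: float = 0.84  # leaf absorptance, fraction
    Theta: float = 0.7  # convexity of the light-response hyperbola
    Jmax_CL: float = 3.0  # CET Jmax scaling with cytochrome f
    n_Chl: float = 0.0158887  # chlorophyll per thylakoid nitrogen
    PSI: float = 2.0  # photosystem I per chlorophyll, mmol (mol Chl)-1
    PSII: float = 2.5  # photosystem II per chlorophyll, mmol (mol Chl)-1
    pI_Chl: float = 184.0  # Chl per PSI complex
    pII_Chl: float = 60.0  # Chl per PSII complex
    l_Chl: float = 13.0  # Chl per LHC complex
    pI_N: float = 32.8  # N cost of PSI, mol N (mol Chl)-1
    pII_N: float = 83.3  # N cost of PSII, mol N (mol Chl)-1
    l_N: float = 26.0  # N cost of LHC, mol N (mol Chl)-1
    MW_PEPC: float = 96000.0  # Da
    MW_PPDK: float = 95000.0  # Da
    kcat_PEPC: float = 66.0  # s-1
    kcat_PPDK: float = 6.02  # s-1
    protein_N_fraction: float = 0.16  # nitrogen mass fraction of protein
    h_per_atp: float = 4.0  # protons per ATP at the ATP synthase
    nps_fraction: float = 0.75  # photosynthetic fraction of leaf nitrogen
    cm_over_ci: float = 0.85  # mesophyll/intercellular CO2 ratio

    def __post_init__(self) -> None:
        for fld in fields(self):
            value = getattr(self, fld.name)
            if not (isinstance(value, (int, float)) and value > 0):
                raise ValidationError(
                    f"constant {fld.name!r} must be strictly positive, "
                    f"got {value!r}"
                )
        if not 0 < self.Theta <= 1:
            raise ValidationError("Theta must lie in (0, 1]")
        if not 0 < self.alpha <= 1:
            raise ValidationError("alpha must lie in (0, 1]")
        if not 0 < self.f < 1:
            raise ValidationError("f must lie in (0, 1)")

    @property
    def mw_star_pepc(self) -> float:
        """Nitrogen per PEPC catalytic site, umol N (umol sites)-1.

        The molecular weight is converted from a protein-mass basis to a
        nitrogen-mole basis assuming a 16% nitrogen mass fraction and
        14 g mol-1 for nitrogen.
        """
        return self.protein_N_fraction * self.MW_PEPC / 14.0

    @property
    def mw_star_ppdk(self) -> float:
        return self.protein_N_fraction * self.MW_PPDK / 14.0

    def p_min(self) -> float:
        """Smallest LET proportion with a feasible thylakoid composition.

        Below this value the chlorophyll assigned to the linear chain cannot
        cover PSII and the LET share of PSI, so the LHC abundance would be
        negative.
        """
        return (self.PSII * self.pII_Chl) / (1000.0 - self.PSI * self.pI_Chl)


@dataclass(frozen=True)
class RubiscoKinetics:
    """Michaelis constants and specificity implied by a turnover number."""

    K_c: float  # ubar
    K_o: float  # mbar
    S_co: float  # dimensionless (bar/bar) CO2/O2 specificity


#: Anchor points of the Rubisco kinetic trade-off: turnover (s-1) against
#: (K_c [ubar], K_o [mbar], S_co).  Faster Rubiscos have weaker substrate
#: affinity and lower specificity; values follow the classical C3 and C4
#: parameterisations of the von Caemmerer model family.
DEFAULT_KINETIC_ANCHORS = (
    (2.9, 260.0, 179.0, 2590.0),
    (3.8, 650.0, 450.0, 2280.0),
)


def kinetics_from_kcat(
    k_ccat: float,
    anchors: tuple = DEFAULT_KINETIC_ANCHORS,
) -> RubiscoKinetics:
    """Derive (K_c, K_o, S_co) from the Rubisco turnover number.

    Log-log interpolation between two anchor parameter sets, extrapolated
    linearly (in log space) outside the anchored range.  Monotone: K_c and
    K_o increase with k_ccat, S_co decreases.
    """
    if k_ccat <= 0:
        raise ValidationError("k_ccat must be positive")
    (k0, kc0, ko0, s0), (k1, kc1, ko1, s1) = anchors
    t = (math.log(k_ccat) - math.log(k0)) / (math.log(k1) - math.log(k0))

    def loginterp(a: float, b: float) -> float:
        return math.exp(math.log(a) + t * (math.log(b) - math.log(a)))

    return RubiscoKinetics(
        K_c=loginterp(kc0, kc1), K_o=loginterp(ko0, ko1), S_co=loginterp(s0, s1)
    )


@dataclass(frozen=True)
class Environment:
    """The independent variables of a simulation.

    Parameters
    ----------
    I : float
        Incident irradiance, umol quanta m-2 s-1.
    T : float
        Leaf temperature in degrees Celsius (user-facing; converted to
        Kelvin wherever the temperature response is evaluated).
    C_m : float, optional
        Mesophyll CO2 partial pressure, ubar.  May be omitted when ``C_a``
        is given, in which case it is derived per-species from the
        atmospheric CO2 through the Ca/Ci and Cm/Ci ratios.
    O : float
        O2 partial pressure, mbar.
    N_t : float
        Total leaf nitrogen, mmol m-2.
    C_a : float, optional
        Atmospheric CO2 partial pressure, ubar.
    """

    I: float
    T: float
    C_m: float | None = None
    O: float = 200.0
    N_t: float = 130.0
    C_a: float | None = None

    def __post_init__(self) -> None:
        if self.I < 0:
            raise ValidationError("irradiance must be non-negative")
        if self.O < 0:
            raise ValidationError("O2 partial pressure must be non-negative")
        if self.N_t < 0:
            raise ValidationError("leaf nitrogen must be non-negative")
        if self.C_m is None and self.C_a is None:
            raise ValidationError("either C_m or C_a must be given")
        for name in ("C_m", "C_a"):
            value = getattr(self, name)
            if value is not None and value < 0:
                raise ValidationError(f"{name} must be non-negative")
        if self.C_m is not None and self.C_a is not None and self.C_m >= self.C_a:
            raise ValidationError(
                "C_m must be below C_a: CO2 enters the mesophyll by diffusion"
            )

    @property
    def T_K(self) -> float:
        """Leaf temperature in Kelvin."""
        return self.T + 273.15

    def resolve_cm(
        self,
        species: "SpeciesParams | None" = None,
        constants: StoichiometryConstants | None = None,
    ) -> float:
        """The mesophyll CO2 level, deriving it from ``C_a`` if needed."""
        if self.C_m is not None:
            return self.C_m
        constants = constants or StoichiometryConstants()
        ca_over_ci = species.ca_over_ci if species is not None else 1.0 / 0.7
        return derive_cm(self.C_a, ca_over_ci, constants.cm_over_ci)


def derive_cm(C_a: float, Ca_over_Ci: float, Cm_over_Ci: float) -> float:
    """Mesophyll CO2 from atmospheric CO2 via the Ca/Ci and Cm/Ci ratios.

    ``C_m = C_a / (Ca/Ci) * (Cm/Ci)``.  The Cm/Ci ratio must not exceed one
    (CO2 enters the mesophyll through diffusion) and Ca/Ci must be at least
    one (CO2 enters the leaf through stomata).
    """
    if C_a < 0:
        raise ValidationError("C_a must be non-negative")
    if Ca_over_Ci <= 0 or Cm_over_Ci <= 0:
        raise ValidationError("ratios must be positive")
    if Ca_over_Ci < 1:
        raise ValidationError("Ca/Ci must be >= 1: CO2 enters through stomata")
    if Cm_over_Ci > 1:
        raise ValidationError(
            "Cm/Ci must be <= 1: CO2 enters the mesophyll through diffusion"
        )
    return C_a / Ca_over_Ci * Cm_over_Ci


def pepc_invitro_to_invivo(v_invitro: float) -> float:
    """Convert an in vitro PEPC activity to an in vivo estimate (divide by 3)."""
    if v_invitro < 0:
        raise ValidationError("PEPC activity must be non-negative")
    return v_invitro / 3.0


_DEFAULT_BOUNDS = {
    "n_Etot": (0.0, 1.0),
    "n_C4": (0.0, 1.0),
    "n_Jmax": (0.0, 1.0),
    "p": (0.0, 1.0),
}


@dataclass(frozen=True)
class SpeciesParams:
    """The six parameters defining a photosynthetic type, plus bounds.

    ``beta`` is the fraction of Rubisco located in the bundle sheath
    (0 for C3, approaching 1 for C4).  ``xi`` is the fraction of glycine
    decarboxylated in the bundle sheath that derives from mesophyll
    oxygenation (the C3-C4 glycine shuttle).  ``g_s`` is the bundle-sheath
    CO2 conductance in umol m-2 s-1 ubar-1 (leakage = g_s * (C_s - C_m)).
    """

    label: str
    ptype: str
    beta: float
    k_ccat: float
    xi: float
    K_p: float  # ubar
    g_s: float  # umol m-2 s-1 ubar-1
    allocation_bounds: dict = field(default_factory=lambda: dict(_DEFAULT_BOUNDS))
    ca_over_ci: float | None = None
    n_Rubisco: float | None = None  # empirical C3 baseline, reporting only
    n_fit: float | None = None  # empirical thylakoid fraction, reporting only
    kinetic_anchors: tuple = DEFAULT_KINETIC_ANCHORS
    provisional: bool = True

    def __post_init__(self) -> None:
        if self.ptype not in PHOTOSYNTHETIC_TYPES:
            raise ValidationError(
                f"ptype must be one of {PHOTOSYNTHETIC_TYPES}, got {self.ptype!r}"
            )
        if not 0 <= self.beta <= 1:
            raise ValidationError("beta must lie in [0, 1]")
        if not 0 <= self.xi <= 1:
            raise ValidationError("xi must lie in [0, 1]")
        for name in ("k_ccat", "K_p", "g_s"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be strictly positive")
        bounds = dict(_DEFAULT_BOUNDS)
        bounds.update(self.allocation_bounds)
        unknown = set(bounds) - set(_DEFAULT_BOUNDS)
        if unknown:
            raise ValidationError(f"unknown allocation bound keys: {sorted(unknown)}")
        for key, (lo, hi) in bounds.items():
            if not (0 <= lo <= hi <= 1):
                raise ValidationError(
                    f"allocation bound {key} must satisfy 0 <= lo <= hi <= 1"
                )
        if self.ptype == "C3" and bounds["n_C4"][1] > 0:
            raise ValidationError(
                "C3 species cannot invest nitrogen into the C4 cycle: "
                "upper bound on n_C4 must be 0"
            )
        object.__setattr__(self, "allocation_bounds", bounds)
        if self.ca_over_ci is None:
            ratio = 1.0 / 0.7 if self.ptype in ("C3", "C3-C4") else 1.0 / 0.4
            object.__setattr__(self, "ca_over_ci", ratio)

    @property
    def kinetics(self) -> RubiscoKinetics:
        return kinetics_from_kcat(self.k_ccat, self.kinetic_anchors)


@dataclass(frozen=True)
class ArrheniusEntry:
    """Peaked-Arrhenius parameters for one temperature-dependent quantity.

    ``H = inf`` is the sentinel for "no deactivation", reducing the response
    to a plain Arrhenius curve.
    """

    k25: float = 1.0  # value at 25 degC, native units (1.0 = scale factor)
    E: float = 0.0  # activation energy, J mol-1
    H: float = math.inf  # deactivation energy, J mol-1
    S: float = 0.0  # entropy factor, J mol-1 K-1

    def __post_init__(self) -> None:
        if self.H < 0:
            raise ValidationError("deactivation energy H must be >= 0")


#: Quantities whose temperature dependence the model tracks.
TEMPERATURE_QUANTITIES = (
    "V_pmax",
    "k_ccat",
    "J_max",
    "K_p",
    "K_c",
    "K_o",
    "S_co",
)


def default_temperature_params() -> dict:
    """Default peaked-Arrhenius parameter sets, J mol-1 (S in J mol-1 K-1).

    C4-cycle and electron-transport quantities use peaked responses in the
    style of Massad et al.'s C4 parameterisation; Michaelis constants and
    specificity use plain Arrhenius curves in the style of the standard C3
    literature.  All are provisional defaults and config-overridable.
    """
    return {
        "V_pmax": ArrheniusEntry(E=70373.0, H=117910.0, S=376.0),
        "k_ccat": ArrheniusEntry(E=67294.0, H=144568.0, S=472.0),
        "J_max": ArrheniusEntry(E=77900.0, H=191929.0, S=627.0),
        "K_p": ArrheniusEntry(E=36300.0),
        "K_c": ArrheniusEntry(E=79430.0),
        "K_o": ArrheniusEntry(E=36380.0),
        "S_co": ArrheniusEntry(E=-37830.0),
    }


def default_species() -> dict:
    """Archetype species registry for the four photosynthetic types.

    The archetypes emulate the four *Flaveria* types studied in the genus
    (a C3 like F. pringlei, a C3-C4 intermediate like F. floridana, a
    C4-like species resembling F. palmeri and a C4 like F. bidentis).
    Values are provisional literature-style parameterisations.
    """
    return {
        "C3": SpeciesParams(
            label="C3",
            ptype="C3",
            beta=0.0,
            k_ccat=2.9,
            xi=0.0,
            K_p=80.0,
            g_s=0.003,
            allocation_bounds={"n_C4": (0.0, 0.0)},
            n_Rubisco=0.25,
        ),
        "C3-C4": SpeciesParams(
            label="C3-C4",
            ptype="C3-C4",
            beta=0.25,
            k_ccat=3.0,
            xi=0.95,
            K_p=80.0,
            g_s=0.003,
            allocation_bounds={"n_C4": (0.0, 0.1)},
        ),
        "C4-like": SpeciesParams(
            label="C4-like",
            ptype="C4-like",
            beta=0.95,
            k_ccat=3.6,
            xi=1.0,
            K_p=80.0,
            g_s=0.003,
        ),
        "C4": SpeciesParams(
            label="C4",
            ptype="C4",
            beta=1.0,
            k_ccat=3.8,
            xi=1.0,
            K_p=80.0,
            g_s=0.003,
        ),
    }


def default_environments() -> dict:
    """Environment presets: the evolutionary scenario and three growth setups.

    The evolutionary scenario is an open, hot, high-light habitat at a
    pre-industrial 280 ubar atmospheric CO2; the specific irradiance of
    1500 umol m-2 s-1 is a flagged assumption.  The growth presets mirror
    the growth-chamber conditions of the three *Flaveria* gas-exchange and
    resource-allocation studies the model is compared against.
    """
    return {
        "evolutionary": Environment(I=1500.0, T=30.0, C_a=280.0, O=200.0),
        "growth_aci": Environment(I=560.0, T=37.0, C_a=380.0, O=200.0),
        "growth_nitrogen": Environment(I=554.0, T=30.0, C_a=380.0, O=200.0),
        "growth_pools_25": Environment(I=550.0, T=25.0, C_a=380.0, O=200.0),
        "growth_pools_35": Environment(I=550.0, T=35.0, C_a=380.0, O=200.0),
    }


_MEASUREMENT_COLUMNS = ["curve_id", "x_kind", "x", "quantity", "value", "se", "n"]


class MeasurementTable:
    """Long-format container for measured or predicted response curves.

    Wraps a :class:`pandas.DataFrame` with columns
    ``(curve_id, x_kind, x, quantity, value, se, n)``.  Quantities come from
    a closed vocabulary; the independent-variable kind is one of
    ``Ci``/``T``/``N``/``none``.
    """

    columns = tuple(_MEASUREMENT_COLUMNS)

    def __init__(self, df: pd.DataFrame):
        df = df.copy()
        missing = set(_MEASUREMENT_COLUMNS) - set(df.columns)
        if missing:
            raise ValidationError(f"measurement table missing columns {sorted(missing)}")
        df = df[_MEASUREMENT_COLUMNS].reset_index(drop=True)
        bad_q = set(df["quantity"]) - MEASUREMENT_QUANTITIES
        if bad_q:
            raise ValidationError(f"unknown quantities {sorted(bad_q)}")
        bad_x = set(df["x_kind"]) - X_KINDS
        if bad_x:
            raise ValidationError(f"unknown x kinds {sorted(bad_x)}")
        if (df["se"].fillna(0) < 0).any():
            raise ValidationError("standard errors must be non-negative")
        self.df = df

    @classmethod
    def from_records(cls, records: list[dict]) -> "MeasurementTable":
        return cls(pd.DataFrame.from_records(records, columns=_MEASUREMENT_COLUMNS))

    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other) -> bool:
        return isinstance(other, MeasurementTable) and self.df.equals(other.df)

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path) -> "MeasurementTable":
        return cls(pd.read_csv(path))


def with_nitrogen(env: Environment, N_t: float) -> Environment:
    """A copy of ``env`` with the leaf nitrogen replaced."""
    return replace(env, N_t=N_t)
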