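"""Core thermodynamic types and state-function utilities.

Unit conventions
----------------
Internal quantities are kept in molar (M), litres (L) and calories (cal):
equilibrium constants in M^-1 for bimolecular steps and M^-2 for
termolecular steps, molar enthalpies in cal/mol, and heats in cal.  The
public reporting surface (tables, CSV files, CLI) uses the calorimetry
conventions of uM, uL, kcal/mol and ucal.

The model system is a self-associating "hub" protein A (the nucleoporin
Nup53 core fragment, which homodimerizes through its RRM domain) carrying
two independent IDR binding sites: a C-terminal site for a karyopherin B
(Kap121) and an N-terminal site for a partner C (Nic96).  The schemes below
cover homodimerization, bivalent hub-Kap binding, and the allosterically
coupled ternary system.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace

from .errors import InvalidComparisonError, InvalidParameterError

#: Gas constant in cal mol^-1 K^-1.  Calorimetry tables often quote the
#: two-decimal convention 1.99; the four-digit value is used here because
#: the rounding shifts dG by up to ~0.06 kcal/mol for the strongest
#: termolecular constants, more than the precision such tables print.
R_CAL = 1.9872

#: Default experiment temperature, K (15 degrees C).
T_DEFAULT = 288.0

KCAL = 1000.0  # cal per kcal


class SchemeId(enum.Enum):
    """Reaction schemes of increasing complexity.

    MONOMER_DIMER      2A <-> A2 only.
    SINGLE_SITE        A + B <-> AB only (classic 1:1).
    TWO_MODE           1:1 (AB) and bivalent 2:1 (A2*B) complexes of a
                       monomeric hub; equals MULTI_EQ with K_sc=K1=K2=0.
    MULTI_EQ           TWO_MODE plus hub dimerization and dimer-Kap
                       complexes A2B and A2B2.
    TERNARY            MULTI_EQ plus partner C binding at the hub's second
                       site with state-dependent constants K5, K6, K7.
    TERNARY_MONOMERIC  TERNARY with K_sc=K1=K2=K6=0 (dimerization-deficient
                       hub; used to isolate K7).
    """

    MONOMER_DIMER = "MONOMER_DIMER"
    SINGLE_SITE = "SINGLE_SITE"
    TWO_MODE = "TWO_MODE"
    MULTI_EQ = "MULTI_EQ"
    TERNARY = "TERNARY"
    TERNARY_MONOMERIC = "TERNARY_MONOMERIC"


#: Equilibrium-constant names active in each scheme.  The paired enthalpy
#: dH_<x> is active exactly when K_<x> is.
ACTIVE_CONSTANTS: dict[SchemeId, tuple[str, ...]] = {
    SchemeId.MONOMER_DIMER: ("K_sc",),
    SchemeId.SINGLE_SITE: ("K3",),
    SchemeId.TWO_MODE: ("K3", "K4"),
    SchemeId.MULTI_EQ: ("K_sc", "K1", "K2", "K3", "K4"),
    SchemeId.TERNARY: ("K_sc", "K1", "K2", "K3", "K4", "K5", "K6", "K7"),
    SchemeId.TERNARY_MONOMERIC: ("K3", "K4", "K5", "K7"),
}

#: Units of each constant: termolecular steps are tabulated in M^-2.
CONSTANT_UNITS: dict[str, str] = {
    "K_sc": "M^-1",
    "K1": "M^-1",
    "K2": "M^-2",
    "K3": "M^-1",
    "K4": "M^-2",
    "K5": "M^-1",
    "K6": "M^-1",
    "K7": "M^-1",
}

_K_NAMES = ("K_sc", "K1", "K2", "K3", "K4", "K5", "K6", "K7")
_DH_NAMES = ("dH_sc", "dH1", "dH2", "dH3", "dH4", "dH5", "dH6", "dH7")


def dh_name_for(k_name: str) -> str:
    """Enthalpy field paired with an equilibrium-constant field."""
    return "dH_sc" if k_name == "K_sc" else "dH" + k_name[1:]


@dataclass(frozen=True)
class ThermoScheme:
    """A reaction scheme with its equilibrium constants and enthalpies.

    Reaction steps (A = hub, B = karyopherin, C = partner):

    ====== ======================= ======= =================================
    K      step                    units   meaning
    ====== ======================= ======= =================================
    K_sc   2A <-> A2               M^-1    hub homodimerization
    K1     A2 + B <-> A2B          M^-1    dimer binds one Kap
    K2     A2 + 2B <-> A2B2        M^-2    dimer binds two Kaps
    K3     A + B <-> AB            M^-1    monomer binds Kap 1:1
    K4     2A + B <-> A2*B         M^-2    one Kap bridges two monomers
    K5     C on Kap-free hub site  M^-1    partner binds unliganded hub
    K6     C on A2B / A2B2 site    M^-1    partner binds Kap-loaded dimer
    K7     C on AB / A2*B site     M^-1    partner binds Kap-loaded monomer
    ====== ======================= ======= =================================

    K5-K7 are per-site constants: species with two hub N-terminal sites
    carry a statistical factor of 2 for the first C and the squared
    constant for the second.  Enthalpies are in cal/mol and pair with the
    constant of the same index; constants not used by ``scheme_id`` must be
    exactly zero.
    """

    scheme_id: SchemeId
    K_sc: float = 0.0
    K1: float = 0.0
    K2: float = 0.0
    K3: float = 0.0
    K4: float = 0.0
    K5: float = 0.0
    K6: float = 0.0
    K7: float = 0.0
    dH_sc: float = 0.0
    dH1: float = 0.0
    dH2: float = 0.0
    dH3: float = 0.0
    dH4: float = 0.0
    dH5: float = 0.0
    dH6: float = 0.0
    dH7: float = 0.0
    T: float = T_DEFAULT
    R: float = field(default=R_CAL)

    def __post_init__(self) -> None:
        if self.T <= 0:
            raise InvalidParameterError(f"temperature must be positive, got {self.T}")
        active = ACTIVE_CONSTANTS[self.scheme_id]
        for k in _K_NAMES:
            v = getattr(self, k)
            if v < 0:
                raise InvalidParameterError(f"{k} must be >= 0, got {v}")
            if k not in active and v != 0.0:
                raise InvalidParameterError(
                    f"{k} is not used by scheme {self.scheme_id.value} and must be 0"
                )
        for k in _K_NAMES:
            dh = dh_name_for(k)
            if k not in active and getattr(self, dh) != 0.0:
                raise InvalidParameterError(
                    f"{dh} is not used by scheme {self.scheme_id.value} and must be 0"
                )

    @property
    def RT(self) -> float:
        """R*T in cal/mol."""
        return self.R * self.T

    def active_parameters(self) -> tuple[str, ...]:
        """Names of the K and dH parameters the scheme actually uses."""
        ks = ACTIVE_CONSTANTS[self.scheme_id]
        return ks + tuple(dh_name_for(k) for k in ks)

    def with_updates(self, **kwargs: float) -> "ThermoScheme":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class StateFunctions:
    """State functions of one binding step, reported in kcal/mol.

    ``dG = -R*T*ln(K)`` with K taken as its numeric value in the tabulated
    unit (M^-1 or M^-2), and ``TdS = dH - dG`` exactly.
    """

    K: float
    dG: float
    dH: float
    TdS: float


def derive_state_functions(K: float, dH: float, scheme: ThermoScheme) -> StateFunctions:
    """Free energy and entropic term of a step from its K and enthalpy.

    Parameters
    ----------
    K : equilibrium constant, numeric value in M^-1 or M^-2.
    dH : standard enthalpy in kcal/mol.
    scheme : supplies R and T.

    Returns
    -------
    StateFunctions with dG and TdS in kcal/mol.
    """
    if K <= 0:
        raise InvalidParameterError(f"K must be positive to take ln, got {K}")
    dG = -scheme.RT * math.log(K) / KCAL
    return StateFunctions(K=K, dG=dG, dH=dH, TdS=dH - dG)


def fold_change(
    K_ref: float,
    K_alt: float,
    unit_ref: str = "M^-1",
    unit_alt: str = "M^-1",
) -> float:
    """Affinity ratio K_ref / K_alt between two same-unit constants."""
    if unit_ref != unit_alt:
        raise InvalidComparisonError(
            f"cannot compare constants in {unit_ref} and {unit_alt}"
        )
    if K_ref <= 0 or K_alt <= 0:
        raise InvalidParameterError("fold_change requires positive constants")
    return K_ref / K_alt
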