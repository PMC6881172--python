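"""Species population distributions versus titrant:hub molar ratio.

Populations are expressed as fractions of hub monomer equivalents: a
species containing a hub dimer contributes two monomer equivalents, so the
fractions of mutually exclusive hub states always sum to one.  (A
per-particle weighting is available via ``per="particle"``.)
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .equilibrium import SpeciesState, solve_species, solve_ternary
from .errors import InvalidParameterError
from .thermo import ThermoScheme

#: (A, B, C) stoichiometry of each species field.
STOICHIOMETRY: dict[str, tuple[int, int, int]] = {
    "free_A": (1, 0, 0),
    "free_B": (0, 1, 0),
    "free_C": (0, 0, 1),
    "A2": (2, 0, 0),
    "AB": (1, 1, 0),
    "A2B": (2, 1, 0),
    "A2B2": (2, 2, 0),
    "A2starB": (2, 1, 0),
    "AC": (1, 0, 1),
    "A2C": (2, 0, 1),
    "A2C2": (2, 0, 2),
    "ABC": (1, 1, 1),
    "A2BC": (2, 1, 1),
    "A2BC2": (2, 1, 2),
    "A2B2C": (2, 2, 1),
    "A2B2C2": (2, 2, 2),
    "A2starBC": (2, 1, 1),
    "A2starBC2": (2, 1, 2),
}

_HUB_SPECIES = [name for name, (a, _, _) in STOICHIOMETRY.items() if a > 0 and name != "free_B" and name != "free_C"]

#: Species-level classification of hub states by bound ligand types.
_HUB_STATE_GROUPS: dict[str, tuple[str, ...]] = {
    "free": ("free_A", "A2"),
    "B_only": ("AB", "A2B", "A2B2", "A2starB"),
    "C_only": ("AC", "A2C", "A2C2"),
    "B_and_C": (
        "ABC",
        "A2BC",
        "A2BC2",
        "A2B2C",
        "A2B2C2",
        "A2starBC",
        "A2starBC2",
    ),
}

#: Kap-binding-mode grouping for two-component titrations (hub + Kap):
#: "AB" is the 1:1 complex, "A2*B" the bivalent 2:1 complex of two hub
#: monomers, "A2B"/"A2B2" the preformed-dimer complexes.
_KAP_MODE_GROUPS: dict[str, tuple[str, ...]] = {
    "free": ("free_A", "A2"),
    "AB": ("AB",),
    "A2*B": ("A2starB",),
    "A2B": ("A2B",),
    "A2B2": ("A2B2",),
}

GROUPINGS = ("species", "hub_state", "kap_modes")


@dataclass(frozen=True)
class PopulationGrid:
    """Fractional hub populations on a molar-ratio grid.

    ``fractions`` maps a species or group name to its fraction array —
    1-D over ``ratio_axis`` for curves, 2-D (len(ratio_axis) x
    len(second_axis)) for surfaces.  ``total_hub`` is the fixed hub
    concentration (molar) the grid was computed at.
    """

    ratio_axis: np.ndarray
    fractions: dict[str, np.ndarray]
    total_hub: float
    second_axis: np.ndarray | None = None


def _hub_fraction(state: SpeciesState, names: tuple[str, ...], total_hub: float,
                  per: str) -> float:
    d = state.as_dict()
    if per == "monomer":
        return sum(STOICHIOMETRY[n][0] * d[n] for n in names) / total_hub
    if per == "particle":
        particles = sum(d[n] for n in _HUB_SPECIES)
        return sum(d[n] for n in names) / particles if particles > 0 else 0.0
    raise InvalidParameterError(f"unknown weighting {per!r}")


def population_curve(
    scheme: ThermoScheme,
    total_hub: float = 15e-6,
    ratio_axis: np.ndarray | None = None,
    grouping: str = "species",
    component: str = "B",
    per: str = "monomer",
) -> PopulationGrid:
    """Hub-state fractions versus titrant:hub molar ratio.

    For each ratio r the equilibrium is solved at a fixed hub concentration
    and a titrant concentration of r * total_hub (titrant = component B or
    C).  ``grouping`` selects per-species fractions or one of the named
    aggregations in :data:`GROUPINGS`.
    """
    if total_hub <= 0:
        raise InvalidParameterError("total_hub must be positive")
    if grouping not in GROUPINGS:
        raise InvalidParameterError(
            f"unknown grouping {grouping!r}; choose one of {GROUPINGS}"
        )
    if component not in ("B", "C"):
        raise InvalidParameterError("titrant component must be 'B' or 'C'")
    if ratio_axis is None:
        ratio_axis = np.linspace(0.0, 3.0, 101)
    ratio_axis = np.asarray(ratio_axis, dtype=float)
    if np.any(ratio_axis < 0):
        raise InvalidParameterError("molar ratios must be non-negative")

    if grouping == "species":
        groups = {name: (name,) for name in _HUB_SPECIES}
    elif grouping == "hub_state":
        groups = _HUB_STATE_GROUPS
    else:
        groups = _KAP_MODE_GROUPS

    fractions = {name: np.empty(len(ratio_axis)) for name in groups}
    for i, r in enumerate(ratio_axis):
        titrant = r * total_hub
        totals = (total_hub, titrant, 0.0) if component == "B" else (
            total_hub, 0.0, titrant)
        state = solve_species(*totals, scheme)
        for name, members in groups.items():
            fractions[name][i] = _hub_fraction(state, members, total_hub, per)
    return PopulationGrid(
        ratio_axis=ratio_axis, fractions=fractions, total_hub=total_hub
    )


def ternary_population_surface(
    scheme: ThermoScheme,
    total_hub: float = 15e-6,
    total_C_ratio_axis: np.ndarray | None = None,
    total_B_ratio_axis: np.ndarray | None = None,
) -> PopulationGrid:
    """Fraction of hub sites occupied by the partner C over a (C-ratio,
    B-ratio) grid — the allosteric-destabilization surface.

    ``fractions["hub_C_bound"][i, j]`` is the number of hub-bound C
    molecules per hub monomer at C = ratio_axis[i] * total_hub and
    B = second_axis[j] * total_hub.  With the Kap-loaded site constants
    weaker than the free-site constant, the surface decreases along the
    B axis at fixed C.
    """
    if total_hub <= 0:
        raise InvalidParameterError("total_hub must be positive")
    if total_C_ratio_axis is None:
        total_C_ratio_axis = np.linspace(0.0, 3.0, 101)
    if total_B_ratio_axis is None:
        total_B_ratio_axis = np.linspace(0.0, 3.0, 101)
    c_axis = np.asarray(total_C_ratio_axis, dtype=float)
    b_axis = np.asarray(total_B_ratio_axis, dtype=float)
    if np.any(c_axis < 0) or np.any(b_axis < 0):
        raise InvalidParameterError("molar ratios must be non-negative")

    frac = np.empty((len(c_axis), len(b_axis)))
    for i, rc in enumerate(c_axis):
        for j, rb in enumerate(b_axis):
            state = solve_ternary(
                total_hub, rb * total_hub, rc * total_hub, scheme
            )
            d = state.as_dict()
            bound_c = sum(
                STOICHIOMETRY[n][2] * d[n]
                for n in STOICHIOMETRY
                if STOICHIOMETRY[n][0] > 0 and STOICHIOMETRY[n][2] > 0
            )
            frac[i, j] = bound_c / total_hub
    return PopulationGrid(
        ratio_axis=c_axis,
        second_axis=b_axis,
        fractions={"hub_C_bound": frac},
        total_hub=total_hub,
    )
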