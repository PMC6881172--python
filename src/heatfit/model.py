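"""Per-injection heat forward model for titration calorimetry.

Each injection is treated as an equilibrium-to-equilibrium step: the
injected volume is assumed instantaneously mixed into the cell before an
equal volume of the mixture overflows (displacement), the new totals are
re-equilibrated, and the heat is the enthalpy-weighted change in "bond"
content of the cell with the standard trapezoidal correction for material
reacted in the displaced volume:

    q_i = V_cell * sum_k dH_k * ( [G_k]_i - [G_k]_{i-1} - v*[G_k]_syr
                                  + v*([G_k]_i + [G_k]_{i-1})/2 )

with v = V_inj/V_cell and [G_k] the concentration of formed bonds of step k
(see :func:`heatfit.equilibrium.bond_group_concentrations`).  The
``v*[G_k]_syr`` term subtracts bonds delivered pre-formed from the syringe,
which makes the same expression cover association titrations (syringe holds
a free component, the term vanishes) and dilution-driven dissociation
(concentrated self-associating titrant, where the term is the source of the
measured dissociation heat).  Exothermic events give negative q.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidDesignError, InvalidParameterError, SolverFailureError
from .equilibrium import bond_group_concentrations, solve_species
from .thermo import KCAL, SchemeId, T_DEFAULT, ThermoScheme

UL = 1e-6  # litres per microlitre
UM = 1e-6  # molar per micromolar
UCAL = 1e-6  # cal per microcalorie


@dataclass(frozen=True)
class TitrationExperiment:
    """Instrument geometry and compositions of a titration.

    Concentrations are molar and volumes litres; ``from_lab_units`` accepts
    the conventional uM / uL surface.  ``cell`` and ``syringe`` are total
    concentrations of components (A, B, C): the self-associating hub, the
    karyopherin, and the partner nucleoporin.
    """

    cell: tuple[float, float, float]
    syringe: tuple[float, float, float]
    V_cell: float = 202.8 * UL
    injections: tuple[float, ...] = tuple([2.0 * UL] * 20)
    T: float = T_DEFAULT
    direction_label: str = "forward"
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if self.V_cell <= 0:
            raise InvalidParameterError("V_cell must be positive")
        if len(self.injections) == 0:
            raise InvalidDesignError("at least one injection is required")
        for v in self.injections:
            if v <= 0:
                raise InvalidParameterError("every injection volume must be positive")
            if v > 0.2 * self.V_cell:
                raise InvalidDesignError(
                    "injection volume must be small relative to the cell"
                )
        if min(self.cell) < 0 or min(self.syringe) < 0:
            raise InvalidParameterError("concentrations must be non-negative")
        if max(self.syringe) == 0:
            raise InvalidDesignError("syringe must contain at least one component")

    @classmethod
    def from_lab_units(
        cls,
        cell_uM: tuple[float, float, float],
        syringe_uM: tuple[float, float, float],
        v_cell_ul: float = 202.8,
        n_injections: int = 20,
        v_inj_ul: float = 2.0,
        T: float = T_DEFAULT,
        direction_label: str = "forward",
    ) -> "TitrationExperiment":
        return cls(
            cell=tuple(c * UM for c in cell_uM),
            syringe=tuple(c * UM for c in syringe_uM),
            V_cell=v_cell_ul * UL,
            injections=tuple([v_inj_ul * UL] * n_injections),
            T=T,
            direction_label=direction_label,
        )

    def scaled(self, activity: float) -> "TitrationExperiment":
        """Experiment with all stated concentrations multiplied by an
        activity factor (effective-concentration correction)."""
        return TitrationExperiment(
            cell=tuple(c * activity for c in self.cell),
            syringe=tuple(c * activity for c in self.syringe),
            V_cell=self.V_cell,
            injections=self.injections,
            T=self.T,
            direction_label=self.direction_label,
            meta=dict(self.meta),
        )

    @property
    def injectant_index(self) -> int:
        """Index of the dominant syringe component (the titrant)."""
        return int(np.argmax(self.syringe))

    @property
    def cell_reference_index(self) -> int | None:
        """Index of the dominant initial cell component, or None for a
        buffer-only cell (dilution experiments)."""
        if max(self.cell) == 0:
            return None
        return int(np.argmax(self.cell))


@dataclass(frozen=True)
class Isotherm:
    """Per-injection heats with their molar-ratio axis.

    ``q`` is in ucal.  ``molar_ratio`` is the cumulative titrant:cell-
    component total-concentration ratio after each injection; for a
    buffer-only cell it falls back to the titrant concentration in the
    cell in uM.  ``normalized_q`` is kcal per mole of injectant.
    """

    q: np.ndarray
    molar_ratio: np.ndarray
    moles_injected: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "q", np.asarray(self.q, dtype=float))
        object.__setattr__(self, "molar_ratio", np.asarray(self.molar_ratio, dtype=float))
        object.__setattr__(
            self, "moles_injected", np.asarray(self.moles_injected, dtype=float)
        )
        if not (len(self.q) == len(self.molar_ratio) == len(self.moles_injected)):
            raise InvalidParameterError("isotherm arrays must have equal length")

    @property
    def normalized_q(self) -> np.ndarray:
        """Heats per mole of injectant, kcal/mol."""
        return self.q * UCAL / self.moles_injected / KCAL

    def __len__(self) -> int:
        return len(self.q)


def update_cell_totals(
    pre_injection_totals: tuple[float, float, float],
    experiment: TitrationExperiment,
    injection_index: int,
) -> tuple[float, float, float]:
    """Component totals after one injection under instantaneous mixing.

    Each total becomes old*(1 - v) + syringe*v with v = V_inj/V_cell: the
    injected material mixes fully before an equal volume of the mixture is
    displaced from the active cell volume.
    """
    if not 0 <= injection_index < len(experiment.injections):
        raise IndexError(f"injection index {injection_index} out of range")
    v = experiment.injections[injection_index] / experiment.V_cell
    return tuple(
        old * (1.0 - v) + syr * v
        for old, syr in zip(pre_injection_totals, experiment.syringe)
    )


def _molar_ratio_axis(
    experiment: TitrationExperiment, totals_trace: list[tuple[float, float, float]]
) -> np.ndarray:
    inj = experiment.injectant_index
    ref = experiment.cell_reference_index
    out = []
    for tot in totals_trace[1:]:
        if ref is None or tot[ref] == 0:
            out.append(tot[inj] / UM)  # dilution design: plot vs cell conc (uM)
        else:
            out.append(tot[inj] / tot[ref])
    return np.asarray(out)


def molar_ratio_for(experiment: TitrationExperiment) -> np.ndarray:
    """Molar-ratio axis implied by a design alone (no heats needed)."""
    totals = tuple(experiment.cell)
    trace = [totals]
    for i in range(len(experiment.injections)):
        totals = update_cell_totals(totals, experiment, i)
        trace.append(totals)
    return _molar_ratio_axis(experiment, trace)


def moles_injected_for(experiment: TitrationExperiment) -> np.ndarray:
    """Moles of the dominant syringe component delivered per injection."""
    inj = experiment.injectant_index
    return np.asarray(
        [experiment.syringe[inj] * v_inj for v_inj in experiment.injections]
    )


def injection_heats(experiment: TitrationExperiment, scheme: ThermoScheme) -> Isotherm:
    """Forward-simulate the per-injection heats of a titration.

    Solves the scheme's equilibrium in the syringe and in the cell after
    every injection, and accumulates the enthalpy-weighted bond changes
    with the displacement correction described in the module docstring.
    """
    dh = {name: getattr(scheme, name) for name in (
        "dH_sc", "dH1", "dH2", "dH3", "dH4", "dH5", "dH6", "dH7")}

    try:
        syr_state = solve_species(*experiment.syringe, scheme)
    except SolverFailureError as exc:
        raise SolverFailureError(f"syringe equilibrium failed: {exc}") from exc
    g_syr = bond_group_concentrations(syr_state)

    totals = tuple(experiment.cell)
    state = solve_species(*totals, scheme)
    g_prev = bond_group_concentrations(state)

    q = np.empty(len(experiment.injections))
    totals_trace = [totals]
    for i, v_inj in enumerate(experiment.injections):
        v = v_inj / experiment.V_cell
        totals = update_cell_totals(totals, experiment, i)
        totals_trace.append(totals)
        try:
            state = solve_species(*totals, scheme)
        except SolverFailureError as exc:
            raise SolverFailureError(f"injection {i + 1}: {exc}") from exc
        g = bond_group_concentrations(state)
        heat_cal = experiment.V_cell * sum(
            dh[k]
            * (g[k] - g_prev[k] - v * g_syr[k] + v * (g[k] + g_prev[k]) / 2.0)
            for k in dh
        )
        q[i] = heat_cal / UCAL
        g_prev = g

    inj = experiment.injectant_index
    moles = np.asarray(
        [experiment.syringe[inj] * v_inj for v_inj in experiment.injections]
    )
    return Isotherm(
        q=q,
        molar_ratio=_molar_ratio_axis(experiment, totals_trace),
        moles_injected=moles,
    )


def dissociation_isotherm(
    experiment: TitrationExperiment, K_sc: float, dH_sc: float
) -> Isotherm:
    """Heats of injecting a concentrated self-associating species into buffer.

    The syringe carries the hub at high concentration (largely dimeric);
    each injection dilutes it into the cell, shifting the monomer-dimer
    equilibrium.  The heat of injection i is -dH_sc * V_cell * lambda_i
    (plus the displacement correction), where lambda_i is the dimer
    concentration lost to dissociation: syringe- and cell-carried dimer
    after mixing minus dimer at the new equilibrium.  dH_sc is in cal/mol;
    with endothermic dimer formation the dissociation heats are negative.
    """
    if max(experiment.cell) != 0:
        raise InvalidDesignError(
            "dissociation design requires a buffer-only cell (all totals zero)"
        )
    nonzero = [i for i, c in enumerate(experiment.syringe) if c > 0]
    if nonzero != [0]:
        raise InvalidDesignError(
            "dissociation design requires the syringe to contain component A only"
        )
    scheme = ThermoScheme(
        scheme_id=SchemeId.MONOMER_DIMER, K_sc=K_sc, dH_sc=dH_sc, T=experiment.T
    )
    return injection_heats(experiment, scheme)
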