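"""Forward heat model: displacement bookkeeping, signs, discretization."""

import math

import numpy as np
import pytest

from heatfit import (
    InvalidDesignError,
    SchemeId,
    ThermoScheme,
    TitrationExperiment,
    dissociation_isotherm,
    injection_heats,
    update_cell_totals,
)
from heatfit import bond_group_concentrations, solve_species
from heatfit.model import UL, UM

V = 2.0 / 202.8  # default injection-to-cell volume ratio


def test_update_totals_steady_state_when_syringe_matches_cell():
    exp = TitrationExperiment.from_lab_units((15, 5, 0), (15, 5, 0))
    assert update_cell_totals(exp.cell, exp, 0) == pytest.approx(exp.cell, rel=1e-14)


def test_update_totals_hand_value():
    """15 uM cell, 150 uM syringe, 2/202.8 uL: 15*0.990138 + 150*0.009862."""
    exp = TitrationExperiment.from_lab_units((15, 0, 0), (150, 0, 0))
    new = update_cell_totals(exp.cell, exp, 0)
    assert new[0] / UM == pytest.approx(16.33, abs=0.005)


def test_update_totals_buffer_syringe_dilutes():
    exp = TitrationExperiment.from_lab_units((15, 0, 0), (0, 150, 0))
    new = update_cell_totals(exp.cell, exp, 0)
    assert new[0] == pytest.approx(15 * UM * (1 - V), rel=1e-14)
    with pytest.raises(IndexError):
        update_cell_totals(exp.cell, exp, len(exp.injections))


def test_zero_enthalpies_give_zero_heat(standard_forward):
    sch = ThermoScheme(scheme_id=SchemeId.MULTI_EQ, K_sc=1e4, K1=5.6e7,
                       K2=3.9e14, K3=4.2e6, K4=1.9e11)
    iso = injection_heats(standard_forward, sch)
    assert np.all(iso.q == 0.0)


def test_first_injection_heat_in_stoichiometric_limit():
    """With saturating K and excess cell hub, every injected mole binds:
    q1 = dH * moles injected (negative for exothermic binding)."""
    sch = ThermoScheme(scheme_id=SchemeId.SINGLE_SITE, K3=1e10, dH3=-10_000.0)
    exp = TitrationExperiment.from_lab_units((150, 0, 0), (0, 150, 0))
    iso = injection_heats(exp, sch)
    moles = 150 * UM * 2 * UL
    assert iso.q[0] * 1e-6 == pytest.approx(-10_000.0 * moles, rel=5e-3)
    assert iso.normalized_q[0] == pytest.approx(-10.0, rel=5e-3)


def test_multi_equilibrium_isotherm_is_biphasic(standard_forward, multi_eq_scheme):
    """Hub-into-excess-Kap titration starts endothermic (cooperative 2:1
    dimer binding) and turns exothermic (1:1 mode) — the published
    fingerprint of the coupled scheme."""
    iso = injection_heats(standard_forward, multi_eq_scheme)
    assert iso.q[0] > 0.5
    assert iso.q.min() < -0.5
    signs = np.sign(iso.q)
    flips = np.sum(signs[:-1] != signs[1:])
    assert flips == 1  # endo -> exo, single crossover


def test_molar_ratio_axis_is_cumulative(standard_forward):
    iso = injection_heats(
        standard_forward, ThermoScheme(scheme_id=SchemeId.SINGLE_SITE, K3=1e6)
    )
    assert np.all(np.diff(iso.molar_ratio) > 0)
    assert iso.molar_ratio[0] == pytest.approx(150 * V / (15 * (1 - V)), rel=1e-12)


# -- dissociation by dilution -------------------------------------------------

def _dilution_experiment(syringe_uM=300.0, n=20):
    return TitrationExperiment.from_lab_units(
        (0.0, 0.0, 0.0), (syringe_uM, 0.0, 0.0), n_injections=n,
        direction_label="dilution",
    )


def test_dissociation_zero_constant_gives_zero_heat():
    iso = dissociation_isotherm(_dilution_experiment(), 0.0, 6500.0)
    assert np.all(iso.q == 0.0)


@pytest.mark.parametrize("dH_sc", [6500.0, -6500.0])
def test_dissociation_heat_sign_opposes_formation_enthalpy(dH_sc):
    iso = dissociation_isotherm(_dilution_experiment(), 1e4, dH_sc)
    assert np.all(np.sign(iso.q) == -np.sign(dH_sc))


def test_dissociation_first_injection_matches_hand_lambda():
    """lambda_1 from the closed-form dimer concentrations: dimer arriving
    from the syringe minus dimer surviving at the diluted equilibrium."""
    K, dH = 1e4, 6500.0
    syr = 300 * UM
    iso = dissociation_isotherm(_dilution_experiment(300.0), K, dH)

    def dimer(total):  # explicit quadratic-root form
        if total == 0:
            return 0.0
        free = (-1.0 + math.sqrt(1.0 + 8.0 * K * total)) / (4.0 * K)
        return K * free * free

    cell_total = syr * V
    lam = V * dimer(syr) - dimer(cell_total)  # pre-equilibration minus post
    v_cell = 202.8 * UL
    expected = dH * v_cell * (-lam + V * dimer(cell_total) / 2.0)
    assert iso.q[0] == pytest.approx(expected / 1e-6, rel=1e-10)
    assert iso.q[0] < 0  # endothermic formation => exothermic dissociation


def test_dissociation_requires_buffer_cell_and_pure_syringe():
    bad_cell = TitrationExperiment.from_lab_units((5, 0, 0), (300, 0, 0))
    with pytest.raises(InvalidDesignError):
        dissociation_isotherm(bad_cell, 1e4, 6500.0)
    bad_syr = TitrationExperiment.from_lab_units((0, 0, 0), (300, 10, 0))
    with pytest.raises(InvalidDesignError):
        dissociation_isotherm(bad_syr, 1e4, 6500.0)


# -- state-function / discretization properties -------------------------------

@pytest.mark.parametrize("scheme_fixture", ["single_site_scheme", "multi_eq_scheme"])
def test_cumulative_heat_is_discretization_stable(scheme_fixture, request):
    """Halving injection volumes (doubling their number) changes the
    cumulative heat by < 0.1% of the total absolute heat.  (For the
    biphasic scheme the plain cumulative sum nearly cancels between the
    endothermic and exothermic phases, so the change is normalized by the
    heat scale rather than by the cancelling sum.)"""
    scheme = request.getfixturevalue(scheme_fixture)
    coarse = TitrationExperiment.from_lab_units((15, 0, 0), (0, 150, 0),
                                                n_injections=20, v_inj_ul=2.0)
    fine = TitrationExperiment.from_lab_units((15, 0, 0), (0, 150, 0),
                                              n_injections=40, v_inj_ul=1.0)
    q_coarse = injection_heats(coarse, scheme).q
    q_fine = injection_heats(fine, scheme).q
    assert abs(q_fine.sum() - q_coarse.sum()) < 1e-3 * np.abs(q_coarse).sum()


def test_cumulative_heat_equals_state_function_difference(multi_eq_scheme):
    """Sum of injection heats equals the enthalpy-weighted difference in
    bond content between final and initial cell states, corrected for
    delivered and displaced material (independent re-walk of the states)."""
    exp = TitrationExperiment.from_lab_units((15, 0, 0), (0, 150, 0))
    iso = injection_heats(exp, multi_eq_scheme)

    dh = {k: getattr(multi_eq_scheme, k)
          for k in ("dH_sc", "dH1", "dH2", "dH3", "dH4", "dH5", "dH6", "dH7")}
    g_syr = bond_group_concentrations(solve_species(*exp.syringe, multi_eq_scheme))
    totals = tuple(exp.cell)
    groups = [bond_group_concentrations(solve_species(*totals, multi_eq_scheme))]
    for i in range(len(exp.injections)):
        totals = update_cell_totals(totals, exp, i)
        groups.append(bond_group_concentrations(solve_species(*totals, multi_eq_scheme)))
    total = 0.0
    for k, dhk in dh.items():
        delivered = sum(
            (v / exp.V_cell) * g_syr[k] for v in exp.injections
        )
        displaced = sum(
            (v / exp.V_cell) * (groups[i][k] + groups[i + 1][k]) / 2.0
            for i, v in enumerate(exp.injections)
        )
        total += dhk * exp.V_cell * (
            groups[-1][k] - groups[0][k] - delivered + displaced
        )
    assert iso.q.sum() == pytest.approx(total / 1e-6, rel=1e-6)
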