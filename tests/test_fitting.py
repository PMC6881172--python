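"""Global fitting: residuals, recovery, uncertainties, model comparison."""

import numpy as np
import pytest

from heatfit import (
    FitSpec,
    InvalidComparisonError,
    InvalidParameterError,
    Isotherm,
    NoiseModel,
    SchemeId,
    compare_models,
    fit_global,
    generate_titration,
    injection_heats,
    residuals,
)
from heatfit.thermo import KCAL

from conftest import noise_free_datasets


def _single_site_spec(scheme, exp, iso=None, **kwargs):
    iso = iso if iso is not None else injection_heats(exp, scheme)
    return FitSpec(
        datasets=[(exp, iso)],
        scheme_id=SchemeId.SINGLE_SITE,
        free_parameters=("K3", "dH3"),
        **kwargs,
    )


def test_residuals_vanish_at_generating_truth(single_site_scheme, standard_forward):
    spec = _single_site_spec(single_site_scheme, standard_forward)
    x = spec.pack(
        {"K3": single_site_scheme.K3, "dH3": single_site_scheme.dH3},
        [{"activity": 1.0, "dilution_ucal": 0.0}],
    )
    assert np.allclose(residuals(spec, x), 0.0, atol=1e-12)


def test_dilution_local_absorbs_flat_offset(single_site_scheme, standard_forward):
    """A constant +1 ucal on every injection is explained entirely by the
    per-dataset dilution nuisance parameter."""
    iso = injection_heats(standard_forward, single_site_scheme)
    shifted = Isotherm(
        q=iso.q + 1.0, molar_ratio=iso.molar_ratio, moles_injected=iso.moles_injected
    )
    spec = _single_site_spec(
        single_site_scheme, standard_forward, iso=shifted, fit_dilution=True
    )
    res = fit_global(spec, seed=0)
    assert res.chi2 < 1e-10
    assert res.local_estimates[0]["dilution_ucal"] == pytest.approx(1.0, abs=1e-4)


def test_chi2_increases_away_from_truth(single_site_scheme, standard_forward):
    spec = _single_site_spec(single_site_scheme, standard_forward)
    truth = {"K3": single_site_scheme.K3, "dH3": single_site_scheme.dH3}
    loc = [{"activity": 1.0, "dilution_ucal": 0.0}]
    chi2_true = np.sum(residuals(spec, spec.pack(truth, loc)) ** 2)
    bumped = dict(truth, K3=truth["K3"] * 1.1)
    chi2_bump = np.sum(residuals(spec, spec.pack(bumped, loc)) ** 2)
    assert chi2_bump > chi2_true + 1e-6


def test_noise_free_single_site_recovery(single_site_scheme, standard_forward, table):
    """Round-trip identity: the fit returns the generating constants to
    three significant figures, with near-zero SDs on exact data."""
    spec = _single_site_spec(single_site_scheme, standard_forward)
    res = fit_global(spec, seed=1)
    assert res.estimates["K3"] == pytest.approx(table["3"]["K"], rel=1e-3)
    assert res.estimates["dH3"] / KCAL == pytest.approx(table["3"]["dH"], rel=1e-3)
    assert res.sd["K3"] < 1e-6 * res.estimates["K3"]
    assert res.sd["dH3"] < 1e-6 * abs(res.estimates["dH3"])


def test_forward_reverse_joint_fit_matches_single_direction(
    two_mode_scheme, standard_forward, standard_reverse, table
):
    """Forward and reverse designs carry the same thermodynamics: jointly
    or separately fitted, the noise-free truth is recovered."""
    datasets = noise_free_datasets(two_mode_scheme, [standard_forward, standard_reverse])
    for subset in ([datasets[0]], [datasets[1]], datasets):
        spec = FitSpec(
            datasets=subset,
            scheme_id=SchemeId.TWO_MODE,
            free_parameters=("K3", "dH3", "K4", "dH4"),
        )
        res = fit_global(spec, seed=3)
        assert res.estimates["K3"] == pytest.approx(table["2a"]["K"], rel=1e-3)
        assert res.estimates["K4"] == pytest.approx(table["2b"]["K"], rel=1e-3)


def test_activity_factor_is_identifiable_with_fixed_constants(
    single_site_scheme, standard_forward
):
    """Data simulated at 85% active protein, fitted with a free activity
    factor, recovers 0.85.  The binding constant is fixed at its known
    value, as in the published global-analysis practice: a single activity
    factor scaling every concentration is exactly degenerate with (K, dH)
    -> (aK, a*dH) when all constants float, so activity is identifiable
    only against constants pinned by other experiments."""
    iso = generate_titration(
        standard_forward, single_site_scheme,
        NoiseModel(sigma_q=0.0, activity_true=0.85, seed=0),
    )
    spec = FitSpec(
        datasets=[(standard_forward, iso)],
        scheme_id=SchemeId.SINGLE_SITE,
        free_parameters=("dH3",),
        fixed_parameters={"K3": single_site_scheme.K3},
        fit_activity=True,
    )
    res = fit_global(spec, seed=2)
    assert res.local_estimates[0]["activity"] == pytest.approx(0.85, abs=0.02)
    assert res.estimates["dH3"] == pytest.approx(single_site_scheme.dH3, rel=1e-3)


def test_noisy_recovery_within_two_reported_sds(single_site_scheme, standard_forward):
    iso = generate_titration(
        standard_forward, single_site_scheme, NoiseModel(sigma_q=0.2, seed=11)
    )
    spec = _single_site_spec(single_site_scheme, standard_forward, iso=iso)
    res = fit_global(spec, seed=11)
    assert abs(res.estimates["K3"] - single_site_scheme.K3) < 2 * res.sd["K3"]


def test_duplicated_datasets_shrink_sds_by_sqrt2(single_site_scheme, standard_forward):
    """Information additivity: two identical copies of a dataset halve the
    parameter variance."""
    iso = generate_titration(
        standard_forward, single_site_scheme, NoiseModel(sigma_q=0.3, seed=5)
    )
    one = _single_site_spec(single_site_scheme, standard_forward, iso=iso)
    two = FitSpec(
        datasets=[(standard_forward, iso), (standard_forward, iso)],
        scheme_id=SchemeId.SINGLE_SITE,
        free_parameters=("K3", "dH3"),
    )
    sd1 = fit_global(one, seed=5).sd["K3"]
    sd2 = fit_global(two, seed=5).sd["K3"]
    assert sd1 / sd2 == pytest.approx(np.sqrt(2.0), rel=0.15)


def test_compare_models_identity_and_nesting(single_site_scheme, standard_forward):
    iso = generate_titration(
        standard_forward, single_site_scheme, NoiseModel(sigma_q=0.25, seed=9)
    )
    spec_small = _single_site_spec(single_site_scheme, standard_forward, iso=iso)
    spec_large = _single_site_spec(
        single_site_scheme, standard_forward, iso=iso, fit_dilution=True
    )
    fit_small = fit_global(spec_small, seed=9)
    fit_large = fit_global(spec_large, seed=9)
    assert compare_models(fit_small, fit_small).chi2_ratio == 1.0
    # nesting: the model with strictly more freedom cannot fit worse
    assert compare_models(fit_small, fit_large).chi2_ratio <= 1.0 + 1e-9


def test_compare_models_rejects_different_data(single_site_scheme, standard_forward):
    iso = injection_heats(standard_forward, single_site_scheme)
    shifted = Isotherm(q=iso.q + 3.0, molar_ratio=iso.molar_ratio,
                       moles_injected=iso.moles_injected)
    fit_a = fit_global(
        _single_site_spec(single_site_scheme, standard_forward, iso=iso), seed=0
    )
    fit_b = fit_global(
        _single_site_spec(single_site_scheme, standard_forward, iso=shifted,
                          fit_dilution=True),
        seed=0,
    )
    with pytest.raises(InvalidComparisonError):
        compare_models(fit_a, fit_b)


def test_spec_validation_errors(single_site_scheme, standard_forward):
    iso = injection_heats(standard_forward, single_site_scheme)
    with pytest.raises(InvalidParameterError):  # overlap free/fixed
        FitSpec([(standard_forward, iso)], SchemeId.SINGLE_SITE,
                ("K3", "dH3"), fixed_parameters={"K3": 1e6})
    with pytest.raises(InvalidParameterError):  # dH3 unassigned
        FitSpec([(standard_forward, iso)], SchemeId.SINGLE_SITE, ("K3",))
    with pytest.raises(InvalidParameterError):  # inactive parameter
        FitSpec([(standard_forward, iso)], SchemeId.SINGLE_SITE,
                ("K3", "dH3", "K5", "dH5"))
    with pytest.raises(InvalidParameterError):  # no datasets
        FitSpec([], SchemeId.SINGLE_SITE, ("K3", "dH3"))
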