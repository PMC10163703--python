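"""BMD/BMDL: closed forms, profile likelihood, bootstrap and model retention."""

from types import SimpleNamespace

import numpy as np
import pytest
from scipy.optimize import brentq

from bmdkit import (
    BenchmarkConfig,
    DoseResponseSpec,
    IndividualDataset,
    bmd_from_spec,
    bmdl_closed_form,
    bmdl_parametric_bootstrap,
    bmdl_profile_likelihood,
    evaluate_f,
    fit_kpower,
    fit_linear,
    fit_piecewise,
    generate,
    select_models,
)
from conftest import linear_truth, noiseless_dataset, uniform_config


# -- BMD point estimates ------------------------------------------------------


@pytest.mark.parametrize(
    "spec, expected",
    [
        (DoseResponseSpec.linear(-0.05), 2.1072),
        (DoseResponseSpec.hockey(-0.05, gamma=10.0), 12.1072),
        (DoseResponseSpec.kpower(-0.01, K=2.0), 3.2459),
        (DoseResponseSpec.piecewise(-0.02, -0.1, d0=5.0), 5.0536),
    ],
)
def test_bmd_closed_forms(spec, expected):
    bmd = bmd_from_spec(spec, 0.10)
    assert bmd == pytest.approx(expected, abs=5e-5)
    # independent root-finding oracle on f(d) = log(1 - BMR)
    root = brentq(lambda d: evaluate_f(spec, d) - np.log(0.9), 1e-9, 1e3,
                  xtol=1e-12)
    assert bmd == pytest.approx(root, abs=1e-8)


@pytest.mark.parametrize(
    "spec",
    [
        DoseResponseSpec.linear(0.02),
        DoseResponseSpec.kpower(0.0, K=2.0),
        DoseResponseSpec.piecewise(-5e-4, 0.01, d0=100.0),  # BMD above break, b2 >= 0
    ],
)
def test_bmd_undefined_for_non_adverse_slopes(spec):
    assert np.isnan(bmd_from_spec(spec, 0.10))


def test_bmd_bmr_ratio_is_log_ratio():
    ratio = np.log(0.95) / np.log(0.90)
    for spec in (DoseResponseSpec.linear(-0.034), DoseResponseSpec.kpower(-0.02, K=1.0)):
        assert bmd_from_spec(spec, 0.05) / bmd_from_spec(spec, 0.10) == pytest.approx(
            ratio, rel=1e-12
        )


# -- closed-form BMDL ---------------------------------------------------------


def test_closed_form_zero_uncertainty_limit():
    """With a perfect fit (se = 0) the BMDL collapses onto the BMD."""
    data = noiseless_dataset(DoseResponseSpec.linear(-0.05))
    res = bmdl_closed_form(fit_linear(data), BenchmarkConfig(bmr=0.10))
    assert res.bmd == pytest.approx(2.1072, abs=5e-5)
    assert res.bmdl == pytest.approx(res.bmd, rel=1e-6)


def test_closed_form_bmdl_ratio(noisy_linear_data):
    fit = fit_linear(noisy_linear_data)
    b5 = bmdl_closed_form(fit, BenchmarkConfig(bmr=0.05)).bmdl
    b10 = bmdl_closed_form(fit, BenchmarkConfig(bmr=0.10)).bmdl
    assert b5 / b10 == pytest.approx(np.log(0.95) / np.log(0.90), rel=1e-12)


def test_closed_form_requires_linear_in_parameters(noisy_linear_data):
    with pytest.raises(ValueError, match="linear in its parameters"):
        bmdl_closed_form(fit_kpower(noisy_linear_data), BenchmarkConfig())


def test_closed_form_undefined_when_lower_slope_nonnegative():
    rng = np.random.default_rng(0)
    d = rng.uniform(0, 20, 100)
    y = 1.0 + 0.05 * d + 0.1 * rng.standard_normal(100)  # protective slope
    res = bmdl_closed_form(
        fit_linear(IndividualDataset(y=y, dose=d)), BenchmarkConfig(bmr=0.10)
    )
    assert np.isnan(res.bmdl) and "undefined" in res.diagnostics
    assert not res.defined


def test_bmdl_below_bmd_all_methods(noisy_linear_data):
    fit = fit_linear(noisy_linear_data)
    cf = bmdl_closed_form(fit, BenchmarkConfig(bmr=0.10))
    pl = bmdl_profile_likelihood(
        noisy_linear_data, "linear", BenchmarkConfig(bmr=0.10, method="profile_likelihood")
    )
    bs = bmdl_parametric_bootstrap(
        noisy_linear_data, "linear",
        BenchmarkConfig(bmr=0.10, method="parametric_bootstrap", n_boot=200, seed=1),
    )
    for res in (cf, pl, bs):
        assert res.defined
        assert res.bmdl <= res.bmd


# -- profile likelihood -------------------------------------------------------


def test_chi_square_cutoff_constant():
    from bmdkit import CHI2_1_90

    assert round(CHI2_1_90, 2) == 2.71


@pytest.mark.parametrize("family, d0", [("linear", None), ("piecewise", 10.0),
                                        ("kpower", None)])
def test_profile_deviance_at_bmdl_equals_cutoff(noisy_linear_data, family, d0):
    from bmdkit import CHI2_1_90

    res = bmdl_profile_likelihood(
        noisy_linear_data, family,
        BenchmarkConfig(bmr=0.10, method="profile_likelihood"), d0=d0,
    )
    assert res.diagnostics["deviance_at_bmdl"] == pytest.approx(CHI2_1_90, abs=1e-3)
    assert res.bmdl < res.bmd


def test_profile_agrees_with_closed_form_piecewise():
    truth_spec = DoseResponseSpec.piecewise(-0.03, -0.08, d0=10.0)
    from bmdkit import ModelParameters

    truth = ModelParameters(1.0, np.empty(0), truth_spec, 0.25)
    data = generate(uniform_config(2000, truth, high=30.0), seed=4)
    cf = bmdl_closed_form(fit_piecewise(data, d0=10.0), BenchmarkConfig(bmr=0.10))
    pl = bmdl_profile_likelihood(
        data, "piecewise", BenchmarkConfig(bmr=0.10, method="profile_likelihood"),
        d0=10.0,
    )
    assert pl.bmdl == pytest.approx(cf.bmdl, rel=0.02)


# -- parametric bootstrap -----------------------------------------------------


def test_bootstrap_deterministic_under_seed(noisy_linear_data):
    config = BenchmarkConfig(bmr=0.10, method="parametric_bootstrap", n_boot=150,
                             seed=42)
    r1 = bmdl_parametric_bootstrap(noisy_linear_data, "linear", config)
    r2 = bmdl_parametric_bootstrap(noisy_linear_data, "linear", config)
    assert r1.bmdl == r2.bmdl  # bit-identical


def test_bootstrap_degenerate_noise_limit():
    rng = np.random.default_rng(2)
    d = rng.uniform(0, 20, 100)
    y = 1.0 - 0.05 * d + 1e-8 * rng.standard_normal(100)
    data = IndividualDataset(y=y, dose=d)
    res = bmdl_parametric_bootstrap(
        data, "linear",
        BenchmarkConfig(bmr=0.10, method="parametric_bootstrap", n_boot=100, seed=0),
    )
    assert res.bmdl == pytest.approx(res.bmd, rel=1e-5)


def test_bootstrap_matches_closed_form_linear():
    """Bootstrap and closed-form BMDL agree within 10% on linear data."""
    config_gen = uniform_config(100, linear_truth())
    for seed in (0, 1, 2):
        data = generate(config_gen, seed=seed)
        cf = bmdl_closed_form(fit_linear(data), BenchmarkConfig(bmr=0.10))
        bs = bmdl_parametric_bootstrap(
            data, "linear",
            BenchmarkConfig(bmr=0.10, method="parametric_bootstrap", n_boot=500,
                            seed=seed),
        )
        assert bs.bmdl == pytest.approx(cf.bmdl, rel=0.10)


def test_bootstrap_flags_majority_undefined():
    rng = np.random.default_rng(3)
    d = rng.uniform(0, 20, 100)
    y = 1.0 + 0.05 * d + 0.2 * rng.standard_normal(100)  # protective: BMD undefined
    res = bmdl_parametric_bootstrap(
        IndividualDataset(y=y, dose=d), "linear",
        BenchmarkConfig(bmr=0.10, method="parametric_bootstrap", n_boot=100, seed=0),
    )
    assert np.isnan(res.bmdl)
    assert res.diagnostics["n_undefined"] > 50


# -- model retention ----------------------------------------------------------


def _fake(aic, bmdl, family="linear"):
    return (
        SimpleNamespace(aic=aic, family=family),
        SimpleNamespace(bmdl=bmdl),
    )


def test_select_models_delta_aic_rule():
    fits, results = zip(*[_fake(100.0, 3.0), _fake(101.9, 1.4), _fake(103.0, 0.9)])
    sel = select_models(list(fits), list(results))
    assert sel.retained == [0, 1]
    assert sel.reported_bmdl == 1.4


def test_select_models_single_and_ties():
    fits, results = zip(*[_fake(50.0, 2.0)])
    sel = select_models(list(fits), list(results))
    assert sel.retained == [0] and sel.reported_bmdl == 2.0

    fits, results = zip(*[_fake(10.0, 2.0), _fake(10.0, 1.0)])
    sel = select_models(list(fits), list(results))
    assert sel.retained == [0, 1] and sel.reported_bmdl == 1.0


def test_select_models_excludes_undefined_bmdl():
    # best AIC model has no BMDL (as for the hockey stick): excluded from
    # retention and from the AIC reference
    fits, results = zip(*[_fake(99.0, float("nan"), "hockey"), _fake(100.0, 3.0),
                          _fake(101.0, 2.5)])
    sel = select_models(list(fits), list(results))
    assert sel.retained == [1, 2]
    assert sel.excluded_undefined == [0]
    assert sel.reported_bmdl == 2.5

    with pytest.raises(ValueError, match="no candidate"):
        select_models([_fake(1.0, float("nan"))[0]], [_fake(1.0, float("nan"))[1]])


def test_config_validation():
    with pytest.raises(ValueError):
        BenchmarkConfig(bmr=0.0)
    with pytest.raises(ValueError):
        BenchmarkConfig(alpha=0.7)
    with pytest.raises(ValueError):
        BenchmarkConfig(n_boot=10)
    with pytest.raises(ValueError):
        BenchmarkConfig(method="waldo")
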