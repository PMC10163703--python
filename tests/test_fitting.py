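"""Estimation: exact recovery, nesting, profiling and summary-data fits."""

import numpy as np
import pytest

from bmdkit import (
    DoseResponseSpec,
    IndividualDataset,
    fit_hockey,
    fit_kpower,
    fit_linear,
    fit_piecewise,
    fit_summary,
    generate,
    make_deciles,
)
from conftest import linear_truth, noiseless_dataset, uniform_config


# -- exact recovery from noiseless data -------------------------------------


def test_linear_noiseless_recovery():
    data = noiseless_dataset(DoseResponseSpec.linear(-0.1))
    fit = fit_linear(data)
    assert fit.params.drs.beta == pytest.approx(-0.1, abs=1e-12)
    assert fit.rss == pytest.approx(0.0, abs=1e-20)


def test_piecewise_noiseless_recovery():
    spec = DoseResponseSpec.piecewise(-0.02, -0.1, d0=5.0)
    data = noiseless_dataset(spec, n=200)
    fit = fit_piecewise(data, d0=5.0)
    assert fit.params.drs.beta1 == pytest.approx(-0.02, abs=1e-10)
    assert fit.params.drs.beta2 == pytest.approx(-0.1, abs=1e-10)
    assert fit.rss == pytest.approx(0.0, abs=1e-18)


def test_kpower_noiseless_recovery():
    data = noiseless_dataset(DoseResponseSpec.kpower(-0.01, K=2.0), high=10.0)
    fit = fit_kpower(data)
    assert fit.params.drs.K == pytest.approx(2.0, abs=1e-6)
    assert fit.params.drs.beta == pytest.approx(-0.01, rel=1e-6)


def test_hockey_noiseless_recovery():
    data = noiseless_dataset(DoseResponseSpec.hockey(-0.05, gamma=10.0), n=200)
    fit, profile = fit_hockey(data)
    resolution = profile.gamma_grid[1] - profile.gamma_grid[0]
    assert abs(profile.gamma_hat - 10.0) <= resolution


# -- invariances and identities ---------------------------------------------


def test_row_permutation_leaves_estimates_unchanged(noisy_linear_data):
    perm = np.random.default_rng(5).permutation(noisy_linear_data.n)
    shuffled = IndividualDataset(
        y=noisy_linear_data.y[perm], dose=noisy_linear_data.dose[perm]
    )
    f1, f2 = fit_linear(noisy_linear_data), fit_linear(shuffled)
    np.testing.assert_allclose(f1.coef, f2.coef, rtol=1e-10)
    assert f1.logL == pytest.approx(f2.logL)


def test_aic_identity_and_df(noisy_linear_data):
    fits = [
        fit_linear(noisy_linear_data),
        fit_piecewise(noisy_linear_data),
        fit_kpower(noisy_linear_data),
        fit_hockey(noisy_linear_data)[0],
    ]
    for f in fits:
        assert f.aic == f.neg2logL + 2 * f.p_count  # exact arithmetic identity
        assert f.cov.shape[0] == f.cov.shape[1] == len(f.coef)
        # covariance symmetric PSD
        np.testing.assert_allclose(f.cov, f.cov.T, atol=1e-12)
        assert np.all(np.linalg.eigvalsh(f.cov) > -1e-12)
    lin, pw, kp, hk = fits
    assert lin.df == noisy_linear_data.n - 2


def test_nesting_inequalities(noisy_linear_data):
    lin = fit_linear(noisy_linear_data)
    assert fit_kpower(noisy_linear_data).neg2logL <= lin.neg2logL + 1e-8
    assert fit_piecewise(noisy_linear_data).neg2logL <= lin.neg2logL + 1e-8
    hk, profile = fit_hockey(noisy_linear_data)
    assert profile.profile_neg2logL.min() <= lin.neg2logL + 1e-8


def test_kpower_collapses_to_linear_on_linear_truth():
    """On data from the linear model, K is at the boundary about half the
    time; whenever it is, the fit must coincide with the plain linear OLS."""
    n_boundary = 0
    for seed in range(10):
        data = generate(uniform_config(500, linear_truth()), seed=seed)
        kp = fit_kpower(data)
        lin = fit_linear(data)
        assert kp.neg2logL <= lin.neg2logL + 1e-8
        if kp.boundary_K:
            n_boundary += 1
            assert kp.params.drs.K == 1.0
            np.testing.assert_allclose(kp.coef, lin.coef, rtol=1e-8)
            assert kp.logL == pytest.approx(lin.logL, abs=1e-8)
    assert n_boundary >= 1


def test_parameter_recovery_unbiased():
    """Estimates across 200 replicates at n=500 are unbiased within 3 MC se."""
    truths = {
        "linear": DoseResponseSpec.linear(-0.05),
        "piecewise": DoseResponseSpec.piecewise(-0.02, -0.08, d0=10.0),
        "kpower": DoseResponseSpec.kpower(-0.005, K=1.8),
    }
    from bmdkit import ModelParameters

    for family, spec in truths.items():
        truth = ModelParameters(alpha0=1.0, alpha=np.empty(0), drs=spec, sigma2=0.25)
        config = uniform_config(500, truth)
        estimates = []
        for child in np.random.SeedSequence(17).spawn(200):
            data = generate(config, seed=np.random.default_rng(child))
            if family == "linear":
                estimates.append(fit_linear(data).params.drs.beta)
            elif family == "piecewise":
                estimates.append(fit_piecewise(data, d0=10.0).params.drs.beta1)
            else:
                estimates.append(fit_kpower(data).params.drs.K)
        est = np.asarray(estimates)
        target = {"linear": -0.05, "piecewise": -0.02, "kpower": 1.8}[family]
        mc_se = est.std(ddof=1) / np.sqrt(est.size)
        assert abs(est.mean() - target) < 3 * mc_se, family


def test_hockey_grid_matches_brute_force_oracle():
    """The returned threshold equals an independent exhaustive scan."""
    data = generate(
        uniform_config(50, linear_truth(sigma2=1.0)), seed=3
    )
    grid_n = 1000
    fit, profile = fit_hockey(data, grid_size=grid_n)
    d, y = data.single_dose, data.y
    grid = np.linspace(0.0, np.quantile(d, 0.95), grid_n)
    rss = []
    for g in grid:
        X = np.column_stack([np.ones(d.size), np.maximum(d - g, 0.0)])
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        r = y - X @ coef
        rss.append(r @ r)
    rss = np.asarray(rss)
    oracle_gamma = grid[np.argmax(rss <= rss.min() * (1 + 1e-9))]
    assert profile.gamma_hat == pytest.approx(oracle_gamma, abs=1e-12)


# -- input validation --------------------------------------------------------


def test_piecewise_break_validation(noisy_linear_data):
    with pytest.raises(ValueError, match="inside the observed dose range"):
        fit_piecewise(noisy_linear_data, d0=1e6)
    # default break is the median dose
    fit = fit_piecewise(noisy_linear_data)
    assert fit.d0 == pytest.approx(np.median(noisy_linear_data.single_dose))


def test_hockey_preconditions(noisy_linear_data):
    with pytest.raises(ValueError, match="grid_size"):
        fit_hockey(noisy_linear_data, grid_size=5)
    small = IndividualDataset(y=noisy_linear_data.y[:10], dose=noisy_linear_data.dose[:10])
    with pytest.raises(ValueError, match="at least 20"):
        fit_hockey(small)


def test_rank_deficient_design_names_columns():
    rng = np.random.default_rng(0)
    d = rng.uniform(0, 10, 50)
    z = rng.standard_normal(50)
    data = IndividualDataset(
        y=rng.standard_normal(50),
        dose=d,
        covariates=np.column_stack([z, z]),  # duplicated covariate
        covariate_names=("zdup1", "zdup2"),
    )
    with pytest.raises(ValueError, match="zdup"):
        fit_linear(data)


# -- summary data ------------------------------------------------------------


def test_summary_fit_exact_on_noiseless_linear():
    data = noiseless_dataset(DoseResponseSpec.linear(-0.07), n=200)
    summary = make_deciles(data)
    f_ind = fit_linear(data)
    f_sum = fit_summary(summary, "linear")
    assert f_sum.params.drs.beta == pytest.approx(f_ind.params.drs.beta, abs=1e-12)


def test_summary_piecewise_break_warning(noisy_linear_data):
    summary = make_deciles(noisy_linear_data)
    with pytest.warns(UserWarning, match="not a group boundary"):
        fit_summary(summary, "piecewise", d0=summary.mean_dose[3] + 0.01)


def test_summary_rejects_hockey(noisy_linear_data):
    with pytest.raises(ValueError, match="not supported"):
        fit_summary(make_deciles(noisy_linear_data), "hockey")


def test_summary_kpower_noiseless_recovery():
    spec = DoseResponseSpec.kpower(-0.001, K=2.0)
    data = noiseless_dataset(spec, n=400, high=10.0)
    summary = make_deciles(data, K=20)
    fit = fit_summary(summary, "kpower")
    # group means of d^2 differ from (mean d)^2, so recovery is approximate
    assert fit.params.drs.K == pytest.approx(2.0, abs=0.2)
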