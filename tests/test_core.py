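"""Unit tests for genotype standardization and the marginal CAMP fit."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize

from camp import fit_camp_snp, standardize_genotypes, survival_curve
from camp.core import SurvivalCohort
from camp.exceptions import (
    AllMarkersMonomorphic,
    MonomorphicMarker,
    NoEvents,
    NotConverged,
)


# --- standardization -----------------------------------------------------


def test_standardize_basic_column():
    panel = standardize_genotypes(np.array([[0.0], [1.0], [2.0], [1.0]]))
    col = panel.dosages[:, 0]
    assert abs(col.mean()) < 1e-12
    assert abs(col.std() - 1.0) < 1e-12


def test_standardize_drops_constant_column_with_report():
    raw = np.column_stack([[2.0, 2.0, 2.0, 2.0], [0.0, 1.0, 2.0, 1.0]])
    panel = standardize_genotypes(raw)
    assert list(panel.marker_id) == ["snp2"]
    assert panel.exclusions["marker_id"].tolist() == ["snp1"]
    assert panel.exclusions["reason"].tolist() == ["zero_variance"]


def test_standardize_mean_imputes_missing():
    raw = np.array([[0.0, 0.0], [np.nan, 1.0], [2.0, 2.0], [0.0, 1.0]])
    panel = standardize_genotypes(raw)
    col = panel.dosages[:, 0]
    # observed mean 2/3 imputed before centering: filled = (0, 2/3, 2, 0)
    filled = np.array([0.0, 2.0 / 3.0, 2.0, 0.0])
    expected = (filled - filled.mean()) / filled.std()
    np.testing.assert_allclose(col, expected, atol=1e-12)
    assert abs(col.mean()) < 1e-12


def test_standardize_maf_filter():
    # first marker: 3 carriers among 20,000 -> MAF 7.5e-5, below threshold
    n = 20_000
    rare = np.zeros(n)
    rare[:3] = 1.0
    common = np.random.default_rng(0).binomial(2, 0.3, n).astype(float)
    panel = standardize_genotypes(np.column_stack([rare, common]),
                                  maf_threshold=0.0002)
    assert "snp1" not in panel.marker_id
    assert panel.exclusions["reason"].tolist() == ["maf_below_threshold"]


def test_standardize_all_monomorphic_raises():
    with pytest.raises(AllMarkersMonomorphic):
        standardize_genotypes(np.ones((4, 2)))


# --- independent partial-likelihood oracle -------------------------------


def naive_log_partial_likelihood(theta, age, event, x, t0):
    """Direct transcription of the Cox partial likelihood for the hazard
    lambda0(t)*exp(x*(b0 + b1*(t - t0))); Efron-free (tie-free data)."""
    b0, b1 = theta
    ll = 0.0
    for t in np.sort(age[event == 1]):
        eta = x * (b0 + b1 * (t - t0))
        at_risk = age >= t
        who = (age == t) & (event == 1)
        ll += eta[who].sum() - np.log(np.exp(eta[at_risk]).sum())
    return ll


def test_fit_matches_derivative_free_oracle(d1, d1_fit):
    """The Newton maximizer agrees with Nelder-Mead applied to an
    independently written log partial likelihood."""
    panel, cohort = d1
    x = panel.dosages[:, 0]
    assert np.unique(cohort.age[cohort.event == 1]).size == cohort.n_events  # tie-free
    res = minimize(
        lambda th: -naive_log_partial_likelihood(th, cohort.age, cohort.event, x, 49.0),
        x0=np.zeros(2), method="Nelder-Mead",
        options={"xatol": 1e-10, "fatol": 1e-14, "maxiter": 5000},
    )
    np.testing.assert_allclose([d1_fit.beta0, d1_fit.beta1], res.x, atol=1e-6)
    # the two likelihood implementations agree at the optimum
    assert abs(d1_fit.log_partial_likelihood + res.fun) < 1e-8


def test_constrained_fit_matches_reference_cox(d1):
    """With beta1 fixed at 0 the fit is a plain Cox model and matches
    lifelines to high precision."""
    lifelines = pytest.importorskip("lifelines")
    panel, cohort = d1
    x = panel.dosages[:, 0]
    fit = fit_camp_snp(cohort, x, fit_slope=False)
    df = pd.DataFrame({"T": cohort.age, "E": cohort.event, "x": x})
    cph = lifelines.CoxPHFitter().fit(df, "T", "E")
    assert abs(fit.beta0 - cph.params_["x"]) < 1e-6
    assert abs(fit.var0 - cph.variance_matrix_.values[0, 0]) < 1e-8


def test_reparameterization_invariance(d1, d1_fit):
    panel, cohort = d1
    refit = fit_camp_snp(cohort, panel.dosages[:, 0], t0=54.0)
    assert abs(refit.beta0 - (d1_fit.beta0 + 5.0 * d1_fit.beta1)) < 1e-8
    assert abs(refit.beta1 - d1_fit.beta1) < 1e-8


def test_efron_equals_breslow_without_ties(d1):
    panel, cohort = d1
    x = panel.dosages[:, 1]
    fe = fit_camp_snp(cohort, x, ties_method="efron")
    fb = fit_camp_snp(cohort, x, ties_method="breslow")
    assert abs(fe.beta0 - fb.beta0) < 1e-10
    assert abs(fe.beta1 - fb.beta1) < 1e-10


def test_ties_methods_differ_on_tied_data(rng):
    age = np.round(rng.uniform(40, 60, 300))  # whole years: heavy ties
    event = rng.random(300) < 0.7
    x = rng.integers(0, 3, 300).astype(float)
    x = (x - x.mean()) / x.std()
    cohort = SurvivalCohort(ids=np.arange(300), age=age, event=event.astype(int))
    fe = fit_camp_snp(cohort, x, ties_method="efron")
    fb = fit_camp_snp(cohort, x, ties_method="breslow")
    assert fe.converged and fb.converged
    assert fe.beta0 != fb.beta0


def test_covariance_block_is_psd(d1_fit):
    assert d1_fit.var0 > 0
    assert d1_fit.var1 > 0
    assert d1_fit.cov01 ** 2 <= d1_fit.var0 * d1_fit.var1


def test_fit_with_offset_and_covariates(d1, rng):
    """xi and delta are estimated jointly; adding pure-noise columns leaves
    the marker effect nearly unchanged."""
    panel, cohort = d1
    x = panel.dosages[:, 0]
    base = fit_camp_snp(cohort, x)
    loco = rng.normal(0, 0.1, cohort.n)
    covs = SurvivalCohort(
        ids=cohort.ids, age=cohort.age, event=cohort.event,
        covariates=rng.normal(size=(cohort.n, 2)),
    )
    fit = fit_camp_snp(covs, x, loco=loco)
    assert fit.converged
    assert fit.xi is not None and fit.delta.shape == (2,)
    assert abs(fit.beta0 - base.beta0) < 0.1


def test_monotone_likelihood_flagged():
    cohort = SurvivalCohort(ids=["a", "b"], age=[50.0, 55.0], event=[1, 1])
    fit = fit_camp_snp(cohort, np.array([1.0, -1.0]))
    assert fit.monotone_likelihood
    assert not fit.converged


def test_input_validation():
    cohort = SurvivalCohort(ids=["a", "b", "c"], age=[50.0, 55.0, 60.0], event=[0, 0, 0])
    with pytest.raises(NoEvents):
        fit_camp_snp(cohort, np.array([1.0, -1.0, 0.0]))
    cohort2 = SurvivalCohort(ids=["a", "b", "c"], age=[50.0, 55.0, 60.0], event=[1, 0, 1])
    with pytest.raises(MonomorphicMarker):
        fit_camp_snp(cohort2, np.ones(3))


def test_loglik_improves_and_gradient_vanishes(d1):
    from camp import _cox

    panel, cohort = d1
    for j in (0, 3, 7):
        x = panel.dosages[:, j]
        data = _cox.prepare(cohort.age, cohort.event, x[:, None], 49.0)
        ll0, _, _ = _cox.loglik_grad_hess(np.zeros(2), data)
        theta, ll, H, conv, _, _ = _cox.newton_maximize(data)
        assert conv
        assert ll >= ll0
        _, grad, _ = _cox.loglik_grad_hess(theta, data)
        assert np.abs(grad).max() < 1e-6


# --- survival curves ------------------------------------------------------


def test_survival_curve_baseline_and_monotone(d1, d1_fit):
    panel, cohort = d1
    curve = survival_curve(d1_fit, cohort, panel.dosages[:, 0], x_value=0.0)
    assert curve(0.0) == 1.0
    assert np.all(np.diff(curve.survival) <= 1e-15)
    # x = 0: the curve is exp(-Lambda0(t)) by construction
    from camp._cox import breslow_baseline, prepare

    data = prepare(cohort.age, cohort.event, panel.dosages[:, 0][:, None], 49.0)
    _, dlam = breslow_baseline(np.array([d1_fit.beta0, d1_fit.beta1]), data)
    np.testing.assert_allclose(curve.survival, np.exp(-np.cumsum(dlam)), rtol=1e-12)


def test_survival_curves_cross_when_effect_changes_sign():
    """With beta(t) changing sign inside the age range, curves for opposite
    dosages cross — impossible under a constant-effect Cox model."""
    from camp import SimulationConfig, simulate_genotypes, simulate_times

    cfg = SimulationConfig(n=4000, m=1, mafs=[0.3], seed=99,
                           causal_effects=[(0, 0.8, -0.4)])
    panel = simulate_genotypes(cfg)
    cohort = simulate_times(panel, cfg)
    keep = np.isin(panel.sample_ids, cohort.ids)
    x = panel.dosages[keep, 0]
    x = (x - x.mean()) / x.std()
    fit = fit_camp_snp(cohort, x)
    hi = survival_curve(fit, cohort, x, x_value=1.0)
    lo = survival_curve(fit, cohort, x, x_value=-1.0)
    diff = hi.survival - lo.survival
    assert diff.min() < -0.01 and diff.max() > 0.01  # sign change = crossing


def test_survival_curve_requires_convergence(d1):
    panel, cohort = d1
    from camp.core import CampFit

    bad = CampFit(beta0=0, beta1=0, t0=49, var0=1, var1=1, cov01=0, converged=False)
    with pytest.raises(NotConverged):
        survival_curve(bad, cohort, panel.dosages[:, 0])
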