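"""Ridge Weibull-AFT LOCO predictors."""

import copy

import numpy as np
import pytest
from scipy.optimize import check_grad, minimize
from scipy import stats

from camp import (
    SimulationConfig,
    fit_camp_snp,
    fit_weibull_aft_ridge,
    loco_predict,
    simulate_genotypes,
    simulate_times,
)
from camp.core import SurvivalCohort
from camp.loco import LocoModel, _aft_negloglik
from camp.exceptions import NoEvents, UnknownChromosome


def _gumbel_cohort(rng, panel, beta, mu=np.log(50.0), alpha=10.0, censor=None):
    """Ages drawn exactly from the AFT mean model with Weibull shape alpha."""
    n = panel.n
    logy = mu + panel.dosages @ beta + np.log(rng.exponential(size=n)) / alpha
    age = np.exp(logy)
    if censor is None:
        return SurvivalCohort(ids=panel.sample_ids, age=age, event=np.ones(n))
    event = (age <= censor).astype(int)
    return SurvivalCohort(ids=panel.sample_ids, age=np.minimum(age, censor), event=event)


def test_penalized_gradient_is_exact(rng):
    cfg = SimulationConfig(n=300, m=4, seed=5)
    panel = simulate_genotypes(cfg)
    coh = _gumbel_cohort(rng, panel, rng.normal(0, 0.02, panel.m),
                         censor=rng.uniform(45, 60, panel.n))
    params = np.concatenate([[3.8], rng.normal(0, 0.02, panel.m), [np.log(7.0)]])
    err = check_grad(
        lambda p: _aft_negloglik(p, np.log(coh.age), coh.event.astype(float),
                                 panel.dosages, None, 0.7)[0],
        lambda p: _aft_negloglik(p, np.log(coh.age), coh.event.astype(float),
                                 panel.dosages, None, 0.7)[1],
        params,
    )
    assert err < 1e-3  # finite-difference noise on an O(1e3) objective


def test_strong_penalty_shrinks_null_effects(rng):
    cfg = SimulationConfig(n=2000, m=10, seed=12)
    panel = simulate_genotypes(cfg)
    cohort = simulate_times(panel, cfg)
    keep = np.isin(panel.sample_ids, cohort.ids)
    panel = copy.copy(panel)
    panel.dosages, panel.sample_ids = panel.dosages[keep], panel.sample_ids[keep]
    model = fit_weibull_aft_ridge(cohort, panel, ridge_penalty=200.0)
    assert np.abs(model.marker_effects).max() < 0.01


def test_shape_recovery_from_exact_aft_data(rng):
    cfg = SimulationConfig(n=5000, m=20, seed=11)
    panel = simulate_genotypes(cfg)
    alpha = 10.0
    coh = _gumbel_cohort(rng, panel, rng.normal(0, 0.01, panel.m), alpha=alpha)
    model = fit_weibull_aft_ridge(coh, panel, ridge_penalty=0.5)
    assert abs(model.weibull_shape - alpha) / alpha < 0.10


def test_unpenalized_single_marker_matches_generic_optimizer(rng):
    """penalty = 0, one marker, no censoring: the fit agrees with a
    derivative-free maximizer of an independently written Weibull AFT
    log-likelihood (scipy's weibull_min)."""
    cfg = SimulationConfig(n=800, m=1, mafs=[0.3], seed=21)
    panel = simulate_genotypes(cfg)
    coh = _gumbel_cohort(rng, panel, np.array([0.05]), alpha=8.0)
    model = fit_weibull_aft_ridge(coh, panel, ridge_penalty=0.0)

    x = panel.dosages[:, 0]

    def negll(p):
        mu, beta, log_alpha = p
        scale = np.exp(mu + beta * x)
        return -stats.weibull_min.logpdf(coh.age, np.exp(log_alpha), scale=scale).sum()

    res = minimize(negll, x0=np.array([3.9, 0.0, np.log(5.0)]),
                   method="Nelder-Mead",
                   options={"xatol": 1e-9, "fatol": 1e-12, "maxiter": 5000})
    np.testing.assert_allclose(
        [model.intercept, model.marker_effects[0], np.log(model.weibull_shape)],
        res.x, atol=1e-4,
    )


def test_objective_decreases_across_accepted_steps(rng):
    cfg = SimulationConfig(n=1000, m=8, seed=31)
    panel = simulate_genotypes(cfg)
    coh = _gumbel_cohort(rng, panel, rng.normal(0, 0.02, panel.m),
                         censor=rng.uniform(45, 60, panel.n))
    logy, ev = np.log(coh.age), coh.event.astype(float)
    trace = []
    x0 = np.zeros(2 + panel.m)
    x0[0], x0[-1] = logy[coh.event == 1].mean(), 0.0
    minimize(_aft_negloglik, x0, args=(logy, ev, panel.dosages, None, 1.0),
             jac=True, method="L-BFGS-B",
             callback=lambda xk: trace.append(_aft_negloglik(xk, logy, ev, panel.dosages, None, 1.0)[0]))
    assert len(trace) > 1
    assert np.all(np.diff(trace) <= 1e-8)


def test_no_events_raises():
    cfg = SimulationConfig(n=50, m=2, seed=41)
    panel = simulate_genotypes(cfg)
    coh = SurvivalCohort(ids=panel.sample_ids, age=np.full(50, 50.0),
                         event=np.zeros(50, dtype=int))
    with pytest.raises(NoEvents):
        fit_weibull_aft_ridge(coh, panel)


# --- LOCO predictions -----------------------------------------------------


def test_loco_zero_effects_gives_zero_predictors():
    cfg = SimulationConfig(n=100, m=6, seed=51)
    panel = simulate_genotypes(cfg)
    model = LocoModel(intercept=3.9, marker_effects=np.zeros(panel.m),
                      marker_id=panel.marker_id, chromosome=panel.chromosome,
                      covariate_effects=None, weibull_shape=10.0, ridge_penalty=1.0)
    g = loco_predict(model, panel)
    assert np.allclose(g.to_numpy(), 0.0)


def test_loco_leaves_own_chromosome_out():
    cfg = SimulationConfig(n=200, m=6, seed=52)
    panel = simulate_genotypes(cfg)
    chrom = np.asarray([str(c) for c in panel.chromosome])
    effects = np.where(chrom == "1", 0.05, 0.0)  # causal markers on chr1 only
    model = LocoModel(intercept=3.9, marker_effects=effects,
                      marker_id=panel.marker_id, chromosome=panel.chromosome,
                      covariate_effects=None, weibull_shape=10.0, ridge_penalty=1.0)
    g = loco_predict(model, panel, center=False)
    full = panel.dosages[:, chrom == "1"] @ effects[chrom == "1"]
    assert np.allclose(g["1"].to_numpy(), 0.0)           # chr1 excluded
    np.testing.assert_allclose(g["2"].to_numpy(), full)  # everything else kept


def test_loco_invariant_to_marker_order():
    cfg = SimulationConfig(n=150, m=8, seed=53)
    panel = simulate_genotypes(cfg)
    eff = np.linspace(-0.03, 0.03, panel.m)
    model = LocoModel(intercept=3.9, marker_effects=eff,
                      marker_id=panel.marker_id, chromosome=panel.chromosome,
                      covariate_effects=None, weibull_shape=10.0, ridge_penalty=1.0)
    g1 = loco_predict(model, panel)
    perm = np.random.default_rng(1).permutation(panel.m)
    shuffled = LocoModel(intercept=3.9, marker_effects=eff[perm],
                         marker_id=panel.marker_id[perm], chromosome=panel.chromosome[perm],
                         covariate_effects=None, weibull_shape=10.0, ridge_penalty=1.0)
    g2 = loco_predict(shuffled, panel)
    np.testing.assert_allclose(g1.to_numpy(), g2.to_numpy(), atol=1e-12)


def test_loco_unknown_chromosome():
    cfg = SimulationConfig(n=50, m=4, n_chromosomes=2, seed=54)
    panel = simulate_genotypes(cfg)
    model = LocoModel(intercept=3.9, marker_effects=np.full(2, 0.1),
                      marker_id=panel.marker_id[:2], chromosome=np.array(["1", "1"]),
                      covariate_effects=None, weibull_shape=10.0, ridge_penalty=1.0)
    with pytest.raises(UnknownChromosome):
        loco_predict(model, panel)


def test_loco_offset_reduces_marginal_estimation_error():
    """In a polygenic cohort, conditioning on the LOCO predictor lowers the
    MSE of per-SNP effect estimates at the reference age."""
    rng = np.random.default_rng(77)
    n, m, n_causal = 5000, 220, 200
    cfg = SimulationConfig(
        n=n, m=m, seed=78, n_chromosomes=4,
        causal_effects=[(j, b, 0.0) for j, b in
                        zip(range(n_causal), rng.normal(0, 0.05, n_causal))],
    )
    panel = simulate_genotypes(cfg)
    cohort = simulate_times(panel, cfg)
    keep = np.isin(panel.sample_ids, cohort.ids)
    panel = copy.copy(panel)
    panel.dosages, panel.sample_ids = panel.dosages[keep], panel.sample_ids[keep]

    model = fit_weibull_aft_ridge(cohort, panel, ridge_penalty=float(m))
    g = loco_predict(model, panel)
    truth = dict((j, b) for j, b, _ in [(j, b0, b1) for j, b0, b1 in cfg.causal_effects])

    err_with, err_without = [], []
    for j in range(0, n_causal, 4):  # every 4th causal SNP keeps runtime modest
        x = panel.dosages[:, j]
        loco = g[str(panel.chromosome[j])].to_numpy()
        fw = fit_camp_snp(cohort, x, loco=loco)
        fo = fit_camp_snp(cohort, x)
        err_with.append((fw.beta0 - truth[j]) ** 2)
        err_without.append((fo.beta0 - truth[j]) ** 2)
    assert np.mean(err_with) < np.mean(err_without)
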