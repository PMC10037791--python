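"""Move-persistence model: likelihood oracle, fitting, ranking, residuals."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_tiny_mpmm_data
from persistforage import mpmm, simdata
from persistforage.mpmm import (
    FormulaError,
    MpmmFormula,
    RankingError,
    fit_mpmm,
    ghq_marginal_nll,
    loo_cv,
    mpmm_negloglik,
    n_params,
    osa_residuals,
    parse_formula,
    rank_models,
)


def random_theta(rng, p=1):
    return np.concatenate([
        rng.normal(0, 0.8, p + 1),
        [np.log(rng.uniform(0.2, 0.6)), np.log(rng.uniform(0.2, 0.6)),
         rng.normal(0, 0.3), rng.normal(0, 0.3), rng.normal(0, 0.4)],
    ])


# ---------------------------------------------------------------------------
# formula mini-language


def test_parse_formula_roundtrip():
    f = parse_formula("gamma ~ diversity + bathy + (1|id)")
    assert f.covariates == ("diversity", "bathy")
    assert parse_formula("~ (1 | id)").covariates == ()
    with pytest.raises(FormulaError):
        parse_formula("gamma ~ bathy + (bathy|id)")  # random slopes unsupported
    with pytest.raises(FormulaError):
        parse_formula("gamma ~ bathy")  # random intercept mandatory


def test_parameter_count_follows_covariate_count():
    assert n_params(0) == 6
    assert n_params(1) == 7
    assert n_params(2) == 8


# ---------------------------------------------------------------------------
# likelihood oracle


def test_laplace_matches_gauss_hermite_on_tiny_instances():
    """Laplace vs brute-force adaptive GH quadrature, 4 latent dims."""
    rng = np.random.default_rng(123)
    worst = 0.0
    for i in range(8):
        data = make_tiny_mpmm_data(seed=1000 + i, n_steps=3, n_ind=1)
        theta = random_theta(rng)
        lap = mpmm_negloglik(theta, data)
        ghq = ghq_marginal_nll(theta, data, n_nodes=12)
        worst = max(worst, abs(lap - ghq))
    assert worst < 1e-3


def test_sigma_gamma_limit_recovers_deterministic_likelihood():
    """At sigma_gamma -> 0 the marginal reduces to the deterministic-gamma
    likelihood integrated over b alone (1-D quadrature oracle)."""
    from scipy.integrate import quad
    from scipy.special import expit

    data = make_tiny_mpmm_data(seed=5, n_steps=4, n_ind=1)
    theta = np.array([0.4, -0.3, np.log(0.4), np.log(1e-6), 0.1, -0.1, 0.2])
    beta, sigma_b, _, Sd = mpmm._unpack(theta, 1)
    Si = np.linalg.inv(Sd)
    _, ld = np.linalg.slogdet(Sd)

    def cond_lik(b):
        gam = expit(data.X @ beta + b)
        r = data.dcur - gam[:, None] * data.dprev
        ll = -data.n_steps * (np.log(2 * np.pi) + 0.5 * ld)
        ll -= 0.5 * np.einsum("ni,ij,nj->", r, Si, r)
        return np.exp(ll) * np.exp(-0.5 * b**2 / sigma_b**2) / np.sqrt(2 * np.pi * sigma_b**2)

    integral, _ = quad(cond_lik, -6 * 0.4, 6 * 0.4, limit=200)
    oracle = -np.log(integral)
    lap = mpmm_negloglik(theta, data)
    assert abs(lap - oracle) < 1e-3


def test_covariate_permutation_symmetry():
    rng = np.random.default_rng(7)
    n = 6
    dprev = rng.normal(0, 1, (n, 2))
    dcur = rng.normal(0, 1, (n, 2))
    X = np.column_stack([np.ones(n), rng.normal(0, 1, n), rng.normal(0, 1, n)])
    base = dict(ind_ids=["a"], ind=np.zeros(n, int),
                seg_id=np.array(["a_s0"] * n, dtype=object),
                time=np.arange(n).astype("datetime64[s]"))
    d1 = mpmm.MpmmData(covariate_names=("u", "v"), dprev=dprev, dcur=dcur, X=X, **base)
    Xp = X[:, [0, 2, 1]]
    d2 = mpmm.MpmmData(covariate_names=("v", "u"), dprev=dprev, dcur=dcur, X=Xp, **base)
    theta = np.array([0.2, 0.5, -0.4, np.log(0.3), np.log(0.3), 0.0, 0.0, 0.1])
    theta_p = theta[[0, 2, 1, 3, 4, 5, 6, 7]]
    assert mpmm_negloglik(theta, d1) == pytest.approx(mpmm_negloglik(theta_p, d2), abs=1e-8)


def test_likelihood_invariant_under_individual_relabelling():
    data = make_tiny_mpmm_data(seed=9, n_steps=4, n_ind=3)
    theta = random_theta(np.random.default_rng(0))
    # reverse the individual labels (and index mapping)
    relabel = mpmm.MpmmData(
        list(reversed(data.ind_ids)), data.covariate_names, data.dprev, data.dcur,
        data.X, (data.n_individuals - 1) - data.ind, data.seg_id, data.time)
    assert mpmm_negloglik(theta, data) == pytest.approx(
        mpmm_negloglik(theta, relabel), abs=1e-8)


# ---------------------------------------------------------------------------
# fitting


@pytest.fixture(scope="module")
def fitted_world():
    cfg = simdata.SimConfig(n_individuals=12, steps_per_track=80, seed=31)
    grids, truths, raws, dives = simdata.simulate_all(cfg)
    data = mpmm.build_data_from_truth(truths, ("diversity", "bathy"))
    fits = {
        "div2": fit_mpmm(data, "gamma ~ diversity + bathy + (1|id)"),
        "env2": fit_mpmm(data, "gamma ~ bathy + (1|id)"),
        "null1": fit_mpmm(data, "gamma ~ (1|id)"),
    }
    return cfg, truths, data, fits


def test_k_and_aic_identity(fitted_world):
    _, _, _, fits = fitted_world
    assert fits["null1"].k == 6 and fits["env2"].k == 7 and fits["div2"].k == 8
    for f in fits.values():
        assert f.aic == pytest.approx(2 * f.k - 2 * f.loglik, abs=1e-8)
        assert np.all((f.gamma_hat > 0) & (f.gamma_hat < 1))


def test_bathymetry_slope_recovered_with_correct_sign(fitted_world):
    cfg, _, _, fits = fitted_world
    fit = fits["div2"]
    assert fit.converged
    # truth: diversity +0.5, bathy -0.5 on the logit scale
    assert fit.beta[2] < 0
    assert abs(fit.beta[2] - (-0.5)) < 3 * fit.beta_se[2] + 0.15


def test_rank_models_orders_by_aic_and_applies_parsimony(fitted_world):
    _, _, _, fits = fitted_world
    tab = rank_models(fits)
    assert tab["delta_aic"].iloc[0] == 0.0
    assert (tab["aic"].diff().dropna() >= 0).all()
    assert tab["selected"].sum() == 1


def test_rank_models_parsimony_tie_rule_constructed():
    def stub(name, k, aic):
        return mpmm.MpmmFit(
            formula=MpmmFormula(tuple(f"c{i}" for i in range(k - 6))),
            beta=np.zeros(k - 5), beta_se=np.zeros(k - 5),
            beta_ci=np.zeros((k - 5, 2)), sigma_b=0.3, sigma_gamma=0.3,
            disp_cov=np.eye(2), b_hat=np.zeros(2), gamma_hat=np.array([0.5]),
            loglik=k - aic / 2.0, k=k, aic=aic, converged=True, grad_norm=0.0,
            n_steps=100)

    # dAIC of model2 = 0.5 < 2 and it has fewer parameters -> selected
    fits = {"m1": stub("m1", 8, -100.0), "m2": stub("m2", 7, -99.5),
            "m3": stub("m3", 6, -90.0)}
    tab = rank_models(fits)
    assert tab.loc[tab["selected"], "model"].iloc[0] == "m2"
    # unique minimum, everything else far away -> minimum selected
    fits2 = {"m1": stub("m1", 8, -100.0), "m2": stub("m2", 6, -80.0)}
    tab2 = rank_models(fits2)
    assert tab2.loc[tab2["selected"], "model"].iloc[0] == "m1"
    # differing data sizes refuse to rank
    bad = stub("m4", 6, -50.0)
    bad.n_steps = 99
    with pytest.raises(RankingError):
        rank_models({"m1": fits["m1"], "m4": bad})
    # unconverged fits refuse to rank
    nc = stub("m5", 6, -50.0)
    nc.converged = False
    with pytest.raises(RankingError):
        rank_models({"m1": fits["m1"], "m5": nc})


def test_loo_refit_count_and_coverage_fields():
    theta = np.array([0.5, -0.4, np.log(0.3), np.log(0.3), 0.0, 0.0, 0.2])
    data = mpmm.simulate_instance(theta, n_steps=40, n_ind=3, seed=77)
    res = loo_cv(data, "gamma ~ x0 + (1|id)")
    assert len(res.left_out) + res.n_failed == 3
    assert res.estimates.shape[1] == 2
    assert 0.0 <= res.coverage <= 1.0


def test_osa_residual_length_and_calibration(fitted_world):
    cfg, truths, data, fits = fitted_world
    fit = fits["div2"]
    res = osa_residuals(fit, data)
    # one residual row per modelled step: positions L -> L-1 displacements
    # -> L-2 modelled steps per track
    expected = sum(len(t.times) - 2 for t in truths)
    assert len(res) == expected
    r = np.concatenate([res["resid_x"], res["resid_y"]])
    assert abs(r.mean()) < 0.05
    assert 0.9 < r.std() < 1.1


def test_osa_residuals_approximately_normal_when_well_specified():
    """Type-I calibration: a normality test on well-specified residuals
    should reject at about its nominal rate."""
    from scipy import stats

    rejections = 0
    n_rep = 10
    for seed in range(n_rep):
        cfg = simdata.SimConfig(n_individuals=4, steps_per_track=60, seed=400 + seed)
        grids, truths, raws, dives = simdata.simulate_all(cfg)
        data = mpmm.build_data_from_truth(truths, ("diversity", "bathy"))
        fit = fit_mpmm(data, "gamma ~ diversity + bathy + (1|id)")
        res = osa_residuals(fit, data)
        r = np.concatenate([res["resid_x"], res["resid_y"]])
        if stats.shapiro(r).pvalue < 0.05:
            rejections += 1
    assert rejections <= 2
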