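import numpy as np
import pytest
from scipy import stats

from lnireg.families import LOG_NORMAL, LOG_SLASH, LOG_T
from lnireg.monotone import RegressionData, arrange_monotone
from lnireg.sampler import (
    ModelSpec,
    PriorSpec,
    _Layout,
    draw_b_psi,
    draw_nu_slash,
    draw_nu_t,
    draw_weights,
    impute_monotone_missing,
    init_state,
    run_mda,
    summarize,
)

from conftest import make_complete_data


def _layout(data):
    return _Layout(data, arrange_monotone(data))


# ------------------------------------------------------------ initialization


def test_init_complete_data_is_ols(complete_data):
    data, _, _ = complete_data
    lay = _layout(data)
    state = init_state(lay, ModelSpec(LOG_T))
    T = lay.T_obs
    B_ols, *_ = np.linalg.lstsq(lay.X, T, rcond=None)
    np.testing.assert_allclose(state.B, B_ols, atol=1e-10)
    assert state.nu == 7.0
    assert np.all(state.w == 1.0)


def test_init_rank_deficient_covariates(rng):
    X = np.ones((10, 2))  # duplicated intercept
    data = RegressionData(Y=np.exp(rng.normal(size=(10, 1))), X=X)
    with pytest.raises(ValueError, match="rank deficient"):
        init_state(_layout(data), ModelSpec(LOG_NORMAL))


def test_init_fills_only_fill_in_cells(missing_data):
    data, _, _ = missing_data
    lay = _layout(data)
    state = init_state(lay, ModelSpec(LOG_SLASH))
    # fill-in cells imputed, trailing monotone-missing cells untouched (NaN)
    assert not np.isnan(state.T[lay.fill_mask]).any()
    trailing = ~lay.obs_mask & ~lay.fill_mask
    assert np.isnan(state.T[trailing]).all()


# ------------------------------------------------------------------ (B, Psi)


def test_b_psi_concentrates_on_wls_at_tiny_noise(rng):
    n, r = 200, 2
    X = np.column_stack([np.ones(n), rng.normal(size=n)])
    beta = np.array([0.4, -0.7])
    T = (X @ beta + 1e-6 * rng.normal(size=n))[:, None]
    data = RegressionData(Y=np.exp(T), X=X)
    lay = _layout(data)
    w = rng.uniform(0.5, 2.0, size=n)
    Zw = X * w[:, None]
    wls = np.linalg.solve(X.T @ Zw, Zw.T @ T[:, 0])
    draws = np.array(
        [draw_b_psi(lay, lay.T_obs, w, PriorSpec(), rng)[0][:, 0] for _ in range(50)]
    )
    np.testing.assert_allclose(draws.mean(axis=0), wls, atol=1e-6)


def test_b_psi_matches_univariate_conjugate_posterior(rng):
    """p=1, w=1, A=0, m=p: (beta, psi) draws follow the standard
    noninformative posterior (scaled inverse-chi^2 and conditional normal)."""
    data, _, _ = make_complete_data(rng, n=60, p=1, r=2)
    lay = _layout(data)
    t = lay.T_obs[:, 0]
    n, r = 60, 2
    S = 4000
    psi_d = np.empty(S)
    b_d = np.empty((S, r))
    w = np.ones(n)
    prior = PriorSpec()
    for s in range(S):
        B, Psi = draw_b_psi(lay, lay.T_obs, w, prior, rng)
        psi_d[s], b_d[s] = Psi[0, 0], B[:, 0]
    bhat = np.linalg.lstsq(lay.X, t, rcond=None)[0]
    ssr = float(((t - lay.X @ bhat) ** 2).sum())
    ks_psi = stats.kstest(psi_d, stats.invgamma(a=(n - r) / 2, scale=ssr / 2).cdf)
    assert ks_psi.pvalue > 0.01
    # marginal of each coefficient is a scaled t with n - r df
    G = np.linalg.inv(lay.X.T @ lay.X)
    for j in range(r):
        scale = np.sqrt(ssr / (n - r) * G[j, j])
        ks_b = stats.kstest(
            (b_d[:, j] - bhat[j]) / scale, stats.t(df=n - r).cdf
        )
        assert ks_b.pvalue > 0.01


def test_b_psi_unidentifiable_block(rng):
    data, _, _ = make_complete_data(rng, n=3, p=2, r=3)
    lay = _layout(data)
    with pytest.raises(ValueError, match="unidentifiable|rank"):
        draw_b_psi(lay, lay.T_obs, np.ones(3), PriorSpec(), rng)


def test_b_psi_rejects_nonpositive_weights(complete_data, rng):
    data, _, _ = complete_data
    lay = _layout(data)
    w = np.ones(data.n)
    w[0] = 0.0
    with pytest.raises(ValueError, match="positive"):
        draw_b_psi(lay, lay.T_obs, w, PriorSpec(), rng)


# ---------------------------------------------------------------- imputation


def _interior_missing_bivariate(rng, n=20_000, n_fill=4_000, n_trail=12_000):
    """Bivariate data whose first ``n_fill`` rows are (obs, mis) — fill-in
    cells at original column 1 — and whose last ``n_trail`` rows are
    (mis, obs), trailing monotone missingness that is never imputed."""
    Y = np.exp(rng.normal(size=(n, 2)))
    Y[:n_fill, 1] = np.nan
    Y[n - n_trail:, 0] = np.nan
    return RegressionData(Y=Y, X=np.ones((n, 1)))


def test_impute_gaussian_conditioning_moments(rng):
    """Bivariate fill-in draws match textbook Gaussian conditioning."""
    rho, psi1, psi2 = 0.6, 0.5, 0.8
    cov = rho * np.sqrt(psi1 * psi2)
    data = _interior_missing_bivariate(rng)
    lay = _layout(data)
    state = init_state(lay, ModelSpec(LOG_NORMAL))
    # internal (ascending) columns: position of original columns 0 and 1
    a0 = int(np.where(lay.arr.column_order[::-1] == 0)[0][0])
    a1 = 1 - a0
    Psi_int = np.empty((2, 2))
    Psi_int[a0, a0], Psi_int[a1, a1] = psi1, psi2
    Psi_int[a0, a1] = Psi_int[a1, a0] = cov
    state.B = np.zeros((1, 2))
    state.Psi = Psi_int
    assert lay.fill_mask[:, a1].sum() == 4000
    impute_monotone_missing(lay, state, rng)
    rows = lay.fill_mask[:, a1]
    filled = state.T[rows, a1]
    obs = state.T[rows, a0]
    k = cov / psi1
    cond_var = psi2 - k * cov
    resid = filled - k * obs
    assert abs(resid.mean()) < 3 * np.sqrt(cond_var / resid.size)
    assert np.var(resid) == pytest.approx(cond_var, rel=0.05)


def test_impute_diagonal_psi_uses_marginal_mean(rng):
    data = _interior_missing_bivariate(rng, n=8000, n_fill=3000, n_trail=4000)
    lay = _layout(data)
    state = init_state(lay, ModelSpec(LOG_NORMAL))
    a0 = int(np.where(lay.arr.column_order[::-1] == 0)[0][0])
    a1 = 1 - a0
    B = np.zeros((1, 2))
    B[0, a1] = 0.7
    state.B = B
    state.Psi = np.diag([0.3, 0.5])
    impute_monotone_missing(lay, state, rng)
    rows = lay.fill_mask[:, a1]
    filled = state.T[rows, a1]
    assert abs(filled.mean() - 0.7) < 3 * np.sqrt(state.Psi[a1, a1] / rows.sum())


# ------------------------------------------------------------------- weights


def test_weights_log_normal_degenerate():
    w = draw_weights(LOG_NORMAL, None, np.ones(7), np.ones(7, dtype=int), np.random.default_rng(0))
    assert np.array_equal(w, np.ones(7))


def test_weights_t_gamma_mean(rng):
    n = 100_000
    w = draw_weights(LOG_T, 1.0, np.ones(n), np.ones(n, dtype=int), rng)
    # Gamma((nu+p)/2, (nu+delta2)/2) = Gamma(1, 1): mean 1, var 1
    assert abs(w.mean() - 1.0) < 3 / np.sqrt(n)


def test_weights_slash_prior_when_no_data(rng):
    n = 50_000
    w = draw_weights(LOG_SLASH, 2.0, np.zeros(n), np.zeros(n, dtype=int), rng)
    ks = stats.kstest(w, stats.beta(2.0, 1.0).cdf)
    assert ks.pvalue > 0.01
    assert w.min() > 0 and w.max() < 1


def test_weights_slash_truncated_gamma_moments(rng):
    from scipy.integrate import quad

    nu, p_i, d2 = 2.0, 3, 6.0
    n = 100_000
    w = draw_weights(LOG_SLASH, nu, np.full(n, d2), np.full(n, p_i), rng)
    a, rate = nu + p_i / 2, d2 / 2
    f = lambda x: x ** (a - 1) * np.exp(-rate * x)
    Z = quad(f, 0, 1)[0]
    m1 = quad(lambda x: x * f(x), 0, 1)[0] / Z
    v = quad(lambda x: x * x * f(x), 0, 1)[0] / Z - m1**2
    assert abs(w.mean() - m1) < 3 * np.sqrt(v / n)


# ------------------------------------------------------------------ nu draws


def test_nu_slash_prior_with_no_cases(rng):
    prior = PriorSpec(slash_a=6.0, slash_b=2.0)
    draws = np.array([draw_nu_slash(np.empty(0), prior, rng) for _ in range(20_000)])
    ks = stats.kstest(draws, stats.gamma(a=6.0, scale=0.5).cdf)
    assert ks.pvalue > 0.01


def test_nu_slash_single_observation_conjugacy(rng):
    """a=6, b=2, one weight e^-1: posterior is Gamma(7, 3) with mean 7/3."""
    prior = PriorSpec(slash_a=6.0, slash_b=2.0)
    w = np.array([np.exp(-1.0)])
    draws = np.array([draw_nu_slash(w, prior, rng) for _ in range(50_000)])
    se = np.sqrt(7 / 9 / draws.size)
    assert abs(draws.mean() - 7 / 3) < 3 * se


def test_nu_slash_rejects_weights_outside_unit_interval(rng):
    with pytest.raises(ValueError):
        draw_nu_slash(np.array([1.2]), PriorSpec(), rng)


def test_nu_t_recovers_simulated_dof(rng):
    nu_true, n, p = 5.0, 500, 3
    w = rng.gamma(nu_true / 2, 2 / nu_true, size=n)
    z = rng.standard_normal((n, p))
    d2 = (z**2).sum(axis=1) / w
    draws = np.array(
        [draw_nu_t(d2, np.full(n, p), PriorSpec(), rng) for _ in range(500)]
    )
    assert 3.0 < np.median(draws) < 8.0


def test_nu_t_prior_only_when_no_data(rng):
    prior = PriorSpec()
    draws = np.array(
        [draw_nu_t(np.zeros(0), np.zeros(0, dtype=int), prior, rng) for _ in range(5000)]
    )
    assert draws.min() >= prior.grid_lo and draws.max() <= prior.grid_hi
    # prior ~ nu^-2 puts most mass near the lower bound
    assert np.median(draws) < 2.0


# ----------------------------------------------------------------- summaries


def test_summarize_order_statistics_rule():
    from lnireg.sampler import PosteriorDraws

    chain = np.arange(1.0, 101.0)
    draws = PosteriorDraws(
        B=chain[:, None, None],
        Psi=np.broadcast_to(chain[:, None, None], (100, 1, 1)).copy(),
        nu=chain.copy(),
        family=LOG_SLASH,
        response_names=["y1"],
        covariate_names=["intercept"],
    )
    s = summarize(draws)
    assert s.nu_median == pytest.approx(50.5)
    assert s.nu_lower == pytest.approx(3.475)
    assert s.nu_upper == pytest.approx(97.525)


def test_summarize_constant_and_symmetric_chains():
    from lnireg.sampler import PosteriorDraws

    const = np.full(50, 2.5)
    sym = np.linspace(-1, 1, 50)
    draws = PosteriorDraws(
        B=np.stack([const, sym], axis=1)[:, None, :],
        Psi=np.broadcast_to(np.eye(2), (50, 2, 2)).copy(),
        nu=None,
        family=LOG_NORMAL,
        response_names=["a", "b"],
        covariate_names=["intercept"],
    )
    s = summarize(draws)
    assert s.B_median[0, 0] == 2.5 and s.B_lower[0, 0] == s.B_upper[0, 0] == 2.5
    assert s.B_lower[0, 1] < 0 < s.B_upper[0, 1]
    assert not s.B_excludes_zero[0, 1]
    assert s.B_excludes_zero[0, 0]


def test_summarize_empty_chain():
    from lnireg.sampler import PosteriorDraws

    draws = PosteriorDraws(
        B=np.empty((0, 1, 1)), Psi=np.empty((0, 1, 1)), nu=None,
        family=LOG_NORMAL, response_names=["y"], covariate_names=["i"],
    )
    with pytest.raises(ValueError, match="empty"):
        summarize(draws)


# ------------------------------------------------------------------ full MDA


def test_run_mda_reproducible_and_observed_untouched(missing_data):
    data, _, _ = missing_data
    a = run_mda(data, ModelSpec(LOG_SLASH), iterations=200, burn_in=20, seed=5,
                check_invariants=True)
    b = run_mda(data, ModelSpec(LOG_SLASH), iterations=200, burn_in=20, seed=5)
    assert np.array_equal(a.B, b.B)
    assert np.array_equal(a.Psi, b.Psi)
    assert np.array_equal(a.nu, b.nu)


def test_run_mda_psi_draws_stay_spd(missing_data):
    data, _, _ = missing_data
    draws = run_mda(data, ModelSpec(LOG_T), iterations=400, burn_in=0, seed=3)
    for Psi in draws.Psi:
        np.linalg.cholesky(Psi)  # raises if not SPD


def test_run_mda_lognormal_matches_conjugate_posterior(rng):
    """Complete data, w = 1: the log-normal sampler's stationary law is the
    matrix-normal-inverse-Wishart conjugate posterior."""
    data, _, _ = make_complete_data(rng, n=80, p=2, r=2)
    S = 4000
    draws = run_mda(data, ModelSpec(LOG_NORMAL), iterations=S, burn_in=0, seed=8)
    T = np.log(data.Y)
    n, r, p = 80, 2, 2
    Bhat = np.linalg.lstsq(data.X, T, rcond=None)[0]
    Se = (T - data.X @ Bhat).T @ (T - data.X @ Bhat)
    oracle = stats.invwishart(df=n - r, scale=Se).rvs(S, random_state=rng)
    se = oracle.std(axis=0) / np.sqrt(S)
    assert np.all(np.abs(draws.Psi.mean(axis=0) - oracle.mean(axis=0)) < 4 * se)
    b_se = draws.B.std(axis=0) / np.sqrt(S)
    assert np.all(np.abs(draws.B.mean(axis=0) - Bhat) < 4 * b_se)


def test_run_mda_monotone_data_has_no_fill_in(rng):
    """Monotone-complete input takes the non-iterative path (empty fill set)."""
    data, _, _ = make_complete_data(rng, n=30, p=3, r=2)
    Y = data.Y.copy()
    Y[:10, 0] = np.nan  # already monotone: column 0 most missing
    Y[:4, 1] = np.nan
    data2 = RegressionData(Y=Y, X=data.X)
    assert arrange_monotone(data2).fill_in_cells == frozenset()
    draws = run_mda(data2, ModelSpec(LOG_SLASH), iterations=150, burn_in=10, seed=2)
    assert len(draws) == 140


def test_run_mda_recovers_slash_parameters():
    """Moderate-n parameter recovery for the full missing-data pipeline."""
    from lnireg.synth import SimulationDesign, make_dataset, TRUE_PARAMS

    design = SimulationDesign(n=400, family="log-slash", seed=13, kn=0.0)
    data = make_dataset(design, np.random.default_rng(99))
    draws = run_mda(data, ModelSpec(LOG_SLASH), iterations=1200, burn_in=200, seed=7)
    s = draws.summarize()
    true = TRUE_PARAMS["log-slash"]
    np.testing.assert_allclose(s.B_median[:2], true.B[:2], atol=0.08)
    assert s.nu_lower < true.nu < s.nu_upper or abs(s.nu_median - true.nu) < 1.0


def test_run_mda_validates_iterations(complete_data):
    data, _, _ = complete_data
    with pytest.raises(ValueError):
        run_mda(data, ModelSpec(LOG_NORMAL), iterations=10, burn_in=10, seed=0)
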