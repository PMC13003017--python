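"""State-space trend model: density oracle, derived quantities, small fits."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from phitrend import synthetic_data as syn
from phitrend import trend_model as tm
from phitrend.growth_metrics import ValidationError, constant_SL, SLValue
from phitrend.trend_model import _TrendModel


def _tiny_data(n_years=5, methods=("otolith", "mark_recapture")):
    """Two-method, five-year toy dataset with handpicked values."""
    y = np.array([3.1, 3.0, 3.3, 2.9, 3.2, 3.05])
    return tm.StateSpaceData(
        y=y,
        year_index=np.array([0, 0, 1, 2, 3, 4]),
        family_index=np.array([0, 1, 0, 1, 0, 1]),
        method_index=np.array([0, 1, 0, 0, 1, 0]),
        x_sst=np.array([-0.5, 0.2, 0.1, -0.1, 0.4, -0.1]),
        years=np.arange(2000, 2000 + n_years),
        methods=methods,
        n_families=2,
    )


def _density_oracle(model, data, cfg, theta):
    """Recompose the joint density from scipy.stats building blocks."""
    p = model.unpack(theta)
    x0, u = p["x0"][0], p["u"][0]
    sigma_q, tau = math.exp(p["lsq"][0]), math.exp(p["ltau"][0])
    sigma_fam = math.exp(p["lsfam"][0])
    sigma_r = np.exp(p["lsr"])
    beta = p["beta"][0]
    w = sigma_q * p["z_w"]
    x = x0 + u * np.arange(1, model.T + 1) + np.cumsum(w)
    alpha_fam = sigma_fam * p["z_fam"]
    v_cell = sigma_r[model.cell_method] * p["z_v"]
    c_full = np.concatenate([[0.0], p["c"]])
    log_mu = (
        x[data.year_index]
        + c_full[data.method_index]
        + v_cell[model.obs_cell]
        + alpha_fam[data.family_index]
        + beta * data.x_sst
    )
    lp = float(np.sum(stats.gamma.logpdf(data.y, a=tau, scale=np.exp(log_mu) / tau)))
    lp += stats.norm.logpdf(x0, 0, cfg.sd_x0) + stats.norm.logpdf(u, 0, cfg.sd_u)
    lp += stats.norm.logpdf(beta, 0, cfg.sd_beta)
    lp += float(np.sum(stats.norm.logpdf(p["c"], 0, cfg.sd_scalar)))
    for z in (p["z_w"], p["z_v"], p["z_fam"]):
        lp += float(np.sum(stats.norm.logpdf(z)))
    for s in (sigma_q, sigma_fam, *sigma_r):
        lp += stats.halfnorm.logpdf(s) + math.log(s)  # + log-Jacobian of exp
    lp += stats.gamma.logpdf(tau, a=cfg.tau_prior_shape, scale=1 / cfg.tau_prior_rate)
    lp += p["ltau"][0]  # Jacobian of the log parameterisation
    return lp


class TestLogDensity:
    def test_matches_scipy_composition(self):
        """The joint density equals a term-by-term scipy.stats recomposition."""
        data = _tiny_data()
        cfg = tm.StateSpaceConfig.test_scale()
        model = _TrendModel(data, cfg)
        rng = np.random.default_rng(0)
        for _ in range(5):
            theta = 0.5 * rng.standard_normal(model.ndim)
            lp, _ = model.logp_and_grad(theta)
            assert lp == pytest.approx(_density_oracle(model, data, cfg, theta), rel=1e-10)

    def test_single_observation_gamma_oracle(self):
        """With all effects zero, the likelihood is one closed-form gamma term."""
        data = tm.StateSpaceData(
            y=np.array([3.0]),
            year_index=np.array([0]),
            family_index=np.array([0]),
            method_index=np.array([0]),
            x_sst=np.array([0.0]),
            years=np.array([2000]),
            methods=("otolith",),
            n_families=1,
        )
        cfg = tm.StateSpaceConfig.test_scale()
        model = _TrendModel(data, cfg)
        theta = np.zeros(model.ndim)
        tau = math.exp(0.0)  # ltau = 0
        mu = math.exp(0.0)   # all effects zero
        lp, _ = model.logp_and_grad(theta)
        gamma_term = stats.gamma.logpdf(3.0, a=tau, scale=mu / tau)
        # residual prior terms at theta = 0
        prior = (
            stats.norm.logpdf(0, 0, cfg.sd_x0) + stats.norm.logpdf(0, 0, cfg.sd_u)
            + stats.norm.logpdf(0, 0, cfg.sd_beta)
            + 2 * float(np.sum(stats.norm.logpdf(0)))  # z_w=z_v for 1 year, 1 cell
            + 3 * (stats.halfnorm.logpdf(1.0) + 0.0)   # sigma_q, sigma_r, sigma_fam at 1
            + float(np.sum(stats.norm.logpdf(np.zeros(1))))  # z_fam
            + stats.gamma.logpdf(tau, a=0.01, scale=100.0)
        )
        assert lp == pytest.approx(gamma_term + prior, rel=1e-10)

    def test_purity(self):
        data = _tiny_data()
        model = _TrendModel(data, tm.StateSpaceConfig.test_scale())
        theta = 0.3 * np.random.default_rng(1).standard_normal(model.ndim)
        assert model.logp_and_grad(theta)[0] == model.logp_and_grad(theta.copy())[0]

    def test_out_of_support_returns_neg_inf(self):
        data = _tiny_data()
        model = _TrendModel(data, tm.StateSpaceConfig.test_scale())
        theta = np.zeros(model.ndim)
        theta[model.idx["ltau"]] = 1e4  # absurd shape
        lp, g = model.logp_and_grad(theta)
        assert lp == -np.inf and np.all(np.isfinite(g) | (g == 0))
        theta2 = np.full(model.ndim, np.nan)
        assert model.logp_and_grad(theta2)[0] == -np.inf

    def test_gradient_matches_finite_differences(self):
        data = _tiny_data()
        model = _TrendModel(data, tm.StateSpaceConfig.test_scale())
        rng = np.random.default_rng(2)
        theta = 0.3 * rng.standard_normal(model.ndim)
        _, g = model.logp_and_grad(theta)
        eps = 1e-6
        for i in range(model.ndim):
            a, b = theta.copy(), theta.copy()
            a[i] += eps
            b[i] -= eps
            fd = (model.logp_and_grad(a)[0] - model.logp_and_grad(b)[0]) / (2 * eps)
            assert g[i] == pytest.approx(fd, rel=1e-4, abs=1e-6)

    def test_public_wrapper_validates_length(self):
        data = _tiny_data()
        with pytest.raises(ValidationError):
            tm.log_density(data, np.zeros(3))


class TestDataValidation:
    def test_rejects_nonpositive_y(self):
        with pytest.raises(ValidationError):
            tm.StateSpaceData(
                y=np.array([3.0, -0.1]),
                year_index=np.array([0, 0]),
                family_index=np.array([0, 0]),
                method_index=np.array([0, 0]),
                x_sst=np.zeros(2),
                years=np.array([2000]),
                methods=("otolith",),
                n_families=1,
            )

    def test_gap_years_allowed(self):
        data = tm.StateSpaceData(
            y=np.array([3.0, 3.1]),
            year_index=np.array([0, 9]),  # eight empty years between
            family_index=np.zeros(2, dtype=int),
            method_index=np.zeros(2, dtype=int),
            x_sst=np.zeros(2),
            years=np.arange(2000, 2010),
            methods=("otolith",),
            n_families=1,
        )
        assert data.n_years == 10

    def test_from_table_roundtrip(self, small_trend_dataset):
        _, table, _ = small_trend_dataset
        data = tm.StateSpaceData.from_table(table, year_span=(1990, 2010))
        assert data.n_obs == len(table)
        assert data.methods[0] == "otolith"
        assert data.x_sst.mean() == pytest.approx(0.0, abs=1e-9)


def _degenerate_posterior(x_by_year, years, n=40):
    """A TrendPosterior whose every draw equals the given latent path."""
    x = np.tile(np.asarray(x_by_year, dtype=float), (2, n, 1))
    zeros = np.zeros((2, n))
    return tm.TrendPosterior(
        x=x, u=zeros, sigma_q=zeros + 0.01, sigma_r=np.zeros((2, n, 1)) + 0.01,
        scalars=np.zeros((2, n, 0)), tau=zeros + 100.0, beta=None, x0=zeros,
        years=np.asarray(years), methods=("otolith",), scalar_methods=(),
        converged=True, convergence=pd.DataFrame(),
    )


class TestDerivedQuantities:
    def test_percent_change_degenerate(self):
        post = _degenerate_posterior([math.log(3.3), math.log(3.0)], [1908, 2021])
        out = post.percent_change(1908, 2021)
        assert out["median"] == pytest.approx(100 * (1 - 3.0 / 3.3), abs=1e-9)
        assert out["q05"] == pytest.approx(out["median"])

    def test_percent_change_zero(self):
        post = _degenerate_posterior([1.0, 1.0], [2000, 2001])
        assert post.percent_change(2000, 2001)["median"] == pytest.approx(0.0)

    def test_year_outside_span_rejected(self):
        post = _degenerate_posterior([1.0, 1.0], [2000, 2001])
        with pytest.raises(ValidationError):
            post.percent_change(1999, 2001)

    def test_equivalent_changes_match_printed_pair(self):
        """A response-scale drop of 0.2588 is a 44.9% K / 22.8% L_inf decline."""
        phi_a = 3.3
        phi_b = phi_a - 0.2588
        post = _degenerate_posterior([math.log(phi_a), math.log(phi_b)], [1908, 2021])
        out = post.equivalent_K_Linf_change(1908, 2021)
        assert out["K"]["median"] == pytest.approx(44.9, abs=0.05)
        assert out["L_inf"]["median"] == pytest.approx(22.8, abs=0.05)

    def test_equivalent_changes_zero(self):
        post = _degenerate_posterior([1.2, 1.2], [2000, 2001])
        out = post.equivalent_K_Linf_change(2000, 2001)
        assert out["K"]["median"] == pytest.approx(0.0, abs=1e-9)
        assert out["L_inf"]["median"] == pytest.approx(0.0, abs=1e-9)

    def test_K_Linf_algebraic_identity_per_draw(self):
        """(1 - K decline)^(1/(m b)) equals 1 - L_inf decline, draw by draw."""
        rng = np.random.default_rng(6)
        x = np.stack([np.full((50,), 1.2), 1.2 + 0.1 * rng.standard_normal(50)], axis=-1)
        post = _degenerate_posterior([0, 0], [2000, 2001])
        post.x = x[None, ...]  # (1 chain, 50 draws, 2 years)
        dphi = np.exp(post.x[..., 1]) - np.exp(post.x[..., 0])
        k_ratio = 10.0**dphi
        l_ratio = 10.0 ** (-dphi / constant_SL().value)
        np.testing.assert_allclose(k_ratio ** (1 / (0.761 * 3.03)), l_ratio, rtol=1e-9)

    def test_interval_quantile_equivariance(self):
        """Interval endpoints equal the monotone transform of the dx quantiles."""
        rng = np.random.default_rng(7)
        n = 4000
        xa = 1.19 + 0.02 * rng.standard_normal((2, n))
        xb = 1.10 + 0.02 * rng.standard_normal((2, n))
        post = _degenerate_posterior([0, 0], [2000, 2001])
        post.x = np.stack([xa, xb], axis=-1)
        out = post.percent_change(2000, 2001)
        dx = (xb - xa).ravel()
        # the transform 100(1-exp(.)) is decreasing: quantiles swap ends
        oracle_med = 100 * (1 - np.exp(np.percentile(dx, 50)))
        oracle_q05 = 100 * (1 - np.exp(np.percentile(dx, 95)))
        oracle_q95 = 100 * (1 - np.exp(np.percentile(dx, 5)))
        assert out["median"] == pytest.approx(oracle_med, abs=1e-6)
        assert out["q05"] == pytest.approx(oracle_q05, abs=1e-6)
        assert out["q95"] == pytest.approx(oracle_q95, abs=1e-6)

    def test_trend_summary_intervals_nested(self, small_trend_dataset):
        data, _, _ = small_trend_dataset
        post = tm.fit(data, tm.StateSpaceConfig(chains=2, iterations=300, warmup=150, seed=1))
        summ = post.trend_summary()
        assert (summ["q05"] <= summ["q25"]).all()
        assert (summ["q25"] <= summ["median"]).all()
        assert (summ["median"] <= summ["q75"]).all()
        assert (summ["q75"] <= summ["q95"]).all()


class TestFit:
    def test_deterministic_under_seed(self, small_trend_dataset):
        data, _, _ = small_trend_dataset
        cfg = tm.StateSpaceConfig(chains=2, iterations=240, warmup=120, seed=5)
        a = tm.fit(data, cfg)
        b = tm.fit(data, cfg)
        np.testing.assert_array_equal(a.x, b.x)
        np.testing.assert_array_equal(a.u, b.u)
        pd.testing.assert_frame_equal(a.convergence, b.convergence)

    def test_flat_state_recovery(self):
        """No drift and near-zero process noise yield a near-constant trend."""
        design = syn.SimulationDesign(
            n_obs=500, n_species=40, n_families=5, year_start=1980, year_end=2009
        )
        data, _, _ = syn.simulate_trend_dataset(
            design,
            truth={"u": 0.0, "sigma_q": 1e-5,
                   "sigma_r": {m: 0.003 for m in design.method_mix},
                   "scalars": {}, "beta": 0.0, "sigma_fam": 0.0},
            seed=13,
        )
        post = tm.fit(data, tm.StateSpaceConfig.test_scale(seed=13))
        med = post.trend_summary()["median"].to_numpy()
        assert med.max() / med.min() - 1 < 0.02

    def test_config_validation(self):
        with pytest.raises(ValidationError):
            tm.StateSpaceConfig(iterations=100, warmup=100)
        with pytest.raises(ValidationError):
            tm.StateSpaceConfig(chains=1)
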