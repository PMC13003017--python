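"""Bayesian state-space model of annual growth performance.

Observed growth-performance values y_{i,t} (strictly positive) follow a
gamma distribution with shape tau and rate lambda_{i,t} = tau / mu_{i,t}
(so E[y] = mu and Var[y] = mu^2 / tau), with log link

    log(mu_{i,t}) = alpha_{method(i), t} + alpha_fam(i) + beta * X_i

The method-specific annual effect decomposes into a shared latent state, a
constant per-method scalar offset relative to the otolith baseline, and a
per-method annual observation deviation:

    alpha_{m,t} = x_t + c_m + v_{m,t},   c_otolith = 0
    v_{m,t} ~ Normal(0, sigma_{r,m})

The latent population state is a random walk with drift:

    x_t = x_{t-1} + u + w_t,   w_t ~ Normal(0, sigma_q),
    x_1 = x_0 + u + w_1

Priors: tau ~ Gamma(0.01, 0.01); beta ~ Normal(0, 2); x_0, u, and the method
scalars ~ Normal(0, 5); sigma_{r,m} ~ half-normal(0, 1); sigma_q ~
half-normal(0, 1); family effects hierarchical Normal(0, sigma_fam) with
sigma_fam ~ half-normal(0, 1) (the last two scales mirror the sigma_r
prior; see docs/methods.md).

Production MCMC settings are four chains of 6000 iterations with 3000
warmup; convergence is assessed at Rhat < 1.01 and ESS > 1500.  Inference
here is adaptive HMC on the non-centred parameterisation with analytic
gradients (see :mod:`phitrend.mcmc`).

The reported trend is exp(x_t): the response-scale mean at the reference
cell (otolith method, family effect zero, temperature covariate at its
centring value).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import digamma, gammaln

from . import mcmc
from .growth_metrics import AGING_METHODS, SLValue, ValidationError, constant_SL

REFERENCE_METHOD = "otolith"


# ---------------------------------------------------------------------------
# Data container
# ---------------------------------------------------------------------------


@dataclass
class StateSpaceData:
    """Validated inputs for the trend model.

    y must be strictly positive; year_index maps each observation to
    0..n_years-1 over the modelled span (gap years are allowed — the latent
    walk bridges them); method_index maps into ``methods`` with the otolith
    baseline first when present; x_sst is the (optionally centred)
    temperature covariate.
    """

    y: np.ndarray
    year_index: np.ndarray
    family_index: np.ndarray
    method_index: np.ndarray
    x_sst: np.ndarray
    years: np.ndarray
    methods: tuple[str, ...]
    n_families: int

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        self.year_index = np.asarray(self.year_index, dtype=int)
        self.family_index = np.asarray(self.family_index, dtype=int)
        self.method_index = np.asarray(self.method_index, dtype=int)
        self.x_sst = np.asarray(self.x_sst, dtype=float)
        n = self.y.size
        if not np.all(self.y > 0):
            raise ValidationError("growth performance observations must be strictly positive")
        for name, arr in (("year_index", self.year_index),
                          ("family_index", self.family_index),
                          ("method_index", self.method_index),
                          ("x_sst", self.x_sst)):
            if arr.size != n:
                raise ValidationError(f"{name} length {arr.size} != {n}")
        if self.year_index.min() < 0 or self.year_index.max() >= len(self.years):
            raise ValidationError("year_index out of range")
        if self.method_index.min() < 0 or self.method_index.max() >= len(self.methods):
            raise ValidationError("method_index out of range")
        if self.family_index.min() < 0 or self.family_index.max() >= self.n_families:
            raise ValidationError("family_index out of range")

    @property
    def n_obs(self) -> int:
        return self.y.size

    @property
    def n_years(self) -> int:
        return len(self.years)

    @classmethod
    def from_table(
        cls,
        df: pd.DataFrame,
        year_span: tuple[int, int] | None = None,
        centre_sst: bool = True,
    ) -> "StateSpaceData":
        """Build from a table with columns phi, year, family, aging_method and
        (optionally) sst.  Missing sst yields a zero covariate."""
        years_obs = df["year"].to_numpy(dtype=int)
        if year_span is None:
            year_span = (int(years_obs.min()), int(years_obs.max()))
        years = np.arange(year_span[0], year_span[1] + 1)
        year_index = years_obs - year_span[0]

        methods_present = [m for m in AGING_METHODS if m in set(df["aging_method"])]
        extra = sorted(set(df["aging_method"]) - set(AGING_METHODS))
        if extra:
            raise ValidationError(f"unknown aging methods: {extra}")
        m_map = {m: i for i, m in enumerate(methods_present)}
        fam_labels = sorted(set(df["family"]))
        f_map = {f: i for i, f in enumerate(fam_labels)}

        if "sst" in df.columns:
            x = df["sst"].to_numpy(dtype=float)
            if centre_sst:
                x = x - x.mean()
        else:
            x = np.zeros(len(df))
        return cls(
            y=df["phi"].to_numpy(dtype=float),
            year_index=year_index,
            family_index=np.array([f_map[f] for f in df["family"]]),
            method_index=np.array([m_map[m] for m in df["aging_method"]]),
            x_sst=x,
            years=years,
            methods=tuple(methods_present),
            n_families=len(fam_labels),
        )


@dataclass
class StateSpaceConfig:
    """MCMC and prior settings; defaults are the full production scale."""

    chains: int = 4
    iterations: int = 6000
    warmup: int = 3000
    seed: int = 0
    include_sst: bool = True
    target_accept: float = 0.85
    max_leapfrog: int = 64
    trajectory_length: float = 1.2
    # prior scales
    sd_x0: float = 5.0
    sd_u: float = 5.0
    sd_beta: float = 2.0
    sd_scalar: float = 5.0
    tau_prior_shape: float = 0.01
    tau_prior_rate: float = 0.01

    def __post_init__(self) -> None:
        if self.warmup >= self.iterations:
            raise ValidationError("warmup must be below iterations")
        if self.chains < 2:
            raise ValidationError("at least two chains are required")

    @property
    def n_draws(self) -> int:
        return self.iterations - self.warmup

    @classmethod
    def test_scale(cls, seed: int = 0, **kw) -> "StateSpaceConfig":
        """Reduced scale for desk-size recovery runs (2 chains x 900/450)."""
        return cls(chains=2, iterations=900, warmup=450, seed=seed, **kw)


# ---------------------------------------------------------------------------
# Model: packing, log density, gradient
# ---------------------------------------------------------------------------


class _TrendModel:
    """Joint log density of the state-space model on the unconstrained scale.

    Parameter vector layout (non-centred):
      [x0, u, log sigma_q, log tau, (beta,) c_1..c_{M-1},
       log sigma_r (M), log sigma_fam, z_fam (F), z_w (T), z_v (n_cells)]
    where v deviations exist only for (method, year) cells that contain
    observations (cells without data integrate out of the likelihood).
    """

    def __init__(self, data: StateSpaceData, config: StateSpaceConfig) -> None:
        self.d = data
        self.cfg = config
        self.T = data.n_years
        self.M = len(data.methods)
        self.F = data.n_families
        self.use_beta = config.include_sst
        self.has_ref = data.methods[0] == REFERENCE_METHOD

        # observed (method, year) cells
        cell_key = data.method_index * self.T + data.year_index
        uniq, self.obs_cell = np.unique(cell_key, return_inverse=True)
        self.cell_method = uniq // self.T
        self.n_cells = uniq.size

        # scalar offsets: one per non-reference method
        self.scalar_methods = [m for m in data.methods if m != REFERENCE_METHOD]
        self.n_scalars = len(self.scalar_methods)
        self._scalar_pos = np.array(
            [(-1 if m == REFERENCE_METHOD else self.scalar_methods.index(m))
             for m in data.methods]
        )

        idx = {}
        pos = 0
        for name, size in [
            ("x0", 1), ("u", 1), ("lsq", 1), ("ltau", 1),
            ("beta", 1 if self.use_beta else 0),
            ("c", self.n_scalars),
            ("lsr", self.M),
            ("lsfam", 1), ("z_fam", self.F),
            ("z_w", self.T), ("z_v", self.n_cells),
        ]:
            idx[name] = slice(pos, pos + size)
            pos += size
        self.idx = idx
        self.ndim = pos
        self._t = np.arange(1, self.T + 1, dtype=float)
        self._sum_log_y = float(np.sum(np.log(data.y)))

        # prior normalisation constants so the density is exact, not just
        # proportional: scaled normals, standard-normal z blocks, half-normal
        # scales, and the gamma prior on tau
        cfg = config
        n_z = self.F + self.T + self.n_cells
        n_halfnormal = self.M + 2  # sigma_r per method, sigma_q, sigma_fam
        const = -(2 + self.n_scalars + (1 if self.use_beta else 0) + n_z) \
            * 0.5 * math.log(2.0 * math.pi)
        const -= math.log(cfg.sd_x0) + math.log(cfg.sd_u)
        const -= self.n_scalars * math.log(cfg.sd_scalar)
        if self.use_beta:
            const -= math.log(cfg.sd_beta)
        const += n_halfnormal * 0.5 * math.log(2.0 / math.pi)
        const += cfg.tau_prior_shape * math.log(cfg.tau_prior_rate) \
            - float(gammaln(cfg.tau_prior_shape))
        self._prior_const = const

    def unpack(self, theta: np.ndarray) -> dict[str, np.ndarray]:
        return {k: theta[s] for k, s in self.idx.items()}

    def logp_and_grad(self, theta: np.ndarray) -> tuple[float, np.ndarray]:
        d, cfg = self.d, self.cfg
        # out-of-support or absurd values: density zero, never an exception
        if not np.all(np.isfinite(theta)) or np.max(np.abs(theta)) > 50.0:
            return -np.inf, np.zeros(self.ndim)
        p = self.unpack(theta)
        x0 = p["x0"][0]
        u = p["u"][0]
        sigma_q = math.exp(p["lsq"][0])
        tau = math.exp(p["ltau"][0])
        beta = p["beta"][0] if self.use_beta else 0.0
        c = p["c"]
        sigma_r = np.exp(p["lsr"])
        sigma_fam = math.exp(p["lsfam"][0])
        z_fam, z_w, z_v = p["z_fam"], p["z_w"], p["z_v"]

        w = sigma_q * z_w
        x = x0 + u * self._t + np.cumsum(w)
        alpha_fam = sigma_fam * z_fam
        v_cell = sigma_r[self.cell_method] * z_v

        c_full = np.concatenate([[0.0], c]) if self.has_ref else c
        c_obs = np.where(self._scalar_pos[d.method_index] >= 0,
                         np.concatenate([c, [0.0]])[self._scalar_pos[d.method_index]], 0.0)

        log_mu = (
            x[d.year_index]
            + c_obs
            + v_cell[self.obs_cell]
            + alpha_fam[d.family_index]
        )
        if self.use_beta:
            log_mu = log_mu + beta * d.x_sst

        n = d.n_obs
        if np.max(np.abs(log_mu)) > 500.0:
            return -np.inf, np.zeros(self.ndim)
        inv_mu_y = d.y * np.exp(-log_mu)
        ll = (
            n * (tau * math.log(tau) - gammaln(tau))
            - tau * float(np.sum(log_mu))
            + (tau - 1.0) * self._sum_log_y
            - tau * float(np.sum(inv_mu_y))
        )

        # priors (z terms standard normal; scales via log with Jacobian)
        lp = ll + self._prior_const
        lp += -0.5 * x0**2 / cfg.sd_x0**2
        lp += -0.5 * u**2 / cfg.sd_u**2
        lp += -0.5 * float(np.sum(z_w**2)) - 0.5 * float(np.sum(z_v**2))
        lp += -0.5 * float(np.sum(z_fam**2))
        if self.use_beta:
            lp += -0.5 * beta**2 / cfg.sd_beta**2
        lp += -0.5 * float(np.sum(c**2)) / cfg.sd_scalar**2
        # half-normal(0,1) scales, log-parameterised: -s^2/2 + log s
        lp += -0.5 * sigma_q**2 + p["lsq"][0]
        lp += -0.5 * float(np.sum(sigma_r**2)) + float(np.sum(p["lsr"]))
        lp += -0.5 * sigma_fam**2 + p["lsfam"][0]
        # tau ~ Gamma(a, b) with log-Jacobian: a*log tau - b*tau
        lp += cfg.tau_prior_shape * p["ltau"][0] - cfg.tau_prior_rate * tau

        if not np.isfinite(lp):
            return -np.inf, np.zeros(self.ndim)

        # ---- gradient ----
        g = np.zeros(self.ndim)
        g_logmu = tau * (inv_mu_y - 1.0)

        g_x = np.bincount(d.year_index, weights=g_logmu, minlength=self.T)
        g[self.idx["x0"]] = float(np.sum(g_x)) - x0 / cfg.sd_x0**2
        g[self.idx["u"]] = float(np.sum(self._t * g_x)) - u / cfg.sd_u**2
        g_w = np.cumsum(g_x[::-1])[::-1]
        g[self.idx["z_w"]] = sigma_q * g_w - z_w
        g[self.idx["lsq"]] = float(np.sum(g_w * w)) + (-sigma_q**2 + 1.0)

        g_cell = np.bincount(self.obs_cell, weights=g_logmu, minlength=self.n_cells)
        g[self.idx["z_v"]] = sigma_r[self.cell_method] * g_cell - z_v
        g_lsr = np.bincount(self.cell_method, weights=g_cell * v_cell, minlength=self.M)
        g[self.idx["lsr"]] = g_lsr + (-sigma_r**2 + 1.0)

        g_fam = np.bincount(d.family_index, weights=g_logmu, minlength=self.F)
        g[self.idx["z_fam"]] = sigma_fam * g_fam - z_fam
        g[self.idx["lsfam"]] = float(np.sum(g_fam * alpha_fam)) + (-sigma_fam**2 + 1.0)

        if self.n_scalars:
            g_method = np.bincount(d.method_index, weights=g_logmu, minlength=self.M)
            g_c = np.array(
                [g_method[d.methods.index(m)] for m in self.scalar_methods]
            )
            g[self.idx["c"]] = g_c - c / cfg.sd_scalar**2

        if self.use_beta:
            g[self.idx["beta"]] = float(np.sum(g_logmu * d.x_sst)) - beta / cfg.sd_beta**2

        dll_dtau = (
            n * (math.log(tau) + 1.0 - digamma(tau))
            - float(np.sum(log_mu))
            + self._sum_log_y
            - float(np.sum(inv_mu_y))
        )
        g[self.idx["ltau"]] = tau * dll_dtau + cfg.tau_prior_shape - cfg.tau_prior_rate * tau

        return float(lp), g


def _make_recenter(model: "_TrendModel"):
    """Exact Gibbs recentering moves for the trend model.

    Each move shifts a location parameter and compensates through the
    standard-normal innovations so the latent path — and hence the entire
    likelihood — is unchanged; only Gaussian priors enter the conditional.
    Directions: drift u vs the mean innovation; x0 vs the first innovation;
    x0 vs the family effects; x0 vs all observation deviations; each method
    scalar vs its own method's observation deviations.
    """
    idx = model.idx
    cfg = model.cfg
    cells_of_method = [
        np.nonzero(model.cell_method == m)[0] + idx["z_v"].start
        for m in range(model.M)
    ]

    def recenter(theta: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        theta = theta.copy()
        sigma_q = math.exp(theta[idx["lsq"].start])
        sigma_fam = math.exp(theta[idx["lsfam"].start])
        sigma_r = np.exp(theta[idx["lsr"]])
        # drift vs mean innovation
        mcmc.gibbs_shift(theta, rng, idx["u"].start, cfg.sd_u,
                         idx["z_w"], 1.0 / sigma_q)
        # x0 vs first innovation
        mcmc.gibbs_shift(theta, rng, idx["x0"].start, cfg.sd_x0,
                         slice(idx["z_w"].start, idx["z_w"].start + 1), 1.0 / sigma_q)
        # x0 vs family effects
        if model.F > 0:
            mcmc.gibbs_shift(theta, rng, idx["x0"].start, cfg.sd_x0,
                             idx["z_fam"], 1.0 / sigma_fam)
        # x0 vs all per-cell observation deviations
        mcmc.gibbs_shift(theta, rng, idx["x0"].start, cfg.sd_x0,
                         idx["z_v"], 1.0 / sigma_r[model.cell_method])
        # each scalar vs its method's deviations
        for j, m_name in enumerate(model.scalar_methods):
            m = model.d.methods.index(m_name)
            if cells_of_method[m].size:
                mcmc.gibbs_shift(theta, rng, idx["c"].start + j, cfg.sd_scalar,
                                 cells_of_method[m], 1.0 / sigma_r[m])
        # centred-coordinate scale updates (break the sigma-z funnels)
        mcmc.gibbs_rescale(theta, rng, idx["lsq"].start, idx["z_w"])
        mcmc.gibbs_rescale(theta, rng, idx["lsfam"].start, idx["z_fam"])
        for m in range(model.M):
            if cells_of_method[m].size:
                mcmc.gibbs_rescale(theta, rng, idx["lsr"].start + m,
                                   cells_of_method[m])
        return theta

    return recenter


def log_density(data: StateSpaceData, params: np.ndarray,
                config: StateSpaceConfig | None = None) -> float:
    """Joint log density for one unconstrained parameter vector.

    Returns -inf (never raises) for out-of-support parameter values.
    """
    if config is None:
        config = StateSpaceConfig()
    model = _TrendModel(data, config)
    theta = np.asarray(params, dtype=float)
    if theta.size != model.ndim:
        raise ValidationError(f"expected {model.ndim} parameters, got {theta.size}")
    lp, _ = model.logp_and_grad(theta)
    return lp


# ---------------------------------------------------------------------------
# Posterior container and derived quantities
# ---------------------------------------------------------------------------


@dataclass
class TrendPosterior:
    """Posterior draws from the state-space model.

    Arrays are (n_chains, n_draws[, ...]); ``x`` holds the latent annual
    states over ``years``.  exp(x_t) is the response-scale trend at the
    otolith reference.
    """

    x: np.ndarray
    u: np.ndarray
    sigma_q: np.ndarray
    sigma_r: np.ndarray   # (chains, draws, M)
    scalars: np.ndarray   # (chains, draws, n_scalars)
    tau: np.ndarray
    beta: np.ndarray | None
    x0: np.ndarray
    years: np.ndarray
    methods: tuple[str, ...]
    scalar_methods: tuple[str, ...]
    converged: bool
    convergence: pd.DataFrame
    sampler_stats: list[mcmc.SamplerStats] = field(repr=False, default_factory=list)

    def _year_pos(self, year: int) -> int:
        hits = np.nonzero(self.years == year)[0]
        if not hits.size:
            raise ValidationError(
                f"year {year} outside modelled span {self.years.min()}-{self.years.max()}"
            )
        return int(hits[0])

    def scalar(self, method: str) -> np.ndarray:
        """Posterior draws of one aging-method scalar offset."""
        return self.scalars[..., self.scalar_methods.index(method)]

    def percent_change(self, year_a: int, year_b: int) -> dict[str, float]:
        """Percent decline of the response-scale trend from year_a to year_b.

        Per draw: 100 * (1 - exp(x_b - x_a)); summarised by the median and
        the 5th/95th percentiles (a 90% credible interval).  Positive values
        are declines.
        """
        ia, ib = self._year_pos(year_a), self._year_pos(year_b)
        dx = (self.x[..., ib] - self.x[..., ia]).ravel()
        decline = 100.0 * (1.0 - np.exp(dx))
        q5, q50, q95 = np.percentile(decline, [5, 50, 95])
        return {"median": float(q50), "q05": float(q5), "q95": float(q95)}

    def equivalent_K_Linf_change(
        self, year_a: int, year_b: int, sl: SLValue | None = None
    ) -> dict[str, dict[str, float]]:
        """K-equivalent and L_inf-equivalent percent declines between two years.

        Per draw the response-scale change delta_phi = mu_b - mu_a feeds the
        ratio identities: K ratio 10^delta_phi (L_inf held), L_inf ratio
        10^(-delta_phi / S_L) (K held).  Reported as percent declines.
        """
        if sl is None:
            sl = constant_SL()
        if sl.value == 0:
            raise ValidationError("S_L must be nonzero")
        ia, ib = self._year_pos(year_a), self._year_pos(year_b)
        dphi = (np.exp(self.x[..., ib]) - np.exp(self.x[..., ia])).ravel()
        k_decline = 100.0 * (1.0 - 10.0**dphi)
        linf_decline = 100.0 * (1.0 - 10.0 ** (-dphi / sl.value))
        out = {}
        for name, arr in (("K", k_decline), ("L_inf", linf_decline)):
            q5, q50, q95 = np.percentile(arr, [5, 50, 95])
            out[name] = {"median": float(q50), "q05": float(q5), "q95": float(q95)}
        return out

    def trend_summary(self) -> pd.DataFrame:
        """Per-year median and 50%/90% credible intervals of exp(x_t)."""
        resp = np.exp(self.x.reshape(-1, self.x.shape[-1]))
        q = np.percentile(resp, [5, 25, 50, 75, 95], axis=0)
        return pd.DataFrame(
            {"year": self.years, "q05": q[0], "q25": q[1],
             "median": q[2], "q75": q[3], "q95": q[4]}
        )

    def convergence_report(self) -> pd.DataFrame:
        return self.convergence


def _monitored(model: _TrendModel, draws: np.ndarray) -> dict[str, np.ndarray]:
    """Scalar chains monitored for convergence (constrained scale)."""
    idx = model.idx
    out = {
        "x0": draws[..., idx["x0"].start],
        "u": draws[..., idx["u"].start],
        "sigma_q": np.exp(draws[..., idx["lsq"].start]),
        "tau": np.exp(draws[..., idx["ltau"].start]),
    }
    if model.use_beta:
        out["beta"] = draws[..., idx["beta"].start]
    for j, m in enumerate(model.scalar_methods):
        out[f"c_{m}"] = draws[..., idx["c"].start + j]
    for j, m in enumerate(model.d.methods):
        out[f"sigma_r_{m}"] = np.exp(draws[..., idx["lsr"].start + j])
    return out


def fit(data: StateSpaceData, config: StateSpaceConfig | None = None) -> TrendPosterior:
    """Fit the state-space model by adaptive HMC.

    Reproducible under a fixed seed.  A non-converged fit (any monitored
    Rhat >= 1.01 or ESS <= 1500) is still returned, flagged through
    ``converged=False``.
    """
    if config is None:
        config = StateSpaceConfig()
    model = _TrendModel(data, config)

    def init(rng: np.random.Generator) -> np.ndarray:
        theta0 = 0.1 * rng.standard_normal(model.ndim)
        # start the walk near the data so warmup does not wander
        theta0[model.idx["x0"]] = math.log(max(float(np.median(data.y)), 1e-3))
        theta0[model.idx["u"]] = 0.0
        theta0[model.idx["lsq"]] = -3.0
        theta0[model.idx["ltau"]] = math.log(
            max(1.0 / max(float(np.var(np.log(data.y))), 1e-4), 1.0)
        )
        theta0[model.idx["lsr"]] = -2.0
        return theta0

    draws, stats = mcmc.sample(
        model.logp_and_grad,
        model.ndim,
        n_chains=config.chains,
        n_warmup=config.warmup,
        n_draws=config.n_draws,
        seed=config.seed,
        initial=init,
        target_accept=config.target_accept,
        max_leapfrog=config.max_leapfrog,
        trajectory_length=config.trajectory_length,
        recenter=_make_recenter(model),
    )

    # reconstruct the latent path per draw
    idx = model.idx
    x0 = draws[..., idx["x0"].start]
    u = draws[..., idx["u"].start]
    sigma_q = np.exp(draws[..., idx["lsq"].start])
    z_w = draws[..., idx["z_w"]]
    t = np.arange(1, model.T + 1)
    x = x0[..., None] + u[..., None] * t + np.cumsum(sigma_q[..., None] * z_w, axis=-1)

    table = mcmc.convergence_table(_monitored(model, draws))
    converged = bool(table["rhat_ok"].all() and table["ess_ok"].all())

    return TrendPosterior(
        x=x,
        u=u,
        sigma_q=sigma_q,
        sigma_r=np.exp(draws[..., idx["lsr"]]),
        scalars=draws[..., idx["c"]],
        tau=np.exp(draws[..., idx["ltau"].start]),
        beta=draws[..., idx["beta"].start] if model.use_beta else None,
        x0=x0,
        years=data.years,
        methods=data.methods,
        scalar_methods=tuple(model.scalar_methods),
        converged=converged,
        convergence=table,
        sampler_stats=stats,
    )
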