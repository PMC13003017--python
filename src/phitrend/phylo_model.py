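"""Phylogenetic gamma GLMM for management x temperature effects.

Growth performance y_i is gamma-distributed with shape tau and rate
tau / mu_i, with log link

    log(mu_i) = beta_0 + beta_fish * x_fish + beta_sst * x_sst
                + beta_int * x_fish * x_sst
                + alpha_species + alpha_method + alpha_year + b_phylo

Management is treatment-coded with "managed" as the reference, so the
managed temperature slope is beta_sst and the unmanaged/unfished slopes add
the corresponding interaction contrast.  Species, aging method, and year
enter as exchangeable random intercepts; b_phylo is a species-level random
effect whose covariance is sigma_phylo^2 times the Brownian-motion
correlation matrix derived from a time-calibrated phylogeny (shared
root-to-MRCA path length, scaled to unit diagonal).

Priors: tau ~ Gamma(0.01, 0.01); beta_0 ~ Normal(0, 5); the management,
temperature and interaction contrasts ~ Normal(0, 2); all random-effect
scales half-normal(0, 1).  Production MCMC settings: four chains, 4000
iterations, 2000 warmup.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import digamma, gammaln

import dendropy

from . import mcmc
from .covariates import MANAGEMENT_CLASSES
from .growth_metrics import ValidationError

REFERENCE_CLASS = "managed"


# ---------------------------------------------------------------------------
# Phylogenetic correlation
# ---------------------------------------------------------------------------


@dataclass
class PhyloCorrelation:
    """Species x species Brownian-motion trait correlation matrix."""

    species: tuple[str, ...]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.species), len(self.species)):
            raise ValidationError("correlation matrix shape mismatch")
        self.matrix = m

    @classmethod
    def identity(cls, species) -> "PhyloCorrelation":
        species = tuple(species)
        return cls(species=species, matrix=np.eye(len(species)))

    def cholesky(self, jitter: float = 1e-9) -> np.ndarray:
        m = self.matrix + jitter * np.eye(len(self.species))
        try:
            return np.linalg.cholesky(m)
        except np.linalg.LinAlgError:
            # clip tiny negative eigenvalues from numerically non-PSD input
            vals, vecs = np.linalg.eigh(self.matrix)
            vals = np.clip(vals, 1e-9, None)
            return np.linalg.cholesky(
                (vecs * vals) @ vecs.T + jitter * np.eye(len(self.species))
            )


def _norm_label(label: str) -> str:
    return label.replace("_", " ").strip()


def tree_to_correlation(
    tree: dendropy.Tree, species: list[str] | tuple[str, ...]
) -> PhyloCorrelation:
    """Brownian-motion correlation from shared branch lengths of a rooted tree.

    Entry (i, j) is the root-to-MRCA shared path length; an ultrametric tree
    yields an exact unit diagonal after dividing by the root-to-tip depth,
    and non-ultrametric trees are normalised per pair by the geometric mean
    of the two tip depths.
    """
    species = list(species)
    # newick readers conventionally map underscores to spaces in labels
    taxa = {_norm_label(t.label): t for t in tree.taxon_namespace}
    missing = [s for s in species if _norm_label(s) not in taxa]
    if missing:
        raise ValidationError(f"species missing from tree: {missing}")

    depth = {}
    for leaf in tree.leaf_node_iter():
        depth[_norm_label(leaf.taxon.label)] = leaf.distance_from_root()

    keys = [_norm_label(s) for s in species]
    pdm = tree.phylogenetic_distance_matrix()
    n = len(species)
    corr = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            dist = pdm.patristic_distance(taxa[keys[i]], taxa[keys[j]])
            shared = 0.5 * (depth[keys[i]] + depth[keys[j]] - dist)
            denom = math.sqrt(depth[keys[i]] * depth[keys[j]])
            corr[i, j] = corr[j, i] = shared / denom if denom > 0 else 0.0
    return PhyloCorrelation(species=tuple(species), matrix=corr)


def graft_missing_species(
    tree: dendropy.Tree, species_to_genus: dict[str, str]
) -> dendropy.Tree:
    """Synthetic stand-in utility: graft species absent from the tree onto the
    MRCA of their congeners at zero-length branches.

    This is a crude placement — it encodes taxonomy, not inferred
    divergence times — and is intended only to make a user-supplied tree
    cover the observation table.  Species whose genus has no tip in the tree
    are attached at the root.
    """
    tree = tree.clone(depth=1)
    # treat the chronogram as rooted; otherwise bipartition encoding for the
    # MRCA lookup collapses the basal split
    tree.is_rooted = True
    present = {_norm_label(t.label) for t in tree.taxon_namespace}
    for sp, genus in species_to_genus.items():
        if _norm_label(sp) in present:
            continue
        congeners = [
            lf for lf in tree.leaf_node_iter()
            if _norm_label(lf.taxon.label).split(" ")[0] == genus
            and _norm_label(lf.taxon.label) != _norm_label(sp)
        ]
        if len(congeners) >= 2:
            node = tree.mrca(taxa=[lf.taxon for lf in congeners])
        elif len(congeners) == 1:
            node = congeners[0].parent_node
        else:
            node = tree.seed_node
        taxon = tree.taxon_namespace.new_taxon(label=sp)
        node.new_child(taxon=taxon, edge_length=0.0)
        present.add(_norm_label(sp))
    return tree


# ---------------------------------------------------------------------------
# PGLMM
# ---------------------------------------------------------------------------


@dataclass
class PGLMMConfig:
    """MCMC and prior settings; defaults are the full production scale."""

    chains: int = 4
    iterations: int = 4000
    warmup: int = 2000
    seed: int = 0
    centre_sst: bool = True
    target_accept: float = 0.85
    max_leapfrog: int = 64
    trajectory_length: float = 1.2
    sd_intercept: float = 5.0
    sd_beta: float = 2.0
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
    def test_scale(cls, seed: int = 0, **kw) -> "PGLMMConfig":
        return cls(chains=2, iterations=700, warmup=350, seed=seed, **kw)


@dataclass
class PGLMMPosterior:
    """Posterior draws from the phylogenetic gamma GLMM; arrays (chains, draws, ...)."""

    beta0: np.ndarray
    beta_fish: np.ndarray      # contrasts for non-reference classes
    beta_sst: np.ndarray
    beta_int: np.ndarray       # interaction contrasts, aligned with classes
    tau: np.ndarray
    sigma_species: np.ndarray
    sigma_method: np.ndarray
    sigma_year: np.ndarray
    sigma_phylo: np.ndarray
    classes: tuple[str, ...]   # non-reference classes in contrast order
    converged: bool
    convergence: pd.DataFrame
    sampler_stats: list = field(repr=False, default_factory=list)

    def slope_by_management(self) -> dict[str, dict[str, float]]:
        """Per-class temperature slope with medians and 50%/90% intervals.

        The reference-class slope is beta_sst itself; other classes add
        their interaction contrast.
        """
        out = {}
        for cls_name in (REFERENCE_CLASS, *self.classes):
            if cls_name == REFERENCE_CLASS:
                draws = self.beta_sst.ravel()
            else:
                j = self.classes.index(cls_name)
                draws = (self.beta_sst + self.beta_int[..., j]).ravel()
            q5, q25, q50, q75, q95 = np.percentile(draws, [5, 25, 50, 75, 95])
            out[cls_name] = {
                "median": float(q50), "q05": float(q5), "q25": float(q25),
                "q75": float(q75), "q95": float(q95),
            }
        return out

    def slope_draws(self, cls_name: str) -> np.ndarray:
        if cls_name == REFERENCE_CLASS:
            return self.beta_sst.ravel()
        if cls_name not in self.classes:
            raise ValidationError(f"unknown management class {cls_name!r}")
        return (self.beta_sst + self.beta_int[..., self.classes.index(cls_name)]).ravel()

    def convergence_report(self) -> pd.DataFrame:
        return self.convergence


class _PGLMMModel:
    """Unconstrained joint density; layout:
    [b0, bfish (C-1), bsst, bint (C-1), ltau,
     lssp, z_sp (S), lsmeth, z_meth (M), lsyr, z_yr (Y), lsphy, z_phy (S)]
    """

    def __init__(
        self,
        y: np.ndarray,
        class_index: np.ndarray,
        x_sst: np.ndarray,
        species_index: np.ndarray,
        method_index: np.ndarray,
        year_index: np.ndarray,
        chol: np.ndarray,
        n_classes: int,
        cfg: PGLMMConfig,
    ) -> None:
        self.y = y
        self.ci = class_index
        self.x = x_sst
        self.si = species_index
        self.mi = method_index
        self.yi = year_index
        self.L = chol
        self.C = n_classes
        self.S = chol.shape[0]
        self.M = int(method_index.max()) + 1
        self.Y = int(year_index.max()) + 1
        self.cfg = cfg

        idx = {}
        pos = 0
        for name, size in [
            ("b0", 1), ("bfish", self.C - 1), ("bsst", 1), ("bint", self.C - 1),
            ("ltau", 1),
            ("lssp", 1), ("z_sp", self.S),
            ("lsmeth", 1), ("z_meth", self.M),
            ("lsyr", 1), ("z_yr", self.Y),
            ("lsphy", 1), ("z_phy", self.S),
        ]:
            idx[name] = slice(pos, pos + size)
            pos += size
        self.idx = idx
        self.ndim = pos
        self._sum_log_y = float(np.sum(np.log(y)))

        n_z = 2 * self.S + self.M + self.Y
        n_beta = 2 * (self.C - 1) + 1
        const = -(1 + n_beta + n_z) * 0.5 * math.log(2.0 * math.pi)
        const -= math.log(cfg.sd_intercept) + n_beta * math.log(cfg.sd_beta)
        const += 4 * 0.5 * math.log(2.0 / math.pi)  # four half-normal scales
        const += cfg.tau_prior_shape * math.log(cfg.tau_prior_rate) \
            - float(gammaln(cfg.tau_prior_shape))
        self._prior_const = const
        # indicator columns for non-reference classes
        self._class_onehot = [
            (self.ci == (j + 1)).astype(float) for j in range(self.C - 1)
        ]

    def logp_and_grad(self, theta: np.ndarray) -> tuple[float, np.ndarray]:
        cfg = self.cfg
        if not np.all(np.isfinite(theta)) or np.max(np.abs(theta)) > 50.0:
            return -np.inf, np.zeros(self.ndim)
        p = {k: theta[s] for k, s in self.idx.items()}
        b0 = p["b0"][0]
        bfish, bsst, bint = p["bfish"], p["bsst"][0], p["bint"]
        tau = math.exp(p["ltau"][0])
        s_sp = math.exp(p["lssp"][0])
        s_meth = math.exp(p["lsmeth"][0])
        s_yr = math.exp(p["lsyr"][0])
        s_phy = math.exp(p["lsphy"][0])
        z_sp, z_meth, z_yr, z_phy = p["z_sp"], p["z_meth"], p["z_yr"], p["z_phy"]

        if not np.isfinite(tau) or tau <= 0:
            return -np.inf, np.zeros(self.ndim)

        a_sp = s_sp * z_sp
        a_meth = s_meth * z_meth
        a_yr = s_yr * z_yr
        Lz = self.L @ z_phy
        b_phy = s_phy * Lz

        bfish_full = np.concatenate([[0.0], bfish])
        bint_full = np.concatenate([[0.0], bint])
        log_mu = (
            b0
            + bfish_full[self.ci]
            + (bsst + bint_full[self.ci]) * self.x
            + a_sp[self.si]
            + a_meth[self.mi]
            + a_yr[self.yi]
            + b_phy[self.si]
        )
        n = self.y.size
        if np.max(np.abs(log_mu)) > 500.0:
            return -np.inf, np.zeros(self.ndim)
        inv_mu_y = self.y * np.exp(-log_mu)
        ll = (
            n * (tau * math.log(tau) - gammaln(tau))
            - tau * float(np.sum(log_mu))
            + (tau - 1.0) * self._sum_log_y
            - tau * float(np.sum(inv_mu_y))
        )

        lp = ll + self._prior_const
        lp += -0.5 * b0**2 / cfg.sd_intercept**2
        lp += -0.5 * (float(np.sum(bfish**2)) + bsst**2 + float(np.sum(bint**2))) / cfg.sd_beta**2
        for z in (z_sp, z_meth, z_yr, z_phy):
            lp += -0.5 * float(np.sum(z**2))
        for s, ls in ((s_sp, "lssp"), (s_meth, "lsmeth"), (s_yr, "lsyr"), (s_phy, "lsphy")):
            lp += -0.5 * s**2 + p[ls][0]
        lp += cfg.tau_prior_shape * p["ltau"][0] - cfg.tau_prior_rate * tau
        if not np.isfinite(lp):
            return -np.inf, np.zeros(self.ndim)

        g = np.zeros(self.ndim)
        g_logmu = tau * (inv_mu_y - 1.0)

        g[self.idx["b0"]] = float(np.sum(g_logmu)) - b0 / cfg.sd_intercept**2
        for j in range(self.C - 1):
            ind = self._class_onehot[j]
            g[self.idx["bfish"].start + j] = float(np.sum(g_logmu * ind)) - bfish[j] / cfg.sd_beta**2
            g[self.idx["bint"].start + j] = (
                float(np.sum(g_logmu * ind * self.x)) - bint[j] / cfg.sd_beta**2
            )
        g[self.idx["bsst"]] = float(np.sum(g_logmu * self.x)) - bsst / cfg.sd_beta**2

        g_sp = np.bincount(self.si, weights=g_logmu, minlength=self.S)
        g_meth = np.bincount(self.mi, weights=g_logmu, minlength=self.M)
        g_yr = np.bincount(self.yi, weights=g_logmu, minlength=self.Y)

        g[self.idx["z_sp"]] = s_sp * g_sp - z_sp
        g[self.idx["lssp"]] = float(np.sum(g_sp * a_sp)) + (-s_sp**2 + 1.0)
        g[self.idx["z_meth"]] = s_meth * g_meth - z_meth
        g[self.idx["lsmeth"]] = float(np.sum(g_meth * a_meth)) + (-s_meth**2 + 1.0)
        g[self.idx["z_yr"]] = s_yr * g_yr - z_yr
        g[self.idx["lsyr"]] = float(np.sum(g_yr * a_yr)) + (-s_yr**2 + 1.0)
        g[self.idx["z_phy"]] = s_phy * (self.L.T @ g_sp) - z_phy
        g[self.idx["lsphy"]] = float(np.sum(g_sp * b_phy)) + (-s_phy**2 + 1.0)

        dll_dtau = (
            n * (math.log(tau) + 1.0 - digamma(tau))
            - float(np.sum(log_mu))
            + self._sum_log_y
            - float(np.sum(inv_mu_y))
        )
        g[self.idx["ltau"]] = tau * dll_dtau + cfg.tau_prior_shape - cfg.tau_prior_rate * tau
        return float(lp), g


def _make_recenter(model: "_PGLMMModel"):
    """Exact Gibbs recentering for the PGLMM.

    Shifts the global intercept against each random-intercept block (and the
    phylogenetic effect, through L^-1 applied to the unit shift) without
    changing any fitted mean, then redraws each half-normal scale in centred
    coordinates.  Same rationale as for the trend model: these directions
    are likelihood-invariant, so their conditionals are exact.
    """
    idx = model.idx
    cfg = model.cfg
    # unit shift of b_phylo corresponds to a z shift along L^-1 1
    w_phylo_unit = np.linalg.solve(model.L, np.ones(model.S))

    def recenter(theta: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        theta = theta.copy()
        s_sp = math.exp(theta[idx["lssp"].start])
        s_meth = math.exp(theta[idx["lsmeth"].start])
        s_yr = math.exp(theta[idx["lsyr"].start])
        s_phy = math.exp(theta[idx["lsphy"].start])
        mcmc.gibbs_shift(theta, rng, idx["b0"].start, cfg.sd_intercept,
                         idx["z_sp"], 1.0 / s_sp)
        mcmc.gibbs_shift(theta, rng, idx["b0"].start, cfg.sd_intercept,
                         idx["z_meth"], 1.0 / s_meth)
        mcmc.gibbs_shift(theta, rng, idx["b0"].start, cfg.sd_intercept,
                         idx["z_yr"], 1.0 / s_yr)
        mcmc.gibbs_shift(theta, rng, idx["b0"].start, cfg.sd_intercept,
                         idx["z_phy"], w_phylo_unit / s_phy)
        mcmc.gibbs_rescale(theta, rng, idx["lssp"].start, idx["z_sp"])
        mcmc.gibbs_rescale(theta, rng, idx["lsmeth"].start, idx["z_meth"])
        mcmc.gibbs_rescale(theta, rng, idx["lsyr"].start, idx["z_yr"])
        mcmc.gibbs_rescale(theta, rng, idx["lsphy"].start, idx["z_phy"])
        return theta

    return recenter


def fit_pglmm(
    data: pd.DataFrame,
    corr: PhyloCorrelation,
    config: PGLMMConfig | None = None,
) -> PGLMMPosterior:
    """Fit the phylogenetic gamma GLMM by adaptive HMC.

    ``data`` must have columns phi, management, sst, species, aging_method,
    year; ``corr`` must cover every species present.  Management classes are
    treatment-coded against "managed" (or the alphabetically first present
    class if managed is absent).
    """
    if config is None:
        config = PGLMMConfig()

    classes_present = [c for c in MANAGEMENT_CLASSES if c in set(data["management"])]
    if len(classes_present) < 2:
        raise ValidationError("at least two management classes are required")
    if REFERENCE_CLASS in classes_present:
        classes_present = [REFERENCE_CLASS] + [c for c in classes_present if c != REFERENCE_CLASS]
    class_map = {c: i for i, c in enumerate(classes_present)}

    species = sorted(set(data["species"]))
    missing = [s for s in species if s not in corr.species]
    if missing:
        raise ValidationError(f"species missing from correlation matrix: {missing}")
    # align (and subset) the correlation to the modelled species
    sel = [corr.species.index(s) for s in species]
    corr_sub = PhyloCorrelation(
        species=tuple(species), matrix=corr.matrix[np.ix_(sel, sel)]
    )

    sp_map = {s: i for i, s in enumerate(species)}
    methods = sorted(set(data["aging_method"]))
    m_map = {m: i for i, m in enumerate(methods)}
    years = sorted(set(data["year"]))
    y_map = {y: i for i, y in enumerate(years)}

    x = data["sst"].to_numpy(dtype=float)
    if config.centre_sst:
        x = x - x.mean()

    y = data["phi"].to_numpy(dtype=float)
    if not np.all(y > 0):
        raise ValidationError("phi observations must be strictly positive")

    model = _PGLMMModel(
        y=y,
        class_index=np.array([class_map[c] for c in data["management"]]),
        x_sst=x,
        species_index=np.array([sp_map[s] for s in data["species"]]),
        method_index=np.array([m_map[m] for m in data["aging_method"]]),
        year_index=np.array([y_map[int(t)] for t in data["year"]]),
        chol=corr_sub.cholesky(),
        n_classes=len(classes_present),
        cfg=config,
    )

    def init(rng: np.random.Generator) -> np.ndarray:
        theta0 = 0.1 * rng.standard_normal(model.ndim)
        theta0[model.idx["b0"]] = math.log(max(float(np.median(y)), 1e-3))
        theta0[model.idx["ltau"]] = math.log(
            max(1.0 / max(float(np.var(np.log(y))), 1e-4), 1.0)
        )
        for ls in ("lssp", "lsmeth", "lsyr", "lsphy"):
            theta0[model.idx[ls]] = -2.0
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

    idx = model.idx
    monitored = {
        "beta0": draws[..., idx["b0"].start],
        "beta_sst": draws[..., idx["bsst"].start],
        "tau": np.exp(draws[..., idx["ltau"].start]),
        "sigma_species": np.exp(draws[..., idx["lssp"].start]),
        "sigma_phylo": np.exp(draws[..., idx["lsphy"].start]),
    }
    for j, c in enumerate(classes_present[1:]):
        monitored[f"beta_fish_{c}"] = draws[..., idx["bfish"].start + j]
        monitored[f"beta_int_{c}"] = draws[..., idx["bint"].start + j]
    table = mcmc.convergence_table(monitored)
    converged = bool(table["rhat_ok"].all() and table["ess_ok"].all())

    return PGLMMPosterior(
        beta0=draws[..., idx["b0"].start],
        beta_fish=draws[..., idx["bfish"]],
        beta_sst=draws[..., idx["bsst"].start],
        beta_int=draws[..., idx["bint"]],
        tau=np.exp(draws[..., idx["ltau"].start]),
        sigma_species=np.exp(draws[..., idx["lssp"].start]),
        sigma_method=np.exp(draws[..., idx["lsmeth"].start]),
        sigma_year=np.exp(draws[..., idx["lsyr"].start]),
        sigma_phylo=np.exp(draws[..., idx["lsphy"].start]),
        classes=tuple(classes_present[1:]),
        converged=converged,
        convergence=table,
        sampler_stats=stats,
    )
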