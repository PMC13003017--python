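"""Adaptive Hamiltonian Monte Carlo with analytic gradients.

A compact gradient-based MCMC engine used by the state-space trend model and
the phylogenetic GLMM.  Models supply ``logp_and_grad(theta)`` returning the
joint log density on the unconstrained scale and its gradient; the sampler
provides

* leapfrog integration with a diagonal mass matrix,
* dual-averaging step-size adaptation towards a target acceptance rate,
* windowed estimation of the (diagonal) posterior metric during warmup,
* jittered trajectory lengths to break periodicity,
* divergence accounting and per-chain determinism from a seed sequence.

Both models are parameterised non-centred (latent innovations and random
effects as standard-normal z-scores, scales on the log with the Jacobian
term included), which keeps the posterior geometry well conditioned for a
diagonal metric.

Convergence diagnostics (split-chain rank-normalised Rhat and ESS) are
delegated to arviz.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from typing import Callable

import numpy as np

logger = logging.getLogger(__name__)

LogpGrad = Callable[[np.ndarray], tuple[float, np.ndarray]]

#: energy error beyond which a trajectory is counted divergent
DIVERGENCE_THRESHOLD = 1000.0


@dataclass
class SamplerStats:
    accept_rate: float
    n_divergent: int
    step_size: float
    n_leapfrog_mean: float


def _leapfrog(
    logp_and_grad: LogpGrad,
    theta: np.ndarray,
    p: np.ndarray,
    grad: np.ndarray,
    eps: float,
    n_steps: int,
    inv_mass: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, float, np.ndarray, bool]:
    theta = theta.copy()
    p = p + 0.5 * eps * grad
    for step in range(n_steps):
        theta = theta + eps * inv_mass * p
        logp, grad = logp_and_grad(theta)
        if not np.isfinite(logp):
            return theta, p, -np.inf, grad, True
        if step < n_steps - 1:
            p = p + eps * grad
    p = p + 0.5 * eps * grad
    return theta, p, logp, grad, False


class DualAveraging:
    """Nesterov dual averaging of log step size (standard HMC warmup schedule)."""

    def __init__(self, eps0: float, target: float = 0.8, gamma: float = 0.05,
                 t0: float = 10.0, kappa: float = 0.75) -> None:
        self.mu = np.log(10.0 * eps0)
        self.target = target
        self.gamma = gamma
        self.t0 = t0
        self.kappa = kappa
        self.log_eps = np.log(eps0)
        self.log_eps_bar = 0.0
        self.h_bar = 0.0
        self.t = 0

    def update(self, accept_prob: float) -> float:
        self.t += 1
        eta = 1.0 / (self.t + self.t0)
        self.h_bar = (1 - eta) * self.h_bar + eta * (self.target - accept_prob)
        self.log_eps = self.mu - np.sqrt(self.t) / self.gamma * self.h_bar
        w = self.t ** (-self.kappa)
        self.log_eps_bar = w * self.log_eps + (1 - w) * self.log_eps_bar
        return float(np.exp(self.log_eps))

    @property
    def adapted(self) -> float:
        return float(np.exp(self.log_eps_bar))


def _find_initial_step_size(
    logp_and_grad: LogpGrad, theta: np.ndarray, rng: np.random.Generator,
    inv_mass: np.ndarray,
) -> float:
    """Heuristic: scale eps until one leapfrog step has accept prob near 0.5."""
    eps = 0.1
    logp0, grad0 = logp_and_grad(theta)
    p0 = rng.standard_normal(theta.size) / np.sqrt(inv_mass)
    h0 = logp0 - 0.5 * np.sum(inv_mass * p0**2)
    _, p1, logp1, _, diverged = _leapfrog(logp_and_grad, theta, p0, grad0, eps, 1, inv_mass)
    h1 = logp1 - 0.5 * np.sum(inv_mass * p1**2) if not diverged else -np.inf
    direction = 1.0 if (h1 - h0) > np.log(0.5) else -1.0
    for _ in range(50):
        eps *= 2.0**direction
        _, p1, logp1, _, diverged = _leapfrog(logp_and_grad, theta, p0, grad0, eps, 1, inv_mass)
        h1 = logp1 - 0.5 * np.sum(inv_mass * p1**2) if not diverged else -np.inf
        if direction == 1.0 and (h1 - h0) <= np.log(0.5):
            break
        if direction == -1.0 and (h1 - h0) >= np.log(0.5):
            break
    return float(min(eps, 1.0))


def _run_chain(
    logp_and_grad: LogpGrad,
    theta0: np.ndarray,
    n_warmup: int,
    n_draws: int,
    rng: np.random.Generator,
    target_accept: float,
    max_leapfrog: int,
    trajectory_length: float,
    recenter: Callable[[np.ndarray, np.random.Generator], np.ndarray] | None = None,
) -> tuple[np.ndarray, SamplerStats]:
    ndim = theta0.size
    inv_mass = np.ones(ndim)
    theta = theta0.copy()
    logp, grad = logp_and_grad(theta)
    if not np.isfinite(logp):
        raise ValueError("initial point has non-finite log density")

    eps = _find_initial_step_size(logp_and_grad, theta, rng, inv_mass)
    da = DualAveraging(eps, target=target_accept)

    # windowed diagonal metric adaptation: an initial step-size phase, doubling
    # covariance windows, and a terminal step-size phase (Stan-like schedule)
    init_buffer = max(int(0.15 * n_warmup), 10)
    term_buffer = max(int(0.10 * n_warmup), 10)
    window_starts: list[int] = []
    w = max(int(0.25 * n_warmup) // 4, 25)
    pos = init_buffer
    while pos < n_warmup - term_buffer:
        window_starts.append(pos)
        pos += w
        w *= 2
    window_ends = window_starts[1:] + [n_warmup - term_buffer]

    welford_n = 0
    welford_mean = np.zeros(ndim)
    welford_m2 = np.zeros(ndim)

    draws = np.empty((n_draws, ndim))
    n_div = 0
    accept_sum = 0.0
    nl_sum = 0
    n_total = n_warmup + n_draws

    win_idx = 0
    for it in range(n_total):
        sampling = it >= n_warmup
        p0 = rng.standard_normal(ndim) / np.sqrt(inv_mass)
        h0 = logp - 0.5 * np.sum(inv_mass * p0**2)
        jitter = rng.uniform(0.5, 1.5)
        n_steps = int(np.clip(round(jitter * trajectory_length / eps), 1, max_leapfrog))
        theta_new, p_new, logp_new, grad_new, diverged = _leapfrog(
            logp_and_grad, theta, p0, grad, eps, n_steps, inv_mass
        )
        h1 = logp_new - 0.5 * np.sum(inv_mass * p_new**2)
        delta_h = h1 - h0
        if diverged or (not np.isfinite(delta_h)) or (-delta_h > DIVERGENCE_THRESHOLD):
            accept_prob = 0.0
            if sampling:
                n_div += 1
        else:
            accept_prob = float(min(1.0, np.exp(min(delta_h, 0.0))))
            if np.log(rng.uniform()) < delta_h:
                theta, logp, grad = theta_new, logp_new, grad_new

        if recenter is not None:
            # exact Gibbs moves along likelihood-invariant directions supplied
            # by the model (e.g. drift vs mean innovation); these kill ridge
            # degeneracies a diagonal-metric HMC mixes through only slowly
            theta = recenter(theta, rng)
            logp, grad = logp_and_grad(theta)

        if sampling:
            draws[it - n_warmup] = theta
            accept_sum += accept_prob
            nl_sum += n_steps
        else:
            eps = da.update(accept_prob)
            in_window = win_idx < len(window_starts) and it >= window_starts[win_idx]
            if in_window:
                welford_n += 1
                delta = theta - welford_mean
                welford_mean += delta / welford_n
                welford_m2 += delta * (theta - welford_mean)
                if it + 1 == window_ends[win_idx]:
                    if welford_n > 4:
                        var = welford_m2 / (welford_n - 1)
                        # regularise towards unit metric as Stan does
                        var = (welford_n / (welford_n + 5.0)) * var + \
                              (5.0 / (welford_n + 5.0)) * 1e-3
                        inv_mass = np.maximum(var, 1e-10)
                    welford_n = 0
                    welford_mean[:] = 0.0
                    welford_m2[:] = 0.0
                    win_idx += 1
                    # metric changed: re-tune the step size from scratch
                    eps = _find_initial_step_size(logp_and_grad, theta, rng, inv_mass)
                    da = DualAveraging(eps, target=target_accept)
            if it + 1 == n_warmup:
                eps = da.adapted

    stats = SamplerStats(
        accept_rate=accept_sum / max(n_draws, 1),
        n_divergent=n_div,
        step_size=float(eps),
        n_leapfrog_mean=nl_sum / max(n_draws, 1),
    )
    return draws, stats


def sample(
    logp_and_grad: LogpGrad,
    ndim: int,
    n_chains: int = 4,
    n_warmup: int = 500,
    n_draws: int = 500,
    seed: int = 0,
    initial: np.ndarray | Callable[[np.random.Generator], np.ndarray] | None = None,
    target_accept: float = 0.8,
    max_leapfrog: int = 64,
    trajectory_length: float = 1.2,
    recenter: Callable[[np.ndarray, np.random.Generator], np.ndarray] | None = None,
) -> tuple[np.ndarray, list[SamplerStats]]:
    """Run ``n_chains`` sequential HMC chains; returns draws of shape
    (n_chains, n_draws, ndim) and per-chain statistics.

    Fully deterministic for a given seed: chain RNGs are spawned from one
    ``SeedSequence`` and chains run sequentially.
    """
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.spawn(n_chains)
    all_draws = np.empty((n_chains, n_draws, ndim))
    stats = []
    for c in range(n_chains):
        rng = np.random.Generator(np.random.PCG64(child_seeds[c]))
        if initial is None:
            theta0 = 0.1 * rng.standard_normal(ndim)
        elif callable(initial):
            theta0 = np.asarray(initial(rng), dtype=float)
        else:
            theta0 = np.asarray(initial, dtype=float) + 0.01 * rng.standard_normal(ndim)
        draws, st = _run_chain(
            logp_and_grad, theta0, n_warmup, n_draws, rng,
            target_accept, max_leapfrog, trajectory_length, recenter,
        )
        if st.n_divergent > 0.05 * n_draws:
            logger.warning("chain %d: %d divergent transitions", c, st.n_divergent)
        all_draws[c] = draws
        stats.append(st)
    return all_draws, stats


def gibbs_shift(
    theta: np.ndarray,
    rng: np.random.Generator,
    a_pos: int,
    prior_sd: float,
    z_idx: np.ndarray | slice,
    w: np.ndarray | float,
) -> None:
    """Exact Gibbs update along theta_a -> theta_a + eps, z -> z - eps*w.

    Valid whenever the likelihood is invariant along the direction (the
    location parameter and a compensating shift of standard-normal z scores),
    so the full conditional of eps involves only the two quadratic priors:

        eps | rest ~ Normal(b/a, 1/a),
        a = 1/prior_sd^2 + w.w,   b = -theta_a/prior_sd^2 + z.w

    Mutates ``theta`` in place.
    """
    z = theta[z_idx]
    w_arr = np.broadcast_to(np.asarray(w, dtype=float), z.shape)
    a = 1.0 / prior_sd**2 + float(w_arr @ w_arr)
    b = -theta[a_pos] / prior_sd**2 + float(z @ w_arr)
    eps = rng.normal(b / a, math.sqrt(1.0 / a))
    theta[a_pos] += eps
    theta[z_idx] = z - eps * w_arr


def _slice_1d(logf, x0: float, rng: np.random.Generator,
              width: float = 0.7, max_steps: int = 30) -> float:
    """One stepping-out/shrinkage slice-sampling update of a 1-D log density."""
    y = logf(x0) - rng.exponential()
    left = x0 - width * rng.uniform()
    right = left + width
    for _ in range(max_steps):
        if logf(left) <= y:
            break
        left -= width
    for _ in range(max_steps):
        if logf(right) <= y:
            break
        right += width
    for _ in range(60):
        x1 = rng.uniform(left, right)
        if logf(x1) >= y:
            return x1
        if x1 < x0:
            left = x1
        else:
            right = x1
    return x0


def gibbs_rescale(
    theta: np.ndarray,
    rng: np.random.Generator,
    ls_pos: int,
    z_idx: np.ndarray | slice,
) -> None:
    """Update a half-normal(0,1) scale in centred coordinates.

    Holding the centred effects w = sigma * z fixed (so the likelihood is
    unchanged), the conditional of ls = log(sigma) is

        log p(ls | w) = (1 - K) ls - e^(2 ls)/2 - S e^(-2 ls)/2 + const

    with K = len(z) and S = sum(w^2) (a generalized-inverse-Gaussian law in
    sigma^2).  A slice-sampling step leaves this conditional invariant; z is
    then rescaled back to the non-centred parameterisation.  Mutates
    ``theta`` in place.
    """
    sigma = math.exp(theta[ls_pos])
    w = sigma * theta[z_idx]
    S = float(w @ w)
    K = w.size
    if S < 1e-300:
        return

    def logf(ls: float) -> float:
        if abs(ls) > 300.0:
            return -np.inf
        return (1.0 - K) * ls - 0.5 * math.exp(2 * ls) - 0.5 * S * math.exp(-2 * ls)

    ls_new = _slice_1d(logf, float(theta[ls_pos]), rng)
    theta[ls_pos] = ls_new
    theta[z_idx] = w / math.exp(ls_new)


# ---------------------------------------------------------------------------
# Convergence diagnostics
# ---------------------------------------------------------------------------

RHAT_THRESHOLD = 1.01
ESS_THRESHOLD = 1500.0


def rhat(chains: np.ndarray) -> float:
    """Split-chain rank-normalised Rhat for draws of shape (n_chains, n_draws)."""
    import arviz as az

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return float(np.asarray(az.rhat(az.convert_to_dataset(chains))["x"].values).item())


def ess(chains: np.ndarray) -> float:
    """Rank-normalised bulk effective sample size for (n_chains, n_draws) draws."""
    import arviz as az

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return float(np.asarray(az.ess(az.convert_to_dataset(chains))["x"].values).item())


def convergence_table(named_chains: dict[str, np.ndarray]) -> "pd.DataFrame":
    """Rhat/ESS table with pass flags at the analysis thresholds
    (Rhat < 1.01, ESS > 1500).  Single-chain input reports Rhat as NaN."""
    import pandas as pd

    rows = []
    for name, chains in named_chains.items():
        chains = np.asarray(chains)
        if chains.ndim != 2:
            raise ValueError(f"{name}: expected (n_chains, n_draws) array")
        if chains.shape[0] < 2:
            r = float("nan")
        else:
            r = rhat(chains)
        e = ess(chains)
        rows.append(
            {
                "parameter": name,
                "rhat": r,
                "ess": e,
                "rhat_ok": bool(r < RHAT_THRESHOLD) if np.isfinite(r) else False,
                "ess_ok": bool(e > ESS_THRESHOLD),
            }
        )
    return pd.DataFrame(rows)
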